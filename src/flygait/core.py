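"""Shared domain objects: legs, calibration, stance events, step patterns, body tracks.

Conventions used throughout the package:

* Image/world coordinates: origin top-left, x to the right, y down, 0-based
  pixels.  World positions are in micrometres on the same axes.
* Body frame: +x anterior (along the displacement axis), +y to the animal's
  left.  With the image y-axis pointing down this makes left-leg lateral
  coordinates positive.
* Frames are 0-based; frame ``i`` is at time ``i * 1000 / fps`` ms.
* Stance intervals are half-open ``[onset, offset)`` in milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

#: Leg labels in canonical digit order (used by the 6-bit combination code).
LEGS: Tuple[str, ...] = ("LF", "LM", "LH", "RF", "RM", "RH")

LEFT_LEGS: Tuple[str, ...] = ("LF", "LM", "LH")
RIGHT_LEGS: Tuple[str, ...] = ("RF", "RM", "RH")

#: Segment of each leg: F(ore), M(id), H(ind).
SEGMENT = {leg: leg[1] for leg in LEGS}
SIDE = {leg: leg[0] for leg in LEGS}


def other_side(side: str) -> str:
    return {"L": "R", "R": "L"}[side]


@dataclass(frozen=True)
class Calibration:
    """Acquisition-rate and spatial calibration of an image sequence."""

    fps: float
    um_per_px: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be > 0, got {self.um_per_px}")

    @property
    def frame_interval_ms(self) -> float:
        return 1000.0 / self.fps

    def to_dict(self) -> dict:
        return {"fps": self.fps, "um_per_px": self.um_per_px}

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(fps=float(d["fps"]), um_per_px=float(d["um_per_px"]))


@dataclass
class StanceEvent:
    """One ground-contact interval of one leg, in continuous time.

    ``x_um``/``y_um`` hold the world-frame footprint position (NaN when the
    pattern carries no spatial information, e.g. pure timing generators).
    """

    onset_ms: float
    offset_ms: float
    x_um: float = math.nan
    y_um: float = math.nan

    def __post_init__(self) -> None:
        if not self.offset_ms > self.onset_ms:
            raise ValueError(
                f"stance offset ({self.offset_ms}) must be after onset ({self.onset_ms})"
            )

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    @property
    def position_um(self) -> Tuple[float, float]:
        return (self.x_um, self.y_um)

    def covers(self, t_ms: float) -> bool:
        """Half-open containment test [onset, offset)."""
        return self.onset_ms <= t_ms < self.offset_ms

    def to_dict(self) -> dict:
        return {
            "onset_ms": self.onset_ms,
            "offset_ms": self.offset_ms,
            "x_um": None if math.isnan(self.x_um) else self.x_um,
            "y_um": None if math.isnan(self.y_um) else self.y_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StanceEvent":
        x = d.get("x_um")
        y = d.get("y_um")
        return cls(
            onset_ms=float(d["onset_ms"]),
            offset_ms=float(d["offset_ms"]),
            x_um=math.nan if x is None else float(x),
            y_um=math.nan if y is None else float(y),
        )


@dataclass
class StepPattern:
    """Per-leg ordered stance intervals with optional footprint positions.

    The canonical product of tracking, and of the synthetic generators (which
    produce intervals in continuous time, not quantized to frames).
    """

    legs: Dict[str, List[StanceEvent]]
    fps: Optional[float] = None

    def __post_init__(self) -> None:
        for leg in self.legs:
            if leg not in LEGS:
                raise ValueError(f"unknown leg label {leg!r}; expected one of {LEGS}")
            events = sorted(self.legs[leg], key=lambda e: e.onset_ms)
            for a, b in zip(events, events[1:]):
                if b.onset_ms < a.offset_ms:
                    raise ValueError(f"overlapping stance intervals for leg {leg}")
            self.legs[leg] = events

    def events(self, leg: str) -> List[StanceEvent]:
        return self.legs.get(leg, [])

    def onsets_ms(self, leg: str) -> np.ndarray:
        return np.array([e.onset_ms for e in self.events(leg)], dtype=float)

    def offsets_ms(self, leg: str) -> np.ndarray:
        return np.array([e.offset_ms for e in self.events(leg)], dtype=float)

    def swing_onsets_ms(self, leg: str) -> np.ndarray:
        """Swing begins at stance offset (liftoff)."""
        return self.offsets_ms(leg)

    def in_stance(self, leg: str, t_ms: float) -> bool:
        return any(e.covers(t_ms) for e in self.events(leg))

    @property
    def t_end_ms(self) -> float:
        ends = [e.offset_ms for evs in self.legs.values() for e in evs]
        return max(ends) if ends else 0.0

    def to_dict(self) -> dict:
        return {
            "fps": self.fps,
            "legs": {leg: [e.to_dict() for e in evs] for leg, evs in self.legs.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StepPattern":
        fps = d.get("fps")
        return cls(
            legs={
                leg: [StanceEvent.from_dict(e) for e in evs]
                for leg, evs in d["legs"].items()
            },
            fps=None if fps is None else float(fps),
        )


@dataclass
class BodyTrack:
    """Per-frame body centroid, length and displacement axis.

    ``centroid_px`` is an (N, 2) array of (x, y) pixel coordinates;
    ``axis`` holds unit displacement-axis vectors; ``valid`` flags frames
    where the body was found; ``axis_fallback`` flags frames where the axis
    came from the body-ellipse orientation rather than displacement.
    """

    centroid_px: np.ndarray
    length_px: np.ndarray
    axis: np.ndarray
    valid: np.ndarray
    calibration: Calibration
    axis_fallback: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.centroid_px = np.asarray(self.centroid_px, dtype=float)
        self.length_px = np.asarray(self.length_px, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.valid)
        if self.centroid_px.shape != (n, 2) or self.axis.shape != (n, 2):
            raise ValueError("centroid_px and axis must be (N, 2) arrays")
        if self.axis_fallback is None:
            self.axis_fallback = np.zeros(n, dtype=bool)
        norms = np.linalg.norm(self.axis[self.valid], axis=1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("displacement axis vectors must be unit length where valid")

    def __len__(self) -> int:
        return len(self.valid)

    @property
    def n_frames(self) -> int:
        return len(self.valid)

    def body_length_px(self) -> float:
        """Median body length over valid frames (robust per-video scalar)."""
        lengths = self.length_px[self.valid]
        if len(lengths) == 0:
            raise ValueError("no valid body frames")
        return float(np.median(lengths))

    def body_length_um(self) -> float:
        return self.body_length_px() * self.calibration.um_per_px

    def to_dict(self) -> dict:
        return {
            "calibration": self.calibration.to_dict(),
            "centroid_px": self.centroid_px.tolist(),
            "length_px": self.length_px.tolist(),
            "axis": self.axis.tolist(),
            "valid": self.valid.tolist(),
            "axis_fallback": np.asarray(self.axis_fallback).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BodyTrack":
        return cls(
            centroid_px=np.array(d["centroid_px"], dtype=float),
            length_px=np.array(d["length_px"], dtype=float),
            axis=np.array(d["axis"], dtype=float),
            valid=np.array(d["valid"], dtype=bool),
            calibration=Calibration.from_dict(d["calibration"]),
            axis_fallback=np.array(d["axis_fallback"], dtype=bool),
        )


def body_basis(axis: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Orthonormal body-frame basis (anterior, left) for a displacement axis.

    With image y pointing down, the left-hand side of an animal heading along
    ``axis`` is obtained by rotating the axis by -90 degrees in (x, y):
    ``left = (axis_y, -axis_x)``.
    """
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("zero-length axis")
    a = a / n
    left = np.array([a[1], -a[0]])
    return a, left


def world_to_body(points: np.ndarray, centroid: Sequence[float], axis: Sequence[float]) -> np.ndarray:
    """Map world points (same units as centroid) into unnormalized body frame."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a, left = body_basis(axis)
    d = pts - np.asarray(centroid, dtype=float)
    out = np.column_stack([d @ a, d @ left])
    return out if np.asarray(points).ndim > 1 else out[0]


def body_to_world(points: np.ndarray, centroid: Sequence[float], axis: Sequence[float]) -> np.ndarray:
    """Inverse of :func:`world_to_body`."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a, left = body_basis(axis)
    out = np.asarray(centroid, dtype=float) + pts[:, :1] * a + pts[:, 1:2] * left
    return out if np.asarray(points).ndim > 1 else out[0]
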