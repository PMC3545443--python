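"""Parametric hexapod walking ground truth and fTIR-like frame rendering.

Generates step patterns (tripod, right/left tetrapod, wave) in continuous
time, simulates a straight constant-speed walk with world-frame footprints,
and renders image sequences with the signal structure of footprint-contact
videos: bright compact contact spots that stay fixed in the world during
stance, a dim body glow, static dust present before the animal enters, and
additive sensor noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    LEGS,
    BodyTrack,
    Calibration,
    StanceEvent,
    StepPattern,
    body_basis,
)

GAIT_NAMES = ("tripod", "tetrapod_right", "tetrapod_left", "wave")

#: Stance triplet in phase with the left-fore leg in the alternating-tripod gait.
TRIPOD_GROUP_A = ("LF", "LH", "RM")
TRIPOD_GROUP_B = ("RF", "RH", "LM")


# --------------------------------------------------------------------------- #
# optics helper

def critical_angle(n_dense: float, n_rare: float) -> float:
    """Critical angle (degrees) for total internal reflection at an interface.

    Light travelling in the denser medium (refractive index ``n_dense``) is
    totally internally reflected beyond ``arcsin(n_rare / n_dense)``.
    """
    if n_dense <= 0 or n_rare <= 0:
        raise ValueError("refractive indices must be positive")
    if n_rare >= n_dense:
        raise ValueError("no total internal reflection from rarer to denser medium")
    return math.degrees(math.asin(n_rare / n_dense))


# --------------------------------------------------------------------------- #
# specs

@dataclass(frozen=True)
class GaitSpec:
    """Timing and speed parameters of a generated walk."""

    gait_name: str = "tripod"
    period_ms: float = 100.0
    duty_factor: float = 0.5
    n_cycles: int = 10
    fps: float = 250.0
    speed_mm_s: float = 20.0
    metachronal_lag_ms: Optional[float] = None
    #: Relative amplitude of the within-cycle speed oscillation (0 = constant
    #: speed).  Peaks fall midway through each tripod-group stance phase.
    speed_modulation: float = 0.0

    def __post_init__(self) -> None:
        if self.gait_name not in GAIT_NAMES:
            raise ValueError(f"gait_name must be one of {GAIT_NAMES}")
        if self.period_ms <= 0:
            raise ValueError("period_ms must be > 0")
        if not 0.0 < self.duty_factor <= 1.0:
            raise ValueError("duty_factor must be in (0, 1]")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.speed_mm_s < 0:
            raise ValueError("speed_mm_s must be >= 0")
        if not 0.0 <= self.speed_modulation < 1.0:
            raise ValueError("speed_modulation must be in [0, 1)")

    @property
    def duration_ms(self) -> float:
        return self.n_cycles * self.period_ms

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_ms * self.fps / 1000.0))

    def to_dict(self) -> dict:
        return {
            "gait_name": self.gait_name,
            "period_ms": self.period_ms,
            "duty_factor": self.duty_factor,
            "n_cycles": self.n_cycles,
            "fps": self.fps,
            "speed_mm_s": self.speed_mm_s,
            "metachronal_lag_ms": self.metachronal_lag_ms,
            "speed_modulation": self.speed_modulation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaitSpec":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class BodyPlan:
    """Neutral footprint geometry in body-length-normalized body frame.

    Lateral convention: +y is the animal's left, so left-leg lateral
    coordinates are positive.  For every leg the neutral touchdown position
    (AEP) must be anterior to the neutral liftoff position (PEP).
    """

    body_length_um: float
    aep: Dict[str, Tuple[float, float]]
    pep: Dict[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        if self.body_length_um <= 0:
            raise ValueError("body_length_um must be > 0")
        for leg in LEGS:
            if leg not in self.aep or leg not in self.pep:
                raise ValueError(f"plan missing leg {leg}")
            if not self.aep[leg][0] > self.pep[leg][0]:
                raise ValueError(
                    f"AEP must be anterior to PEP for leg {leg}: "
                    f"{self.aep[leg][0]} vs {self.pep[leg][0]}"
                )
            lateral = self.aep[leg][1]
            if leg.startswith("L") and lateral <= 0:
                raise ValueError(f"left leg {leg} must have positive lateral AEP")
            if leg.startswith("R") and lateral >= 0:
                raise ValueError(f"right leg {leg} must have negative lateral AEP")

    def to_dict(self) -> dict:
        return {
            "body_length_um": self.body_length_um,
            "aep": {k: list(v) for k, v in self.aep.items()},
            "pep": {k: list(v) for k, v in self.pep.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BodyPlan":
        return cls(
            body_length_um=float(d["body_length_um"]),
            aep={k: tuple(v) for k, v in d["aep"].items()},
            pep={k: tuple(v) for k, v in d["pep"].items()},
        )


def default_body_plan(body_length_um: float = 2500.0) -> BodyPlan:
    """Footprint geometry loosely matching an adult fly (units: body lengths)."""
    long_aep = {"F": 0.45, "M": 0.05, "H": -0.30}
    lateral = {"F": 0.25, "M": 0.30, "H": 0.28}
    stride = 0.35
    aep, pep = {}, {}
    for leg in LEGS:
        seg, side = leg[1], leg[0]
        y = lateral[seg] * (1.0 if side == "L" else -1.0)
        aep[leg] = (long_aep[seg], y)
        pep[leg] = (long_aep[seg] - stride, y)
    return BodyPlan(body_length_um=body_length_um, aep=aep, pep=pep)


# --------------------------------------------------------------------------- #
# step-pattern generation

def _cycle_stance_onsets(spec: GaitSpec) -> Dict[str, float]:
    """Stance-onset offset (ms within one cycle) for each leg."""
    p = spec.period_ms
    swing = (1.0 - spec.duty_factor) * p

    if spec.gait_name == "tripod":
        onsets = {leg: 0.0 for leg in TRIPOD_GROUP_A}
        onsets.update({leg: p / 2.0 for leg in TRIPOD_GROUP_B})
        return onsets

    if spec.gait_name in ("tetrapod_right", "tetrapod_left"):
        if spec.metachronal_lag_ms is not None:
            # Custom hind-to-fore swing-onset lag; mid legs halfway through the
            # ipsilateral wave, contralateral hind legs half a period apart.
            lag = spec.metachronal_lag_ms
            swing_onsets = {
                "RH": 0.0, "RM": lag / 2.0, "RF": lag,
                "LH": p / 2.0, "LM": p / 2.0 + lag / 2.0, "LF": p / 2.0 + lag,
            }
            if spec.gait_name == "tetrapod_left":
                swing_onsets = {_mirror(leg): t for leg, t in swing_onsets.items()}
        else:
            if spec.duty_factor < 2.0 / 3.0:
                raise ValueError(
                    "tetrapod with duty_factor < 2/3 forces more than two "
                    "simultaneous swings"
                )
            # Swing-pair cycle (RH,LM) -> (RM,LF) -> (RF,LH), mirrored for
            # the left-handed variant.
            groups = [("RH", "LM"), ("RM", "LF"), ("RF", "LH")]
            if spec.gait_name == "tetrapod_left":
                groups = [tuple(_mirror(l) for l in g) for g in groups]
            swing_onsets = {}
            for gi, pair in enumerate(groups):
                for leg in pair:
                    swing_onsets[leg] = gi * p / 3.0
        return {leg: (t + swing) % p for leg, t in swing_onsets.items()}

    # wave: one leg swinging at a time, back-to-front on each side, sides
    # offset by half a period.
    order = ["RH", "RM", "RF", "LH", "LM", "LF"]
    swing_onsets = {leg: i * p / 6.0 for i, leg in enumerate(order)}
    return {leg: (t + swing) % p for leg, t in swing_onsets.items()}


def _mirror(leg: str) -> str:
    return {"L": "R", "R": "L"}[leg[0]] + leg[1]


def make_step_pattern(spec: GaitSpec) -> StepPattern:
    """Continuous-time per-leg stance intervals over ``n_cycles`` periods.

    Onsets are exact reals (no frame quantization); intervals are clipped to
    the record [0, n_cycles * period].
    """
    p, d = spec.period_ms, spec.duty_factor
    t_end = spec.duration_ms
    legs: Dict[str, List[StanceEvent]] = {}
    if d == 1.0:
        for leg in LEGS:
            legs[leg] = [StanceEvent(0.0, t_end)]
        return StepPattern(legs=legs, fps=spec.fps)

    onsets = _cycle_stance_onsets(spec)
    stance = d * p
    for leg in LEGS:
        events: List[StanceEvent] = []
        for k in range(-2, spec.n_cycles + 2):
            on = onsets[leg] + k * p
            off = on + stance
            lo, hi = max(on, 0.0), min(off, t_end)
            if hi > lo:
                events.append(StanceEvent(lo, hi))
        legs[leg] = events
    return StepPattern(legs=legs, fps=spec.fps)


def quantize_pattern(pattern: StepPattern, fps: float) -> StepPattern:
    """Round all onsets/offsets to the frame grid of the given rate."""
    if fps <= 0:
        raise ValueError("fps must be > 0")
    dt = 1000.0 / fps
    legs: Dict[str, List[StanceEvent]] = {}
    for leg, events in pattern.legs.items():
        out = []
        for e in events:
            on = round(e.onset_ms / dt) * dt
            off = round(e.offset_ms / dt) * dt
            if off > on:
                out.append(StanceEvent(on, off, e.x_um, e.y_um))
        legs[leg] = out
    return StepPattern(legs=legs, fps=fps)


def make_blended_pattern(alpha: float, period_ms: float = 100.0,
                         n_cycles: int = 10, fps: float = 250.0) -> StepPattern:
    """Diagnostic generator interpolating tetrapod (alpha=0) to tripod (alpha=1).

    Per-leg stance onsets and the duty factor are linearly interpolated
    between the two canonical timings; useful for checking that the gait
    index rises continuously along the tetrapod-to-tripod continuum.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    p = period_ms
    # Stance onsets: tetrapod (duty 2/3) vs tripod (duty 1/2), expressed so
    # every leg's interpolation path is monotone within one cycle.
    tetra = {"RH": p / 3, "LM": p / 3, "RM": 2 * p / 3, "LF": 2 * p / 3,
             "RF": p, "LH": p}
    tri = {"LF": p, "LH": p, "RM": p, "RF": p / 2, "RH": p / 2, "LM": p / 2}
    duty = (1 - alpha) * (2.0 / 3.0) + alpha * 0.5
    t_end = n_cycles * p
    stance = duty * p
    legs: Dict[str, List[StanceEvent]] = {}
    for leg in LEGS:
        onset0 = (1 - alpha) * tetra[leg] + alpha * tri[leg]
        events = []
        for k in range(-2, n_cycles + 2):
            on = onset0 + k * p
            off = on + stance
            lo, hi = max(on, 0.0), min(off, t_end)
            if hi > lo:
                events.append(StanceEvent(lo, hi))
        legs[leg] = events
    return StepPattern(legs=legs, fps=fps)


# --------------------------------------------------------------------------- #
# walk simulation

@dataclass
class GroundTruth:
    """Synthetic-run truth: trajectory, continuous step pattern, footprints."""

    trajectory_um: np.ndarray          # (n_frames, 2) world centroid
    heading_rad: np.ndarray            # (n_frames,)
    pattern: StepPattern               # continuous time, world footprints
    spec: GaitSpec
    plan: BodyPlan
    seed: Optional[int] = None

    @property
    def n_frames(self) -> int:
        return len(self.trajectory_um)

    def position_at(self, t_ms: float) -> np.ndarray:
        """World centroid at an arbitrary time (linear interp on the frame grid)."""
        dt = 1000.0 / self.spec.fps
        i = t_ms / dt
        x = np.interp(i, np.arange(self.n_frames), self.trajectory_um[:, 0])
        y = np.interp(i, np.arange(self.n_frames), self.trajectory_um[:, 1])
        return np.array([x, y])

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "plan": self.plan.to_dict(),
            "seed": self.seed,
            "trajectory_um": self.trajectory_um.tolist(),
            "heading_rad": self.heading_rad.tolist(),
            "pattern": self.pattern.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            trajectory_um=np.array(d["trajectory_um"], dtype=float),
            heading_rad=np.array(d["heading_rad"], dtype=float),
            pattern=StepPattern.from_dict(d["pattern"]),
            spec=GaitSpec.from_dict(d["spec"]),
            plan=BodyPlan.from_dict(d["plan"]),
            seed=d.get("seed"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _position_fn(spec: GaitSpec, start_um: Sequence[float]):
    """Closed-form body position: constant mean speed, optional oscillation.

    The oscillation has two peaks per period, midway through each alternating
    stance half-cycle, and integrates to zero over a full period.
    """
    v = spec.speed_mm_s  # mm/s == um/ms
    m = spec.speed_modulation
    p = spec.period_ms
    omega = 4.0 * math.pi / p
    x0, y0 = float(start_um[0]), float(start_um[1])

    def pos(t_ms: float) -> np.ndarray:
        t = float(t_ms)
        x = v * t
        if m > 0:
            x += v * (m / omega) * (
                math.sin(omega * (t - p / 4.0)) + math.sin(omega * p / 4.0)
            )
        return np.array([x0 + x, y0])

    return pos


def simulate_walk(
    spec: GaitSpec,
    plan: BodyPlan,
    seed: Optional[int] = None,
    aep_jitter_norm: float = 0.0,
    pep_jitter_norm: float = 0.0,
    start_um: Sequence[float] = (0.0, 0.0),
) -> GroundTruth:
    """Simulate a straight walk along +x and pin world footprints.

    Each leg's touchdown world position is the body position at touchdown
    plus its neutral AEP offset (de-normalized, rotated to world); footprints
    stay fixed for the whole stance.  ``aep_jitter_norm`` adds per-step
    Gaussian noise (body lengths) to the touchdown position;
    ``pep_jitter_norm`` perturbs liftoff times so that liftoff (PEP)
    positions scatter independently of touchdowns while the footprint itself
    remains stationary.
    """
    rng = np.random.default_rng(seed)
    pos = _position_fn(spec, start_um)
    bl = plan.body_length_um
    v = spec.speed_mm_s

    # Unclipped stance schedule so edge-clipped events keep their true
    # touchdown geometry.
    if spec.duty_factor == 1.0:
        onsets = {leg: 0.0 for leg in LEGS}
    else:
        onsets = _cycle_stance_onsets(spec)
    stance_ms = spec.duty_factor * spec.period_ms
    t_end = spec.duration_ms
    anterior, left = body_basis((1.0, 0.0))  # heading fixed along +x

    legs: Dict[str, List[StanceEvent]] = {}
    for leg in LEGS:
        events: List[StanceEvent] = []
        for k in range(-2, spec.n_cycles + 2):
            on = onsets[leg] + k * spec.period_ms
            off = on + stance_ms if spec.duty_factor < 1.0 else t_end
            if off <= 0 or on >= t_end:
                continue
            aep = np.array(plan.aep[leg], dtype=float)
            if aep_jitter_norm > 0:
                aep = aep + rng.normal(0.0, aep_jitter_norm, size=2)
            foot = pos(on) + bl * (aep[0] * anterior + aep[1] * left)
            if pep_jitter_norm > 0 and v > 0 and spec.duty_factor < 1.0:
                dt_sigma = pep_jitter_norm * bl / v
                off = off + rng.normal(0.0, dt_sigma)
                off = min(max(off, on + 0.1 * stance_ms), on + spec.period_ms - 1e-9)
            lo, hi = max(on, 0.0), min(off, t_end)
            if hi > lo:
                events.append(StanceEvent(lo, hi, x_um=foot[0], y_um=foot[1]))
            if spec.duty_factor == 1.0:
                break
        legs[leg] = events

    n_frames = spec.n_frames
    dt = 1000.0 / spec.fps
    trajectory = np.array([pos(i * dt) for i in range(n_frames)])
    heading = np.zeros(n_frames)
    pattern = StepPattern(legs=legs, fps=spec.fps)

    # Kinematic sanity: derived liftoff (PEP) may never be anterior to the
    # touchdown (AEP) for a forward walk.
    for leg, events in legs.items():
        for e in events:
            pep_x = e.x_um - pos(e.offset_ms)[0]
            aep_x = e.x_um - pos(e.onset_ms)[0]
            if pep_x > aep_x + 1e-9:
                raise ValueError(
                    f"kinematically impossible step for {leg}: PEP anterior to AEP"
                )

    return GroundTruth(
        trajectory_um=trajectory,
        heading_rad=heading,
        pattern=pattern,
        spec=spec,
        plan=plan,
        seed=seed,
    )


def body_track_from_truth(truth: GroundTruth, um_per_px: float = 40.0) -> BodyTrack:
    """Exact BodyTrack on the truth trajectory (bypasses image tracking)."""
    n = truth.n_frames
    axis = np.column_stack([np.cos(truth.heading_rad), np.sin(truth.heading_rad)])
    return BodyTrack(
        centroid_px=truth.trajectory_um / um_per_px,
        length_px=np.full(n, truth.plan.body_length_um / um_per_px),
        axis=axis,
        valid=np.ones(n, dtype=bool),
        calibration=Calibration(fps=truth.spec.fps, um_per_px=um_per_px),
    )


# --------------------------------------------------------------------------- #
# rendering

@dataclass(frozen=True)
class RenderConfig:
    """Appearance of the rendered image sequence (intensities in [0, 1])."""

    shape_px: Tuple[int, int] = (110, 1200)   # (height, width)
    um_per_px: float = 40.0
    spot_amp: float = 0.6
    spot_sigma_px: float = 1.5
    body_amp: float = 0.2
    body_axes_px: Tuple[float, float] = (31.25, 7.8)  # semi-axes (a, b)
    background: float = 0.05
    noise_sigma: float = 0.03
    dust: Tuple[Tuple[float, float, float, float], ...] = ()  # (x, y, amp, sigma)
    n_pre_entry_frames: int = 20
    body_edge_sharpness: float = 20.0

    def __post_init__(self) -> None:
        if self.spot_sigma_px <= 0:
            raise ValueError("spot radius must be > 0")
        if not self.spot_amp > self.body_amp > self.noise_sigma >= 0:
            raise ValueError(
                "require spot_amp > body_amp > noise_sigma >= 0, got "
                f"{self.spot_amp}, {self.body_amp}, {self.noise_sigma}"
            )
        if self.n_pre_entry_frames < 0:
            raise ValueError("n_pre_entry_frames must be >= 0")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")

    def to_dict(self) -> dict:
        return {
            "shape_px": list(self.shape_px),
            "um_per_px": self.um_per_px,
            "spot_amp": self.spot_amp,
            "spot_sigma_px": self.spot_sigma_px,
            "body_amp": self.body_amp,
            "body_axes_px": list(self.body_axes_px),
            "background": self.background,
            "noise_sigma": self.noise_sigma,
            "dust": [list(d) for d in self.dust],
            "n_pre_entry_frames": self.n_pre_entry_frames,
            "body_edge_sharpness": self.body_edge_sharpness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RenderConfig":
        d = dict(d)
        if "shape_px" in d:
            d["shape_px"] = tuple(d["shape_px"])
        if "body_axes_px" in d:
            d["body_axes_px"] = tuple(d["body_axes_px"])
        if "dust" in d:
            d["dust"] = tuple(tuple(x) for x in d["dust"])
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


def _add_gaussian_spot(img: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    h, w = img.shape
    r = int(math.ceil(4 * sigma))
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma * sigma))
    img[y0:y1, x0:x1] += amp * g


def _add_body_ellipse(img: np.ndarray, cx: float, cy: float, heading: float,
                      a: float, b: float, amp: float, sharpness: float) -> None:
    h, w = img.shape
    r = int(math.ceil(max(a, b) + 3))
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    ca, sa = math.cos(heading), math.sin(heading)
    u = xs[None, :] * ca + ys[:, None] * sa
    v = -xs[None, :] * sa + ys[:, None] * ca
    r_ell = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    img[y0:y1, x0:x1] += amp * np.clip((1.0 - r_ell) * sharpness, 0.0, 1.0)


def render_ftir_frames(truth: GroundTruth, cfg: RenderConfig,
                       seed: Optional[int] = None):
    """Render the walk as a calibrated FrameStack.

    Frame timestamps: the first ``n_pre_entry_frames`` frames precede the
    animal's entry (dust + background + noise only); simulation time zero is
    the first post-entry frame.  Stance membership uses the half-open
    [onset, offset) convention against frame timestamps.
    """
    from .imaging_io import FrameStack  # local import to avoid a cycle

    h, w = cfg.shape_px
    upx = cfg.um_per_px
    n_pre = cfg.n_pre_entry_frames
    dt = 1000.0 / truth.spec.fps
    n_total = n_pre + truth.n_frames
    rng = np.random.default_rng(seed)

    # Bounds check before rendering: body extent and every footprint.
    a_px = cfg.body_axes_px[0]
    for i in range(truth.n_frames):
        cx, cy = truth.trajectory_um[i] / upx
        if not (a_px <= cx <= w - 1 - a_px and cfg.body_axes_px[1] <= cy <= h - 1 - cfg.body_axes_px[1]):
            raise ValueError(f"trajectory exits the frame at frame {n_pre + i}")
    margin = 4 * cfg.spot_sigma_px
    for leg, events in truth.pattern.legs.items():
        for e in events:
            x, y = e.x_um / upx, e.y_um / upx
            if not (margin <= x <= w - 1 - margin and margin <= y <= h - 1 - margin):
                frame = n_pre + int(e.onset_ms / dt)
                raise ValueError(
                    f"footprint of {leg} exits the frame at frame {frame}"
                )

    frames = np.empty((n_total, h, w), dtype=np.float32)
    base = np.full((h, w), cfg.background, dtype=np.float64)
    for (dx, dy, damp, dsig) in cfg.dust:
        _add_gaussian_spot(base, dx, dy, damp, dsig)

    for i in range(n_total):
        img = base.copy()
        t = (i - n_pre) * dt
        if i >= n_pre:
            cx, cy = truth.trajectory_um[i - n_pre] / upx
            _add_body_ellipse(img, cx, cy, truth.heading_rad[i - n_pre],
                              cfg.body_axes_px[0], cfg.body_axes_px[1],
                              cfg.body_amp, cfg.body_edge_sharpness)
            for leg in LEGS:
                for e in truth.pattern.events(leg):
                    if e.covers(t):
                        _add_gaussian_spot(img, e.x_um / upx, e.y_um / upx,
                                           cfg.spot_amp, cfg.spot_sigma_px)
        if cfg.noise_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
        frames[i] = np.clip(img, 0.0, 1.0)

    cal = Calibration(fps=truth.spec.fps, um_per_px=upx)
    return FrameStack(frames=frames, calibration=cal)


def auto_layout(spec: GaitSpec, plan: BodyPlan, um_per_px: float = 40.0
                ) -> Tuple[Tuple[int, int], Tuple[float, float], Tuple[float, float]]:
    """Image shape, start position (um) and body semi-axes (px) for a run.

    Sizes the canvas so the full straight trajectory, the body ellipse and
    all footprints fit with a safety margin.
    """
    bl = plan.body_length_um
    margin = 0.9 * bl
    path = spec.speed_mm_s * spec.duration_ms
    width = int(math.ceil((path + 2 * margin) / um_per_px))
    height = int(math.ceil(1.5 * bl / um_per_px))
    start = (margin, height * um_per_px / 2.0)
    axes = (0.5 * bl / um_per_px, 0.125 * bl / um_per_px)
    return (height, width), start, axes


def synthesize(spec: GaitSpec, plan: Optional[BodyPlan] = None,
               seed: Optional[int] = None, um_per_px: float = 40.0,
               aep_jitter_norm: float = 0.0, pep_jitter_norm: float = 0.0,
               **render_overrides):
    """Convenience: simulate a walk and render it on an auto-sized canvas.

    Returns ``(stack, truth, cfg)``.
    """
    plan = plan if plan is not None else default_body_plan()
    shape, start, axes = auto_layout(spec, plan, um_per_px)
    truth = simulate_walk(spec, plan, seed=seed, start_um=start,
                          aep_jitter_norm=aep_jitter_norm,
                          pep_jitter_norm=pep_jitter_norm)
    cfg = RenderConfig(shape_px=shape, um_per_px=um_per_px,
                       body_axes_px=axes, **render_overrides)
    stack = render_ftir_frames(truth, cfg, seed=seed)
    return stack, truth, cfg
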