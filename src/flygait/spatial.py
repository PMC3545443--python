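"""Body-frame spatial parameters: stance traces, AEP/PEP, stance linearity,
footprint clustering and footprint alignment.

All positions are expressed in a body frame normalized by the (median) body
length: +x anterior along the displacement axis, +y to the animal's left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import LEGS, SEGMENT, SIDE, BodyTrack, StepPattern, world_to_body


@dataclass
class StanceTrace:
    """Body-frame path swept by one stationary footprint during one stance."""

    leg: str
    cycle: int
    frames: np.ndarray        # frame indices covered by the stance
    xy_norm: np.ndarray       # (k, 2) body-length-normalized positions

    @property
    def aep(self) -> np.ndarray:
        """Touchdown position (first trace point)."""
        return self.xy_norm[0]

    @property
    def pep(self) -> np.ndarray:
        """Liftoff position (last trace point)."""
        return self.xy_norm[-1]

    def __len__(self) -> int:
        return len(self.xy_norm)


def to_body_frame(points_world_um: np.ndarray, body_track: BodyTrack,
                  frame: int) -> np.ndarray:
    """World micrometres -> body-length-normalized body frame at a frame."""
    if not body_track.valid[frame]:
        raise ValueError(f"body track invalid at frame {frame}")
    upx = body_track.calibration.um_per_px
    centroid_um = body_track.centroid_px[frame] * upx
    bl_um = body_track.body_length_um()
    return world_to_body(points_world_um, centroid_um, body_track.axis[frame]) / bl_um


def stance_traces(pattern: StepPattern, body_track: BodyTrack) -> List[StanceTrace]:
    """One trace per stance interval: the fixed world footprint mapped into
    the moving body frame at every covered frame."""
    fps = pattern.fps if pattern.fps is not None else body_track.calibration.fps
    dt = 1000.0 / fps
    n = body_track.n_frames
    traces: List[StanceTrace] = []
    for leg in LEGS:
        for cycle, e in enumerate(pattern.events(leg)):
            if math.isnan(e.x_um):
                continue
            f0 = int(math.ceil(e.onset_ms / dt - 1e-9))
            f1 = int(math.ceil(e.offset_ms / dt - 1e-9))  # half-open
            frames = [f for f in range(max(f0, 0), min(f1, n))
                      if body_track.valid[f]]
            if not frames:
                continue
            pts = np.array([
                to_body_frame(np.array([e.x_um, e.y_um]), body_track, f)
                for f in frames
            ])
            traces.append(StanceTrace(leg=leg, cycle=cycle,
                                      frames=np.array(frames), xy_norm=pts))
    return traces


def stance_linearity(xy: np.ndarray, knot_step: int = 5) -> Optional[float]:
    """Mean distance between a trace and its decimated-and-interpolated copy.

    The smoothed trace is the polyline through every ``knot_step``-th sample
    (first and last always included), linearly interpolated back to per-frame
    resolution.  Traces shorter than 6 points are excluded (returns None).
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 6:
        return None
    idx = np.arange(len(xy))
    knots = list(range(0, len(xy), knot_step))
    if knots[-1] != len(xy) - 1:
        knots.append(len(xy) - 1)
    knots = np.array(knots)
    sx = np.interp(idx, knots, xy[knots, 0])
    sy = np.interp(idx, knots, xy[knots, 1])
    return float(np.mean(np.hypot(xy[:, 0] - sx, xy[:, 1] - sy)))


def video_stance_linearity(traces: Sequence[StanceTrace]) -> Tuple[Optional[float], int, int]:
    """Mean linearity index over all usable traces; returns (mean, used, skipped)."""
    vals = [stance_linearity(tr.xy_norm) for tr in traces]
    used = [v for v in vals if v is not None]
    if not used:
        return None, 0, len(vals)
    return float(np.mean(used)), len(used), len(vals) - len(used)


def footprint_clustering(positions: np.ndarray) -> Optional[float]:
    """Vector magnitude of the x/y sample standard deviations.

    ``sqrt(std_x**2 + std_y**2)`` with (n-1) standard deviations; undefined
    (None) for fewer than two positions.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) < 2:
        return None
    sx = float(np.std(positions[:, 0], ddof=1))
    sy = float(np.std(positions[:, 1], ddof=1))
    return math.hypot(sx, sy)


def clustering_summary(traces: Sequence[StanceTrace]) -> Dict[str, Dict[str, Optional[float]]]:
    """Per-leg AEP/PEP means and clustering values (normalized units)."""
    out: Dict[str, Dict[str, Optional[float]]] = {}
    for leg in LEGS:
        aeps = np.array([tr.aep for tr in traces if tr.leg == leg])
        peps = np.array([tr.pep for tr in traces if tr.leg == leg])
        entry: Dict[str, Optional[float]] = {
            "aep_clustering": footprint_clustering(aeps) if len(aeps) else None,
            "pep_clustering": footprint_clustering(peps) if len(peps) else None,
        }
        if len(aeps):
            entry["aep_mean_x"] = float(aeps[:, 0].mean())
            entry["aep_mean_y"] = float(aeps[:, 1].mean())
        if len(peps):
            entry["pep_mean_x"] = float(peps[:, 0].mean())
            entry["pep_mean_y"] = float(peps[:, 1].mean())
        out[leg] = entry
    return out


def footprint_alignment(pattern: StepPattern, body_track: BodyTrack,
                        match_radius_norm: float = 0.3
                        ) -> Tuple[List[float], Optional[float]]:
    """Follow-the-leader precision: STD of fore/mid/hind projections (um).

    Triplets are formed per side: each foreleg touchdown is matched to the
    nearest-in-world-space subsequent ipsilateral midleg touchdown (within
    ``match_radius_norm`` body lengths), and that midleg to the nearest
    subsequent hindleg touchdown.  The three world positions are projected
    onto the displacement axis; the per-triplet value is the (n-1) STD of the
    three projections, and the video value the mean over triplets.
    """
    bl_um = body_track.body_length_um()
    radius = match_radius_norm * bl_um
    dt = body_track.calibration.frame_interval_ms
    values: List[float] = []
    for side in ("L", "R"):
        fore = [e for e in pattern.events(side + "F") if not math.isnan(e.x_um)]
        mids = [e for e in pattern.events(side + "M") if not math.isnan(e.x_um)]
        hinds = [e for e in pattern.events(side + "H") if not math.isnan(e.x_um)]
        used_m: set = set()
        used_h: set = set()
        for fe in fore:
            m = _nearest_after(fe, mids, radius, used_m)
            if m is None:
                continue
            h = _nearest_after(mids[m], hinds, radius, used_h)
            if h is None:
                continue
            used_m.add(m)
            used_h.add(h)
            trio = [fe, mids[m], hinds[h]]
            f = int(round(fe.onset_ms / dt))
            f = min(max(f, 0), body_track.n_frames - 1)
            if not body_track.valid[f]:
                vi = np.nonzero(body_track.valid)[0]
                f = int(vi[np.argmin(np.abs(vi - f))])
            axis = body_track.axis[f]
            proj = [e.x_um * axis[0] + e.y_um * axis[1] for e in trio]
            values.append(float(np.std(proj, ddof=1)))
    mean = float(np.mean(values)) if values else None
    return values, mean


def _nearest_after(ref, events, radius: float, used: set) -> Optional[int]:
    best, best_d = None, math.inf
    for i, e in enumerate(events):
        if i in used or e.onset_ms <= ref.onset_ms:
            continue
        d = math.hypot(e.x_um - ref.x_um, e.y_um - ref.y_um)
        if d <= radius and d < best_d:
            best, best_d = i, d
    return best
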