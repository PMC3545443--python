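"""From image stack to labeled step pattern: background subtraction, blob
detection, body tracking, leg-identity assignment, edits, stance extraction."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from skimage import measure

from .core import (
    LEFT_LEGS,
    LEGS,
    RIGHT_LEGS,
    BodyTrack,
    Calibration,
    StanceEvent,
    StepPattern,
    world_to_body,
)
from .imaging_io import FrameStack

#: Longitudinal priors (body lengths) used to bootstrap leg labels before any
#: history exists: fore anterior, mid central, hind posterior.
SEGMENT_PRIOR = {"F": 0.4, "M": 0.0, "H": -0.4}


@dataclass(frozen=True)
class RawDetection:
    """One candidate footprint blob in one frame."""

    frame: int
    x_px: float
    y_px: float
    area: int
    peak: float


@dataclass
class ContactTrack:
    """A linked run of detections belonging to one ground contact."""

    frames: List[int]
    positions_px: List[Tuple[float, float]]
    leg: Optional[str] = None
    flagged: bool = False

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    @property
    def last_position(self) -> Tuple[float, float]:
        return self.positions_px[-1]


@dataclass
class LabeledTracks:
    """Contact tracks with leg labels plus the context needed downstream."""

    tracks: List[ContactTrack]
    body_track: BodyTrack
    calibration: Calibration

    def contacts(self, leg: str) -> Dict[int, Tuple[float, float]]:
        """frame -> mean pixel position over all tracks of this leg."""
        acc: Dict[int, List[Tuple[float, float]]] = {}
        for tr in self.tracks:
            if tr.leg != leg:
                continue
            for f, p in zip(tr.frames, tr.positions_px):
                acc.setdefault(f, []).append(p)
        return {f: tuple(np.mean(ps, axis=0)) for f, ps in acc.items()}


@dataclass(frozen=True)
class EditRecord:
    """One declarative correction: add / remove / relabel a footprint."""

    frame: int
    action: str  # "add" | "remove" | "relabel"
    leg: str
    position_px: Optional[Tuple[float, float]] = None
    new_leg: Optional[str] = None

    def __post_init__(self) -> None:
        if self.action not in ("add", "remove", "relabel"):
            raise ValueError(f"unknown edit action {self.action!r}")
        if self.action == "add" and self.position_px is None:
            raise ValueError("add edits require position_px")
        if self.action == "relabel" and self.new_leg not in LEGS:
            raise ValueError("relabel edits require a valid new_leg")
        if self.leg not in LEGS:
            raise ValueError(f"unknown leg {self.leg!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "EditRecord":
        pos = d.get("position_px")
        return cls(
            frame=int(d["frame"]),
            action=d["action"],
            leg=d["leg"],
            position_px=None if pos is None else (float(pos[0]), float(pos[1])),
            new_leg=d.get("new_leg"),
        )


# --------------------------------------------------------------------------- #
# background and thresholds

def estimate_background(stack: FrameStack, n_pre_entry: int,
                        method: str = "max") -> np.ndarray:
    """Static-signal image from the frames that precede the animal's entry.

    The pixelwise maximum (default) of the pre-entry frames captures constant
    artifacts such as dust; it is subtracted (clipped at zero) from all frames
    before any detection step.
    """
    if n_pre_entry == 0:
        warnings.warn("n_pre_entry is 0; using a zero background", stacklevel=2)
        return np.zeros(stack.shape, dtype=np.float32)
    if not 1 <= n_pre_entry < stack.n_frames:
        raise ValueError("n_pre_entry must be >= 1 and < the stack length")
    pre = stack.frames[:n_pre_entry]
    if method == "max":
        return pre.max(axis=0)
    if method == "median":
        return np.median(pre, axis=0).astype(np.float32)
    raise ValueError(f"unknown background method {method!r}")


def subtract_background(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    return np.clip(frame - background, 0.0, None)


def noise_mad(stack: FrameStack, background: np.ndarray, n_pre_entry: int) -> float:
    """Median absolute residual of the pre-entry frames after subtraction.

    The default detection thresholds are expressed as multiples of this value
    (robust to exposure differences).
    """
    if n_pre_entry < 1:
        raise ValueError("need at least one pre-entry frame to estimate noise")
    resid = stack.frames[:n_pre_entry] - background
    return float(np.median(np.abs(resid - np.median(resid))))


# --------------------------------------------------------------------------- #
# body tracking

def _principal_axis(coords: np.ndarray) -> Tuple[np.ndarray, float]:
    """Major-axis direction and full extent (4*sqrt(lambda_max)) of a blob."""
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / len(c)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    length = 4.0 * math.sqrt(max(evals[-1], 0.0))
    return v, length


def track_body(
    stack: FrameStack,
    background: np.ndarray,
    body_threshold: float,
    smooth_sigma_px: float = 1.0,
    axis_window: int = 5,
    min_area_px: int = 30,
    min_step_px: float = 0.25,
) -> BodyTrack:
    """Track the dim body glow: centroid, length and displacement axis.

    The largest connected component above ``body_threshold`` (on a lightly
    smoothed, background-subtracted frame) is the body.  The displacement
    axis is the unit direction of centroid displacement smoothed over a
    centered window; frames where the body barely moves fall back to the
    body-ellipse major-axis orientation (flagged in ``axis_fallback``).

    The returned track carries a ``masks`` attribute (bool, N x H x W) with
    the per-frame body mask, used to keep the body out of footprint detection.
    """
    n = stack.n_frames
    centroids = np.full((n, 2), np.nan)
    lengths = np.zeros(n)
    orientations = np.zeros((n, 2))
    valid = np.zeros(n, dtype=bool)
    masks = np.zeros((n,) + stack.shape, dtype=bool)

    for i in range(n):
        diff = subtract_background(stack.frames[i], background)
        sm = ndi.gaussian_filter(diff, smooth_sigma_px)
        mask = sm > body_threshold
        labels, n_lab = ndi.label(mask)
        if n_lab == 0:
            continue
        sizes = ndi.sum_labels(np.ones_like(labels), labels, range(1, n_lab + 1))
        best = int(np.argmax(sizes)) + 1
        if sizes[best - 1] < min_area_px:
            continue
        comp = labels == best
        ys, xs = np.nonzero(comp)
        # Unweighted mask centroid: intensity weighting would let the smoothed
        # tails of nearby footprint spots bias the body position.
        cx = float(xs.mean())
        cy = float(ys.mean())
        v, length = _principal_axis(np.column_stack([xs, ys]).astype(float))
        centroids[i] = (cx, cy)
        lengths[i] = length
        orientations[i] = v
        valid[i] = True
        masks[i] = comp

    if valid.sum() <= 0.5 * n:
        raise ValueError("fly not found: no valid body in more than 50% of frames")

    # Smooth valid centroids (centered moving average) and differentiate.
    axis = np.zeros((n, 2))
    fallback = np.zeros(n, dtype=bool)
    vidx = np.nonzero(valid)[0]
    sm_c = centroids.copy()
    half = axis_window // 2
    for j, i in enumerate(vidx):
        lo, hi = max(0, j - half), min(len(vidx), j + half + 1)
        sm_c[i] = centroids[vidx[lo:hi]].mean(axis=0)
    for j, i in enumerate(vidx):
        jp = vidx[max(0, j - 1)]
        jn = vidx[min(len(vidx) - 1, j + 1)]
        step = sm_c[jn] - sm_c[jp]
        span = max(jn - jp, 1)
        if np.linalg.norm(step) / span < min_step_px:
            v = orientations[i]
            # Orientation sign is ambiguous; align with overall travel if any.
            travel = sm_c[vidx[-1]] - sm_c[vidx[0]]
            if np.linalg.norm(travel) > min_step_px and v @ travel < 0:
                v = -v
            axis[i] = v / np.linalg.norm(v)
            fallback[i] = True
        else:
            axis[i] = step / np.linalg.norm(step)

    track = BodyTrack(
        centroid_px=np.nan_to_num(centroids),
        length_px=lengths,
        axis=axis,
        valid=valid,
        calibration=stack.calibration,
        axis_fallback=fallback,
    )
    track.masks = masks  # type: ignore[attr-defined]
    return track


# --------------------------------------------------------------------------- #
# footprint detection

def detect_footprints(
    stack: FrameStack,
    background: np.ndarray,
    spot_threshold: float,
    min_area: int = 3,
    max_area: int = 400,
    body_masks: Optional[np.ndarray] = None,
    body_dilate_px: int = 2,
) -> List[List[RawDetection]]:
    """Connected bright components per frame, area-filtered, body excluded.

    Returns one list of :class:`RawDetection` per frame with
    intensity-weighted centroids.  Components overlapping the (dilated) body
    mask are discarded so the body glow is never called a footprint.
    """
    if spot_threshold <= 0 or min_area <= 0 or max_area < min_area:
        raise ValueError("thresholds must be positive and max_area >= min_area")
    out: List[List[RawDetection]] = []
    struct = np.ones((3, 3), dtype=bool)
    for i in range(stack.n_frames):
        diff = subtract_background(stack.frames[i], background)
        mask = diff > spot_threshold
        if body_masks is not None and body_masks[i].any():
            body = ndi.binary_dilation(body_masks[i], struct, iterations=body_dilate_px)
        else:
            body = None
        labels, n_lab = ndi.label(mask)
        dets: List[RawDetection] = []
        for p in measure.regionprops(labels, intensity_image=diff):
            if not min_area <= p.area <= max_area:
                continue
            if body is not None:
                ys, xs = p.coords[:, 0], p.coords[:, 1]
                if body[ys, xs].any():
                    continue
            cy, cx = p.centroid_weighted
            dets.append(RawDetection(frame=i, x_px=float(cx), y_px=float(cy),
                                     area=int(p.area), peak=float(p.intensity_max)))
        out.append(dets)
    return out


# --------------------------------------------------------------------------- #
# leg-identity assignment

def assign_leg_identities(
    detections: Sequence[Sequence[RawDetection]],
    body_track: BodyTrack,
    link_radius_px: float = 2.0,
) -> LabeledTracks:
    """Link detections into contact tracks and label them LF..RH.

    Tracks link detections within ``link_radius_px`` between consecutive
    frames (footprints are stationary in the world, so contacts form tight
    tracks).  A new track is labeled on its first frame: side from the sign
    of its body-frame lateral coordinate (left positive), segment by matching
    its longitudinal coordinate against the label's historical touchdown
    position (or an anatomical prior before history exists), restricted to
    labels not currently in use on that side.  A persisting track keeps its
    label; unresolvable conflicts are flagged for the edit log.
    """
    bl_px = body_track.body_length_px()
    history: Dict[str, List[float]] = {leg: [] for leg in LEGS}
    all_tracks: List[ContactTrack] = []
    active: List[ContactTrack] = []

    for f in range(len(detections)):
        dets = list(detections[f])
        # Match active tracks (alive through the previous frame) to detections.
        alive = [t for t in active if t.last_frame == f - 1]
        matched_dets: set = set()
        matched_tracks: List[ContactTrack] = []
        if alive and dets:
            cost = np.full((len(alive), len(dets)), 1e9)
            for a, tr in enumerate(alive):
                for b, d in enumerate(dets):
                    dist = math.hypot(d.x_px - tr.last_position[0],
                                      d.y_px - tr.last_position[1])
                    if dist <= link_radius_px:
                        cost[a, b] = dist
            rows, cols = linear_sum_assignment(cost)
            for a, b in zip(rows, cols):
                if cost[a, b] < 1e8:
                    alive[a].frames.append(f)
                    alive[a].positions_px.append((dets[b].x_px, dets[b].y_px))
                    matched_dets.add(b)
                    matched_tracks.append(alive[a])

        new_tracks = [
            ContactTrack(frames=[f], positions_px=[(d.x_px, d.y_px)])
            for b, d in enumerate(dets)
            if b not in matched_dets
        ]
        current = matched_tracks + new_tracks
        if len(current) >= 7:
            raise ValueError(f"more than six simultaneous contacts at frame {f}")

        if new_tracks and body_track.valid[f]:
            _label_new_tracks(new_tracks, current, body_track, f, bl_px, history)

        all_tracks.extend(new_tracks)
        active = [t for t in active if t.last_frame >= f - 1] + new_tracks

    return LabeledTracks(tracks=all_tracks, body_track=body_track,
                         calibration=body_track.calibration)


def _label_new_tracks(new_tracks, current, body_track, frame, bl_px, history):
    upx = body_track.calibration.um_per_px
    centroid = body_track.centroid_px[frame]
    axis = body_track.axis[frame]
    by_side: Dict[str, List[ContactTrack]] = {"L": [], "R": []}
    coords: Dict[int, np.ndarray] = {}
    for tr in new_tracks:
        p = world_to_body(np.array(tr.last_position), centroid, axis) / bl_px
        coords[id(tr)] = p
        by_side["L" if p[1] > 0 else "R"].append(tr)

    used = {t.leg for t in current if t.leg is not None}
    for side, side_tracks in by_side.items():
        if not side_tracks:
            continue
        labels = [l for l in (LEFT_LEGS if side == "L" else RIGHT_LEGS)
                  if l not in used]
        if not labels:
            for tr in side_tracks:
                tr.flagged = True
            continue
        refs = []
        for leg in labels:
            if history[leg]:
                refs.append(float(np.mean(history[leg])))
            else:
                refs.append(SEGMENT_PRIOR[leg[1]])
        cost = np.zeros((len(side_tracks), len(labels)))
        for a, tr in enumerate(side_tracks):
            for b in range(len(labels)):
                cost[a, b] = abs(coords[id(tr)][0] - refs[b])
        rows, cols = linear_sum_assignment(cost)
        assigned = set()
        for a, b in zip(rows, cols):
            leg = labels[b]
            side_tracks[a].leg = leg
            history[leg].append(float(coords[id(side_tracks[a])][0]))
            used.add(leg)
            assigned.add(a)
        for a, tr in enumerate(side_tracks):
            if a not in assigned:
                tr.flagged = True


# --------------------------------------------------------------------------- #
# edits

def apply_edits(labeled: LabeledTracks, edits: Sequence[EditRecord]) -> LabeledTracks:
    """Apply an ordered edit log; an empty log is the identity."""
    for idx, rec in enumerate(edits):
        if rec.action == "add":
            labeled.tracks.append(
                ContactTrack(frames=[rec.frame], positions_px=[rec.position_px],
                             leg=rec.leg)
            )
        elif rec.action == "remove":
            tr, j = _find_contact(labeled, rec, idx)
            del tr.frames[j]
            del tr.positions_px[j]
            if not tr.frames:
                labeled.tracks.remove(tr)
        elif rec.action == "relabel":
            tr, _ = _find_contact(labeled, rec, idx)
            target_frames = {
                f for t in labeled.tracks if t.leg == rec.new_leg for f in t.frames
            }
            overlap = target_frames.intersection(tr.frames)
            if overlap:
                raise ValueError(
                    f"edit record {idx}: relabel {rec.leg}->{rec.new_leg} would "
                    f"put two active stances of {rec.new_leg} in frame {min(overlap)}"
                )
            tr.leg = rec.new_leg
    return labeled


def _find_contact(labeled: LabeledTracks, rec: EditRecord, idx: int
                  ) -> Tuple[ContactTrack, int]:
    candidates = []
    for tr in labeled.tracks:
        if tr.leg != rec.leg:
            continue
        for j, f in enumerate(tr.frames):
            if f == rec.frame:
                if rec.position_px is not None:
                    d = math.hypot(tr.positions_px[j][0] - rec.position_px[0],
                                   tr.positions_px[j][1] - rec.position_px[1])
                    candidates.append((d, tr, j))
                else:
                    candidates.append((0.0, tr, j))
    if not candidates:
        raise ValueError(
            f"edit record {idx}: no detection of {rec.leg} at frame {rec.frame}"
        )
    candidates.sort(key=lambda c: c[0])
    return candidates[0][1], candidates[0][2]


def load_edit_log(path) -> List[EditRecord]:
    import json
    from pathlib import Path

    data = json.loads(Path(path).read_text())
    return [EditRecord.from_dict(d) for d in data]


# --------------------------------------------------------------------------- #
# stance extraction

def extract_step_pattern(
    labeled: LabeledTracks,
    min_stance_frames: int = 2,
    max_gap_frames: int = 1,
) -> StepPattern:
    """Contiguous contact runs -> half-open stance intervals per leg.

    Gaps of at most ``max_gap_frames`` are bridged; runs shorter than
    ``min_stance_frames`` are dropped.  Each interval carries the mean world
    footprint position in micrometres.
    """
    cal = labeled.calibration
    dt = cal.frame_interval_ms
    upx = cal.um_per_px
    legs: Dict[str, List[StanceEvent]] = {leg: [] for leg in LEGS}
    for leg in LEGS:
        contacts = labeled.contacts(leg)
        if not contacts:
            continue
        frames = sorted(contacts)
        runs: List[List[int]] = [[frames[0]]]
        for f in frames[1:]:
            if f - runs[-1][-1] <= max_gap_frames + 1 and f - runs[-1][-1] >= 1:
                runs[-1].append(f)
            elif f == runs[-1][-1]:
                continue
            else:
                runs.append([f])
        for run in runs:
            if run[-1] - run[0] + 1 < min_stance_frames:
                continue
            pos = np.mean([contacts[f] for f in run], axis=0) * upx
            legs[leg].append(
                StanceEvent(
                    onset_ms=run[0] * dt,
                    offset_ms=(run[-1] + 1) * dt,
                    x_um=float(pos[0]),
                    y_um=float(pos[1]),
                )
            )
    return StepPattern(legs=legs, fps=cal.fps)


# --------------------------------------------------------------------------- #
# convenience pipeline

def track_video(
    stack: FrameStack,
    n_pre_entry: int = 20,
    spot_mad_mult: float = 8.0,
    body_mad_mult: float = 2.0,
    min_area: int = 3,
    max_area: int = 400,
    min_stance_frames: int = 2,
    max_gap_frames: int = 1,
    link_radius_px: float = 2.0,
    edits: Sequence[EditRecord] = (),
    background_method: str = "max",
) -> Tuple[StepPattern, BodyTrack, dict]:
    """Full tracking pass with MAD-relative thresholds; returns provenance too."""
    background = estimate_background(stack, n_pre_entry, method=background_method)
    mad = noise_mad(stack, background, max(n_pre_entry, 1))
    spot_thr = spot_mad_mult * mad
    body_thr = body_mad_mult * mad
    body = track_body(stack, background, body_thr)
    dets = detect_footprints(stack, background, spot_thr, min_area=min_area,
                             max_area=max_area,
                             body_masks=getattr(body, "masks", None))
    labeled = assign_leg_identities(dets, body, link_radius_px=link_radius_px)
    labeled = apply_edits(labeled, edits)
    pattern = extract_step_pattern(labeled, min_stance_frames=min_stance_frames,
                                   max_gap_frames=max_gap_frames)
    provenance = {
        "n_pre_entry": n_pre_entry,
        "noise_mad": mad,
        "spot_threshold": spot_thr,
        "body_threshold": body_thr,
        "n_detections": int(sum(len(d) for d in dets)),
        "n_tracks": len(labeled.tracks),
        "n_flagged_tracks": int(sum(t.flagged for t in labeled.tracks)),
        "n_edits": len(edits),
    }
    return pattern, body, provenance
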