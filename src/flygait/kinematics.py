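"""Temporal step parameters: speeds, periods, stance/swing durations,
step lengths, swing speeds, metachronal lags and inter-leg phases."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import LEGS, BodyTrack, Calibration, StepPattern


@dataclass
class SpeedSeries:
    """Instantaneous body speed (mm/s) on the frame grid plus the average."""

    t_ms: np.ndarray
    mm_s: np.ndarray            # NaN where the body is invalid
    edge: np.ndarray            # True where the window was truncated
    average_mm_s: float


def speeds(body_track: BodyTrack, calibration: Optional[Calibration] = None,
           integration_ms: float = 25.0) -> SpeedSeries:
    """Centered-window instantaneous speed and path-length average speed.

    Speed at frame t is the centroid displacement across a centered window of
    ``integration_ms`` divided by the elapsed time; edge frames use truncated
    windows and are flagged.  The average speed is total path length over
    total duration (both over valid frames).
    """
    cal = calibration if calibration is not None else body_track.calibration
    dt = cal.frame_interval_ms
    if integration_ms < 2 * dt:
        raise ValueError("integration_ms must span at least 2 frame intervals")
    vidx = np.nonzero(body_track.valid)[0]
    if len(vidx) < 2:
        raise ValueError("need at least 2 valid body frames")
    if integration_ms > (vidx[-1] - vidx[0]) * dt:
        raise ValueError("integration window is longer than the video")

    half = int(round(integration_ms / 2.0 / dt))
    n = body_track.n_frames
    c_um = body_track.centroid_px * cal.um_per_px
    v = np.full(n, np.nan)
    edge = np.zeros(n, dtype=bool)
    pos = {i: j for j, i in enumerate(vidx)}
    for i in vidx:
        j = pos[i]
        j0, j1 = max(0, j - half), min(len(vidx) - 1, j + half)
        if j1 == j0:
            continue
        i0, i1 = vidx[j0], vidx[j1]
        dist = float(np.linalg.norm(c_um[i1] - c_um[i0]))
        v[i] = dist / ((i1 - i0) * dt)  # um/ms == mm/s
        edge[i] = (j - j0 != half) or (j1 - j != half)

    steps = np.linalg.norm(np.diff(c_um[vidx], axis=0), axis=1)
    path = float(steps.sum())
    duration = (vidx[-1] - vidx[0]) * dt
    avg = path / duration
    t_ms = np.arange(n) * dt
    return SpeedSeries(t_ms=t_ms, mm_s=v, edge=edge, average_mm_s=avg)


def _complete_events(pattern: StepPattern, leg: str):
    """Leg events with a leading clipped remnant dropped.

    A record that starts mid-stance leaves a truncated first interval whose
    onset is not a real touchdown; it is detected as a first event much
    shorter than the leg's typical stance and excluded from cycle-based
    parameters.
    """
    events = pattern.events(leg)
    if len(events) >= 2:
        durations = [e.duration_ms for e in events]
        ref = float(np.median(durations[1:])) if len(events) > 2 else durations[1]
        if events[0].onset_ms <= 1e-9 and durations[0] < 0.5 * ref:
            events = events[1:]
    return events


def step_timings(pattern: StepPattern) -> pd.DataFrame:
    """Per-leg per-cycle period, stance, swing and duty factor (ms).

    A cycle runs touchdown-to-touchdown; the trailing incomplete cycle (the
    last stance, which has no following touchdown) is excluded, as is a
    leading clipped stance remnant.
    """
    rows = []
    for leg in LEGS:
        events = _complete_events(pattern, leg)
        for i in range(len(events) - 1):
            a, b = events[i], events[i + 1]
            period = b.onset_ms - a.onset_ms
            stance = a.duration_ms
            swing = b.onset_ms - a.offset_ms
            rows.append({
                "leg": leg,
                "cycle": i,
                "touchdown_ms": a.onset_ms,
                "period_ms": period,
                "stance_ms": stance,
                "swing_ms": swing,
                "duty_factor": stance / period,
            })
    return pd.DataFrame(rows, columns=["leg", "cycle", "touchdown_ms",
                                       "period_ms", "stance_ms", "swing_ms",
                                       "duty_factor"])


def step_lengths(pattern: StepPattern) -> pd.DataFrame:
    """Per-cycle step length (um) and swing speed (mm/s).

    Step length is the world-frame Euclidean distance between consecutive
    touchdown positions of the same leg; swing speed divides it by the
    intervening swing duration.
    """
    rows = []
    for leg in LEGS:
        events = _complete_events(pattern, leg)
        for i in range(len(events) - 1):
            a, b = events[i], events[i + 1]
            if math.isnan(a.x_um) or math.isnan(b.x_um):
                continue
            d = math.hypot(b.x_um - a.x_um, b.y_um - a.y_um)
            swing = b.onset_ms - a.offset_ms
            rows.append({
                "leg": leg,
                "cycle": i,
                "step_length_um": d,
                "swing_ms": swing,
                "swing_speed_mm_s": d / swing if swing > 0 else np.nan,
            })
    return pd.DataFrame(rows, columns=["leg", "cycle", "step_length_um",
                                       "swing_ms", "swing_speed_mm_s"])


def metachronal_lags(pattern: StepPattern, side: str, tol_ms: float = 1e-9
                     ) -> List[float]:
    """Hind-to-fore ipsilateral swing-onset lags (ms), one per wave.

    For each hindleg swing onset, the lag to the first ipsilateral foreleg
    swing onset strictly after it; simultaneous onsets are skipped (so an
    ideal alternating-tripod pattern yields lag = period) and waves with no
    subsequent foreleg onset are dropped.
    """
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    # A stance clipped by the end of the record leaves a false swing onset at
    # the record boundary; drop offsets that coincide with it.
    t_clip = pattern.t_end_ms
    hind = pattern.swing_onsets_ms(side + "H")
    hind = hind[hind < t_clip - tol_ms]
    fore = np.sort(pattern.swing_onsets_ms(side + "F"))
    fore = fore[fore < t_clip - tol_ms]
    lags = []
    for t in hind:
        later = fore[fore > t + tol_ms]
        if len(later):
            lags.append(float(later[0] - t))
    return lags


def phases(pattern: StepPattern, leg_x: str, leg_y: str) -> List[float]:
    """Per-cycle phase of ``leg_y`` within each complete cycle of ``leg_x``.

    phase = (first touchdown of y at/after x's touchdown - x's touchdown)
    divided by that cycle's period, reduced mod 1.
    """
    on_x = pattern.onsets_ms(leg_x)
    on_y = np.sort(pattern.onsets_ms(leg_y))
    out = []
    for i in range(len(on_x) - 1):
        t, t_next = on_x[i], on_x[i + 1]
        period = t_next - t
        later = on_y[on_y >= t - 1e-9]
        if len(later) == 0:
            continue
        out.append(float(((later[0] - t) / period) % 1.0))
    return out
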