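"""Per-frame leg-combination coding, gait classification and gait indexes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import LEGS, StepPattern

#: Canonical tripod codes: {LF, LH, RM} in stance vs the complementary triplet.
TRIPOD_CODES = frozenset({"101010", "010101"})

#: Canonical tetrapod codes: two contralateral, segment-offset legs in swing,
#: enumerating the right- and left-handed swing-pair cycles.
TETRAPOD_CODES = frozenset(
    {"101110", "011101", "110011", "110101", "101011", "011110"}
)

CLASS_TRIPOD = "tripod"
CLASS_TETRAPOD = "tetrapod"
CLASS_NONCANONICAL = "noncanonical"

_SCORE = {CLASS_TRIPOD: 1.0, CLASS_TETRAPOD: -1.0, CLASS_NONCANONICAL: 0.0}


@dataclass
class GaitMap:
    """Per-frame combination code, class and stance count."""

    codes: List[str]
    classes: List[str]
    fps: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.codes) != len(self.classes):
            raise ValueError("codes and classes must align")

    @property
    def n_frames(self) -> int:
        return len(self.codes)

    @property
    def stance_counts(self) -> np.ndarray:
        return np.array([c.count("1") for c in self.codes], dtype=int)

    @property
    def pentapod(self) -> np.ndarray:
        """Exactly one leg in swing."""
        return self.stance_counts == 5

    @property
    def all_stance(self) -> np.ndarray:
        return self.stance_counts == 6


@dataclass
class GaitSummary:
    average_gait_index: float
    tripod_index_pct: float
    tetrapod_index_pct: float
    pentapod_pct: float
    n_frames: int
    frequency_table: pd.DataFrame = field(repr=False)


def validate_code(code: str) -> str:
    if len(code) != 6 or any(ch not in "01" for ch in code):
        raise ValueError(f"malformed combination code {code!r}")
    return code


def frame_codes(pattern: StepPattern, n_frames: int, fps: Optional[float] = None) -> List[str]:
    """6-bit stance code per frame, digit order LF LM LH RF RM RH.

    A digit is 1 iff the leg has a stance interval covering the frame's
    timestamp under the half-open [onset, offset) convention.
    """
    fps = fps if fps is not None else pattern.fps
    if fps is None or fps <= 0:
        raise ValueError("frame_codes needs a positive fps (argument or pattern.fps)")
    dt = 1000.0 / fps
    codes = []
    for i in range(n_frames):
        t = i * dt
        codes.append("".join("1" if pattern.in_stance(leg, t) else "0" for leg in LEGS))
    return codes


def classify(code: str) -> str:
    validate_code(code)
    if code in TRIPOD_CODES:
        return CLASS_TRIPOD
    if code in TETRAPOD_CODES:
        return CLASS_TETRAPOD
    return CLASS_NONCANONICAL


def build_gait_map(pattern: StepPattern, n_frames: int, fps: Optional[float] = None) -> GaitMap:
    codes = frame_codes(pattern, n_frames, fps=fps)
    return GaitMap(codes=codes, classes=[classify(c) for c in codes],
                   fps=fps if fps is not None else pattern.fps)


def contact_span(gait_map: GaitMap) -> Tuple[int, int]:
    """Half-open frame range from first to last frame with any contact.

    Frames before the first and after the last tracked contact carry no gait
    information and are excluded from the indexes.
    """
    counts = gait_map.stance_counts
    nz = np.nonzero(counts > 0)[0]
    if len(nz) == 0:
        return (0, 0)
    return int(nz[0]), int(nz[-1]) + 1


def gait_index(gait_map: GaitMap, window: int = 8) -> Tuple[np.ndarray, float]:
    """Sliding gait index and the per-video average.

    Each frame scores +1 (tripod), -1 (tetrapod) or 0 (noncanonical).  The
    sliding series is the mean score over a trailing window of ``window``
    frames (the first ``window - 1`` frames average the partial window); the
    average gait index is the mean of the raw per-frame scores across the
    contact span.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    lo, hi = contact_span(gait_map)
    scores = np.array([_SCORE[c] for c in gait_map.classes], dtype=float)
    series = np.full(len(scores), np.nan)
    for i in range(lo, hi):
        j0 = max(lo, i - window + 1)
        series[i] = scores[j0 : i + 1].mean()
    average = float(scores[lo:hi].mean()) if hi > lo else float("nan")
    return series, average


def gait_summary(gait_map: GaitMap, window: int = 8) -> GaitSummary:
    """Tripod/tetrapod indexes, average gait index and combination table."""
    lo, hi = contact_span(gait_map)
    n = hi - lo
    if n < 1:
        raise ValueError("gait map has no frames with tracked contacts")
    codes = gait_map.codes[lo:hi]
    classes = gait_map.classes[lo:hi]

    counts: Dict[str, int] = {}
    for c in codes:
        counts[c] = counts.get(c, 0) + 1
    rows = [
        {
            "code": code,
            "class": classify(code),
            "pentapod": code.count("1") == 5,
            "pct": 100.0 * k / n,
        }
        for code, k in counts.items()
    ]
    table = pd.DataFrame(rows).sort_values("pct", ascending=False, kind="stable")
    table = table.reset_index(drop=True)

    tripod = 100.0 * sum(cl == CLASS_TRIPOD for cl in classes) / n
    tetrapod = 100.0 * sum(cl == CLASS_TETRAPOD for cl in classes) / n
    pentapod = 100.0 * sum(c.count("1") == 5 for c in codes) / n
    _, average = gait_index(gait_map, window=window)
    return GaitSummary(
        average_gait_index=average,
        tripod_index_pct=tripod,
        tetrapod_index_pct=tetrapod,
        pentapod_pct=pentapod,
        n_frames=n,
        frequency_table=table,
    )
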