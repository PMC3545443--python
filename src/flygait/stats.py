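"""Circular statistics for leg phases and the least-squares fits used in plots."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class CircularSummary:
    """Mean phase, mean resultant length and (optionally) Rayleigh p."""

    mean_phase: float
    r: float
    n: int
    p: Optional[float] = None


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r: float
    n: int


def circular_mean(phases: Sequence[float]) -> CircularSummary:
    """Circular mean of phase values on [0, 1).

    Phases are mapped to angles ``theta = 2*pi*phase``; ``r`` is the length of
    the mean unit vector and the mean phase is the mean-vector angle mapped
    back to [0, 1).
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("circular_mean requires at least one phase value")
    theta = 2.0 * math.pi * phases
    c = float(np.mean(np.cos(theta)))
    s = float(np.mean(np.sin(theta)))
    r = min(math.hypot(c, s), 1.0)
    mean = math.atan2(s, c) / (2.0 * math.pi) % 1.0
    if mean >= 1.0:  # tiny negative angles round up to exactly 1.0 under mod
        mean = 0.0
    return CircularSummary(mean_phase=mean, r=r, n=int(phases.size))


def rayleigh_p(n: int, r: float) -> float:
    """Rayleigh-test p value for uniformity, series approximation.

    With ``Z = n * r**2``::

        p = exp(-Z) * [1 + (2Z - Z^2)/(4n)
                         - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]

    clipped to (0, 1].
    """
    if n < 2:
        raise ValueError("rayleigh_p requires n >= 2")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    z = n * r * r
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))


def circular_summary(phases: Sequence[float]) -> CircularSummary:
    """Circular mean plus Rayleigh p (p omitted when n < 2)."""
    base = circular_mean(phases)
    p = rayleigh_p(base.n, base.r) if base.n >= 2 else None
    return CircularSummary(mean_phase=base.mean_phase, r=base.r, n=base.n, p=p)


def ols_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares line with Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("ols_fit requires n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    res = sps.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r=float(res.rvalue), n=int(x.size))
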