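"""Sequential effect existence and significance testing (SEXIT) summaries.

Given a vector of posterior draws for one effect, the reporting quadruple is:
the posterior median E_M, the highest density interval (HDI) of the full
posterior, the probability of direction D_p, and the proportion ROPE_p of the
full posterior inside the region of practical equivalence. For linear models
the ROPE is +/- 0.05 * SD(y), with SD(y) the standard deviation of the
dependent variable. An effect with ROPE_p < 2.5% is declared not practically
equivalent to zero. Reports are rendered as "E_M (low, high), D_p, ROPE_p".

This module consumes posterior draws; fitting the Bayesian models that
produce them is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

#: decision threshold: effects with ROPE_p below this are "not practically
#: equivalent to zero"
ROPE_DECISION_THRESHOLD = 0.025
#: half-width of the ROPE as a multiple of SD(y)
ROPE_SD_MULTIPLIER = 0.05


def _validate_draws(draws: np.ndarray, min_len: int = 1) -> np.ndarray:
    d = np.asarray(draws, dtype=float).ravel()
    if d.size < min_len:
        raise ValueError(f"need at least {min_len} draws, got {d.size}")
    if not np.all(np.isfinite(d)):
        raise ValueError("draws must be finite")
    return d


def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` of the sorted draws.

    Implemented as a sliding-window minimum-width search over the sorted
    sample; ties in width resolve to the left-most (lowest) window.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    d = np.sort(_validate_draws(draws, min_len=math.ceil(1.0 / (1.0 - mass))))
    n = d.size
    k = math.ceil(mass * n)
    widths = d[k - 1 :] - d[: n - k + 1]
    i = int(np.argmin(widths))
    return float(d[i]), float(d[i + k - 1])


def probability_of_direction(draws) -> float:
    """D_p: the larger of the positive and negative posterior fractions.

    Exact zeros are split evenly between the two directions, so D_p is in
    [0.5, 1].
    """
    d = _validate_draws(draws)
    # integer counts keep the result exact (and sign-symmetric) in floats
    n_pos = 2 * int(np.count_nonzero(d > 0)) + int(np.count_nonzero(d == 0))
    n2 = 2 * d.size
    return max(n_pos, n2 - n_pos) / n2


def rope_bounds(sd_y: float) -> tuple[float, float]:
    """Region of practical equivalence: +/- 0.05 * SD of the outcome."""
    if sd_y <= 0:
        raise ValueError(f"sd_y must be > 0, got {sd_y}")
    half = ROPE_SD_MULTIPLIER * sd_y
    return (-half, half)


@dataclass
class SexitSummary:
    """The SEXIT reporting quadruple plus the practical-equivalence decision."""

    e_m: float
    hdi_low: float
    hdi_high: float
    hdi_mass: float
    d_p: float
    rope_low: float
    rope_high: float
    rope_p: float
    decision: bool  # True = not practically equivalent to zero

    def report(self, digits: int = 2) -> str:
        return (
            f"{self.e_m:.{digits}f} ({self.hdi_low:.{digits}f}, "
            f"{self.hdi_high:.{digits}f}), {self.d_p:.{digits}f}, "
            f"{self.rope_p:.{digits}f}"
        )

    def to_dict(self) -> dict:
        return asdict(self)


def sexit_summary(
    draws,
    sd_y: float,
    mass: float = 0.95,
    min_draws: int = 100,
    rope_within_hdi: bool = False,
) -> SexitSummary:
    """Assemble the full SEXIT summary from posterior draws.

    ROPE membership uses the closed interval (bound values count as inside —
    conservative for the decision). ``rope_within_hdi=True`` restricts the
    ROPE proportion to draws inside the HDI instead of the full posterior.
    """
    d = _validate_draws(draws, min_len=max(min_draws, math.ceil(1.0 / (1.0 - mass))))
    lo, hi = hdi(d, mass)
    r_lo, r_hi = rope_bounds(sd_y)
    pool = d[(d >= lo) & (d <= hi)] if rope_within_hdi else d
    rope_p = float(np.mean((pool >= r_lo) & (pool <= r_hi)))
    return SexitSummary(
        e_m=float(np.median(d)),
        hdi_low=lo,
        hdi_high=hi,
        hdi_mass=mass,
        d_p=probability_of_direction(d),
        rope_low=r_lo,
        rope_high=r_hi,
        rope_p=rope_p,
        decision=bool(rope_p < ROPE_DECISION_THRESHOLD),
    )
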