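"""Count statistics for metaphase-spread readouts.

Chromosomal aberrations per cell are modelled as Poisson counts: with x total
aberrations over N cells the rate is x/N and its standard error sqrt(x)/N
(the SE of a Poisson total divided by N).  Sister chromatid exchange (SCE)
distributions are compared with the two-sided Mann-Whitney U test, and
UV-induced SCE is obtained by subtracting the spontaneous mean from the
post-irradiation mean with errors added in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DataError
from .spectra import round_half_up


@dataclass(frozen=True)
class AberrationCount:
    """Aberrations scored over N metaphase spreads of one line."""

    label: str
    n_cells: int
    chromatid_gaps: int = 0
    chromatid_breaks: int = 0
    isochromatid_gaps: int = 0
    isochromatid_breaks: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise DataError("aberration count requires N >= 1 cells")
        if min(self.chromatid_gaps, self.chromatid_breaks, self.isochromatid_gaps, self.isochromatid_breaks) < 0:
            raise DataError("negative aberration count")

    @property
    def total(self) -> int:
        return (
            self.chromatid_gaps
            + self.chromatid_breaks
            + self.isochromatid_gaps
            + self.isochromatid_breaks
        )


@dataclass(frozen=True)
class RateEstimate:
    """Poisson mean and SE per cell, with the 2-decimal presentation values."""

    mean: float
    se: float

    @property
    def mean_2dp(self) -> float:
        return round_half_up(self.mean, 2)

    @property
    def se_2dp(self) -> float:
        return round_half_up(self.se, 2)

    def __str__(self) -> str:
        return f"{self.mean_2dp:.2f}±{self.se_2dp:.2f}"


def poisson_rate(x: int | AberrationCount, n_cells: int | None = None) -> RateEstimate:
    """Aberrations per cell as x/N with SE sqrt(x)/N.

    Accepts either an :class:`AberrationCount` or the pair ``(x, n_cells)``.
    """
    if isinstance(x, AberrationCount):
        count, n = x.total, x.n_cells
    else:
        if n_cells is None:
            raise DataError("poisson_rate needs n_cells when given a bare total")
        count, n = int(x), int(n_cells)
    if n < 1:
        raise DataError("poisson_rate requires N >= 1")
    if count < 0:
        raise DataError("poisson_rate requires x >= 0")
    return RateEstimate(count / n, math.sqrt(count) / n)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # the classic statistic, min(U_a, U_b)
    u_a: float
    p: float
    method: str  # exact | asymptotic


def _exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements giving each U value, by the standard
    recurrence f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u)."""
    max_u = n1 * n2
    table = {(0, 0): np.ones(1)}
    for a in range(n1 + 1):
        for b in range(n2 + 1):
            if (a, b) in table:
                continue
            dist = np.zeros(a * b + 1)
            if a > 0:
                prev = table[(a - 1, b)]
                dist[b : b + len(prev)] += prev
            if b > 0:
                prev = table[(a, b - 1)]
                dist[: len(prev)] += prev
            table[(a, b)] = dist
    full = np.zeros(max_u + 1)
    d = table[(n1, n2)]
    full[: len(d)] = d
    return full


def _has_ties(a: Sequence[float], b: Sequence[float]) -> bool:
    pooled = list(a) + list(b)
    return len(set(pooled)) != len(pooled)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution (two-sided p as twice the one-sided
    tail, capped at 1) when ``min(n_a, n_b) <= 8`` and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    a = list(a)
    b = list(b)
    if not a or not b:
        raise DataError("mann_whitney requires two non-empty samples")
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(a + b)
    r1 = float(ranks[:n1].sum())
    u_a = r1 - n1 * (n1 + 1) / 2.0
    u_b = n1 * n2 - u_a
    u_min = min(u_a, u_b)
    if min(n1, n2) <= 8 and not _has_ties(a, b):
        dist = _exact_u_distribution(n1, n2)
        total = dist.sum()
        tail = dist[: int(u_min) + 1].sum() / total
        p = min(1.0, 2.0 * tail)
        return MannWhitneyResult(u_min, u_a, float(p), "exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return MannWhitneyResult(u_min, u_a, float(res.pvalue), "asymptotic")


# ---------------------------------------------------------------------------
# SCE summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SCESample:
    """Per-cell SCE counts for one condition (50 metaphases in the study)."""

    condition: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise DataError(f"SCE sample {self.condition!r} is empty")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise DataError(f"SCE sample {self.condition!r}: counts must be non-negative integers")

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sem(self) -> float:
        if len(self.counts) == 1:
            return 0.0
        return float(np.std(self.counts, ddof=1) / math.sqrt(len(self.counts)))


@dataclass(frozen=True)
class InducedEstimate:
    mean: float
    se: float


def induced_sce(treated: SCESample, control: SCESample) -> InducedEstimate:
    """UV-induced SCE: treated mean minus spontaneous mean, SEs in quadrature."""
    return InducedEstimate(
        treated.mean - control.mean,
        math.sqrt(treated.sem**2 + control.sem**2),
    )
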