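"""2×2 contingency utilities and the network-score transform.

Two clinical/enrichment statistics accompany the expression pipeline: exact
and chi-squared tests on 2×2 tables (e.g. miRNA detection state against a
perinatal outcome such as periventricular leukomalacia), and the network
score used by pathway-analysis software, which is simply ``−log10`` of a
right-tailed Fisher exact p (so p = 1e−24 scores 24).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = exposure, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("at least one margin must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def degenerate(self) -> bool:
        """True when a full row or column is zero (association undefined)."""
        t = self.to_array()
        return bool((t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any())


@dataclass(frozen=True)
class ScoreResult:
    p: float
    network_score: float


def network_score(p: float) -> ScoreResult:
    """Network score ``−log10(p)`` of an enrichment p-value.

    Strictly decreasing in p, zero at p = 1; inputs outside ``(0, 1]`` are a
    domain error (no clamping — a zero p would be an upstream bug, not an
    infinitely significant network).
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return ScoreResult(float(p), -math.log10(p))


@dataclass(frozen=True)
class FisherResult:
    p: float
    odds_ratio: float
    alternative: str
    degenerate: bool


def fisher_exact(table: ContingencyTable2x2, alternative: str = "two-sided") -> FisherResult:
    """Fisher's exact test on a 2×2 table.

    The two-sided p sums the probabilities of all tables (with the observed
    margins) whose hypergeometric point mass does not exceed the observed
    one; ``"greater"`` gives the right tail.  A degenerate margin yields
    p = 1 with the ``degenerate`` flag set.
    """
    if table.degenerate:
        return FisherResult(1.0, float("nan"), alternative, True)
    odds, p = stats.fisher_exact(table.to_array(), alternative=alternative)
    return FisherResult(float(p), float(odds), alternative, False)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p: float
    continuity_correction: bool


def chi_square_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-squared test (1 df) on a 2×2 table.

    Yates continuity correction is off by default.  Requires all expected
    counts positive; a zero expected cell raises with a pointer to
    :func:`fisher_exact`.
    """
    arr = table.to_array()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected == 0).any():
        raise ValueError("zero expected count; use fisher_exact instead")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=continuity_correction)
    return ChiSquareResult(float(chi2), float(p), continuity_correction)
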