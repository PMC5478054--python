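"""Premating (sexual) isolation statistics from multiple-choice mating tests.

A two-strain multiple-choice test yields four mating counts: n11 (female A x
male A), n12 (female A x male B), n21 (female B x male A), n22 (female B x
male B), with total n.  From these the module computes:

* the joint isolation index  I  = (n11 + n22 - n12 - n21) / n,
  which is 0 under random mating, +1 under complete assortative (homotypic)
  mating and -1 under complete disassortative mating;
* the female-side indices for each strain,
  I1 = (n11 - n12) / (n11 + n12)  and  I2 = (n22 - n21) / (n22 + n21),
  measuring whether each strain's females favour homotypic males;
* the large-sample standard error  SE = sqrt((1 - I^2) / n), using the
  pair's total mating count n for all three indices;
* a Pearson chi-square test of the 1:1:1:1 random-mating expectation
  (df = 3, no continuity correction).

An index is flagged significant when |index| >= 2 * SE, evaluated on the
unrounded values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .io_formats import MatingTrialRow, MatingTrialTable

__all__ = [
    "UndefinedStatisticError",
    "IsolationResult",
    "joint_isolation_index",
    "sex_specific_indices",
    "isolation_se",
    "random_mating_chi2",
    "analyze_pair",
    "analyze_table",
]


class UndefinedStatisticError(ValueError):
    """A statistic was requested for data on which it is undefined."""


Counts = tuple[int, int, int, int]


@dataclass(frozen=True)
class IsolationResult:
    """Premating isolation statistics for one strain pair.

    ``I1``/``I2`` (and their SEs and flags) are ``None`` when the relevant
    female class produced no matings at all, in which case the index has a
    zero denominator and is undefined rather than zero.
    """

    pair: tuple[str, str]
    n: int
    I: float
    se_I: float
    I1: float | None
    se_I1: float | None
    I2: float | None
    se_I2: float | None
    chi2: float
    df: int
    p_value: float
    significant_I: bool
    significant_I1: bool | None
    significant_I2: bool | None
    n_reported: int | None = None

    @property
    def n_mismatch(self) -> bool:
        return self.n_reported is not None and self.n_reported != self.n


def _total(counts: Counts) -> int:
    n = sum(counts)
    if n <= 0:
        raise UndefinedStatisticError(
            "isolation statistics are undefined for zero total matings"
        )
    return n


def joint_isolation_index(counts: Counts) -> float:
    """Joint isolation index (homotypic minus heterotypic over total)."""
    n11, n12, n21, n22 = counts
    n = _total(counts)
    return (n11 + n22 - n12 - n21) / n


def sex_specific_indices(counts: Counts) -> tuple[float | None, float | None]:
    """Female-side isolation indices (I1, I2); None where the denominator is 0."""
    n11, n12, n21, n22 = counts
    i1 = (n11 - n12) / (n11 + n12) if n11 + n12 > 0 else None
    i2 = (n22 - n21) / (n22 + n21) if n22 + n21 > 0 else None
    return i1, i2


def isolation_se(index: float, n: int) -> float:
    """Large-sample standard error sqrt((1 - I^2) / n) of an isolation index."""
    if n <= 0:
        raise UndefinedStatisticError("SE undefined for n = 0")
    if abs(index) > 1:
        raise ValueError(f"index {index} outside [-1, 1]")
    return math.sqrt((1.0 - index * index) / n)


def random_mating_chi2(counts: Counts) -> tuple[float, int, float]:
    """Pearson chi-square of the four counts against 1:1:1:1 (df = 3)."""
    _total(counts)
    chi2, p = stats.chisquare(list(counts))
    return float(chi2), 3, float(p)


def _significant(index: float | None, se: float | None) -> bool | None:
    if index is None or se is None:
        return None
    # Degenerate |I| = 1 gives SE = 0: complete isolation counts as
    # significant even though both sides are then 0 vs 0 at I = 0 only.
    return abs(index) >= 2.0 * se


def analyze_pair(row: MatingTrialRow) -> IsolationResult:
    """All premating-isolation statistics for one strain pair.

    All three standard errors use the pair's total mating count ``n`` (the
    sample size of the whole choice test), not the index-specific
    denominators.
    """
    counts = row.counts
    n = _total(counts)
    I = joint_isolation_index(counts)
    i1, i2 = sex_specific_indices(counts)
    se = isolation_se(I, n)
    se1 = isolation_se(i1, n) if i1 is not None else None
    se2 = isolation_se(i2, n) if i2 is not None else None
    chi2, df, p = random_mating_chi2(counts)
    return IsolationResult(
        pair=(row.strain_a, row.strain_b),
        n=n,
        I=I,
        se_I=se,
        I1=i1,
        se_I1=se1,
        I2=i2,
        se_I2=se2,
        chi2=chi2,
        df=df,
        p_value=p,
        significant_I=bool(_significant(I, se)),
        significant_I1=_significant(i1, se1),
        significant_I2=_significant(i2, se2),
        n_reported=row.n_reported,
    )


def analyze_table(table: MatingTrialTable) -> list[IsolationResult]:
    """Analyze every strain pair of a mating-trial table, in input order."""
    return [analyze_pair(row) for row in table]
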