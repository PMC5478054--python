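"""Postzygotic isolation statistics for reciprocal crosses.

Each directed cross (mother strain x father strain) contributes pooled
offspring counts by sex and a count of dissected F1 males with at least one
motile sperm.  Two summaries are computed per cross:

* a Pearson chi-square test of the 1:1 offspring sex ratio (df = 1, no
  continuity correction), a biased ratio being one signature of hybrid
  incompatibility (dead or missing sons);
* the fraction of dissected males with motile sperm, with an exact
  Clopper-Pearson 95% confidence interval, and a coarse fertility category:

  - ``sterile``  — no dissected male had motile sperm;
  - ``fertile``  — the Clopper-Pearson lower bound on the motile fraction is
    at least 0.85 (the data are consistent only with near-universal
    motility; a fully motile cross qualifies at every dissection size from
    about 25 males up, covering the 28-70 range these experiments use);
  - ``reduced``  — anything in between;
  - ``unknown``  — no males were dissected.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io_formats import CrossRecord, CrossTable
from .mating import UndefinedStatisticError

__all__ = [
    "FertilityResult",
    "sex_ratio_chi2",
    "motility_summary",
    "analyze_crosses",
    "FERTILE_LOWER_BOUND",
]

# The Clopper-Pearson 95% lower confidence bound on the motile fraction must
# reach this value for a cross to be called fertile outright.
FERTILE_LOWER_BOUND = 0.85


@dataclass(frozen=True)
class FertilityResult:
    cross: tuple[str, str]
    total_offspring: int
    chi2_sex: float
    df: int
    p_value: float
    motile_fraction: float | None
    motile_ci: tuple[float, float] | None
    category: str


def sex_ratio_chi2(females: int, males: int) -> tuple[float, int, float]:
    """Pearson chi-square of offspring sex counts against 1:1 (df = 1)."""
    if females + males <= 0:
        raise UndefinedStatisticError("sex-ratio test undefined for zero offspring")
    chi2, p = stats.chisquare([females, males])
    return float(chi2), 1, float(p)


def motility_summary(record: CrossRecord) -> FertilityResult:
    """Sex-ratio test plus sperm-motility fraction, CI and category."""
    chi2, df, p = sex_ratio_chi2(record.females, record.males)
    n = record.males_dissected
    x = record.males_motile
    if n == 0:
        fraction = None
        ci = None
        category = "unknown"
    else:
        fraction = x / n
        low, high = proportion_confint(x, n, alpha=0.05, method="beta")
        ci = (float(low), float(high))
        if x == 0:
            category = "sterile"
        elif ci[0] >= FERTILE_LOWER_BOUND:
            category = "fertile"
        else:
            category = "reduced"
    return FertilityResult(
        cross=(record.mother, record.father),
        total_offspring=record.total_offspring,
        chi2_sex=chi2,
        df=df,
        p_value=p,
        motile_fraction=fraction,
        motile_ci=ci,
        category=category,
    )


def analyze_crosses(table: CrossTable) -> list[FertilityResult]:
    """Summaries for every cross of a table, in input order.

    Replicates of a cross are assumed already pooled into the row's counts
    (a single test per directed cross).
    """
    return [motility_summary(record) for record in table]
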