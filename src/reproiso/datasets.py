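"""Bundled transcriptions of the published result tables.

Two observed datasets ship with the package as CSV fixtures: the fifteen
two-strain multiple-choice mating tests (four mating counts plus the
published total per strain pair) and the six homotypic reciprocal crosses
(pooled offspring sex counts and dissected-male motility).  Alongside each
sits a transcription of the statistics as printed in the source tables,
kept as strings so their printed precision is preserved; these are used only
to cross-check recomputed values and to surface discrepancies, never as a
substitute for computation.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .io_formats import CrossTable, MatingTrialTable, read_cross_records, read_mating_trials

__all__ = [
    "data_path",
    "mating_trials",
    "homotypic_crosses",
    "printed_isolation_stats",
    "printed_cross_stats",
]


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(resources.files("reproiso") / "data" / name)


def mating_trials() -> MatingTrialTable:
    """The fifteen published multiple-choice mating tests.

    Two rows (OAX-SON, TEH-SON) carry a published total that differs from
    the sum of their four counts; reading them emits a data-quality warning
    and the analysis uses the count sum.
    """
    return read_mating_trials(data_path("mating_trials.csv"))


def homotypic_crosses() -> CrossTable:
    """The six published homotypic reciprocal crosses (pooled replicates)."""
    return read_cross_records(data_path("homotypic_crosses.csv"))


def printed_isolation_stats() -> pd.DataFrame:
    """Published isolation statistics, as printed (strings; `sig_*` are 0/1)."""
    return pd.read_csv(data_path("table3_printed.csv"), dtype=str)


def printed_cross_stats() -> pd.DataFrame:
    """Published sex-ratio chi-squares for the homotypic crosses (strings)."""
    return pd.read_csv(data_path("table2a_printed.csv"), dtype=str)
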