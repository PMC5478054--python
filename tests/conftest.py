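import warnings

import pytest

from reproiso import datasets
from reproiso.io_formats import DataQualityWarning


@pytest.fixture(scope="session")
def paper_trials():
    """The bundled 15-pair mating-trial table (data-quality warnings expected)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DataQualityWarning)
        return datasets.mating_trials()


@pytest.fixture(scope="session")
def paper_crosses():
    return datasets.homotypic_crosses()


@pytest.fixture(scope="session")
def printed_isolation():
    return datasets.printed_isolation_stats()


@pytest.fixture(scope="session")
def printed_crosses():
    return datasets.printed_cross_stats()


# Statistics known not to match their printed values, from transcription or
# typesetting slips in the source tables.  Keys are (pair, statistic name).
TRANSPOSED_I1_I2 = {frozenset({"BAJ", "GUR"})}
DISCREPANT = {
    (frozenset({"OAX", "TEH"}), "chi2"),
    (frozenset({"TEH", "SON"}), "chi2"),
    (frozenset({"OAX", "SON"}), "chi2"),
    (frozenset({"OAX", "SON"}), "I"),
    (frozenset({"OAX", "SON"}), "I1"),
    (frozenset({"OAX", "SON"}), "I2"),
}
# Rows whose printed N disagrees with the sum of the four printed counts.
N_MISMATCH_PAIRS = {frozenset({"OAX", "SON"}), frozenset({"TEH", "SON"})}
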