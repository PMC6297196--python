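import numpy as np
import pandas as pd
import pytest

from endosig.quantify import FivePLCurve, PeptideQuantSet
from endosig.synth import SimConfig, simulate_cohort, simulate_tmt


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_subjects=40, n_proteins=30, n_signal_proteins=4, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_tmt(small_config, small_cohort) -> PeptideQuantSet:
    _, matrix, _ = small_cohort
    return simulate_tmt(matrix, small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def elisa_curve() -> FivePLCurve:
    # Increasing sandwich-assay curve in the canonical form (b > 0,
    # a = zero-concentration asymptote).
    return FivePLCurve(a=0.04, d=2.8, c=120.0, b=1.3, g=0.9)


def make_peptide_set(rows, ref_channel="TMT131") -> PeptideQuantSet:
    """Build a PeptideQuantSet from (plex, channel, protein, isoform, peptide,
    intensity) tuples."""
    rec = pd.DataFrame(rows, columns=["plex", "channel", "protein", "isoform",
                                      "peptide", "intensity"])
    return PeptideQuantSet(records=rec, ref_channel=ref_channel)
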