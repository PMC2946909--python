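import numpy as np
import pandas as pd
import pytest

from uromarker import PeptideMatrix, SimConfig, generate_cohort


def make_matrix(masses, times, amps, sample_ids=None, ids=None) -> PeptideMatrix:
    """Construct a small PeptideMatrix from plain lists/arrays."""
    amps = np.atleast_2d(np.asarray(amps, float))
    n_pep, n_samp = amps.shape
    ids = ids or [f"p{i + 1}" for i in range(n_pep)]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n_samp)]
    peptides = pd.DataFrame(
        {"mass_da": masses, "cetime_min": times},
        index=pd.Index(ids, name="peptide_id"),
    )
    amp_df = pd.DataFrame(amps, index=peptides.index, columns=sample_ids)
    return PeptideMatrix(peptides, amp_df)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = SimConfig(
        n_t1d=30,
        n_t2d=25,
        n_peptides=300,
        n_differential_type=30,
        n_age_correlated=20,
        n_housekeeping=15,
        n_calibrants=8,
        seed=42,
    )
    cohort, matrix, truth = generate_cohort(cfg)
    return cfg, cohort, matrix, truth
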