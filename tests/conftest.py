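import numpy as np
import pandas as pd
import pytest

from clonotrace import is_io, sim


def make_is_frame(rows):
    """Build an IS DataFrame from (patient, comp, months, chrom, pos, strand, reads) tuples."""
    return pd.DataFrame(
        rows, columns=["patient", "compartment", "timepoint_months", "chrom", "pos", "strand", "reads"]
    )


@pytest.fixture
def toy_is_frame():
    return make_is_frame(
        [
            ("P1", "TN", 12, "chr1", 100, "+", 30),
            ("P1", "TN", 12, "chr1", 200, "-", 70),
            ("P1", "TN", 24, "chr1", 100, "+", 10),
            ("P1", "TCM", 12, "chr1", 200, "-", 5),
            ("P1", "TCM", 24, "chr2", 300, "+", 20),
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated cohort shared across tests (fixed seed)."""
    cfg = sim.SimConfig(n_clones_per_patient=400, seed=7)
    is_df, tcr_df, truth = sim.simulate_cohort(cfg)
    return cfg, is_df, tcr_df, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    _, is_df, _, _ = small_cohort
    filtered, _ = is_io.collision_filter(is_df)
    return is_io.build_matrix(filtered)


@pytest.fixture
def rng():
    return np.random.default_rng(20210312)
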