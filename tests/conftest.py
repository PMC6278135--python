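import numpy as np
import pandas as pd
import pytest

from epnmethyl.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the package defaults (45 PFA, 15 PFB, 6 controls)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def tumor_labels(default_cohort):
    sheet = default_cohort.sample_sheet
    return dict(zip(sheet["sample_id"], sheet["subgroup"]))


@pytest.fixture(scope="session")
def tumor_beta(default_cohort, tumor_labels):
    tumors = [s for s in default_cohort.beta.columns
              if tumor_labels[s] in ("PFA", "PFB")]
    return default_cohort.beta[tumors]


def gene_panel_cohort(n_pfa: int, n_pfb: int, seed: int) -> pd.DataFrame:
    """A gene-panel-only cohort (no array probes) at the default per-class
    distributions: 100 x Beta(8, 6) for PFA, 100 x Beta(1, 15) for PFB."""
    config = CohortConfig(n_pfa=n_pfa, n_pfb=n_pfb, n_controls=0,
                          n_probes_total=10, n_sex_probes=0,
                          n_island_probes=0, n_marker_probes=0, seed=seed)
    return generate_cohort(config).gene_panel


@pytest.fixture
def rng():
    return np.random.default_rng(42)
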