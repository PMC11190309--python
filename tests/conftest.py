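import numpy as np
import pytest

import niptcnv as nc


@pytest.fixture(scope="session")
def mini_genome():
    return nc.mini_genome(seed=0)


@pytest.fixture(scope="session")
def euploid_cohort(mini_genome):
    """60 euploid samples with counts on the mini genome (shared, read-only)."""
    return nc.simulate_cohort(nc.euploid_spec(60, seed=101), mini_genome)


@pytest.fixture(scope="session")
def reference_panel(mini_genome, euploid_cohort):
    return nc.build_panel(euploid_cohort, mini_genome)


@pytest.fixture(scope="session")
def clinical_depth_panel(mini_genome):
    """Panel at the clinical per-bin depth (~24 reads per 20 kb bin)."""
    return nc.build_euploid_panel(mini_genome, 100, seed=7,
                                  clinical_depth=True)
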