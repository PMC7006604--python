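import pytest

from retroburst import SimConfig
from retroburst.pipeline import evaluate_recovery, run_pipeline

#: Small study used by module tests: one 200 kb chromosome, 8 elements.
SMALL_CONFIG = dict(n_chromosomes=1, chrom_length=200_000, n_elements=8,
                    n_genes=6, n_solo_ltrs=3, n_truncated=3, n_varieties=2)


@pytest.fixture(scope="session")
def small_result():
    return run_pipeline(SimConfig(seed=3, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def default_result():
    """The full desk-scale benchmark: 2 x 1 Mb, 50 elements, 6 varieties."""
    return run_pipeline(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_metrics(default_result):
    return evaluate_recovery(default_result)
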