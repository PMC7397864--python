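import pytest

from lncscreen import ScreenConfig, null_config, simulate_screen


@pytest.fixture(scope="session")
def small_null_screen():
    """Null screen: no planted effects of any kind."""
    return simulate_screen(null_config(seed=42, n_targets=10, n_genes=300))


@pytest.fixture(scope="session")
def effect_screen():
    """Mid-size screen with planted growth and molecular effects."""
    cfg = ScreenConfig(seed=7, n_targets=20, n_genes=600,
                       frac_true_growth_hits=0.25,
                       frac_true_molecular_hits=0.25,
                       n_gene_sets=15)
    return simulate_screen(cfg)
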