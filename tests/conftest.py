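import pytest

from stcr import (
    MODE_NPK_ALONE,
    MODE_NPK_FYM,
    default_design,
    default_truth,
    simulate_main_experiment,
)


def noiseless_truth(mode: str, **overrides):
    return default_truth(
        mode, uptake_noise_cv=0.0, yield_noise_cv=0.0, stv_spread_cv=0.0, **overrides
    )


@pytest.fixture(scope="session")
def alone_truth():
    """Noiseless NPK-alone truth (no manure contribution)."""
    return noiseless_truth(MODE_NPK_ALONE)


@pytest.fixture(scope="session")
def fym_truth():
    """Noiseless integrated-mode truth with manure contributions."""
    return noiseless_truth(MODE_NPK_FYM)


@pytest.fixture(scope="session")
def alone_table(alone_truth):
    """Noiseless 72-plot table with per-nutrient consistency (all NR exact)."""
    return simulate_main_experiment(
        alone_truth, default_design(), seed=11, per_nutrient_consistency=True
    )


@pytest.fixture(scope="session")
def fym_table(fym_truth):
    """Noiseless 72-plot table under the integrated truth."""
    return simulate_main_experiment(fym_truth, default_design(), seed=12)
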