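import pytest

from metaboscan import normalization, qc, synthetic


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size dataset with the default planted effects (no drift)."""
    return synthetic.generate(synthetic.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_normalized(default_dataset):
    normalized, _ = normalization.pool_normalize(default_dataset.intensity,
                                                 default_dataset.runs)
    return normalized


@pytest.fixture(scope="session")
def default_rsd(default_dataset):
    return qc.compute_rsd("pools_raw", raw=default_dataset.intensity,
                          runs=default_dataset.runs)


@pytest.fixture(scope="session")
def default_filtered(default_normalized, default_rsd):
    return qc.filter_matrix(default_normalized, default_rsd)


@pytest.fixture(scope="session")
def small_null_dataset():
    """Small dataset with no planted effects and no drift."""
    cfg = synthetic.null_config(n_cases=16, n_controls=16, n_metabolites=24,
                                frac_low_rsd=0.6, seed=11)
    return synthetic.generate(cfg)


@pytest.fixture(scope="session")
def small_null_normalized(small_null_dataset):
    normalized, _ = normalization.pool_normalize(small_null_dataset.intensity,
                                                 small_null_dataset.runs)
    return normalized
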