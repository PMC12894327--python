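import pytest

import sabrefit as sf


@pytest.fixture(scope="session")
def noise_free_datasets():
    """Six noise-free curves from the default three-agonist design."""
    return sf.simulate_furchgott(sf.table1_design(noise_sd=0.0, replicates=1))


@pytest.fixture(scope="session")
def noise_free_fit(noise_free_datasets):
    plan = sf.strategy5_plan(noise_free_datasets, phase="final")
    return sf.fit_global(plan, noise_free_datasets)


@pytest.fixture(scope="session")
def noisy_fit():
    """One converged fit of the default noisy design (noise_sd = 4)."""
    datasets = sf.simulate_furchgott(sf.table1_design())
    plan = sf.strategy5_plan(datasets, phase="final")
    fit = sf.fit_global(plan, datasets)
    assert fit.converged
    return fit
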