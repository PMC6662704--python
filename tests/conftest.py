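import warnings

import pytest

from sedch4 import agemodel, gascalc, synthdata


@pytest.fixture(scope="session")
def zero_noise_tables():
    """Full synthetic design with all noise off: (slices, truth, vials)."""
    noise = synthdata.NoiseSpec(replicate_cv=0.0, ln_residual_sd=0.0, seed=11)
    slices, truth = synthdata.generate_design(noise=noise)
    vials = synthdata.generate_incubation(slices, truth, noise=noise)
    return slices, truth, vials


@pytest.fixture(scope="session")
def noisy_tables():
    """Synthetic design at study-like noise levels: (slices, truth, vials)."""
    noise = synthdata.NoiseSpec(seed=5)
    slices, truth = synthdata.generate_design(noise=noise)
    vials = synthdata.generate_incubation(slices, truth, noise=noise)
    return slices, truth, vials


@pytest.fixture(scope="session")
def annotated_rates(noisy_tables):
    slices, _, vials = noisy_tables
    rates = gascalc.compute_rates(vials, slices)
    return agemodel.annotate_rates(rates, slices)


@pytest.fixture(scope="session")
def pooled_rates(annotated_rates):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        flagged = gascalc.apply_exclusions(annotated_rates)
        return gascalc.pool_replicates(flagged)
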