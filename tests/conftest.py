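import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240722)


@pytest.fixture(scope="session")
def noiseless_explant():
    """One noiseless synthetic explant (mid-gastrula-like) shared by tests."""
    from borderquant.synthetic_data import ExplantImageParams, make_explant_image

    params = ExplantImageParams(
        width=384, height=384, n_nuclei=150, noise_sd=0.0, seed=5,
        frac_double_given_pax3=0.79,
    )
    stack, truth = make_explant_image(params)
    return params, stack, truth
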