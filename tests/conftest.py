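import numpy as np
import pytest

import countvae as cv


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_params():
    """G=3, D=2 generative parameters with known weights."""
    return cv.GenerativeParams(
        W=np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]),
        theta=np.array([2.0, 2.0, 2.0]),
        s_mu=3.0,
        s_sigma=0.3,
    )


@pytest.fixture(scope="session")
def small_block_data():
    """A small block-program dataset with ground truth, shared across tests."""
    spec = cv.SimScenario(
        n_cells=800,
        n_genes=60,
        n_factors=3,
        program_structure="block",
        theta_range=(5.0, 5.0),
        depth_log_mean=7.0,
        depth_log_sd=0.3,
        seed=7,
    )
    params, meta = cv.make_scenario(spec)
    counts, latent = cv.sample_generative(params, spec.n_cells, seed=7)
    return {"spec": spec, "params": params, "meta": meta,
            "counts": counts, "latent": latent}


@pytest.fixture(scope="session")
def small_fit(small_block_data):
    """One linear-decoder fit on the shared dataset (normal latent)."""
    fit = cv.fit(
        small_block_data["counts"],
        cv.ModelConfig(n_latent=3, latent_family="normal"),
        cv.TrainConfig(n_epochs=40, seed=0, learning_rate=1e-3),
    )
    return fit
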