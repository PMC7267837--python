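import time

import numpy as np
import pytest

import countvae as cv
from countvae.errors import ConfigurationError, DomainError, ShapeError
from countvae.inference import forward_elbo, init_model_state
from countvae.training import _resolve_epochs, backward_elbo


class TestRecommendedEpochs:
    def test_million_cells_one_epoch(self):
        assert cv.recommended_epochs(1_000_000) == 1

    def test_hundred_thousand_cells_ten_epochs(self):
        assert cv.recommended_epochs(100_000) == 10

    def test_clamped_below_at_one(self):
        assert cv.recommended_epochs(3_000_000) == 1

    def test_rounds_up(self):
        assert cv.recommended_epochs(300_000) == 4

    def test_invalid(self):
        with pytest.raises(DomainError):
            cv.recommended_epochs(0)

    def test_auto_resolution(self):
        assert _resolve_epochs("auto", 250_000) == 4
        assert _resolve_epochs(17, 250_000) == 17
        with pytest.raises(ConfigurationError):
            _resolve_epochs(0, 100)


@pytest.mark.parametrize(
    "latent,decoder,bn",
    [
        ("normal", "linear", False),
        ("normal", "linear", True),
        ("ln", "linear", False),
        ("normal", "nn", False),
    ],
)
def test_gradients_match_finite_differences(latent, decoder, bn):
    """Every analytic gradient agrees with central finite differences."""
    rng = np.random.default_rng(0)
    G, D, B = 5, 2, 4
    state = init_model_state(
        G, D, cv.EncoderConfig(n_hidden=6), latent_family=latent,
        decoder=decoder, use_batch_norm=bn, dec_hidden=4,
        s_mu=2.0, s_sigma=0.5, seed=3,
    )
    for v in state.trainable().values():
        v += 0.1 * rng.standard_normal(v.shape)
    Y = rng.poisson(3.0, size=(B, G)).astype(float)
    eps_z = rng.standard_normal((B, D))
    eps_s = rng.standard_normal(B)

    def loss():
        r, _ = forward_elbo(Y, state, eps_z, eps_s, kl_weight=0.7, bn_training=True)
        return -np.mean(r["per_cell_objective"])

    _, cache = forward_elbo(Y, state, eps_z, eps_s, kl_weight=0.7, bn_training=True)
    grads = backward_elbo(state, cache)
    for key, p in state.trainable().items():
        flat = p.ravel()
        idx = rng.choice(flat.size, size=min(4, flat.size), replace=False)
        for i in idx:
            h = 1e-6 * max(1.0, abs(flat[i]))
            old = flat[i]
            flat[i] = old + h
            lp = loss()
            flat[i] = old - h
            lm = loss()
            flat[i] = old
            fd = (lp - lm) / (2 * h)
            an = grads[key].ravel()[i]
            assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd)), (key, i, fd, an)


class TestFit:
    def test_objective_improves(self, small_block_data):
        fit = cv.fit(
            small_block_data["counts"],
            cv.ModelConfig(n_latent=3),
            cv.TrainConfig(n_epochs=50, seed=0),
        )
        assert fit.history[-1]["train_objective"] > fit.history[0]["train_objective"]

    def test_holdout_split_arithmetic(self, small_block_data):
        fit = cv.fit(
            small_block_data["counts"],
            cv.ModelConfig(n_latent=2),
            cv.TrainConfig(n_epochs=2, seed=1, holdout_fraction=0.1),
        )
        n = small_block_data["counts"].n_cells
        assert len(fit.heldout_idx) == round(0.1 * n)
        assert len(np.intersect1d(fit.train_idx, fit.heldout_idx)) == 0
        assert len(fit.train_idx) + len(fit.heldout_idx) == n

    def test_history_shape(self, small_fit):
        assert len(small_fit.history) == 40
        assert all(h["heldout_objective"] is not None for h in small_fit.history)

    def test_no_holdout_history(self, small_block_data):
        fit = cv.fit(
            small_block_data["counts"],
            cv.ModelConfig(n_latent=2),
            cv.TrainConfig(n_epochs=2, seed=1, holdout_fraction=0.0),
        )
        assert all(h["heldout_objective"] is None for h in fit.history)

    def test_same_seed_reproducible(self, small_block_data):
        cfg = cv.TrainConfig(n_epochs=5, seed=3)
        a = cv.fit(small_block_data["counts"], cv.ModelConfig(n_latent=2), cfg)
        b = cv.fit(small_block_data["counts"], cv.ModelConfig(n_latent=2), cfg)
        hold = small_block_data["counts"].subset(a.heldout_idx)
        ea = cv.heldout_reconstruction_error(a, hold)
        eb = cv.heldout_reconstruction_error(b, hold)
        assert ea == eb
        assert np.array_equal(a.state.W, b.state.W)
        assert a.history == b.history

    def test_warm_start_gene_mismatch(self, small_block_data):
        st = init_model_state(10, 2, seed=0)
        with pytest.raises(ShapeError):
            cv.fit(
                small_block_data["counts"],
                cv.ModelConfig(n_latent=2),
                cv.TrainConfig(n_epochs=1),
                warm_start=st,
            )

    def test_trend_on_fixtures(self, small_block_data):
        # epoch-mean ELBO improves from first to last epoch for both latent
        # families on the shared fixture
        for family in ("normal", "ln"):
            fit = cv.fit(
                small_block_data["counts"],
                cv.ModelConfig(n_latent=3, latent_family=family),
                cv.TrainConfig(n_epochs=15, seed=2),
            )
            assert (
                fit.history[-1]["train_objective"]
                > fit.history[0]["train_objective"]
            )


class TestHeldoutReconstructionError:
    def test_deterministic(self, small_fit, small_block_data):
        hold = small_block_data["counts"].subset(small_fit.heldout_idx)
        assert cv.heldout_reconstruction_error(
            small_fit, hold
        ) == cv.heldout_reconstruction_error(small_fit, hold)

    def test_gene_mismatch_raises(self, small_fit):
        bad = cv.CountMatrix(
            np.zeros((3, 5), dtype=int),
            [f"g{i}" for i in range(5)],
            [f"c{i}" for i in range(3)],
        )
        with pytest.raises(ShapeError):
            cv.heldout_reconstruction_error(small_fit, bad)

    def test_likelihood_dominance_oracle(self):
        # a model whose mu equals the empirical gene proportions (large theta)
        # must beat a uniform-mu model on strongly non-uniform counts
        rng = np.random.default_rng(0)
        G, N = 20, 200
        p = np.linspace(1, 40, G)
        p /= p.sum()
        depth = 500
        counts = rng.poisson(depth * p, size=(N, G))
        cm = cv.CountMatrix(
            counts, [f"g{i}" for i in range(G)], [f"c{i}" for i in range(N)]
        )

        def make_state(col):
            st = init_model_state(G, 1, s_mu=np.log(depth), s_sigma=0.5, seed=0)
            st.log_theta[:] = np.log(1e4)
            st.W[:, 0] = col
            # encoder outputs: z_loc = 1, log s = log(total depth)
            for key in ("z_loc", "s_loc"):
                W, b = st.encoder.heads[key]
                W[...] = 0.0
            st.encoder.heads["z_loc"][1][:] = 1.0
            st.encoder.heads["s_loc"][1][:] = np.log(depth)
            for i, (Wl, bl) in enumerate(st.encoder.layers):
                Wl[...] = 0.0
            return st

        def wrap(st):
            return cv.FitResult(
                state=st, history=[], model_config=cv.ModelConfig(n_latent=1),
                train_config=cv.TrainConfig(n_epochs=1), seed=0,
                gene_ids=cm.gene_ids, train_idx=np.array([]),
                heldout_idx=np.array([]),
            )

        err_prop = cv.heldout_reconstruction_error(wrap(make_state(np.log(p))), cm)
        err_unif = cv.heldout_reconstruction_error(wrap(make_state(np.zeros(G))), cm)
        # independent oracle computed directly from nb_log_pmf
        oracle_prop = -cv.nb_log_pmf(
            counts, depth * p + 1e-10, 1e4
        ).sum(axis=1).mean()
        oracle_unif = -cv.nb_log_pmf(
            counts, np.full(G, depth / G) + 1e-10, 1e4
        ).sum(axis=1).mean()
        assert oracle_prop < oracle_unif
        assert err_prop < err_unif
        assert np.isclose(err_prop, oracle_prop, rtol=1e-6)

    def test_finite_with_zero_count_training_gene(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3, size=(50, 6))
        counts[:, 2] = 0  # gene absent in training
        cm = cv.CountMatrix(
            counts, [f"g{i}" for i in range(6)], [f"c{i}" for i in range(50)]
        )
        fit = cv.fit(cm, cv.ModelConfig(n_latent=2), cv.TrainConfig(n_epochs=3, seed=0))
        hold = cv.CountMatrix(
            rng.poisson(3, size=(10, 6)),
            cm.gene_ids,
            [f"h{i}" for i in range(10)],
        )
        assert np.isfinite(cv.heldout_reconstruction_error(fit, hold))


@pytest.mark.slow
def test_runtime_scales_roughly_linearly():
    """Doubling N should cost at most ~2.5x per epoch (linear-time claim)."""
    spec = cv.SimScenario(n_cells=20_000, n_genes=40, n_factors=2, seed=3,
                          theta_range=(5.0, 5.0), depth_log_mean=6.0)
    params, _ = cv.make_scenario(spec)
    cm, _ = cv.sample_generative(params, 20_000, seed=3)

    def time_fit(n):
        sub = cm.subset(np.arange(n))
        best = np.inf
        for _ in range(2):
            t0 = time.perf_counter()
            cv.fit(sub, cv.ModelConfig(n_latent=2, encoder=cv.EncoderConfig(n_hidden=32)),
                   cv.TrainConfig(n_epochs=2, seed=0, holdout_fraction=0.0))
            best = min(best, time.perf_counter() - t0)
        return best

    time_fit(1000)  # warm-up
    t5, t20 = time_fit(5000), time_fit(20_000)
    # 4x data: allow 2.5x per doubling -> 6.25x
    assert t20 <= 6.25 * t5 + 0.05


def test_nonlinear_truth_directional_small():
    """On nonlinear ground truth the nn decoder reconstructs held-out data
    at least as well as the linear decoder (seed-averaged)."""
    cm, _ = cv.sample_nonlinear(1200, n_genes=40, n_factors=2, seed=5)
    errs = {"nn": [], "linear": []}
    for seed in (0, 1):
        for dec in ("nn", "linear"):
            fit = cv.fit(
                cm,
                cv.ModelConfig(n_latent=2, decoder=dec, dec_hidden=64),
                cv.TrainConfig(n_epochs=60, seed=seed),
            )
            hold = cm.subset(fit.heldout_idx)
            errs[dec].append(cv.heldout_reconstruction_error(fit, hold))
    assert np.mean(errs["nn"]) <= np.mean(errs["linear"]) + 1e-9
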