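"""Mini-batch training of the variational objective.

Gradients are derived by hand and checked against finite differences in the
test suite; :func:`backward_elbo` consumes the cache produced by
:func:`countvae.inference.forward_elbo`.  The loss minimized is the
negative per-cell-mean ELBO of each mini-batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.special import digamma

from .errors import ConfigurationError, DomainError, ShapeError
from .inference import (
    EncoderConfig,
    ModelState,
    forward_elbo,
    init_model_state,
    posterior_mean_latent,
)
from .model import MEAN_EPS, CountMatrix, nb_log_pmf

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "FitResult",
    "recommended_epochs",
    "fit",
    "heldout_reconstruction_error",
    "backward_elbo",
    "Adam",
]


@dataclass
class ModelConfig:
    """Architecture of the model to fit."""

    n_latent: int = 10
    latent_family: str = "normal"  # "normal" | "ln"
    decoder: str = "linear"  # "linear" | "nn"
    use_batch_norm: bool = False
    dec_hidden: int = 32
    encoder: EncoderConfig = field(default_factory=EncoderConfig)


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    n_epochs: Union[int, str] = "auto"
    batch_size: int = 128
    learning_rate: float = 1e-3
    holdout_fraction: float = 0.1
    seed: int = 0
    kl_warmup_epochs: int = 0
    patience: Optional[int] = None  # early stopping on held-out objective
    n_restarts: int = 1  # independent initializations; best final ELBO kept

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not (0.0 <= self.holdout_fraction < 1.0):
            raise ConfigurationError("holdout_fraction must lie in [0, 1)")
        if isinstance(self.n_epochs, str) and self.n_epochs != "auto":
            raise ConfigurationError("n_epochs must be an integer or 'auto'")
        if self.n_restarts < 1:
            raise ConfigurationError("n_restarts must be >= 1")


@dataclass
class FitResult:
    """Trained model state plus the per-epoch objective history."""

    state: ModelState
    history: list  # dicts: epoch, train_objective, heldout_objective
    model_config: ModelConfig
    train_config: TrainConfig
    seed: int
    gene_ids: list
    train_idx: np.ndarray
    heldout_idx: np.ndarray

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def recommended_epochs(n_cells: int) -> int:
    """First-pass epoch budget: one million divided by the dataset size.

    Clamped below at one epoch; fractional results round up.
    """
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    return max(1, math.ceil(1_000_000 / n_cells))


class Adam:
    """In-place Adam over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def backward_elbo(state: ModelState, cache: dict) -> dict:
    """Gradients of ``-mean_n(objective_n)`` w.r.t. every trainable array."""
    Y = cache["Y"]
    B = Y.shape[0]
    theta = cache["theta"]
    mean = cache["mean"]
    mu = cache["mu"]
    s = cache["s"]
    t = cache["t"]
    kl_w = cache["kl_weight"]
    c = -1.0 / B  # d loss / d objective_n

    grads = {}

    # --- negative binomial emission ---
    dmean = c * (Y / mean - (Y + theta) / (theta + mean))
    dtheta = c * (
        digamma(Y + theta)
        - digamma(theta)
        + np.log(theta)
        + 1.0
        - np.log(theta + mean)
        - (Y + theta) / (theta + mean)
    )
    grads["log_theta"] = theta * dtheta.sum(axis=0)

    dmu = dmean * s[:, None]
    dlogs_recon = (dmean * (s[:, None] * mu)).sum(axis=1)

    # --- softmax over genes ---
    dlogits = mu * (dmu - (dmu * mu).sum(axis=1, keepdims=True))

    # --- batch norm (training statistics) ---
    dec_cache = cache["dec"]
    if state.use_batch_norm:
        bn = state.bn
        Pn = dec_cache["Pn"]
        inv_sd = dec_cache["inv_sd"]
        grads["bn_scale"] = (dlogits * Pn).sum(axis=0)
        grads["bn_shift"] = dlogits.sum(axis=0)
        dPn = dlogits * bn.scale
        if dec_cache.get("bn_training", True):
            dP = inv_sd * (
                dPn - dPn.mean(axis=0) - Pn * (dPn * Pn).mean(axis=0)
            )
        else:
            dP = dPn * inv_sd
    else:
        dP = dlogits

    # --- decoder ---
    if state.decoder == "linear":
        grads["dec_W"] = dP.T @ t
        dt = dP @ state.W
    else:
        hd = dec_cache["hd"]
        grads["d2_W"] = hd.T @ dP
        grads["d2_b"] = dP.sum(axis=0)
        dhd = dP @ state.dec_nn["d2_W"].T
        da1 = dhd * (hd > 0)
        grads["d1_W"] = t.T @ da1
        grads["d1_b"] = da1.sum(axis=0)
        dt = da1 @ state.dec_nn["d1_W"].T

    # --- latent reparameterization ---
    if state.latent_family == "ln":
        du = t * (dt - (dt * t).sum(axis=1, keepdims=True))
    else:
        du = dt
    zm, zls = cache["zm"], cache["zls"]
    sm, sls = cache["sm"], cache["sls"]
    dzm = du.copy()
    dzls = du * cache["eps_z"] * cache["z_scale"]

    # --- KL terms (loss gradient sign: +kl_w / B) ---
    k = kl_w / B
    dzm += k * zm
    dzls += k * (np.exp(2 * zls) - 1.0)
    dlogs = dlogs_recon
    dsm = dlogs + k * (sm - state.s_mu) / state.s_sigma**2
    dsls = dlogs * cache["eps_s"] * cache["s_scale"] + k * (
        np.exp(2 * sls) / state.s_sigma**2 - 1.0
    )

    # --- clip masks on the log-scale heads ---
    dzls *= cache["enc"]["zls_mask"]
    dsls *= cache["enc"]["sls_mask"]

    # --- encoder heads ---
    hs = cache["enc"]["hs"]
    hL = hs[-1]
    heads = state.encoder.heads
    dh = np.zeros_like(hL)
    for key, dout in (
        ("z_loc", dzm),
        ("z_logscale", dzls),
        ("s_loc", dsm[:, None]),
        ("s_logscale", dsls[:, None]),
    ):
        Wh, _ = heads[key]
        grads[f"{key}_W"] = hL.T @ dout
        grads[f"{key}_b"] = dout.sum(axis=0)
        dh = dh + dout @ Wh.T

    # --- encoder trunk ---
    act = state.enc_config.activation
    for i in range(len(state.encoder.layers) - 1, -1, -1):
        Wl, _ = state.encoder.layers[i]
        h_out = hs[i + 1]
        if act == "relu":
            da = dh * (h_out > 0)
        else:  # tanh
            da = dh * (1.0 - h_out**2)
        grads[f"enc{i}_W"] = hs[i].T @ da
        grads[f"enc{i}_b"] = da.sum(axis=0)
        dh = da @ Wl.T

    return grads


def _resolve_epochs(n_epochs: Union[int, str], n_cells: int) -> int:
    if n_epochs == "auto":
        return recommended_epochs(n_cells)
    n = int(n_epochs)
    if n < 1:
        raise ConfigurationError("n_epochs must be >= 1")
    return n


def _empirical_exposure_prior(Y: np.ndarray) -> tuple[float, float]:
    totals = np.maximum(Y.sum(axis=1), 1.0)
    log_totals = np.log(totals)
    s_mu = float(log_totals.mean())
    s_sigma = float(max(log_totals.std(), 1e-3))
    return s_mu, s_sigma


def fit(
    data: CountMatrix,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    warm_start: ModelState | None = None,
) -> FitResult:
    """Train the model by seeded shuffled mini-batch gradient ascent on the ELBO.

    The exposure prior (``s_mu``, ``s_sigma``) is set empirically from the
    training cells' log total counts.  Per-epoch mean objectives on the
    training and held-out cells are recorded; identical seeds and configs
    reproduce the history exactly.  With ``n_restarts > 1`` the model is
    trained from several seeded initializations and the run with the best
    final training objective is returned (restarts share the same
    train/held-out split).
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig(n_epochs=20)

    N = data.n_cells
    split_rng = np.random.default_rng(train_config.seed)
    n_hold = int(round(train_config.holdout_fraction * N))
    perm = split_rng.permutation(N)
    heldout_idx = np.sort(perm[:n_hold])
    train_idx = np.sort(perm[n_hold:])
    if train_idx.size == 0:
        raise ConfigurationError("holdout fraction leaves no training cells")
    Y_train = data.counts[train_idx].astype(float)
    Y_hold = data.counts[heldout_idx].astype(float) if n_hold else None

    s_mu, s_sigma = _empirical_exposure_prior(Y_train)

    n_epochs = _resolve_epochs(train_config.n_epochs, N)
    n_restarts = 1 if warm_start is not None else train_config.n_restarts
    best = None
    for restart in range(n_restarts):
        result = _fit_single(
            data, model_config, train_config, warm_start, restart,
            train_idx, heldout_idx, Y_train, Y_hold, s_mu, s_sigma, n_epochs,
        )
        if best is None or (
            result.history[-1]["train_objective"]
            > best.history[-1]["train_objective"]
        ):
            best = result
    return best


def _fit_single(
    data, model_config, train_config, warm_start, restart,
    train_idx, heldout_idx, Y_train, Y_hold, s_mu, s_sigma, n_epochs,
) -> FitResult:
    rng = np.random.default_rng((train_config.seed, restart, 1))

    if warm_start is not None:
        if warm_start.n_genes != data.n_genes:
            raise ShapeError(
                f"warm-start state has {warm_start.n_genes} genes, data has "
                f"{data.n_genes}"
            )
        state = warm_start
    else:
        state = init_model_state(
            n_genes=data.n_genes,
            n_latent=model_config.n_latent,
            enc_config=model_config.encoder,
            latent_family=model_config.latent_family,
            decoder=model_config.decoder,
            use_batch_norm=model_config.use_batch_norm,
            dec_hidden=model_config.dec_hidden,
            s_mu=s_mu,
            s_sigma=s_sigma,
            seed=train_config.seed + 104729 * restart,
        )

    opt = Adam(state.trainable(), lr=train_config.learning_rate)

    history = []
    best_hold = np.inf
    stale = 0
    n_train = Y_train.shape[0]
    B = min(train_config.batch_size, n_train)
    for epoch in range(n_epochs):
        if train_config.kl_warmup_epochs > 0:
            kl_w = min(1.0, (epoch + 1) / train_config.kl_warmup_epochs)
        else:
            kl_w = 1.0
        order = rng.permutation(n_train)
        obj_sum = 0.0
        for start in range(0, n_train, B):
            batch = Y_train[order[start : start + B]]
            eps_z = rng.standard_normal((batch.shape[0], state.n_latent))
            eps_s = rng.standard_normal(batch.shape[0])
            result, cache = forward_elbo(
                batch,
                state,
                eps_z,
                eps_s,
                kl_weight=kl_w,
                bn_training=True,
                update_running=True,
            )
            grads = backward_elbo(state, cache)
            opt.step(grads)
            # log the plain (unweighted) objective for comparability
            obj_sum += result["reconstruction"] - result["kl"]
        record = {
            "epoch": epoch + 1,
            "train_objective": obj_sum / n_train,
            "heldout_objective": None,
        }
        if Y_hold is not None:
            eval_rng = np.random.default_rng((train_config.seed, epoch))
            eps_z = eval_rng.standard_normal((Y_hold.shape[0], state.n_latent))
            eps_s = eval_rng.standard_normal(Y_hold.shape[0])
            res, _ = forward_elbo(
                Y_hold, state, eps_z, eps_s, kl_weight=1.0, bn_training=False
            )
            record["heldout_objective"] = res["objective"] / Y_hold.shape[0]
        history.append(record)
        if (
            train_config.patience is not None
            and record["heldout_objective"] is not None
        ):
            score = -record["heldout_objective"]
            if score < best_hold - 1e-9:
                best_hold = score
                stale = 0
            else:
                stale += 1
                if stale > train_config.patience:
                    break

    return FitResult(
        state=state,
        history=history,
        model_config=model_config,
        train_config=train_config,
        seed=train_config.seed,
        gene_ids=list(data.gene_ids),
        train_idx=train_idx,
        heldout_idx=heldout_idx,
    )


def heldout_reconstruction_error(fit_result: FitResult, heldout: CountMatrix) -> float:
    """Mean per-cell negative NB log-likelihood at the posterior mean.

    The cell embedding is the variational location (softmaxed for the
    logistic-normal family) and the exposure is ``exp(s_loc)``; no sampling
    noise enters, so repeated evaluation is exactly reproducible.
    """
    state = fit_result.state
    if heldout.n_genes != state.n_genes:
        raise ShapeError(
            f"held-out data has {heldout.n_genes} genes, model has {state.n_genes}"
        )
    Z, s = posterior_mean_latent(heldout, state)
    from .inference import _decode_forward

    log_mu, _ = _decode_forward(Z, state, bn_training=False)
    mean = s[:, None] * np.exp(log_mu) + MEAN_EPS
    ll = nb_log_pmf(heldout.counts, mean, state.theta)
    return float(-ll.sum(axis=1).mean())
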