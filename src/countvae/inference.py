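"""Amortized variational inference: encoder, reparameterized sampling, ELBO.

The encoder is a small fully connected network applied to log1p-transformed
counts; it outputs Gaussian location/scale parameters for the latent
coordinates ``z`` (pre-softmax Gaussian when the latent family is
logistic-normal) and for the log exposure ``log s``.  The evidence lower
bound combines the negative binomial reconstruction term with the two
Gaussian KL terms.

Everything here is plain NumPy.  :func:`forward_elbo` records enough
intermediate state in a cache for the manual backward pass implemented in
:mod:`countvae.training`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import log_softmax

from .errors import ConfigurationError, DomainError, ShapeError, StateError
from .model import (
    MEAN_EPS,
    BatchNormState,
    CountMatrix,
    GenerativeParams,
    LatentState,
    _canonical_family,
    nb_log_pmf,
)

__all__ = [
    "EncoderConfig",
    "EncoderState",
    "LatentPosterior",
    "ModelState",
    "init_encoder",
    "init_model_state",
    "encode",
    "sample_latent",
    "kl_normal",
    "elbo",
    "forward_elbo",
    "posterior_mean_latent",
]

# log-scale heads are clipped into this range for numerical safety
LOGSCALE_CLIP = 8.0


@dataclass
class EncoderConfig:
    n_hidden: int = 128
    n_layers: int = 1
    activation: str = "relu"
    input_transform: str = "log1p"

    def __post_init__(self):
        if self.n_hidden < 1 or self.n_layers < 1:
            raise ConfigurationError("n_hidden and n_layers must be >= 1")
        if self.activation not in ("relu", "tanh"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        if self.input_transform not in ("log1p", "identity"):
            raise ConfigurationError(
                f"unknown input transform {self.input_transform!r}"
            )


@dataclass
class EncoderState:
    """Weights of the encoder MLP and its four posterior-parameter heads."""

    layers: list  # list of (W, b)
    heads: dict  # keys: z_loc, z_logscale, s_loc, s_logscale -> (W, b)
    n_genes: int
    n_latent: int


@dataclass
class LatentPosterior:
    """Per-cell variational Gaussian parameters for z and log s.

    For the logistic-normal family ``(z_loc, z_scale)`` parameterize the
    pre-softmax Gaussian, not the simplex coordinates themselves.
    """

    z_loc: np.ndarray
    z_scale: np.ndarray
    s_loc: np.ndarray
    s_scale: np.ndarray

    def __post_init__(self):
        if np.any(self.z_scale <= 0) or np.any(self.s_scale <= 0):
            raise DomainError("posterior scales must be strictly positive")


@dataclass
class ModelState:
    """Full trainable state: decoder parameters plus encoder weights."""

    W: Optional[np.ndarray]  # G x D, linear decoder only
    log_theta: np.ndarray  # (G,)
    s_mu: float
    s_sigma: float
    encoder: EncoderState
    enc_config: EncoderConfig
    n_latent: int
    latent_family: str = "normal"
    decoder: str = "linear"
    use_batch_norm: bool = False
    bn: Optional[BatchNormState] = None
    dec_nn: Optional[dict] = None  # d1_W, d1_b, d2_W, d2_b

    @property
    def n_genes(self) -> int:
        return self.log_theta.shape[0]

    @property
    def theta(self) -> np.ndarray:
        return np.exp(self.log_theta)

    def generative_params(self) -> GenerativeParams:
        if self.decoder != "linear":
            from .errors import UnsupportedModelError

            raise UnsupportedModelError(
                "generative_params is only defined for linear-decoder models"
            )
        return GenerativeParams(
            W=self.W,
            theta=self.theta,
            s_mu=self.s_mu,
            s_sigma=self.s_sigma,
            bn_state=self.bn,
        )

    def trainable(self) -> dict:
        """Dict of live references to every trainable array (in-place updates)."""
        params = {}
        for i, (W, b) in enumerate(self.encoder.layers):
            params[f"enc{i}_W"], params[f"enc{i}_b"] = W, b
        for key, (W, b) in self.encoder.heads.items():
            params[f"{key}_W"], params[f"{key}_b"] = W, b
        if self.decoder == "linear":
            params["dec_W"] = self.W
        else:
            params.update(self.dec_nn)
        params["log_theta"] = self.log_theta
        if self.use_batch_norm:
            params["bn_scale"] = self.bn.scale
            params["bn_shift"] = self.bn.shift
        return params


def init_encoder(
    n_genes: int,
    n_latent: int,
    config: EncoderConfig,
    rng: np.random.Generator,
) -> EncoderState:
    """He-style initialization of the encoder MLP and its heads."""
    layers = []
    fan_in = n_genes
    for _ in range(config.n_layers):
        W = rng.standard_normal((fan_in, config.n_hidden)) * np.sqrt(2.0 / fan_in)
        b = np.zeros(config.n_hidden)
        layers.append((W, b))
        fan_in = config.n_hidden
    heads = {}
    # z_loc starts larger: factor discovery is a bilinear saddle between the
    # decoder column and this head, and a near-zero product escapes slowly
    for key, width, scale in (
        ("z_loc", n_latent, 0.1),
        ("z_logscale", n_latent, 0.01),
        ("s_loc", 1, 0.01),
        ("s_logscale", 1, 0.01),
    ):
        W = rng.standard_normal((fan_in, width)) * scale
        b = np.zeros(width)
        heads[key] = (W, b)
    return EncoderState(layers=layers, heads=heads, n_genes=n_genes, n_latent=n_latent)


def init_model_state(
    n_genes: int,
    n_latent: int,
    enc_config: EncoderConfig | None = None,
    latent_family: str = "normal",
    decoder: str = "linear",
    use_batch_norm: bool = False,
    dec_hidden: int = 32,
    s_mu: float = 0.0,
    s_sigma: float = 1.0,
    seed: int = 0,
) -> ModelState:
    if decoder not in ("linear", "nn"):
        raise ConfigurationError(f"unknown decoder family {decoder!r}")
    enc_config = enc_config or EncoderConfig()
    rng = np.random.default_rng(seed)
    encoder = init_encoder(n_genes, n_latent, enc_config, rng)
    W = None
    dec_nn = None
    if decoder == "linear":
        W = rng.standard_normal((n_genes, n_latent)) * 0.1
    else:
        dec_nn = {
            "d1_W": rng.standard_normal((n_latent, dec_hidden))
            * np.sqrt(2.0 / n_latent),
            "d1_b": np.zeros(dec_hidden),
            "d2_W": rng.standard_normal((dec_hidden, n_genes))
            * np.sqrt(2.0 / dec_hidden),
            "d2_b": np.zeros(n_genes),
        }
    return ModelState(
        W=W,
        log_theta=np.zeros(n_genes),
        s_mu=s_mu,
        s_sigma=s_sigma,
        encoder=encoder,
        enc_config=enc_config,
        n_latent=n_latent,
        latent_family=_canonical_family(latent_family),
        decoder=decoder,
        use_batch_norm=use_batch_norm,
        bn=BatchNormState.initial(n_genes) if use_batch_norm else None,
        dec_nn=dec_nn,
    )


def _activation(a: np.ndarray, name: str) -> np.ndarray:
    return np.maximum(a, 0.0) if name == "relu" else np.tanh(a)


def _encoder_forward(X: np.ndarray, state: ModelState):
    """Run the encoder; returns raw head outputs and a cache for backprop."""
    enc, cfg = state.encoder, state.enc_config
    if X.shape[1] != enc.n_genes:
        raise ShapeError(
            f"input has {X.shape[1]} genes but encoder was built for {enc.n_genes}"
        )
    h = np.log1p(X) if cfg.input_transform == "log1p" else X
    hs = [h]
    for W, b in enc.layers:
        a = h @ W + b
        h = _activation(a, cfg.activation)
        hs.append(h)
    zm = h @ enc.heads["z_loc"][0] + enc.heads["z_loc"][1]
    zls_raw = h @ enc.heads["z_logscale"][0] + enc.heads["z_logscale"][1]
    sm = (h @ enc.heads["s_loc"][0] + enc.heads["s_loc"][1])[:, 0]
    sls_raw = (h @ enc.heads["s_logscale"][0] + enc.heads["s_logscale"][1])[:, 0]
    zls = np.clip(zls_raw, -LOGSCALE_CLIP, LOGSCALE_CLIP)
    sls = np.clip(sls_raw, -LOGSCALE_CLIP, LOGSCALE_CLIP)
    cache = {
        "hs": hs,
        "zls_mask": (np.abs(zls_raw) < LOGSCALE_CLIP).astype(float),
        "sls_mask": (np.abs(sls_raw) < LOGSCALE_CLIP).astype(float),
    }
    return zm, zls, sm, sls, cache


def encode(counts, state: ModelState) -> LatentPosterior:
    """Map count rows to their variational posterior parameters.

    Deterministic given the encoder weights; rows are processed
    independently, so permuting cells permutes the posterior identically.
    """
    X = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    if np.any(X < 0):
        raise DomainError("counts must be non-negative")
    zm, zls, sm, sls, _ = _encoder_forward(np.asarray(X, dtype=float), state)
    return LatentPosterior(
        z_loc=zm, z_scale=np.exp(zls), s_loc=sm, s_scale=np.exp(sls)
    )


def _row_softmax(u: np.ndarray) -> np.ndarray:
    shifted = u - u.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def sample_latent(
    post: LatentPosterior,
    latent_family: str = "normal",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise: tuple[np.ndarray, np.ndarray] | None = None,
) -> LatentState:
    """Reparameterized draw from the variational posterior.

    ``z = z_loc + z_scale * eps`` (softmaxed row-wise for the
    logistic-normal family) and ``s = exp(s_loc + s_scale * eps')``.
    Supply ``noise`` to reuse explicit standard-normal draws.
    """
    family = _canonical_family(latent_family)
    if noise is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        eps_z = rng.standard_normal(post.z_loc.shape)
        eps_s = rng.standard_normal(post.s_loc.shape)
    else:
        eps_z, eps_s = noise
    u = post.z_loc + post.z_scale * eps_z
    z = _row_softmax(u) if family == "ln" else u
    s = np.exp(post.s_loc + post.s_scale * eps_s)
    return LatentState(z=z, s=s, latent_family=family)


def kl_normal(q_loc, q_scale, p_loc, p_scale) -> np.ndarray:
    """Elementwise KL( N(q_loc, q_scale^2) || N(p_loc, p_scale^2) )."""
    q_loc = np.asarray(q_loc, dtype=float)
    q_scale = np.asarray(q_scale, dtype=float)
    p_loc = np.asarray(p_loc, dtype=float)
    p_scale = np.asarray(p_scale, dtype=float)
    if np.any(q_scale <= 0) or np.any(p_scale <= 0):
        raise DomainError("scales must be strictly positive")
    return (
        np.log(p_scale / q_scale)
        + (q_scale**2 + (q_loc - p_loc) ** 2) / (2.0 * p_scale**2)
        - 0.5
    )


def _decode_forward(t: np.ndarray, state: ModelState, bn_training: bool,
                    update_running: bool = False):
    """Decoder forward pass to log-mean-proportions; returns cache."""
    cache = {}
    if state.decoder == "linear":
        P = t @ state.W.T
    else:
        a1 = t @ state.dec_nn["d1_W"] + state.dec_nn["d1_b"]
        hd = np.maximum(a1, 0.0)
        P = hd @ state.dec_nn["d2_W"] + state.dec_nn["d2_b"]
        cache["hd"] = hd
    if state.use_batch_norm:
        bn = state.bn
        if bn is None:
            raise StateError("batch norm enabled but state is missing")
        if bn_training:
            m = P.mean(axis=0)
            var = P.var(axis=0)
            if update_running:
                bn.running_mean = (1 - bn.momentum) * bn.running_mean + bn.momentum * m
                bn.running_var = (1 - bn.momentum) * bn.running_var + bn.momentum * var
        else:
            if not bn.populated:
                raise StateError("evaluation-mode batch norm needs running statistics")
            m, var = bn.running_mean, bn.running_var
        inv_sd = 1.0 / np.sqrt(var + bn.eps)
        Pn = (P - m) * inv_sd
        logits = bn.scale * Pn + bn.shift
        cache.update({"Pn": Pn, "inv_sd": inv_sd, "bn_training": bn_training})
    else:
        logits = P
    cache["t"] = t
    cache["logits"] = logits
    log_mu = log_softmax(logits, axis=1)
    return log_mu, cache


def forward_elbo(
    Y: np.ndarray,
    state: ModelState,
    eps_z: np.ndarray,
    eps_s: np.ndarray,
    kl_weight: float = 1.0,
    bn_training: bool = True,
    update_running: bool = False,
):
    """Single-sample ELBO forward pass over a batch of count rows.

    Returns a result dict (per-cell and summed objective / reconstruction /
    KL terms) and a cache consumed by the backward pass in
    :mod:`countvae.training`.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] == 0:
        raise DomainError("batch must contain at least one cell")
    zm, zls, sm, sls, enc_cache = _encoder_forward(Y, state)
    z_scale = np.exp(zls)
    s_scale = np.exp(sls)
    u = zm + z_scale * eps_z
    if state.latent_family == "ln":
        t = _row_softmax(u)
    else:
        t = u
    logs = sm + s_scale * eps_s
    s = np.exp(logs)

    log_mu, dec_cache = _decode_forward(
        t, state, bn_training=bn_training, update_running=update_running
    )
    mu = np.exp(log_mu)
    mean = s[:, None] * mu + MEAN_EPS
    theta = state.theta
    ll = nb_log_pmf(Y, mean, theta)
    recon = ll.sum(axis=1)

    kl_z = (-zls + 0.5 * (np.exp(2 * zls) + zm**2) - 0.5).sum(axis=1)
    kl_s = (
        np.log(state.s_sigma)
        - sls
        + (np.exp(2 * sls) + (sm - state.s_mu) ** 2) / (2 * state.s_sigma**2)
        - 0.5
    )
    kl = kl_z + kl_s
    objective = recon - kl_weight * kl

    result = {
        "objective": float(objective.sum()),
        "reconstruction": float(recon.sum()),
        "kl": float(kl.sum()),
        "per_cell_objective": objective,
        "per_cell_recon": recon,
        "per_cell_kl": kl,
    }
    cache = {
        "Y": Y,
        "enc": enc_cache,
        "zm": zm,
        "zls": zls,
        "sm": sm,
        "sls": sls,
        "z_scale": z_scale,
        "s_scale": s_scale,
        "eps_z": eps_z,
        "eps_s": eps_s,
        "u": u,
        "t": t,
        "s": s,
        "mu": mu,
        "mean": mean,
        "theta": theta,
        "dec": dec_cache,
        "kl_weight": kl_weight,
    }
    return result, cache


def elbo(
    counts,
    state: ModelState,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise: tuple[np.ndarray, np.ndarray] | None = None,
    kl_weight: float = 1.0,
    bn_training: bool = False,
) -> tuple[float, float, float]:
    """Single-sample ELBO of a batch: (objective, reconstruction, KL sums).

    The objective is ``reconstruction - kl_weight * KL`` summed over the
    batch; one reparameterized draw of (z, s) per cell.
    """
    Y = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    Y = np.atleast_2d(Y)
    if Y.shape[0] == 0:
        raise DomainError("batch must contain at least one cell")
    if noise is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        eps_z = rng.standard_normal((Y.shape[0], state.n_latent))
        eps_s = rng.standard_normal(Y.shape[0])
    else:
        eps_z, eps_s = noise
    result, _ = forward_elbo(
        Y, state, eps_z, eps_s, kl_weight=kl_weight, bn_training=bn_training
    )
    return result["objective"], result["reconstruction"], result["kl"]


def posterior_mean_latent(counts, state: ModelState) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free latent embedding: posterior locations (softmaxed for ln).

    Returns (Z, s) with ``Z`` of shape cells x factors and ``s = exp(s_loc)``.
    """
    post = encode(counts, state)
    if state.latent_family == "ln":
        Z = _row_softmax(post.z_loc)
    else:
        Z = post.z_loc
    return Z, np.exp(post.s_loc)
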