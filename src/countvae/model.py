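"""Generative model for count matrices.

A cell ``n`` is represented by a low-dimensional coordinate vector ``z_n``
(either unconstrained Gaussian or simplex-valued via a softmax of a
Gaussian).  A linear map ``z W^T`` followed by a row-wise softmax produces
per-gene mean proportions ``mu_n``; counts arise from a Gamma-Poisson
(negative binomial) emission scaled by a lognormal per-cell exposure
``s_n``:

    z_n  ~ Normal(0, I)           (or softmax(Normal(0, I)) rows)
    s_n  ~ LogNormal(s_mu, s_sigma^2)
    mu_n = softmax(z_n W^T)       (optionally batch-normalized pre-softmax)
    v_ng ~ Gamma(shape=theta_g, mean=mu_ng)
    y_ng ~ Poisson(v_ng * s_n)

The Gamma-Poisson emission is evaluated through its analytic negative
binomial marginal (:func:`nb_log_pmf`) rather than by sampling ``v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, log_softmax

from .errors import ConfigurationError, DomainError, ShapeError, StateError

__all__ = [
    "BatchNormState",
    "GenerativeParams",
    "CountMatrix",
    "LatentState",
    "decode_linear",
    "nb_log_pmf",
    "sample_generative",
]

#: additive floor applied to composite NB means inside training loops
MEAN_EPS = 1e-10

LATENT_FAMILIES = ("normal", "ln")


def _canonical_family(tag: str) -> str:
    alias = {"normal": "normal", "ln": "ln", "logistic-normal": "ln",
             "logistic_normal": "ln"}
    try:
        return alias[tag]
    except KeyError:
        raise ConfigurationError(
            f"unknown latent family {tag!r}; expected one of "
            f"{sorted(set(alias))}"
        ) from None


@dataclass
class BatchNormState:
    """Running statistics and affine parameters for pre-softmax batch norm."""

    running_mean: np.ndarray
    running_var: np.ndarray
    scale: np.ndarray
    shift: np.ndarray
    eps: float = 1e-5
    momentum: float = 0.1

    @classmethod
    def initial(cls, n_genes: int) -> "BatchNormState":
        return cls(
            running_mean=np.zeros(n_genes),
            running_var=np.ones(n_genes),
            scale=np.ones(n_genes),
            shift=np.zeros(n_genes),
        )

    @property
    def populated(self) -> bool:
        return (
            self.running_mean is not None
            and self.running_var is not None
            and np.all(np.isfinite(self.running_mean))
            and np.all(np.isfinite(self.running_var))
        )


@dataclass
class GenerativeParams:
    """Decoder-side parameters of the generative model.

    Parameters
    ----------
    W
        Loading matrix, genes x factors.  Column ``d`` is the gene program
        attached to latent coordinate ``d``.
    theta
        Per-gene inverse dispersions (Gamma shapes); strictly positive.
    s_mu, s_sigma
        Mean and standard deviation of the log-exposure prior.
    bn_state
        Optional batch-norm state applied to the pre-softmax activations.
    """

    W: np.ndarray
    theta: np.ndarray
    s_mu: float = 0.0
    s_sigma: float = 1.0
    bn_state: Optional[BatchNormState] = None

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.W.ndim != 2:
            raise ShapeError(f"W must be 2-D (genes x factors), got {self.W.ndim}-D")
        G, D = self.W.shape
        if G < 2 or D < 1:
            raise ShapeError(f"need at least 2 genes and 1 factor, got W of shape {self.W.shape}")
        if self.theta.shape != (G,):
            raise ShapeError(
                f"theta must have shape ({G},) to match W, got {self.theta.shape}"
            )
        if not np.all(self.theta > 0):
            raise DomainError("all entries of theta must be strictly positive")
        if not self.s_sigma > 0:
            raise DomainError("s_sigma must be strictly positive")

    @property
    def n_genes(self) -> int:
        return self.W.shape[0]

    @property
    def n_factors(self) -> int:
        return self.W.shape[1]


@dataclass
class CountMatrix:
    """A cells x genes matrix of non-negative integer counts."""

    counts: np.ndarray
    gene_ids: Sequence[str]
    cell_ids: Sequence[str]

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ShapeError("counts must be a 2-D cells x genes matrix")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if np.any(np.mod(counts, 1) != 0):
                raise DomainError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise DomainError("counts must be non-negative")
        self.counts = counts.astype(np.int64, copy=False)
        n, g = counts.shape
        if n < 1 or g < 2:
            raise ShapeError(f"need at least 1 cell and 2 genes, got {counts.shape}")
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if len(self.gene_ids) != g:
            raise ShapeError(
                f"{len(self.gene_ids)} gene identifiers for {g} gene columns"
            )
        if len(self.cell_ids) != n:
            raise ShapeError(
                f"{len(self.cell_ids)} cell identifiers for {n} cell rows"
            )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[idx],
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in np.atleast_1d(idx)],
        )


@dataclass
class LatentState:
    """Latent variables accompanying a (sampled or inferred) count matrix."""

    z: np.ndarray
    s: np.ndarray
    v: Optional[np.ndarray] = None
    latent_family: str = "normal"

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.z.ndim != 2:
            raise ShapeError("z must be 2-D (cells x factors)")
        if self.s.shape != (self.z.shape[0],):
            raise ShapeError("s must be a vector with one entry per cell")
        if not np.all(self.s > 0):
            raise DomainError("exposures s must be strictly positive")
        self.latent_family = _canonical_family(self.latent_family)
        if self.latent_family == "ln":
            if np.any(self.z < -1e-9):
                raise DomainError("simplex latent coordinates must be non-negative")
            if np.any(np.abs(self.z.sum(axis=1) - 1.0) > 1e-6):
                raise DomainError("simplex latent rows must sum to 1 within 1e-6")


def decode_linear(
    z: np.ndarray,
    params: GenerativeParams,
    use_batch_norm: bool = False,
    training_mode: bool = False,
    return_logits: bool = False,
) -> np.ndarray:
    """Map latent coordinates to per-gene mean proportions.

    Computes ``softmax(z W^T)`` row-wise, optionally passing the linear
    pre-activation through batch normalization first.  In training mode the
    batch statistics of the supplied rows are used; in evaluation mode the
    stored running statistics are required.

    Parameters
    ----------
    z
        A single D-vector or an N x D matrix of latent coordinates.
    params
        Generative parameters holding ``W`` and (optionally) batch-norm state.
    use_batch_norm
        Apply the batch-norm transform to the pre-softmax activations.
    training_mode
        Use batch statistics instead of running statistics.
    return_logits
        Return the (batch-normalized) pre-softmax activations instead of
        the softmax output.

    Returns
    -------
    numpy.ndarray
        Rows on the gene simplex (or raw logits), same leading shape as ``z``.
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    z2 = z[None, :] if single else z
    if z2.ndim != 2 or z2.shape[1] != params.n_factors:
        raise ShapeError(
            f"z has trailing dimension {z2.shape[-1] if z2.ndim else 0}, "
            f"but W has {params.n_factors} factors"
        )
    pre = z2 @ params.W.T
    if use_batch_norm:
        bn = params.bn_state
        if bn is None:
            raise StateError("batch norm requested but bn_state is absent")
        if training_mode:
            mean = pre.mean(axis=0)
            var = pre.var(axis=0)
        else:
            if not bn.populated:
                raise StateError(
                    "batch norm in evaluation mode requires populated running statistics"
                )
            mean, var = bn.running_mean, bn.running_var
        pre = bn.scale * (pre - mean) / np.sqrt(var + bn.eps) + bn.shift
    out = pre if return_logits else np.exp(log_softmax(pre, axis=1))
    return out[0] if single else out


def nb_log_pmf(y, mean, theta):
    """Log pmf of the negative binomial in (mean, inverse-dispersion) form.

    This is the analytic marginal of ``v ~ Gamma(shape=theta, mean=mean)``
    followed by ``y ~ Poisson(v)``:

        log NB(y; m, t) = lgamma(y+t) - lgamma(t) - lgamma(y+1)
                          + t*log(t/(t+m)) + y*log(m/(t+m))

    All arguments broadcast elementwise.
    """
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(y < 0) or np.any(np.mod(y, 1) != 0):
        raise DomainError("y must contain non-negative integers")
    if np.any(mean <= 0):
        raise DomainError("mean must be strictly positive")
    if np.any(theta <= 0):
        raise DomainError("theta must be strictly positive")
    log_t_tm = np.log(theta) - np.log(theta + mean)
    log_m_tm = np.log(mean) - np.log(theta + mean)
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * log_t_tm
        + y * log_m_tm
    )


def sample_generative(
    params: GenerativeParams,
    n_cells: int,
    latent_family: str = "normal",
    seed: int = 0,
    use_batch_norm: bool = False,
) -> tuple[CountMatrix, LatentState]:
    """Forward-sample cells from the generative model.

    Draws latent coordinates (Gaussian, or softmax-of-Gaussian rows for the
    logistic-normal family), lognormal exposures, per-cell-gene Gamma rates
    and Poisson counts.  The latent truth is returned alongside the counts
    so recovery can be scored.
    """
    family = _canonical_family(latent_family)
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    G, D = params.W.shape
    raw = rng.standard_normal((n_cells, D))
    if family == "ln":
        shifted = raw - raw.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        z = e / e.sum(axis=1, keepdims=True)
    else:
        z = raw
    s = np.exp(params.s_mu + params.s_sigma * rng.standard_normal(n_cells))
    mu = decode_linear(z, params, use_batch_norm=use_batch_norm, training_mode=False)
    v = rng.gamma(shape=params.theta, scale=mu / params.theta)
    y = rng.poisson(v * s[:, None]).astype(np.int64)
    counts = CountMatrix(
        counts=y,
        gene_ids=[f"gene_{g:04d}" for g in range(G)],
        cell_ids=[f"cell_{n:06d}" for n in range(n_cells)],
    )
    latent = LatentState(z=z, s=s, v=v, latent_family=family)
    return counts, latent
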