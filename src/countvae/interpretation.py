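"""Factor interpretation: loadings, factor covariance, ordering, top genes.

The latent representation ``Z`` of a fitted linear-decoder model is
interpreted through (i) the effective gene loadings of each factor and
(ii) the eigendecomposition of the correlation matrix of ``Z``, which
quantifies the proportion of variance explained by each factor and exposes
the rank deficiency of simplex-valued latent spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, UnsupportedModelError
from .inference import ModelState, posterior_mean_latent
from .model import CountMatrix

__all__ = [
    "FactorReport",
    "SimplexRankDiagnostic",
    "get_loadings",
    "center_scale",
    "factor_covariance",
    "order_factors",
    "simplex_rank_check",
    "top_genes",
    "factor_report",
]


def get_loadings(fit_or_state) -> np.ndarray:
    """Effective genes x factors loading matrix of a linear-decoder model.

    Without batch norm this is the decoder weight matrix ``W`` itself.  With
    batch norm, each gene row is rescaled by ``scale_g / sqrt(var_g + eps)``
    so that the returned matrix is the evaluation-mode linear map from ``z``
    to pre-softmax logits (additive offsets do not enter a loading matrix).
    """
    state: ModelState = getattr(fit_or_state, "state", fit_or_state)
    if state.decoder != "linear":
        raise UnsupportedModelError(
            "loadings are only defined for linear-decoder models"
        )
    W = state.W
    if state.use_batch_norm:
        bn = state.bn
        factor = bn.scale / np.sqrt(bn.running_var + bn.eps)
        return W * factor[:, None]
    return W.copy()


def center_scale(Z: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Center columns to mean zero and scale non-degenerate ones to unit sd.

    Columns with zero spread are centered and left at zero; a warning is
    emitted for them.  ``ddof=1`` (sample standard deviation) is the
    convention used by :func:`factor_covariance`; ``ddof=0`` gives
    population scaling.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise DomainError("Z must be 2-D with at least 2 rows")
    centered = Z - Z.mean(axis=0)
    sd = centered.std(axis=0, ddof=ddof)
    degenerate = sd <= 1e-300
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} latent column(s) have zero spread; "
            "left at zero after centering",
            stacklevel=2,
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    out = centered / safe_sd
    out[:, degenerate] = 0.0
    return out


def factor_covariance(Z: np.ndarray) -> np.ndarray:
    """Correlation-scaled factor covariance ``Zhat^T Zhat / (N - 1)``.

    ``Zhat`` is the centered, sample-sd-scaled version of ``Z``; the result
    is symmetric with unit diagonal for non-degenerate columns.
    """
    Zhat = center_scale(Z, ddof=1)
    n = Zhat.shape[0]
    return (Zhat.T @ Zhat) / (n - 1)


def order_factors(
    cov: np.ndarray, sym_tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecompose a factor covariance and order factors by variance.

    Returns ``(eigenvalues, variance_explained, factor_order)`` with
    eigenvalues sorted descending and ``variance_explained`` their share of
    the trace (tiny negative eigenvalues are clipped to zero before
    normalizing).  ``factor_order[r]`` is the original factor whose
    component dominates the rank-``r`` eigenvector; when several
    eigenvectors share a dominant factor, assignment is greedy over
    decreasing eigenvalue.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise DomainError("covariance must be a square matrix")
    scale = max(np.abs(cov).max(), 1.0)
    if np.abs(cov - cov.T).max() > sym_tol * scale:
        raise DomainError("covariance matrix is not symmetric within tolerance")
    evals, evecs = np.linalg.eigh((cov + cov.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    clipped = np.clip(evals, 0.0, None)
    total = clipped.sum()
    variance_explained = clipped / total if total > 0 else np.full_like(clipped, 1.0 / len(clipped))
    D = len(evals)
    factor_order = np.full(D, -1, dtype=int)
    taken = np.zeros(D, dtype=bool)
    for r in range(D):
        comp = np.abs(evecs[:, r])
        for d in np.argsort(comp)[::-1]:
            if not taken[d]:
                factor_order[r] = d
                taken[d] = True
                break
    return evals, variance_explained, factor_order


@dataclass
class SimplexRankDiagnostic:
    smallest_eigenvalue: float
    largest_eigenvalue: float
    rank_deficient: bool


def simplex_rank_check(
    Z: np.ndarray, rel_tol: float = 1e-8, require_simplex: bool = True
) -> SimplexRankDiagnostic:
    """Detect the linear dependence among simplex-valued factors.

    Computes the smallest eigenvalue of the centered (unscaled) covariance
    of ``Z`` and flags rank deficiency when it falls below ``rel_tol``
    times the largest eigenvalue.  Rows summing to a constant always
    trigger the flag: they live in an affine subspace of dimension D - 1.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise DomainError("Z must be 2-D with at least 2 rows")
    if require_simplex:
        if np.any(Z < -1e-9) or np.any(np.abs(Z.sum(axis=1) - 1.0) > 1e-6):
            raise DomainError("rows must be non-negative and sum to 1 (simplex)")
    centered = Z - Z.mean(axis=0)
    cov = centered.T @ centered / (Z.shape[0] - 1)
    evals = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    smallest, largest = float(evals[0]), float(evals[-1])
    deficient = largest <= 0.0 or smallest <= rel_tol * largest
    return SimplexRankDiagnostic(
        smallest_eigenvalue=smallest,
        largest_eigenvalue=largest,
        rank_deficient=bool(deficient),
    )


def top_genes(
    loadings: np.ndarray,
    gene_ids: Sequence[str],
    factor: int,
    k: int,
    direction: str = "both",
) -> list[tuple[str, float]]:
    """Top-k genes of one factor, ranked by loading weight.

    ``direction='both'`` ranks by absolute weight, ``'positive'`` by signed
    weight descending, ``'negative'`` by signed weight ascending.  Ties are
    broken by lexicographic gene identifier.  ``factor`` is 0-based.
    """
    loadings = np.asarray(loadings, dtype=float)
    G, D = loadings.shape
    if not (0 <= factor < D):
        raise IndexError(f"factor {factor} out of range for {D} factors")
    if k < 1:
        raise DomainError("k must be >= 1")
    if direction not in ("both", "positive", "negative"):
        raise DomainError(f"unknown direction {direction!r}")
    col = loadings[:, factor]
    if direction == "both":
        keys = -np.abs(col)
    elif direction == "positive":
        keys = -col
    else:
        keys = col
    order = sorted(range(G), key=lambda g: (keys[g], str(gene_ids[g])))
    return [(str(gene_ids[g]), float(col[g])) for g in order[: min(k, G)]]


@dataclass
class FactorReport:
    """Ordered factor summary of a fitted linear-decoder model."""

    loadings: np.ndarray
    gene_ids: list
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    factor_order: np.ndarray
    top_genes: list  # one ranked [(gene, weight), ...] per factor, in factor_order
    simplex_diagnostic: Optional[SimplexRankDiagnostic] = None

    def to_dict(self) -> dict:
        d = {
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "variance_explained": [float(v) for v in self.variance_explained],
            "factor_order": [int(v) for v in self.factor_order],
            "top_genes": [
                [{"gene": g, "weight": w} for g, w in lst] for lst in self.top_genes
            ],
        }
        if self.simplex_diagnostic is not None:
            sd = self.simplex_diagnostic
            d["simplex_rank_deficient"] = sd.rank_deficient
            d["simplex_smallest_eigenvalue"] = sd.smallest_eigenvalue
            d["simplex_largest_eigenvalue"] = sd.largest_eigenvalue
        return d


def factor_report(fit_result, data: CountMatrix, k_top: int = 10) -> FactorReport:
    """Build a :class:`FactorReport` from a fit and a dataset.

    Embeds the cells at their posterior mean, eigendecomposes the factor
    correlation matrix, orders factors by variance explained, and attaches
    per-factor top-gene lists.  For logistic-normal fits the simplex rank
    diagnostic is included.
    """
    state: ModelState = fit_result.state
    gene_ids = list(fit_result.gene_ids)
    loadings = get_loadings(state)
    Z, _ = posterior_mean_latent(data, state)
    cov = factor_covariance(Z)
    evals, ve, order = order_factors(cov)
    tops = [top_genes(loadings, gene_ids, int(d), k_top) for d in order]
    diag = None
    if state.latent_family == "ln":
        diag = simplex_rank_check(Z)
    return FactorReport(
        loadings=loadings,
        gene_ids=gene_ids,
        eigenvalues=evals,
        variance_explained=ve,
        factor_order=order,
        top_genes=tops,
        simplex_diagnostic=diag,
    )
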