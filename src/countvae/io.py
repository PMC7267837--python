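"""Readers and writers for count matrices, model state and reports.

Count matrices are exchanged as Matrix Market coordinate integer files with
gene/barcode TSV sidecars (accepted in the common genes-by-cells dialect
and transposed on load) or as CSV with a gene-name header.  Model state is
stored as an ``npz`` weight archive plus a JSON metadata file carrying the
configuration and a gene-schema hash so mismatched datasets are refused.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import FormatError, ShapeError
from .inference import EncoderConfig, EncoderState, ModelState
from .model import BatchNormState, CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "write_loadings_csv",
    "write_latent_csv",
    "write_history_csv",
    "write_report_json",
    "save_model",
    "load_model",
    "gene_schema_hash",
]


def _synth_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i + 1:04d}" for i in range(n)]


def _read_id_file(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def _validate_integer(dense: np.ndarray) -> np.ndarray:
    frac = np.mod(dense, 1) != 0
    if np.any(frac):
        i, j = np.argwhere(frac)[0]
        raise FormatError(
            f"non-integer entry {dense[i, j]!r} at row {i + 1}, column {j + 1}"
        )
    neg = dense < 0
    if np.any(neg):
        i, j = np.argwhere(neg)[0]
        raise FormatError(
            f"negative entry {dense[i, j]!r} at row {i + 1}, column {j + 1}"
        )
    return dense.astype(np.int64)


def read_counts(
    path,
    fmt: str | None = None,
    orientation: str | None = None,
    genes_path=None,
    cells_path=None,
) -> CountMatrix:
    """Load a count matrix from MTX (plus sidecars) or CSV.

    Default orientation is genes-by-cells for MTX and cells-by-genes for
    CSV, following the dominant conventions of each format.  Missing
    identifier sidecars produce synthesized identifiers with a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix.lower() in (".mtx", ".mm") else "csv"
    if fmt not in ("mtx", "csv"):
        raise FormatError(f"unknown format {fmt!r}")
    if orientation is None:
        orientation = "genes-by-cells" if fmt == "mtx" else "cells-by-genes"
    if orientation not in ("genes-by-cells", "cells-by-genes"):
        raise FormatError(f"unknown orientation {orientation!r}")

    if fmt == "mtx":
        try:
            mat = spio.mmread(path)
        except Exception as exc:  # noqa: BLE001 - rewrap parser errors
            raise FormatError(f"failed to parse Matrix Market file {path}: {exc}") from exc
        dense = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        dense = _validate_integer(np.asarray(dense, dtype=float))
        if genes_path is None:
            for cand in ("genes.tsv", "features.tsv"):
                if (path.parent / cand).exists():
                    genes_path = path.parent / cand
                    break
        if cells_path is None and (path.parent / "barcodes.tsv").exists():
            cells_path = path.parent / "barcodes.tsv"
        gene_ids = _read_id_file(Path(genes_path)) if genes_path else None
        cell_ids = _read_id_file(Path(cells_path)) if cells_path else None
        if orientation == "genes-by-cells":
            dense = dense.T
        n, g = dense.shape
        if gene_ids is None:
            warnings.warn("no gene identifier file; synthesizing gene_0001...", stacklevel=2)
            gene_ids = _synth_ids("gene", g)
        if cell_ids is None:
            warnings.warn("no cell identifier file; synthesizing cell_0001...", stacklevel=2)
            cell_ids = _synth_ids("cell", n)
        if len(gene_ids) != g:
            raise FormatError(
                f"{len(gene_ids)} gene identifiers for {g} genes"
            )
        if len(cell_ids) != n:
            raise FormatError(
                f"{len(cell_ids)} cell identifiers for {n} cells"
            )
        return CountMatrix(counts=dense, gene_ids=gene_ids, cell_ids=cell_ids)

    df = pd.read_csv(path, index_col=0)
    dense = _validate_integer(df.to_numpy(dtype=float))
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if orientation == "genes-by-cells":
        dense = dense.T
        gene_ids, cell_ids = row_ids, col_ids
    else:
        gene_ids, cell_ids = col_ids, row_ids
    return CountMatrix(counts=dense, gene_ids=gene_ids, cell_ids=cell_ids)


def write_counts(cm: CountMatrix, path, fmt: str = "mtx") -> None:
    """Write counts as MTX (genes-by-cells, with TSV sidecars) or CSV."""
    path = Path(path)
    if fmt == "mtx":
        spio.mmwrite(
            path, sparse.coo_matrix(cm.counts.T), field="integer"
        )
        with open(path.parent / "genes.tsv", "w") as fh:
            fh.write("\n".join(cm.gene_ids) + "\n")
        with open(path.parent / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(cm.cell_ids) + "\n")
    elif fmt == "csv":
        pd.DataFrame(cm.counts, index=cm.cell_ids, columns=cm.gene_ids).to_csv(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def write_loadings_csv(loadings: np.ndarray, gene_ids, path) -> None:
    cols = [f"Z{d + 1}" for d in range(loadings.shape[1])]
    pd.DataFrame(loadings, index=list(gene_ids), columns=cols).to_csv(
        path, index_label="gene"
    )


def write_latent_csv(Z: np.ndarray, cell_ids, path, s: np.ndarray | None = None) -> None:
    cols = [f"Z{d + 1}" for d in range(Z.shape[1])]
    df = pd.DataFrame(Z, index=list(cell_ids), columns=cols)
    if s is not None:
        df["exposure"] = s
    df.to_csv(path, index_label="cell")


def write_history_csv(history: list, path) -> None:
    pd.DataFrame(history)[["epoch", "train_objective", "heldout_objective"]].to_csv(
        path, index=False
    )


def write_report_json(report, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def gene_schema_hash(gene_ids) -> str:
    h = hashlib.sha256("\n".join(map(str, gene_ids)).encode())
    return h.hexdigest()[:16]


def save_model(fit_result, out_dir) -> None:
    """Serialize a fit to ``weights.npz`` + ``meta.json`` in a directory."""
    from .training import FitResult  # local import to avoid cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    state: ModelState = fit_result.state
    arrays = {"log_theta": state.log_theta}
    if state.W is not None:
        arrays["dec_W"] = state.W
    for i, (W, b) in enumerate(state.encoder.layers):
        arrays[f"enc{i}_W"], arrays[f"enc{i}_b"] = W, b
    for key, (W, b) in state.encoder.heads.items():
        arrays[f"head_{key}_W"], arrays[f"head_{key}_b"] = W, b
    if state.dec_nn is not None:
        for k, v in state.dec_nn.items():
            arrays[f"nn_{k}"] = v
    if state.bn is not None:
        arrays["bn_running_mean"] = state.bn.running_mean
        arrays["bn_running_var"] = state.bn.running_var
        arrays["bn_scale"] = state.bn.scale
        arrays["bn_shift"] = state.bn.shift
    np.savez(out_dir / "weights.npz", **arrays)
    meta = {
        "n_genes": state.n_genes,
        "n_latent": state.n_latent,
        "latent_family": state.latent_family,
        "decoder": state.decoder,
        "use_batch_norm": state.use_batch_norm,
        "s_mu": state.s_mu,
        "s_sigma": state.s_sigma,
        "enc_config": {
            "n_hidden": state.enc_config.n_hidden,
            "n_layers": state.enc_config.n_layers,
            "activation": state.enc_config.activation,
            "input_transform": state.enc_config.input_transform,
        },
        "n_encoder_layers": len(state.encoder.layers),
        "gene_ids": list(fit_result.gene_ids),
        "gene_schema_hash": gene_schema_hash(fit_result.gene_ids),
        "seed": int(fit_result.seed),
    }
    with open(out_dir / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(model_dir):
    """Load a serialized fit; returns a minimal object with state + gene_ids."""
    from .training import FitResult, ModelConfig, TrainConfig

    model_dir = Path(model_dir)
    with open(model_dir / "meta.json") as fh:
        meta = json.load(fh)
    npz = np.load(model_dir / "weights.npz")
    enc_cfg = EncoderConfig(**meta["enc_config"])
    layers = [
        (npz[f"enc{i}_W"], npz[f"enc{i}_b"]) for i in range(meta["n_encoder_layers"])
    ]
    heads = {
        key: (npz[f"head_{key}_W"], npz[f"head_{key}_b"])
        for key in ("z_loc", "z_logscale", "s_loc", "s_logscale")
    }
    encoder = EncoderState(
        layers=layers,
        heads=heads,
        n_genes=meta["n_genes"],
        n_latent=meta["n_latent"],
    )
    bn = None
    if meta["use_batch_norm"]:
        bn = BatchNormState(
            running_mean=npz["bn_running_mean"],
            running_var=npz["bn_running_var"],
            scale=npz["bn_scale"],
            shift=npz["bn_shift"],
        )
    dec_nn = None
    if meta["decoder"] == "nn":
        dec_nn = {k: npz[f"nn_{k}"] for k in ("d1_W", "d1_b", "d2_W", "d2_b")}
    state = ModelState(
        W=npz["dec_W"] if "dec_W" in npz else None,
        log_theta=npz["log_theta"],
        s_mu=meta["s_mu"],
        s_sigma=meta["s_sigma"],
        encoder=encoder,
        enc_config=enc_cfg,
        n_latent=meta["n_latent"],
        latent_family=meta["latent_family"],
        decoder=meta["decoder"],
        use_batch_norm=meta["use_batch_norm"],
        bn=bn,
        dec_nn=dec_nn,
    )
    return FitResult(
        state=state,
        history=[],
        model_config=ModelConfig(
            n_latent=meta["n_latent"],
            latent_family=meta["latent_family"],
            decoder=meta["decoder"],
            use_batch_norm=meta["use_batch_norm"],
            encoder=enc_cfg,
        ),
        train_config=TrainConfig(n_epochs=1),
        seed=meta["seed"],
        gene_ids=meta["gene_ids"],
        train_idx=np.array([], dtype=int),
        heldout_idx=np.array([], dtype=int),
    )


def check_gene_schema(fit_result, cm: CountMatrix) -> None:
    if gene_schema_hash(fit_result.gene_ids) != gene_schema_hash(cm.gene_ids):
        raise ShapeError(
            "gene identifiers of the dataset do not match the trained model"
        )
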