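"""QC filtering, log-normalization, HVG selection and label attachment.

Cells are filtered on the number of detected genes with *strict*
inequalities (< min or > max removed; boundary cells kept).  Normalization
is the standard per-cell scaling to a fixed total followed by log1p.
Highly variable genes are ranked by clipped standardized variance around a
quadratic mean-variance trend — a deterministic, loess-free variant of the
"vst" scheme.  Clustering is deliberately not re-implemented: subtype
labels are pluggable inputs (synthetic truth or user-supplied), with a
small k-means-on-PCs helper provided as plumbing only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Audit of a qc_filter call: boundary cells (exactly min or max
    detected genes) are retained — removal uses strict inequalities."""

    n_input: int
    n_retained: int
    removed_low: int
    removed_high: int
    min_genes: int
    max_genes: int
    removed_cells: list[str] = field(default_factory=list)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def detected_genes_per_cell(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sparse.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel()
    return (np.asarray(X) > 0).sum(axis=1)


def qc_filter(adata: ad.AnnData, min_genes: int = 200, max_genes: int = 10000
              ) -> tuple[ad.AnnData, QCReport]:
    """Remove cells expressing fewer than ``min_genes`` or more than
    ``max_genes`` genes (strict; boundary values are kept).  Idempotent."""
    detected = detected_genes_per_cell(adata)
    low = detected < min_genes
    high = detected > max_genes
    keep = ~(low | high)
    if not keep.any():
        raise ValueError("qc_filter removed every cell; check thresholds")
    report = QCReport(
        n_input=int(adata.n_obs),
        n_retained=int(keep.sum()),
        removed_low=int(low.sum()),
        removed_high=int(high.sum()),
        min_genes=min_genes,
        max_genes=max_genes,
        removed_cells=adata.obs_names[~keep].tolist(),
    )
    out = adata[keep].copy()
    out.obs["n_genes_detected"] = detected[keep]
    return out, report


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """log1p(count / cell_total * scale_factor) per cell.

    Returns a new AnnData whose ``.X`` holds the normalized values
    (float64) and whose ``.uns['normalization']`` records the scheme.
    Scale-invariant per cell: doubling a cell's counts leaves its column
    unchanged.
    """
    X = _dense(adata.X).astype(np.float64)
    totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = adata.obs_names[zero].tolist()
        raise ValueError(f"cells with zero total counts cannot be normalized: {bad[:5]}")
    norm = np.log1p(X / totals[:, None] * scale_factor)
    out = ad.AnnData(X=norm, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns.update(adata.uns)
    out.uns["normalization"] = {"scheme": "log1p_total", "scale_factor": scale_factor}
    return out


def select_hvgs(norm: ad.AnnData, n_top: int = 2000) -> list[str]:
    """Top ``n_top`` genes by clipped standardized variance.

    A degree-2 polynomial is fit to log10(variance) vs log10(mean) over
    genes with positive mean and variance; per-gene values are
    standardized by the trend-predicted sd, clipped to +-sqrt(n_cells),
    and re-ranked by the variance of the clipped values.  Deterministic;
    ties break by gene id (lexicographic).
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > norm.n_vars:
        raise ValueError(f"n_top={n_top} exceeds the {norm.n_vars} available genes")
    X = _dense(norm.X)
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n > 1 else np.zeros(X.shape[1])

    std_var = np.zeros(X.shape[1])
    ok = (var > 0) & (mean > 0)
    if ok.sum() >= 3:
        coef = np.polyfit(np.log10(mean[ok]), np.log10(var[ok]), deg=2)
        exp_sd = np.sqrt(10 ** np.polyval(coef, np.log10(mean[ok])))
        clip = np.sqrt(n)
        z = (X[:, ok] - mean[ok][None, :]) / exp_sd[None, :]
        z = np.clip(z, -clip, clip)
        std_var[ok] = z.var(axis=0, ddof=1)
    else:
        std_var[ok] = var[ok]

    order = sorted(range(norm.n_vars), key=lambda i: (-std_var[i], norm.var_names[i]))
    return [norm.var_names[i] for i in order[:n_top]]


def attach_labels(adata: ad.AnnData, labels: pd.DataFrame, *,
                  allow_partial: bool = False, ignore_unknown: bool = False) -> ad.AnnData:
    """Populate obs subtype / major_type columns from an external table
    keyed by cell_id.  Duplicate cell ids in the table are an error;
    unlabeled cells become "unassigned" only with ``allow_partial``."""
    if "cell_id" in labels.columns:
        labels = labels.set_index("cell_id")
    if labels.index.duplicated().any():
        dups = labels.index[labels.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate cell_id rows in label table: {dups[:5]}")
    unknown = labels.index.difference(adata.obs_names)
    if len(unknown) and not ignore_unknown:
        raise ValueError(f"label table references unknown cells: {list(unknown[:5])}")
    out = adata.copy()
    missing = out.obs_names.difference(labels.index)
    if len(missing) and not allow_partial:
        raise ValueError(f"{len(missing)} cells missing from label table (use allow_partial)")
    for col in labels.columns:
        aligned = labels[col].reindex(out.obs_names)
        if col in ("subtype", "major_type"):
            aligned = aligned.fillna("unassigned")
        out.obs[col] = aligned.values
    log.info("attach_labels: %d/%d cells labeled", len(out.obs_names) - len(missing), out.n_obs)
    return out


def kmeans_subtypes(norm: ad.AnnData, n_clusters: int = 11, n_pcs: int = 20,
                    seed: int = 0) -> pd.Series:
    """Convenience k-means-on-PCs clusterer (plumbing only; real analyses
    should attach externally derived labels)."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = _dense(norm.X)
    X = X - X.mean(axis=0, keepdims=True)
    pcs = PCA(n_components=min(n_pcs, min(X.shape) - 1), random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit(pcs)
    return pd.Series([f"K{c + 1}" for c in km.labels_], index=norm.obs_names, name="subtype")
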