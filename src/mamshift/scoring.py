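"""Per-cell gene-set module scoring with expression-bin-matched controls.

The score of a cell for a gene set is the mean normalized expression of
the set genes minus the mean expression of control genes drawn, for each
set gene, from the same dataset-average-expression bin.  Genes are ranked
by average expression (ties broken by gene id), cut into ``n_bins``
equal-frequency bins, and ``n_ctrl`` controls are sampled without
replacement per set gene from its bin (excluding the gene itself), using
a seeded RNG.  The control term of a cell is the average over set genes
of the per-gene control means, so each set gene contributes equally.

The packaged default set is the 13-gene MAM (mitochondria-associated ER
membrane) program.  Missing set genes are dropped with a warning rather
than failing, since some symbols ("Vdac", "Ptpip51") are aliases that a
given annotation may lack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from mamshift.preprocessing import _dense
from mamshift.simulate import MAM_GENES

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError("gene set is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene set contains duplicates")

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "GeneSet":
        """Read a GMT line (name<TAB>desc<TAB>genes...) or a one-gene-per-
        line text file."""
        text = open(path).read().strip()
        first = text.splitlines()[0]
        if "\t" in first:
            parts = first.split("\t")
            return cls(name=name or parts[0], genes=tuple(parts[2:]))
        genes = tuple(g.strip() for g in text.splitlines() if g.strip())
        return cls(name=name or "custom", genes=genes)


MAM_GENE_SET = GeneSet(name="MAM", genes=MAM_GENES)


@dataclass
class ScoreResult:
    scores: pd.Series            # one score per cell, indexed by cell id
    gene_set: str
    genes_used: list[str]
    genes_missing: list[str]
    params: dict


def _expression_bins(avg: np.ndarray, gene_ids: list[str], n_bins: int) -> list[np.ndarray]:
    """Equal-frequency bins of genes by dataset-average expression; the
    ordering key is (avg, gene id) so ties are handled stably."""
    order = sorted(range(len(gene_ids)), key=lambda i: (avg[i], gene_ids[i]))
    return [np.array(chunk) for chunk in np.array_split(np.array(order), n_bins)]


def module_score(norm: ad.AnnData, gene_set: GeneSet, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> ScoreResult:
    """Binned-control module score per cell.

    score(cell) = mean_{g in set} x[cell, g]
                - mean_{g in set} mean_{c in controls(g)} x[cell, c]

    Deterministic under a fixed seed.  A bin with fewer than ``n_ctrl``
    eligible genes contributes all of them (logged).
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be >= 1")
    gene_ids = list(norm.var_names)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    used = [g for g in gene_set.genes if g in gene_pos]
    missing = [g for g in gene_set.genes if g not in gene_pos]
    if not used:
        raise ValueError(f"no genes of set {gene_set.name!r} present in the matrix")
    if missing:
        log.warning("gene set %s: %d genes missing (%s)", gene_set.name, len(missing), missing)

    X = _dense(norm.X)
    avg = X.mean(axis=0)
    bins = _expression_bins(avg, gene_ids, n_bins)
    bin_of = np.empty(len(gene_ids), dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b

    rng = np.random.default_rng(seed)
    ctrl_mean = np.zeros(X.shape[0])
    for g in sorted(used):  # canonical order: invariant to gene-set listing
        gi = gene_pos[g]
        pool = bins[bin_of[gi]]
        pool = pool[pool != gi]
        if len(pool) == 0:
            continue
        if len(pool) <= n_ctrl:
            chosen = pool
            if len(pool) < n_ctrl:
                log.warning("bin of %s has %d eligible genes < n_ctrl=%d; using all",
                            g, len(pool), n_ctrl)
        else:
            chosen = rng.choice(pool, size=n_ctrl, replace=False)
        ctrl_mean += X[:, chosen].mean(axis=1)
    ctrl_mean /= len(used)

    set_idx = np.array([gene_pos[g] for g in used])
    scores = X[:, set_idx].mean(axis=1) - ctrl_mean
    return ScoreResult(
        scores=pd.Series(scores, index=norm.obs_names, name=f"{gene_set.name}_score"),
        gene_set=gene_set.name,
        genes_used=used,
        genes_missing=missing,
        params={"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed},
    )


def stage_score_summary(result: ScoreResult, obs: pd.DataFrame,
                        stages: list[str] | None = None,
                        restrict_type: str | None = None) -> pd.DataFrame:
    """Per-stage n / mean / sd / 95% CI of the score, in stage order.
    Empty stages yield n=0 rows with null statistics."""
    df = obs.copy()
    df["score"] = result.scores.reindex(df.index)
    if restrict_type is not None:
        df = df[df["major_type"] == restrict_type]
    if stages is None:
        if isinstance(obs["stage"].dtype, pd.CategoricalDtype):
            stages = list(obs["stage"].cat.categories)
        else:
            stages = list(pd.unique(obs["stage"]))
    rows = []
    for stage in stages:
        s = df.loc[df["stage"] == stage, "score"]
        n = int(s.notna().sum())
        if n == 0:
            rows.append({"stage": stage, "n": 0, "mean": np.nan, "sd": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        mean = float(s.mean())
        sd = float(s.std(ddof=1)) if n > 1 else 0.0
        half = 1.96 * sd / np.sqrt(n)
        rows.append({"stage": stage, "n": n, "mean": mean, "sd": sd,
                     "ci_low": mean - half, "ci_high": mean + half})
    return pd.DataFrame(rows).set_index("stage")


def mean_set_expression_by_type(norm: ad.AnnData, gene_set: GeneSet,
                                obs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean normalized expression and nonzero fraction per (major type,
    gene) for the set genes present in the matrix.  Columns are a
    MultiIndex (gene, {mean, frac_nonzero})."""
    obs = norm.obs if obs is None else obs
    present = [g for g in gene_set.genes if g in norm.var_names]
    X = _dense(norm[:, present].X)
    types = sorted(pd.unique(obs["major_type"].astype(str)))
    rows = {}
    for t in types:
        mask = (obs["major_type"].astype(str) == t).values
        if mask.sum() == 0:
            rows[t] = [np.nan] * (2 * len(present))
            continue
        sub = X[mask]
        rows[t] = list(sub.mean(axis=0)) + list((sub > 0).mean(axis=0))
    cols = pd.MultiIndex.from_tuples(
        [(g, "mean") for g in present] + [(g, "frac_nonzero") for g in present]
    )
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).sort_index()
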