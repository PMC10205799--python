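"""Synthetic stage-labelled single-cell cohort with planted ground truth.

The generator emulates the structure of a TAC (transverse aortic
constriction) cardiac-hypertrophy time course: five stages (0/2/5/8/11
weeks), six major cell types (CM, EC, FB, MP, T, GN), eleven cardiomyocyte
subtypes (CM1..CM11), a MAM (mitochondria-associated ER membrane) gene
program whose per-cell module score peaks at 2 weeks and declines
thereafter, designated genes with monotonically falling expression, and
planted ancestor -> descendant conversion events between consecutive
stages (CM2 -> CM9, CM3 -> CM10 by default).

Counts follow a gamma-Poisson (negative binomial) model with per-gene
baseline means, subtype marker blocks, per-cell library-size scaling and a
shared dispersion.  Converting descendant cells are generated as noisy
copies of one specific ancestor cell (a convex combination, in log1p
space, of the ancestor's realized profile and the descendant subtype's
baseline), so that rank-correlation ancestor inference has a recoverable
signal.  Every planted quantity is recorded in a :class:`GroundTruth`
ledger for parameter-recovery tests.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

STAGES_DEFAULT = ("0w", "2w", "5w", "8w", "11w")

MAM_GENES = (
    "Mfn1", "Mfn2", "Bcap31", "Pacs2", "Tespa1", "Hspa9", "Itpr3",
    "Sigmar1", "Vapb", "Fis1", "Vdac", "Mcu", "Ptpip51",
)

NONCM_TYPES = ("EC", "FB", "MP", "T", "GN")
CM_SUBTYPES = tuple(f"CM{i}" for i in range(1, 12))

# Fractions of CM cells per stage per subtype (each stage sums to 1).
# CM2+CM3 peak at 2w and decline; CM9/CM10/CM11 expand from 5w on.
_CM_SCHEDULE = {
    "0w":  {"CM1": 0.22, "CM2": 0.24, "CM3": 0.20, "CM4": 0.05, "CM5": 0.05,
            "CM6": 0.04, "CM7": 0.04, "CM8": 0.04, "CM9": 0.04, "CM10": 0.04, "CM11": 0.04},
    "2w":  {"CM1": 0.16, "CM2": 0.30, "CM3": 0.26, "CM4": 0.04, "CM5": 0.04,
            "CM6": 0.03, "CM7": 0.03, "CM8": 0.03, "CM9": 0.04, "CM10": 0.04, "CM11": 0.03},
    "5w":  {"CM1": 0.15, "CM2": 0.18, "CM3": 0.16, "CM4": 0.04, "CM5": 0.04,
            "CM6": 0.03, "CM7": 0.03, "CM8": 0.03, "CM9": 0.14, "CM10": 0.13, "CM11": 0.07},
    "8w":  {"CM1": 0.12, "CM2": 0.10, "CM3": 0.09, "CM4": 0.04, "CM5": 0.04,
            "CM6": 0.03, "CM7": 0.03, "CM8": 0.03, "CM9": 0.22, "CM10": 0.20, "CM11": 0.10},
    "11w": {"CM1": 0.10, "CM2": 0.06, "CM3": 0.05, "CM4": 0.04, "CM5": 0.04,
            "CM6": 0.03, "CM7": 0.03, "CM8": 0.03, "CM9": 0.26, "CM10": 0.24, "CM11": 0.12},
}

# Non-CM major types as a fraction of all cells (stage-constant).
_NONCM_FRACTIONS = {"EC": 0.125, "FB": 0.10, "MP": 0.06, "T": 0.04, "GN": 0.05}
_CM_TOTAL_FRACTION = 1.0 - sum(_NONCM_FRACTIONS.values())  # 0.625


def default_subtype_schedule() -> dict[str, dict[str, float]]:
    """Per-stage proportions over all 16 cell labels (11 CM subtypes + 5
    non-CM major types); each stage sums to 1.  CM cells are 62.5% of the
    cohort, so the default 3200 cells/stage yield ~2000 CM cells/stage."""
    sched: dict[str, dict[str, float]] = {}
    for stage, cm in _CM_SCHEDULE.items():
        row = {sub: frac * _CM_TOTAL_FRACTION for sub, frac in cm.items()}
        row.update(_NONCM_FRACTIONS)
        sched[stage] = row
    return sched


def default_conversion_plan() -> list[tuple[str, str, tuple[str, str], int]]:
    return [
        ("CM2", "CM9", ("2w", "5w"), 100),
        ("CM3", "CM10", ("2w", "5w"), 100),
        ("CM2", "CM9", ("5w", "8w"), 120),
        ("CM3", "CM10", ("5w", "8w"), 120),
        ("CM2", "CM9", ("8w", "11w"), 100),
        ("CM3", "CM10", ("8w", "11w"), 100),
    ]


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Parameters
    ----------
    n_genes
        Gene universe size; must accommodate the MAM set and one marker
        block per cell label.
    n_cells_per_stage
        Cells drawn per stage (all types).  The default 3200 gives ~2000
        CM cells per stage under the default schedule.
    stages
        Ordered stage labels (weeks after TAC).
    subtype_schedule
        stage -> label -> proportion; labels are CM subtypes plus non-CM
        major types; each stage must sum to 1.
    mam_genes
        Gene symbols forming the MAM program.
    mam_offset_by_stage
        Stage-specific additive log-mean shift of MAM genes in CM cells
        (the planted Fig-1C-shaped program: peak at 2w, decline after).
    mam_cm_baseline
        Stage-constant log-mean elevation of MAM genes in CM cells, making
        the program CM-enriched at every stage.
    gene_stage_offsets
        gene -> stage -> log offset; for CM cells these *replace* the MAM
        stage offset for that gene (used to plant the declining Mfn1 /
        Hspa9 trends).
    conversion_plan
        (ancestor subtype, descendant subtype, (stage_from, stage_to), n)
        entries; n descendant cells at stage_to are generated as noisy
        copies of distinct ancestor cells at stage_from.
    ancestor_weight
        Convex weight of the ancestor profile in converting cells
        (1 = clone of ancestor, 0 = plain subtype cell).
    baseline_mean, dispersion
        Gamma-Poisson parameters: per-gene means are drawn lognormally
        around ``baseline_mean``; ``dispersion`` is the quadratic
        overdispersion alpha in Var = mu + alpha * mu^2.
    library_size_range
        Per-cell target total counts, uniform over [min, max].
    n_low_quality_per_stage
        Extra planted low-complexity cells per stage (total counts 50-150,
        hence < 200 detected genes) for QC-recovery tests.
    proportion_mode
        "exact" assigns subtype counts by largest-remainder rounding
        (deterministic at small n); "multinomial" draws them.
    """

    n_genes: int = 1000
    n_cells_per_stage: int = 3200
    stages: tuple[str, ...] = STAGES_DEFAULT
    subtype_schedule: dict[str, dict[str, float]] = field(default_factory=default_subtype_schedule)
    mam_genes: tuple[str, ...] = MAM_GENES
    mam_offset_by_stage: dict[str, float] = field(
        default_factory=lambda: {"0w": 0.0, "2w": 0.8, "5w": 0.5, "8w": 0.2, "11w": 0.0}
    )
    mam_cm_baseline: float = 0.4
    gene_stage_offsets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Mfn1": {"0w": 0.9, "2w": 0.7, "5w": 0.45, "8w": 0.2, "11w": 0.0},
            "Hspa9": {"0w": 0.9, "2w": 0.7, "5w": 0.45, "8w": 0.2, "11w": 0.0},
        }
    )
    conversion_plan: list[tuple[str, str, tuple[str, str], int]] = field(
        default_factory=default_conversion_plan
    )
    ancestor_weight: float = 0.7
    baseline_mean: float = 1.0
    dispersion: float = 0.35
    library_size_range: tuple[int, int] = (2000, 6000)
    marker_genes_per_label: int = 25
    marker_log_fold: float = 1.6
    n_low_quality_per_stage: int = 0
    proportion_mode: str = "exact"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < len(self.mam_genes):
            raise ValueError("n_genes smaller than the MAM gene set")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if self.library_size_range[0] <= 0 or self.library_size_range[0] > self.library_size_range[1]:
            raise ValueError("invalid library_size_range")
        if self.proportion_mode not in ("exact", "multinomial"):
            raise ValueError(f"unknown proportion_mode {self.proportion_mode!r}")
        if set(self.subtype_schedule) != set(self.stages):
            raise ValueError("subtype_schedule stages do not match the stage list")
        for stage, props in self.subtype_schedule.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"stage {stage!r} proportions sum to {total}, not 1")
            if any(p < 0 for p in props.values()):
                raise ValueError(f"stage {stage!r} has a negative proportion")
        for anc, desc, (s_from, s_to), n in self.conversion_plan:
            if s_from not in self.stages or s_to not in self.stages:
                raise ValueError(f"conversion {anc}->{desc}: unknown stage in {(s_from, s_to)}")
            if self.stages.index(s_to) - self.stages.index(s_from) != 1:
                raise ValueError(f"conversion {anc}->{desc}: stages {s_from},{s_to} not adjacent")
            for stage, sub in ((s_from, anc), (s_from, desc), (s_to, anc), (s_to, desc)):
                if self.subtype_schedule[stage].get(sub, 0.0) <= 0:
                    raise ValueError(
                        f"conversion {anc}->{desc} references subtype {sub!r} absent at stage {stage!r}"
                    )
            if n <= 0:
                raise ValueError("conversion n must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class GroundTruth:
    """Ledger of everything planted by :func:`generate_cohort`."""

    cell_ancestor: dict[str, str]
    true_proportions: dict[str, dict[str, float]]
    true_mam_offsets: dict[str, float]
    planted_edges: list[dict]
    low_quality_cells: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            cell_ancestor=d["cell_ancestor"],
            true_proportions=d["true_proportions"],
            true_mam_offsets=d["true_mam_offsets"],
            planted_edges=d["planted_edges"],
            low_quality_cells=d.get("low_quality_cells", []),
        )


def _largest_remainder(props: dict[str, float], n: int) -> dict[str, int]:
    """Round proportions*n to integers summing exactly to n; ties on the
    fractional part break by label order for determinism."""
    labels = sorted(props)
    raw = np.array([props[l] * n for l in labels])
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    frac = raw - base
    order = sorted(range(len(labels)), key=lambda i: (-frac[i], labels[i]))
    for i in order[:short]:
        base[i] += 1
    return {l: int(c) for l, c in zip(labels, base)}


def _major_type(label: str) -> str:
    return "CM" if label.startswith("CM") else label


def _gene_ids(config: SimConfig) -> list[str]:
    extra = [f"G{i:04d}" for i in range(1, config.n_genes - len(config.mam_genes) + 1)]
    return list(config.mam_genes) + extra


def generate_cohort(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate the cohort; deterministic under a fixed config (incl. seed).

    Returns an AnnData (cells x genes, integer counts in ``.X``, metadata
    in ``.obs``: stage, major_type, subtype, n_genes_detected,
    total_counts) and the :class:`GroundTruth` ledger.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_ids(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    mam_idx = np.array([gene_index[g] for g in config.mam_genes])

    # Per-gene baseline means, lognormal around baseline_mean.
    gene_log_base = np.log(config.baseline_mean) + rng.normal(0.0, 0.5, size=config.n_genes)

    # Marker blocks: contiguous runs of non-MAM genes, one per label.
    labels = sorted({l for row in config.subtype_schedule.values() for l in row})
    non_mam = [i for i, g in enumerate(genes) if g not in config.mam_genes]
    need = config.marker_genes_per_label * len(labels)
    if need > len(non_mam):
        raise ValueError("not enough genes for marker blocks; increase n_genes")
    marker_idx = {
        lab: np.array(non_mam[i * config.marker_genes_per_label:(i + 1) * config.marker_genes_per_label])
        for i, lab in enumerate(labels)
    }

    shape = 1.0 / config.dispersion  # gamma shape for Var = mu + alpha*mu^2

    def _nb(mu: np.ndarray) -> np.ndarray:
        lam = rng.gamma(shape, mu / shape)
        return rng.poisson(lam).astype(np.int32)

    def _label_probs(label: str, stage: str) -> np.ndarray:
        logmu = gene_log_base.copy()
        logmu[marker_idx[label]] += config.marker_log_fold
        if _major_type(label) == "CM":
            stage_off = config.mam_offset_by_stage.get(stage, 0.0)
            logmu[mam_idx] += config.mam_cm_baseline + stage_off
            for g, per_stage in config.gene_stage_offsets.items():
                if g in gene_index:
                    gi = gene_index[g]
                    base = gene_log_base[gi] + (config.marker_log_fold if gi in marker_idx[label] else 0.0)
                    extra = config.mam_cm_baseline if g in config.mam_genes else 0.0
                    logmu[gi] = base + extra + per_stage.get(stage, 0.0)
        p = np.exp(logmu)
        return p / p.sum()

    counts_blocks: list[np.ndarray] = []
    obs_rows: list[dict] = []
    truth_ancestor: dict[str, str] = {}
    low_quality: list[str] = []
    # Realized per-stage state kept for conversion generation.
    prev_cells_by_subtype: dict[str, list[int]] = {}
    prev_counts: np.ndarray | None = None
    prev_ids: list[str] = []

    lo, hi = config.library_size_range
    planted_counter: dict[tuple[str, str, str], int] = {}

    for stage in config.stages:
        props = config.subtype_schedule[stage]
        if config.proportion_mode == "exact":
            alloc = _largest_remainder(props, config.n_cells_per_stage)
        else:
            labs = sorted(props)
            draws = rng.multinomial(config.n_cells_per_stage, [props[l] for l in labs])
            alloc = {l: int(c) for l, c in zip(labs, draws)}

        stage_labels: list[str] = []
        for lab in sorted(alloc):
            stage_labels.extend([lab] * alloc[lab])
        n_stage = len(stage_labels)
        cell_ids = [f"{stage}_C{i:05d}" for i in range(n_stage)]
        libs = rng.integers(lo, hi + 1, size=n_stage).astype(float)

        stage_counts = np.zeros((n_stage, config.n_genes), dtype=np.int32)
        pos = 0
        label_probs_cache: dict[str, np.ndarray] = {}
        for lab in sorted(alloc):
            n_lab = alloc[lab]
            if n_lab == 0:
                continue
            probs = _label_probs(lab, stage)
            label_probs_cache[lab] = probs
            mu = libs[pos:pos + n_lab, None] * probs[None, :]
            stage_counts[pos:pos + n_lab] = _nb(mu)
            pos += n_lab

        cells_by_subtype: dict[str, list[int]] = {}
        for i, lab in enumerate(stage_labels):
            cells_by_subtype.setdefault(lab, []).append(i)

        # Planted conversions into this stage: overwrite descendant rows
        # with noisy copies of one ancestor cell each.
        for anc_sub, desc_sub, (s_from, s_to), n_conv in config.conversion_plan:
            if s_to != stage:
                continue
            if prev_counts is None:
                raise ValueError(f"conversion into first stage {stage!r} impossible")
            desc_pool = cells_by_subtype.get(desc_sub, [])
            anc_pool = prev_cells_by_subtype.get(anc_sub, [])
            if n_conv > len(desc_pool):
                raise ValueError(
                    f"conversion {anc_sub}->{desc_sub} at {s_from}->{s_to}: "
                    f"{n_conv} converting cells requested but only {len(desc_pool)} available"
                )
            if not anc_pool:
                raise ValueError(f"no {anc_sub} ancestors at stage {s_from}")
            desc_cells = sorted(rng.choice(desc_pool, size=n_conv, replace=False).tolist())
            replace = len(anc_pool) < n_conv
            anc_cells = rng.choice(anc_pool, size=n_conv, replace=replace).tolist()
            w = config.ancestor_weight
            base_probs = label_probs_cache[desc_sub]
            for d_i, a_i in zip(desc_cells, anc_cells):
                lib = libs[d_i]
                anc_row = prev_counts[a_i].astype(float)
                anc_total = anc_row.sum()
                if anc_total == 0:
                    continue
                p_anc = anc_row / anc_total * lib
                p_base = base_probs * lib
                v = w * np.log1p(p_anc) + (1.0 - w) * np.log1p(p_base)
                mu = np.expm1(v)
                mu = np.clip(mu, 0.0, None)
                stage_counts[d_i] = _nb(mu[None, :])[0]
                truth_ancestor[cell_ids[d_i]] = prev_ids[a_i]
            key = (anc_sub, desc_sub, f"{s_from}->{s_to}")
            planted_counter[key] = planted_counter.get(key, 0) + n_conv

        # Planted low-complexity cells (tiny libraries, < 200 detected genes).
        if config.n_low_quality_per_stage > 0:
            n_lq = config.n_low_quality_per_stage
            lq_ids = [f"{stage}_LQ{i:04d}" for i in range(n_lq)]
            lq_labels = rng.choice(sorted(props), size=n_lq, p=[props[l] for l in sorted(props)])
            lq_libs = rng.integers(50, 151, size=n_lq).astype(float)
            lq_counts = np.zeros((n_lq, config.n_genes), dtype=np.int32)
            for j, lab in enumerate(lq_labels):
                probs = label_probs_cache.get(lab)
                if probs is None:
                    probs = _label_probs(lab, stage)
                    label_probs_cache[lab] = probs
                lq_counts[j] = _nb((lq_libs[j] * probs)[None, :])[0]
            stage_counts = np.vstack([stage_counts, lq_counts])
            cell_ids = cell_ids + lq_ids
            stage_labels = stage_labels + list(lq_labels)
            low_quality.extend(lq_ids)

        counts_blocks.append(stage_counts)
        for cid, lab in zip(cell_ids, stage_labels):
            obs_rows.append({"cell_id": cid, "stage": stage,
                             "major_type": _major_type(lab), "subtype": lab})
        prev_counts = stage_counts[:n_stage]
        prev_ids = cell_ids[:n_stage]
        prev_cells_by_subtype = cells_by_subtype

    counts = np.vstack(counts_blocks)
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    obs.index.name = "cell_id"
    obs["stage"] = pd.Categorical(obs["stage"], categories=list(config.stages), ordered=True)
    obs["n_genes_detected"] = (counts > 0).sum(axis=1)
    obs["total_counts"] = counts.sum(axis=1)

    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
    adata.uns["config_hash"] = config.config_hash()
    adata.uns["stages"] = list(config.stages)

    edges = [
        {"ancestor": a, "descendant": d, "transition": t, "n": n}
        for (a, d, t), n in sorted(planted_counter.items())
    ]
    truth = GroundTruth(
        cell_ancestor=truth_ancestor,
        true_proportions={s: dict(sorted(config.subtype_schedule[s].items())) for s in config.stages},
        true_mam_offsets={s: config.mam_offset_by_stage.get(s, 0.0) for s in config.stages},
        planted_edges=edges,
        low_quality_cells=low_quality,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(adata: ad.AnnData, truth: GroundTruth, outdir, *,
                  config: SimConfig | None = None, overwrite: bool = False) -> dict:
    """Write the cohort as MTX (genes x cells) + TSV + JSON; returns the
    manifest.  Refuses to write into a non-empty directory unless
    ``overwrite`` is set."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{outdir} is not empty; pass overwrite=True")
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    X = adata.X
    if sparse.issparse(X):
        mat = X.T.tocoo()
    else:
        mat = sparse.coo_matrix(np.asarray(X).T)
    spio.mmwrite(outdir / "matrix.mtx", mat, field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    adata.obs.reset_index().to_csv(outdir / "cells.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json())

    manifest = {
        "n_genes": int(adata.n_vars),
        "n_cells": int(adata.n_obs),
        "stages": list(adata.uns.get("stages", [])),
        "config_hash": (config.config_hash() if config is not None
                        else adata.uns.get("config_hash", "")),
        "seed": (config.seed if config is not None else None),
        "files": ["matrix.mtx", "genes.tsv", "barcodes.tsv", "cells.tsv", "truth.json"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def read_fixture(indir) -> tuple[ad.AnnData, GroundTruth]:
    """Round-trip reader for :func:`write_fixture` output."""
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx")  # genes x cells
    counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat).T.astype(np.int32)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cells_meta = pd.read_csv(indir / "cells.tsv", sep="\t").set_index("cell_id")
    manifest = json.loads((indir / "manifest.json").read_text())
    stages = manifest.get("stages") or list(pd.unique(cells_meta["stage"]))
    cells_meta["stage"] = pd.Categorical(cells_meta["stage"], categories=stages, ordered=True)
    adata = ad.AnnData(X=counts, obs=cells_meta,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
    adata.uns["stages"] = stages
    adata.uns["config_hash"] = manifest.get("config_hash", "")
    truth = GroundTruth.from_json((indir / "truth.json").read_text())
    return adata, truth
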