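"""Stage-wise subtype proportions, score/proportion coupling, gene trends.

These summaries reproduce the analysis shape of the time-course figures:
per-stage CM-subtype fractions, the rank correlation between the
stage-mean MAM score and the combined CM2+CM3 fraction, and smoothed
per-gene expression along a deterministic pseudo-order (stage order,
within-stage by MAM score descending) classified as rising / falling /
rise-then-fall / flat.

With only five stages a rank correlation is descriptive, not
inferential; results carry a small-n caveat flag and no p-value.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from mamshift.preprocessing import _dense

log = logging.getLogger(__name__)


@dataclass
class StageProportions:
    fractions: pd.DataFrame        # stage x subtype, rows sum to 1 (or NaN)
    n_per_stage: pd.Series
    restrict_type: str | None


@dataclass
class TrendResult:
    name: str
    positions: np.ndarray
    smoothed: np.ndarray
    stage_means: pd.Series
    direction: str                 # rising | falling | rise-then-fall | flat | mixed
    params: dict = field(default_factory=dict)


@dataclass
class CorrelationResult:
    rho: float
    n: int
    small_n_caveat: bool
    subtypes: tuple[str, ...]
    undefined: bool = False


def stage_proportions(obs: pd.DataFrame, stages: list[str] | None = None,
                      restrict: str | None = "CM") -> StageProportions:
    """Exact per-stage subtype fractions (of ``restrict``-type cells).
    Subtypes absent at a stage are reported as 0; a stage with no cells
    yields a null row and a warning."""
    df = obs
    if restrict is not None:
        df = df[df["major_type"].astype(str) == restrict]
    if stages is None:
        if isinstance(obs["stage"].dtype, pd.CategoricalDtype):
            stages = list(obs["stage"].cat.categories)
        else:
            stages = list(pd.unique(obs["stage"]))
    subtypes = sorted(pd.unique(df["subtype"].astype(str)))
    rows = {}
    ns = {}
    for stage in stages:
        sub = df[df["stage"].astype(str) == str(stage)]
        n = len(sub)
        ns[stage] = n
        if n == 0:
            log.warning("stage %s has no %s cells", stage, restrict)
            rows[stage] = {s: np.nan for s in subtypes}
            continue
        counts = sub["subtype"].astype(str).value_counts()
        rows[stage] = {s: counts.get(s, 0) / n for s in subtypes}
    fractions = pd.DataFrame.from_dict(rows, orient="index", columns=subtypes)
    fractions.index.name = "stage"
    return StageProportions(fractions=fractions,
                            n_per_stage=pd.Series(ns, name="n"),
                            restrict_type=restrict)


def score_proportion_correlation(stage_scores: pd.Series, props: StageProportions,
                                 subtypes: tuple[str, ...] = ("CM2", "CM3"),
                                 small_n_threshold: int = 10) -> CorrelationResult:
    """Spearman rho between the per-stage mean score and the summed
    fraction of the named subtypes, across stages.  Undefined (constant
    input) correlations are reported as such rather than raising."""
    present = [s for s in subtypes if s in props.fractions.columns]
    frac = props.fractions[present].sum(axis=1) if present else pd.Series(
        0.0, index=props.fractions.index)
    joined = pd.DataFrame({"score": stage_scores, "frac": frac}).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need >= 3 stages with both quantities, got {n}")
    if joined["score"].nunique() == 1 or joined["frac"].nunique() == 1:
        return CorrelationResult(rho=float("nan"), n=n,
                                 small_n_caveat=n < small_n_threshold,
                                 subtypes=tuple(subtypes), undefined=True)
    rho = float(spearmanr(joined["score"], joined["frac"]).statistic)
    return CorrelationResult(rho=rho, n=n, small_n_caveat=n < small_n_threshold,
                             subtypes=tuple(subtypes))


def _classify(diffs: np.ndarray, eps: float) -> str:
    signs = np.where(diffs > eps, 1, np.where(diffs < -eps, -1, 0))
    if not signs.any():
        return "flat"
    nz = signs[signs != 0]
    if (nz > 0).all():
        return "rising"
    if (nz < 0).all():
        return "falling"
    first_neg = np.flatnonzero(signs < 0)
    last_pos = np.flatnonzero(signs > 0)
    if len(last_pos) and len(first_neg) and last_pos.max() < first_neg.min():
        return "rise-then-fall"
    return "mixed"


def ordered_gene_trend(norm: ad.AnnData, gene: str,
                       stages: list[str] | None = None,
                       order: pd.Series | None = None,
                       scores: pd.Series | None = None,
                       window: int = 51,
                       restrict: str | None = "CM",
                       epsilon_frac: float = 0.05) -> TrendResult:
    """Smoothed expression of one gene along a pseudo-order.

    Default order: stage order, within a stage by module score descending
    (if ``scores`` given, else by cell id).  ``order`` overrides with an
    explicit per-cell sort key.  Direction is classified from the sign
    pattern of first differences of the *stage-level* means, with
    threshold eps = ``epsilon_frac`` x (max - min of stage means).
    """
    if gene not in norm.var_names:
        raise ValueError(f"gene {gene!r} not in the matrix")
    obs = norm.obs
    mask = np.ones(norm.n_obs, dtype=bool)
    if restrict is not None:
        mask &= (obs["major_type"].astype(str) == restrict).values
    if stages is None:
        stages = list(norm.uns.get("stages") or obs["stage"].cat.categories)
    expr = pd.Series(_dense(norm[:, [gene]].X).ravel(), index=norm.obs_names)[mask]
    sub = obs[mask]
    if window < 1 or window > len(expr):
        raise ValueError(f"window must be in [1, {len(expr)}]")

    if order is not None:
        key = order.reindex(expr.index)
        ordered_ids = key.sort_values(kind="stable").index
    else:
        stage_rank = sub["stage"].astype(str).map({s: i for i, s in enumerate(stages)})
        if scores is not None:
            inner = -scores.reindex(expr.index)
        else:
            inner = pd.Series(np.arange(len(expr)), index=expr.index)
        ordered_ids = pd.DataFrame({"a": stage_rank, "b": inner}).sort_values(
            ["a", "b"], kind="stable").index
    values = expr.loc[ordered_ids].to_numpy()
    smoothed = pd.Series(values).rolling(window, min_periods=1, center=True).mean().to_numpy()

    stage_means = pd.Series(
        {s: expr[sub["stage"].astype(str) == s].mean() for s in stages}, name=gene)
    sm = stage_means.dropna().to_numpy()
    rng_ = sm.max() - sm.min() if len(sm) else 0.0
    eps = epsilon_frac * rng_
    direction = _classify(np.diff(sm), eps) if len(sm) >= 2 else "flat"
    return TrendResult(name=gene, positions=np.arange(len(values)),
                       smoothed=smoothed, stage_means=stage_means,
                       direction=direction,
                       params={"window": window, "epsilon_frac": epsilon_frac,
                               "restrict": restrict})


# ---------------------------------------------------------------------------
# run report


def build_report(*, qc=None, stage_scores: pd.DataFrame | None = None,
                 proportions: StageProportions | None = None,
                 selection=None, trends: dict[str, TrendResult] | None = None,
                 correlation: CorrelationResult | None = None,
                 config: dict | None = None, seed: int | None = None,
                 versions: dict | None = None) -> dict:
    """Assemble the run report; deterministic (no timestamps), so the same
    inputs give byte-identical JSON."""
    report: dict = {"config": config or {}, "seed": seed, "versions": versions or {}}
    report["qc"] = (
        {"n_input": qc.n_input, "n_retained": qc.n_retained,
         "removed_low": qc.removed_low, "removed_high": qc.removed_high,
         "min_genes": qc.min_genes, "max_genes": qc.max_genes}
        if qc is not None else {"status": "not run"})
    report["stage_scores"] = (
        json.loads(stage_scores.to_json(orient="index"))
        if stage_scores is not None else {"status": "not run"})
    report["proportions"] = (
        {"fractions": json.loads(proportions.fractions.to_json(orient="index")),
         "n_per_stage": {str(k): int(v) for k, v in proportions.n_per_stage.items()}}
        if proportions is not None else {"status": "not run"})
    if selection is not None:
        report["ancestry"] = {
            "retained_subtypes": selection.retained_subtypes,
            "edges": selection.edges.to_dict(orient="records"),
            "retained_edges": selection.retained_edges.to_dict(orient="records"),
        }
    else:
        report["ancestry"] = {"status": "not run"}
    report["trends"] = (
        {name: {"direction": t.direction,
                "stage_means": {str(k): (None if pd.isna(v) else float(v))
                                for k, v in t.stage_means.items()}}
         for name, t in trends.items()}
        if trends else {"status": "not run"})
    report["score_proportion_correlation"] = (
        {"rho": (None if np.isnan(correlation.rho) else correlation.rho),
         "n": correlation.n, "small_n_caveat": correlation.small_n_caveat,
         "subtypes": list(correlation.subtypes), "undefined": correlation.undefined}
        if correlation is not None else {"status": "not run"})
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=1)


def report_to_markdown(report: dict) -> str:
    lines = ["# mamshift run report", ""]
    qc = report.get("qc", {})
    lines.append("## QC")
    if "status" in qc:
        lines.append(qc["status"])
    else:
        lines.append(f"- input cells: {qc['n_input']}; retained: {qc['n_retained']} "
                     f"(removed {qc['removed_low']} low / {qc['removed_high']} high; "
                     f"thresholds {qc['min_genes']}-{qc['max_genes']})")
    lines.append("")
    lines.append("## Stage scores")
    ss = report.get("stage_scores", {})
    if "status" in ss:
        lines.append(ss["status"])
    else:
        for stage, row in ss.items():
            mean = row.get("mean")
            lines.append(f"- {stage}: n={row.get('n')} mean="
                         f"{mean if mean is None else round(mean, 4)}")
    lines.append("")
    anc = report.get("ancestry", {})
    lines.append("## Conversion edges")
    if "status" in anc:
        lines.append(anc["status"])
    else:
        lines.append(f"retained subtypes: {', '.join(anc['retained_subtypes'])}")
        for e in anc["edges"]:
            tag = "retained" if e["retained"] else f"excluded ({e['exclusion_reason']})"
            lines.append(f"- {e['ancestor']} -> {e['descendant']} [{e['transition']}] "
                         f"support={e['support']} — {tag}")
    lines.append("")
    tr = report.get("trends", {})
    lines.append("## Gene trends")
    if "status" in tr:
        lines.append(tr["status"])
    else:
        for g, t in tr.items():
            lines.append(f"- {g}: {t['direction']}")
    corr = report.get("score_proportion_correlation", {})
    lines.append("")
    lines.append("## Score / proportion coupling")
    if "status" in corr:
        lines.append(corr["status"])
    else:
        caveat = " (small-n caveat)" if corr.get("small_n_caveat") else ""
        lines.append(f"Spearman rho = {corr['rho']} over {corr['n']} stages{caveat}")
    return "\n".join(lines) + "\n"
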