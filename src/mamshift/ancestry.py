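"""Cross-stage ancestor-voting conversion inference between CM subtypes.

Each cardiomyocyte of the current stage is Spearman-correlated (over a
chosen gene universe, HVGs by default) with every cardiomyocyte of the
previous stage; its top-k (k=5) most correlated previous-stage cells are
its "potential ancestors", and the plurality of their subtype labels is
the voted ancestor subtype.  Aggregating votes yields a conversion graph
whose edge support(A -> B) counts current-stage cells of subtype B whose
voted ancestor subtype is A.

Subclusters and edges are then gated by three rules before any trajectory
analysis: (1) a subtype must exceed 10% of CM cells at some stage
(strict), (2) an edge needs at least 10 supporting cells (inclusive), and
(3) the conversion direction must not conflict with the subtype
proportion change across that transition.

All tie-breaks (correlation cutoff, vote ties) are deterministic:
correlation ties break by previous-cell id, vote ties by larger summed
correlation then by subtype label.  Because the correlations are rank
based, every result is invariant under strictly increasing transforms of
the expression values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from mamshift.preprocessing import _dense, select_hvgs

log = logging.getLogger(__name__)


@dataclass
class AncestorAssignment:
    """Top-k potential ancestors of one current-stage cell."""

    cell_id: str
    ancestors: list[tuple[str, float]]      # (prev cell id, rho), rho descending
    voted_subtype: str | None = None
    tally: dict[str, int] = field(default_factory=dict)


@dataclass
class ConversionGraph:
    """Directed subtype-conversion edges across adjacent stage transitions.

    ``edges`` columns: ancestor, descendant, transition ("prev->curr"),
    support (cells voting), vote_fraction (support / valid votes of the
    descendant subtype at that transition).
    """

    nodes: list[str]
    edges: pd.DataFrame
    params: dict
    n_valid_votes: dict[str, int] = field(default_factory=dict)   # per transition
    n_invalid_votes: dict[str, int] = field(default_factory=dict)

    def support(self, ancestor: str, descendant: str, transition: str) -> int:
        m = self.edges
        hit = m[(m.ancestor == ancestor) & (m.descendant == descendant)
                & (m.transition == transition)]
        return int(hit["support"].sum())


# ---------------------------------------------------------------------------
# correlation primitives


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return rankdata(X, axis=1, method="average")


def _standardize_rows(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale rows; returns (Z, valid) where invalid rows (zero
    variance) are zeroed out."""
    mu = R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, keepdims=True)
    valid = sd[:, 0] > 0
    sd[~valid] = 1.0
    Z = (R - mu) / sd
    Z[~valid] = 0.0
    return Z, valid


def spearman_to_previous(query: np.ndarray, prev: np.ndarray) -> np.ndarray:
    """Spearman rho of one query cell against each previous-stage cell
    (rows of ``prev``), over a common gene vector.  Ties get average
    ranks; a zero-variance previous cell yields NaN (logged upstream).
    """
    query = np.asarray(query, dtype=float)
    prev = np.atleast_2d(np.asarray(prev, dtype=float))
    if prev.shape[0] == 0:
        raise ValueError("previous stage is empty")
    if prev.shape[1] != query.shape[0]:
        raise ValueError("gene dimensions differ between query and previous matrix")
    nz = np.count_nonzero(query != query[0])
    if query.shape[0] < 3 or nz == 0:
        raise ValueError("query cell needs >= 3 genes with nonzero variance")
    rq = rankdata(query, method="average")
    zq, q_ok = _standardize_rows(rq[None, :])
    Rp = _rank_rows(prev)
    Zp, p_ok = _standardize_rows(Rp)
    rho = (Zp @ zq[0]) / query.shape[0]
    rho[~p_ok] = np.nan
    return rho


def top_k_ancestors(corr: np.ndarray, prev_cell_ids: list[str], k: int = 5,
                    cell_id: str = "") -> AncestorAssignment:
    """The k most correlated previous cells; ties at the cutoff break by
    previous-cell id.  NaN correlations are excluded; if fewer than k
    valid cells exist, all are returned with a warning."""
    if k < 1:
        raise ValueError("k must be >= 1")
    corr = np.asarray(corr, dtype=float)
    valid = ~np.isnan(corr)
    if not valid.any():
        raise ValueError("all correlations are NaN; no ancestors available")
    ids = np.asarray(prev_cell_ids)
    idx = np.flatnonzero(valid)
    order = sorted(idx, key=lambda i: (-corr[i], ids[i]))
    if len(order) < k:
        log.warning("only %d valid previous cells for k=%d", len(order), k)
    chosen = order[:k]
    return AncestorAssignment(
        cell_id=cell_id,
        ancestors=[(str(ids[i]), float(corr[i])) for i in chosen],
    )


def vote_ancestor_subtype(assignment: AncestorAssignment,
                          prev_labels: pd.Series | dict) -> tuple[str, dict[str, int]]:
    """Plurality subtype among the potential ancestors; ties break by
    larger summed rho, then lexicographically.  Tally recorded on the
    assignment."""
    get = prev_labels.get if hasattr(prev_labels, "get") else prev_labels.__getitem__
    tally: dict[str, int] = {}
    rho_sum: dict[str, float] = {}
    for cid, rho in assignment.ancestors:
        lab = str(get(cid))
        tally[lab] = tally.get(lab, 0) + 1
        rho_sum[lab] = rho_sum.get(lab, 0.0) + rho
    winner = min(tally, key=lambda lab: (-tally[lab], -rho_sum[lab], lab))
    assignment.voted_subtype = winner
    assignment.tally = dict(sorted(tally.items()))
    return winner, assignment.tally


# ---------------------------------------------------------------------------
# per-transition conversion computation


def conversion_matrix(norm: ad.AnnData, stage_prev: str, stage_curr: str,
                      genes: list[str] | None = None, k: int = 5,
                      restrict_type: str = "CM",
                      return_assignments: bool = False):
    """Vote an ancestor subtype for every current-stage cell of
    ``restrict_type`` and aggregate edge supports for the transition.

    Returns an edge DataFrame (ancestor, descendant, transition, support,
    vote_fraction) plus vote bookkeeping; optionally the per-cell
    assignments.  Sum of supports equals the number of current cells with
    valid votes (conservation).
    """
    obs = norm.obs
    mask_prev = (obs["stage"].astype(str) == stage_prev).values
    mask_curr = (obs["stage"].astype(str) == stage_curr).values
    if restrict_type is not None:
        type_mask = (obs["major_type"].astype(str) == restrict_type).values
        mask_prev &= type_mask
        mask_curr &= type_mask
    if mask_prev.sum() == 0:
        raise ValueError(f"previous stage {stage_prev!r} has no {restrict_type} cells")
    if mask_curr.sum() == 0:
        raise ValueError(f"current stage {stage_curr!r} has no {restrict_type} cells")

    sub = norm[:, genes] if genes is not None else norm
    X = _dense(sub.X)
    P = X[mask_prev]
    C = X[mask_curr]
    prev_ids = obs.index[mask_prev].to_numpy()
    curr_ids = obs.index[mask_curr].to_numpy()
    prev_subtypes = obs.loc[mask_prev, "subtype"].astype(str).to_numpy()
    curr_subtypes = obs.loc[mask_curr, "subtype"].astype(str).to_numpy()
    G = P.shape[1]

    Zp, p_ok = _standardize_rows(_rank_rows(P))
    Zc, c_ok = _standardize_rows(_rank_rows(C))
    # lexicographic rank of previous ids, for deterministic tie-breaks
    id_rank = np.empty(len(prev_ids), dtype=int)
    id_rank[np.argsort(prev_ids, kind="stable")] = np.arange(len(prev_ids))

    transition = f"{stage_prev}->{stage_curr}"
    support: dict[tuple[str, str], int] = {}
    desc_valid: dict[str, int] = {}
    assignments: list[AncestorAssignment] = []
    n_valid = 0
    n_invalid = 0
    k_eff = min(k, int(p_ok.sum()))
    if k_eff == 0:
        raise ValueError(f"no previous-stage cell has expression variance at {transition}")
    if k_eff < k:
        log.warning("transition %s: only %d valid previous cells for k=%d",
                    transition, k_eff, k)

    for qi in range(C.shape[0]):
        if not c_ok[qi]:
            n_invalid += 1
            continue
        rho = (Zp @ Zc[qi]) / G
        rho[~p_ok] = -np.inf           # excluded from top-k
        order = np.lexsort((id_rank, -rho))[:k_eff]
        assignment = AncestorAssignment(
            cell_id=str(curr_ids[qi]),
            ancestors=[(str(prev_ids[i]), float(rho[i])) for i in order],
        )
        tally: dict[str, int] = {}
        rho_sum: dict[str, float] = {}
        for i in order:
            lab = prev_subtypes[i]
            tally[lab] = tally.get(lab, 0) + 1
            rho_sum[lab] = rho_sum.get(lab, 0.0) + rho[i]
        winner = min(tally, key=lambda lab: (-tally[lab], -rho_sum[lab], lab))
        assignment.voted_subtype = winner
        assignment.tally = dict(sorted(tally.items()))
        if return_assignments:
            assignments.append(assignment)
        desc = curr_subtypes[qi]
        support[(winner, desc)] = support.get((winner, desc), 0) + 1
        desc_valid[desc] = desc_valid.get(desc, 0) + 1
        n_valid += 1

    rows = [
        {"ancestor": a, "descendant": d, "transition": transition,
         "support": s, "vote_fraction": s / desc_valid[d]}
        for (a, d), s in sorted(support.items())
    ]
    edges = pd.DataFrame(rows, columns=["ancestor", "descendant", "transition",
                                        "support", "vote_fraction"])
    if n_invalid:
        log.warning("transition %s: %d cells had invalid votes", transition, n_invalid)
    result = (edges, n_valid, n_invalid)
    return (*result, assignments) if return_assignments else result


def infer_conversions(norm: ad.AnnData, stages: list[str] | None = None,
                      k: int = 5, gene_universe: str = "hvg",
                      n_hvg: int = 500, restrict_type: str = "CM") -> ConversionGraph:
    """Run :func:`conversion_matrix` over every adjacent stage pair.

    ``gene_universe`` is "hvg" (HVGs of the combined two-stage submatrix,
    the default) or "all".
    """
    if stages is None:
        stages = list(norm.uns.get("stages") or norm.obs["stage"].cat.categories)
    all_edges = []
    n_valid: dict[str, int] = {}
    n_invalid: dict[str, int] = {}
    for s_prev, s_curr in zip(stages[:-1], stages[1:]):
        genes = None
        if gene_universe == "hvg":
            pair_mask = norm.obs["stage"].astype(str).isin([s_prev, s_curr]).values
            if restrict_type is not None:
                pair_mask &= (norm.obs["major_type"].astype(str) == restrict_type).values
            genes = select_hvgs(norm[pair_mask], n_top=min(n_hvg, norm.n_vars))
        edges, nv, ni = conversion_matrix(norm, s_prev, s_curr, genes=genes, k=k,
                                          restrict_type=restrict_type)
        all_edges.append(edges)
        t = f"{s_prev}->{s_curr}"
        n_valid[t] = nv
        n_invalid[t] = ni
    edges = pd.concat(all_edges, ignore_index=True) if all_edges else pd.DataFrame(
        columns=["ancestor", "descendant", "transition", "support", "vote_fraction"])
    nodes = sorted(set(edges["ancestor"]) | set(edges["descendant"]))
    return ConversionGraph(
        nodes=nodes, edges=edges,
        params={"k": k, "gene_universe": gene_universe, "n_hvg": n_hvg,
                "correlation": "spearman", "restrict_type": restrict_type},
        n_valid_votes=n_valid, n_invalid_votes=n_invalid,
    )


# ---------------------------------------------------------------------------
# subcluster / edge selection rules


@dataclass
class SelectionResult:
    retained_subtypes: list[str]
    edges: pd.DataFrame            # full audit: retained + exclusion_reason
    subtype_audit: pd.DataFrame    # per subtype: max fraction, retained

    @property
    def retained_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["retained"]].reset_index(drop=True)


def direction_consistent(frac_anc_prev: float, frac_anc_curr: float,
                         frac_desc_prev: float, frac_desc_curr: float,
                         strict: bool = False) -> bool:
    """Rule 3 predicate: a conversion A -> B conflicts with the observed
    proportion change when B's fraction strictly fell while A's strictly
    rose across the transition.  The strict variant additionally demands
    that B's fraction did not fall at all."""
    if strict:
        return frac_desc_curr >= frac_desc_prev
    return not (frac_desc_curr < frac_desc_prev and frac_anc_curr > frac_anc_prev)


def select_trajectory_subclusters(graph: ConversionGraph,
                                  proportions: pd.DataFrame,
                                  min_frac: float = 0.10,
                                  min_support: int = 10,
                                  strict_consistency: bool = False) -> SelectionResult:
    """Apply the three selection rules with a full exclusion audit.

    ``proportions`` is a stage x subtype DataFrame of CM-cell fractions
    (rows in stage order).  Rules: (1) subtype retained iff its fraction
    exceeds ``min_frac`` at some stage (strict >); (2) edge support must
    be >= ``min_support`` (inclusive); (3) the conversion direction must
    not conflict with the proportion change (see
    :func:`direction_consistent`).  Every excluded edge carries the names
    of the rules it failed.
    """
    stages = list(proportions.index)
    max_frac = proportions.max(axis=0)
    nodes = sorted(set(graph.nodes) | set(proportions.columns))
    subtype_rows = []
    retained_subtypes = []
    for sub in nodes:
        mf = float(max_frac.get(sub, 0.0))
        ok = mf > min_frac
        subtype_rows.append({"subtype": sub, "max_fraction": mf, "retained": ok})
        if ok:
            retained_subtypes.append(sub)
    subtype_audit = pd.DataFrame(subtype_rows).set_index("subtype")

    def frac(stage: str, sub: str) -> float:
        if stage in proportions.index and sub in proportions.columns:
            return float(proportions.loc[stage, sub])
        return 0.0

    edge_rows = []
    for _, e in graph.edges.iterrows():
        reasons = []
        s_prev, s_curr = e["transition"].split("->")
        if s_prev not in stages or s_curr not in stages:
            reasons.append("unknown_transition")
            consistent = False
        else:
            consistent = direction_consistent(
                frac(s_prev, e["ancestor"]), frac(s_curr, e["ancestor"]),
                frac(s_prev, e["descendant"]), frac(s_curr, e["descendant"]),
                strict=strict_consistency,
            )
        if e["ancestor"] not in retained_subtypes:
            reasons.append("ancestor_below_min_frac")
        if e["descendant"] not in retained_subtypes:
            reasons.append("descendant_below_min_frac")
        if e["support"] < min_support:
            reasons.append("support_below_min")
        if not consistent:
            reasons.append("inconsistent_direction")
        edge_rows.append({
            "ancestor": e["ancestor"], "descendant": e["descendant"],
            "transition": e["transition"], "support": int(e["support"]),
            "vote_fraction": float(e["vote_fraction"]), "consistent": bool(consistent),
            "retained": not reasons, "exclusion_reason": ";".join(reasons),
        })
    edges = pd.DataFrame(edge_rows, columns=[
        "ancestor", "descendant", "transition", "support", "vote_fraction",
        "consistent", "retained", "exclusion_reason"])
    if len(edges) and not edges["retained"].any():
        log.warning("selection retained no edges (all excluded; see audit)")
    return SelectionResult(retained_subtypes=retained_subtypes, edges=edges,
                           subtype_audit=subtype_audit)


def stage_order_graph(edges: pd.DataFrame) -> list[list[str]]:
    """Topological layering of the retained conversion edges (self-loops
    dropped; parallel edges collapsed).  A cycle raises with the cycle
    listed."""
    g = nx.DiGraph()
    for _, e in edges.iterrows():
        if e["ancestor"] != e["descendant"]:
            g.add_edge(e["ancestor"], e["descendant"])
    if g.number_of_edges() == 0:
        return []
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise ValueError(f"conversion graph contains a cycle: {cycle}")
    return [sorted(layer) for layer in nx.topological_generations(g)]
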