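"""Independent brute-force reference implementations used as oracles.

Everything here is written with plain loops and scipy.stats calls,
deliberately sharing no code path with the package implementation.
"""

from collections import Counter

import numpy as np
from scipy.stats import spearmanr


def naive_log_normalize(counts: np.ndarray, scale: float) -> np.ndarray:
    """Two-loop log-normalization reference (cells x genes)."""
    n, g = counts.shape
    out = np.zeros((n, g))
    for i in range(n):
        total = counts[i].sum()
        for j in range(g):
            out[i, j] = np.log1p(counts[i, j] / total * scale)
    return out


def naive_module_score(X: np.ndarray, gene_ids, set_genes, n_bins, n_ctrl, seed):
    """Per-cell loop reference of the binned-control module score.

    Mirrors the documented contract (equal-frequency bins of the
    (average, gene id) ordering; per-set-gene control sample without
    replacement, excluding the gene; control term = mean over set genes
    of per-gene control means) using independent plumbing.
    """
    n_cells, n_genes = X.shape
    avg = [X[:, j].mean() for j in range(n_genes)]
    order = sorted(range(n_genes), key=lambda j: (avg[j], gene_ids[j]))
    bins = [list(chunk) for chunk in np.array_split(np.array(order), n_bins)]
    bin_of = {}
    for b, members in enumerate(bins):
        for j in members:
            bin_of[j] = b
    pos = {g: j for j, g in enumerate(gene_ids)}
    used = [g for g in set_genes if g in pos]
    rng = np.random.default_rng(seed)
    controls = {}
    for g in sorted(used):
        j = pos[g]
        pool = [m for m in bins[bin_of[j]] if m != j]
        if len(pool) <= n_ctrl:
            controls[g] = pool
        else:
            controls[g] = list(rng.choice(np.array(pool), size=n_ctrl, replace=False))
    scores = np.zeros(n_cells)
    for i in range(n_cells):
        set_mean = np.mean([X[i, pos[g]] for g in used])
        ctrl_means = []
        for g in used:
            if controls[g]:
                ctrl_means.append(np.mean([X[i, m] for m in controls[g]]))
            else:
                ctrl_means.append(0.0)
        scores[i] = set_mean - np.mean(ctrl_means)
    return scores


def naive_hvg_ranking(X: np.ndarray, gene_ids, n_top):
    """Loop-based clipped standardized-variance ranking."""
    n, g = X.shape
    mean = np.array([X[:, j].mean() for j in range(g)])
    var = np.array([X[:, j].var(ddof=1) for j in range(g)])
    std_var = np.zeros(g)
    ok = [j for j in range(g) if var[j] > 0 and mean[j] > 0]
    if len(ok) >= 3:
        coef = np.polyfit(np.log10(mean[ok]), np.log10(var[ok]), 2)
        clip = np.sqrt(n)
        for j in ok:
            sd = np.sqrt(10 ** np.polyval(coef, np.log10(mean[j])))
            z = [min(max((X[i, j] - mean[j]) / sd, -clip), clip) for i in range(n)]
            std_var[j] = np.var(z, ddof=1)
    else:
        for j in ok:
            std_var[j] = var[j]
    order = sorted(range(g), key=lambda j: (-std_var[j], gene_ids[j]))
    return [gene_ids[j] for j in order[:n_top]]


def naive_ancestor_pipeline(prev_X, prev_ids, prev_subtypes, curr_X, curr_ids,
                            curr_subtypes, k=5):
    """Quadruple-loop reference: spearmanr per pair -> sorted top-k with
    id tie-break -> plurality vote with (count, summed rho, label)
    tie-break -> edge support counts.  Returns (support dict, votes dict,
    n_valid)."""
    support = {}
    votes = {}
    n_valid = 0
    for qi in range(curr_X.shape[0]):
        q = curr_X[qi]
        if np.all(q == q[0]):
            continue
        rhos = []
        for pi in range(prev_X.shape[0]):
            p = prev_X[pi]
            if np.all(p == p[0]):
                continue
            rho = spearmanr(q, p).statistic
            rhos.append((pi, float(rho)))
        if not rhos:
            continue
        rhos.sort(key=lambda t: (-t[1], prev_ids[t[0]]))
        top = rhos[:k]
        tally = Counter(prev_subtypes[pi] for pi, _ in top)
        rho_sum = {}
        for pi, rho in top:
            rho_sum[prev_subtypes[pi]] = rho_sum.get(prev_subtypes[pi], 0.0) + rho
        winner = sorted(tally, key=lambda lab: (-tally[lab], -rho_sum[lab], lab))[0]
        votes[curr_ids[qi]] = winner
        key = (winner, curr_subtypes[qi])
        support[key] = support.get(key, 0) + 1
        n_valid += 1
    return support, votes, n_valid
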