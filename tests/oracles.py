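"""Independent brute-force oracles used to cross-check the implementation.

Every function here is written as the slowest, most literal evaluation
of the corresponding definition — explicit loops over voxels, all-pairs
distances, exhaustive threshold enumeration — and stays independent of
the code paths it checks.
"""

import itertools

import numpy as np


def surface_points_brute(grid: np.ndarray) -> set:
    """Foreground voxels with >= 1 face-neighbour background voxel (edge = background)."""
    grid = np.asarray(grid)
    ndim = grid.ndim
    offsets = []
    for ax in range(ndim):
        for d in (-1, 1):
            o = [0] * ndim
            o[ax] = d
            offsets.append(tuple(o))
    out = set()
    for idx in itertools.product(*(range(s) for s in grid.shape)):
        if not grid[idx]:
            continue
        for o in offsets:
            nb = tuple(i + oi for i, oi in zip(idx, o))
            outside = any(not 0 <= n < s for n, s in zip(nb, grid.shape))
            if outside or not grid[nb]:
                out.add(idx)
                break
    return out


def hd_percentile_brute(pred_grid, truth_grid, percentile=95.0, symmetric=False) -> float:
    """Directed percentile Hausdorff via all-pairs distances between brute surfaces."""

    def directed(src, dst):
        sp = sorted(surface_points_brute(src))
        dp = sorted(surface_points_brute(dst))
        dists = []
        for p in sp:
            best = min(
                sum((a - b) ** 2 for a, b in zip(p, q)) ** 0.5 for q in dp
            )
            dists.append(best)
        return float(np.percentile(dists, percentile))

    d = directed(pred_grid, truth_grid)
    if symmetric:
        d = max(d, directed(truth_grid, pred_grid))
    return d


def dice_brute(a, b) -> float:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def confusion_brute(truth, pred) -> tuple:
    truth = np.asarray(truth).astype(bool)
    pred = np.asarray(pred).astype(bool)
    tp = fp = fn = tn = 0
    for idx in itertools.product(*(range(s) for s in truth.shape)):
        t, p = truth[idx], pred[idx]
        if t and p:
            tp += 1
        elif p:
            fp += 1
        elif t:
            fn += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else np.nan
    sensitivity = tp / (tp + fn) if tp + fn else np.nan
    accuracy = (tp + tn) / truth.size
    return precision, sensitivity, accuracy


def majority_vote_brute(grids) -> np.ndarray:
    grids = [np.asarray(g) for g in grids]
    out = np.zeros_like(grids[0])
    n = len(grids)
    for idx in itertools.product(*(range(s) for s in grids[0].shape)):
        votes = sum(int(g[idx]) for g in grids)
        out[idx] = 1 if votes * 2 > n else 0
    return out


def kappa_brute(a, b) -> float:
    """Cohen's kappa from explicit contingency counts."""
    a = list(a)
    b = list(b)
    n = len(a)
    classes = sorted(set(a) | set(b))
    counts = {(x, y): 0 for x in classes for y in classes}
    for x, y in zip(a, b):
        counts[(x, y)] += 1
    p_o = sum(counts[(c, c)] for c in classes) / n
    p_e = sum(
        (sum(counts[(c, y)] for y in classes) / n) * (sum(counts[(x, c)] for x in classes) / n)
        for c in classes
    )
    if abs(1.0 - p_e) < 1e-15:
        return np.nan
    return (p_o - p_e) / (1.0 - p_e)


def best_kappa_brute(values, accepted, higher_is_better=True) -> float:
    """Exhaustive max kappa over every distinct cut of the value axis.

    Enumerates all n+1 possible partitions induced by a threshold
    (including the all-accept and all-reject ones) and evaluates kappa
    on each via the contingency oracle.
    """
    values = np.asarray(values, dtype=float)
    accepted = np.asarray(accepted, dtype=bool)
    uniq = np.unique(values)
    cuts = np.concatenate([[uniq[0] - 1.0], uniq, [uniq[-1] + 1.0]])
    best = -np.inf
    for t in cuts:
        pred = values >= t if higher_is_better else values <= t
        k = kappa_brute(pred.tolist(), accepted.tolist())
        if not np.isnan(k):
            best = max(best, k)
    return best


def kruskal_h_brute(groups) -> float:
    """H from the textbook rank formula, midranks by explicit averaging."""
    pooled = [(v, gi) for gi, g in enumerate(groups) for v in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i][0])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]][0] == pooled[order[i]][0]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    h = 0.0
    pos = 0
    for g in groups:
        r = ranks[pos : pos + len(g)]
        pos += len(g)
        h += len(g) * (sum(r) / len(r) - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    tie_sum = 0.0
    for v in set(x for x, _ in pooled):
        t = sum(1 for x, _ in pooled if x == v)
        tie_sum += t**3 - t
    corr = 1.0 - tie_sum / (n**3 - n)
    return h / corr if corr > 0 else 0.0


def kruskal_pvalue_permutation(groups, n_perm=2000, seed=0) -> float:
    """Permutation p-value for the Kruskal-Wallis H statistic."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    h_obs = kruskal_h_brute(groups)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts, pos = [], 0
        for s in sizes:
            parts.append(perm[pos : pos + s].tolist())
            pos += s
        if kruskal_h_brute(parts) >= h_obs - 1e-12:
            count += 1
    return count / n_perm
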