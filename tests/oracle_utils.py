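"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — per-fragment / per-base loops,
exhaustive enumeration, O(n^2)/O(n^3) algorithms — and shares no code
with the implementation under test.
"""

import itertools
import math

import numpy as np


def brute_window_midpoint_counts(fragments, tss, flank):
    """Count fragments per TSS window by testing every (fragment, window) pair."""
    counts = {}
    for rec in tss.records:
        c = 0
        for frag in fragments.fragments:
            mid = (frag.start + frag.end) // 2
            if frag.chrom == rec.chrom and rec.tss - flank <= mid < rec.tss + flank:
                c += 1
        counts[rec.gene_id] = c
    return counts


def brute_base_depth(fragments, chrom, position):
    """Coverage depth of one genomic base by scanning every fragment."""
    d = 0
    for frag in fragments.fragments:
        if frag.chrom == chrom and frag.start <= position < frag.end:
            d += 1
    return d


def brute_ndr_depth(fragments, rec, window):
    """Total per-base depth over a strand-mirrored NDR window."""
    a, b = window
    if rec.strand == "+":
        lo, hi = rec.tss + a, rec.tss + b
    else:
        lo, hi = rec.tss - b + 1, rec.tss - a + 1
    return sum(brute_base_depth(fragments, rec.chrom, p)
               for p in range(max(lo, 0), max(hi, 0)))


def brute_metagene(fragments_list, tss, subset_ids, flank):
    """Mean depth per strand-oriented offset via per-base counting."""
    offsets = range(-flank, flank)
    profile = np.zeros(2 * flank)
    for fragments in fragments_list:
        acc = np.zeros(2 * flank)
        for gid in subset_ids:
            rec = next(r for r in tss.records if r.gene_id == gid)
            sign = 1 if rec.strand == "+" else -1
            for j, off in enumerate(offsets):
                pos = rec.tss + sign * off
                if pos >= 0:
                    acc[j] += brute_base_depth(fragments, rec.chrom, pos)
        profile += acc / len(subset_ids)
    return profile / len(fragments_list)


def exact_wilcoxon_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of rank assignments.

    Only valid without ties. Enumerates every C(n+m, n) choice of which
    pooled ranks belong to x.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    mean_w = n * (len(pooled) + 1) / 2
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            extreme += 1
    return extreme / total


def exact_wilcoxon_p_dp(x, y):
    """Exact two-sided rank-sum p via the subset generating function.

    Dynamic programming equivalent of enumerating all C(n+m, n) rank
    assignments; feasible for 12-vs-12.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n, N = len(x), len(pooled)
    max_w = sum(range(N - n + 1, N + 1))
    # dp[k][w] = number of k-subsets of ranks 1..r summing to w
    dp = np.zeros((n + 1, max_w + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n), 0, -1):
            dp[k, r:] += dp[k - 1, :-r] if r > 0 else dp[k - 1]
    counts = dp[n]
    total = counts.sum()
    mean_w = n * (N + 1) / 2
    dev = abs(w_obs - mean_w)
    ws = np.arange(max_w + 1)
    extreme = counts[np.abs(ws - mean_w) >= dev - 1e-9].sum()
    return extreme / total


def bh_stepup(p):
    """Benjamini–Hochberg by the direct step-up formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        adjusted[idx] = val
        prev = val
    return np.minimum(adjusted, 1.0)


def pairwise_auc(scores, labels):
    """AUC as the mean over positive x negative pairs, ties counting 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def upgma_reference(points):
    """O(n^3) UPGMA on Euclidean distances; returns merge list
    [(members, height), ...] where members is the frozenset of leaf
    indices of the newly formed cluster."""
    points = [np.asarray(p, dtype=float) for p in points]
    clusters = [frozenset([i]) for i in range(len(points))]

    def dist(a, b):
        return float(np.mean([
            np.linalg.norm(points[i] - points[j]) for i in a for j in b
        ]))

    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = dist(a, b)
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        clusters = [c for c in clusters if c not in (a, b)]
        clusters.append(a | b)
        merges.append((a | b, d))
    return merges


def exhaustive_best_balanced_accuracy(values, labels):
    """Best (sens+spec)/2 over every midpoint threshold and orientation."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    uniq = np.unique(v)
    cands = [-math.inf, math.inf] + [
        (uniq[i] + uniq[i + 1]) / 2 for i in range(len(uniq) - 1)
    ]
    best = 0.0
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    for t in cands:
        for pred1 in (v > t, v < t):
            sens = (pred1 & (y == 1)).sum() / n1
            spec = (~pred1 & (y == 0)).sum() / n0
            best = max(best, (sens + spec) / 2)
    return best


def midrank_spearman(x, y):
    """Spearman rho by explicit mid-rank arithmetic."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = (v < vi).sum()
            equal = (v == vi).sum()
            r[i] = less + (equal + 1) / 2.0
        return r

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def hypergeometric_mean(n_a, n_b, n_universe):
    return n_a * n_b / n_universe
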