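"""Independent brute-force oracles used to cross-check the implementations.

These deliberately share no code with the package: loops and explicit set
arithmetic only.
"""

import numpy as np


def brute_force_scores(net, ann, genes, terms):
    """O(G^2 T) double-loop neighbor voting."""
    idx = net.gene_index()
    out = np.zeros((len(genes), len(terms)))
    for a, g in enumerate(genes):
        i = idx[g]
        degree = sum(net.weights[i, l] for l in range(net.n_genes) if l != i)
        for b, t in enumerate(terms):
            members = ann.genes_for(t)
            num = sum(
                net.weights[i, idx[k]]
                for k in net.gene_ids
                if k in members and idx[k] != i
            )
            out[a, b] = num / degree if degree > 0 else np.nan
    return out


def oracle_gene_pr(scores, truth, grid):
    """Per-gene AUPRC by explicit threshold enumeration + trapezoid."""
    pts = []
    true_set = {j for j, v in enumerate(truth) if v}
    for t in grid:
        pred = {j for j, s in enumerate(scores) if s >= t}
        if not pred:
            continue
        tp = len(pred & true_set)
        pts.append((tp / len(true_set), tp / len(pred)))
    pts.sort()
    area = 0.0
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        area += (r1 - r0) * (p0 + p1) / 2.0
    return area


def oracle_average_pr(scores, truth, grid):
    """Average PR curve, avgAUPRC and Fmax by explicit enumeration."""
    m_genes = scores.shape[0]
    curve = []
    for t in grid:
        prs, rcs = [], []
        for i in range(m_genes):
            pred = {j for j, s in enumerate(scores[i]) if s >= t}
            true_set = {j for j, v in enumerate(truth[i]) if v}
            if pred:
                prs.append(len(pred & true_set) / len(pred))
            rcs.append(len(pred & true_set) / len(true_set))
        curve.append((t, np.mean(prs) if prs else None, np.mean(rcs), len(prs)))
    pts = sorted((rc, pr) for _, pr, rc, m in curve if m > 0)
    area = sum((r1 - r0) * (p0 + p1) / 2.0
               for (r0, p0), (r1, p1) in zip(pts, pts[1:]))
    fmax = max(
        2 * pr * rc / (pr + rc)
        for _, pr, rc, m in curve
        if m > 0 and pr is not None and (pr + rc) > 0
    )
    return curve, area, fmax


def oracle_ru_mi(scores, truth, ic, grid):
    """IC-weighted error curves and Smin by explicit set arithmetic."""
    out = []
    for t in grid:
        rus, mis = [], []
        for i in range(scores.shape[0]):
            pred = {j for j, s in enumerate(scores[i]) if s >= t}
            true_set = {j for j, v in enumerate(truth[i]) if v}
            denom = sum(ic[j] for j in pred | true_set)
            rus.append(sum(ic[j] for j in true_set - pred) / denom)
            mis.append(sum(ic[j] for j in pred - true_set) / denom)
        out.append((np.mean(rus), np.mean(mis)))
    smin = min(np.sqrt(ru ** 2 + mi ** 2) for ru, mi in out)
    return out, smin


def oracle_auroc(scores, labels):
    """O(n^2) pairwise-comparison AUROC; ties count half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def random_instance(rng, n_genes=None, n_terms=None):
    """A random score/annotation instance; every gene has >= 1 true term."""
    g = n_genes or int(rng.integers(2, 11))
    t = n_terms or int(rng.integers(2, 6))
    scores = np.round(rng.random((g, t)), 3)
    truth = rng.random((g, t)) < 0.4
    for i in range(g):
        if not truth[i].any():
            truth[i, rng.integers(t)] = True
    return scores, truth
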