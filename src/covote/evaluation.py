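"""Gene-centric and term-centric evaluation of relevance scores.

Gene-centric metrics follow the CAFA conventions: per-gene precision-recall
curves on a fixed threshold grid (0.01..1.00, step 0.01), an average PR
curve whose precision at threshold t is averaged over the m(t) genes with at
least one prediction while recall is averaged over all M tested genes,
Fmax = max_t of the harmonic mean of average precision and recall, and
information-content-weighted remaining-uncertainty / misinformation curves
with their minimum semantic distance Smin = min_t sqrt(ru(t)^2 + mi(t)^2).
Term-centric evaluation is a plain binary-classification AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .expression import ValidationError

__all__ = [
    "DEFAULT_GRID",
    "EvaluationResult",
    "gene_pr_curve",
    "average_pr_curve",
    "ru_mi_curve",
    "roc_auc",
    "avg_auroc",
    "evaluate_gene_centric",
]

#: the threshold grid: 0.01 to 1.00 with step 0.01
DEFAULT_GRID = np.round(np.arange(1, 101) / 100.0, 2)


@dataclass
class EvaluationResult:
    """Threshold-indexed curves plus scalar summaries."""

    curve: pd.DataFrame  # columns: threshold, precision, recall, m, ru, mi
    avg_auprc: float = np.nan
    fmax: float = np.nan
    fmax_threshold: float = np.nan
    smin: float = np.nan
    smin_threshold: float = np.nan
    n_genes: int = 0
    gene_auprc: pd.Series | None = None
    term_auroc: pd.Series | None = None
    avg_auroc: float = np.nan
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "avgAUPRC": self.avg_auprc,
            "Fmax": self.fmax,
            "Fmax_threshold": self.fmax_threshold,
            "Smin": self.smin,
            "avgAUROC": self.avg_auroc,
            "M": self.n_genes,
        }


def _trapezoid_by_recall(recall: np.ndarray, precision: np.ndarray) -> float:
    """Area under a PR point set, points sorted by recall ascending; no
    extrapolation to recall 0 or 1."""
    order = np.argsort(recall, kind="stable")
    return float(np.trapezoid(precision[order], recall[order]))


def gene_pr_curve(scores, truth, grid=None):
    """Per-gene PR curve and AUPRC.

    Parameters
    ----------
    scores : (T,) relevance scores for one gene over the term list
    truth : (T,) boolean membership of each term in the gene's true set T_i

    Returns a DataFrame (threshold, precision, recall) where precision is
    NaN at thresholds with no prediction (those points are skipped in the
    AUPRC), and the trapezoid AUPRC over recall-sorted defined points.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if grid is None:
        grid = DEFAULT_GRID
    n_true = int(truth.sum())
    if n_true == 0:
        raise ValidationError("gene has no true terms")
    pred = scores[None, :] >= grid[:, None]  # (n_thresh, T)
    tp = (pred & truth[None, :]).sum(axis=1)
    npred = pred.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(npred > 0, tp / np.maximum(npred, 1), np.nan)
    recall = tp / n_true
    df = pd.DataFrame({"threshold": grid, "precision": precision, "recall": recall})
    ok = npred > 0
    auprc = _trapezoid_by_recall(recall[ok], precision[ok]) if ok.any() else np.nan
    return df, auprc


def average_pr_curve(scores, truth, grid=None):
    """Average PR curve over genes, with avgAUPRC and Fmax.

    ``scores`` is an (M, T) matrix, ``truth`` the matching boolean matrix.
    Precision at t averages over the m(t) genes with >= 1 prediction;
    recall averages over all M genes.  Fmax ties resolve to the smallest t.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if grid is None:
        grid = DEFAULT_GRID
    m_genes = scores.shape[0]
    if m_genes < 1:
        raise ValidationError("need at least one tested gene")
    n_true = truth.sum(axis=1)
    if np.any(n_true == 0):
        raise ValidationError("every tested gene needs at least one true term")
    pr_t = np.full(grid.shape, np.nan)
    rc_t = np.zeros(grid.shape)
    m_t = np.zeros(grid.shape, dtype=int)
    for k, t in enumerate(grid):
        pred = scores >= t
        tp = (pred & truth).sum(axis=1)
        npred = pred.sum(axis=1)
        has = npred > 0
        m_t[k] = int(has.sum())
        if m_t[k]:
            pr_t[k] = float((tp[has] / npred[has]).mean())
        rc_t[k] = float((tp / n_true).mean())
    if not (m_t > 0).any():
        raise ValidationError("no predictions at any threshold")
    ok = m_t > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        f_t = np.where(
            ok & (pr_t + rc_t > 0), 2 * pr_t * rc_t / (pr_t + rc_t), np.nan
        )
    fmax_idx = int(np.nanargmax(f_t))  # argmax returns the first (smallest t) on ties
    curve = pd.DataFrame(
        {"threshold": grid, "precision": pr_t, "recall": rc_t, "m": m_t, "F": f_t}
    )
    avg_auprc = _trapezoid_by_recall(rc_t[ok], pr_t[ok])
    return curve, avg_auprc, float(f_t[fmax_idx]), float(grid[fmax_idx])


def ru_mi_curve(scores, truth, ic, grid=None):
    """Information-content-weighted error curves and Smin.

    Per gene and threshold, the remaining-uncertainty component is the IC
    mass of false negatives and the misinformation component the IC mass of
    false positives, both normalized by the IC mass of the union of
    predicted and true terms; ru(t) and mi(t) average the components over
    genes, and Smin = min_t sqrt(ru^2 + mi^2).

    ``ic`` is a (T,) vector of information contents aligned to the term axis.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    ic = np.asarray(ic, dtype=float)
    if grid is None:
        grid = DEFAULT_GRID
    if np.any(~np.isfinite(ic)) or np.any(ic < 0):
        raise ValidationError("information content must be finite and >= 0")
    ru_t = np.zeros(grid.shape)
    mi_t = np.zeros(grid.shape)
    for k, t in enumerate(grid):
        pred = scores >= t
        union_ic = ((pred | truth) * ic[None, :]).sum(axis=1)
        if np.any(union_ic <= 0):
            raise ValidationError(
                "a gene has zero IC mass over predicted union true terms"
            )
        fn_ic = ((truth & ~pred) * ic[None, :]).sum(axis=1)
        fp_ic = ((pred & ~truth) * ic[None, :]).sum(axis=1)
        ru_t[k] = float((fn_ic / union_ic).mean())
        mi_t[k] = float((fp_ic / union_ic).mean())
    dist = np.sqrt(ru_t ** 2 + mi_t ** 2)
    idx = int(np.argmin(dist))
    return ru_t, mi_t, float(dist[idx]), float(grid[idx])


def roc_auc(scores, labels) -> float:
    """AUROC via the rank (Mann-Whitney U) formula; ties count half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUROC needs at least one positive and one negative")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def avg_auroc(term_aurocs) -> float:
    """Unweighted mean of per-term (cross-validated) AUROCs."""
    vals = np.asarray(list(term_aurocs), dtype=float)
    if vals.size == 0:
        raise ValidationError("no term AUROCs to average")
    return float(vals.mean())


def evaluate_gene_centric(scores, truth, ic=None, grid=None,
                          gene_ids=None) -> EvaluationResult:
    """Full gene-centric evaluation of a score matrix against a truth matrix."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if grid is None:
        grid = DEFAULT_GRID
    curve, avg_auprc_v, fmax, fmax_t = average_pr_curve(scores, truth, grid)
    per_gene = []
    for i in range(scores.shape[0]):
        _, a = gene_pr_curve(scores[i], truth[i], grid)
        per_gene.append(a)
    gene_auprc = pd.Series(
        per_gene, index=gene_ids if gene_ids is not None else range(scores.shape[0])
    )
    res = EvaluationResult(
        curve=curve,
        avg_auprc=avg_auprc_v,
        fmax=fmax,
        fmax_threshold=fmax_t,
        n_genes=scores.shape[0],
        gene_auprc=gene_auprc,
    )
    if ic is not None:
        ru_t, mi_t, smin, smin_t = ru_mi_curve(scores, truth, ic, grid)
        res.curve = res.curve.assign(ru=ru_t, mi=mi_t)
        res.smin = smin
        res.smin_threshold = smin_t
    return res
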