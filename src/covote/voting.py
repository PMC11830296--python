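"""Neighbor voting on rank-normalized co-expression networks.

A gene inherits the labels of its network neighborhood: the relevance of
term f to gene i is the fraction of gene i's degree contributed by
neighbors annotated to f,

    Score(f, i) = sum_{k in f, k != i} W_ik / sum_{l != i} W_il.

Self-exclusion is structural (the diagonal is zero and the scored gene's
own annotation never enters its numerator), so gene-centric evaluation is a
leave-one-out scheme by construction.  Term-centric performance is measured
by 10-fold cross-validation: each fold of a term's annotated genes is
hidden, scores are recomputed from the remaining positives, and held-out
positives are ranked against genes never annotated to the term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .evaluation import roc_auc
from .expression import ValidationError
from .network import CoexpressionNetwork, node_degree

__all__ = [
    "RelevanceScores",
    "PredictionResult",
    "relevance_scores",
    "predict_at_threshold",
    "threshold_at_fmax",
    "term_auroc_cv",
    "term_auroc_cv_table",
]


@dataclass
class RelevanceScores:
    """Gene x term neighbor-voting scores in [0, 1].

    Rows for genes with zero network degree are NaN and flagged in
    ``zero_degree``.
    """

    scores: np.ndarray
    gene_ids: list
    term_ids: list
    zero_degree: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.gene_ids, columns=self.term_ids)


@dataclass
class PredictionResult:
    """Thresholded predictions and their overlap with the gold standard."""

    threshold: float
    predicted: dict  # gene -> set of predicted terms P_i(t)
    recalled_terms: dict  # gene -> P_i(t) & T_i
    recalled_genes: dict  # term -> predicted genes & annotated genes
    tested_genes: list


def relevance_scores(
    net: CoexpressionNetwork,
    ann: AnnotationSet,
    genes=None,
    terms=None,
) -> RelevanceScores:
    """Eq.-style neighbor-voting scores for ``genes`` x ``terms``.

    Votes come only from network genes annotated to the term; the scored
    gene's own annotation is excluded by the zero diagonal.  The denominator
    is the gene's full degree, so scores lie in [0, 1].
    """
    if genes is None:
        genes = list(net.gene_ids)
    if terms is None:
        terms = sorted(ann.term_universe)
    gidx = net.gene_index()
    missing = [g for g in genes if g not in gidx]
    if missing:
        raise ValidationError(f"genes absent from network: {missing[:5]}")
    rows = np.array([gidx[g] for g in genes])
    incidence = ann.to_incidence(net.gene_ids, terms).astype(float)
    empty = incidence.sum(axis=0) == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} terms annotate no network gene; their scores are 0",
            stacklevel=2,
        )
    degree = node_degree(net)[rows]
    votes = net.weights[rows, :] @ incidence  # diagonal zero => k != i
    zero_deg = degree == 0
    if zero_deg.any():
        warnings.warn(
            f"{int(zero_deg.sum())} genes have zero degree; scores flagged NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = votes / degree[:, None]
    scores[zero_deg, :] = np.nan
    return RelevanceScores(
        scores=scores, gene_ids=list(genes), term_ids=list(terms),
        zero_degree=zero_deg,
    )


def predict_at_threshold(s: RelevanceScores, ann: AnnotationSet, t: float) -> PredictionResult:
    """Predict term f for gene i when Score(f, i) >= t (inclusive).

    Recalled terms per gene are the true positives P_i(t) & T_i; recalled
    genes per term are the term's predicted genes that are also annotated.
    """
    if not (0 < t <= 1):
        raise ValidationError(f"threshold must lie in (0, 1], got {t}")
    pred_mask = s.scores >= t  # NaN compares False
    predicted, recalled_terms = {}, {}
    recalled_genes = {term: set() for term in s.term_ids}
    terms = np.array(s.term_ids, dtype=object)
    for i, g in enumerate(s.gene_ids):
        p = set(terms[pred_mask[i]])
        true = ann.terms_for(g)
        predicted[g] = p
        recalled_terms[g] = p & true
        for term in p & true:
            recalled_genes[term].add(g)
    return PredictionResult(
        threshold=float(t),
        predicted=predicted,
        recalled_terms=recalled_terms,
        recalled_genes=recalled_genes,
        tested_genes=list(s.gene_ids),
    )


def threshold_at_fmax(result) -> float:
    """The grid threshold achieving Fmax on an average PR curve (ties break
    toward the smaller threshold)."""
    t = getattr(result, "fmax_threshold", None)
    if t is None or not np.isfinite(t):
        raise ValidationError("evaluation result carries no Fmax threshold")
    return float(t)


def term_auroc_cv(
    net: CoexpressionNetwork,
    ann: AnnotationSet,
    term,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Average AUROC for one term over seeded k-fold cross-validation.

    Positives (the term's annotated genes present in the network) are split
    into size-balanced folds.  Per fold, scores are recomputed from the
    training positives only; the held-out positives are ranked against
    genes never annotated to the term (training positives excluded from the
    ROC set).  Genes with zero degree are excluded with a warning.
    """
    gidx = net.gene_index()
    positives = sorted(g for g in ann.genes_for(term) if g in gidx)
    if len(positives) < folds:
        raise ValidationError(
            f"term {term} has {len(positives)} annotated network genes; "
            f"needs >= {folds} (use fewer folds)"
        )
    degree = node_degree(net)
    zero = degree == 0
    if zero.any():
        warnings.warn("zero-degree genes excluded from CV", stacklevel=2)
    pos_idx = np.array([gidx[g] for g in positives])
    pos_idx = pos_idx[~zero[pos_idx]]
    neg_idx = np.array(
        [i for g, i in gidx.items()
         if g not in ann.genes_for(term) and not zero[i]]
    )
    if len(pos_idx) < folds or len(neg_idx) == 0:
        raise ValidationError(f"not enough usable genes for CV on term {term}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pos_idx))
    fold_of = perm % folds  # size-balanced assignment of shuffled positives
    aurocs = []
    for f in range(folds):
        held = pos_idx[fold_of == f]
        train = pos_idx[fold_of != f]
        votes = net.weights[:, train].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = votes / degree
        eval_idx = np.concatenate([held, neg_idx])
        labels = np.zeros(len(eval_idx), dtype=bool)
        labels[: len(held)] = True
        aurocs.append(roc_auc(score[eval_idx], labels))
    return float(np.mean(aurocs))


def term_auroc_cv_table(net, ann, terms, folds=10, seed=0) -> pd.Series:
    """Cross-validated AUROC for each term, with per-term derived seeds."""
    rng = np.random.default_rng(seed)
    out = {}
    for term in terms:
        out[term] = term_auroc_cv(
            net, ann, term, folds=folds, seed=int(rng.integers(2 ** 31))
        )
    return pd.Series(out, name="cv_auroc")
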