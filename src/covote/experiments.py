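"""End-to-end pipeline runs and the comparative experiments.

Each run takes a raw single-cell TPM matrix through QC, gene filtering,
network construction, neighbor voting and evaluation.  On top of single
runs sit the study designs: per-stratum runs (by cell type or by sample)
with stratum-specific recalled-function analysis, stepwise cell-number
subsampling, and fixed-cell-count comparisons between datasets.

QC thresholds default to genome-scale values (2000 expressed genes); runs
on small synthetic panels must scale ``min_genes`` to the panel size via
``RunConfig``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import expression as xp
from .annotations import (
    AnnotationSet,
    information_content,
    select_evaluation_terms,
)
from .evaluation import EvaluationResult, avg_auroc, evaluate_gene_centric
from .expression import ExpressionMatrix, ValidationError
from .network import NetworkVariantSpec, build_network
from .voting import (
    PredictionResult,
    predict_at_threshold,
    relevance_scores,
    term_auroc_cv_table,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "SpecificityReport",
    "run_pipeline",
    "run_stratified",
    "specificity_analysis",
    "merge_prediction_strata",
    "subsample_performance",
    "fixed_cell_compare",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    dataset_tag: str = "run"
    subset: str = "all_cells"  # all_cells | by_cell_type | by_sample
    variant: NetworkVariantSpec = field(default_factory=NetworkVariantSpec)
    threshold_policy: str = "fmax"  # "fmax" or "fixed"
    fixed_threshold: float | None = None
    seed: int = 0
    # QC / filtering knobs (paper-scale defaults; scale min_genes to panel)
    min_genes: int = 2000
    min_hk: float = 2.5
    ea_min: float = 2.0
    min_detect_frac: float = 0.20
    min_terms: int = 2
    # term-centric evaluation
    folds: int = 10
    eval_term_min: int = 20
    eval_term_max: int = 1000
    run_term_cv: bool = True
    min_overlap: int = 10

    def __post_init__(self):
        if self.threshold_policy == "fixed":
            t = self.fixed_threshold
            if t is None or not (0 < t <= 1):
                raise ValidationError("fixed threshold must lie in (0, 1]")
        elif self.threshold_policy != "fmax":
            raise ValidationError(f"unknown threshold policy {self.threshold_policy!r}")


@dataclass
class RunResult:
    """One pipeline run: what was kept, scored and how it evaluated."""

    tag: str
    evaluation: EvaluationResult
    prediction: PredictionResult
    tested_genes: list
    network_genes: list
    n_cells: int
    threshold: float


@dataclass
class SpecificityReport:
    """Stratum-specific recalled functions across a set of strata.

    An item is stratum-specific when it is recalled in at least one but not
    all strata.  ``gene_ratio`` is the fraction of tested genes with >= 1
    stratum-specific recalled term; ``term_ratio`` the fraction of recalled
    terms with >= 1 stratum-specific recalled gene.
    """

    strata: list
    gene_specific_terms: dict  # gene -> set of stratum-specific terms
    term_specific_genes: dict  # term -> set of stratum-specific genes
    gene_ratio: float
    term_ratio: float


# ---------------------------------------------------------------------------
# Single run
# ---------------------------------------------------------------------------

def run_pipeline(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    ann: AnnotationSet,
    cfg: RunConfig,
    housekeeping,
    ic=None,
    bulk: ExpressionMatrix | None = None,
    gene_restriction=None,
) -> RunResult:
    """QC -> filter -> network -> neighbor voting -> evaluation, one stratum.

    ``ann`` must already be evidence-filtered and ancestor-propagated.
    ``ic`` is an information-content Series over terms; when None it is
    computed on the annotation gene universe.  ``bulk`` (optional, already
    filtered) restricts tested genes to those detected in bulk as well;
    ``gene_restriction`` restricts tested genes to an explicit set.
    """
    logm = xp.sc_log_transform(expr)
    logm = xp.qc_filter_cells(
        logm, housekeeping, min_genes=cfg.min_genes, min_hk=cfg.min_hk
    )
    if logm.n_units == 0:
        raise ValidationError(f"{cfg.dataset_tag}: no cells pass QC")
    tpm = expr.subset_units(logm.unit_ids)
    logm = xp.filter_genes_sc(
        logm, tpm, ea_min=cfg.ea_min, min_detect_frac=cfg.min_detect_frac
    )
    if logm.n_genes < 2:
        raise ValidationError(f"{cfg.dataset_tag}: fewer than 2 genes pass filters")

    terms_per_gene = ann.terms_per_gene()
    tested = sorted(
        g for g in logm.gene_ids if terms_per_gene.get(g, 0) >= cfg.min_terms
    )
    if bulk is not None:
        tested = sorted(set(tested) & set(bulk.gene_ids))
    if gene_restriction is not None:
        tested = sorted(set(tested) & set(gene_restriction))
    if not tested:
        raise ValidationError(f"{cfg.dataset_tag}: no tested genes")

    net = build_network(logm, cfg.variant, min_overlap=cfg.min_overlap)
    network_gene_set = set(net.gene_ids)
    terms = sorted(
        t for t in ann.term_universe if ann.genes_for(t) & network_gene_set
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = relevance_scores(net, ann, genes=tested, terms=terms)

    truth = ann.to_incidence(tested, terms)
    if ic is None:
        ic = information_content(ann)
    ic_vec = ic.reindex(terms).fillna(0.0).to_numpy()
    usable = ~scores.zero_degree
    evaluation = evaluate_gene_centric(
        scores.scores[usable], truth[usable], ic=ic_vec,
        gene_ids=[g for g, u in zip(tested, usable) if u],
    )

    if cfg.run_term_cv:
        sizes = ann.term_sizes()
        eligible = []
        n_net = len(net.gene_ids)
        for t in select_evaluation_terms(
            ann, min_genes=cfg.eval_term_min, max_genes=cfg.eval_term_max
        ):
            pos_in_net = len(ann.genes_for(t) & network_gene_set)
            if pos_in_net >= cfg.folds and (n_net - pos_in_net) >= 1:
                eligible.append(t)
        if eligible:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = term_auroc_cv_table(
                    net, ann, eligible, folds=cfg.folds, seed=cfg.seed
                )
            evaluation.term_auroc = table
            evaluation.avg_auroc = avg_auroc(table.values)

    if cfg.threshold_policy == "fixed":
        threshold = float(cfg.fixed_threshold)
    else:
        threshold = float(evaluation.fmax_threshold)
    prediction = predict_at_threshold(scores, ann, threshold)

    return RunResult(
        tag=cfg.dataset_tag,
        evaluation=evaluation,
        prediction=prediction,
        tested_genes=tested,
        network_genes=list(net.gene_ids),
        n_cells=logm.n_units,
        threshold=threshold,
    )


def run_stratified(expr, meta, ann, cfg, housekeeping, ic=None,
                   min_cells: int = 50, **kwargs) -> dict:
    """One pipeline run per stratum (cell type or sample).

    Gene filters and networks are recomputed within each stratum, and each
    stratum uses its own Fmax threshold.  Strata with fewer than
    ``min_cells`` cells are skipped with a warning.
    """
    if cfg.subset == "by_cell_type":
        column = "cell_type"
    elif cfg.subset == "by_sample":
        column = "sample_id"
    else:
        raise ValidationError("run_stratified needs subset by_cell_type/by_sample")
    results = {}
    for stratum in sorted(meta[column].unique()):
        cells = meta.loc[meta[column] == stratum, "cell_id"].tolist()
        cells = [c for c in cells if c in set(expr.unit_ids)]
        if len(cells) < min_cells:
            warnings.warn(
                f"stratum {stratum}: {len(cells)} cells < {min_cells}; skipped",
                stacklevel=2,
            )
            continue
        sub_cfg = replace(cfg, dataset_tag=f"{cfg.dataset_tag}:{stratum}")
        results[stratum] = run_pipeline(
            expr.subset_units(cells), meta, ann, sub_cfg, housekeeping,
            ic=ic, **kwargs,
        )
    if len(results) < 2:
        raise ValidationError("fewer than 2 usable strata")
    return results


# ---------------------------------------------------------------------------
# Specificity
# ---------------------------------------------------------------------------

def specificity_analysis(runs: dict) -> SpecificityReport:
    """Stratum-specific recalled terms and genes across per-stratum runs.

    ``runs`` maps stratum name to a RunResult (or PredictionResult).  A
    recalled item counts as stratum-specific when it appears in >= 1 but
    not all strata.
    """
    if len(runs) < 2:
        raise ValidationError("specificity needs at least 2 strata")
    strata = sorted(runs)
    preds = {
        s: (r.prediction if isinstance(r, RunResult) else r) for s, r in runs.items()
    }
    n_strata = len(strata)

    # gene -> term -> number of strata recalling it
    gene_term_count: dict = {}
    term_gene_count: dict = {}
    tested_union = set()
    for s in strata:
        p = preds[s]
        tested_union.update(p.tested_genes)
        for g, terms in p.recalled_terms.items():
            for t in terms:
                gene_term_count.setdefault(g, {}).setdefault(t, 0)
                gene_term_count[g][t] += 1
        for t, genes in p.recalled_genes.items():
            for g in genes:
                term_gene_count.setdefault(t, {}).setdefault(g, 0)
                term_gene_count[t][g] += 1

    gene_specific = {
        g: {t for t, c in tc.items() if 0 < c < n_strata}
        for g, tc in gene_term_count.items()
    }
    gene_specific = {g: ts for g, ts in gene_specific.items() if ts}
    term_specific = {
        t: {g for g, c in gc.items() if 0 < c < n_strata}
        for t, gc in term_gene_count.items()
    }
    term_specific = {t: gs for t, gs in term_specific.items() if gs}

    recalled_terms_union = {
        t for tc in gene_term_count.values() for t in tc
    }
    gene_ratio = len(gene_specific) / len(tested_union) if tested_union else 0.0
    term_ratio = (
        len(term_specific) / len(recalled_terms_union) if recalled_terms_union else 0.0
    )
    return SpecificityReport(
        strata=strata,
        gene_specific_terms=gene_specific,
        term_specific_genes=term_specific,
        gene_ratio=gene_ratio,
        term_ratio=term_ratio,
    )


def merge_prediction_strata(preds) -> PredictionResult:
    """Union-merge per-stratum predictions into one composite stratum.

    A merged stratum recalls everything any member recalled; its tested
    genes are the union.  Merging strata this way can only remove
    stratum-specific items, never create them, so specificity ratios are
    monotone non-increasing under merging.
    """
    preds = [p.prediction if isinstance(p, RunResult) else p for p in preds]
    if not preds:
        raise ValidationError("nothing to merge")
    predicted, recalled_terms = {}, {}
    recalled_genes: dict = {}
    tested = set()
    for p in preds:
        tested.update(p.tested_genes)
        for g, ts in p.predicted.items():
            predicted.setdefault(g, set()).update(ts)
        for g, ts in p.recalled_terms.items():
            recalled_terms.setdefault(g, set()).update(ts)
        for t, gs in p.recalled_genes.items():
            recalled_genes.setdefault(t, set()).update(gs)
    return PredictionResult(
        threshold=float("nan"),
        predicted=predicted,
        recalled_terms=recalled_terms,
        recalled_genes=recalled_genes,
        tested_genes=sorted(tested),
    )


# ---------------------------------------------------------------------------
# Cell-number stepping and platform comparison
# ---------------------------------------------------------------------------

DEFAULT_SUBSAMPLE_GRID = (10, 20, 30, 50, 100, 200, 300, 400, 500, 750, 1000)


def subsample_performance(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    ann: AnnotationSet,
    cfg: RunConfig,
    housekeeping,
    grid=None,
    repeats: int = 10,
    seed: int = 0,
    ic=None,
) -> pd.DataFrame:
    """Prediction performance at stepped cell numbers.

    For each n in the grid and each repeat, n cells are drawn without
    replacement (seeded), the pipeline is rebuilt from scratch (gene
    filters and network recomputed) and evaluated.  Returns a tidy frame
    with one row per (n, repeat) holding avgAUPRC, Fmax, Smin and avgAUROC.
    """
    n_total = expr.n_units
    if grid is None:
        grid = [n for n in DEFAULT_SUBSAMPLE_GRID if n <= n_total]
    grid = sorted(set(int(n) for n in grid))
    if grid and grid[-1] > n_total:
        raise ValidationError(f"n={grid[-1]} exceeds the {n_total} available cells")
    rng = np.random.default_rng(seed)
    rows = []
    for n in grid:
        for rep in range(repeats):
            sub_seed = int(rng.integers(2 ** 31))
            sub_rng = np.random.default_rng(sub_seed)
            cells = [expr.unit_ids[i]
                     for i in sub_rng.choice(n_total, size=n, replace=False)]
            sub_cfg = replace(
                cfg, dataset_tag=f"{cfg.dataset_tag}:n{n}r{rep}", seed=sub_seed
            )
            try:
                res = run_pipeline(
                    expr.subset_units(cells), meta, ann, sub_cfg, housekeeping, ic=ic
                )
            except ValidationError as exc:
                warnings.warn(f"n={n} repeat={rep} failed: {exc}", stacklevel=2)
                continue
            rows.append(
                {
                    "n": n,
                    "repeat": rep,
                    "avgAUPRC": res.evaluation.avg_auprc,
                    "Fmax": res.evaluation.fmax,
                    "Smin": res.evaluation.smin,
                    "avgAUROC": res.evaluation.avg_auroc,
                    "n_tested_genes": len(res.tested_genes),
                }
            )
    return pd.DataFrame(rows)


def fixed_cell_compare(
    datasets: dict,
    ann: AnnotationSet,
    cfg: RunConfig,
    housekeeping,
    n: int = 550,
    repeats: int = 10,
    seed: int = 0,
    ic=None,
) -> pd.DataFrame:
    """Compare datasets at a fixed cell count.

    ``datasets`` maps a tag to ``(expr, meta)``.  Tested genes are
    restricted to genes passing the expression filters in every dataset
    (on the full data), so the comparison is over a common gene set.  Each
    repeat draws ``n`` cells without replacement per dataset.
    """
    for tag, (expr, _) in datasets.items():
        if expr.n_units < n:
            raise ValidationError(f"dataset {tag} has {expr.n_units} cells < n={n}")
    common = None
    for tag, (expr, _) in datasets.items():
        logm = xp.sc_log_transform(expr)
        logm = xp.qc_filter_cells(
            logm, housekeeping, min_genes=cfg.min_genes, min_hk=cfg.min_hk
        )
        tpm = expr.subset_units(logm.unit_ids)
        logm = xp.filter_genes_sc(
            logm, tpm, ea_min=cfg.ea_min, min_detect_frac=cfg.min_detect_frac
        )
        genes = set(logm.gene_ids)
        common = genes if common is None else (common & genes)
    if not common:
        raise ValidationError("no gene passes the filters in every dataset")
    rng = np.random.default_rng(seed)
    rows = []
    for tag, (expr, meta) in sorted(datasets.items()):
        for rep in range(repeats):
            sub_seed = int(rng.integers(2 ** 31))
            sub_rng = np.random.default_rng(sub_seed)
            cells = [expr.unit_ids[i]
                     for i in sub_rng.choice(expr.n_units, size=n, replace=False)]
            sub_cfg = replace(cfg, dataset_tag=f"{tag}:r{rep}", seed=sub_seed)
            res = run_pipeline(
                expr.subset_units(cells), meta, ann, sub_cfg, housekeeping,
                ic=ic, gene_restriction=common,
            )
            platform = (
                meta.loc[meta["cell_id"].isin(cells), "platform"].mode().iat[0]
                if "platform" in meta.columns else "unknown"
            )
            rows.append(
                {
                    "dataset": tag,
                    "platform": platform,
                    "repeat": rep,
                    "avgAUPRC": res.evaluation.avg_auprc,
                    "Fmax": res.evaluation.fmax,
                    "Smin": res.evaluation.smin,
                    "avgAUROC": res.evaluation.avg_auroc,
                }
            )
    return pd.DataFrame(rows)
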