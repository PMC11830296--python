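"""Synthetic zero-inflated single-cell TPM data with planted function.

The generator emulates the statistical structure that co-expression-based
function prediction relies on: groups of genes (modules) whose expression
co-varies because they respond to a shared, per-cell activity, each tied to
one term of a small synthetic ontology.  Module activity can be restricted
to particular cell types and/or samples, which induces cell-type- and
sample-specific recallable function.  Technical zeros (dropout) follow a
logistic mean-dependent detection model; housekeeping genes are high-mean,
low-variance and nearly dropout-free; every cell is rescaled to TPM
(columns sum to 10^6).  Matched pseudobulk profiles average TPM over
bootstrap samples of cells.

The model is deliberately simple: it produces lognormal expression rather
than counts (the framework consumes TPM), and it contains no batch effects,
ambient RNA or doublets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .annotations import AnnotationSet, OntologyDAG
from .expression import BULK, RAW_TPM, SINGLE_CELL, ExpressionMatrix, ValidationError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_sc_dataset",
    "generate_pseudobulk",
    "write_fixture_bundle",
    "ROOT_TERM",
]

ROOT_TERM = "SYN:0000000"
_MID_TERMS = ("SYN:0000101", "SYN:0000102", "SYN:0000103")


def _default_restriction():
    """Planted stratum structure: one immune-only module, one tumor-only
    module, one module active in the first two samples only."""
    return {
        0: {"cell_types": ("immune",)},
        1: {"cell_types": ("tumor",)},
        2: {"samples": ("S1", "S2")},
    }


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``n_genes`` counts module plus background genes; ``n_housekeeping``
    high-expression low-variance genes are appended on top.  Expression is
    built on a log2 scale: per-gene baseline ~ Normal(baseline_mean,
    baseline_sd); module genes add ``module_activity`` times a per-cell
    standard-normal activity; lognormal noise with sd ``noise_sd`` (log2
    units) multiplies everything.  A gene is detected in a cell with
    probability sigmoid(dropout_slope * (log2-signal - dropout_midpoint)).
    """

    n_genes: int = 900
    n_cells: int = 1000
    n_modules: int = 10
    genes_per_module: int = 30
    module_activity: float = 1.5
    n_samples: int = 4
    cell_types: tuple = ("tumor", "immune")
    module_restriction: dict = field(default_factory=_default_restriction)
    dropout_midpoint: float = 4.85
    dropout_slope: float = 1.0
    baseline_mean: float = 4.0
    baseline_sd: float = 1.0
    noise_sd: float = 1.0
    n_housekeeping: int = 95
    hk_log_mean: float = 6.5
    hk_noise_sd: float = 0.2
    annotation_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise ValidationError("modules need more genes than n_genes provides")
        if not (0 <= self.annotation_noise < 1):
            raise ValidationError("annotation_noise must lie in [0, 1)")
        if self.n_samples < 1 or self.n_cells < 1:
            raise ValidationError("need at least one sample and one cell")


@dataclass
class GroundTruth:
    """What was planted: module membership, module terms, active strata."""

    module_genes: dict  # module index -> list of gene ids
    module_terms: dict  # module index -> term id
    module_restriction: dict  # module index -> {"cell_types": ..., "samples": ...}
    housekeeping: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "module_genes": {str(k): v for k, v in self.module_genes.items()},
                "module_terms": {str(k): v for k, v in self.module_terms.items()},
                "module_restriction": {
                    str(k): {kk: list(vv) for kk, vv in v.items()}
                    for k, v in self.module_restriction.items()
                },
                "housekeeping": self.housekeeping,
            },
            indent=1,
        )


def _module_term(m: int) -> str:
    return f"SYN:{1000 + m:07d}"


def _build_ontology(n_modules: int) -> OntologyDAG:
    edges = [(mid, ROOT_TERM, "is_a") for mid in _MID_TERMS]
    for m in range(n_modules):
        parent = _MID_TERMS[m % len(_MID_TERMS)]
        edges.append((_module_term(m), parent, "is_a"))
    return OntologyDAG.from_edges(edges)


def generate_sc_dataset(cfg: SyntheticConfig):
    """Generate one synthetic dataset.

    Returns ``(expr, meta, ann, dag, truth)``: a raw-TPM ExpressionMatrix,
    a cell metadata DataFrame (cell_id, sample_id, cell_type, platform), a
    direct (unpropagated) AnnotationSet with IDA evidence, the synthetic
    ontology, and the planted ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n_reg = cfg.n_genes
    n_mod_genes = cfg.n_modules * cfg.genes_per_module

    gene_ids = [f"GENE{i:05d}" for i in range(n_reg)]
    hk_ids = [f"HK{i:04d}" for i in range(cfg.n_housekeeping)]
    all_genes = gene_ids + hk_ids

    samples = [f"S{i + 1}" for i in range(cfg.n_samples)]
    meta = pd.DataFrame(
        {
            "cell_id": [f"CELL{j:05d}" for j in range(cfg.n_cells)],
            "sample_id": rng.choice(samples, size=cfg.n_cells),
            "cell_type": rng.choice(list(cfg.cell_types), size=cfg.n_cells),
            "platform": "tenx",
        }
    )

    # per-gene baselines (log2 scale)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_reg)
    # module membership: first n_modules * genes_per_module regular genes
    module_of = np.full(n_reg, -1)
    for m in range(cfg.n_modules):
        module_of[m * cfg.genes_per_module:(m + 1) * cfg.genes_per_module] = m

    # per-cell module activities, masked by stratum restriction
    activity = rng.normal(0.0, 1.0, size=(cfg.n_modules, cfg.n_cells))
    for m in range(cfg.n_modules):
        restr = cfg.module_restriction.get(m)
        if not restr:
            continue
        active = np.ones(cfg.n_cells, dtype=bool)
        if "cell_types" in restr:
            active &= meta["cell_type"].isin(restr["cell_types"]).to_numpy()
        if "samples" in restr:
            active &= meta["sample_id"].isin(restr["samples"]).to_numpy()
        activity[m, ~active] = 0.0

    signal = np.tile(baseline[:, None], (1, cfg.n_cells))
    in_module = module_of >= 0
    signal[in_module, :] += cfg.module_activity * activity[module_of[in_module], :]

    log_expr = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    # mean-dependent detection: high-signal gene-cell entries rarely drop out
    keep_p = 1.0 / (1.0 + np.exp(-cfg.dropout_slope * (signal - cfg.dropout_midpoint)))
    detected = rng.random(size=signal.shape) < keep_p
    expr = np.where(detected, np.exp2(log_expr), 0.0)

    if cfg.n_housekeeping:
        hk_log = cfg.hk_log_mean + rng.normal(
            0.0, cfg.hk_noise_sd, size=(cfg.n_housekeeping, cfg.n_cells)
        )
        hk_detected = rng.random(size=hk_log.shape) < 0.995
        hk_expr = np.where(hk_detected, np.exp2(hk_log), 0.0)
        expr = np.vstack([expr, hk_expr])

    # rescale each cell to TPM
    col_sums = expr.sum(axis=0)
    if np.any(col_sums <= 0):
        raise ValidationError("a cell has zero total expression; adjust dropout")
    expr = expr / col_sums[None, :] * 1e6

    expr_m = ExpressionMatrix(
        values=expr,
        gene_ids=all_genes,
        unit_ids=list(meta["cell_id"]),
        transform=RAW_TPM,
        modality=SINGLE_CELL,
    )

    # annotations: module genes -> module terms, plus spurious noise pairs
    pairs = []
    module_genes, module_terms = {}, {}
    for m in range(cfg.n_modules):
        term = _module_term(m)
        members = [gene_ids[i] for i in np.flatnonzero(module_of == m)]
        module_genes[m] = members
        module_terms[m] = term
        pairs.extend((g, term, "IDA") for g in members)
    n_noise = int(round(cfg.annotation_noise * len(pairs)))
    if n_noise and cfg.n_modules:
        noise_genes = rng.choice(gene_ids, size=n_noise)
        noise_terms = rng.choice([_module_term(m) for m in range(cfg.n_modules)],
                                 size=n_noise)
        pairs.extend(zip(noise_genes, noise_terms, ["IDA"] * n_noise))
    ann = AnnotationSet.from_pairs(pairs)
    dag = _build_ontology(cfg.n_modules)
    restr = {
        m: dict(cfg.module_restriction.get(m, {})) for m in range(cfg.n_modules)
    }
    truth = GroundTruth(
        module_genes=module_genes,
        module_terms=module_terms,
        module_restriction=restr,
        housekeeping=hk_ids,
    )
    return expr_m, meta, ann, dag, truth


def generate_pseudobulk(
    sc: ExpressionMatrix,
    meta: pd.DataFrame,
    n_bulk_samples: int,
    seed: int = 0,
    by_sample: bool = False,
) -> ExpressionMatrix:
    """Bulk-like profiles: mean TPM over bootstrap draws of cells, rescaled.

    With ``by_sample`` each bulk sample bootstraps within one sc sample_id
    (cycled); otherwise cells are drawn from the whole dataset.  No dropout
    is injected, so pseudobulk has fewer zeros than its single-cell input.
    """
    if sc.transform != RAW_TPM:
        raise ValidationError("pseudobulk starts from raw TPM")
    if n_bulk_samples < 1:
        raise ValidationError("need at least one bulk sample")
    if sc.n_units == 0:
        raise ValidationError("no cells to aggregate")
    rng = np.random.default_rng(seed)
    cols = []
    sample_ids = []
    groups = (
        [meta.loc[meta["sample_id"] == s, "cell_id"].tolist()
         for s in sorted(meta["sample_id"].unique())]
        if by_sample
        else [list(sc.unit_ids)]
    )
    cell_pos = {c: i for i, c in enumerate(sc.unit_ids)}
    for b in range(n_bulk_samples):
        pool = groups[b % len(groups)]
        draw = rng.choice([cell_pos[c] for c in pool], size=len(pool), replace=True)
        prof = sc.values[:, draw].mean(axis=1)
        prof = prof / prof.sum() * 1e6
        cols.append(prof)
        sample_ids.append(f"BULK{b + 1:03d}")
    return ExpressionMatrix(
        values=np.column_stack(cols),
        gene_ids=list(sc.gene_ids),
        unit_ids=sample_ids,
        transform=RAW_TPM,
        modality=BULK,
    )


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(outputs, outdir) -> dict:
    """Write a loadable fixture set: dense TSV + MTX expression, metadata,
    2-column+evidence TSV and GAF annotations, OBO ontology, truth JSON."""
    expr, meta, ann, dag, truth = outputs
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    files["expr_tsv"] = outdir / "expression.tsv"
    expr.to_frame().to_csv(files["expr_tsv"], sep="\t")

    files["expr_mtx"] = outdir / "expression.mtx"
    scipy.io.mmwrite(
        files["expr_mtx"], scipy.sparse.coo_matrix(expr.values), precision=10
    )
    (outdir / "genes.tsv").write_text("\n".join(expr.gene_ids) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(expr.unit_ids) + "\n")

    files["meta"] = outdir / "cell_metadata.tsv"
    meta.to_csv(files["meta"], sep="\t", index=False)

    files["annotations_tsv"] = outdir / "annotations.tsv"
    ann.write_tsv(files["annotations_tsv"])

    files["annotations_gaf"] = outdir / "annotations.gaf"
    _write_gaf(ann, files["annotations_gaf"])

    files["ontology"] = outdir / "ontology.obo"
    _write_obo(dag, files["ontology"])

    files["truth"] = outdir / "ground_truth.json"
    files["truth"].write_text(truth.to_json())

    files["housekeeping"] = outdir / "housekeeping.txt"
    files["housekeeping"].write_text("\n".join(truth.housekeeping) + "\n")
    return files


def _write_gaf(ann: AnnotationSet, path):
    """Emit a minimal 17-column GAF 2.2 file, aspect P."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene, term, ev in ann.pairs.itertuples(index=False):
            cols = [
                "SYNDB", gene, gene, "involved_in", term, "SYNREF:0000001",
                ev or "IDA", "", "P", "", "", "protein", "taxon:9606",
                "20250101", "SYNDB", "", "",
            ]
            fh.write("\t".join(cols) + "\n")


def _write_obo(dag: OntologyDAG, path):
    """Emit a minimal OBO 1.4 file readable by obonet."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.4\nontology: syn\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
            for parent in sorted(dag.graph.successors(term)):
                fh.write(f"is_a: {parent} ! parent\n")
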