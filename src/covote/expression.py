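"""Expression matrices, transforms and quality-control filters.

Single-cell profiles are TPM matrices transformed as ``log2(TPM/10 + 1)``;
the division by 10 reflects the ~100,000-transcript complexity of a
single-cell library, under which plain TPM over-counts each transcript
roughly tenfold.  Bulk profiles use ``log2(TPM + 1)``.  Cells are kept when
they express enough genes and show adequate housekeeping expression; genes
are kept by aggregate expression and detection fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "load_expression",
    "load_cell_metadata",
    "load_housekeeping",
    "sc_log_transform",
    "bulk_log_transform",
    "qc_filter_cells",
    "aggregate_expression",
    "filter_genes_sc",
    "filter_bulk",
    "select_tested_genes",
]

RAW_TPM = "raw_tpm"
SC_LOG = "sc_log"
BULK_LOG = "bulk_log"

SINGLE_CELL = "single_cell"
BULK = "bulk"


class ValidationError(ValueError):
    """Raised when an input violates a stated contract."""


class TransformStateError(ValidationError):
    """Raised when an operation is applied in the wrong transform state."""


@dataclass
class ExpressionMatrix:
    """A gene x unit (cell or sample) non-negative expression matrix.

    Parameters
    ----------
    values
        2-D float array, genes in rows, cells/samples in columns.
    gene_ids, unit_ids
        Ordered, duplicate-free identifier lists matching the array shape.
    transform
        One of ``raw_tpm``, ``sc_log`` (log2(TPM/10+1)) or ``bulk_log``
        (log2(TPM+1)).
    modality
        ``single_cell`` or ``bulk``.
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    unit_ids: list = field(default_factory=list)
    transform: str = RAW_TPM
    modality: str = SINGLE_CELL

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.unit_ids = list(self.unit_ids)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-D")
        if self.values.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.unit_ids)} units"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene IDs: {sorted(dupes)[:5]}")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            dupes = _duplicates(self.unit_ids)
            raise ValidationError(f"duplicate unit IDs: {sorted(dupes)[:5]}")
        if self.values.size and np.nanmin(self.values) < 0:
            raise ValidationError("expression values must be non-negative")
        if self.transform not in (RAW_TPM, SC_LOG, BULK_LOG):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.modality not in (SINGLE_CELL, BULK):
            raise ValidationError(f"unknown modality {self.modality!r}")

    # -- conveniences -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return replace(self, values=self.values[rows, :], gene_ids=list(genes))

    def subset_units(self, units) -> "ExpressionMatrix":
        idx = {u: i for i, u in enumerate(self.unit_ids)}
        cols = [idx[u] for u in units]
        return replace(self, values=self.values[:, cols], unit_ids=list(units))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.unit_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, transform=RAW_TPM, modality=SINGLE_CELL):
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(g) for g in df.index],
            unit_ids=[str(u) for u in df.columns],
            transform=transform,
            modality=modality,
        )


def _duplicates(ids):
    seen, dupes = set(), set()
    for x in ids:
        (dupes if x in seen else seen).add(x)
    return dupes


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_expression(path, format=None, modality=SINGLE_CELL) -> ExpressionMatrix:
    """Read a raw-TPM expression matrix from dense TSV/CSV or Matrix Market.

    Dense files carry gene IDs in the first column and a header row of unit
    IDs.  ``mtx`` files are Matrix Market coordinate format with sidecar
    ``genes.tsv`` and ``barcodes.tsv`` (one ID per line) next to the matrix.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas names the line
            raise ValidationError(f"could not parse {path}: {exc}") from exc
        df.index = df.index.map(str)
        return ExpressionMatrix.from_frame(df, transform=RAW_TPM, modality=modality)
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_id_list(path.parent / "genes.tsv")
        units = _read_id_list(path.parent / "barcodes.tsv")
        return ExpressionMatrix(
            values=np.asarray(mat, dtype=float),
            gene_ids=genes,
            unit_ids=units,
            transform=RAW_TPM,
            modality=modality,
        )
    raise ValidationError(f"unknown expression format {format!r}")


def _read_id_list(path) -> list:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing sidecar index file {path}")
    with open(path) as fh:
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def load_cell_metadata(path) -> pd.DataFrame:
    """Read the cell metadata table (cell_id, sample_id, cell_type, platform)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "sample_id", "cell_type", "platform"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"cell metadata missing columns {sorted(missing)}")
    if meta["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id in metadata")
    return meta


def load_housekeeping(path) -> list:
    """Read a housekeeping gene list, one symbol per line."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise ValidationError(f"empty housekeeping list {path}")
    return genes


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def sc_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM/10 + 1) for single-cell profiles."""
    if m.transform != RAW_TPM:
        raise TransformStateError(f"expected raw_tpm input, got {m.transform}")
    if m.modality != SINGLE_CELL:
        raise TransformStateError("sc_log_transform requires single_cell modality")
    return replace(m, values=np.log2(m.values / 10.0 + 1.0), transform=SC_LOG)


def bulk_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) for bulk profiles."""
    if m.transform != RAW_TPM:
        raise TransformStateError(f"expected raw_tpm input, got {m.transform}")
    if m.modality != BULK:
        raise TransformStateError("bulk_log_transform requires bulk modality")
    return replace(m, values=np.log2(m.values + 1.0), transform=BULK_LOG)


def invert_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Recover raw TPM from a log-transformed matrix (exact inverse)."""
    if m.transform == SC_LOG:
        tpm = (np.exp2(m.values) - 1.0) * 10.0
    elif m.transform == BULK_LOG:
        tpm = np.exp2(m.values) - 1.0
    else:
        raise TransformStateError("matrix is not log-transformed")
    return replace(m, values=np.clip(tpm, 0.0, None), transform=RAW_TPM)


# ---------------------------------------------------------------------------
# Cell / sample QC
# ---------------------------------------------------------------------------

def qc_filter_cells(
    m: ExpressionMatrix,
    housekeeping,
    min_genes: int = 2000,
    min_hk: float = 2.5,
    return_report: bool = False,
):
    """Drop low-quality cells.

    A cell is retained when it expresses at least ``min_genes`` genes
    (``E > 0``) and its mean log expression over the housekeeping genes
    present in the matrix is at least ``min_hk``.  Housekeeping genes absent
    from the panel are ignored (not treated as zeros); at least one must be
    present.
    """
    if m.transform != SC_LOG:
        raise TransformStateError("qc_filter_cells expects an sc_log matrix")
    hk = [g for g in housekeeping if g in set(m.gene_ids)]
    if not hk:
        raise ValidationError("no housekeeping gene found in the matrix")
    idx = m.gene_index()
    hk_rows = [idx[g] for g in hk]
    n_expressed = (m.values > 0).sum(axis=0)
    hk_mean = m.values[hk_rows, :].mean(axis=0)
    keep = (n_expressed >= min_genes) & (hk_mean >= min_hk)
    report = pd.DataFrame(
        {
            "cell_id": m.unit_ids,
            "n_expressed_genes": n_expressed,
            "housekeeping_mean": hk_mean,
            "pass_qc": keep,
        }
    )
    if not keep.any():
        warnings.warn("all cells removed by QC", stacklevel=2)
    out = replace(
        m,
        values=m.values[:, keep],
        unit_ids=[u for u, k in zip(m.unit_ids, keep) if k],
    )
    return (out, report) if return_report else out


def aggregate_expression(m: ExpressionMatrix) -> np.ndarray:
    """Aggregate expression Ea(i) = log2(mean TPM across cells + 1)."""
    if m.transform != RAW_TPM or m.modality != SINGLE_CELL:
        raise TransformStateError("aggregate_expression expects single-cell raw TPM")
    if m.n_units == 0:
        raise ValidationError("cannot aggregate over zero cells")
    return np.log2(m.values.mean(axis=1) + 1.0)


def filter_genes_sc(
    m: ExpressionMatrix,
    tpm: ExpressionMatrix,
    ea_min: float = 2.0,
    min_detect_frac: float = 0.20,
) -> ExpressionMatrix:
    """Keep genes with aggregate expression strictly above ``ea_min`` and
    detected (TPM > 0) in at least ``min_detect_frac`` of cells.

    ``tpm`` supplies the raw values on the same (QC-passing) cells as ``m``;
    both statistics are computed on that basis.
    """
    if tpm.transform != RAW_TPM:
        raise TransformStateError("gene filtering needs the raw TPM matrix")
    if tpm.gene_ids != m.gene_ids or tpm.unit_ids != m.unit_ids:
        raise ValidationError("log and TPM matrices must align on genes and cells")
    ea = aggregate_expression(tpm)
    detect = (tpm.values > 0).mean(axis=1)
    keep = (ea > ea_min) & (detect >= min_detect_frac)
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return m.subset_genes(genes)


def filter_bulk(
    m: ExpressionMatrix,
    min_genes: int = 2000,
    min_detect_frac: float = 0.20,
) -> ExpressionMatrix:
    """Bulk QC: drop samples expressing fewer than ``min_genes`` genes, then
    keep genes detected in at least ``min_detect_frac`` of remaining samples."""
    if m.transform != BULK_LOG:
        raise TransformStateError("filter_bulk expects a bulk_log matrix")
    expressed = m.values > 0
    keep_samples = expressed.sum(axis=0) >= min_genes
    vals = m.values[:, keep_samples]
    units = [u for u, k in zip(m.unit_ids, keep_samples) if k]
    if not units:
        warnings.warn("all bulk samples removed by QC", stacklevel=2)
        return replace(m, values=vals, unit_ids=units)
    keep_genes = (vals > 0).mean(axis=1) >= min_detect_frac
    genes = [g for g, k in zip(m.gene_ids, keep_genes) if k]
    out = replace(m, values=vals[keep_genes, :], gene_ids=genes, unit_ids=units)
    if not genes:
        warnings.warn("all genes removed by bulk filtering", stacklevel=2)
    return out


def select_tested_genes(sc, bulk, ann, min_terms: int = 2) -> list:
    """Genes detected in both (filtered) profiles and annotated with at
    least ``min_terms`` terms, in lexicographic order."""
    annotated = {
        g for g, n in ann.terms_per_gene().items() if n >= min_terms
    }
    tested = sorted(set(sc.gene_ids) & set(bulk.gene_ids) & annotated)
    if not tested:
        raise ValidationError("no tested genes: empty intersection")
    return tested
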