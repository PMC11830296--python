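"""Co-expression network construction.

Ten network variants are defined by three choices: the association metric
(Pearson, Spearman or mutual information), whether each gene pair is
evaluated over all cells or only over cells where both genes are detected
(the ``_dp`` "dropout" variants), and whether edges are ranked by signed or
absolute association (``_abs``; meaningless for MI, which is non-negative).
Raw associations are then rank-normalized so that edge weights are uniform
on (0, 1] with the strongest association receiving weight 1; a node's degree
is the sum of its incident edge weights.  Integrated networks average the
normalized weights of member networks and re-rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .expression import SC_LOG, ExpressionMatrix, ValidationError

__all__ = [
    "NetworkVariantSpec",
    "CoexpressionNetwork",
    "STANDARD_VARIANTS",
    "INTEGRATION_GROUPS",
    "pairwise_association",
    "rank_normalize",
    "node_degree",
    "build_network",
    "build_all_variants",
    "integrate_networks",
]

_METRICS = ("pearson", "spearman", "mi")


@dataclass(frozen=True)
class NetworkVariantSpec:
    """One of the 10 valid (metric, drop_zeros, absolute) combinations."""

    metric: str = "spearman"
    drop_zeros: bool = False
    absolute: bool = False

    def __post_init__(self):
        if self.metric not in _METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}")
        if self.absolute and self.metric == "mi":
            raise ValidationError("absolute ranking is invalid for MI (non-negative)")

    @property
    def name(self) -> str:
        tag = self.metric if self.metric != "mi" else "MI"
        if self.drop_zeros:
            tag += "_dp"
        if self.absolute:
            tag += "_abs"
        return tag


#: the full set of 10 variants, in canonical order
STANDARD_VARIANTS = tuple(
    NetworkVariantSpec(metric, dp, ab)
    for metric in ("mi", "pearson", "spearman")
    for dp in (False, True)
    for ab in (False, True)
    if not (metric == "mi" and ab)
)

INTEGRATION_GROUPS = {
    "integrated_MI": tuple(v for v in STANDARD_VARIANTS if v.metric == "mi"),
    "integrated_pearson": tuple(v for v in STANDARD_VARIANTS if v.metric == "pearson"),
    "integrated_spearman": tuple(v for v in STANDARD_VARIANTS if v.metric == "spearman"),
    "integrated_all": STANDARD_VARIANTS,
}


@dataclass
class CoexpressionNetwork:
    """Symmetric gene x gene weight matrix in [0, 1] with zero diagonal."""

    weights: np.ndarray
    gene_ids: list
    variant: str = "unspecified"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.gene_ids = list(self.gene_ids)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise ValidationError("weight matrix shape mismatch")
        if not np.allclose(self.weights, self.weights.T, equal_nan=True):
            raise ValidationError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValidationError("diagonal must be zero")
        off = self.weights[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValidationError("weights must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}


# ---------------------------------------------------------------------------
# Raw associations
# ---------------------------------------------------------------------------

def _safe_corr(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; constant rows give NaN, not warnings."""
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c = np.asarray(c, dtype=float)
    bad = sd == 0
    c[bad, :] = np.nan
    c[:, bad] = np.nan
    return np.clip(c, -1.0, 1.0)  # NaN passes through clip unchanged


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization (ties collapse duplicate edges)."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="right")


def _mi_from_bins(bi: np.ndarray, bj: np.ndarray, n_bins: int) -> float:
    """Plug-in mutual information (bits) from two integer bin vectors."""
    n = bi.size
    joint = np.bincount(bi * n_bins + bj, minlength=n_bins * n_bins).astype(float)
    joint = joint.reshape(n_bins, n_bins) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def _mi_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs MI with ceil(sqrt(N)) equal-frequency bins per gene."""
    g, n = values.shape
    n_bins = max(2, math.ceil(math.sqrt(n)))
    bins = np.vstack([_quantile_bins(values[i], n_bins) for i in range(g)])
    out = np.zeros((g, g))
    # one bincount of length g*n_bins^2 per anchor gene
    b2 = n_bins * n_bins
    offsets = np.arange(g)[:, None] * b2
    for i in range(g):
        idx = (offsets + bins[i][None, :] * n_bins + bins).ravel()
        joint = np.bincount(idx, minlength=g * b2).reshape(g, n_bins, n_bins)
        joint = joint.astype(float) / n
        px = joint.sum(axis=2)  # marginals of gene i per partner (identical rows)
        py = joint.sum(axis=1)
        outer = px[:, :, None] * py[:, None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            term = joint * np.log2(joint / outer)
        out[i, :] = np.nansum(term, axis=(1, 2))
    out = (out + out.T) / 2.0  # symmetric up to float noise
    np.fill_diagonal(out, 0.0)
    return out


def pairwise_association(
    m: ExpressionMatrix,
    spec: NetworkVariantSpec,
    min_overlap: int = 10,
) -> np.ndarray:
    """Raw gene x gene association matrix (diagonal NaN, may contain NaN).

    For ``drop_zeros`` variants each pair is computed over the cells where
    both genes are detected (E > 0); pairs with fewer than ``min_overlap``
    co-detected cells are NaN.  Constant vectors give NaN correlations.
    """
    if m.transform != SC_LOG:
        raise ValidationError("networks are built from sc_log matrices")
    if m.n_genes < 2:
        raise ValidationError("need at least 2 genes")
    if m.n_units < 2:
        raise ValidationError("need at least 2 cells")
    x = m.values
    if not spec.drop_zeros:
        if spec.metric == "pearson":
            raw = _safe_corr(x)
        elif spec.metric == "spearman":
            ranks = np.vstack([scipy.stats.rankdata(r) for r in x])
            raw = _safe_corr(ranks)
        else:
            raw = _mi_matrix(x)
    else:
        raw = _dropout_association(x, spec.metric, min_overlap)
    np.fill_diagonal(raw, np.nan)
    return raw


def _dropout_association(x: np.ndarray, metric: str, min_overlap: int) -> np.ndarray:
    g = x.shape[0]
    mask = x > 0
    if metric == "pearson":
        # closed-form masked moments: zeros annihilate, so X*joint_mask = X o M_other
        mt = mask.astype(float)
        n = mt @ mt.T
        sx = x @ mt.T            # sx[i,j] = sum_c x_i[c] * [both detected]
        sxx = (x * x) @ mt.T
        sxy = x @ x.T
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n * sxy - sx * sx.T
            var_i = n * sxx - sx ** 2
            denom = np.sqrt(var_i * var_i.T)
            raw = cov / denom
        raw[n < min_overlap] = np.nan
        raw[denom <= 0] = np.nan
        return np.clip(raw, -1.0, 1.0)
    # spearman/MI on per-pair subsets cannot share ranks/bins; explicit loop
    raw = np.full((g, g), np.nan)
    n_all = x.shape[1]
    for i in range(g):
        for j in range(i + 1, g):
            sel = mask[i] & mask[j]
            k = int(sel.sum())
            if k < max(min_overlap, 2):
                continue
            xi, xj = x[i, sel], x[j, sel]
            if metric == "spearman":
                if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                    continue
                ri = scipy.stats.rankdata(xi)
                rj = scipy.stats.rankdata(xj)
                with np.errstate(invalid="ignore"):
                    v = np.corrcoef(ri, rj)[0, 1]
                if np.isfinite(v):
                    raw[i, j] = raw[j, i] = float(np.clip(v, -1, 1))
            else:  # mi with bins recomputed on the co-detected subset
                nb = max(2, math.ceil(math.sqrt(k)))
                bi = _quantile_bins(xi, nb)
                bj = _quantile_bins(xj, nb)
                raw[i, j] = raw[j, i] = _mi_from_bins(bi, bj, nb)
    return raw


# ---------------------------------------------------------------------------
# Rank normalization, degree, composition
# ---------------------------------------------------------------------------

def rank_normalize(raw: np.ndarray, absolute: bool = False,
                   gene_ids=None, variant: str = "unspecified") -> CoexpressionNetwork:
    """Turn raw associations into edge weights in (0, 1].

    The upper-triangle values (absolute values when ``absolute``) are ranked
    ascending with average ranks on ties and divided by the number of valid
    (non-NaN) pairs, so the strongest association gets weight exactly 1.
    NaN pairs receive the neutral mid-rank weight 0.5.
    """
    raw = np.asarray(raw, dtype=float)
    g = raw.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(g)]
    iu = np.triu_indices(g, k=1)
    vals = raw[iu]
    if absolute:
        vals = np.abs(vals)
    valid = np.isfinite(vals)
    if not valid.any():
        raise ValidationError("all pairwise associations are undefined")
    weights = np.full(vals.shape, 0.5)
    ranks = scipy.stats.rankdata(vals[valid])  # average ranks on ties
    weights[valid] = ranks / valid.sum()
    w = np.zeros((g, g))
    w[iu] = weights
    w = w + w.T
    return CoexpressionNetwork(weights=w, gene_ids=gene_ids, variant=variant)


def node_degree(net: CoexpressionNetwork) -> np.ndarray:
    """degree(i) = sum of weights of all edges incident to gene i."""
    return net.weights.sum(axis=1)


def build_network(
    m: ExpressionMatrix,
    spec: NetworkVariantSpec,
    min_overlap: int = 10,
) -> CoexpressionNetwork:
    """Compose pairwise association and rank normalization."""
    raw = pairwise_association(m, spec, min_overlap=min_overlap)
    return rank_normalize(raw, absolute=spec.absolute,
                          gene_ids=m.gene_ids, variant=spec.name)


def build_all_variants(m: ExpressionMatrix, min_overlap: int = 10) -> dict:
    """All 10 standard variants on the same gene set, keyed by variant name."""
    return {s.name: build_network(m, s, min_overlap=min_overlap)
            for s in STANDARD_VARIANTS}


def integrate_networks(nets, variant: str = None) -> CoexpressionNetwork:
    """Average normalized weights edgewise across networks, then re-rank.

    ``variant`` may name one of the canonical groups (integrated_MI,
    integrated_pearson, integrated_spearman, integrated_all), in which case
    the member variants are checked against the group definition.
    """
    nets = list(nets)
    if len(nets) < 2:
        raise ValidationError("integration needs at least 2 networks")
    genes = nets[0].gene_ids
    for n in nets[1:]:
        if n.gene_ids != genes:
            raise ValidationError("networks must share an identical gene set")
    if variant in INTEGRATION_GROUPS:
        expected = sorted(s.name for s in INTEGRATION_GROUPS[variant])
        got = sorted(n.variant for n in nets)
        if got != expected:
            raise ValidationError(
                f"{variant} requires member variants {expected}, got {got}"
            )
    mean_w = np.mean([n.weights for n in nets], axis=0)
    np.fill_diagonal(mean_w, np.nan)
    name = variant or "integrated:" + "+".join(n.variant for n in nets)
    return rank_normalize(mean_w, absolute=False, gene_ids=genes, variant=name)
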