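"""Gene-term annotations, ontology propagation and information content.

The gold standard for "experimentally validated" function is the set of
gene-term pairs carrying one of the evidence codes EXP, IDA, IMP, IGI, IEP,
TAS or IC, restricted to the Biological Process aspect.  Annotations are
propagated up the ontology (a gene annotated to a term is annotated to every
ancestor reachable through is_a/part_of edges), after which a term's
information content is IC(f) = -log2 Pr(f) with Pr(f) the fraction of
annotated genes carrying f.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ValidationError

__all__ = [
    "AnnotationSet",
    "OntologyDAG",
    "GOLD_EVIDENCE_CODES",
    "load_annotations",
    "load_obo",
    "filter_gold_standard",
    "propagate_to_ancestors",
    "information_content",
    "select_evaluation_terms",
]

GOLD_EVIDENCE_CODES = frozenset({"EXP", "IDA", "IMP", "IGI", "IEP", "TAS", "IC"})

PROPAGATED_RELATIONS = ("is_a", "part_of")


class AnnotationSet:
    """A deduplicated bipartite gene-term incidence with optional evidence.

    Stored as a DataFrame with columns ``gene_id``, ``term_id`` and
    ``evidence`` (None when the source carried no codes).
    """

    def __init__(self, pairs: pd.DataFrame):
        pairs = pairs.copy()
        if "evidence" not in pairs.columns:
            pairs["evidence"] = None
        pairs = pairs[["gene_id", "term_id", "evidence"]].astype(
            {"gene_id": str, "term_id": str}
        )
        pairs = pairs.drop_duplicates(subset=["gene_id", "term_id"])
        self.pairs = pairs.reset_index(drop=True)
        self._terms_for = None
        self._genes_for = None

    @classmethod
    def from_pairs(cls, triples) -> "AnnotationSet":
        """Build from an iterable of (gene, term) or (gene, term, evidence)."""
        rows = []
        for t in triples:
            if len(t) == 2:
                rows.append((t[0], t[1], None))
            else:
                rows.append((t[0], t[1], t[2]))
        return cls(pd.DataFrame(rows, columns=["gene_id", "term_id", "evidence"]))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def gene_universe(self) -> list:
        return sorted(self.pairs["gene_id"].unique())

    @property
    def term_universe(self) -> list:
        return sorted(self.pairs["term_id"].unique())

    def _build_maps(self):
        if self._terms_for is None:
            self._terms_for = {
                g: set(sub) for g, sub in self.pairs.groupby("gene_id")["term_id"]
            }
            self._genes_for = {
                t: set(sub) for t, sub in self.pairs.groupby("term_id")["gene_id"]
            }

    def terms_for(self, gene) -> set:
        self._build_maps()
        return set(self._terms_for.get(gene, set()))

    def genes_for(self, term) -> set:
        self._build_maps()
        return set(self._genes_for.get(term, set()))

    def terms_per_gene(self) -> dict:
        self._build_maps()
        return {g: len(ts) for g, ts in self._terms_for.items()}

    def term_sizes(self) -> pd.Series:
        """Number of annotated genes per term."""
        return self.pairs.groupby("term_id")["gene_id"].nunique()

    def has_evidence(self) -> bool:
        return self.pairs["evidence"].notna().any()

    def to_incidence(self, genes, terms) -> np.ndarray:
        """Boolean gene x term membership matrix on explicit orderings."""
        self._build_maps()
        out = np.zeros((len(genes), len(terms)), dtype=bool)
        tpos = {t: j for j, t in enumerate(terms)}
        for i, g in enumerate(genes):
            for t in self._terms_for.get(g, ()):  # noqa: B909
                j = tpos.get(t)
                if j is not None:
                    out[i, j] = True
        return out

    def write_tsv(self, path):
        self.pairs.to_csv(path, sep="\t", index=False)


@dataclass
class OntologyDAG:
    """A child-to-parent DAG over ontology terms (is_a / part_of edges)."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_edges(cls, edges) -> "OntologyDAG":
        """Build from (child, parent) or (child, parent, relation) tuples."""
        g = nx.DiGraph()
        for e in edges:
            child, parent = e[0], e[1]
            rel = e[2] if len(e) > 2 else "is_a"
            if rel in PROPAGATED_RELATIONS:
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("ontology contains a cycle")
        return cls(graph=g)

    @classmethod
    def from_obonet(cls, multigraph) -> "OntologyDAG":
        """Convert an obonet graph (child->parent MultiDiGraph) keeping only
        is_a and part_of relations."""
        g = nx.DiGraph()
        g.add_nodes_from(multigraph.nodes())
        for u, v, key in multigraph.edges(keys=True):
            if key in PROPAGATED_RELATIONS:
                g.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("ontology contains a cycle")
        return cls(graph=g)

    @property
    def terms(self) -> set:
        return set(self.graph.nodes())

    @property
    def roots(self) -> set:
        return {n for n in self.graph.nodes() if self.graph.out_degree(n) == 0}

    def ancestors(self, term) -> set:
        """All ancestors of ``term`` (excluding itself)."""
        # edges point child -> parent, so ancestors are graph descendants
        return nx.descendants(self.graph, term)


def load_obo(path) -> OntologyDAG:
    """Read an OBO 1.4 ontology file."""
    import obonet

    return OntologyDAG.from_obonet(obonet.read_obo(path))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_annotations(path, format="tsv2col") -> AnnotationSet:
    """Read gene-term annotations.

    ``tsv2col``: tab-separated gene_id / term_id with an optional third
    evidence column (a header line starting with ``gene`` is tolerated).
    ``gaf``: GAF 2.x, filtered to aspect "P" (Biological Process).
    """
    path = Path(path)
    if format == "tsv2col":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if lineno == 1 and fields[0].lower() in ("gene", "gene_id"):
                    continue
                if len(fields) < 2:
                    raise ValidationError(
                        f"{path}:{lineno}: expected >= 2 tab-separated columns"
                    )
                evidence = fields[2] if len(fields) > 2 and fields[2] else None
                rows.append((fields[0], fields[1], evidence))
        if not rows:
            warnings.warn(f"no annotations read from {path}", stacklevel=2)
            return AnnotationSet(
                pd.DataFrame(columns=["gene_id", "term_id", "evidence"])
            )
        return AnnotationSet(
            pd.DataFrame(rows, columns=["gene_id", "term_id", "evidence"])
        )
    if format == "gaf":
        from Bio.UniProt.GOA import gafiterator

        rows = []
        with open(path) as fh:
            try:
                for rec in gafiterator(fh):
                    if rec.get("Aspect") != "P":
                        continue
                    rows.append(
                        (rec["DB_Object_Symbol"] or rec["DB_Object_ID"],
                         rec["GO_ID"],
                         rec["Evidence"] or None)
                    )
            except (KeyError, IndexError) as exc:
                raise ValidationError(f"malformed GAF record in {path}: {exc}") from exc
        if not rows:
            warnings.warn(f"no BP annotations read from {path}", stacklevel=2)
            return AnnotationSet(
                pd.DataFrame(columns=["gene_id", "term_id", "evidence"])
            )
        return AnnotationSet(
            pd.DataFrame(rows, columns=["gene_id", "term_id", "evidence"])
        )
    raise ValidationError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Gold standard, propagation, IC
# ---------------------------------------------------------------------------

def filter_gold_standard(ann: AnnotationSet, codes=GOLD_EVIDENCE_CODES) -> AnnotationSet:
    """Keep pairs with an experimental-grade evidence code.

    Input without evidence codes passes through unchanged with a warning.
    """
    if not ann.has_evidence():
        warnings.warn(
            "annotations carry no evidence codes; gold-standard filter skipped",
            stacklevel=2,
        )
        return AnnotationSet(ann.pairs)
    keep = ann.pairs["evidence"].isin(set(codes))
    return AnnotationSet(ann.pairs[keep])


def propagate_to_ancestors(ann: AnnotationSet, dag: OntologyDAG) -> AnnotationSet:
    """Annotate each gene to every ancestor of its directly annotated terms.

    Idempotent; propagated pairs inherit the evidence code of the source
    pair (first occurrence wins on duplicates).
    """
    unknown = sorted(set(ann.pairs["term_id"]) - dag.terms)
    if unknown:
        raise ValidationError(f"terms absent from ontology: {unknown[:10]}")
    anc_cache = {t: dag.ancestors(t) for t in set(ann.pairs["term_id"])}
    rows = []
    for gene, term, ev in ann.pairs.itertuples(index=False):
        rows.append((gene, term, ev))
        for a in anc_cache[term]:
            rows.append((gene, a, ev))
    return AnnotationSet(pd.DataFrame(rows, columns=["gene_id", "term_id", "evidence"]))


def information_content(ann: AnnotationSet, gene_universe=None) -> pd.Series:
    """IC(f) = log2(1 / Pr(f)) in bits over an (optionally explicit) gene
    universe; terms annotating no universe gene are excluded."""
    if gene_universe is None:
        gene_universe = ann.gene_universe
    universe = set(gene_universe)
    if not universe:
        raise ValidationError("empty gene universe")
    sub = ann.pairs[ann.pairs["gene_id"].isin(universe)]
    counts = sub.groupby("term_id")["gene_id"].nunique()
    pr = counts / float(len(universe))
    ic = -np.log2(pr)
    ic.name = "information_content"
    return ic


def select_evaluation_terms(ann: AnnotationSet, min_genes=20, max_genes=1000) -> list:
    """Terms annotated with between ``min_genes`` and ``max_genes`` genes,
    bounds inclusive, in lexicographic order."""
    sizes = ann.term_sizes()
    keep = sizes[(sizes >= min_genes) & (sizes <= max_genes)]
    return sorted(keep.index)
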