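"""Hypergeometric over-representation analysis against an ontology.

Self-contained engine: OBO parsing (via ``obonet``), true-path propagation
of gene annotations to ancestor terms over ``is_a`` and ``part_of`` edges,
one-sided hypergeometric tests per term, and Benjamini-Hochberg FDR
control.  The choice of background gene universe dominates the outcome of
any over-representation analysis; callers should default to the set of
genes detected in their expression data rather than the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Ontology",
    "AnnotationSet",
    "EnrichmentResult",
    "load_obo",
    "load_associations",
    "propagate",
    "enrich",
    "no_enrichment_check",
]

_PROPAGATING = ("is_a", "part_of")


@dataclass
class Ontology:
    """Term DAG with child -> parent edges restricted to is_a / part_of."""

    graph: nx.DiGraph  # edge u -> v means u is_a/part_of v
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology edge graph contains a cycle: {cycle}")

    def resolve(self, term: str) -> str | None:
        if term in self.graph:
            return term
        return self.alt_ids.get(term)

    def ancestors(self, term: str) -> set[str]:
        t = self.resolve(term)
        if t is None:
            raise KeyError(term)
        return set(nx.descendants(self.graph, t))

    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    @classmethod
    def from_edges(
        cls,
        terms: Iterable[str],
        edges: Iterable[tuple[str, str]],
        names: Mapping[str, str] | None = None,
        namespaces: Mapping[str, str] | None = None,
    ) -> "Ontology":
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from(edges)
        return cls(graph=g, names=dict(names or {}), namespaces=dict(namespaces or {}))


def load_obo(path: str | Path) -> Ontology:
    """Parse an OBO 1.2/1.4 file.

    Keeps ``is_a`` and ``relationship: part_of`` edges, maps ``alt_id`` to
    the primary id, drops obsolete terms from propagation, and counts
    skipped stanzas.  Rejects cyclic edge graphs, listing one cycle.
    """
    import obonet

    full = obonet.read_obo(str(path), ignore_obsolete=True)
    g = nx.DiGraph()
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    alt: dict[str, str] = {}
    for node, data in full.nodes(data=True):
        g.add_node(node)
        names[node] = data.get("name", node)
        namespaces[node] = data.get("namespace", "")
        for a in data.get("alt_id", []):
            alt[a] = node
    for u, v, key in full.edges(keys=True):
        if key in _PROPAGATING and u in g and v in g:
            g.add_edge(u, v)
    onto = Ontology(graph=g, names=names, namespaces=namespaces)
    onto.alt_ids = alt
    return onto


@dataclass
class AnnotationSet:
    """Gene -> term annotations, direct and ancestor-propagated."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    n_dropped: int = 0

    def genes(self) -> list[str]:
        return sorted(self.propagated)


def load_associations(path: str | Path) -> dict[str, set[str]]:
    """Gene -> term ids from GAF 2.x or a two-column gene,term TSV.

    GAF lines use column 3 (symbol) and column 5 (term id); comment lines
    start with ``!``.
    """
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("!") or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 15:  # GAF
            gene, term = parts[2], parts[4]
        elif len(parts) >= 2:
            gene, term = parts[0], parts[1]
        else:
            continue
        if gene.lower() == "gene" and term.lower() == "term":
            continue
        out.setdefault(gene.upper(), set()).add(term)
    return out


def propagate(annotations: Mapping[str, Iterable[str]], ontology: Ontology) -> AnnotationSet:
    """Apply the true-path rule: a gene annotated to a term is annotated to
    every ancestor of that term.  Unresolvable term ids are dropped and
    counted."""
    direct: dict[str, set[str]] = {}
    propagated: dict[str, set[str]] = {}
    dropped = 0
    for gene, terms in annotations.items():
        g = gene.upper()
        for t in terms:
            r = ontology.resolve(t)
            if r is None:
                dropped += 1
                continue
            direct.setdefault(g, set()).add(r)
            propagated.setdefault(g, set()).add(r)
            propagated[g] |= ontology.ancestors(r)
    return AnnotationSet(direct=direct, propagated=propagated, n_dropped=dropped)


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    namespace: str
    k: int  # query genes annotated to the term
    n: int  # query size
    K: int  # background genes annotated to the term
    M: int  # background size
    p_value: float
    q_value: float
    genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "term_id": self.term_id,
            "name": self.name,
            "namespace": self.namespace,
            "k": self.k,
            "n": self.n,
            "K": self.K,
            "M": self.M,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "genes": list(self.genes),
        }


def enrich(
    query: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationSet,
    ontology: Ontology | None = None,
    min_term_size: int = 2,
) -> list[EnrichmentResult]:
    """Rank terms by one-sided hypergeometric over-representation.

    For a term annotated to K of the M background genes, with k of the n
    query genes among them, the upper-tail p-value is

        p = sum_{i=k}^{min(n, K)} C(K, i) C(M-K, n-i) / C(M, n)

    Terms with K < ``min_term_size`` are not tested.  q-values are
    Benjamini-Hochberg step-up over all tested terms jointly; results are
    sorted by p ascending, ties broken by term id.
    """
    q_set = {g.upper() for g in query}
    bg_set = {g.upper() for g in background}
    if not q_set:
        raise ValueError("empty query gene set")
    stray = sorted(q_set - bg_set)
    if stray:
        raise ValueError(f"query genes missing from background: {', '.join(stray)}")

    term_bg: dict[str, set[str]] = {}
    for gene, terms in annotations.propagated.items():
        if gene in bg_set:
            for t in terms:
                term_bg.setdefault(t, set()).add(gene)

    M, n = len(bg_set), len(q_set)
    rows: list[EnrichmentResult] = []
    for term in sorted(term_bg):
        members = term_bg[term]
        K = len(members)
        if K < min_term_size:
            continue
        in_query = sorted(members & q_set)
        k = len(in_query)
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append(
            EnrichmentResult(
                term_id=term,
                name=(ontology.names.get(term, term) if ontology else term),
                namespace=(ontology.namespaces.get(term, "") if ontology else ""),
                k=k,
                n=n,
                K=K,
                M=M,
                p_value=min(p, 1.0),
                q_value=1.0,
                genes=in_query,
            )
        )
    if rows:
        _, qvals, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
        for r, q in zip(rows, qvals):
            r.q_value = float(q)
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def no_enrichment_check(results: Sequence[EnrichmentResult], alpha: float = 0.05) -> bool:
    """True when no term is significant after FDR control (q < alpha)."""
    return all(r.q_value >= alpha for r in results)
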