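"""Cross-space co-occurrence counting and relationship-graph construction.

The canonical edge weight is the integer number of documents in which both
endpoint terms occur; the normalized ``probability`` (weight / corpus size)
is carried alongside.  Graphs are simple, undirected, and strictly
bipartite across the two term-space categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .corpus import RGB, Corpus, TermSpace, match_terms, normalize_term

__all__ = [
    "Association",
    "RelationshipGraph",
    "GraphMetrics",
    "count_cooccurrences",
    "build_relationship_graph",
    "compute_metrics",
    "top_associations",
    "load_edge_table",
    "save_edge_table",
    "write_graphml",
    "read_graphml",
]

logger = logging.getLogger(__name__)

SIGNS = ("positive", "negative", "neutral")


@dataclass(frozen=True)
class Association:
    """One weighted cross-space edge with its supporting documents.

    ``weight`` is the integer document count for corpus-inferred edges; the
    LSA baseline reuses the slot with real-valued cosine strengths.
    """

    term_a: str
    term_b: str
    weight: int | float
    probability: float = 0.0
    doc_ids: tuple[str, ...] = ()
    sign: str | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("association weight must be non-negative")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")
        if self.sign is not None and self.sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}, got {self.sign!r}")


@dataclass
class RelationshipGraph:
    """Weighted bipartite-flavored term graph backed by ``networkx.Graph``.

    Node attributes: ``category`` and ``color``.  Edge attributes:
    ``weight``, ``probability``, ``doc_ids``, ``sign``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    provenance: str = ""

    def add_term(self, term: str, category: str, color: RGB) -> None:
        self.graph.add_node(term, category=category, color=tuple(color))

    def add_association(self, assoc: Association) -> None:
        if assoc.term_a == assoc.term_b:
            raise ValueError(f"self-loop on {assoc.term_a!r} not allowed")
        for t in (assoc.term_a, assoc.term_b):
            if t not in self.graph:
                raise KeyError(f"term {t!r} not added as a node")
        ca = self.graph.nodes[assoc.term_a]["category"]
        cb = self.graph.nodes[assoc.term_b]["category"]
        if ca == cb:
            raise ValueError(
                f"edge {assoc.term_a!r}-{assoc.term_b!r} does not cross term spaces"
            )
        self.graph.add_edge(
            assoc.term_a,
            assoc.term_b,
            weight=assoc.weight,
            probability=assoc.probability,
            doc_ids=assoc.doc_ids,
            sign=assoc.sign,
        )

    def associations(self) -> list[Association]:
        out = []
        for u, v, data in self.graph.edges(data=True):
            # orient so term_a carries the first-seen category ordering
            out.append(
                Association(
                    term_a=u,
                    term_b=v,
                    weight=data["weight"],
                    probability=data.get("probability", 0.0),
                    doc_ids=tuple(data.get("doc_ids", ())),
                    sign=data.get("sign"),
                )
            )
        return out

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "RelationshipGraph":
        return RelationshipGraph(graph=self.graph.copy(), provenance=self.provenance)


@dataclass(frozen=True)
class GraphMetrics:
    node_count: int
    edge_count: int
    avg_node_degree: float
    avg_edge_weight: float


def count_cooccurrences(
    corpus: Corpus, space_a: TermSpace, space_b: TermSpace
) -> list[Association]:
    """Count, per cross-space pair, the documents matching both terms.

    Returns one :class:`Association` per pair with at least one supporting
    document; ``doc_ids`` sorted, ``probability = weight / |corpus|``.
    An empty corpus yields an empty list.
    """
    overlap = set(space_a.terms) & set(space_b.terms)
    if overlap:
        raise ValueError(f"term spaces are not disjoint: {sorted(overlap)}")
    support: dict[tuple[str, str], list[str]] = {}
    for doc in corpus:
        matched_a = match_terms(doc, space_a)
        if not matched_a:
            continue
        matched_b = match_terms(doc, space_b)
        for a in matched_a:
            for b in matched_b:
                support.setdefault((a, b), []).append(doc.id)
    n = corpus.size
    return [
        Association(
            term_a=a,
            term_b=b,
            weight=len(ids),
            probability=len(ids) / n,
            doc_ids=tuple(sorted(ids)),
        )
        for (a, b), ids in sorted(support.items())
    ]


def build_relationship_graph(
    associations: Iterable[Association],
    space_a: TermSpace,
    space_b: TermSpace,
    min_weight: int = 0,
    provenance: str = "",
) -> RelationshipGraph:
    """Keep associations with weight strictly greater than ``min_weight``.

    Endpoint nodes are added with their space's category and color; isolated
    nodes (terms with no surviving edge) are not included.
    """
    if min_weight < 0:
        raise ValueError("min_weight must be non-negative")
    g = RelationshipGraph(provenance=provenance)
    a_terms = set(space_a.terms)
    b_terms = set(space_b.terms)
    for assoc in associations:
        if assoc.weight <= min_weight:
            continue
        if assoc.term_a in a_terms and assoc.term_b in b_terms:
            pass
        elif assoc.term_a in b_terms and assoc.term_b in a_terms:
            assoc = replace(assoc, term_a=assoc.term_b, term_b=assoc.term_a)
        else:
            raise ValueError(
                f"association ({assoc.term_a!r}, {assoc.term_b!r}) not covered "
                "by the two term spaces"
            )
        g.add_term(assoc.term_a, space_a.category, space_a.color)
        g.add_term(assoc.term_b, space_b.category, space_b.color)
        g.add_association(assoc)
    return g


def compute_metrics(graph: RelationshipGraph) -> GraphMetrics:
    """Average node degree and average edge weight of a non-empty graph."""
    n, m = graph.node_count, graph.edge_count
    if n == 0 or m == 0:
        raise ValueError("empty graph")
    weights = [d["weight"] for _, _, d in graph.graph.edges(data=True)]
    return GraphMetrics(
        node_count=n,
        edge_count=m,
        avg_node_degree=2.0 * m / n,
        avg_edge_weight=sum(weights) / m,
    )


def _rank_key(assoc: Association):
    return (-assoc.weight, assoc.term_b, assoc.term_a)


def top_associations(graph: RelationshipGraph, k: int) -> list[Association]:
    """The ``k`` heaviest edges, weight descending, ties lexicographic by
    (term_b, term_a).  Returns fewer than ``k`` if the graph is smaller."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sorted(graph.associations(), key=_rank_key)[:k]


def _parse_sign(token: str) -> str | None:
    token = token.strip().strip("()").lower()
    if not token:
        return None
    if token not in SIGNS:
        raise ValueError(f"unknown sign label {token!r}")
    return token


def load_edge_table(
    path: str | Path,
    space_a: TermSpace,
    space_b: TermSpace,
    strict: bool = False,
) -> RelationshipGraph:
    """Load a TSV edge table with rows ``term_b  term_a  weight  [sign]``.

    The first column belongs to space B (conditions), the second to space A
    (foods), mirroring the printed-table layout.  Unknown terms are skipped
    with a warning, or raise when ``strict`` is true.  Loaded edges have no
    supporting document ids.
    """
    path = Path(path)
    a_terms = set(space_a.terms)
    b_terms = set(space_b.terms)
    g = RelationshipGraph(provenance=str(path))
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        term_b = normalize_term(parts[0])
        term_a = normalize_term(parts[1])
        weight_field = parts[2].strip()
        sign: str | None = None
        # tolerate the printed style "2098 (positive)" in the weight column
        if "(" in weight_field:
            weight_str, _, rest = weight_field.partition("(")
            sign = _parse_sign(rest)
            weight_field = weight_str.strip()
        if len(parts) >= 4:
            sign = _parse_sign(parts[3])
        try:
            weight = int(weight_field)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
        if term_a not in a_terms or term_b not in b_terms:
            msg = f"{path}:{lineno}: unknown term pair ({term_b!r}, {term_a!r})"
            if strict:
                raise ValueError(msg)
            logger.warning("%s — skipped", msg)
            continue
        g.add_term(term_a, space_a.category, space_a.color)
        g.add_term(term_b, space_b.category, space_b.color)
        g.add_association(Association(term_a=term_a, term_b=term_b, weight=weight, sign=sign))
    return g


def save_edge_table(graph: RelationshipGraph, path: str | Path) -> None:
    """Write edges as TSV ``term_b  term_a  weight  sign`` sorted by rank."""
    lines = []
    for assoc in sorted(graph.associations(), key=_rank_key):
        lines.append(
            "\t".join(
                [assoc.term_b, assoc.term_a, str(assoc.weight), assoc.sign or ""]
            ).rstrip("\t")
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_graphml(graph: RelationshipGraph, path: str | Path) -> None:
    """GraphML export; tuple attributes flattened to comma-joined strings."""
    g = nx.Graph()
    for node, data in graph.graph.nodes(data=True):
        color = data.get("color", (0, 0, 0))
        g.add_node(
            node,
            category=data.get("category", ""),
            color=",".join(str(c) for c in color),
        )
    for u, v, data in graph.graph.edges(data=True):
        g.add_edge(
            u,
            v,
            weight=int(data["weight"]),
            probability=float(data.get("probability", 0.0)),
            sign=data.get("sign") or "",
            doc_ids=",".join(data.get("doc_ids", ())),
        )
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path, provenance: str | None = None) -> RelationshipGraph:
    raw = nx.read_graphml(str(path))
    g = RelationshipGraph(provenance=provenance or str(path))
    for node, data in raw.nodes(data=True):
        color_str = data.get("color", "0,0,0")
        color = tuple(int(c) for c in str(color_str).split(","))
        g.graph.add_node(str(node), category=data.get("category", ""), color=color)
    for u, v, data in raw.edges(data=True):
        doc_ids = tuple(i for i in str(data.get("doc_ids", "")).split(",") if i)
        sign = data.get("sign") or None
        g.graph.add_edge(
            str(u),
            str(v),
            weight=int(data.get("weight", 0)),
            probability=float(data.get("probability", 0.0)),
            doc_ids=doc_ids,
            sign=sign,
        )
    return g
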