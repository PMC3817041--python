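"""Query-centered graph-of-interest extraction and profile personalization.

A GOI is the induced subgraph within a hop radius of a query term.
Personalization intersects the GOI with a user-profile graph: surviving
nodes are those in both, surviving edges those whose endpoint pair appears
in both (undirected), keeping the GOI's weights and document lists.
"""

from __future__ import annotations

import difflib
import random
from dataclasses import dataclass, field

import networkx as nx

from .corpus import normalize_term
from .graph_inference import RelationshipGraph

__all__ = [
    "GOI",
    "UserProfile",
    "extract_goi",
    "personalize",
    "overlap_fraction",
    "load_profile",
    "save_profile",
    "make_worked_example",
]


@dataclass
class GOI:
    """A query-centered subgraph of a relationship graph."""

    center: str
    subgraph: RelationshipGraph
    radius: int
    center_dropped: bool = False

    @property
    def node_count(self) -> int:
        return self.subgraph.node_count

    @property
    def edge_count(self) -> int:
        return self.subgraph.edge_count


@dataclass
class UserProfile:
    """A user's interest graph; only topology matters for intersection."""

    id: str
    graph: nx.Graph = field(default_factory=nx.Graph)


def extract_goi(graph: RelationshipGraph, query: str, radius: int = 1) -> GOI:
    """Induced subgraph on all nodes within ``radius`` hops of ``query``.

    Radius 0 yields the single query node with no edges.  An unknown query
    raises ``KeyError`` listing the nearest lexical matches.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    center = normalize_term(query)
    if center not in graph.graph:
        near = difflib.get_close_matches(center, list(graph.graph.nodes), n=3)
        hint = f"; nearest matches: {', '.join(near)}" if near else ""
        raise KeyError(f"query term {query!r} not in graph{hint}")
    lengths = nx.single_source_shortest_path_length(graph.graph, center, cutoff=radius)
    sub = graph.graph.subgraph(lengths).copy()
    return GOI(
        center=center,
        subgraph=RelationshipGraph(graph=sub, provenance=graph.provenance),
        radius=radius,
    )


def personalize(goi: GOI, profile: UserProfile) -> GOI:
    """Intersection of the GOI with a profile graph.

    Node set is the intersection of node sets; an edge survives iff its
    endpoint pair is an edge of both graphs.  GOI edge attributes (weight,
    probability, doc_ids, sign) are retained.  If the center itself is not
    in the profile the result is flagged ``center_dropped``.
    """
    g, p = goi.subgraph.graph, profile.graph
    common_nodes = set(g.nodes) & set(p.nodes)
    out = nx.Graph()
    for node in common_nodes:
        out.add_node(node, **g.nodes[node])
    for u, v, data in g.edges(data=True):
        if u in common_nodes and v in common_nodes and p.has_edge(u, v):
            out.add_edge(u, v, **data)
    return GOI(
        center=goi.center,
        subgraph=RelationshipGraph(graph=out, provenance=goi.subgraph.provenance),
        radius=goi.radius,
        center_dropped=goi.center not in common_nodes,
    )


def overlap_fraction(goi: GOI, personalized: GOI) -> float:
    """Personalized edge count over GOI edge count, as a percentage rounded
    to one decimal.  Raises on an edgeless GOI."""
    m = goi.edge_count
    if m == 0:
        raise ValueError("GOI has no edges; overlap undefined")
    return round(100.0 * personalized.edge_count / m, 1)


def load_profile(path, profile_id: str | None = None) -> UserProfile:
    g = nx.read_graphml(str(path))
    clean = nx.Graph()
    clean.add_nodes_from(str(n) for n in g.nodes)
    clean.add_edges_from((str(u), str(v)) for u, v in g.edges)
    return UserProfile(id=profile_id or str(path), graph=clean)


def save_profile(profile: UserProfile, path) -> None:
    nx.write_graphml(profile.graph, str(path))


def make_worked_example(seed: int = 7) -> tuple[GOI, UserProfile]:
    """Seeded fixture reproducing the published personalization example.

    Builds a star GOI of 74 nodes / 73 edges centered on ``palpitations``
    and a 50-node / 96-edge profile sharing the center, 48 of the leaves
    and the 48 corresponding star edges, so that intersection yields
    49 nodes / 48 edges (overlap 48/73 = 65.8%).
    """
    rng = random.Random(seed)
    center = "palpitations"
    leaves = [f"food{idx:02d}" for idx in range(73)]

    g = nx.Graph()
    g.add_node(center, category="condition", color=(255, 0, 0))
    weights = rng.sample(range(51, 2500), len(leaves))
    for leaf, w in zip(leaves, weights):
        g.add_node(leaf, category="food", color=(0, 255, 0))
        g.add_edge(center, leaf, weight=w, probability=0.0, doc_ids=(), sign=None)
    goi = GOI(center=center, subgraph=RelationshipGraph(graph=g, provenance="fixture"), radius=1)

    shared_leaves = rng.sample(leaves, 48)
    extra_node = "profile-only-interest"
    p = nx.Graph()
    p.add_node(center)
    p.add_nodes_from(shared_leaves)
    p.add_node(extra_node)
    for leaf in shared_leaves:  # the 48 star edges present in both graphs
        p.add_edge(center, leaf)
    # 48 further profile edges that are NOT GOI edges: leaf-leaf and
    # extra-node links (the GOI star has no such edges)
    candidates = [
        (shared_leaves[i], shared_leaves[j])
        for i in range(len(shared_leaves))
        for j in range(i + 1, len(shared_leaves))
    ]
    rng.shuffle(candidates)
    added = 0
    for u, v in candidates:
        if added == 40:
            break
        p.add_edge(u, v)
        added += 1
    for leaf in shared_leaves[:8]:
        p.add_edge(extra_node, leaf)
    assert p.number_of_nodes() == 50 and p.number_of_edges() == 96
    return goi, UserProfile(id=f"user-seed{seed}", graph=p)
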