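"""Result-processing pipeline: coarsening, layout, screen filtering, XML.

Coarsening groups the full graph (level 0) into supernodes whose
aggregated superedge weights conserve total cross-group weight.  Layout is
a seeded force-directed embedding followed by a separation pass that
enforces a minimum inter-node pixel distance (touch-target sized).  The
view filter keeps the query center plus the heaviest-attached neighbors up
to the screen budget.  The XML stream round-trips graph + layout exactly.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import networkx as nx

from .corpus import RGB
from .graph_inference import RelationshipGraph

__all__ = [
    "ViewSpec",
    "AbstractGraph",
    "LayoutGraph",
    "abstract_graph",
    "layout_graph",
    "filter_view",
    "mix_color",
    "serialize_xml",
    "parse_xml",
    "validate_xml",
]

GROUPING_POLICIES = ("category", "density", "singleton")
DEFAULT_SEED = 7
DEFAULT_TOUCH_TARGET = 96


@dataclass(frozen=True)
class ViewSpec:
    """Screen constraints: pixel size and minimum clickable target size."""

    width: int
    height: int
    touch_target: int = DEFAULT_TOUCH_TARGET
    center: str | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.touch_target <= 0:
            raise ValueError("width, height and touch_target must be positive")

    @property
    def budget(self) -> int:
        """Maximum displayable node count: whole touch targets per axis."""
        return (self.width // self.touch_target) * (self.height // self.touch_target)


@dataclass
class AbstractGraph:
    """Coarsened graph: supernode groups plus aggregated superedges."""

    supernodes: dict[str, tuple[str, ...]]  # group id -> member node labels
    representatives: dict[str, str]  # group id -> representative member
    superedges: dict[tuple[str, str], int]  # (group, group) sorted -> weight
    level: int = 1

    def total_weight(self) -> int:
        return sum(self.superedges.values())

    def to_graph(self) -> RelationshipGraph:
        """Render supernodes as plain nodes labeled by representative."""
        g = nx.Graph()
        for gid, members in self.supernodes.items():
            g.add_node(gid, category="group", color=(128, 128, 128),
                       label=self.representatives[gid], size=len(members))
        for (ga, gb), w in self.superedges.items():
            g.add_edge(ga, gb, weight=w, probability=0.0, doc_ids=(), sign=None)
        return RelationshipGraph(graph=g, provenance=f"abstract-level-{self.level}")


@dataclass
class LayoutGraph:
    """Node positions in the unit square, with the seed that produced them."""

    positions: dict[str, tuple[float, float]]
    seed: int
    min_separation_px: float = 0.0


def abstract_graph(g1: RelationshipGraph, policy: str = "category") -> AbstractGraph:
    """Partition nodes per ``policy`` and aggregate cross-group weights.

    Policies: ``category`` (group by term-space category, the default),
    ``density`` (greedy modularity communities), ``singleton`` (identity
    partition).  Representative label of a group is its highest-degree
    member, ties broken lexicographically.
    """
    if g1.node_count == 0:
        raise ValueError("cannot abstract an empty graph")
    g = g1.graph
    if policy == "category":
        groups: dict[str, list[str]] = {}
        for node, data in g.nodes(data=True):
            groups.setdefault(str(data.get("category", "uncategorized")), []).append(node)
        partition = {f"cat:{k}": sorted(v) for k, v in sorted(groups.items())}
    elif policy == "density":
        communities = nx.community.greedy_modularity_communities(g, weight="weight")
        partition = {
            f"com:{i}": sorted(c) for i, c in enumerate(sorted(communities, key=sorted))
        }
    elif policy == "singleton":
        partition = {f"n:{node}": [node] for node in sorted(g.nodes)}
    else:
        raise ValueError(f"unknown grouping policy {policy!r}; choose from {GROUPING_POLICIES}")

    node_to_group = {n: gid for gid, members in partition.items() for n in members}
    reps = {
        gid: max(members, key=lambda n: (g.degree(n), n))
        for gid, members in partition.items()
    }
    superedges: dict[tuple[str, str], int] = {}
    for u, v, data in g.edges(data=True):
        gu, gv = node_to_group[u], node_to_group[v]
        if gu == gv:
            continue
        key = (gu, gv) if gu < gv else (gv, gu)
        superedges[key] = superedges.get(key, 0) + int(data.get("weight", 0))
    return AbstractGraph(
        supernodes={gid: tuple(m) for gid, m in partition.items()},
        representatives=reps,
        superedges=superedges,
        level=1,
    )


def _as_nx(graph) -> nx.Graph:
    return graph.graph if isinstance(graph, RelationshipGraph) else graph


def layout_graph(graph, view: ViewSpec, seed: int = DEFAULT_SEED) -> LayoutGraph:
    """Seed-deterministic spring layout plus a minimum-separation pass.

    Positions are normalized to [0, 1]^2.  Separation is enforced in pixel
    space: after scaling by the view size, every node pair is at least one
    touch target apart.  When the iterative push-apart pass cannot achieve
    this and the node count fits the view budget, nodes fall back to a
    deterministic grid of touch-target cells (which satisfies the bound by
    construction).
    """
    g = _as_nx(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty graph")
    order = sorted(g.nodes)
    pos = nx.spring_layout(g, seed=seed, weight="weight")
    pts = {n: [float(pos[n][0]), float(pos[n][1])] for n in order}
    _normalize_unit(pts)

    w, h, t = float(view.width), float(view.height), float(view.touch_target)

    def min_pair_dist() -> float:
        best = math.inf
        for i, a in enumerate(order):
            xa, ya = pts[a][0] * w, pts[a][1] * h
            for b in order[i + 1 :]:
                xb, yb = pts[b][0] * w, pts[b][1] * h
                best = min(best, math.hypot(xa - xb, ya - yb))
        return best

    for _ in range(300):
        if len(order) == 1 or min_pair_dist() >= t:
            break
        for i, a in enumerate(order):
            for b in order[i + 1 :]:
                ax, ay = pts[a][0] * w, pts[a][1] * h
                bx, by = pts[b][0] * w, pts[b][1] * h
                dx, dy = bx - ax, by - ay
                d = math.hypot(dx, dy)
                if d >= t:
                    continue
                if d < 1e-9:
                    # deterministic tie-break direction from node order
                    dx, dy, d = 1.0, 0.0, 1.0
                push = (t - d) / 2.0 + 0.5
                ux, uy = dx / d, dy / d
                pts[a][0] = (ax - ux * push) / w
                pts[a][1] = (ay - uy * push) / h
                pts[b][0] = (bx + ux * push) / w
                pts[b][1] = (by + uy * push) / h
        _clamp_unit(pts)

    if len(order) > 1 and min_pair_dist() < t and len(order) <= view.budget:
        cols = int(w // t)
        for idx, n in enumerate(order):
            r, c = divmod(idx, cols)
            pts[n][0] = ((c + 0.5) * t) / w
            pts[n][1] = ((r + 0.5) * t) / h

    achieved = 0.0 if len(order) == 1 else min_pair_dist()
    return LayoutGraph(
        positions={n: (pts[n][0], pts[n][1]) for n in order},
        seed=seed,
        min_separation_px=achieved,
    )


def _normalize_unit(pts: dict[str, list[float]]) -> None:
    xs = [p[0] for p in pts.values()]
    ys = [p[1] for p in pts.values()]
    span_x = max(xs) - min(xs) or 1.0
    span_y = max(ys) - min(ys) or 1.0
    for p in pts.values():
        p[0] = (p[0] - min(xs)) / span_x
        p[1] = (p[1] - min(ys)) / span_y


def _clamp_unit(pts: dict[str, list[float]]) -> None:
    for p in pts.values():
        p[0] = min(1.0, max(0.0, p[0]))
        p[1] = min(1.0, max(0.0, p[1]))


def filter_view(graph: RelationshipGraph, view: ViewSpec) -> RelationshipGraph:
    """Trim a graph to the screen budget around the view center.

    Grows greedily from the center, always admitting the candidate with the
    heaviest edge into the retained set, until ``view.budget`` nodes are
    kept; returns the induced subgraph.  The center is always retained.
    """
    if view.center is None:
        raise ValueError("view has no center term")
    g = graph.graph
    if view.center not in g:
        raise KeyError(f"center {view.center!r} not in graph")
    budget = view.budget
    if budget >= g.number_of_nodes():
        return graph.copy()
    retained = {view.center}
    # best known edge weight from each frontier node into the retained set
    best: dict[str, int] = {}
    for nbr in g.neighbors(view.center):
        best[nbr] = int(g[view.center][nbr].get("weight", 0))
    while len(retained) < budget and best:
        pick = max(best, key=lambda n: (best[n], n))
        del best[pick]
        retained.add(pick)
        for nbr in g.neighbors(pick):
            if nbr in retained:
                continue
            w = int(g[pick][nbr].get("weight", 0))
            if w > best.get(nbr, -1):
                best[nbr] = w
    sub = g.subgraph(retained).copy()
    return RelationshipGraph(graph=sub, provenance=graph.provenance)


def mix_color(a: RGB, b: RGB) -> RGB:
    """Channel-wise floor mean of two RGB triples."""
    for c in (*a, *b):
        if not (0 <= int(c) <= 255):
            raise ValueError("RGB channel out of range [0, 255]")
    return tuple((int(x) + int(y)) // 2 for x, y in zip(a, b))  # type: ignore[return-value]


def _color_str(color) -> str:
    return ",".join(str(int(c)) for c in color)


def _parse_color(s: str) -> RGB:
    parts = tuple(int(c) for c in s.split(","))
    if len(parts) != 3:
        raise ValueError(f"bad colour attribute {s!r}")
    return parts  # type: ignore[return-value]


def serialize_xml(
    graph: RelationshipGraph,
    layout: LayoutGraph,
    level: int = 0,
    centre: str | None = None,
) -> str:
    """Serialize graph + layout to the GOI XML stream.

    Root ``<goi level centre>``; one ``<node>`` per node with id, label,
    category, colour and unit-square position; one ``<edge>`` per edge with
    weight, sign, mixed colour, and the supporting document ids/urls as
    ``<url>`` children.  Positions use ``repr`` floats so the round trip is
    bit-exact.
    """
    g = graph.graph
    missing = [n for n in g.nodes if n not in layout.positions]
    if missing:
        raise ValueError(f"layout missing positions for nodes: {sorted(missing)[:5]}")
    root = ET.Element("goi", level=str(level), centre=centre or "")
    for node in sorted(g.nodes):
        data = g.nodes[node]
        x, y = layout.positions[node]
        ET.SubElement(
            root,
            "node",
            id=node,
            label=str(data.get("label", node)),
            category=str(data.get("category", "")),
            colour=_color_str(data.get("color", (0, 0, 0))),
            x=repr(float(x)),
            y=repr(float(y)),
        )
    for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges)):
        data = g[u][v]
        cu = g.nodes[u].get("color", (0, 0, 0))
        cv = g.nodes[v].get("color", (0, 0, 0))
        edge = ET.SubElement(
            root,
            "edge",
            source=u,
            target=v,
            weight=str(int(data.get("weight", 0))),
            sign=str(data.get("sign") or ""),
            colour=_color_str(mix_color(cu, cv)),
        )
        for doc_id in data.get("doc_ids", ()):
            url_el = ET.SubElement(edge, "url")
            url_el.text = doc_id
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def parse_xml(doc: str) -> tuple[RelationshipGraph, LayoutGraph, int, str]:
    """Inverse of :func:`serialize_xml`.

    Returns ``(graph, layout, level, centre)``.  Malformed documents raise
    ``ValueError`` naming the offending element or parse position.
    """
    try:
        root = ET.fromstring(doc)
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML: {exc}") from exc
    if root.tag != "goi":
        raise ValueError(f"expected root element 'goi', got {root.tag!r}")
    level = int(root.get("level", "0"))
    centre = root.get("centre", "")
    g = nx.Graph()
    positions: dict[str, tuple[float, float]] = {}
    for i, el in enumerate(root):
        if el.tag == "node":
            node_id = el.get("id")
            if node_id is None or el.get("x") is None or el.get("y") is None:
                raise ValueError(f"node element #{i} missing id/x/y attributes")
            g.add_node(
                node_id,
                category=el.get("category", ""),
                color=_parse_color(el.get("colour", "0,0,0")),
                label=el.get("label", node_id),
            )
            positions[node_id] = (float(el.get("x")), float(el.get("y")))
        elif el.tag == "edge":
            u, v = el.get("source"), el.get("target")
            if u is None or v is None:
                raise ValueError(f"edge element #{i} missing source/target")
            if u not in g or v not in g:
                raise ValueError(f"edge element #{i} references unknown node")
            doc_ids = tuple(url.text or "" for url in el.findall("url"))
            g.add_edge(
                u,
                v,
                weight=int(el.get("weight", "0")),
                probability=0.0,
                doc_ids=doc_ids,
                sign=el.get("sign") or None,
            )
        else:
            raise ValueError(f"unexpected element <{el.tag}> at position {i}")
    graph = RelationshipGraph(graph=g, provenance="xml-stream")
    return graph, LayoutGraph(positions=positions, seed=-1), level, centre


_REQUIRED_NODE_ATTRS = ("id", "label", "category", "colour", "x", "y")
_REQUIRED_EDGE_ATTRS = ("source", "target", "weight", "sign", "colour")


def validate_xml(doc: str) -> None:
    """Structural validation against the stream schema (see data/goi.xsd).

    Stdlib ElementTree cannot run XSD validation, so the same constraints
    are checked programmatically; raises ``ValueError`` on violation.
    """
    try:
        root = ET.fromstring(doc)
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML: {exc}") from exc
    if root.tag != "goi" or root.get("level") is None or root.get("centre") is None:
        raise ValueError("root must be <goi> with 'level' and 'centre' attributes")
    for el in root:
        if el.tag == "node":
            for attr in _REQUIRED_NODE_ATTRS:
                if el.get(attr) is None:
                    raise ValueError(f"<node> missing required attribute {attr!r}")
            _parse_color(el.get("colour"))
            for coord in ("x", "y"):
                val = float(el.get(coord))
                if not (0.0 <= val <= 1.0):
                    raise ValueError(f"<node> {coord} out of unit range: {val}")
        elif el.tag == "edge":
            for attr in _REQUIRED_EDGE_ATTRS:
                if el.get(attr) is None:
                    raise ValueError(f"<edge> missing required attribute {attr!r}")
            int(el.get("weight"))
            for child in el:
                if child.tag != "url":
                    raise ValueError(f"<edge> may only contain <url> children, got <{child.tag}>")
        else:
            raise ValueError(f"unexpected element <{el.tag}> under <goi>")
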