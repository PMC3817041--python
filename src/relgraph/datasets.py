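"""Accessors for the small text fixtures shipped with the package."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .corpus import TermSpace, load_term_space
from .graph_inference import RelationshipGraph, load_edge_table

__all__ = [
    "data_path",
    "obesity_condition_space",
    "obesity_food_space",
    "cardio_condition_space",
    "cardio_food_space",
    "obesity_edge_graph",
    "cardio_edge_graph",
]

GREEN = (0, 170, 0)
RED = (200, 0, 0)


def data_path(name: str) -> Path:
    with resources.as_file(resources.files("relgraph").joinpath("data", name)) as p:
        return Path(p)


def obesity_condition_space() -> TermSpace:
    return load_term_space(
        data_path("table3_condition_terms.txt"), "obesity-conditions", "condition", RED
    )


def obesity_food_space() -> TermSpace:
    return load_term_space(data_path("table3_food_terms.txt"), "obesity-foods", "food", GREEN)


def cardio_condition_space() -> TermSpace:
    return load_term_space(
        data_path("table4_condition_terms.txt"), "cardio-conditions", "condition", RED
    )


def cardio_food_space() -> TermSpace:
    return load_term_space(data_path("table4_food_terms.txt"), "cardio-foods", "food", GREEN)


def obesity_edge_graph() -> RelationshipGraph:
    """The ten strongest published food-obesity associations."""
    return load_edge_table(
        data_path("table3_edges.tsv"),
        obesity_food_space(),
        obesity_condition_space(),
        strict=True,
    )


def cardio_edge_graph() -> RelationshipGraph:
    """The ten strongest published food-cardiovascular associations."""
    return load_edge_table(
        data_path("table4_edges.tsv"),
        cardio_food_space(),
        cardio_condition_space(),
        strict=True,
    )
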