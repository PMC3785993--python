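"""Similarity treemaps.

The formalized result of a frailty assessment is a small tree rooted at
the studied instance: its children are the most similar instances in
the patient stack, and each child in turn carries the instances most
similar *to it* among those not yet placed.  Depth and branching are
capped (three levels, three children per node by default) because
deeper levels carry ever lower similarity to the studied patient and
stop being clinically readable.

Every node records four attributes — parent instance id, instance id,
patient age and the similarity coefficient to its parent (1 for the
root) — and the tree is rendered as nested rectangles whose areas,
within a sibling set, are proportional to the similarity coefficients
(slice-and-dice layout, alternating split direction per level).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FrailtyMapError
from .patient import PatientStack, WeightProfile
from .similarity import PairSimilarity, SimilarityConfig, quantitative_ranges, rank_neighbors


@dataclass(frozen=True)
class TreemapConfig:
    """Structural limits and candidate-exclusion policy.

    ``exclusion_policy``: with ``placed_nodes`` (default) a child list
    may not reuse any instance already placed anywhere in the tree;
    ``path_only`` only forbids the node's own ancestors.
    ``same_patient_rule = "exclude"`` removes the root patient's other
    instances from all candidate lists.
    """

    max_depth: int = 3
    max_children: int = 3
    exclusion_policy: str = "placed_nodes"
    same_patient_rule: str = "allow"

    def __post_init__(self) -> None:
        if self.max_depth < 1 or self.max_children < 1:
            raise ValueError("max_depth and max_children must be >= 1")
        if self.exclusion_policy not in ("placed_nodes", "path_only"):
            raise ValueError("unknown exclusion_policy")
        if self.same_patient_rule not in ("allow", "exclude"):
            raise ValueError("unknown same_patient_rule")


@dataclass
class TreemapNode:
    """One treemap node: the four formalized attributes plus children."""

    parent_instance_id: int | None
    instance_id: int
    age: float
    similarity_coefficient: float
    children: list["TreemapNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def depth(self) -> int:
        if not self.children:
            return 1
        return 1 + max(child.depth() for child in self.children)


def build_treemap_detailed(root_instance: int, stack: PatientStack,
                           weights: WeightProfile,
                           sim_config: SimilarityConfig = SimilarityConfig(),
                           tm_config: TreemapConfig = TreemapConfig(),
                           ) -> tuple[TreemapNode, list[tuple[int, list[PairSimilarity]]]]:
    """Build the treemap and also return every ranked list computed.

    Placement is breadth-first: the root's list is ranked first, then
    each level is expanded left to right, each node ranking candidates
    against *itself* (not the root) among the instances not excluded by
    the policy.  Returns ``(root_node, ranked_lists)`` where each entry
    of ``ranked_lists`` is ``(ranking_node_instance_id, ranked list)``.
    """
    root_inst = stack.get(root_instance)  # raises InstanceLookupError
    ranges = quantitative_ranges(stack)

    always_excluded: set[int] = set()
    if tm_config.same_patient_rule == "exclude":
        always_excluded = {inst.instance_id for inst in stack.instances
                           if inst.patient_id == root_inst.patient_id
                           and inst.instance_id != root_instance}

    root = TreemapNode(parent_instance_id=None, instance_id=root_instance,
                       age=root_inst.age, similarity_coefficient=1.0)
    placed: set[int] = {root_instance}
    ranked_lists: list[tuple[int, list[PairSimilarity]]] = []

    # breadth-first frontier of (node, ancestors-on-path) at the current level
    frontier: list[tuple[TreemapNode, set[int]]] = [(root, {root_instance})]
    for _level in range(1, tm_config.max_depth):
        next_frontier: list[tuple[TreemapNode, set[int]]] = []
        for node, path in frontier:
            if tm_config.exclusion_policy == "placed_nodes":
                exclude = placed | always_excluded
            else:
                exclude = path | always_excluded
            ranked = rank_neighbors(node.instance_id, stack, weights,
                                    sim_config, exclude=frozenset(exclude),
                                    ranges=ranges)
            ranked_lists.append((node.instance_id, ranked))
            for pair in ranked[:tm_config.max_children]:
                child_inst = stack.get(pair.j)
                child = TreemapNode(parent_instance_id=node.instance_id,
                                    instance_id=pair.j, age=child_inst.age,
                                    similarity_coefficient=pair.coefficient)
                node.children.append(child)
                placed.add(pair.j)
                next_frontier.append((child, path | {pair.j}))
        frontier = next_frontier
    return root, ranked_lists


def build_treemap(root_instance: int, stack: PatientStack,
                  weights: WeightProfile,
                  sim_config: SimilarityConfig = SimilarityConfig(),
                  tm_config: TreemapConfig = TreemapConfig()) -> TreemapNode:
    """Build the similarity treemap for a studied instance."""
    return build_treemap_detailed(root_instance, stack, weights, sim_config,
                                  tm_config)[0]


# ---------------------------------------------------------------------------
# JSON serialization


def _node_to_dict(node: TreemapNode) -> dict:
    return {
        "parent_instance_id": node.parent_instance_id,
        "instance_id": node.instance_id,
        "age": node.age,
        "similarity_coefficient": node.similarity_coefficient,
        "children": [_node_to_dict(c) for c in node.children],
    }


def export_treemap_json(tree: TreemapNode, path: str | Path | None = None) -> str:
    """Lossless nested JSON of the four node attributes plus children."""
    text = json.dumps(_node_to_dict(tree), indent=1)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def _node_from_dict(data: dict) -> TreemapNode:
    return TreemapNode(
        parent_instance_id=data["parent_instance_id"],
        instance_id=data["instance_id"],
        age=data["age"],
        similarity_coefficient=data["similarity_coefficient"],
        children=[_node_from_dict(c) for c in data["children"]])


def import_treemap_json(source: str | Path) -> TreemapNode:
    text = source
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif not source.lstrip().startswith("{"):
        text = Path(source).read_text(encoding="utf-8")
    return _node_from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Layout and SVG rendering

#: color ramp endpoints over similarity 0 -> 1
COLOR_LOW = "#deebf7"
COLOR_HIGH = "#08519c"


@dataclass(frozen=True)
class LayoutRect:
    """One node's rectangle in normalized [0, 1] canvas coordinates."""

    node: TreemapNode
    x: float
    y: float
    width: float
    height: float
    color: str


def similarity_color(coefficient: float) -> str:
    """Linear interpolation between the documented ramp endpoints."""
    lo = tuple(int(COLOR_LOW[k:k + 2], 16) for k in (1, 3, 5))
    hi = tuple(int(COLOR_HIGH[k:k + 2], 16) for k in (1, 3, 5))
    c = min(max(coefficient, 0.0), 1.0)
    rgb = tuple(round(l + c * (h - l)) for l, h in zip(lo, hi))
    return "#%02x%02x%02x" % rgb


def layout_treemap(tree: TreemapNode, width: float = 1.0,
                   height: float = 1.0) -> list[LayoutRect]:
    """Slice-and-dice layout: alternate split direction per level.

    Sibling rectangles tile their parent's rectangle exactly, with
    areas proportional to their similarity coefficients (equal split
    when all coefficients are 0).  Coordinates are normalized to
    [0, 1]; ``width``/``height`` set only the canvas aspect used by the
    SVG renderer.
    """
    if width <= 0 or height <= 0:
        raise ValueError("canvas must have positive area")
    rects: list[LayoutRect] = []

    def place(node: TreemapNode, x: float, y: float, w: float, h: float,
              level: int) -> None:
        rects.append(LayoutRect(node, x, y, w, h,
                                similarity_color(node.similarity_coefficient)))
        if not node.children:
            return
        total = sum(c.similarity_coefficient for c in node.children)
        if total == 0:
            fractions = [1.0 / len(node.children)] * len(node.children)
        else:
            fractions = [c.similarity_coefficient / total for c in node.children]
        horizontal = level % 2 == 1  # odd levels split side by side along x
        offset = 0.0
        for child, frac in zip(node.children, fractions):
            if horizontal:
                place(child, x + offset * w, y, w * frac, h, level + 1)
            else:
                place(child, x, y + offset * h, w, h * frac, level + 1)
            offset += frac

    place(tree, 0.0, 0.0, 1.0, 1.0, 1)
    return rects


def export_treemap_svg(rects: list[LayoutRect], path: str | Path,
                       width: float = 640.0, height: float = 480.0) -> None:
    """Write a standalone SVG 1.1 file, one labelled rectangle per node.

    Output is byte-deterministic for identical inputs: coordinates are
    rounded to fixed precision and no timestamps are embedded.
    """
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width:g}" height="{height:g}" '
        f'viewBox="0 0 {width:g} {height:g}">',
    ]
    for r in rects:
        x, y = r.x * width, r.y * height
        w, h = r.width * width, r.height * height
        label = f"{r.node.instance_id} ({r.node.similarity_coefficient:.3f})"
        lines.append(
            f'<rect x="{x:.4f}" y="{y:.4f}" width="{w:.4f}" height="{h:.4f}" '
            f'fill="{r.color}" stroke="#333333" stroke-width="1"/>')
        lines.append(
            f'<text x="{x + 4:.4f}" y="{y + 14:.4f}" font-size="11" '
            f'font-family="sans-serif" fill="#111111">{label}</text>')
    lines.append("</svg>")
    try:
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise FrailtyMapError(f"cannot write SVG to {path}: {exc}") from exc
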