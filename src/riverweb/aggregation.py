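"""Ordered taxonomic aggregation of food webs (steps T1..T5).

Raw webs list nodes exactly as the sources name them, which mixes
size/age variants of one species, species, families and coarse groups.
Aggregation lumps nodes in five cumulative steps: size/age variants to
species (T1), fish species to families (T2), fish families to the two
dominant orders (T3), invertebrates to major groups (T4), and all
producers into a single Producers node (T5, detritus stays separate).
Edges are relabeled through the same mapping; an edge whose two
endpoints merge becomes a self-loop and is retained in the web (it is
excluded from metrics downstream).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .core import FoodWeb, ValidationError, normalize_label

__all__ = [
    "AggregationScheme",
    "SchemeError",
    "apply_step",
    "apply_scheme",
    "merge_webs",
    "read_scheme",
    "write_scheme",
]

STEP_ORDER = ("T1", "T2", "T3", "T4", "T5")


class SchemeError(ValueError):
    """An aggregation scheme violates its invariants."""


@dataclass
class AggregationScheme:
    """Ordered list of (step name, label mapping) pairs.

    Each mapping sends source labels to aggregate labels; labels not
    mentioned pass through unchanged.  Within one step no mapping
    target may also be a source (a node cannot be both absorbed and
    absorbing in the same step), and each source has exactly one
    target.
    """

    steps: list[tuple[str, dict[str, str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s for s, _ in self.steps]
        if len(names) != len(set(names)):
            raise SchemeError("duplicate step names")
        order = [n for n in names if n in STEP_ORDER]
        if order != sorted(order, key=STEP_ORDER.index):
            raise SchemeError(f"steps out of order: {names}")
        for name, mapping in self.steps:
            targets = {normalize_label(t) for t in mapping.values()}
            for src in mapping:
                if normalize_label(src) in targets:
                    raise SchemeError(
                        f"step {name}: {src!r} is both source and target"
                    )

    @property
    def step_names(self) -> list[str]:
        return [s for s, _ in self.steps]


def apply_step(web: FoodWeb, mapping: dict[str, str], step: str = "") -> FoodWeb:
    """Relabel web nodes through one aggregation mapping.

    Matching is case/whitespace insensitive; the mapping's own target
    spelling wins for merged nodes.  Nodes and edges are deduplicated
    after relabeling; merge-induced self-loops are retained.
    """
    norm_map: dict[str, str] = {}
    for src, dst in mapping.items():
        key = normalize_label(src)
        if key in norm_map and norm_map[key] != dst:
            raise SchemeError(f"conflicting targets for source {src!r}")
        norm_map[key] = dst

    def rename(label: str) -> str:
        return norm_map.get(normalize_label(label), label)

    nodes = {rename(n) for n in web.nodes}
    edges = {(rename(u), rename(v)) for u, v in web.edges}
    return FoodWeb(name=web.name, nodes=nodes, edges=edges, level=step or web.level)


def apply_scheme(web: FoodWeb, scheme: AggregationScheme) -> list[FoodWeb]:
    """Apply the scheme's steps cumulatively.

    Returns one web per step, so the T3 web is the raw web pushed
    through the T1, T2 and T3 mappings in order.
    """
    out: list[FoodWeb] = []
    current = web
    for name, mapping in scheme.steps:
        current = apply_step(current, mapping, step=name)
        out.append(current)
    return out if out else [web]


def merge_webs(webs: list[FoodWeb], name: str = "Master") -> FoodWeb:
    """Union of nodes and edges across section webs."""
    if not webs:
        raise ValidationError("merge_webs needs at least one web")
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    # keep the first-seen casing for labels that differ only by case
    canon: dict[str, str] = {}
    for web in webs:
        for n in web.nodes:
            canon.setdefault(normalize_label(n), n)
        nodes.update(canon[normalize_label(n)] for n in web.nodes)
        edges.update(
            (canon[normalize_label(u)], canon[normalize_label(v)])
            for u, v in web.edges
        )
    return FoodWeb(name=name, nodes=nodes, edges=edges, level=webs[0].level)


def read_scheme(path) -> AggregationScheme:
    """Read a scheme CSV with columns ``step,source,target``."""
    path = Path(path)
    by_step: dict[str, dict[str, str]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = [f.strip().lower() for f in reader.fieldnames or []]
        reader.fieldnames = fields
        for col in ("step", "source", "target"):
            if col not in fields:
                raise SchemeError(f"{path}: missing column {col!r}")
        for row in reader:
            step = row["step"].strip()
            src = row["source"].strip()
            dst = row["target"].strip()
            if not (step and src and dst):
                continue
            step_map = by_step.setdefault(step, {})
            if src in step_map and step_map[src] != dst:
                raise SchemeError(f"{path}: conflicting targets for {src!r} at {step}")
            step_map[src] = dst
    ordered = sorted(by_step, key=lambda s: STEP_ORDER.index(s) if s in STEP_ORDER else 99)
    return AggregationScheme(steps=[(s, by_step[s]) for s in ordered])


def write_scheme(scheme: AggregationScheme, path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "source", "target"])
        for step, mapping in scheme.steps:
            for src, dst in sorted(mapping.items()):
                writer.writerow([step, src, dst])
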