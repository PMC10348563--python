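"""Core domain types and readers/writers for binary food webs.

A food web here is a *connectance web*: a directed binary graph whose
edges point from predator to prey, recording only the presence or
absence of a trophic link.  Webs are later made symmetric (each dyad
collapses to a single undirected link) before global and local network
metrics are computed; the directed structure is kept for regular-
equivalence clustering, where edge direction carries the trophic role.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger("riverweb")

__all__ = [
    "FoodWeb",
    "SymmetricWeb",
    "NodeRecord",
    "CentralityTable",
    "FormatError",
    "ValidationError",
    "normalize_label",
    "read_edge_list",
    "write_edge_list",
    "read_node_table",
    "read_centrality_table",
    "write_centrality_table",
    "symmetrize",
]

LEVELS = ("master", "t1", "t2", "t3", "t4", "t5")


class FormatError(ValueError):
    """An input file does not have the expected layout."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


def normalize_label(label: str) -> str:
    """Matching key for a node label: trimmed and case-folded.

    Original casing is preserved everywhere for output; sources mix
    all-caps invertebrate families with italicised species binomials,
    so matching must ignore case but display must not.
    """
    return " ".join(label.split()).casefold()


@dataclass
class FoodWeb:
    """Directed binary predator->prey web for one river section or level.

    Parameters
    ----------
    name:
        Section label, e.g. ``"Upper"`` or ``"Master"``.
    nodes:
        Node labels.  Isolated nodes (no trophic links recorded) are
        legal and retained.
    edges:
        Ordered (predator, prey) pairs.  Set semantics: no duplicates.
        Self-loops (cannibalism within an aggregate group) are allowed.
    level:
        Aggregation tag: ``"raw"`` or ``"T1"``..``"T5"``.
    """

    name: str
    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    directed: bool = True
    level: str = "raw"

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        self.edges = {(u, v) for u, v in self.edges}
        self.validate()

    def validate(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValidationError(f"edge ({u!r}, {v!r}) has endpoint outside node set")
        for n in self.nodes:
            if not str(n).strip():
                raise ValidationError("empty node label")
        keys: dict[str, str] = {}
        for n in self.nodes:
            k = normalize_label(n)
            if k in keys and keys[k] != n:
                raise ValidationError(f"labels {keys[k]!r} and {n!r} collide after normalization")
            keys[k] = n

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Directed link count L (deduplicated, self-loops included)."""
        return len(self.edges)

    @property
    def self_loops(self) -> set[str]:
        return {u for u, v in self.edges if u == v}

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class SymmetricWeb:
    """Undirected, dichotomized view of one :class:`FoodWeb`.

    Symmetrization takes the interaction sum of each dyad, x_ij + x_ji,
    then clamps it back to presence/absence: a mutual-predation pair
    counts as one link.  Self-loops are recorded separately and never
    enter degree, density, distance or betweenness computations.
    """

    name: str
    nodes: set[str]
    links: set[frozenset]
    mutual_pairs: int
    self_loops: set[str]
    level: str = "raw"

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if len(self.links) > n * (n - 1) // 2:
            raise ValidationError("more links than dyads")
        if self.mutual_pairs > len(self.links):
            raise ValidationError("mutual_pairs exceeds link count")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(name=self.name)
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(l) for l in self.links)
        return g


def symmetrize(web: FoodWeb) -> SymmetricWeb:
    """Collapse each ordered predator/prey pair into one undirected link.

    ``mutual_pairs`` counts dyads where both (i, j) and (j, i) were
    present before dichotomization.  Re-symmetrizing the resulting link
    set is a no-op (idempotence at the link level).
    """
    if not web.directed:
        raise ValidationError("symmetrize expects a directed web")
    links: set[frozenset] = set()
    loops: set[str] = set()
    mutual = 0
    for u, v in web.edges:
        if u == v:
            loops.add(u)
            continue
        dyad = frozenset((u, v))
        if dyad in links:
            continue
        links.add(dyad)
        if (v, u) in web.edges:
            mutual += 1
    return SymmetricWeb(
        name=web.name,
        nodes=set(web.nodes),
        links=links,
        mutual_pairs=mutual,
        self_loops=loops,
        level=web.level,
    )


@dataclass
class NodeRecord:
    """One row of the node-code table.

    ``membership`` flags at which aggregation levels the node exists;
    ``group_target`` gives the aggregate label the node maps into at a
    level where it disappears (empty when the node survives unchanged).
    """

    code: int
    label: str
    membership: dict[str, bool] = field(default_factory=dict)
    group_target: dict[str, str] = field(default_factory=dict)


@dataclass
class CentralityTable:
    """Per-node nDC (fraction) and nBC (percent) values for one web."""

    name: str
    rows: dict[str, tuple[float, float]]  # label -> (ndc, nbc)

    def __post_init__(self) -> None:
        keys = set()
        for label, (ndc, nbc) in self.rows.items():
            if not 0.0 <= ndc <= 1.0:
                raise ValidationError(f"nDC out of [0,1] for {label!r}: {ndc}")
            if not 0.0 <= nbc <= 100.0:
                raise ValidationError(f"nBC out of [0,100] for {label!r}: {nbc}")
            k = normalize_label(label)
            if k in keys:
                raise ValidationError(f"duplicate label {label!r}")
            keys.add(k)

    @property
    def labels(self) -> list[str]:
        return list(self.rows)

    def ndc_values(self) -> list[float]:
        return [v[0] for v in self.rows.values()]

    def nbc_values(self) -> list[float]:
        return [v[1] for v in self.rows.values()]


# ---------------------------------------------------------------------------
# readers / writers (CSV is the canonical interchange format)


def _open_rows(path) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        reader.fieldnames = [f.strip().lower() for f in reader.fieldnames]
        return list(reader)


def read_edge_list(
    path,
    name: str | None = None,
    level: str = "raw",
    predator_col: str = "predator",
    prey_col: str = "prey",
    node_col: str = "node",
) -> FoodWeb:
    """Read a directed edge list CSV (header ``predator,prey``).

    Rows with an empty prey cell (or a ``node``-only row) declare an
    isolated node.  Duplicate edges are collapsed; the number dropped is
    logged at INFO level.
    """
    rows = _open_rows(path)
    path = Path(path)
    if rows:
        fields = rows[0].keys()
        if predator_col not in fields and node_col not in fields:
            raise FormatError(f"{path}: missing column {predator_col!r}")
        if predator_col in fields and prey_col not in fields:
            raise FormatError(f"{path}: missing column {prey_col!r}")
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    seen = 0
    for row in rows:
        if node_col in row and (row.get(node_col) or "").strip():
            nodes.add(row[node_col].strip())
            continue
        pred = (row.get(predator_col) or "").strip()
        prey = (row.get(prey_col) or "").strip()
        if not pred and not prey:
            continue
        if pred and not prey:
            nodes.add(pred)
            continue
        if prey and not pred:
            nodes.add(prey)
            continue
        nodes.update((pred, prey))
        seen += 1
        edges.add((pred, prey))
    if not nodes:
        raise FormatError(f"{path}: no nodes in edge list")
    dropped = seen - len(edges)
    if dropped:
        log.info("%s: dropped %d duplicate edges", path.name, dropped)
    return FoodWeb(name=name or path.stem, nodes=nodes, edges=edges, level=level)


def write_edge_list(web: FoodWeb, path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["predator", "prey"])
        for u, v in sorted(web.edges):
            writer.writerow([u, v])
        linked = {n for e in web.edges for n in e}
        for n in sorted(web.nodes - linked):
            writer.writerow([n, ""])


def read_node_table(path) -> list[NodeRecord]:
    """Read the node-code table.

    Expected columns: ``code,name,master,t1,...,t5`` with any truthy
    mark (conventionally ``x``) flagging presence, plus optional
    ``target_t1,...,target_t5`` columns naming the aggregate label a
    node maps into at each step.
    """
    rows = _open_rows(path)
    path = Path(path)
    if rows:
        fields = set(rows[0].keys())
        for col in ("code", "name"):
            if col not in fields:
                raise FormatError(f"{path}: missing column {col!r}")
    records: list[NodeRecord] = []
    codes: set[int] = set()
    for row in rows:
        try:
            code = int(row["code"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: bad code {row.get('code')!r}") from exc
        if code in codes:
            raise ValidationError(f"{path}: duplicate code {code}")
        codes.add(code)
        membership = {
            lvl: bool((row.get(lvl) or "").strip()) for lvl in LEVELS
        }
        targets = {
            lvl: (row.get(f"target_{lvl}") or "").strip()
            for lvl in LEVELS[1:]
        }
        targets = {lvl: t for lvl, t in targets.items() if t}
        if not any(membership.values()):
            log.warning("%s: node %r has no presence marks", path.name, row["name"])
        records.append(
            NodeRecord(
                code=code,
                label=row["name"].strip(),
                membership=membership,
                group_target=targets,
            )
        )
    return records


def read_centrality_table(path, name: str | None = None) -> CentralityTable:
    """Read a per-node centrality CSV with header ``node,ndc,nbc``."""
    rows = _open_rows(path)
    path = Path(path)
    if rows:
        fields = set(rows[0].keys())
        for col in ("node", "ndc", "nbc"):
            if col not in fields:
                raise FormatError(f"{path}: missing column {col!r}")
    table: dict[str, tuple[float, float]] = {}
    for row in rows:
        label = row["node"].strip()
        table[label] = (float(row["ndc"]), float(row["nbc"]))
    return CentralityTable(name=name or path.stem, rows=table)


def write_centrality_table(table: CentralityTable, path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node", "ndc", "nbc"])
        for label, (ndc, nbc) in table.rows.items():
            writer.writerow([label, f"{ndc:.6g}", f"{nbc:.6g}"])
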