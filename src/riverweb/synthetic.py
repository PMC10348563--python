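"""Synthetic food webs, taxonomies and fixtures for end-to-end testing.

Two generators cover the structure the analysis assumes:

* :func:`generate_niche_web` builds a directed binary web with the
  niche model (each species holds a contiguous feeding interval on a
  one-dimensional niche axis), the standard stochastic generator for
  interval-diet, trophic-level-structured food webs.  An Erdos-Renyi
  generator is included as a structureless null.
* :func:`generate_taxonomy` builds a layered node table and matching
  five-step aggregation scheme: size/age variants under species,
  fish species under families under orders, invertebrate families
  under coarse groups, producers lumped into one node, detritus left
  alone — the layering the aggregation pipeline expects.

:func:`load_fixture` exposes small embedded datasets: the published
per-node centrality tables for the Po and Danube master webs (30
shared nodes), the published global-metric table, the cross-river
synonym list, and hand-built worked webs (path, triangle, star,
twin dyads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .aggregation import AggregationScheme
from .core import (
    CentralityTable,
    FoodWeb,
    NodeRecord,
    read_centrality_table,
)

__all__ = [
    "NicheParams",
    "TaxonomyParams",
    "generate_niche_web",
    "generate_random_web",
    "generate_taxonomy",
    "generate_section_web",
    "load_fixture",
    "realized_connectance",
]


@dataclass
class NicheParams:
    """Niche-model parameters: ``n`` species, target directed
    connectance ``C`` = L/n^2, and a seed."""

    n: int = 50
    C: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 < self.C < 0.5:
            raise ValueError("C must be in (0, 0.5)")


@dataclass
class TaxonomyParams:
    """Layered-taxonomy parameters.

    ``n_species`` counts true species (fish + invertebrates +
    producers, before size/age splitting); ``families`` and ``orders``
    structure the fish; ``producer_fraction`` of species are primary
    producers; ``variant_rate`` is the probability a fish species is
    recorded as separate small/large raw nodes.
    """

    n_species: int = 50
    families: int = 8
    orders: int = 2
    producer_fraction: float = 0.15
    variant_rate: float = 0.2
    invert_groups: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.families > self.n_species:
            raise ValueError("more families than species")
        if self.orders > self.families:
            raise ValueError("more orders than families")
        for frac in (self.producer_fraction, self.variant_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def generate_niche_web(params: NicheParams, name: str = "niche") -> FoodWeb:
    """Directed binary web from the niche model.

    Each species i draws a niche value n_i ~ U(0,1), a feeding range
    r_i = x * n_i with x ~ Beta(1, 1/(2C) - 1) (so E[r] matches the
    target connectance), and a range centre c_i ~ U(r_i/2, n_i); i
    preys on every j whose niche value falls inside the interval.
    The species with the smallest niche value gets r = 0, guaranteeing
    at least one basal node.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n, c = params.n, params.C
    niche = rng.uniform(0.0, 1.0, size=n)
    beta = 1.0 / (2.0 * c) - 1.0
    ranges = rng.beta(1.0, beta, size=n) * niche
    ranges[np.argmin(niche)] = 0.0
    centres = rng.uniform(ranges / 2.0, np.maximum(niche, ranges / 2.0))
    labels = [f"sp{i + 1:03d}" for i in range(n)]
    edges: set[tuple[str, str]] = set()
    for i in range(n):
        if ranges[i] <= 0:
            continue
        lo, hi = centres[i] - ranges[i] / 2.0, centres[i] + ranges[i] / 2.0
        for j in np.flatnonzero((niche >= lo) & (niche <= hi)):
            edges.add((labels[i], labels[int(j)]))
    return FoodWeb(name=name, nodes=set(labels), edges=edges)


def generate_random_web(n: int, C: float, seed: int = 0, name: str = "er") -> FoodWeb:
    """Erdos-Renyi directed web (structureless null model), loop-free."""
    rng = np.random.default_rng(seed)
    labels = [f"sp{i + 1:03d}" for i in range(n)]
    mask = rng.random((n, n)) < C
    np.fill_diagonal(mask, False)
    edges = {
        (labels[i], labels[j]) for i, j in zip(*np.nonzero(mask))
    }
    return FoodWeb(name=name, nodes=set(labels), edges=edges)


def realized_connectance(web: FoodWeb) -> float:
    """Directed connectance L / n^2."""
    return web.n_edges / web.n_nodes**2


_COARSE_GROUPS = ("Crustacea", "Insecta", "Mollusca", "Annelida", "Gastropoda", "Turbellaria")


def generate_taxonomy(
    params: TaxonomyParams,
) -> tuple[list[NodeRecord], AggregationScheme]:
    """Node records and a five-step scheme over a synthetic taxonomy.

    Raw nodes are: fish species (some split into _SMALL/_LARGE
    variants), invertebrate family codes, producer nodes, and a
    Detritus node that is never aggregated.
    """
    rng = np.random.default_rng(params.seed)
    n_prod = round(params.producer_fraction * params.n_species)
    n_consumers = params.n_species - n_prod
    n_fish = n_consumers // 2
    n_invert = n_consumers - n_fish

    fish = [f"Fish species {i + 1}" for i in range(n_fish)]
    inverts = [f"INVERTFAM{i + 1}" for i in range(n_invert)]
    producers = [f"Producer {i + 1}" for i in range(n_prod)]

    fam_of = {
        sp: f"Fishfam {int(rng.integers(params.families)) + 1}" for sp in fish
    }
    order_of = {
        f"Fishfam {i + 1}": f"Fishorder {i % params.orders + 1}"
        for i in range(params.families)
    }
    group_of = {
        fam: _COARSE_GROUPS[int(rng.integers(min(params.invert_groups, len(_COARSE_GROUPS))))]
        for fam in inverts
    }

    t1: dict[str, str] = {}
    raw_nodes: list[str] = []
    for sp in fish:
        if rng.random() < params.variant_rate:
            raw_nodes += [f"{sp}_SMALL", f"{sp}_LARGE"]
            t1[f"{sp}_SMALL"] = sp
            t1[f"{sp}_LARGE"] = sp
        else:
            raw_nodes.append(sp)
    raw_nodes += inverts + producers + ["Detritus"]

    t2 = {sp: fam_of[sp] for sp in fish}
    t3 = {fam: order_of[fam] for fam in set(fam_of.values())}
    t4 = dict(group_of)
    t5 = {p: "Producers" for p in producers}
    scheme = AggregationScheme(
        steps=[("T1", t1), ("T2", t2), ("T3", t3), ("T4", t4), ("T5", t5)]
    )

    records: list[NodeRecord] = []
    code = 0

    def survives(label: str, upto: int) -> bool:
        cur = label
        for _, mapping in scheme.steps[:upto]:
            if cur in mapping:
                return False
            cur = mapping.get(cur, cur)
        return True

    for label in raw_nodes:
        code += 1
        membership = {"master": True}
        targets: dict[str, str] = {}
        cur = label
        for i, (step, mapping) in enumerate(scheme.steps, start=1):
            lvl = step.lower()
            if cur in mapping:
                targets[lvl] = mapping[cur]
                membership[lvl] = False
                cur = mapping[cur]
            else:
                membership[lvl] = survives(label, i)
        records.append(
            NodeRecord(code=code, label=label, membership=membership, group_target=targets)
        )
    return records, scheme


def generate_section_web(
    params: TaxonomyParams, connectance: float = 0.1, name: str = "synthetic"
) -> tuple[FoodWeb, AggregationScheme, list[NodeRecord]]:
    """A raw section web wired over a generated taxonomy.

    Niche values are assigned so detritus and producers sit at the
    bottom of the axis (pure resources) and fish at the top, then the
    niche-model interval rule wires predator->prey links among the raw
    nodes.  Returns the web together with its scheme and node table.
    """
    records, scheme = generate_taxonomy(params)
    labels = [r.label for r in records]
    rng = np.random.default_rng(params.seed + 1)
    n = len(labels)

    def rank_key(label: str) -> int:
        if label == "Detritus" or label.startswith("Producer"):
            return 0
        if label.startswith("INVERTFAM"):
            return 1
        return 2

    jitter = rng.uniform(0, 1, size=n)
    order = sorted(range(n), key=lambda i: (rank_key(labels[i]), jitter[i]))
    niche = np.empty(n)
    niche[order] = (np.arange(n) + 0.5) / n
    beta = max(1.0 / (2.0 * connectance) - 1.0, 1e-9)
    ranges = rng.beta(1.0, beta, size=n) * niche
    for i, lab in enumerate(labels):
        if rank_key(lab) == 0:
            ranges[i] = 0.0  # resources do not feed
    centres = rng.uniform(ranges / 2.0, np.maximum(niche, ranges / 2.0))
    edges: set[tuple[str, str]] = set()
    for i in range(n):
        if ranges[i] <= 0:
            continue
        lo, hi = centres[i] - ranges[i] / 2.0, centres[i] + ranges[i] / 2.0
        for j in np.flatnonzero((niche >= lo) & (niche <= hi)):
            edges.add((labels[i], labels[int(j)]))
    web = FoodWeb(name=name, nodes=set(labels), edges=edges)
    return web, scheme, records


# ---------------------------------------------------------------------------
# embedded fixtures


def _worked_web(name: str) -> FoodWeb:
    if name == "path3":
        return FoodWeb("path3", {"A", "B", "C"}, {("A", "B"), ("B", "C")})
    if name == "triangle":
        return FoodWeb("triangle", {"A", "B", "C"}, {("A", "B"), ("B", "C"), ("C", "A")})
    if name == "star4":
        return FoodWeb(
            "star4", {"hub", "a", "b", "c"}, {("hub", "a"), ("hub", "b"), ("hub", "c")}
        )
    if name == "twin_dyads":
        # two disjoint predator->prey dyads: isomorphic positions
        return FoodWeb(
            "twin_dyads", {"A", "B", "C", "D"}, {("A", "B"), ("C", "D")}
        )
    raise KeyError(name)


def load_fixture(name: str):
    """Load an embedded fixture by id.

    Known ids: ``table3_po``, ``table3_danube`` (published per-node
    centralities for the 30 shared nodes), ``synonyms_po_danube``
    (cross-river label pairs), ``table2_global`` (published global
    metric table as a DataFrame), and the worked webs ``path3``,
    ``triangle``, ``star4``, ``twin_dyads``.
    """
    pkg = resources.files("riverweb") / "fixtures"
    if name in ("table3_po", "table3_danube"):
        with resources.as_file(pkg / f"{name}.csv") as path:
            table = read_centrality_table(path, name=name.split("_")[1].capitalize())
        return table
    if name == "synonyms_po_danube":
        from .comparison import read_synonyms

        with resources.as_file(pkg / "synonyms_po_danube.csv") as path:
            return read_synonyms(path)
    if name == "table2_global":
        import pandas as pd

        with resources.as_file(pkg / "table2_global.csv") as path:
            return pd.read_csv(path)
    try:
        return _worked_web(name)
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}") from None
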