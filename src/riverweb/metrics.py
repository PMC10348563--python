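"""Global and local network metrics on symmetrized connectance webs.

Global metrics: node count N, directed link count L, density
D = 2L'/N(N-1) with L' the undirected link count of the symmetrized
dichotomized web, degree-weighted overall clustering coefficient CL,
average geodesic distance d over reachable pairs, and the small-world
index SW = CL/d.  Local metrics: normalized degree centrality
nDC_i = deg_i/(N-1) (a fraction) and normalized betweenness centrality
nBC_i (a percent of the (N-1)(N-2)/2 node pairs whose shortest paths
can pass through i).

Self-loops never contribute: they are stripped at symmetrization, so a
dyad supports at most one link and density stays within [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .core import FoodWeb, SymmetricWeb, symmetrize

__all__ = [
    "MetricsReport",
    "global_metrics",
    "small_world",
    "degree_centrality",
    "betweenness_centrality",
    "local_metrics",
    "metrics_trajectory",
]


@dataclass
class MetricsReport:
    name: str
    level: str
    N: int
    L: int  # directed links of the source web (self-loops included)
    D: float
    CL: float
    d: float
    SW: float
    mutual_pairs: int = 0

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "level": self.level,
            "N": self.N,
            "L": self.L,
            "D": self.D,
            "CL": self.CL,
            "d": self.d,
            "SW": self.SW,
            "mutual_pairs": self.mutual_pairs,
        }


class MetricsError(ValueError):
    pass


def small_world(cl: float, d: float) -> float:
    """SW = CL / d; the index that separates random (low CL, low d),
    small-world (high CL, low d) and lattice-like (high CL, high d)
    graphs."""
    if d <= 0:
        raise MetricsError("average distance must be positive")
    return cl / d


def _weighted_clustering(g: nx.Graph) -> float:
    """Degree-weighted mean of local clustering coefficients.

    Nodes of degree < 2 have an undefined triangle fraction; they get
    c_i = 0 and their weight (0 or 1) keeps their influence marginal.
    """
    local = nx.clustering(g)
    degs = dict(g.degree())
    total = sum(degs.values())
    if total == 0:
        return 0.0
    return sum(degs[n] * local[n] for n in g) / total


def _mean_geodesic(g: nx.Graph) -> float:
    """Mean shortest-path length over reachable unordered pairs.

    Unreachable pairs are excluded rather than treated as infinite, so
    disconnected intermediate webs still get a finite d.
    """
    total = 0
    count = 0
    for source, dists in nx.all_pairs_shortest_path_length(g):
        for target, dist in dists.items():
            if target == source:
                continue
            total += dist
            count += 1
    if count == 0:
        raise MetricsError("no connected pairs: average distance undefined")
    # each unordered pair counted twice; the ratio is unchanged
    return total / count


def global_metrics(
    sweb: SymmetricWeb, directed_links: int | None = None
) -> MetricsReport:
    """All six global metrics for one symmetrized web.

    ``directed_links`` is the L reported alongside: the deduplicated
    directed link count of the source web.  When omitted, the undirected
    link count is used.
    """
    n = sweb.n_nodes
    if n < 2:
        raise MetricsError("need at least 2 nodes")
    g = sweb.to_networkx()
    density = 2 * sweb.n_links / (n * (n - 1))
    cl = _weighted_clustering(g)
    d = _mean_geodesic(g)
    return MetricsReport(
        name=sweb.name,
        level=sweb.level,
        N=n,
        L=directed_links if directed_links is not None else sweb.n_links,
        D=density,
        CL=cl,
        d=d,
        SW=small_world(cl, d),
        mutual_pairs=sweb.mutual_pairs,
    )


def degree_centrality(sweb: SymmetricWeb) -> dict[str, float]:
    """nDC_i = deg_i / (N - 1) on the loop-free undirected web."""
    n = sweb.n_nodes
    if n < 2:
        raise MetricsError("need at least 2 nodes")
    g = sweb.to_networkx()
    return {node: deg / (n - 1) for node, deg in g.degree()}


def betweenness_centrality(sweb: SymmetricWeb) -> dict[str, float]:
    """nBC_i as a percent.

    Raw betweenness counts, for every unordered pair (j, k), the
    fraction of shortest j-k paths through i; the normalizer is the
    number of pairs excluding i, (N-1)(N-2)/2.
    """
    n = sweb.n_nodes
    if n < 3:
        raise MetricsError("need at least 3 nodes")
    g = sweb.to_networkx()
    raw = nx.betweenness_centrality(g, normalized=False)
    denom = (n - 1) * (n - 2) / 2
    return {node: 100.0 * val / denom for node, val in raw.items()}


def local_metrics(sweb: SymmetricWeb) -> dict[str, tuple[float, float]]:
    """Per-node (nDC, nBC) pairs, keyed by label."""
    ndc = degree_centrality(sweb)
    nbc = betweenness_centrality(sweb)
    return {node: (ndc[node], nbc[node]) for node in sorted(sweb.nodes)}


def metrics_trajectory(webs: list[FoodWeb]) -> list[MetricsReport]:
    """Global metrics for a raw web and its aggregation steps."""
    return [global_metrics(symmetrize(w), directed_links=w.n_edges) for w in webs]
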