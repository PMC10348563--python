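"""Global and local network metrics against worked examples and
brute-force oracles."""

import itertools
import random

import numpy as np
import pytest

from riverweb.core import FoodWeb, symmetrize
from riverweb.metrics import (
    MetricsError,
    betweenness_centrality,
    degree_centrality,
    global_metrics,
    small_world,
)
from riverweb.synthetic import generate_random_web, load_fixture


def _sweb_from_links(nodes, links):
    edges = {(u, v) for u, v in links} | {(v, u) for u, v in links}
    return symmetrize(FoodWeb("w", set(nodes), edges))


# --- independent oracle: enumerate every simple path, keep the shortest ---


def _all_shortest_paths(adj, s, t):
    """All shortest s-t paths by plain breadth-limited DFS enumeration."""
    best: list[list] = []
    best_len = [len(adj) + 1]

    def dfs(node, path):
        if len(path) - 1 > best_len[0]:
            return
        if node == t:
            if len(path) - 1 < best_len[0]:
                best_len[0] = len(path) - 1
                best.clear()
            if len(path) - 1 == best_len[0]:
                best.append(list(path))
            return
        for nxt in adj[node]:
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    dfs(s, [s])
    return best


def brute_force_betweenness(nodes, links):
    """Fractional-credit betweenness by exhaustive path enumeration."""
    adj = {n: set() for n in nodes}
    for u, v in links:
        adj[u].add(v)
        adj[v].add(u)
    raw = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for path in paths:
            for mid in path[1:-1]:
                raw[mid] += 1.0 / len(paths)
    return raw


class TestGlobalMetrics:
    def test_triangle_is_fully_clustered(self):
        rep = global_metrics(_sweb_from_links("ABC", [("A", "B"), ("B", "C"), ("C", "A")]))
        assert (rep.D, rep.CL, rep.d, rep.SW) == (1.0, 1.0, 1.0, 1.0)

    def test_path_mean_distance(self):
        rep = global_metrics(_sweb_from_links("ABC", [("A", "B"), ("B", "C")]))
        assert rep.d == pytest.approx((1 + 1 + 2) / 3)
        assert rep.CL == 0.0

    def test_disconnected_pairs_excluded_from_distance(self):
        rep = global_metrics(
            _sweb_from_links("ABCD", [("A", "B"), ("C", "D")])
        )
        assert rep.d == 1.0  # only the two within-component pairs count

    def test_single_node_web_rejected(self):
        with pytest.raises(MetricsError):
            global_metrics(_sweb_from_links("A", []))

    def test_linkless_web_has_undefined_distance(self):
        with pytest.raises(MetricsError):
            global_metrics(_sweb_from_links("AB", []))

    def test_density_uses_undirected_dyads(self):
        # mutual predation counts once: 2 directed edges, 1 dyad
        web = FoodWeb("w", {"A", "B"}, {("A", "B"), ("B", "A")})
        rep = global_metrics(symmetrize(web), directed_links=web.n_edges)
        assert rep.L == 2
        assert rep.D == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_handshake_identity(self, seed):
        web = generate_random_web(20, 0.15, seed=seed)
        sweb = symmetrize(web)
        degs = dict(sweb.to_networkx().degree())
        assert sum(degs.values()) == 2 * sweb.n_links

    def test_er_clustering_matches_density(self):
        """On Erdos-Renyi webs CL is an unbiased triangle-density
        estimate, so it tracks D across seeds."""
        diffs = []
        for seed in range(40):
            sweb = symmetrize(generate_random_web(40, 0.2, seed=seed))
            rep = global_metrics(sweb)
            diffs.append(rep.CL - rep.D)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * max(se, 1e-12)


class TestSmallWorld:
    def test_ratio(self):
        assert small_world(0.308, 1.779) == pytest.approx(0.173, abs=5e-4)
        assert small_world(0.323, 1.648) == pytest.approx(0.196, abs=5e-4)
        assert small_world(0.0, 2.5) == 0.0

    def test_zero_distance_rejected(self):
        with pytest.raises(MetricsError):
            small_world(0.5, 0.0)


class TestDegreeCentrality:
    def test_star_center(self):
        sweb = symmetrize(load_fixture("star4"))
        ndc = degree_centrality(sweb)
        assert ndc["hub"] == 1.0
        assert ndc["a"] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_neighbor_scan(self, seed):
        web = generate_random_web(15, 0.2, seed=seed)
        sweb = symmetrize(web)
        ndc = degree_centrality(sweb)
        for node in sweb.nodes:
            neighbors = {
                other
                for other in sweb.nodes
                if other != node and frozenset((node, other)) in sweb.links
            }
            assert ndc[node] == pytest.approx(len(neighbors) / (sweb.n_nodes - 1))


class TestBetweennessCentrality:
    def test_path_middle_carries_everything(self):
        sweb = symmetrize(load_fixture("path3"))
        nbc = betweenness_centrality(sweb)
        assert nbc == {"A": 0.0, "B": 100.0, "C": 0.0}

    def test_isolated_node_changes_nothing(self):
        links = [("A", "B"), ("B", "C"), ("C", "D"), ("B", "D")]
        base = brute_force_betweenness("ABCD", links)
        with_iso = brute_force_betweenness("ABCDE", links)
        small = _sweb_from_links("ABCDE", links)
        nbc = betweenness_centrality(small)
        assert nbc["E"] == 0.0
        n = 5
        for node in "ABCD":
            assert nbc[node] == pytest.approx(
                100 * with_iso[node] / ((n - 1) * (n - 2) / 2)
            )
            assert with_iso[node] == pytest.approx(base[node])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 7)
        nodes = [f"n{i}" for i in range(n)]
        pairs = list(itertools.combinations(nodes, 2))
        links = [p for p in pairs if rng.random() < 0.45]
        sweb = _sweb_from_links(nodes, links)
        nbc = betweenness_centrality(sweb)
        oracle = brute_force_betweenness(nodes, links)
        denom = (n - 1) * (n - 2) / 2
        for node in nodes:
            assert nbc[node] == pytest.approx(100 * oracle[node] / denom, abs=1e-9)

    def test_relabeling_invariance(self):
        links = [("A", "B"), ("B", "C"), ("C", "D")]
        nbc = betweenness_centrality(_sweb_from_links("ABCD", links))
        renamed = [(u.lower() * 2, v.lower() * 2) for u, v in links]
        nbc2 = betweenness_centrality(
            _sweb_from_links([n.lower() * 2 for n in "ABCD"], renamed)
        )
        for orig, new in zip("ABCD", [n.lower() * 2 for n in "ABCD"]):
            assert nbc[orig] == pytest.approx(nbc2[new])
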