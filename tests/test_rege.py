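"""REGE similarity recurrence and trophic-guild clustering."""

import random

import numpy as np
import pytest

from riverweb.core import FoodWeb
from riverweb.rege import (
    SimilarityMatrix,
    cluster_similarity,
    cut_dendrogram,
    rege_similarity,
)
from riverweb.synthetic import load_fixture


def rege_once_oracle(labels, edges, r_prev):
    """Single REGE pass written as direct nested loops over the
    recurrence, independently of the vectorized implementation."""
    n = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    x = [[0.0] * n for _ in range(n)]
    for u, v in edges:
        x[idx[u]][idx[v]] = 1.0
    neigh = [
        [k for k in range(n) if x[i][k] or x[k][i]] for i in range(n)
    ]
    num = [[0.0] * n for _ in range(n)]
    den = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            for k in neigh[i]:
                if not neigh[j]:
                    den[i][j] += x[i][k] + x[k][i]
                    continue
                best_num = 0.0
                best_den = 0.0
                for m in neigh[j]:
                    cand_num = r_prev[k][m] * (
                        min(x[i][k], x[j][m]) + min(x[k][i], x[m][j])
                    )
                    cand_den = max(x[i][k], x[j][m]) + max(x[k][i], x[m][j])
                    best_num = max(best_num, cand_num)
                    best_den = max(best_den, cand_den)
                num[i][j] += best_num
                den[i][j] += best_den
    out = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            total_den = den[i][j] + den[j][i]
            if total_den > 0:
                out[i][j] = (num[i][j] + num[j][i]) / total_den
        out[i][i] = 1.0
    return out


class TestRecurrence:
    def test_twin_dyads_are_perfectly_equivalent(self):
        sim = rege_similarity(load_fixture("twin_dyads"), iterations=3)
        assert sim.value("A", "C") == 100.0
        assert sim.value("B", "D") == 100.0
        assert sim.value("A", "B") == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_loop_oracle_one_iteration(self, seed):
        rng = random.Random(seed)
        labels = [f"n{i}" for i in range(6)]
        edges = {
            (u, v)
            for u in labels
            for v in labels
            if u != v and rng.random() < 0.3
        }
        web = FoodWeb("w", set(labels), edges)
        sim = rege_similarity(web, iterations=1)
        oracle = rege_once_oracle(
            sim.labels, edges, [[1.0] * 6 for _ in range(6)]
        )
        assert np.allclose(sim.S, 100 * np.array(oracle), atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_permutation_equivariance(self, seed):
        rng = random.Random(100 + seed)
        labels = [f"n{i}" for i in range(7)]
        edges = {
            (u, v) for u in labels for v in labels if u != v and rng.random() < 0.3
        }
        web = FoodWeb("w", set(labels), edges)
        sim = rege_similarity(web, iterations=3)
        renamed = {l: f"z{rng.random():.10f}" for l in labels}
        web2 = FoodWeb(
            "w2",
            {renamed[l] for l in labels},
            {(renamed[u], renamed[v]) for u, v in edges},
        )
        sim2 = rege_similarity(web2, iterations=3)
        for a in labels:
            for b in labels:
                assert sim.value(a, b) == pytest.approx(
                    sim2.value(renamed[a], renamed[b]), abs=1e-9
                )

    def test_strictly_regular_pairs_stay_at_100(self):
        """Two predators with interchangeable prey (and no consumers)
        are strictly regularly equivalent; so are their prey."""
        web = FoodWeb(
            "w",
            {"P1", "P2", "q1", "q2", "q3"},
            {("P1", "q1"), ("P1", "q2"), ("P2", "q2"), ("P2", "q3")},
        )
        for it in (1, 2, 3, 5):
            sim = rege_similarity(web, iterations=it)
            assert sim.value("P1", "P2") == pytest.approx(100.0)
            assert sim.value("q1", "q3") == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_non_increasing_from_all_alike(self, seed):
        rng = random.Random(200 + seed)
        labels = [f"n{i}" for i in range(8)]
        edges = {
            (u, v) for u in labels for v in labels if u != v and rng.random() < 0.25
        }
        web = FoodWeb("w", set(labels), edges)
        prev = np.full((8, 8), 100.0)
        for it in range(1, 5):
            cur = rege_similarity(web, iterations=it).S
            assert (cur <= prev + 1e-9).all()
            prev = cur

    def test_isolated_pair_convention(self):
        web = FoodWeb("w", {"iso1", "iso2", "a", "b"}, {("a", "b")})
        sim = rege_similarity(web)
        assert sim.value("iso1", "iso2") == 100.0
        assert sim.value("iso1", "a") == 0.0

    def test_iterations_must_be_positive(self):
        with pytest.raises(ValueError):
            rege_similarity(load_fixture("path3"), iterations=0)


class TestClustering:
    def test_two_perfect_blocks_split_first(self):
        labels = ["a1", "a2", "b1", "b2"]
        S = np.array(
            [
                [100, 100, 0, 0],
                [100, 100, 0, 0],
                [0, 0, 100, 100],
                [0, 0, 100, 100],
            ],
            dtype=float,
        )
        dend = cluster_similarity(SimilarityMatrix(labels, S, iterations=1))
        clusters = cut_dendrogram(dend, 2)
        assert {frozenset(c) for c in clusters} == {
            frozenset({"a1", "a2"}),
            frozenset({"b1", "b2"}),
        }

    def test_merge_heights_monotone_on_similarity_scale(self):
        rng = np.random.default_rng(5)
        n = 9
        raw = rng.uniform(0, 100, size=(n, n))
        S = (raw + raw.T) / 2
        np.fill_diagonal(S, 100.0)
        sim = SimilarityMatrix([f"n{i}" for i in range(n)], S, iterations=1)
        dend = cluster_similarity(sim)
        heights = dend.merge_similarities
        assert (np.diff(heights) <= 1e-9).all()

    def test_newick_export_is_parseable(self):
        sim = rege_similarity(load_fixture("twin_dyads"))
        dend = cluster_similarity(sim)
        newick = dend.to_newick()
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {
            "A",
            "B",
            "C",
            "D",
        }
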