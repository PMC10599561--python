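"""Gene-sharing network construction and the association statistics."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pleomine._seq import random_protein, substream
from pleomine.netstats import (
    correlations,
    integrase_association_report,
    protein_clusters,
    shared_gene_network,
    wilcoxon_rank_sum,
)
from pleomine.simulate import generate_marker_family


class TestProteinClusters:
    def test_duplicated_protein_set_co_clusters(self):
        rng = substream(1, "pc")
        seqs = [random_protein(120, rng) for _ in range(4)]
        proteins = [("gA", f"p{i}", s) for i, s in enumerate(seqs)] + [
            ("gB", f"p{i}", s) for i, s in enumerate(seqs)
        ]
        clusters = protein_clusters(proteins)
        for i in range(4):
            assert clusters[("gA", f"p{i}")] == clusters[("gB", f"p{i}")]

    def test_unrelated_proteins_stay_singletons(self):
        rng = substream(2, "pc")
        proteins = [("g", f"p{i}", random_protein(150, rng)) for i in range(10)]
        clusters = protein_clusters(proteins)
        assert len(set(clusters.values())) == 10

    def test_transitive_chain_forms_one_component(self):
        rng = substream(3, "pc")
        A = random_protein(160, rng)
        C = random_protein(160, rng)
        B = A[:80] + C[80:]
        clusters = protein_clusters([("g", "A", A), ("g", "B", B), ("g", "C", C)])
        assert len(set(clusters.values())) == 1

    def test_family_members_cluster_together(self):
        fam = generate_marker_family(150, 8, 0.25, seed=4)
        proteins = [(f"g{i}", "p0", seq) for i, (_, seq) in enumerate(fam.members)]
        clusters = protein_clusters(proteins)
        assert len(set(clusters.values())) == 1


class TestNetwork:
    def _assignment(self, spec):
        """spec: genome -> list of cluster ids."""
        return {
            (g, f"p{i}"): cid for g, cids in spec.items() for i, cid in enumerate(cids)
        }

    def test_edge_at_two_shared_clusters(self):
        G = shared_gene_network(self._assignment({"a": [1, 2, 3], "b": [1, 2]}), min_shared=2)
        assert G.has_edge("a", "b")
        assert G.edges["a", "b"]["shared_clusters"] == 2

    def test_one_shared_cluster_needs_relaxed_threshold(self):
        asg = self._assignment({"a": [1, 2], "b": [1, 3]})
        assert not shared_gene_network(asg, min_shared=2).has_edge("a", "b")
        assert shared_gene_network(asg, min_shared=1).has_edge("a", "b")

    def test_monotone_in_min_shared(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            spec = {
                f"g{i}": list(rng.choice(12, size=rng.integers(2, 8), replace=False))
                for i in range(8)
            }
            asg = self._assignment(spec)
            e2 = set(shared_gene_network(asg, min_shared=2).edges)
            e3 = set(shared_gene_network(asg, min_shared=3).edges)
            assert e3 <= e2

    def test_degrees_match_brute_force_recount(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            spec = {
                f"g{i}": list(rng.choice(10, size=rng.integers(1, 6), replace=False))
                for i in range(7)
            }
            G = shared_gene_network(self._assignment(spec), min_shared=2)
            for a in spec:
                expected = sum(
                    1
                    for b in spec
                    if b != a and len(set(spec[a]) & set(spec[b])) >= 2
                )
                assert G.degree(a) == expected

    def test_no_self_edges_and_degree_sum(self):
        rng = np.random.default_rng(7)
        spec = {f"g{i}": list(rng.choice(8, size=4, replace=False)) for i in range(6)}
        G = shared_gene_network(self._assignment(spec), min_shared=2)
        assert all(a != b for a, b in G.edges)
        assert sum(dict(G.degree).values()) == 2 * G.number_of_edges()


class TestWilcoxon:
    def test_exact_enumeration_example(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "wilcoxon-exact"
        assert math.isclose(res.p_value, 0.1, rel_tol=1e-12)

    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value > 0.95

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            x = list(np.round(rng.normal(0, 1, 10), 6))
            y = list(np.round(rng.normal(0.3, 1, 10), 6))
            approx = wilcoxon_rank_sum(x, y)  # n+m=20 -> normal path
            exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert abs(approx.p_value - exact.pvalue) < 0.01

    def test_agrees_with_scipy_on_tied_data(self):
        rng = np.random.default_rng(9)
        x = list(rng.integers(0, 5, size=25).astype(float))
        y = list(rng.integers(1, 6, size=30).astype(float))
        ours = wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert abs(ours.p_value - ref.pvalue) < 0.02

    def test_type_one_error_near_nominal_level(self):
        rng = np.random.default_rng(10)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = list(rng.normal(0, 1, 20))
            y = list(rng.normal(0, 1, 20))
            if wilcoxon_rank_sum(x, y).p_value < 0.05:
                rejections += 1
        rate = rejections / n_sim
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 3 * se

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCorrelations:
    def test_linear_relation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2 * v + 1 for v in x]
        pear, spear = correlations(x, y)
        assert math.isclose(pear.statistic, 1.0, abs_tol=1e-12)
        assert math.isclose(spear.statistic, 1.0, abs_tol=1e-12)

    def test_monotone_nonlinearity(self):
        x = [0.0, 1.0, 2.0, 3.0, 4.0]
        y = [math.exp(v) for v in x]
        pear, spear = correlations(x, y)
        assert math.isclose(spear.statistic, 1.0, abs_tol=1e-12)
        assert pear.statistic < 1.0

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            x = rng.normal(0, 1, 15)
            y = rng.normal(0, 1, 15)
            pear, spear = correlations(x, y)
            # direct product-moment formula
            r = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert abs(pear.statistic - r) < 1e-10
            # Spearman = Pearson on midranks
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            rs = np.sum((rx - rx.mean()) * (ry - ry.mean())) / math.sqrt(
                np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2)
            )
            assert abs(spear.statistic - rs) < 1e-10

    def test_zero_variance_reported_undefined(self):
        pear, spear = correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert pear.p_value is None and "undefined" in pear.note


class TestAssociationReport:
    def _network(self, lengths, integrase, edges=()):
        import networkx as nx

        G = nx.Graph()
        for i, (L, flag) in enumerate(zip(lengths, integrase)):
            G.add_node(f"g{i}", length=L, integrase=flag)
        G.add_edges_from(edges)
        return G

    def test_planted_length_effect_detected(self):
        rng = np.random.default_rng(12)
        lengths = list(rng.normal(8000, 500, 50)) + list(rng.normal(12000, 500, 50))
        flags = [False] * 50 + [True] * 50
        report = integrase_association_report(self._network(lengths, flags))
        row = report[report.analysis == "length~integrase"].iloc[0]
        assert row.p_value < 0.05

    def test_shuffled_flags_control_type_one_error(self):
        rng = np.random.default_rng(13)
        lengths = list(rng.normal(10000, 1000, 40))
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            flags = [bool(b) for b in rng.permutation([True] * 20 + [False] * 20)]
            report = integrase_association_report(self._network(lengths, flags))
            row = report[report.analysis == "length~integrase"].iloc[0]
            if row.p_value < 0.05:
                rejections += 1
        rate = rejections / n_rep
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * se + 0.01

    def test_single_group_skipped_with_reason(self):
        report = integrase_association_report(
            self._network([5000.0, 6000.0, 7000.0], [True, True, True])
        )
        deg = report[report.analysis == "degree~integrase"].iloc[0]
        assert deg.method == "skipped" and "empty" in deg.note

    def test_missing_attributes_rejected(self):
        import networkx as nx

        G = nx.Graph()
        G.add_node("x")
        with pytest.raises(ValueError):
            integrase_association_report(G)
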