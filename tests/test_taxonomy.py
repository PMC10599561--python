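"""Trees and taxonomy: NJ correctness, RF distance, distance matrices,
alignments, bootstrap, hallmark detection and the genus decision rules."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pleomine.simulate import HALLMARKS_BY_GENUS
from pleomine.taxonomy import (
    GenusCall,
    HallmarkProfileCall,
    align_and_concat,
    align_markers,
    assign_genus,
    bootstrap_support,
    detect_hallmarks,
    distance_matrix,
)
from pleomine.trees import PhyloTree, max_rf, nj_tree, rf_distance


def quartet_matrix(rng):
    """Additive distances from ((A,B),(C,D)) with random positive branches."""
    bl = rng.uniform(0.05, 1.0, size=5)  # a, b, c, d, internal
    a, b, c, d, e = bl
    D = np.zeros((4, 4))
    D[0, 1] = D[1, 0] = a + b
    D[0, 2] = D[2, 0] = a + e + c
    D[0, 3] = D[3, 0] = a + e + d
    D[1, 2] = D[2, 1] = b + e + c
    D[1, 3] = D[3, 1] = b + e + d
    D[2, 3] = D[3, 2] = c + d
    return D


class TestNeighborJoining:
    def test_recovers_quartet_on_additive_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            tree = nj_tree(["A", "B", "C", "D"], quartet_matrix(rng))
            assert tree.splits() == {frozenset({"C", "D"})}

    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(["a", "b", "c"], D)
        lengths = {}
        for u, v, w in tree.edges:
            leaf = min(u, v)
            lengths[tree.labels[leaf]] = w
        # three-point formulas: la = (dab + dac - dbc) / 2, etc.
        assert math.isclose(lengths["a"], 0.1, abs_tol=1e-9)
        assert math.isclose(lengths["b"], 0.2, abs_tol=1e-9)
        assert math.isclose(lengths["c"], 0.4, abs_tol=1e-9)

    def test_tie_break_is_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(["a", "b", "c", "d"], D)
        t2 = nj_tree(["a", "b", "c", "d"], D)
        assert t1.edges == t2.edges

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(["a", "b"], np.zeros((2, 2)))
        bad = np.array([[0.0, 1.0, 2.0], [0.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(["a", "b", "c"], bad)


class TestRobinsonFoulds:
    def test_identical_trees(self):
        rng = np.random.default_rng(1)
        t = nj_tree(["A", "B", "C", "D"], quartet_matrix(rng))
        assert rf_distance(t, t) == 0

    def test_distinct_quartet_topologies_differ_by_two(self):
        rng = np.random.default_rng(2)
        t_abcd = nj_tree(["A", "B", "C", "D"], quartet_matrix(rng))
        # relabel so the other topology (A,C)(B,D) is produced
        t_acbd = nj_tree(["A", "C", "B", "D"], quartet_matrix(rng))
        assert rf_distance(t_abcd, t_acbd) == 2

    def test_star_tree_vs_resolved(self):
        rng = np.random.default_rng(3)
        resolved = nj_tree(["A", "B", "C", "D"], quartet_matrix(rng))
        star = PhyloTree(["A", "B", "C", "D"], [(i, 4, 1.0) for i in range(4)])
        assert star.splits() == set()
        assert rf_distance(star, resolved) == len(resolved.splits())

    def test_leaf_set_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        t1 = nj_tree(["A", "B", "C", "D"], quartet_matrix(rng))
        t2 = nj_tree(["A", "B", "C", "E"], quartet_matrix(rng))
        with pytest.raises(ValueError):
            rf_distance(t1, t2)


class TestAlignment:
    def test_identical_genomes_identical_rows(self):
        aln = align_and_concat({"a": "MKL", "b": "MKL"}, {"a": "MWW", "b": "MWW"})
        assert aln.rows["a"] == aln.rows["b"] == "MKLMWW"

    def test_missing_marker_becomes_gap_block(self):
        aln = align_and_concat({"a": "MKL"}, {"a": "MWW", "b": "MWW"})
        assert aln.rows["b"] == "---MWW"
        s, e = aln.blocks["ORF7"]
        assert aln.rows["b"][s:e] == "---"

    def test_column_count_is_sum_of_blocks(self):
        aln = align_and_concat({"a": "MKLAA", "b": "MKLAA"}, {"a": "MW", "b": "MW"})
        assert aln.length == 5 + 2
        assert aln.blocks == {"ORF7": (0, 5), "ORF8": (5, 7)}

    def test_genome_with_neither_marker_warned(self):
        aln = align_and_concat({"a": "MKL"}, {"a": "MWW"}, genomes=["a", "b"])
        assert any("b" in w for w in aln.warnings)
        assert "b" not in aln.labels


class TestDistanceMatrix:
    def test_identical_rows_have_zero_distance(self):
        aln = align_markers({"m": {"a": "MKLMKL", "b": "MKLMKL"}})
        _, D, excluded = distance_matrix(aln)
        assert D[0, 1] == 0.0 and not excluded

    def test_poisson_correction_closed_form(self):
        # 30 mismatches over 100 columns -> p=0.3, d = -ln(0.7)
        row_a = "A" * 100
        row_b = "C" * 30 + "A" * 70
        aln = align_markers({"m": {"a": row_a, "b": row_b}})
        _, D, _ = distance_matrix(aln)
        assert math.isclose(D[0, 1], -math.log(0.7), rel_tol=1e-9)

    def test_hand_computed_three_row_toy(self):
        # a-b differ at 1/4 ungapped columns; a-c at 2/4; b: gap masks column 1
        rows = {"a": "MKLW", "b": "M-LF", "c": "MAAW"}
        aln = align_markers({"m": rows})
        labels, D, _ = distance_matrix(aln)
        i = {lab: k for k, lab in enumerate(labels)}
        assert math.isclose(D[i["a"], i["b"]], -math.log(1 - 1 / 3), rel_tol=1e-9)
        assert math.isclose(D[i["a"], i["c"]], -math.log(1 - 2 / 4), rel_tol=1e-9)

    def test_zero_overlap_pair_reported(self):
        rows = {"a": "MK--", "b": "--LW", "c": "MKLW"}
        aln = align_markers({"m": rows})
        labels, D, excluded = distance_matrix(aln)
        assert ("a", "b") in excluded
        i = {lab: k for k, lab in enumerate(labels)}
        assert np.isnan(D[i["a"], i["b"]])


class TestBootstrap:
    def _two_clade_alignment(self, sim):
        from pleomine.taxonomy import ConcatAlignment

        orf7 = {}
        orf8 = {}
        for g in sim.genomes:
            if g.genus in ("alpha", "epsilon"):
                orf7[g.genome_id] = g.gene("ORF7").protein
                orf8[g.genome_id] = g.gene("ORF8").protein
        return align_and_concat(orf7, orf8)

    def test_well_separated_clades_get_high_support(self, sim_small):
        aln = self._two_clade_alignment(sim_small)
        labels, D, _ = distance_matrix(aln)
        supports = bootstrap_support(aln, 50, seed=5)
        alpha = frozenset(l for l in labels if "alpha" in l)
        epsilon = frozenset(l for l in labels if "epsilon" in l)
        ref = min(labels)
        split = epsilon if ref in alpha else alpha
        assert supports.get(split, 0.0) >= 0.95

    def test_single_replicate_supports_are_binary(self, sim_small):
        aln = self._two_clade_alignment(sim_small)
        supports = bootstrap_support(aln, 1, seed=6)
        assert set(supports.values()) <= {0.0, 1.0}

    def test_same_seed_is_deterministic(self, sim_small):
        aln = self._two_clade_alignment(sim_small)
        assert bootstrap_support(aln, 10, seed=7) == bootstrap_support(aln, 10, seed=7)


class TestHallmarks:
    def _genome_proteins(self, sim, genus):
        g = next(x for x in sim.genomes if x.genus == genus)
        return [(gene.gene_id, gene.protein) for gene in g.genes]

    @pytest.mark.parametrize(
        "genus,true_flags,false_flags",
        [
            ("alpha", ["RCRE"], ["polB", "Rep"]),
            ("gamma", ["polB"], ["RCRE", "Rep"]),
            ("epsilon", [], ["RCRE", "Rep", "polB"]),
        ],
    )
    def test_hallmark_detection_by_genus(self, sim_small, profiles_small, genus, true_flags, false_flags):
        hallmark_profiles = {k: v for k, v in profiles_small.items() if k in ("RCRE", "Rep", "polB", "integrase")}
        call = detect_hallmarks(self._genome_proteins(sim_small, genus), hallmark_profiles)
        for f in true_flags:
            assert getattr(call, f), f
        for f in false_flags:
            assert not getattr(call, f), f


class TestAssignGenus:
    def _classified(self, sim, profiles, n_boot=50):
        hallmark_profiles = {
            k: v for k, v in profiles.items() if k in ("RCRE", "Rep", "polB", "integrase")
        }
        orf7 = {g.genome_id: g.gene("ORF7").protein for g in sim.genomes}
        orf8 = {g.genome_id: g.gene("ORF8").protein for g in sim.genomes}
        aln = align_and_concat(orf7, orf8)
        labels, D, _ = distance_matrix(aln)
        tree = nj_tree(labels, D)
        supports = bootstrap_support(aln, n_boot, seed=3)
        refs = {}
        per = {}
        for g in sim.genomes:
            if per.get(g.genus, 0) < 2:
                refs[g.genome_id] = g.genus
                per[g.genus] = per.get(g.genus, 0) + 1
        calls = {}
        for g in sim.genomes:
            if g.genome_id in refs:
                continue
            hm = detect_hallmarks(
                [(x.gene_id, x.protein) for x in g.genes], hallmark_profiles
            )
            calls[g.genome_id] = assign_genus(g.genome_id, hm, tree, supports, refs)
        return calls

    def test_genus_recovery_on_simulated_genomes(self, sim_small, profiles_small):
        calls = self._classified(sim_small, profiles_small)
        truth = {g.genome_id: g.genus for g in sim_small.genomes}
        correct = sum(1 for gid, c in calls.items() if c.genus == truth[gid])
        assert correct / len(calls) >= 0.95

    def test_conflicting_hallmarks_unassigned(self):
        hm = HallmarkProfileCall(RCRE=True, polB=True)
        tree = PhyloTree(["x", "r1", "r2"], [(0, 3, 1.0), (1, 3, 1.0), (2, 3, 1.0)])
        refs = {"r1": g for g in ["alpha"]}
        refs = {"r1": "alpha", "r2": "beta"}
        call = assign_genus(
            "x", hm, tree, {}, {"r1": "alpha", "r2": "beta", "r3": "gamma", "r4": "delta", "r5": "epsilon"}
        )
        assert call.genus == "unassigned"
        assert any("conflict" in e for e in call.evidence)

    def test_hallmark_free_genome_without_supported_clade_unassigned(self):
        tree = PhyloTree(["x", "r1", "r2"], [(0, 3, 1.0), (1, 3, 1.0), (2, 3, 1.0)])
        refs = {"r1": "alpha", "r2": "beta", "r3": "gamma", "r4": "delta", "r5": "epsilon"}
        call = assign_genus("x", HallmarkProfileCall(), tree, {}, refs)
        assert call.genus == "unassigned"

    def test_missing_reference_genera_rejected(self):
        tree = PhyloTree(["x", "r1", "r2"], [(0, 3, 1.0), (1, 3, 1.0), (2, 3, 1.0)])
        with pytest.raises(ValueError):
            assign_genus("x", HallmarkProfileCall(), tree, {}, {"r1": "alpha"})


class TestMarkerCongruence:
    def test_orf7_orf8_congruent_while_spike_tree_is_not(self, sim_small):
        def tree_for(marker):
            seqs = {
                g.genome_id: g.gene(marker).protein
                for g in sim_small.genomes
                if g.gene(marker)
            }
            aln = align_markers({marker: seqs})
            labels, D, _ = distance_matrix(aln)
            return nj_tree(labels, D)

        t7, t8, t4 = tree_for("ORF7"), tree_for("ORF8"), tree_for("ORF4")
        n = len(t7.labels)
        congruent = rf_distance(t7, t8) / max_rf(n)
        discordant = min(rf_distance(t4, t7), rf_distance(t4, t8)) / max_rf(n)
        assert congruent <= 0.20
        assert discordant > congruent
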