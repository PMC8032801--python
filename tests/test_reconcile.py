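"""Dollo reconstruction: examples, exhaustive-oracle equality, the
simulation lower bound, overrides, and repertoire/ortholog statistics."""

import itertools

import numpy as np
import pytest

from famflux import (
    PhyloTree,
    ProteinRecord,
    SimParams,
    apply_override,
    dollo_reconstruct,
    load_species_tree,
    load_table1,
    ortholog_stats,
    repertoire_report,
    simulate_family,
)

from oracles import SimpleNode, all_topologies, dollo_bruteforce, random_topology


class TestDolloExamples:
    def test_all_present_gain_at_root_no_losses(self):
        tree = PhyloTree.from_newick("((A,B),(C,D));")
        recon = dollo_reconstruct(tree, {n: True for n in "ABCD"})
        assert recon.min_losses == 0
        assert recon.gain_node == recon.tree.node_label(recon.tree.tree.seed_node)

    def test_single_absent_leaf_single_pendant_loss(self):
        tree = PhyloTree.from_newick("((A,B),(C,D));")
        recon = dollo_reconstruct(tree, {"A": True, "B": False, "C": True, "D": True})
        assert recon.min_losses == 1
        assert recon.loss_edges == frozenset({"B"})

    def test_gain_at_mrca_of_present(self):
        tree = PhyloTree.from_newick("((A,B),(C,D));")
        recon = dollo_reconstruct(tree, {"A": True, "B": True, "C": False, "D": False})
        mrca = recon.tree.mrca(["A", "B"])
        assert recon.gain_node == recon.tree.node_label(mrca)
        assert recon.min_losses == 0

    def test_no_present_leaf_rejected(self):
        tree = PhyloTree.from_newick("((A,B),C);")
        with pytest.raises(ValueError, match="absent"):
            dollo_reconstruct(tree, {n: False for n in "ABC"})

    def test_unknown_species_rejected(self):
        tree = PhyloTree.from_newick("((A,B),C);")
        with pytest.raises(ValueError, match="non-leaf"):
            dollo_reconstruct(tree, {"A": True, "Z": True})

    def test_invariant_under_leaf_reordering_and_lengths(self):
        pres = {"A": True, "B": False, "C": True, "D": False, "E": True}
        t1 = PhyloTree.from_newick("(((A,B),(C,D)),E);")
        t2 = PhyloTree.from_newick("(E,((D:9,C:1),(B:2,A:7)));")
        r1 = dollo_reconstruct(t1, pres)
        r2 = dollo_reconstruct(t2, pres)
        assert r1.min_losses == r2.min_losses
        # loss edges land on the same pendant leaves
        assert {e for e in r1.loss_edges if e in "ABCDE"} == {
            e for e in r2.loss_edges if e in "ABCDE"
        }


def _recon_from_simple(root: SimpleNode, presence):
    tree = PhyloTree.from_newick(root.to_newick() + ";")
    return dollo_reconstruct(tree, presence)


class TestDolloOracle:
    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_exhaustive_topologies_and_patterns(self, n):
        """On every rooted topology and every non-empty presence pattern the
        reconstruction matches the enumeration oracle exactly."""
        leaves = [f"L{i}" for i in range(n)]
        for topo in all_topologies(leaves):
            for bits in itertools.product((0, 1), repeat=n):
                if not any(bits):
                    continue
                presence = dict(zip(leaves, map(bool, bits)))
                expected = dollo_bruteforce(topo, presence)
                got = _recon_from_simple(topo, presence)
                assert got.min_losses == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_random_eight_leaf_trees_all_patterns(self, seed):
        rng = np.random.default_rng(seed)
        leaves = [f"L{i}" for i in range(8)]
        topo = random_topology(leaves, rng)
        for bits in itertools.product((0, 1), repeat=8):
            if not any(bits):
                continue
            presence = dict(zip(leaves, map(bool, bits)))
            assert (
                _recon_from_simple(topo, presence).min_losses
                == dollo_bruteforce(topo, presence)
            )


class TestDolloOnSimulations:
    @pytest.mark.parametrize("seed", range(15))
    def test_min_losses_bounds_true_loss_count(self, tree6, seed):
        """Dollo is a lower bound on the simulated loss count; equality
        holds when no branch mixes duplications with total loss (the
        cancellation that hides events from presence/absence data)."""
        truth = simulate_family(
            tree6, SimParams(0.4, 0.5, n0=1, seq_len_aa=40, seed=seed)
        )
        presence = {
            sp: truth.counts.count(sp, "fam1") >= 1 for sp in truth.counts.species
        }
        if not any(presence.values()):
            return  # family extinct: nothing to reconstruct
        recon = dollo_reconstruct(truth.species_tree, presence)
        assert recon.min_losses <= truth.n_losses


class TestOverride:
    def _recon(self):
        tree = PhyloTree.from_newick("(((A,B)ab,C)abc,(D,E)de)r;")
        return dollo_reconstruct(
            tree, {"A": True, "B": True, "C": False, "D": False, "E": False}
        )

    def test_identity_override_is_noop(self):
        recon = self._recon()
        again = apply_override(recon, recon.gain_node)
        assert again.min_losses == recon.min_losses
        assert again.loss_edges == recon.loss_edges
        assert again.override_delta == 0

    def test_rootward_override_exposes_absent_sisters(self):
        recon = self._recon()
        assert recon.gain_node == "ab" and recon.min_losses == 0
        up = apply_override(recon, "abc")
        assert up.min_losses == 1 and up.loss_edges == frozenset({"C"})
        top = apply_override(recon, "r")
        assert top.min_losses == 2
        assert top.loss_edges == frozenset({"C", "de"})
        assert top.override_of == "ab" and top.override_delta == 2

    def test_non_ancestor_override_rejected(self):
        recon = self._recon()
        with pytest.raises(ValueError, match="ancestor"):
            apply_override(recon, "de")


class TestOrthologStats:
    def test_self_comparison_is_all_100(self):
        recs = [
            ProteinRecord("a", "Lec", "MKTAYEWLLNQRSTVDDEHH" * 3),
            ProteinRecord("b", "Lec", "MAGAYEWLLNQRSTVDDEHH" * 3),
        ]
        stats = ortholog_stats(recs, recs)
        assert stats.identities == [100.0, 100.0]
        assert stats.mean == 100.0 and stats.mean_rounded == 100

    def test_range_and_mean_arithmetic(self):
        base = "MKTAYEWLLN" * 10
        mutated = list(base)
        for i in range(1, 20, 2):  # 10 substitutions in 100 -> 90%
            mutated[i] = "G" if base[i] != "G" else "A"
        q1 = ProteinRecord("q1", "Lec", base)
        q2 = ProteinRecord("q2", "Lec", "".join(mutated))
        t = ProteinRecord("t", "Lf", base)
        stats = ortholog_stats([q1, q2], [t])
        assert stats.identities == [100.0, 90.0]
        assert (stats.min, stats.max) == (90.0, 100.0)
        assert stats.mean == 95.0

    def test_empty_sets_rejected(self):
        rec = ProteinRecord("a", "Lec", "MKT")
        with pytest.raises(ValueError):
            ortholog_stats([], [rec])
        with pytest.raises(ValueError):
            ortholog_stats([rec], [])


class TestRepertoireReport:
    def test_arctic_vs_sea_lamprey_is_plus_59(self):
        rep = repertoire_report(load_table1(), pairs=[("Lec", "Pm")])
        assert rep.pct_diff("tarl", "Lec", "Pm") == 59

    def test_equal_counts_zero_percent(self):
        rep = repertoire_report(load_table1(), pairs=[("Cm", "Le")])
        assert rep.pct_diff("tarl", "Cm", "Le") == 0

    def test_zero_denominator_is_undefined(self):
        rep = repertoire_report(load_table1(), pairs=[("Lec", "Nc")])
        assert rep.pct_diff("tarl", "Lec", "Nc") is None

    def test_presence_totals(self):
        rep = repertoire_report(load_table1())
        t1 = load_table1()
        assert rep.presence_totals["tarl"] == sum(
            1 for s in t1.species if t1.count(s, "tarl") >= 1
        )


class TestPaperScaleReconstruction:
    def test_taar13_losses_in_percomorphaceae_at_least_six(self):
        """Scattered taar13 presence in the Percomorphaceae subtree forces
        at least six independent losses under Dollo parsimony."""
        tree = load_species_tree().extract_clade("Percomorphaceae")
        t1 = load_table1()
        presence = {
            sp: v for sp, v in t1.presence("taar13").items() if sp in set(tree.leaf_names)
        }
        recon = dollo_reconstruct(tree, presence, family="taar13")
        assert recon.min_losses >= 6

    def test_taar12_lost_once_in_euteleosteomorpha(self):
        """taar12 is absent from every euteleosteomorphan species: the whole
        clade accounts for a single loss edge on the full tree."""
        tree = load_species_tree()
        recon = dollo_reconstruct(tree, load_table1(), family="taar12")
        assert "Euteleosteomorpha" in recon.loss_edges
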