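"""Distance corrections, neighbor joining, ME refinement, bootstrap."""

import itertools

import dendropy
import numpy as np
import pytest

from modevoprof import (
    DistanceMatrix,
    PhyloTree,
    ProteinAlignment,
    bootstrap_support,
    me_nni_refine,
    nj_tree,
    ols_branch_lengths,
    pairwise_distances,
    same_topology,
)
from modevoprof.errors import CoverageError, SaturationError, TreeShapeError
from modevoprof.simulate import random_tree
from oracles import additive_distances, all_unrooted_topologies, ols_total_length


class TestDistances:
    def test_identical_sequences_zero(self):
        aln = ProteinAlignment(("a", "b"), ("MKVA", "MKVA"))
        for model in ("p", "poisson", "gamma"):
            D = pairwise_distances(aln, model=model)
            assert D.d[0, 1] == 0.0

    def test_poisson_half(self):
        aln = ProteinAlignment(("a", "b"), ("MKVA", "MKLS"))  # p = 0.5
        D = pairwise_distances(aln, model="poisson")
        assert D.d[0, 1] == pytest.approx(np.log(2), abs=1e-12)

    def test_gamma_alpha_one_half(self):
        aln = ProteinAlignment(("a", "b"), ("MKVA", "MKLS"))
        D = pairwise_distances(aln, model="gamma", alpha=1.0)
        assert D.d[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_pairwise_deletion_skips_gap_and_x(self):
        aln = ProteinAlignment(("a", "b"), ("MK-AX", "MKVAS"))
        D = pairwise_distances(aln, model="p")
        assert D.d[0, 1] == 0.0  # only 3 shared residue columns, all equal

    def test_saturation_names_pair(self):
        aln = ProteinAlignment(("sat1", "sat2"), ("MK", "VA"))
        with pytest.raises(SaturationError, match="sat1.*sat2"):
            pairwise_distances(aln, model="poisson")

    def test_no_shared_columns(self):
        aln = ProteinAlignment(("a", "b"), ("MK--", "--VA"))
        with pytest.raises(CoverageError):
            pairwise_distances(aln, model="p")

    def test_gamma_converges_to_poisson(self):
        aln = ProteinAlignment(("a", "b"), ("MKVA", "MKLS"))
        dg = pairwise_distances(aln, model="gamma", alpha=1e6).d[0, 1]
        dp = pairwise_distances(aln, model="poisson").d[0, 1]
        assert dg == pytest.approx(dp, abs=1e-4)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ("A", "B", "C")
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(ids, d, "p"))
        lengths = {n.label: n.length for n in t.leaves()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_too_few_taxa(self):
        with pytest.raises(TreeShapeError):
            nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2)), "p"))

    def test_additive_recovery_and_dendropy_agreement(self, rng):
        for _ in range(10):
            t = random_tree(rng, 6, 3.0)
            labels, d = additive_distances(t)
            D = DistanceMatrix(tuple(labels), d, "p")
            ours = nj_tree(D)
            assert same_topology(ours, t)
            # independent implementation: dendropy NJ
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=_csv(labels, d), delimiter=","
            )
            dt = pdm.nj_tree()
            theirs = PhyloTree.from_newick(
                dt.as_string(schema="newick").replace("[&U]", "").strip()
            )
            assert same_topology(ours, theirs)

    def test_equal_distances_total_length(self):
        # any resolution is acceptable; OLS total length is 2d for all
        # three quartet topologies, which NJ must match
        ids = tuple("ABCD")
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        t = nj_tree(DistanceMatrix(ids, d, "p"))
        assert t.total_length() == pytest.approx(4.0)
        for topo in all_unrooted_topologies(ids):
            assert ols_total_length(topo, list(ids), d) == pytest.approx(4.0)


def _csv(labels, d):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(str(x) for x in d[i]) + "\n")
    buf.seek(0)
    return buf


class TestMERefinement:
    def test_additive_input_is_fixed_point(self, rng):
        t = random_tree(rng, 6, 3.0)
        labels, d = additive_distances(t)
        D = DistanceMatrix(tuple(labels), d, "p")
        start = nj_tree(D)
        refined = me_nni_refine(start, D)
        assert same_topology(refined, start)

    def test_swapped_cherry_restored_vs_exhaustive(self, rng):
        for _ in range(5):
            true = random_tree(rng, 5, 2.5)
            labels, d = additive_distances(true)
            D = DistanceMatrix(tuple(labels), d, "p")
            # search all 15 unrooted 5-leaf topologies for the OLS optimum
            best = min(
                all_unrooted_topologies(labels),
                key=lambda t: ols_total_length(t, labels, d),
            )
            assert same_topology(best, true)
            # start from a deliberately wrong topology
            for wrong in all_unrooted_topologies(labels):
                if not same_topology(wrong, true):
                    break
            refined = me_nni_refine(wrong, D)
            assert same_topology(refined, true)

    def test_refinement_never_increases_ols_length(self, rng):
        t = random_tree(rng, 7, 3.0)
        labels, d = additive_distances(t)
        d_noisy = d + rng.normal(0, 0.05, d.shape)
        d_noisy = np.abs((d_noisy + d_noisy.T) / 2)
        np.fill_diagonal(d_noisy, 0)
        D = DistanceMatrix(tuple(labels), d_noisy, "p")
        start = nj_tree(D)
        _, len0 = ols_branch_lengths(start, D)
        refined = me_nni_refine(start, D)
        _, len1 = ols_branch_lengths(refined, D)
        assert len1 <= len0 + 1e-9

    def test_nonbinary_rejected(self):
        t = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        ids = tuple("ABCD")
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0)
        with pytest.raises(TreeShapeError):
            me_nni_refine(t, DistanceMatrix(ids, d, "p"))


def _simulated_quartet(seed=2):
    from modevoprof import SimConfig, simulate_family

    tree = PhyloTree.from_newick("((A:0.05,B:0.05):0.5,(C:0.05,D:0.05):0.5);")
    flat = {k: 1.0 for k in
            ["SP", "WAP", "FS", "K", "IGc2", "KU1", "KU2", "NTR", "linker"]}
    cfg = SimConfig(seed=seed, tree=tree, duplication=None, p_inv=0.0,
                    rate_multipliers=flat, subfamily_multipliers={})
    return simulate_family(cfg).alignment


class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_hundred(self):
        aln = _simulated_quartet()
        t = bootstrap_support(aln, n_reps=1, seed=5)
        sups = [n.support for n in t.edges() if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_same_seed_reproducible(self):
        aln = _simulated_quartet()
        t1 = bootstrap_support(aln, n_reps=20, seed=9)
        t2 = bootstrap_support(aln, n_reps=20, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_invariant_to_taxon_order(self):
        aln = _simulated_quartet()
        perm = ProteinAlignment(
            tuple(reversed(aln.ids)), tuple(reversed(aln.rows))
        )
        def support_map(t):
            ls = t.leafset_map()
            full = frozenset(t.leaf_labels())
            return {
                frozenset([ls[id(n)], full - ls[id(n)]]): n.support
                for n in t.edges()
                if n.support is not None
            }
        s1 = support_map(bootstrap_support(aln, n_reps=50, seed=3))
        s2 = support_map(bootstrap_support(perm, n_reps=50, seed=3))
        assert s1 == s2
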