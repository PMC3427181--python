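"""Domain-architecture comparison and Dollo / Fitch gain-loss analysis."""

import itertools

import numpy as np
import pytest

from modevoprof import (
    ArchitectureMatrix,
    PhyloTree,
    compare_architectures,
    dollo_reconstruct,
    fitch_presence_changes,
    scenario_presence,
)
from modevoprof.errors import ReferenceIdError
from modevoprof.simulate import plant_domain_scenarios, random_tree

#: Deuterostome species topology: outgroups, then (ambulacraria, chordates)
DEUTEROSTOME = PhyloTree.from_newick(
    "((fly:1,worm:1):1,((sea_urchin:1,acorn_worm:1):1,"
    "((ciona_i:1,ciona_s:1):1,(amphioxus:1,(fish:1,mouse:1):1):1):1):1);"
)
LEAVES = tuple(DEUTEROSTOME.leaf_labels())


def arch(domain_presence: dict[str, list[str]]) -> ArchitectureMatrix:
    domains = tuple(domain_presence)
    pres = np.array(
        [[1 if sp in domain_presence[d] else 0 for d in domains] for sp in LEAVES],
        dtype=np.int8,
    )
    return ArchitectureMatrix(LEAVES, domains, pres)


class TestDollo:
    def test_domain_present_everywhere_gains_at_root(self):
        mat = arch({"WAP": list(LEAVES)})
        sc = dollo_reconstruct(mat, DEUTEROSTOME)["WAP"]
        assert sc.gain_clade == frozenset(LEAVES)
        assert sc.n_losses == 0

    def test_follistatin_gain_in_deuterostomes_with_sea_urchin_loss(self):
        # FS in acorn worm and all chordates, absent in sea urchin and
        # outgroups -> single gain at the deuterostome ancestor, one loss
        # on the sea-urchin edge
        chordates = ["ciona_i", "ciona_s", "amphioxus", "fish", "mouse"]
        mat = arch({"FS": ["acorn_worm"] + chordates})
        sc = dollo_reconstruct(mat, DEUTEROSTOME)["FS"]
        deuterostomes = frozenset(
            ["sea_urchin", "acorn_worm"] + chordates
        )
        assert sc.gain_clade == deuterostomes
        assert sc.loss_edges == (frozenset(["sea_urchin"]),)

    def test_igc2_single_loss_on_ciona_stem(self):
        mat = arch({"IGc2": [s for s in LEAVES if not s.startswith("ciona")]})
        sc = dollo_reconstruct(mat, DEUTEROSTOME)["IGc2"]
        assert sc.gain_clade == frozenset(LEAVES)
        assert sc.loss_edges == (frozenset(["ciona_i", "ciona_s"]),)

    def test_absent_everywhere_flagged(self):
        mat = arch({"NTR": []})
        sc = dollo_reconstruct(mat, DEUTEROSTOME)["NTR"]
        assert sc.gain_clade is None and sc.n_losses == 0

    def test_species_missing_from_tree(self):
        mat = ArchitectureMatrix(
            ("mouse", "yeti"), ("FS",), np.array([[1], [1]], dtype=np.int8)
        )
        with pytest.raises(ReferenceIdError):
            dollo_reconstruct(mat, DEUTEROSTOME)

    def test_replay_reproduces_arbitrary_rows(self, rng):
        """Dollo invariant: replaying (gain, losses) forward reproduces the
        observed presence row exactly, for any input pattern."""
        t = random_tree(rng, 8, 1.0)
        labels = tuple(t.leaf_labels())
        for _ in range(50):
            row = rng.integers(0, 2, size=8)
            if row.sum() == 0:
                continue
            mat = ArchitectureMatrix(
                labels, ("D",), row.reshape(-1, 1).astype(np.int8)
            )
            sc = dollo_reconstruct(mat, t)["D"]
            replay = scenario_presence(t, sc)
            assert [replay[lab] for lab in labels] == list(row)

    def test_planted_recovery(self, rng):
        for seed in range(30):
            t = random_tree(rng, 10, 1.0)
            mat, planted = plant_domain_scenarios(t, seed=seed, n_domains=3)
            rec = dollo_reconstruct(mat, t)
            for sc in planted:
                got = rec[sc.domain]
                assert got.gain_clade == sc.gain_clade
                assert set(got.loss_edges) == set(sc.loss_edges)


class TestFitch:
    def test_all_present_zero_changes(self):
        mat = arch({"WAP": list(LEAVES)})
        assert fitch_presence_changes(mat, DEUTEROSTOME)["WAP"] == 0

    def test_dollo_is_constrained_parsimony(self, rng):
        for seed in range(20):
            t = random_tree(rng, 8, 1.0)
            labels = tuple(t.leaf_labels())
            row = rng.integers(0, 2, size=8).astype(np.int8)
            if row.sum() == 0:
                continue
            mat = ArchitectureMatrix(labels, ("D",), row.reshape(-1, 1))
            dollo = dollo_reconstruct(mat, t)["D"]
            fitch = fitch_presence_changes(mat, t)["D"]
            assert dollo.n_losses + 1 >= fitch

    def test_matches_exhaustive_internal_labelings(self, rng):
        for _ in range(10):
            t = random_tree(rng, 8, 1.0)
            labels = tuple(sorted(t.leaf_labels()))
            row = rng.integers(0, 2, size=8).astype(np.int8)
            mat = ArchitectureMatrix(labels, ("D",), row.reshape(-1, 1))
            fitch = fitch_presence_changes(mat, t)["D"]
            state = dict(zip(labels, row))
            internals = [n for n in t.postorder() if not n.is_leaf]
            best = np.inf
            for assign in itertools.product((0, 1), repeat=len(internals)):
                s = {id(n): v for n, v in zip(internals, assign)}
                cost = 0
                for node in t.postorder():
                    if node.parent is None:
                        continue
                    v = state[node.label] if node.is_leaf else s[id(node)]
                    cost += v != s[id(node.parent)]
                best = min(best, cost)
            assert fitch == best


class TestCompare:
    def test_identical_rows(self):
        mat = arch({"FS": list(LEAVES), "WAP": list(LEAVES)})
        shared, only_a, only_b = compare_architectures(mat, "mouse", "fish")
        assert shared == {"FS", "WAP"} and not only_a and not only_b

    def test_vertebrate_vs_ciona(self):
        vertebrates = ["fish", "mouse"]
        everyone = list(LEAVES)
        mat = arch(
            {
                "WAP": everyone,
                "FS": everyone,
                "K": everyone,
                "IGc2": [s for s in everyone if not s.startswith("ciona")],
                "NTR": [s for s in everyone if not s.startswith("ciona")],
            }
        )
        shared, only_mouse, only_ciona = compare_architectures(
            mat, "mouse", "ciona_i"
        )
        assert only_mouse >= {"IGc2", "NTR"}
        assert not only_ciona

    def test_empty_vs_full(self):
        mat = arch({"FS": ["mouse"], "WAP": ["mouse"]})
        shared, only_a, only_b = compare_architectures(mat, "fly", "mouse")
        assert shared == set() and only_b == {"FS", "WAP"}
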