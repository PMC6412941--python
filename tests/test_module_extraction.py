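import math

import numpy as np
import pytest

from modnmf.io_formats import GeneSetCollection
from modnmf.joint_nmf import JointFactorization
from modnmf.module_extraction import (assign_members, collect_edges,
                                      screen_functional, zscore_normalize,
                                      Module, ModuleSet)
from modnmf.preprocess import BinaryRelationMatrix


def _fact(W, Hs, mrna_ids, entity_ids, layers=("circRNA", "miRNA", "pathway")):
    W = np.asarray(W, float)
    return JointFactorization(
        W=W, H=[np.asarray(h, float) for h in Hs], K=W.shape[1],
        objective_trace=[0.0], restart_seed=0, mrna_ids=list(mrna_ids),
        entity_ids=[list(e) for e in entity_ids], layers=list(layers))


class TestZscore:
    def test_simple_column(self):
        f = _fact([[1], [2], [3]], [[[1.0]]], ["a", "b", "c"], [["c1"]],
                  ["circRNA"])
        Zw, _ = zscore_normalize(f)
        np.testing.assert_allclose(Zw[:, 0], [-1, 0, 1])

    def test_constant_column_gives_zeros(self):
        f = _fact([[2], [2], [2]], [[[1.0]]], ["a", "b", "c"], [["c1"]],
                  ["circRNA"])
        Zw, _ = zscore_normalize(f)
        np.testing.assert_array_equal(Zw[:, 0], 0.0)

    def test_columns_centered(self, rng):
        W = rng.random((20, 3))
        H = [rng.random((3, n)) for n in (5, 4, 3)]
        f = _fact(W, H, [f"g{i}" for i in range(20)],
                  [[f"e{i}" for i in range(n)] for n in (5, 4, 3)])
        Zw, Zh = zscore_normalize(f)
        np.testing.assert_allclose(Zw.mean(axis=0), 0.0, atol=1e-12)
        for z in Zh:
            np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)


def _toy_fact_and_annotation():
    """20 mRNAs, one component; g00..g04 carry the top weights."""
    M = 20
    mrna = [f"g{i:02d}" for i in range(M)]
    w = np.linspace(2.0, 0.1, M)[:, None]
    circ = ["c0", "c1"]
    mirna = ["m0"]
    path = ["p0"]
    f = _fact(w, [np.array([[3.0, 1.0]]), np.array([[1.0]]),
                  np.array([[1.0]])], mrna, [circ, mirna, path])
    ann = GeneSetCollection(sets={
        "T1": {"g00", "g01", "g02"},
        "T2": {"g00", "g01", "g03"},
        "T3": {"g15", "g16", "g17"},
    })
    return f, ann


class TestAssignMembers:
    def test_member_counts_are_ceil_of_percent(self):
        f, ann = _toy_fact_and_annotation()
        mods = assign_members(f, ann)
        mod = mods.modules[0]
        k = mod.chosen_top_percent
        assert len(mod.members["mRNA"]) == max(1, math.ceil(k / 100 * 20))
        assert len(mod.members["circRNA"]) == 1  # ceil of k% of 2, min 1

    def test_tie_chooses_smaller_percent(self):
        # every percent <= 10 of 20 mRNAs yields the same term count,
        # so the tie rule must pick 1%
        M = 20
        mrna = [f"g{i:02d}" for i in range(M)]
        f = _fact(np.linspace(2.0, 0.1, M)[:, None],
                  [np.array([[1.0]])] * 3, mrna, [["c"], ["m"], ["p"]])
        ann = GeneSetCollection(sets={"T": {"g00", "g10", "g11"}})
        mods = assign_members(f, ann)
        assert mods.modules[0].chosen_top_percent == 1

    def test_deterministic_given_inputs(self):
        f, ann = _toy_fact_and_annotation()
        a = assign_members(f, ann)
        b = assign_members(f, ann)
        assert [m.members for m in a.modules] == [m.members for m in b.modules]

    def test_rank_ties_broken_lexicographically(self):
        mrna = ["b", "a", "c", "d"]
        f = _fact(np.array([[1.0], [1.0], [1.0], [0.0]]),
                  [np.array([[1.0]])] * 3, mrna, [["c"], ["m"], ["p"]])
        ann = GeneSetCollection(sets={"T": {"a", "b", "c"}})
        mods = assign_members(f, ann, percents=range(50, 51))
        assert [m for m, _ in mods.modules[0].members["mRNA"]] == ["a", "b"]

    def test_empty_annotation_is_error(self):
        f, _ = _toy_fact_and_annotation()
        with pytest.raises(ValueError, match="annotation"):
            assign_members(f, GeneSetCollection(sets={}))

    def test_planted_module_recovered(self, planted_fit):
        from modnmf.synthetic_data import generate_annotation
        fact, truth = planted_fit
        ann = generate_annotation(truth, seed=12)
        mods = assign_members(fact, ann)
        blocks = [set(b) for b in truth.mrna_blocks]
        for mod in mods.modules:
            members = mod.member_ids("mRNA")
            best = max(len(members & b) for b in blocks)
            assert best >= 27


class TestCollectEdges:
    @staticmethod
    def _mods(members_by_kind):
        mod = Module(index=0, members=members_by_kind, chosen_top_percent=10)
        return ModuleSet(modules=[mod], universe={})

    def test_direct_count(self):
        x1 = BinaryRelationMatrix(["c1"], ["g1", "g2", "g3", "g4"],
                                  np.array([[1.0, 1, 1, 0]]), "circRNA")
        mods = self._mods({"mRNA": [("g1", 0), ("g2", 0), ("g3", 0)],
                           "circRNA": [("c1", 0)], "miRNA": [], "pathway": []})
        collect_edges(mods, [x1])
        mod = mods.modules[0]
        assert sorted(mod.edges) == [("c1", "g1"), ("c1", "g2"), ("c1", "g3")]
        n_nodes = sum(len(v) for v in mod.members.values())
        assert n_nodes == 4

    def test_links_to_non_members_do_not_count(self):
        x1 = BinaryRelationMatrix(["c1"], ["g1", "g2"],
                                  np.array([[1.0, 1]]), "circRNA")
        mods = self._mods({"mRNA": [("g9", 0)], "circRNA": [("c1", 0)],
                           "miRNA": [], "pathway": []})
        collect_edges(mods, [x1])
        assert mods.modules[0].edges == []

    def test_two_module_hand_enumeration(self, rng):
        cols = [f"g{i}" for i in range(6)]
        x1 = BinaryRelationMatrix(
            ["c1", "c2"], cols,
            (rng.random((2, 6)) < 0.5).astype(float), "circRNA")
        x2 = BinaryRelationMatrix(
            ["m1"], cols, (rng.random((1, 6)) < 0.5).astype(float), "miRNA")
        mods = ModuleSet(modules=[
            Module(0, {"mRNA": [(g, 0) for g in cols[:3]],
                       "circRNA": [("c1", 0)], "miRNA": [("m1", 0)],
                       "pathway": []}, 10),
            Module(1, {"mRNA": [(g, 0) for g in cols[3:]],
                       "circRNA": [("c2", 0)], "miRNA": [], "pathway": []}, 10),
        ], universe={})
        collect_edges(mods, [x1, x2])
        for mod, ents in zip(mods.modules, (["c1", "m1"], ["c2"])):
            expected = []
            for x in (x1, x2):
                for e in ents:
                    if e not in x.row_ids:
                        continue
                    i = x.row_ids.index(e)
                    for j, g in enumerate(cols):
                        if x.cells[i, j] == 1 and (g, 0) in mod.members["mRNA"]:
                            expected.append((e, g))
            assert sorted(mod.edges) == sorted(expected)


class TestFunctionalScreen:
    @staticmethod
    def _module_with_terms(n_sig):
        from modnmf.enrichment import EnrichmentResult
        terms = [EnrichmentResult(f"T{i}", 3, 5, 10, 100, 1e-6, 1e-4)
                 for i in range(n_sig)]
        terms += [EnrichmentResult("NS", 1, 5, 10, 100, 0.5, 0.9)]
        return Module(0, {"mRNA": [], "circRNA": [], "miRNA": [],
                          "pathway": []}, 10, enriched_terms=terms)

    @pytest.mark.parametrize("n_sig,expected", [(11, True), (10, False)])
    def test_strictly_more_than_ten(self, n_sig, expected):
        mods = ModuleSet(modules=[self._module_with_terms(n_sig)], universe={})
        screen_functional(mods, min_terms=10)
        assert mods.modules[0].is_functional is expected

    def test_no_functional_modules_propagates_empty(self):
        from modnmf.scoring import prioritize_candidates
        mods = ModuleSet(modules=[self._module_with_terms(2)], universe={})
        screen_functional(mods, min_terms=10)
        assert mods.functional == []
        assert prioritize_candidates(mods, [], [], set(), set()) == []
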