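import numpy as np
import pytest

from modnmf.io_formats import EdgeList, ExpressionMatrix
from modnmf.preprocess import (align_common_mrnas, coexpression_edges,
                               degree_filter, differential_screen,
                               expressed_fraction_filter, expand_columns,
                               BinaryRelationMatrix)
from modnmf.synthetic_data import generate_expression

from _oracles import pearson_r


def _expr(values, n_case, feature_ids=None):
    values = np.asarray(values, float)
    n = values.shape[1]
    samples = [f"s{i}" for i in range(n)]
    groups = {s: ("case" if i < n_case else "control")
              for i, s in enumerate(samples)}
    return ExpressionMatrix(
        feature_ids=feature_ids or [f"f{i}" for i in range(values.shape[0])],
        sample_ids=samples, values=values, group_of=groups)


class TestExpressedFraction:
    def test_strictly_more_than_half(self):
        vals = np.zeros((3, 10))
        vals[0, :6] = 1.0   # 6/10 -> retained
        vals[1, :5] = 1.0   # 5/10 -> dropped (strict >)
        m = _expr(vals, 5)
        assert expressed_fraction_filter(m, 0.5) == ["f0"]

    def test_all_zero_feature_dropped(self):
        m = _expr(np.zeros((1, 4)), 2)
        assert expressed_fraction_filter(m, 0.5) == []


class TestDifferentialScreen:
    def test_fold_change_arithmetic(self):
        m = _expr([[4, 4, 1, 1]], 2)
        r = differential_screen(m, pseudocount=0.0)[0]
        assert r.fold_change == pytest.approx(4.0)
        assert r.passed

    def test_intermediate_fc_fails_both_bounds(self):
        m = _expr([[1.5, 1.5, 1.0, 1.0]], 2)
        r = differential_screen(m, pseudocount=0.0)[0]
        assert r.fold_change == pytest.approx(1.5)
        assert not r.passed

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            _expr([[1, 2]], 0)

    def test_invariant_to_sample_permutation(self, rng):
        m, _ = generate_expression(30, n_case=6, n_control=7, n_de=10, seed=3)
        perm = rng.permutation(len(m.sample_ids))
        shuffled = ExpressionMatrix(
            feature_ids=m.feature_ids,
            sample_ids=[m.sample_ids[i] for i in perm],
            values=m.values[:, perm], group_of=m.group_of)
        a = differential_screen(m, p_cut=0.05)
        b = differential_screen(shuffled, p_cut=0.05)
        assert [(r.feature_id, r.passed) for r in a] == \
            [(r.feature_id, r.passed) for r in b]
        for ra, rb in zip(a, b):
            assert ra.fold_change == pytest.approx(rb.fold_change, rel=1e-12)
            assert ra.p_value == pytest.approx(rb.p_value, rel=1e-9)

    def test_null_features_rarely_pass_p_screen(self):
        # 100 null features at p_cut 0.005: expect about 100 * 0.005 passes
        m, _ = generate_expression(100, n_de=0, seed=42, noise_sd=1.0)
        res = differential_screen(m, p_cut=0.005, fc_low=1.0 - 1e-12,
                                  fc_high=1.0)  # FC gate always open
        assert sum(r.p_value < 0.005 for r in res) <= 3


class TestCoexpression:
    def test_identical_vector_retained_with_r_one(self):
        c = _expr([[1, 2, 3, 4, 5]], 2, ["circ1"])
        g = _expr([[1, 2, 3, 4, 5]], 2, ["g1"])
        (edge,) = coexpression_edges(c, g)
        assert edge.pcc == pytest.approx(1.0)

    def test_anticorrelated_pair_dropped(self):
        c = _expr([[5, 4, 3, 2, 1]], 2, ["circ1"])
        g = _expr([[1, 2, 3, 4, 5]], 2, ["g1"])
        assert coexpression_edges(c, g) == []

    def test_r_matches_definition_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        c = _expr([x], 2, ["circ1"])
        g = _expr([y], 2, ["g1"])
        edges = coexpression_edges(c, g, pcc_cut=0.0, p_cut=1.0)
        assert edges[0].pcc == pytest.approx(pearson_r(x, y), abs=1e-12)

    def test_constant_feature_skipped_not_zero(self):
        c = _expr([[2, 2, 2, 2, 2]], 2, ["circ1"])
        g = _expr([[1, 2, 3, 4, 5]], 2, ["g1"])
        assert coexpression_edges(c, g, pcc_cut=-1.0, p_cut=1.0) == []

    def test_mismatched_samples_is_error(self):
        c = _expr([[1, 2, 3]], 1, ["c"])
        g = _expr([[1, 2, 3, 4]], 2, ["g"])
        with pytest.raises(ValueError, match="sample"):
            coexpression_edges(c, g)

    def test_raising_cut_shrinks_edge_set(self, rng):
        c = _expr(rng.random((5, 12)), 6)
        g = _expr(rng.random((8, 12)), 6, [f"g{i}" for i in range(8)])
        loose = {(e.circ_id, e.mrna_id)
                 for e in coexpression_edges(c, g, 0.1, 1.0)}
        tight = {(e.circ_id, e.mrna_id)
                 for e in coexpression_edges(c, g, 0.5, 1.0)}
        assert tight <= loose

    def test_permutation_p_agrees_with_t_on_strong_signal(self):
        c = _expr([[1, 2, 3, 4, 5, 6]], 3, ["c"])
        g = _expr([[1.1, 2.2, 2.9, 4.2, 5.1, 5.8]], 3, ["g"])
        (t_edge,) = coexpression_edges(c, g, method="t")
        (p_edge,) = coexpression_edges(c, g, method="permutation")
        assert p_edge.p_value < 0.05 and t_edge.p_value < 0.05


class TestDegreeFilter:
    def _edges(self, degrees):
        pairs = {(f"c{i}", f"g{j}") for j, d in enumerate(degrees)
                 for i in range(d)}
        return EdgeList(pairs=pairs, source_kind="circRNA")

    def test_more_than_three_boundary(self):
        x = degree_filter(self._edges([4, 3]), min_degree=4)
        assert x.col_ids == ["g0"]

    def test_toy_degrees_hand_enumeration(self):
        # degrees (1,2,3,4,5): exactly the two columns with degree > 3 remain
        x = degree_filter(self._edges([1, 2, 3, 4, 5]), min_degree=4)
        assert x.col_ids == ["g3", "g4"]
        assert x.cells.sum(axis=0).tolist() == [4, 5]

    def test_all_columns_removed_is_error(self):
        with pytest.raises(ValueError, match="no mRNAs survive"):
            degree_filter(self._edges([1, 1]), min_degree=4)


def _brm(rows, cols, cells, layer="circRNA"):
    return BinaryRelationMatrix(rows, cols, np.asarray(cells, float), layer)


class TestAlign:
    def test_intersection_axis(self):
        x1 = _brm(["c"], ["a", "b", "c"], [[1, 1, 1]])
        x2 = _brm(["m"], ["b", "c", "d"], [[1, 1, 1]], "miRNA")
        x3 = _brm(["p"], ["b", "c"], [[1, 1]], "pathway")
        a1, a2, a3 = align_common_mrnas(x1, x2, x3)
        assert a1.col_ids == a2.col_ids == a3.col_ids == ["b", "c"]

    def test_identical_columns_canonical_order(self):
        x1 = _brm(["c"], ["b", "a"], [[1, 1]])
        x2 = _brm(["m"], ["a", "b"], [[1, 1]], "miRNA")
        x3 = _brm(["p"], ["b", "a"], [[0, 1]], "pathway")
        a1, _, _ = align_common_mrnas(x1, x2, x3)
        assert a1.col_ids == ["a", "b"]

    def test_all_zero_row_dropped(self):
        x1 = _brm(["c1", "c2"], ["a", "z"], [[1, 0], [0, 1]])
        x2 = _brm(["m"], ["a"], [[1]], "miRNA")
        x3 = _brm(["p"], ["a"], [[1]], "pathway")
        a1, _, _ = align_common_mrnas(x1, x2, x3)
        assert a1.row_ids == ["c1"]

    def test_empty_intersection_is_error(self):
        x1 = _brm(["c"], ["a"], [[1]])
        x2 = _brm(["m"], ["b"], [[1]], "miRNA")
        x3 = _brm(["p"], ["a"], [[1]], "pathway")
        with pytest.raises(ValueError, match="intersection"):
            align_common_mrnas(x1, x2, x3)


def test_expand_columns_zero_fills():
    x = _brm(["c"], ["b"], [[1]])
    e = expand_columns(x, ["a", "b", "c"])
    assert e.col_ids == ["a", "b", "c"]
    assert e.cells.tolist() == [[0, 1, 0]]
    with pytest.raises(ValueError, match="outside the universe"):
        expand_columns(x, ["a"])
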