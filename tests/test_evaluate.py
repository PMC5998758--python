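"""Pairwise profiling, gold-standard validation, group-median
thresholds, and similar-pair selection."""

import numpy as np
import pandas as pd
import pytest

from coexsim import (
    GoldStandard,
    SimilarityMatrix,
    WeightedNetwork,
    evaluate_threshold,
    group_medians,
    pairwise_matrix,
    select_similar_pairs,
    spearman_profile,
    spearman_validation,
)
from conftest import make_random_network


def _sm(mat, rows, cols=None, name=""):
    return SimilarityMatrix(
        values=pd.DataFrame(mat, index=rows, columns=cols or rows), measure_name=name
    )


class TestPairwiseMatrix:
    def test_identical_networks_all_ones(self):
        a = make_random_network(0, "a")
        b = a.copy("b")
        m = pairwise_matrix([a, b], measure="coexsim")
        assert (m.values.to_numpy() == 1.0).all()

    def test_disjoint_networks_identity_matrix(self):
        nets = []
        for i in range(3):
            nodes = {f"n{i}_{j}" for j in range(4)}
            lo, hi = sorted(nodes)[:2]
            nets.append(WeightedNetwork(f"net{i}", nodes, {(lo, hi): 0.5}))
        m = pairwise_matrix(nets, measure="fuzzy")
        assert np.array_equal(m.values.to_numpy(), np.eye(3))

    def test_full_matrix_shape_counts_both_orientations(self):
        nets = [make_random_network(s, f"n{s}", n_nodes=12) for s in range(4)]
        m = pairwise_matrix(nets, measure="coexsim")
        assert m.values.size == 16  # 4 networks -> 16 network pairs
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_duplicate_labels_rejected(self):
        a = make_random_network(0, "same")
        b = make_random_network(1, "same")
        with pytest.raises(ValueError, match="duplicate"):
            pairwise_matrix([a, b])

    def test_single_network_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_matrix([make_random_network(0)])


class TestSpearmanValidation:
    def test_hand_ranked_example(self):
        rho, p = spearman_profile([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8, abs=1e-12)
        assert 0 < p <= 1

    def test_perfect_and_reversed(self):
        labels = list("abc")
        gold = GoldStandard(
            values=pd.DataFrame(
                [[1.0, 0.5, 0.2], [0.5, 1.0, 0.7], [0.2, 0.7, 1.0]],
                index=labels,
                columns=labels,
            )
        )
        prof = _sm(gold.values.to_numpy(), labels)
        rho, _ = spearman_validation(prof, gold)
        assert rho == pytest.approx(1.0)
        rev = _sm(1.0 - gold.values.to_numpy(), labels)
        rho, _ = spearman_validation(rev, gold)
        assert rho == pytest.approx(-1.0)

    def test_invariant_under_monotone_transform(self):
        labels = [f"l{i}" for i in range(5)]
        rng = np.random.default_rng(5)
        base = rng.random((5, 5))
        base = (base + base.T) / 2
        gold = GoldStandard(values=pd.DataFrame(base, index=labels, columns=labels))
        prof = _sm(np.exp(3 * base), labels)
        rho, _ = spearman_validation(prof, gold)
        assert rho == pytest.approx(1.0)

    def test_scopes_differ_in_count(self):
        labels = list("abcd")
        rng = np.random.default_rng(6)
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        gold = GoldStandard(values=pd.DataFrame(m, index=labels, columns=labels))
        prof = _sm(m**2, labels)
        for scope in ("full", "offdiag", "upper"):
            rho, _ = spearman_validation(prof, gold, pair_scope=scope)
            assert rho == pytest.approx(1.0)

    def test_constant_profile_rejected(self):
        labels = list("abc")
        gold = GoldStandard(values=pd.DataFrame(np.eye(3), index=labels, columns=labels))
        with pytest.raises(ValueError, match="constant"):
            spearman_validation(_sm(np.full((3, 3), 0.5), labels), gold)

    def test_label_mismatch_rejected(self):
        gold = GoldStandard(values=pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"]))
        with pytest.raises(ValueError, match="label sets"):
            spearman_validation(_sm(np.eye(2), ["a", "c"]), gold)


class TestGroupMedians:
    def test_partition_counts_5_member_group(self):
        labels = [f"n{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        v = rng.random((10, 10))
        m = _sm(v, labels)
        groups = {lab: ("sim" if i < 5 else "ctl") for i, lab in enumerate(labels)}
        members = [lab for lab in labels if groups[lab] == "sim"]
        block = m.values.loc[members, members].to_numpy()
        med_s, med_o = group_medians(m, groups, "sim")
        # 25 within values vs 75 others; medians match direct computation
        assert med_s == pytest.approx(np.median(block))
        rest = np.concatenate(
            [v[5:, :].ravel(), v[:5, 5:].ravel()]
        )
        assert med_o == pytest.approx(np.median(rest))

    def test_constant_block(self):
        labels = list("abcd")
        v = np.full((4, 4), 0.9)
        v[:2, :2] = 0.42
        med_s, _ = group_medians(_sm(v, labels), {"a": "g", "b": "g"}, "g")
        assert med_s == 0.42

    def test_even_count_midpoint(self):
        labels = list("abcd")
        v = np.zeros((4, 4))
        v[:2, :2] = [[1.0, 0.3], [0.3, 1.0]]
        med_s, _ = group_medians(_sm(v, labels), {"a": "g", "b": "g"}, "g")
        assert med_s == pytest.approx(0.65)

    def test_unknown_label_rejected(self):
        labels = list("ab")
        with pytest.raises(ValueError, match="unknown"):
            group_medians(_sm(np.eye(2), labels), {"a": "g", "zz": "g"}, "g")

    def test_single_member_group_rejected(self):
        labels = list("ab")
        with pytest.raises(ValueError, match=">= 2"):
            group_medians(_sm(np.eye(2), labels), {"a": "g"}, "g")


class TestThreshold:
    def test_mean_of_medians(self):
        assert evaluate_threshold(0.4, 0.2) == pytest.approx(0.3, abs=1e-12)
        assert evaluate_threshold(0.7, 0.7) == 0.7

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            evaluate_threshold(-0.1, 0.5)


class TestSelection:
    def _mats(self, c, f, rows, cols):
        return _sm(c, rows, cols, "coexsim"), _sm(f, rows, cols, "fuzzy")

    def test_rectangular_strict_selection(self):
        rows, cols = ["h1", "h2"], ["a1", "a2", "a3"]
        c = [[0.5, 0.13, 0.05], [0.1288, 0.4, 0.2]]
        f = [[0.03, 0.006, 0.01], [0.9, 0.004, 0.0055]]
        cm, fm = self._mats(c, f, rows, cols)
        sel = select_similar_pairs(cm, fm, 0.1288, 0.0055)
        # (h2,a1) fails coexsim strictly; (h2,a3) fails fuzzy strictly;
        # (h2,a2) fails fuzzy; (h1,a2) passes both; (h1,a1) passes
        assert sel.pairs == [
            ("h1", "a1", 0.5, 0.03),
            ("h1", "a2", 0.13, 0.006),
        ]

    def test_sorted_by_coexsim_descending(self):
        rows, cols = ["h1", "h2"], ["a1"]
        cm, fm = self._mats([[0.2], [0.6]], [[0.1], [0.1]], rows, cols)
        sel = select_similar_pairs(cm, fm, 0.1, 0.01)
        assert [p[0] for p in sel.pairs] == ["h2", "h1"]

    def test_impossible_thresholds_select_nothing(self):
        rows, cols = ["h1"], ["a1"]
        cm, fm = self._mats([[1.0]], [[1.0]], rows, cols)
        assert len(select_similar_pairs(cm, fm, 1.1, 1.1)) == 0

    def test_square_matrix_skips_self_pairs(self):
        labels = ["a", "b"]
        cm, fm = self._mats([[1, 0.5], [0.5, 1]], [[1, 0.5], [0.5, 1]], labels, labels)
        sel = select_similar_pairs(cm, fm, 0.1, 0.1)
        assert sel.pairs == [("a", "b", 0.5, 0.5)]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        rows = [f"r{i}" for i in range(4)]
        cols = [f"c{i}" for i in range(3)]
        c, f = rng.random((4, 3)), rng.random((4, 3))
        cm, fm = self._mats(c, f, rows, cols)
        base = select_similar_pairs(cm, fm, 0.3, 0.3).pairs
        perm_r, perm_c = [2, 0, 3, 1], [1, 2, 0]
        cm2 = _sm(c[perm_r][:, perm_c], [rows[i] for i in perm_r], [cols[j] for j in perm_c])
        fm2 = _sm(f[perm_r][:, perm_c], [rows[i] for i in perm_r], [cols[j] for j in perm_c])
        assert select_similar_pairs(cm2, fm2, 0.3, 0.3).pairs == base

    def test_mismatched_labels_rejected(self):
        cm, _ = self._mats([[1.0]], [[1.0]], ["a"], ["x"])
        _, fm = self._mats([[1.0]], [[1.0]], ["b"], ["x"])
        with pytest.raises(ValueError, match="mismatched"):
            select_similar_pairs(cm, fm, 0.1, 0.1)
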