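"""Normalization, replicate QC and differential expression, checked
against independent oracles (rank-split enumeration for the exact
Wilcoxon null, a step-up oracle for Benjamini-Hochberg, pingouin for
the intraclass correlation)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from progenomix import de
from progenomix.io import ExpressionMatrix, SampleSheet


def _matrix(values, columns=None, scale="linear"):
    arr = np.asarray(values, dtype=float)
    cols = columns or [f"S{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"G{i}" for i in range(arr.shape[0])],
                     columns=cols),
        layer="protein", scale=scale)


def _sheet(groups: dict[str, list[str]], replicates=None):
    rows = []
    for g, ids in groups.items():
        for s in ids:
            rows.append({"sample_id": s, "group": g, "replicate_of": None})
    for orig, rep in (replicates or []):
        grp = next(g for g, ids in groups.items() if orig in ids)
        rows.append({"sample_id": rep, "group": grp, "replicate_of": orig})
    return SampleSheet(pd.DataFrame(rows))


class TestNormalize:
    def test_hand_computed_two_column_case(self):
        # log2 of {(1,4),(2,8)} is {(0,2),(1,3)}; sorted-column means are
        # (0.5, 2.5), which every column receives
        mat = _matrix([[1, 2], [4, 8]])
        out = de.normalize(mat)
        expected = np.array([[0.5, 0.5], [2.5, 2.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)
        assert out.scale == "log2"

    def test_identical_columns_unchanged_by_quantile_step(self):
        col = np.array([1.0, 4.0, 16.0])
        out = de.normalize(_matrix(np.stack([col, col, col], axis=1)))
        np.testing.assert_allclose(out.values.to_numpy(),
                                   np.log2(col)[:, None] * np.ones((1, 3)))

    def test_column_means_equalized(self):
        rng = np.random.default_rng(0)
        mat = _matrix(rng.lognormal(2, 1, size=(50, 6)))
        out = de.normalize(mat).values.to_numpy()
        np.testing.assert_allclose(out.mean(axis=0),
                                   out.mean(axis=0)[0] * np.ones(6))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="G1"):
            de.normalize(_matrix([[1, 2], [0, 3]]))


class TestReplicateICC:
    def test_perfect_replicate_gives_one(self):
        x = np.random.default_rng(1).normal(8, 2, 100)
        assert de.icc_oneway(x, x) == pytest.approx(1.0)

    def test_pure_noise_replicate_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 1000)
        y = rng.normal(0, 1, 1000)
        assert abs(de.icc_oneway(x, y)) < 0.1

    def test_anticorrelated_pair_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert de.icc_oneway(x, -x) < 0

    def test_matches_pingouin_oneway_single_icc(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.normal(8, 2, 40)
        y = x + rng.normal(0, 0.5, 40)
        data = pd.DataFrame({
            "targets": np.repeat(np.arange(40), 2),
            "raters": np.tile(["a", "b"], 40),
            "ratings": np.column_stack([x, y]).ravel()})
        ref = pingouin.intraclass_corr(data=data, targets="targets",
                                       raters="raters", ratings="ratings")
        icc1 = ref.loc[ref["Type"].str.startswith(("ICC1", "ICC(1,1")),
                       "ICC"].iloc[0]
        assert de.icc_oneway(x, y) == pytest.approx(icc1, abs=1e-9)


class TestPermutationTest:
    def test_identical_vectors_minimum_p(self):
        x = np.random.default_rng(4).normal(size=1000)
        p = de.replicate_permutation_test(x, x, n_perm=1000, seed=0)
        assert p == pytest.approx(1 / 1001)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=50), rng.normal(size=50)
        p1 = de.replicate_permutation_test(x, y, n_perm=200, seed=7)
        p2 = de.replicate_permutation_test(x, y, n_perm=200, seed=7)
        assert p1 == p2

    def test_independent_vectors_p_near_half_on_average(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(40):
            x, y = rng.normal(size=30), rng.normal(size=30)
            ps.append(de.replicate_permutation_test(x, y, n_perm=99,
                                                    seed=int(rng.integers(1e6))))
        assert abs(np.mean(ps) - 0.5) < 0.15

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            de.replicate_permutation_test(np.ones(10), np.arange(10.0))


class TestAverageReplicates:
    def test_mean_of_pair_and_passthrough(self):
        mat = _matrix([[2.0, 4.0, 7.0]], columns=["A", "A_r", "B"],
                      scale="log2")
        sheet = _sheet({"BPH": ["A", "B"]}, replicates=[("A", "A_r")])
        out = de.average_replicates(mat, sheet)
        assert list(out.values.columns) == ["A", "B"]
        assert out.values.loc["G0", "A"] == 3.0
        assert out.values.loc["G0", "B"] == 7.0


def _wilcoxon_enumeration_p(a, b):
    """Exact two-sided rank-sum p by enumerating all C(nA+nB, nA) rank
    assignments (tie-free inputs only)."""
    pooled = np.concatenate([a, b])
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in a)
    n = len(pooled)
    na = len(a)
    mean = na * (n + 1) / 2
    stats = [sum(combo) for combo in
             itertools.combinations(range(1, n + 1), na)]
    dev = abs(obs - mean)
    count = sum(1 for s in stats if abs(s - mean) >= dev - 1e-9)
    return count / len(stats)


class TestWilcoxon:
    def test_textbook_split_p(self):
        # groups {1,2,3} vs {4,5,6}: 2 of the 20 rank splits are at least
        # as extreme, p = 0.1
        p = de._wilcoxon_p(np.array([1., 2., 3.]), np.array([4., 5., 6.]))
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_equals_rank_split_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(3, 7)), int(rng.integers(3, 7))
        pooled = rng.permutation(np.arange(1.0, na + nb + 1))
        a, b = pooled[:na], pooled[na:]
        assert de._wilcoxon_p(a, b) == pytest.approx(
            _wilcoxon_enumeration_p(a, b), abs=1e-12)

    def test_constant_feature_p_one(self):
        assert de._wilcoxon_p(np.ones(5), np.ones(6)) == 1.0


def _bh_stepup_oracle(pvals):
    """Literal Benjamini-Hochberg step-up: find the largest k with
    p_(k) <= k/m * alpha for every alpha, i.e. adjusted p by min-of-tail
    of m*p_(i)/i."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                max_size=20))
def test_bh_adjustment_matches_stepup_oracle(pvals):
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(pvals, method="fdr_bh")[1]
    np.testing.assert_allclose(adj, _bh_stepup_oracle(np.array(pvals)),
                               atol=1e-12)


class TestDifferentialExpression:
    def _toy(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        ids_a = [f"A{i}" for i in range(6)]
        ids_b = [f"B{i}" for i in range(6)]
        vals = rng.normal(8, 1, size=(30, 12))
        vals[:10, :6] += shift
        mat = _matrix(vals, columns=ids_a + ids_b, scale="log2")
        return mat, _sheet({"PC": ids_a, "BPH": ids_b})

    def test_identical_groups_nothing_significant(self):
        mat, sheet = self._toy(shift=0.0)
        vals = mat.values.copy()
        vals[vals.columns[:6]] = vals[vals.columns[6:]].to_numpy()
        mat = ExpressionMatrix(vals, layer="protein", scale="log2")
        res = de.differential_expression(mat, sheet, "PC", "BPH")
        assert de.significant_features(res) == set()

    def test_swap_inverts_ratio_and_keeps_p(self):
        mat, sheet = self._toy(seed=1, shift=2.0)
        fwd = de.differential_expression(mat, sheet, "PC", "BPH")
        rev = de.differential_expression(mat, sheet, "BPH", "PC")
        for f, r in zip(fwd, rev):
            assert f.median_ratio == pytest.approx(1 / r.median_ratio)
            assert f.p_raw == pytest.approx(r.p_raw)
            assert f.significant == r.significant

    def test_recall_increases_with_effect_size(self):
        recalls = []
        for shift in (0.5, 1.5, 4.0):
            mat, sheet = self._toy(seed=2, shift=shift)
            res = de.differential_expression(mat, sheet, "PC", "BPH")
            sig = de.significant_features(res)
            recalls.append(len(sig & {f"G{i}" for i in range(10)}) / 10)
        assert recalls[0] <= recalls[1] <= recalls[2]
        assert recalls[2] == 1.0

    def test_significance_requires_both_filters(self):
        mat, sheet = self._toy(seed=3, shift=3.0)
        for r in de.differential_expression(mat, sheet, "PC", "BPH"):
            fold = max(r.median_ratio, 1 / r.median_ratio)
            assert r.significant == (r.p_adj < 0.05 and fold > 1.5)
            assert r.p_adj >= r.p_raw - 1e-15


class TestDEOverlap:
    def _result(self, fid, sig, direction):
        return de.DEResult(fid, 2.0 if direction == "up" else 0.5,
                           0.01, 0.01 if sig else 0.9, direction, sig)

    def test_identical_lists(self):
        res = [self._result(f"G{i}", i < 3, "up") for i in range(5)]
        out = de.de_overlap(res, res)
        assert out == {"only_a": 0, "only_b": 0, "both": 3,
                       "direction_concordance": 1.0}

    def test_partial_concordance_hand_count(self):
        a = [self._result("G1", True, "up"), self._result("G2", True, "up"),
             self._result("G3", True, "up"), self._result("G4", True, "up"),
             self._result("G5", True, "down")]
        b = [self._result("G1", True, "up"), self._result("G2", True, "down"),
             self._result("G3", True, "up"), self._result("G4", False, "up"),
             self._result("G5", False, "up")]
        out = de.de_overlap(a, b)
        assert out["both"] == 3
        assert out["direction_concordance"] == pytest.approx(2 / 3)

    def test_disjoint_significant_sets_concordance_nan(self):
        a = [self._result("G1", True, "up"), self._result("G2", False, "up")]
        b = [self._result("G1", False, "up"), self._result("G2", True, "up")]
        out = de.de_overlap(a, b)
        assert out["both"] == 0
        assert math.isnan(out["direction_concordance"])
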