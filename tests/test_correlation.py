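import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cernet.correlation import (
    ConstantVectorError,
    pearson,
    permutation_pvalue,
    screen_negative_pairs,
    screen_positive_pairs,
    spearman,
    t_pvalue,
)
from cernet.io import ExpressionMatrix, ValidationError

from conftest import GROUPS_4, random_matrix


class TestSpearman:
    def test_classic_sum_of_squared_rank_differences_example(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-12)  # 1 - 6*4/(5*24)

    def test_perfect_antitone(self):
        rho, p = spearman([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)
        assert p == 0.0

    def test_tied_data_equals_pearson_of_midranks(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.integers(0, 5, 12).astype(float)  # heavy ties
            y = rng.integers(0, 5, 12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman(x, y)
            oracle = pearson(stats.rankdata(x), stats.rankdata(y))[0]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            x, y = rng.normal(size=(2, 10))
            rho, p = spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 15))
        assert spearman(x, y)[0] == pytest.approx(spearman(y, x)[0], abs=1e-12)
        assert spearman(np.exp(x), y)[0] == pytest.approx(spearman(x, y)[0], abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])  # n < 4
        with pytest.raises(ConstantVectorError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestPearson:
    def test_affine_identity(self):
        x = np.arange(6, dtype=float)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_worked_three_point_example(self):
        r, _ = pearson([0, 1, 2], [0, 1, 4])
        assert r == pytest.approx(0.9607689228305228, abs=1e-12)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            x, y = rng.normal(size=(2, 8))
            r, p = pearson(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)

    @given(st.floats(min_value=0.01, max_value=100), st.floats(min_value=-50, max_value=50))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_positive_affine_invariance(self, a, b):
        rng = np.random.default_rng(17)
        x, y = rng.normal(size=(2, 12))
        assert pearson(a * x + b, y)[0] == pytest.approx(pearson(x, y)[0], abs=1e-9)

    def test_permutation_p_agrees_with_t_approximation(self):
        rng = np.random.default_rng(23)
        x, y = rng.normal(size=(2, 7))
        p_t = spearman(x, y)[1]
        p_perm = permutation_pvalue(x, y, "spearman")  # exhaustive at n = 7
        assert abs(p_t - p_perm) < 0.12


def test_t_pvalue_null_calibration_at_n10():
    # fraction of null pairs with p < 0.05 should sit near 0.05
    rng = np.random.default_rng(29)
    n_pairs, n = 4000, 10
    x = rng.normal(size=(n_pairs, n))
    y = rng.normal(size=(n_pairs, n))
    ps = np.array([spearman(xi, yi)[1] for xi, yi in zip(x, y)])
    frac = (ps < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / n_pairs)
    assert abs(frac - 0.05) < 4 * se + 0.01  # rank statistic is discrete at n=10


class TestScreens:
    def _mat(self, arr, prefix):
        df = pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                          columns=list(GROUPS_4) if arr.shape[1] == 4 else
                          [f"s{i}" for i in range(arr.shape[1])])
        groups = {c: ("LE" if i < arr.shape[1] // 2 else "HE")
                  for i, c in enumerate(df.columns)}
        return ExpressionMatrix(df, "tpm", groups)

    def test_strictness_at_the_exact_spearman_boundary(self):
        # ranks chosen so rho is exactly -0.5: passing requires rho < -0.5
        x = np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5])
        y = np.array([4.0, 2, 5, 3, 1, 4, 2, 5, 3, 1])
        a = self._mat(x[None, :5], "a")
        b = self._mat(y[None, :5], "b")
        rho, _ = spearman(x[:5], y[:5])
        assert rho == pytest.approx(-0.5, abs=1e-12)
        edges = screen_negative_pairs(a, b, rho_max=-0.5, alpha=0.99)
        assert edges[0].passed is False

    def test_pass_requires_both_gates(self):
        rng = np.random.default_rng(31)
        a = random_matrix(rng, "a", 30, list(GROUPS_4), GROUPS_4)
        b = random_matrix(rng, "b", 30, list(GROUPS_4), GROUPS_4)
        edges = screen_negative_pairs(a, b)
        for e in edges:
            assert e.passed == (e.coefficient < -0.5 and e.p_value < 0.05)

    def test_boundary_equality_never_passes(self):
        # setting the gates exactly at the observed statistics must fail them
        rng = np.random.default_rng(37)
        a = random_matrix(rng, "a", 3, [f"s{i}" for i in range(10)],
                          {f"s{i}": ("LE" if i < 5 else "HE") for i in range(10)})
        b = random_matrix(rng, "b", 3, [f"s{i}" for i in range(10)],
                          {f"s{i}": ("LE" if i < 5 else "HE") for i in range(10)})
        e = screen_negative_pairs(a, b)[0]
        at_rho = screen_negative_pairs(a, b, rho_max=e.coefficient, alpha=1.0)[0]
        assert at_rho.passed is False
        pe = screen_positive_pairs(a, b, [(e.id_a, e.id_b)])[0]
        at_r = screen_positive_pairs(a, b, [(e.id_a, e.id_b)], r_min=pe.coefficient)[0]
        assert at_r.passed is False

    def test_positive_screen_ignores_p_and_sign_constrained(self):
        n = 10
        groups = {f"s{i}": ("LE" if i < 5 else "HE") for i in range(n)}
        base = np.linspace(1, 10, n)
        arr_a = base[None, :]
        arr_b = (-base)[None, :] + 20
        a = self._mat(arr_a, "L")
        b = self._mat(arr_b, "G")
        e = screen_positive_pairs(a, b, [("L0", "G0")])[0]
        assert e.coefficient == pytest.approx(-1.0)
        assert e.passed is False  # strong but negative

    def test_whitelist_restricts_candidates(self):
        rng = np.random.default_rng(41)
        a = random_matrix(rng, "a", 5, list(GROUPS_4), GROUPS_4)
        b = random_matrix(rng, "b", 5, list(GROUPS_4), GROUPS_4)
        edges = screen_negative_pairs(a, b, whitelist={("a0", "b1"), ("a2", "b3")})
        assert {(e.id_a, e.id_b) for e in edges} == {("a0", "b1"), ("a2", "b3")}

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(43)
        a = random_matrix(rng, "a", 2, list(GROUPS_4), GROUPS_4)
        other = {"x1": "LE", "x2": "LE", "x3": "HE", "x4": "HE"}
        b = random_matrix(rng, "b", 2, list(other), other)
        with pytest.raises(ValidationError):
            screen_negative_pairs(a, b)

    def test_constant_feature_skipped_with_warning(self):
        groups = {f"s{i}": ("LE" if i < 2 else "HE") for i in range(4)}
        a = self._mat(np.array([[3.0, 3.0, 3.0, 3.0]]), "a")
        b = self._mat(np.array([[1.0, 2.0, 3.0, 4.0]]), "b")
        with pytest.warns(UserWarning, match="constant"):
            edges = screen_negative_pairs(a, b)
        assert edges == []
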