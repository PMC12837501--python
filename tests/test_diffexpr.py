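import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernet.diffexpr import (
    LNCRNA_THRESHOLDS,
    MRNA_THRESHOLDS,
    DEThresholds,
    audit_de,
    bh_fdr,
    classify_de,
    counts_to_tpm,
    de_counts,
    expressed_filter,
    simple_de_test,
)
from cernet.io import ExpressionMatrix, ValidationError
from cernet.simulate import SimulationConfig, generate_bundle

from conftest import GROUPS_4


def _counts(rows, index, columns=("s1", "s2", "s3", "s4")):
    return ExpressionMatrix(
        pd.DataFrame(rows, index=index, columns=list(columns)), "count", dict(GROUPS_4))


class TestCountsToTpm:
    def test_hand_worked_two_feature_example(self):
        m = _counts([[100.0] * 4, [100.0] * 4], ["A", "B"])
        tpm = counts_to_tpm(m, {"A": 1000, "B": 2000})
        np.testing.assert_allclose(tpm.values.loc["A"], 666666.666666, rtol=1e-6)
        np.testing.assert_allclose(tpm.values.loc["B"], 333333.333333, rtol=1e-6)

    def test_equal_lengths_are_proportional(self):
        m = _counts([[10.0] * 4, [90.0] * 4], ["A", "B"])
        tpm = counts_to_tpm(m, {"A": 700, "B": 700})
        np.testing.assert_allclose(tpm.values.loc["A"], 100000.0)
        np.testing.assert_allclose(tpm.values.loc["B"], 900000.0)

    def test_columns_sum_to_one_million(self):
        b = generate_bundle(SimulationConfig(seed=1, n_lnc=20, n_mir=20, n_mrna=20))
        tpm = counts_to_tpm(b.mrna, b.lengths())
        np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_total_sample_is_named(self):
        m = _counts([[0.0, 5.0, 5.0, 5.0]], ["A"])
        with pytest.raises(ValidationError, match="s1"):
            counts_to_tpm(m, {"A": 1000})

    def test_missing_length_rejected(self):
        m = _counts([[1.0] * 4], ["A"])
        with pytest.raises(ValidationError, match="A"):
            counts_to_tpm(m, {})


class TestExpressedFilter:
    def _tpm(self, rows, index):
        return ExpressionMatrix(
            pd.DataFrame(rows, index=index, columns=list(GROUPS_4)), "tpm", dict(GROUPS_4))

    def test_group_mean_exactly_at_floor_is_not_expressed(self):
        m = self._tpm([[0.01, 0.01, 0.01, 0.01]], ["A"])
        per_group, both = expressed_filter(m)
        assert per_group["LE"] == set() and both == set()

    def test_group_specific_expression(self):
        m = self._tpm([[0.5, 0.5, 0.0, 0.0]], ["A"])
        per_group, both = expressed_filter(m)
        assert per_group["LE"] == {"A"} and per_group["HE"] == set() and both == set()

    def test_baseline_expressed_bundle_fully_intersects(self):
        b = generate_bundle(SimulationConfig(
            seed=4, n_lnc=100, n_mir=100, n_mrna=100, n_planted_triplets=0,
            baseline_log2_mean_range=(5.0, 8.0)))
        tpm = counts_to_tpm(b.mrna, b.lengths())
        _, both = expressed_filter(tpm)
        assert len(both) == 100


class TestSimpleDeTest:
    def test_identical_groups_are_null(self):
        m = ExpressionMatrix(
            pd.DataFrame([[5.0, 7.0, 5.0, 7.0]], index=["A"], columns=list(GROUPS_4)),
            "tpm", dict(GROUPS_4))
        tab = simple_de_test(m)
        assert tab.loc["A", "log2fc"] == 0.0
        assert tab.loc["A", "p_value"] == 1.0

    def test_fourfold_ratio_gives_log2fc_two(self):
        m = ExpressionMatrix(
            pd.DataFrame([[10.0, 10.0, 40.0, 40.0]], index=["A"], columns=list(GROUPS_4)),
            "tpm", dict(GROUPS_4))
        tab = simple_de_test(m, pseudocount=1e-9)
        assert tab.loc["A", "log2fc"] == pytest.approx(2.0, abs=1e-6)

    def test_degenerate_equal_constant_groups_give_p_one(self):
        m = ExpressionMatrix(
            pd.DataFrame([[3.0, 3.0, 3.0, 3.0]], index=["A"], columns=list(GROUPS_4)),
            "tpm", dict(GROUPS_4))
        assert simple_de_test(m).loc["A", "p_value"] == 1.0

    def test_planted_upshifted_features_are_detected(self):
        # group_shift 2 with low dispersion: planted mRNAs separate from decoys
        b = generate_bundle(SimulationConfig(
            seed=0, group_shift=2.0, sponge_strength=1.0, nb_dispersion=0.001,
            n_lnc=105, n_mir=105, n_mrna=105, baseline_log2_mean_range=(6.0, 10.0)))
        tpm = counts_to_tpm(b.mrna, b.lengths())
        tab = simple_de_test(tpm)
        planted = [g for _, _, g in b.truth.triplets]
        ps = tab.loc[planted, "p_value"]
        assert np.median(ps) < 0.05
        assert (tab.loc[planted, "log2fc"] > 0).all()


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_worked_step_up_vector(self):
        np.testing.assert_allclose(
            bh_fdr([0.005, 0.011, 0.02, 0.04]),
            [0.02, 0.022, 0.026667, 0.04], atol=5e-7)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.1, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_step_up(self, ps):
        # independent oracle: direct evaluation of q_(i) = min_{j>=i} p_(j) m / j
        p = np.asarray(ps)
        m = len(p)
        order = np.argsort(p, kind="stable")
        sorted_p = p[order]
        q_sorted = [min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
                    for i in range(m)]
        brute = np.empty(m)
        brute[order] = q_sorted
        np.testing.assert_allclose(bh_fdr(p), brute, atol=1e-12)
        # adjusted values nondecreasing in the order of raw p
        assert np.all(np.diff(np.asarray(bh_fdr(p))[order]) >= -1e-12)


def _stats_row(log2fc, p, fdr):
    return pd.DataFrame({"log2fc": [log2fc], "p_value": [p], "fdr": [fdr]}, index=["f"])


class TestClassifyDe:
    def test_mrna_up(self):
        recs = classify_de(_stats_row(1.2, 0.001, 0.03), MRNA_THRESHOLDS)
        assert recs[0].status == "up"

    def test_fold_change_exactly_two_is_ns(self):
        recs = classify_de(_stats_row(1.0, 1e-4, 0.001), MRNA_THRESHOLDS)
        assert recs[0].status == "ns"

    def test_lncrna_down_at_fc_1p62(self):
        recs = classify_de(_stats_row(-0.7, 0.03, 0.9), LNCRNA_THRESHOLDS)
        assert recs[0].status == "down"

    def test_lncrna_mode_ignores_fdr(self):
        recs = classify_de(_stats_row(0.7, 0.03, 0.5), LNCRNA_THRESHOLDS)
        assert recs[0].status == "up"

    def test_status_counts_partition_features(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({
            "log2fc": rng.normal(0, 2, 200),
            "p_value": rng.uniform(0, 1, 200),
        }, index=[f"g{i}" for i in range(200)])
        recs = classify_de(tab, MRNA_THRESHOLDS)
        c = de_counts(recs)
        assert c["n_up"] + c["n_down"] + c["n_ns"] == 200
        audit_de(recs, MRNA_THRESHOLDS)

    def test_stricter_thresholds_never_add_calls(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({
            "log2fc": rng.normal(0, 2, 300),
            "p_value": rng.uniform(0, 0.2, 300),
        }, index=[f"g{i}" for i in range(300)])
        loose = de_counts(classify_de(tab, DEThresholds(1.5, False, 0.05)))
        for fc_min, alpha in [(2.0, 0.05), (1.5, 0.01), (3.0, 0.001)]:
            tight = de_counts(classify_de(tab, DEThresholds(fc_min, False, alpha)))
            assert tight["n_up"] + tight["n_down"] <= loose["n_up"] + loose["n_down"]

    def test_audit_catches_tampered_status(self):
        recs = classify_de(_stats_row(1.2, 0.001, 0.03), MRNA_THRESHOLDS)
        recs[0].status = "down"
        with pytest.raises(ValidationError, match="inconsistent"):
            audit_de(recs, MRNA_THRESHOLDS)
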