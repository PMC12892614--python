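"""z-sum risk score, ROC/AUC, DeLong test and cross-validation harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sncfrag.cohort import CohortConfig, generate_cohort, log2_effect_for_sd_units
from sncfrag.differential import Signature
from sncfrag.risk import (compute_baseline, cross_validate, delong_test,
                          log_expression, risk_score, risk_scores, roc_auc,
                          stratified_folds)


def _sig(entries):
    return Signature(entries=entries, contrasts=("HC_vs_UC", "HC_vs_CD"), alpha=0.05)


class TestBaseline:
    def test_two_sample_hand_arithmetic(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [3.0]}, index=["famA"])
        base = compute_baseline(expr, ["s1", "s2"], _sig([("famA", "up")]))
        assert base.loc["famA", "mu"] == 2.0
        assert base.loc["famA", "tau"] == pytest.approx(np.sqrt(2.0))

    def test_identical_population_drops_all(self, caplog):
        expr = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0]},
                            index=["a", "b"])
        with caplog.at_level("WARNING"):
            base = compute_baseline(expr, ["s1", "s2"],
                                    _sig([("a", "up"), ("b", "up")]))
        assert base.empty
        assert "zero-variance" in caplog.text

    def test_matches_independent_mean_sd(self, rng):
        expr = pd.DataFrame(rng.normal(5, 2, size=(3, 10)),
                            index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(10)])
        base = compute_baseline(expr, expr.columns,
                                _sig([("a", "up"), ("b", "down"), ("c", "up")]))
        for fam in "abc":
            assert base.loc[fam, "mu"] == pytest.approx(expr.loc[fam].mean())
            assert base.loc[fam, "tau"] == pytest.approx(expr.loc[fam].std(ddof=1))

    def test_population_of_one_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match=">= 2"):
            compute_baseline(expr, ["s1"], _sig([("a", "up")]))


class TestRiskScore:
    def test_score_zero_at_population_mean(self):
        base = pd.DataFrame({"mu": [2.0, 5.0], "tau": [1.0, 2.0],
                             "direction": ["up", "up"]}, index=["a", "b"])
        sample = pd.Series({"a": 2.0, "b": 5.0})
        assert risk_score(sample, base) == 0.0

    def test_one_tau_above_mean_scores_one(self):
        base = pd.DataFrame({"mu": [2.0], "tau": [0.5], "direction": ["up"]},
                            index=["a"])
        assert risk_score(pd.Series({"a": 2.5}), base) == pytest.approx(1.0)

    def test_mixed_direction_hand_computed(self):
        # up: (3-2)/1 = 1; up: (6-5)/2 = 0.5; down: -(1-4)/3 = 1 -> total 2.5
        base = pd.DataFrame({"mu": [2.0, 5.0, 4.0], "tau": [1.0, 2.0, 3.0],
                             "direction": ["up", "up", "down"]},
                            index=["a", "b", "c"])
        sample = pd.Series({"a": 3.0, "b": 6.0, "c": 1.0})
        assert risk_score(sample, base) == pytest.approx(2.5)

    def test_missing_family_named(self):
        base = pd.DataFrame({"mu": [2.0], "tau": [1.0], "direction": ["up"]},
                            index=["famX"])
        expr = pd.DataFrame({"s1": [1.0]}, index=["other"])
        with pytest.raises(KeyError, match="famX"):
            risk_scores(expr, base)

    def test_affine_equivariance_preserves_ranks(self, rng):
        expr = pd.DataFrame(rng.normal(size=(2, 8)), index=["a", "b"],
                            columns=[f"s{i}" for i in range(8)])
        base = pd.DataFrame({"mu": [0.0, 0.0], "tau": [2.0, 3.0],
                             "direction": ["up", "up"]}, index=["a", "b"])
        s0 = risk_scores(expr, base)
        shifted = expr.copy()
        shifted.loc["a"] += 5.0
        s1 = risk_scores(shifted, base)
        np.testing.assert_allclose(s1 - s0, 5.0 / 2.0)


class TestROC:
    def test_perfect_separation(self):
        auc, pts = roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert auc == 1.0
        assert pts["tpr"].iloc[-1] == 1.0 and pts["fpr"].iloc[-1] == 1.0

    def test_three_of_four_concordant_pairs(self):
        # cases [0.9, 0.8], controls [0.85, 0.7]
        auc, _ = roc_auc([0.9, 0.8, 0.85, 0.7], [1, 1, 0, 0])
        assert auc == 0.75

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([1.0] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], [1, 1])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_auc_equals_mann_whitney_identity(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(2, 15))
        n_neg = int(rng.integers(2, 15))
        scores = np.round(rng.normal(size=n_pos + n_neg), 1)  # force ties
        labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
        auc, _ = roc_auc(scores, labels)
        u = stats.mannwhitneyu(scores[labels], scores[~labels],
                               alternative="two-sided").statistic
        assert auc == pytest.approx(u / (n_pos * n_neg), abs=1e-12)


class TestDeLong:
    def test_score_against_itself_is_null(self, rng):
        s = rng.normal(size=30)
        labels = rng.integers(0, 2, 30).astype(bool)
        labels[:2] = [True, False]
        res = delong_test(s, s, labels)
        assert res.delta == 0.0
        assert res.p == 1.0

    def test_detects_large_difference(self, rng):
        labels = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        good = np.r_[rng.normal(3, 1, 40), rng.normal(0, 1, 40)]
        bad = rng.normal(size=80)
        res = delong_test(good, bad, labels)
        assert res.delta > 0.3
        assert res.p < 0.01

    def test_variance_close_to_bootstrap_oracle(self):
        rng = np.random.default_rng(9)
        labels = np.r_[np.ones(4, bool), np.zeros(4, bool)]
        a = rng.normal(size=8)
        b = 0.5 * a + rng.normal(size=8)
        res = delong_test(a, b, labels)
        se = abs(res.delta / res.z) if res.z != 0 else np.nan

        # vectorized bootstrap of the paired delta-AUC (resample cases and
        # controls independently, AUC by exhaustive pair comparison)
        B = 100_000
        ip = rng.integers(0, 4, size=(B, 4))
        ineg = 4 + rng.integers(0, 4, size=(B, 4))

        def boot_auc(x):
            c = x[ip][:, :, None]
            d = x[ineg][:, None, :]
            return ((c > d) + 0.5 * (c == d)).mean(axis=(1, 2))

        boots = boot_auc(a) - boot_auc(b)
        assert se == pytest.approx(np.std(boots, ddof=1), rel=0.15)


class TestCrossValidation:
    def test_fold_assignment_stratified_and_exhaustive(self, rng):
        meta = pd.DataFrame({
            "group": ["HC"] * 11 + ["UC"] * 7 + ["CD"] * 6,
        }, index=[f"s{i}" for i in range(24)])
        folds = stratified_folds(meta, 5, rng)
        assert set(folds.unique()) == set(range(5))
        for g, n in (("HC", 11), ("UC", 7), ("CD", 6)):
            sizes = folds[meta["group"] == g].value_counts()
            assert sizes.sum() == n
            assert sizes.max() - sizes.min() <= 1
        # remainder goes to the lowest fold indices
        hc_sizes = folds[meta["group"] == "HC"].value_counts().sort_index()
        assert list(hc_sizes) == [3, 2, 2, 2, 2]

    def test_bit_identical_for_fixed_seed(self, small_cohort):
        rpm = small_cohort.family_rpm()
        a = cross_validate(rpm, small_cohort.metadata, k=3, rounds=3, seed=5)
        b = cross_validate(rpm, small_cohort.metadata, k=3, rounds=3, seed=5)
        np.testing.assert_array_equal(a.round_auc_uc, b.round_auc_uc)
        np.testing.assert_array_equal(a.round_auc_cd, b.round_auc_cd)
        pd.testing.assert_series_equal(a.prioritization, b.prioritization)

    def test_validation_labels_never_leak_into_signature(self, small_cohort):
        # the trained signature of a fold is a function of training rows only
        from sncfrag.differential import derive_signature, fit_all_families
        rpm = small_cohort.family_rpm()
        meta = small_cohort.metadata[
            small_cohort.metadata["group"].isin(["HC", "UC", "CD"])]
        rng = np.random.default_rng(0)
        folds = stratified_folds(meta, 3, rng)
        train_ids = folds.index[folds != 0]
        val_ids = folds.index[folds == 0]
        scrambled = meta.copy()
        scrambled.loc[val_ids, "group"] = rng.permutation(
            scrambled.loc[val_ids, "group"].to_numpy())

        def trained_signature(m):
            mt = m.loc[train_ids]
            return derive_signature(
                fit_all_families(rpm, mt, ("HC", "UC")),
                fit_all_families(rpm, mt, ("HC", "CD")), alpha=0.5).entries

        assert trained_signature(meta) == trained_signature(scrambled)

    def test_planted_signal_reaches_high_auc(self, study_refs):
        fams = sorted({r.family_label for r in study_refs})
        rng = np.random.default_rng(2)
        planted = list(rng.choice(fams, 20, replace=False))
        effect = log2_effect_for_sd_units(2.0, 10.0)
        cohort = generate_cohort(study_refs, CohortConfig(
            effect_families=tuple((f, effect, ("UC", "CD")) for f in planted),
            seed=3))
        rep = cross_validate(cohort.family_rpm(), cohort.metadata,
                             rounds=5, seed=4)
        med_uc, med_cd = rep.median_auc()
        assert med_uc > 0.9 and med_cd > 0.9
        assert rep.prioritization[planted].sum() > 0

    def test_empty_signature_modes(self, small_cohort):
        rpm = small_cohort.family_rpm()
        # alpha tiny forces empty signatures on this tiny null cohort
        rep_ex = cross_validate(rpm, small_cohort.metadata, k=3, rounds=2,
                                alpha=1e-12, seed=1, empty_signature="exclude")
        assert np.isnan(rep_ex.round_auc_uc).all()
        rep_ch = cross_validate(rpm, small_cohort.metadata, k=3, rounds=2,
                                alpha=1e-12, seed=1, empty_signature="chance")
        assert np.allclose(rep_ch.round_auc_uc, 0.5)

    def test_report_serializable(self, small_cohort):
        rep = cross_validate(small_cohort.family_rpm(), small_cohort.metadata,
                             k=3, rounds=2, seed=1)
        d = rep.to_dict()
        assert d["rounds"] == 2 and len(d["round_auc_hc_uc"]) == 2


def test_log_expression_is_log2_rpm_plus_one():
    rpm = pd.DataFrame({"s1": [0.0, 3.0]}, index=["a", "b"])
    le = log_expression(rpm)
    assert le.loc["a", "s1"] == 0.0
    assert le.loc["b", "s1"] == 2.0
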