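"""Class totals, length histograms, cleavage profiles, PCA, FC concordance."""

import numpy as np
import pandas as pd
import pytest

from sncfrag.annotation import aggregate_families, species_table_from_cohort
from sncfrag.cohort import CohortConfig, generate_cohort
from sncfrag.landscape import (class_total_tests, cleavage_profile,
                               fold_change_concordance, length_distribution,
                               length_histograms, pca_categories,
                               per_sample_coverage, welch_t)


def _meta(groups):
    rows = [{"sample_id": f"s{i}", "group": g, "age": 30 + i, "sex": "F"}
            for i, g in enumerate(groups)]
    return pd.DataFrame(rows).set_index("sample_id")


class TestClassTotals:
    def test_identical_groups_give_t0_p1(self):
        meta = _meta(["HC"] * 3 + ["UC"] * 3)
        totals = pd.DataFrame([[5.0] * 6], index=["tsRNA"], columns=meta.index)
        t_table, _ = class_total_tests(totals, meta, contrasts=(("HC", "UC"),))
        assert t_table.iloc[0]["t"] == 0.0
        assert t_table.iloc[0]["p"] == 1.0

    def test_proportional_totals_have_rho_one(self):
        meta = _meta(["HC"] * 3 + ["UC"] * 3)
        ts = np.array([1.0, 3, 2, 8, 5, 4])
        totals = pd.DataFrame([ts, 2 * ts, ts ** 2],
                              index=["tsRNA", "rsRNA", "ysRNA"],
                              columns=meta.index)
        _, rho_table = class_total_tests(totals, meta, contrasts=(("HC", "UC"),))
        pair = rho_table.set_index(["class_a", "class_b"])
        assert pair.loc[("tsRNA", "rsRNA"), "rho"] == pytest.approx(1.0)

    def test_spearman_matches_hand_ranked_formula(self):
        # 6 samples, no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        meta = _meta(["HC"] * 3 + ["UC"] * 3)
        x = np.array([10.0, 40, 30, 20, 60, 50])
        y = np.array([2.0, 4, 1, 3, 6, 5])
        totals = pd.DataFrame([x, y, x + y],
                              index=["tsRNA", "rsRNA", "ysRNA"],
                              columns=meta.index)
        _, rho_table = class_total_tests(totals, meta, contrasts=(("HC", "UC"),))
        rx = x.argsort().argsort() + 1
        ry = y.argsort().argsort() + 1
        d2 = ((rx - ry) ** 2).sum()
        expected = 1 - 6 * d2 / (6 * 35)
        got = rho_table.set_index(["class_a", "class_b"]).loc[("tsRNA", "rsRNA"), "rho"]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_group_reported(self):
        meta = _meta(["HC"] * 4)
        totals = pd.DataFrame([[1.0] * 4], index=["tsRNA"], columns=meta.index)
        with pytest.raises(ValueError, match="UC"):
            class_total_tests(totals, meta, contrasts=(("HC", "UC"),))


class TestLengthDistribution:
    def test_bin_sums_equal_class_totals(self, small_cohort):
        table = species_table_from_cohort(small_cohort)
        fam_rpm, class_totals, denom = aggregate_families(table)
        hists = length_histograms(table, denom)
        for cls in class_totals.index:
            np.testing.assert_allclose(hists[cls].sum(axis=0),
                                       class_totals.loc[cls], rtol=1e-12)

    def test_tsrna_peaks_at_generator_hotspot_lengths(self, small_cohort):
        table = species_table_from_cohort(small_cohort)
        _, _, denom = aggregate_families(table)
        hist = length_histograms(table, denom)["tsRNA"].mean(axis=1)
        # peak-finding oracle: local maxima of the mean histogram
        peaks = {ln for ln in hist.index[1:-1]
                 if hist[ln] > hist[ln - 1] and hist[ln] > hist[ln + 1]}
        assert {17, 22} <= peaks

    def test_group_summary_has_ci_bounds(self, small_cohort):
        table = species_table_from_cohort(small_cohort)
        _, _, denom = aggregate_families(table)
        tidy = length_distribution(table, denom, small_cohort.metadata)
        assert (tidy["ci_high"] >= tidy["mean"]).all()
        assert (tidy["mean"] >= tidy["ci_low"]).all()


class TestCleavageProfile:
    def test_single_species_coverage_block(self, small_refs):
        parent = small_refs[0]
        table = pd.DataFrame({
            "length": [20], "class": ["GtRNA"], "family": [parent.family_label],
            "n_loci": [1], "ambiguous": [False], "multimapped": [False],
            "loci": [[(parent.parent_id, 5, 25)]],
            "count:s1": [10],
        }, index=pd.Index([parent.sequence[5:25]], name="sequence"))
        denom = pd.Series({"s1": 1_000_000})
        cov = per_sample_coverage(table, denom, parent.parent_id, len(parent.sequence))
        assert (cov.loc[5:24, "s1"] == 10.0).all()
        assert cov["s1"].sum() == pytest.approx(10 * 20)
        assert (cov.loc[:4, "s1"] == 0).all()

    def test_profiles_are_additive(self, small_refs):
        parent = small_refs[0]
        base = {"length": 10, "class": "GtRNA", "family": parent.family_label,
                "n_loci": 1, "ambiguous": False, "multimapped": False}
        t1 = pd.DataFrame([{**base, "loci": [(parent.parent_id, 0, 10)], "count:s1": 4}],
                          index=pd.Index(["A1"], name="sequence"))
        t2 = pd.DataFrame([{**base, "loci": [(parent.parent_id, 30, 40)], "count:s1": 6}],
                          index=pd.Index(["A2"], name="sequence"))
        both = pd.concat([t1, t2])
        denom = pd.Series({"s1": 1_000_000})
        L = len(parent.sequence)
        cov = per_sample_coverage(both, denom, parent.parent_id, L)
        cov1 = per_sample_coverage(t1, denom, parent.parent_id, L)
        cov2 = per_sample_coverage(t2, denom, parent.parent_id, L)
        pd.testing.assert_frame_equal(cov, cov1 + cov2)

    def test_positional_sum_conserves_rpm_times_length(self, small_cohort):
        table = species_table_from_cohort(small_cohort)
        _, _, denom = aggregate_families(table)
        fam = small_cohort.species["family_label"].iloc[0]
        parent = [r for r in small_cohort.refs if r.family_label == fam][0]
        cov = per_sample_coverage(table[table["family"] == fam], denom,
                                  parent.parent_id, len(parent.sequence))
        on_parent = table[(table["family"] == fam)
                          & table["loci"].map(
                              lambda L: any(p == parent.parent_id for p, _, _ in L))]
        for s in small_cohort.counts.columns[:5]:
            rpm = on_parent[f"count:{s}"] * 1e6 / denom[s]
            expected = (rpm * on_parent["length"]).sum()
            assert cov[s].sum() == pytest.approx(expected)

    def test_hotspot_argmax_within_planted_locus(self, small_cohort):
        fam = small_cohort.species["family_label"].iloc[0]
        parent = [r for r in small_cohort.refs if r.family_label == fam][0]
        table = species_table_from_cohort(small_cohort)
        _, _, denom = aggregate_families(table)
        profiles = cleavage_profile(table, small_cohort.refs, denom,
                                    small_cohort.metadata, fam)
        prof = profiles[parent.parent_id]
        spots = small_cohort.species[
            small_cohort.species["parent_id"] == parent.parent_id]
        covered = set()
        for _, row in spots.iterrows():
            covered.update(range(row["start"], row["end"]))
        assert int(np.argmax(prof.mean["HC"])) in covered

    def test_empty_family_warns_and_zeroes(self, small_refs, caplog):
        empty = pd.DataFrame(columns=["length", "class", "family", "n_loci",
                                      "ambiguous", "multimapped", "loci",
                                      "count:s1", "count:s2"])
        denom = pd.Series({"s1": 100.0, "s2": 100.0})
        meta = _meta(["HC", "HC"])
        meta.index = ["s1", "s2"]
        with caplog.at_level("WARNING"):
            profiles = cleavage_profile(empty, small_refs, denom, meta,
                                        small_refs[0].family_label)
        assert "zero annotated species" in caplog.text
        assert all((p.mean["HC"] == 0).all() for p in profiles.values())


class TestPCA:
    def test_duplicated_samples_share_scores(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 8))
        X[5] = X[0]
        mat = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(6)])
        meta = _meta(["HC"] * 3 + ["UC"] * 3)
        res, _ = pca_categories(mat, meta)
        np.testing.assert_allclose(res.scores.iloc[0], res.scores.iloc[5],
                                   atol=1e-10)

    def test_explained_variance_properties(self, small_cohort):
        res, _ = pca_categories(small_cohort.family_rpm(), small_cohort.metadata)
        ev = res.explained_variance
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() <= 1 + 1e-9

    def test_scores_orthogonal(self, small_cohort):
        res, _ = pca_categories(small_cohort.family_rpm(), small_cohort.metadata)
        S = res.scores.to_numpy()
        G = S.T @ S
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.outer(norms, norms).max()

    def test_pc1_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 4))
        mat = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(5)])
        meta = _meta(["HC"] * 3 + ["UC"] * 2)
        res, _ = pca_categories(mat, meta)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        evals, evecs = np.linalg.eigh(np.cov(Z.T, ddof=1))
        pc1 = Z @ evecs[:, np.argmax(evals)]
        got = res.scores["PC1"].to_numpy()
        # eigen oracle agrees up to overall scale convention and sign
        got = got / np.linalg.norm(got)
        pc1 = pc1 / np.linalg.norm(pc1)
        assert (np.allclose(got, pc1, atol=1e-8)
                or np.allclose(got, -pc1, atol=1e-8))

    def test_too_few_samples_rejected(self):
        mat = pd.DataFrame(np.ones((4, 2)), columns=["a", "b"])
        meta = _meta(["HC", "UC"])
        with pytest.raises(ValueError, match="3 samples"):
            pca_categories(mat, meta)


class TestFoldChangeConcordance:
    def test_equal_case_means_give_rho_one(self):
        rng = np.random.default_rng(5)
        meta = _meta(["HC"] * 4 + ["UC"] * 4 + ["CD"] * 4)
        hc = rng.uniform(1, 100, size=(20, 4))
        case = rng.uniform(1, 100, size=(20, 4))
        mat = pd.DataFrame(np.hstack([hc, case, case]),
                           index=[f"f{i}" for i in range(20)],
                           columns=meta.index)
        _, rho, _ = fold_change_concordance(mat, meta)
        assert rho == pytest.approx(1.0)

    def test_equal_group_means_give_zero_fc(self):
        meta = _meta(["HC"] * 3 + ["UC"] * 3 + ["CD"] * 3)
        mat = pd.DataFrame([[7.0] * 9, [1, 2, 3, 3, 2, 1, 2, 2, 2]],
                           index=["f0", "f1"], columns=meta.index)
        table, _, _ = fold_change_concordance(mat, meta)
        assert table.loc["f0", "log2fc_UC"] == 0.0
        assert table.loc["f0", "log2fc_CD"] == 0.0

    def test_planted_shared_effects_concordant(self, small_refs):
        fams = sorted({r.family_label for r in small_refs})
        effects = tuple((f, 1.5, ("UC", "CD")) for f in fams[:5])
        cohort = generate_cohort(small_refs, CohortConfig(
            group_sizes={"HC": 10, "UC": 10, "CD": 10},
            library_size_range=(100_000, 120_000),
            effect_families=effects, seed=21))
        _, rho, _ = fold_change_concordance(cohort.family_rpm(), cohort.metadata)
        assert rho > 0.8

    def test_nonpositive_eps_rejected(self):
        meta = _meta(["HC"] * 2 + ["UC"] * 2 + ["CD"] * 2)
        mat = pd.DataFrame([[1.0] * 6], index=["f0"], columns=meta.index)
        with pytest.raises(ValueError, match="eps"):
            fold_change_concordance(mat, meta, eps=0.0)


def test_welch_t_handles_identical_constant_samples():
    t, p = welch_t(np.array([2.0, 2.0, 2.0]), np.array([2.0, 2.0]))
    assert (t, p) == (0.0, 1.0)
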