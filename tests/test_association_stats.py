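"""Statistical layer: shell gradient, adjusted associations, FDR,
biomarker preprocessing, PCA and the joint models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pvspet import association_stats as st
from pvspet import phantom as ph


def bh_brute_force(p):
    """Reference Benjamini-Hochberg: sort, step-up, running minimum."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestShellGradient:
    def test_identical_layers_give_null_result(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(8):
            v = rng.normal()
            for layer in ph.PENUMBRA_LAYERS:
                rows.append({"subject": i, "layer": layer, "value": v})
        comp = st.shell_gradient_test(pd.DataFrame(rows))
        assert comp.anova_f == pytest.approx(0.0, abs=1e-20)
        assert comp.anova_p == pytest.approx(1.0)
        assert (comp.pairwise["p_bonferroni"] == 1.0).all()

    def test_f_matches_hand_decomposition_3x3(self):
        """Classical two-way (subject x layer) decomposition worked by hand
        on a 3-subject, 3-layer table."""
        X = np.array([[1.0, 2.0, 3.0],
                      [2.0, 4.0, 3.0],
                      [3.0, 3.0, 6.0]])
        rows = [{"subject": i, "layer": f"L{j}", "value": X[i, j]}
                for i in range(3) for j in range(3)]
        comp = st.shell_gradient_test(pd.DataFrame(rows))
        grand = X.mean()
        ss_layer = 3 * ((X.mean(axis=0) - grand) ** 2).sum()
        ss_subj = 3 * ((X.mean(axis=1) - grand) ** 2).sum()
        ss_err = ((X - grand) ** 2).sum() - ss_layer - ss_subj
        f_hand = (ss_layer / 2) / (ss_err / 4)
        assert comp.anova_f == pytest.approx(f_hand, rel=1e-12)
        assert comp.df_effect == 2 and comp.df_error == 4

    def test_f_matches_statsmodels_anova_rm(self):
        from statsmodels.stats.anova import AnovaRM

        df = ph.simulate_layer_cohort(12, 0.3, seed=4)
        comp = st.shell_gradient_test(df)
        ref = AnovaRM(df, "value", "subject", within=["layer"]).fit()
        assert comp.anova_f == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]), rel=1e-10)
        assert comp.anova_p == pytest.approx(
            float(ref.anova_table["Pr > F"].iloc[0]), abs=1e-12)

    def test_paired_t_matches_hand_formula(self):
        """Paired t on a printed 4-subject fixture: d = [1, 2, 0, 1],
        mean 1, sd sqrt(2/3), t = 1 / (sqrt(2/3)/2) = sqrt(6)."""
        a = np.array([3.0, 5.0, 2.0, 4.0])
        b = a - np.array([1.0, 2.0, 0.0, 1.0])
        rows = []
        for i in range(4):
            rows += [{"subject": i, "layer": "A", "value": a[i]},
                     {"subject": i, "layer": "B", "value": b[i]}]
        comp = st.shell_gradient_test(pd.DataFrame(rows))
        t = comp.pairwise["t"].iloc[0]
        assert abs(t) == pytest.approx(np.sqrt(6.0), rel=1e-12)
        assert comp.pairwise["p_bonferroni"].iloc[0] == pytest.approx(
            min(1.0, comp.pairwise["p_raw"].iloc[0]), rel=1e-12)

    def test_incomplete_subjects_dropped(self):
        df = ph.simulate_layer_cohort(6, 0.3, seed=1)
        df = df.drop(df[(df.subject == "S001") &
                        (df.layer == "layer3")].index)
        comp = st.shell_gradient_test(df)
        assert comp.n_subjects == 5

    def test_bonferroni_multiplier_is_six_for_four_layers(self):
        df = ph.simulate_layer_cohort(6, 0.3, seed=1)
        comp = st.shell_gradient_test(df)
        assert len(comp.pairwise) == 6
        row = comp.pairwise.iloc[0]
        assert row["p_bonferroni"] == pytest.approx(
            min(1.0, 6 * row["p_raw"]))


class TestPartialSpearman:
    def test_reduces_to_classical_spearman(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = st.partial_spearman(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho, rel=1e-10)
        assert p == pytest.approx(ref_p, rel=0.05)

    def test_perfect_monotone_is_one(self):
        x = np.linspace(0, 1, 25)
        rho, _ = st.partial_spearman(x, np.exp(3 * x))
        assert rho == pytest.approx(1.0)

    def test_confounder_removed(self):
        """x and y depend only on a shared covariate; the partial
        correlation is near zero although the marginal one is large."""
        rng = np.random.default_rng(5)
        n = 1000
        c = rng.normal(size=n)
        x = c + 0.3 * rng.normal(size=n)
        y = c + 0.3 * rng.normal(size=n)
        marg, _ = st.partial_spearman(x, y)
        part, _ = st.partial_spearman(x, y, covariates=c)
        assert marg > 0.7
        assert abs(part) < 0.07

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            st.partial_spearman(np.ones(10), np.arange(10.0))


class TestLinearAssoc:
    def test_two_point_slope(self):
        res = st.linear_assoc([1.0, 3.0, 5.0], [0.0, 1.0, 2.0])
        assert res["beta"] == pytest.approx(2.0)

    def test_duplicated_covariate_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="rank"):
            st.linear_assoc(np.random.default_rng(0).normal(size=10), x,
                            covariates=x)

    def test_slope_recovery_on_simulated_cohort(self):
        rng = np.random.default_rng(8)
        n = 200
        age = rng.normal(70, 10, n)
        sex = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        y = 0.5 * x + 0.02 * age + 0.3 * sex + rng.normal(0, 0.5, n)
        res = st.linear_assoc(y, x, covariates=np.column_stack([age, sex]))
        assert abs(res["beta"] - 0.5) < 2 * res["se"]


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(st.fdr_adjust([0.03]), [0.03])

    def test_hand_worked_example(self):
        np.testing.assert_allclose(st.fdr_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(st.fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(st.fdr_adjust(p), bh_brute_force(p),
                                       rtol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            st.fdr_adjust([0.5, 1.2])


class TestBiomarkerPreprocess:
    def test_plate_median_normalization(self):
        rng = np.random.default_rng(0)
        panel = pd.DataFrame(rng.lognormal(0, 0.2, size=(24, 5)),
                             columns=[f"BM{i}" for i in range(5)])
        plates = np.repeat([0, 1], 12)
        out, log = st.biomarker_preprocess(panel, plates)
        assert set(log["transform"]) <= {"none", "log", "cube_root"}

    def test_per_plate_medians_equal_one_before_transform(self):
        rng = np.random.default_rng(1)
        panel = pd.DataFrame(rng.normal(10, 1, size=(30, 3)),
                             columns=list("abc"))
        plates = np.repeat([0, 1, 2], 10)
        # markers already normal -> untransformed, medians should be 1
        out, log = st.biomarker_preprocess(panel, plates)
        untouched = log.loc[log["transform"] == "none", "marker"]
        for marker in untouched:
            for plate in (0, 1, 2):
                med = out.loc[plates == plate, marker].median()
                assert med == pytest.approx(1.0, rel=1e-12)

    def test_lognormal_marker_gets_log(self):
        """A strongly right-skewed marker is log-transformed in nearly all
        replicates at the cohort sample size."""
        rng = np.random.default_rng(2)
        chosen = 0
        for _ in range(100):
            panel = pd.DataFrame({"m": rng.lognormal(0, 1.0, 54)})
            _, log = st.biomarker_preprocess(panel, np.zeros(54, int))
            chosen += (log["transform"].iloc[0] == "log")
        assert chosen >= 95

    def test_zero_plate_median_rejected(self):
        panel = pd.DataFrame({"m": [0.0, 0.0, 0.0, 1.0]})
        with pytest.raises(ValueError, match="zero plate median"):
            st.biomarker_preprocess(panel, np.zeros(4, int))


class TestPCA:
    def test_three_factor_panel_captured_by_three_components(self):
        recs, plates = ph.simulate_cohort(100, seed=3)
        df = ph.cohort_frame(recs)
        panel = df[[c for c in df.columns if c.startswith("BM")]]
        out, _ = st.biomarker_preprocess(panel, plates)
        pca = st.pca_summary(out)
        assert pca["variance_ratio"][:3].sum() >= 0.80
        assert pca["scores"].shape[1] == 3

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(0)
        panel = pd.DataFrame(rng.normal(size=(50, 8)))
        pca = st.pca_summary(panel, n_components=3)
        s = pca["scores"].to_numpy()
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(0)
        panel = pd.DataFrame(rng.normal(size=(40, 6)))
        a = st.pca_summary(panel)
        b = st.pca_summary(panel.copy())
        pd.testing.assert_frame_equal(a["scores"], b["scores"])
        for col in a["loadings"]:
            j = a["loadings"][col].abs().idxmax()
            assert a["loadings"].loc[j, col] > 0

    def test_more_markers_than_subjects_flagged(self):
        rng = np.random.default_rng(1)
        panel = pd.DataFrame(rng.normal(size=(10, 20)))
        pca = st.pca_summary(panel)
        assert pca["n_lt_p"]


class TestOrdinalModel:
    def test_binary_outcome_equals_logistic_regression(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n = 300
        x = rng.normal(size=(n, 2))
        lin = 0.8 * x[:, 0] - 0.5 * x[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-(lin - 0.2)))).astype(int)
        df = pd.DataFrame({"y": y, "x1": x[:, 0], "x2": x[:, 1]})
        table = st.ordinal_joint_model(df, "y", ["x1", "x2"], covariates=())
        logit = sm.Logit(y, sm.add_constant(x)).fit(disp=False)
        np.testing.assert_allclose(table["coef"].to_numpy(),
                                   logit.params[1:], atol=1e-6)

    def test_proportional_odds_recovery(self):
        rng = np.random.default_rng(1)
        n = 500
        z = rng.normal(size=n)
        latent = 0.8 * z + rng.logistic(size=n)
        y = np.digitize(latent, [-1.5, 0.0, 1.5])
        df = pd.DataFrame({"y": y, "z": z,
                           "age": rng.normal(70, 10, n),
                           "sex": rng.choice(["male", "female"], n)})
        table = st.ordinal_joint_model(df, "y", ["z"])
        row = table[table["predictor"] == "z"].iloc[0]
        assert abs(row["coef"] - 0.8) < 2 * row["se"]

    def test_null_predictor_p_uniform(self):
        """Wald p-values of a zero-effect predictor are uniform across
        replicates (KS test)."""
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(200):
            n = 120
            z = rng.normal(size=n)
            y = np.digitize(rng.logistic(size=n), [-1.0, 1.0])
            df = pd.DataFrame({"y": y, "z": z})
            table = st.ordinal_joint_model(df, "y", ["z"], covariates=())
            pvals.append(table["p"].iloc[0])
        ks_p = stats.kstest(pvals, "uniform").pvalue
        assert ks_p > 0.01

    def test_complete_separation_diagnosed(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": [0] * 10 + [1] * 10,
                           "x1": np.arange(20.0),
                           "x2": rng.normal(size=20)})
        with pytest.raises(RuntimeError, match="separation"):
            st.ordinal_joint_model(df, "y", ["x1", "x2"], covariates=())


class TestJointLinear:
    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.normal(size=30),
                           "a": rng.normal(size=30)})
        df["b"] = 2 * df["a"]
        with pytest.raises(ValueError, match="rank"):
            st.joint_linear_model(df, "y", ["a", "b"], covariates=())

    def test_recovery_on_cohort(self):
        recs, _ = ph.simulate_cohort(
            300, ph.CohortEffect.for_correlation(0.5), seed=9)
        df = ph.cohort_frame(recs)
        df["log_wm_vol"] = np.log(df["wm_pvs_volume_cm3"]
                                  / df["brain_volume_cm3"])
        table = st.joint_linear_model(df, "log_wm_vol",
                                      ["mean_bpnd", "mean_ki"])
        row = table[table["predictor"] == "mean_bpnd"].iloc[0]
        assert row["p"] < 1e-4  # generated association detected
        null_row = table[table["predictor"] == "mean_ki"].iloc[0]
        assert null_row["p"] > 0.001  # no generated K_i association

    def test_matches_single_predictor_when_others_null(self):
        rng = np.random.default_rng(4)
        n = 250
        x = rng.normal(size=n)
        null1 = rng.normal(size=n)
        y = 0.6 * x + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"y": y, "x": x, "null1": null1})
        multi = st.joint_linear_model(df, "y", ["x", "null1"],
                                      covariates=())
        single = st.linear_assoc(y, x)
        row = multi[multi["predictor"] == "x"].iloc[0]
        assert abs(row["coef"] - single["beta"]) < 2 * row["se"]


class TestAssociationTable:
    def test_five_rows_with_fdr(self):
        recs, _ = ph.simulate_cohort(
            60, ph.CohortEffect.for_correlation(0.5), seed=2)
        df = ph.cohort_frame(recs)
        table = st.pvs_association_table(df, "mean_bpnd")
        assert len(table) == 5
        assert (table["fdr_p"] >= table["p"] - 1e-15).all()

    def test_effect_detected_for_wm_score(self):
        recs, _ = ph.simulate_cohort(
            200, ph.CohortEffect.for_correlation(0.5), seed=7)
        df = ph.cohort_frame(recs)
        table = st.pvs_association_table(df, "mean_bpnd")
        row = table[table["pvs_marker"] == "wm_pvs_score"].iloc[0]
        assert 0.3 <= row["coefficient"] <= 0.6
        assert row["fdr_p"] < 0.01
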