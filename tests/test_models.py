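"""Statistics layer: selection, recovery, trees and nonparametric tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pumppass import models
from pumppass.errors import InsufficientData, MissingScenario, SingleCategory


def simulate_survival(
    n, beta0=0.5, beta_len=-0.02, beta_rpm=0.0, seed=0, len_mean=300.0, len_sd=40.0
):
    """Cohort from a known logistic: two rpm scenarios, Gaussian lengths."""
    rng = np.random.default_rng(seed)
    rpm = rng.choice([468, 550], n)
    length = rng.normal(len_mean, len_sd, n)
    logit = beta0 + beta_len * (length - len_mean) + beta_rpm * (rpm == 550)
    y = (rng.random(n) < expit(logit)).astype(int)
    return pd.DataFrame(
        {
            "species": "bream",
            "type": "pump",
            "rpm": rpm,
            "scenario": np.where(rpm == 468, "FNAFP_468", "FNAFP_550"),
            "length_mm": length,
            "survival": y,
        }
    )


class TestStars:
    @pytest.mark.parametrize(
        "p,stars",
        [(0.2, "ns"), (0.05, "*"), (0.02, "*"), (0.01, "**"), (0.002, "**"),
         (0.001, "***"), (0.0005, "***"), (0.00005, "****")],
    )
    def test_bins(self, p, stars):
        assert models.p_stars(p) == stars


class TestLengthAnova:
    def test_identical_means_high_p(self):
        # zero within-noise, equal group means -> no scenario signal
        df = pd.DataFrame(
            {
                "species": "roach",
                "scenario": ["a"] * 30 + ["b"] * 30,
                "length_mm": [170.0, 171.0, 172.0] * 20,
            }
        )
        res = models.LengthAnovaModel(df, "roach").fit()
        assert res.p_value > 0.9
        assert res.tukey is None

    def test_shifted_groups_detected(self, rng):
        df = pd.DataFrame(
            {
                "species": "roach",
                "scenario": ["a"] * 50 + ["b"] * 50,
                "length_mm": np.concatenate(
                    [rng.normal(170, 10, 50), rng.normal(200, 10, 50)]  # 3 SD shift
                ),
            }
        )
        res = models.LengthAnovaModel(df, "roach").fit()
        assert res.p_value < 0.001
        assert res.tukey is not None and len(res.tukey) == 1

    def test_type_i_error_calibrated(self):
        # three groups from one distribution; rejection rate ~ alpha
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 400
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "species": "eel",
                    "scenario": np.repeat(["a", "b", "c"], 20),
                    "length_mm": rng.normal(600, 50, 60),
                }
            )
            if models.LengthAnovaModel(df, "eel").fit().p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.03)

    def test_insufficient_data(self):
        df = pd.DataFrame(
            {"species": "roach", "scenario": ["a"], "length_mm": [170.0]}
        )
        with pytest.raises(InsufficientData):
            models.LengthAnovaModel(df, "roach").fit()


class TestStepwise:
    def test_never_worse_than_full_or_null(self):
        df = simulate_survival(400, beta_len=-0.01, seed=3)
        df["length_c"] = df["length_mm"] - df["length_mm"].mean()

        def fit_fn(terms, d):
            rhs = " + ".join(terms) if terms else "1"
            return models._glm_logit(f"survival ~ {rhs}", d)

        terms = ["C(rpm)", "length_c", "C(rpm):length_c"]
        best, selected = models.stepwise_aic(fit_fn, terms, df)
        assert best.aic <= fit_fn(terms, df).aic + 1e-9
        assert best.aic <= fit_fn([], df).aic + 1e-9

    def test_null_terms_dropped_at_aic_rates(self):
        # no rpm or length effect: AIC retains a useless 1-df term with
        # asymptotic probability P(chi2_1 > 2) ~ 0.157; marginality (a
        # retained interaction forces both main effects) pushes per-term
        # retention toward ~0.3, so each term should still be dropped in a
        # clear majority of reps and the intercept-only model selected in
        # the majority of them
        intercept_only = 0
        kept = {"C(rpm)": 0, "length_c": 0}
        reps = 60
        for s in range(reps):
            df = simulate_survival(500, beta0=0.4, beta_len=0.0, beta_rpm=0.0, seed=s)
            res = models.SurvivalLogitModel(df, "bream").fit()
            if not res.selected_terms:
                intercept_only += 1
            for term in kept:
                if term in res.selected_terms:
                    kept[term] += 1
        assert intercept_only / reps >= 0.5
        for term, count in kept.items():
            assert count / reps <= 0.45, term

    def test_marginality_respected(self):
        assert not models._respects_hierarchy({"C(rpm):length_c", "length_c"})
        assert models._respects_hierarchy({"C(rpm)", "length_c", "C(rpm):length_c"})


class TestSurvivalLogit:
    def test_parameter_recovery_bias_shrinks(self):
        beta_len = -0.02
        biases = []
        for n in (200, 1000, 5000):
            ests = []
            for s in range(30):
                df = simulate_survival(n, beta_len=beta_len, seed=1000 + s)
                res = models.SurvivalLogitModel(df, "bream").fit(selection="none")
                ests.append(res.params["length_c"])
            biases.append(abs(np.mean(ests) - beta_len))
        assert biases[2] < biases[0]
        assert biases[2] < 0.002

    def test_all_survived_stratum_excluded(self):
        df = simulate_survival(300, beta0=0.0, seed=9)
        forced = pd.DataFrame(
            {
                "species": "bream",
                "type": "pump",
                "rpm": 585,
                "scenario": "CAFP_585",
                "length_mm": np.random.default_rng(0).normal(300, 30, 40),
                "survival": 1,  # complete separation in this stratum
            }
        )
        res = models.SurvivalLogitModel(
            pd.concat([df, forced], ignore_index=True), "bream"
        ).fit()
        assert "CAFP_585" in res.excluded_strata
        assert np.isfinite(res.bse).all()

    def test_scenario_predictions_have_bands(self):
        df = simulate_survival(600, beta_rpm=-0.8, seed=2)
        res = models.SurvivalLogitModel(df, "bream").fit()
        sp = res.scenario_predictions
        assert set(sp["scenario"]) == {"FNAFP_468", "FNAFP_550"}
        assert ((sp["lo95"] < sp["survival"]) & (sp["survival"] < sp["hi95"])).all()


class TestMixedCheck:
    @staticmethod
    def grouped_cohort(sigma_u, n_samples=12, per=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(n_samples):
            u = rng.normal(0, sigma_u)
            y = (rng.random(per) < expit(0.3 + u)).astype(int)
            rows.append(
                pd.DataFrame({"sample_id": f"s{g}", "survival": y})
            )
        return pd.concat(rows, ignore_index=True)

    def test_zero_variance_singular_simple(self):
        df = self.grouped_cohort(0.0, seed=1)
        out = models.mixed_model_check(df)
        assert out["decision"] == "simple"
        assert out["sigma_u"] < 0.1

    def test_strong_variance_mixed_retained(self):
        df = self.grouped_cohort(2.0, seed=2)
        out = models.mixed_model_check(df)
        assert out["decision"] == "mixed"
        assert out["sigma_u"] > 0.5

    def test_small_samples_not_attempted(self):
        df = self.grouped_cohort(1.0, n_samples=20, per=3, seed=3)
        out = models.mixed_model_check(df)
        assert out["decision"] == "simple"
        assert "not attempted" in out["reason"]


class TestTrees:
    def test_species_determines_outcome(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "species": np.repeat(["eel", "bream"], 100),
                "type": "pump",
                "rpm": rng.choice([468, 550], 200),
                "length_mm": rng.normal(300, 40, 200),
                "survival": np.repeat([1, 0], 100),
            }
        )
        fit = models.SurvivalTreeModel(df).fit()
        assert fit.has_splits
        root = fit.nodes[0]
        assert root.split_variable.startswith("species_")
        leaves = [n for n in fit.nodes if n.children is None]
        assert all(n.prop_dead in (0.0, 1.0) for n in leaves)

    def test_all_survive_root_only(self):
        df = pd.DataFrame(
            {
                "species": "eel",
                "type": "pump",
                "rpm": np.repeat([468, 550], 50),
                "length_mm": np.linspace(500, 700, 100),
                "survival": 1,
            }
        )
        fit = models.SurvivalTreeModel(df).fit()
        assert not fit.has_splits
        assert fit.nodes[0].label == "Alive"
        assert "No tree" in fit.summary()

    def test_type_effect_splits_first(self, coded_cohort):
        coded, _ = coded_cohort
        bream = coded[coded["species"] == "bream"]
        fit = models.SurvivalTreeModel(
            bream, predictors=("type", "rpm", "length_mm")
        ).fit()
        assert fit.has_splits
        assert fit.nodes[0].split_variable.startswith("type_")

    def test_coverage_conservation(self, coded_cohort):
        coded, _ = coded_cohort
        fit = models.SurvivalTreeModel(coded).fit()
        by_id = {n.node_id: n for n in fit.nodes}
        for n in fit.nodes:
            if n.children is not None:
                left, right = n.children
                assert by_id[left].n + by_id[right].n == n.n
                assert by_id[left].coverage_pct + by_id[right].coverage_pct == pytest.approx(
                    n.coverage_pct
                )

    def test_node_proportions_brute_force(self, coded_cohort):
        coded, _ = coded_cohort
        fit = models.SurvivalTreeModel(coded).fit()
        root = fit.nodes[0]
        y = coded.dropna(subset=["survival", "length_mm"])["survival"]
        assert root.prop_dead == pytest.approx((y == 0).mean(), abs=1e-9)
        assert root.n == len(y)


class TestMultinomial:
    @staticmethod
    def injury_frame(n, beta_len=0.0, seed=0):
        rng = np.random.default_rng(seed)
        length = rng.normal(300, 40, n)
        z = beta_len * (length - 300)
        # category logits: no injury, slight, severe (severe loads on length)
        logits = np.column_stack([np.zeros(n), np.full(n, -0.3), -0.5 + z])
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        cats = np.array(["1", "2", "3"])
        draw = [cats[rng.choice(3, p=pi)] for pi in p]
        return pd.DataFrame(
            {
                "species": "roach",
                "type": "pump",
                "rpm": rng.choice([468, 550], n),
                "scenario": "FNAFP_468",
                "length_mm": length,
                "injury_class": draw,
                "survival": 1,
            }
        )

    def test_probabilities_sum_to_one(self):
        df = self.injury_frame(400, seed=1)
        res = models.InjuryMultinomialModel(df, "roach").fit(selection="none")
        sums = res.scenario_probabilities.groupby("scenario")["prob"].sum()
        assert np.all(np.abs(sums - 1.0) < 1e-9)
        grid = pd.DataFrame({"rpm": [468] * 5, "length_c": np.linspace(-80, 80, 5)})
        probs = res.predict_probs(grid)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_flat_probabilities_without_signal(self):
        rng = np.random.default_rng(7)
        df = self.injury_frame(600, seed=2)
        df["injury_class"] = rng.choice(["1", "2", "3"], len(df))  # uniform
        res = models.InjuryMultinomialModel(df, "roach").fit()
        probs = res.scenario_probabilities["prob"]
        assert np.allclose(probs, 1 / 3, atol=0.07)

    def test_length_slope_sign_recovered(self):
        hits = 0
        reps = 20
        for s in range(reps):
            df = self.injury_frame(800, beta_len=0.02, seed=100 + s)
            res = models.InjuryMultinomialModel(df, "roach").fit(selection="none")
            params = pd.DataFrame(res.fit.params)
            # equation 1 is the severe ("3") category vs the "1" reference
            assert "length_c" in res.fit.params.index
            if float(params.loc["length_c"].iloc[-1]) > 0:
                hits += 1
        assert hits / reps >= 0.95

    def test_two_categories_reduce_to_logistic(self):
        df = self.injury_frame(500, seed=3)
        df["injury_class"] = np.where(df["injury_class"] == "3", "3", "1")
        res = models.InjuryMultinomialModel(df, "roach").fit(selection="none")
        df["severe"] = (df["injury_class"] == "3").astype(int)
        df["length_c"] = df["length_mm"] - df["length_mm"].mean()
        glm = models._glm_logit("severe ~ C(rpm) + length_c", df)
        mn = np.asarray(res.fit.params).ravel()
        np.testing.assert_allclose(
            np.sort(mn), np.sort(np.asarray(glm.params)), atol=1e-5
        )

    def test_single_category_raises(self):
        df = self.injury_frame(50, seed=4)
        df["injury_class"] = "1"
        with pytest.raises(SingleCategory):
            models.InjuryMultinomialModel(df, "roach").fit()


class TestPumpComparison:
    @staticmethod
    def three_scenario_frame(cafp_shift, n=250, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for scen, shift in (
            ("FNAFP_468", 0.0),
            ("FNAFP_550", 0.0),
            ("CAFP_585", cafp_shift),
        ):
            length = rng.normal(168, 20, n)
            y = (rng.random(n) < expit(1.0 + shift - 0.01 * (length - 168))).astype(int)
            frames.append(
                pd.DataFrame(
                    {
                        "species": "roach",
                        "type": "pump",
                        "scenario": scen,
                        "rpm": int(scen.split("_")[1]),
                        "length_mm": length,
                        "survival": y,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_null_contrasts_mostly_nonsignificant(self):
        hits = 0
        reps = 40
        for s in range(reps):
            df = self.three_scenario_frame(0.0, seed=s)
            res = models.PumpComparisonModel(df).fit()
            sub = res.contrasts[res.contrasts["model"] == "with_length"]
            if (sub["p"] < 0.05).any():
                hits += 1
        # familywise false-positive rate over three uncorrected contrasts
        assert hits / reps <= 0.25

    def test_lower_cafp_survival_detected(self):
        df = self.three_scenario_frame(-2.5, seed=1)
        res = models.PumpComparisonModel(df).fit()
        for model_name in ("with_length", "without_length"):
            sub = res.contrasts[res.contrasts["model"] == model_name]
            cafp_rows = sub[sub["contrast"].str.contains("CAFP")]
            assert (cafp_rows["p"] < 0.05).all()
            # conventional pump on the losing side of both contrasts
            assert (cafp_rows["log_odds_diff"] > 0).all()

    def test_missing_scenario(self):
        df = self.three_scenario_frame(0.0, seed=2)
        with pytest.raises(MissingScenario):
            models.PumpComparisonModel(df[df["scenario"] != "CAFP_585"]).fit()


class TestNonparametric:
    def test_identical_samples_p_one(self):
        x = np.arange(10.0)
        res = models.nonparametric_bds({"a": x, "b": x.copy(), "c": x.copy()})
        assert res["kw_p"] == 1.0
        assert len(res["pairwise"]) == 0

    def test_shifted_distributions_significant(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(1.0, 1, 50)  # 1 SD shift
        res = models.nonparametric_bds({"a": a, "b": b})
        assert res["kw_p"] < 0.05
        assert (res["pairwise"]["p_bonferroni"] < 0.05).all()

    def test_bonferroni_formula(self, rng):
        groups = {k: rng.normal(i * 0.8, 1, 30) for i, k in enumerate("abcd")}
        res = models.nonparametric_bds(groups)
        pw = res["pairwise"]
        if len(pw):
            m = len(pw)
            np.testing.assert_allclose(
                pw["p_bonferroni"], np.minimum(1.0, m * pw["p_raw"])
            )

    def test_permutation_null_calibration(self):
        # permuting scenario labels destroys significance at ~alpha
        rng = np.random.default_rng(77)
        pooled = rng.normal(0, 1, 60)
        hits = 0
        reps = 300
        for _ in range(reps):
            perm = rng.permutation(pooled)
            res = models.nonparametric_bds({"a": perm[:20], "b": perm[20:40], "c": perm[40:]})
            if res["kw_p"] < 0.05 and (res["pairwise"]["p_bonferroni"] < 0.05).any():
                hits += 1
        assert hits / reps <= 0.05 + 0.02

    def test_insufficient(self):
        with pytest.raises(InsufficientData):
            models.nonparametric_bds({"a": np.arange(5.0)})
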