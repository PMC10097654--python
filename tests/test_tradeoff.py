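"""Conjugate Bayesian regression against a numerical-integration oracle,
plus the slope-progression, symbiont and confounder analyses."""

import numpy as np
import pandas as pd
import pytest
from coraltrade import synth, tradeoff
from coraltrade.errors import DegenerateFitError, InsufficientDataError
from coraltrade.tradeoff import BayesLMPrior, fit_bayes_lm
from oracles import grid_slope_quantiles


@pytest.fixture(scope="module")
def small_fixture():
    rng = np.random.default_rng(123)
    x = rng.uniform(-2, 2, 12)
    y = 1.0 + 0.8 * x + rng.normal(0, 0.6, 12)
    return x, y


class TestConjugatePosterior:
    def test_quantiles_match_grid_oracle(self, small_fixture):
        x, y = small_fixture
        prior = BayesLMPrior()
        post = fit_bayes_lm(y, x, prior, standardize=False)
        probs = np.array([0.025, 0.125, 0.25, 0.5, 0.75, 0.875, 0.975])
        oracle = grid_slope_quantiles(x, y, prior, probs)
        from scipy import stats
        closed = stats.t.ppf(probs, post.t_df, loc=post.t_loc,
                             scale=post.t_scale)
        np.testing.assert_allclose(closed, oracle, atol=1e-3)

    def test_p_positive_matches_grid_oracle(self, small_fixture):
        x, y = small_fixture
        prior = BayesLMPrior()
        post = fit_bayes_lm(y, x, prior, standardize=False)
        # invert: the oracle quantile at p = P(beta1 <= 0) must be ~0
        q = grid_slope_quantiles(x, y, prior, [1 - post.p_positive])
        assert abs(q[0]) < 1e-3

    def test_standardization_is_transparent(self, small_fixture):
        x, y = small_fixture
        a = fit_bayes_lm(y, x, standardize=True)
        b = fit_bayes_lm(y, x, standardize=False)
        # diffuse prior: both parameterizations agree on the slope posterior
        assert a.beta1_median == pytest.approx(b.beta1_median, rel=1e-4)
        assert a.p_positive == pytest.approx(b.p_positive, abs=1e-6)

    def test_noise_free_line_recovers_slope(self):
        rng = np.random.default_rng(77)
        x = np.linspace(0, 1, 20)
        post = fit_bayes_lm(2.0 * x, x)
        assert post.beta1_median == pytest.approx(2.0, abs=1e-6)
        assert post.p_positive > 0.999999
        # credible interval shrinks toward zero width as noise shrinks
        widths = []
        for noise in (0.5, 0.05, 0.0):
            p = fit_bayes_lm(2.0 * x + rng.normal(0, noise, 20) if noise
                             else 2.0 * x, x)
            lo, hi = p.intervals[0.95]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] < 0.2

    def test_reflection_identity(self, small_fixture):
        x, y = small_fixture
        p_pos = fit_bayes_lm(y, x).p_positive
        p_neg = fit_bayes_lm(y, -x).p_positive
        assert p_pos + p_neg == pytest.approx(1.0, abs=1e-9)

    def test_null_p_positive_centered(self):
        rng = np.random.default_rng(55)
        ps = []
        for _ in range(150):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            ps.append(fit_bayes_lm(y, x).p_positive)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.06)

    def test_intervals_nested(self, small_fixture):
        x, y = small_fixture
        iv = fit_bayes_lm(y, x).intervals
        assert iv[0.95][0] < iv[0.75][0] < iv[0.5][0] < iv[0.5][1] \
            < iv[0.75][1] < iv[0.95][1]

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateFitError):
            fit_bayes_lm(np.arange(10.0), np.ones(10))
        with pytest.raises(InsufficientDataError):
            fit_bayes_lm(np.arange(3.0), np.arange(3.0))
        flat = fit_bayes_lm(np.ones(10), np.arange(10.0))
        assert flat.degenerate
        assert flat.beta1_median == pytest.approx(0.0, abs=1e-12)
        assert flat.p_positive == pytest.approx(0.5, abs=1e-9)

    def test_prob_positive_slope_consistent(self, small_fixture):
        x, y = small_fixture
        post = fit_bayes_lm(y, x)
        assert tradeoff.prob_positive_slope(post) == pytest.approx(
            post.p_positive, abs=1e-12)


class TestOverallAnalysis:
    def test_positive_coupling_detected(self):
        cfg = synth.SyntheticConfig(n_colonies=200,
                                    tolerance_growth_coupling=0.5,
                                    fecundity_fraction=0.0,
                                    symbiont_fraction=0.0, seed=17)
        truth = synth.generate_population(cfg)["truth"]
        summaries = truth.rename(columns={"true_critical_dhw": "average_bsi"})
        res = tradeoff.overall_tradeoff_analysis(
            summaries[["colony_id", "average_bsi"]],
            truth[["colony_id", "true_growth_livesa", "true_growth_vol"]],
            trait_names=("true_growth_livesa", "true_growth_vol"),
            sensitivity=False)
        assert (res["beta1_median"] > 0).all()
        assert (res["p_positive"] > 0.95).all()

    def test_pairwise_dropping_bookkeeping(self, run):
        overall = run["overall"]
        traits_df = run["trait_table"]
        summaries = run["summaries"]
        row = overall[(overall["trait_name"] == "corrected_livesa_growth")
                      & (overall["variant"] == "all")].iloc[0]
        merged = summaries.merge(traits_df, on="colony_id")
        expected_n = merged["corrected_livesa_growth"].notna().sum()
        assert row["n_colonies"] == expected_n

    def test_sensitivity_variants_present(self, run):
        v = set(run["overall"]["variant"])
        assert {"all", "no_shrinkage", "no_max_fecundity"} <= v
        for trait in ("tep", "tev"):
            pair = run["overall"][run["overall"]["trait_name"] == trait]
            ns = pair.set_index("variant")["n_colonies"]
            assert ns["no_max_fecundity"] == ns["all"] - 1


class TestSlopeProgression:
    def test_pre_onset_levels_degenerate(self, run):
        prog = run["progression"]
        first = prog[(prog["trait_name"] == "corrected_livesa_growth")
                     & (prog["dhw_level"] == 0.0)].iloc[0]
        assert first["degenerate"]
        assert first["beta1_median"] == pytest.approx(0.0, abs=1e-12)
        assert first["p_positive"] == pytest.approx(0.5, abs=1e-9)

    def test_trait_negation_negates_slopes(self, run):
        traj = run["trajectories"]
        trait = run["trait_table"].set_index("colony_id")["corrected_vol_growth"]
        fwd = tradeoff.slope_progression(traj, trait)
        rev = tradeoff.slope_progression(traj, -trait)
        np.testing.assert_allclose(fwd["beta1_median"], -rev["beta1_median"],
                                   atol=1e-12)
        np.testing.assert_allclose(fwd["p_positive"], 1 - rev["p_positive"],
                                   atol=1e-9)

    def test_p_positive_peaks_after_onset_spread(self, run, default_config):
        prog = run["progression"]
        g = prog[prog["trait_name"] == "corrected_livesa_growth"]
        p = g.sort_values("dhw_level")["p_positive"].to_numpy()
        levels = g.sort_values("dhw_level")["dhw_level"].to_numpy()
        peak = levels[np.argmax(p)]
        assert p.max() > 0.9
        assert abs(peak - default_config.mean_critical_dhw) < 2.5


def _null_trajectories(rng, groups, n_colonies_per_group=6, n_levels=10):
    rows = []
    cid = 0
    for g in groups:
        for _ in range(n_colonies_per_group):
            cid += 1
            bsi = np.clip(1 - np.sort(rng.uniform(0, 1, n_levels)), 0, 1)
            for lev in range(n_levels):
                rows.append((f"A{cid:02d}", float(lev), bsi[lev], 4, g))
    df = pd.DataFrame(rows, columns=["colony_id", "dhw_level", "bsi",
                                     "n_fragments", "group"])
    profiles = (df[["colony_id", "group"]].drop_duplicates()
                .rename(columns={"group": "its2_profile"}))
    profiles["relative_abundance"] = 1.0
    return df.drop(columns="group"), profiles


class TestSymbiontEffect:
    def test_null_groups_rarely_significant(self):
        rng = np.random.default_rng(31)
        hits = 0
        for _ in range(20):
            traj, prof = _null_trajectories(rng, ["C40", "C3"])
            res = tradeoff.symbiont_effect_test(traj, prof)
            pairs = res[res["adjusted_p"].notna()]
            hits += int((pairs["adjusted_p"] < 0.05).any())
        assert hits <= 4  # ~5% nominal false-positive rate

    def test_singleton_group_flagged_not_tested(self):
        rng = np.random.default_rng(32)
        traj, prof = _null_trajectories(rng, ["C40", "C3"])
        lone = traj["colony_id"].iloc[-1]
        prof.loc[prof["colony_id"] == lone, "its2_profile"] = "D1-D4"
        res = tradeoff.symbiont_effect_test(traj, prof)
        flagged = res[res["flag"].str.contains("insufficient")]
        assert list(flagged["group_a"]) == ["D1-D4"]
        assert flagged["adjusted_p"].isna().all()
        tested = res[res["flag"] == ""]
        assert set(tested[["group_a", "group_b"]].iloc[0]) == {"C40", "C3"}

    def test_adjusted_p_at_least_raw(self, run):
        res = run["symbiont_tests"]
        tested = res[res["adjusted_p"].notna()]
        assert (tested["adjusted_p"] >= tested["raw_p"] - 1e-12).all()

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(33)
        traj, prof = _null_trajectories(rng, ["C40", "C3", "C15"])
        res1 = tradeoff.symbiont_effect_test(traj, prof)
        swapped = prof.replace({"its2_profile": {"C40": "Z1", "C3": "Z2",
                                                 "C15": "Z3"}})
        res2 = tradeoff.symbiont_effect_test(traj, swapped)
        assert sorted(res1["adjusted_p"].round(10)) \
            == sorted(res2["adjusted_p"].round(10))


class TestConfounders:
    def test_bonferroni_identity(self):
        rng = np.random.default_rng(41)
        # heavy-tailed trait forces the nonparametric branch
        data = pd.DataFrame({
            "pm": np.repeat(["none", "some", "lots"], 20),
            "trait": rng.standard_cauchy(60)})
        res = tradeoff.confounder_tests(data, "pm", ["trait"])
        assert (res["flag"].str.contains("kruskal").any())
        wil = res[res["adjustment_method"] == "bonferroni"]
        np.testing.assert_allclose(wil["adjusted_p"],
                                   np.minimum(1.0, wil["raw_p"] * 3))

    def test_normal_data_uses_anova_branch(self):
        rng = np.random.default_rng(42)
        data = pd.DataFrame({
            "pm": np.repeat([False, True], 25),
            "trait": rng.normal(0, 1, 50)})
        res = tradeoff.confounder_tests(data, "pm", ["trait"])
        assert res["flag"].str.contains("anova_tukey").any()
        omnibus = res[res["group_a"] == "omnibus"].iloc[0]
        assert omnibus["raw_p"] > 0.01  # no true group effect

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(43)
        ps = []
        for _ in range(60):
            data = pd.DataFrame({"pm": np.repeat([False, True], 15),
                                 "trait": rng.normal(0, 1, 30)})
            res = tradeoff.confounder_tests(data, "pm", ["trait"])
            ps.append(res[res["group_a"] == "omnibus"]["raw_p"].iloc[0])
        assert 0.3 < np.mean(ps) < 0.7
        assert (np.array(ps) < 0.05).mean() < 0.2


class TestPca:
    def test_two_profile_data_is_rank_one(self):
        rng = np.random.default_rng(51)
        a = rng.uniform(0.2, 0.8, 12)
        prof = pd.DataFrame({
            "colony_id": np.repeat([f"A{i}" for i in range(12)], 2),
            "its2_profile": ["C40", "C3"] * 12,
            "relative_abundance": np.column_stack([a, 1 - a]).ravel()})
        res = tradeoff.its2_pca(prof)
        assert res["explained_variance_ratio"][0] == pytest.approx(1.0)

    def test_identical_profiles_degenerate(self):
        prof = pd.DataFrame({
            "colony_id": [f"A{i}" for i in range(6)] * 2,
            "its2_profile": ["C40"] * 6 + ["C3"] * 6,
            "relative_abundance": [0.7] * 6 + [0.3] * 6})
        with pytest.raises(DegenerateFitError):
            tradeoff.its2_pca(prof)

    def test_scores_invariant_to_colony_order(self, dataset, run):
        prof = dataset["symbiont"]
        cats = run["summaries"].set_index("colony_id")["tolerance_category"]
        a = tradeoff.its2_pca(prof, cats)["scores"]
        shuffled = prof.sample(frac=1.0, random_state=0)
        b = tradeoff.its2_pca(shuffled, cats)["scores"]
        merged = a.merge(b, on="colony_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(np.abs(merged["PC1_a"]),
                                   np.abs(merged["PC1_b"]), atol=1e-9)
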