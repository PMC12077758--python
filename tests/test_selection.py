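import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from latdiv.mixedmodel import DesignSpec, LMMFit, fit_lmm_ml, information_criteria
from latdiv.selection import (
    akaike_weights,
    all_subsets,
    average_terms,
    collinearity_screen,
    compare_global_sets,
    driver_analysis,
    intraspecific_trends,
    model_average,
    polynomial_ladder,
    select_by_delta_rule,
)
from latdiv.synthetic import SimConfig, simulate_env_fields, simulate_response_table

ND_LADDER_AICS = {0: -1553.921, 1: -1555.173, 2: -1559.18, 3: -1559.971,
                  4: -1558.948}
HD_LADDER_AICS = {0: -139.5476, 1: -138.3875, 2: -143.0154, 3: -142.1394,
                  4: -144.0229}


class TestDeltaRule:
    def test_parsimony_within_close_set_nd(self):
        sel, reason = select_by_delta_rule(ND_LADDER_AICS)
        assert sel == 2
        assert reason == "parsimony among close set"

    def test_parsimony_within_close_set_hd(self):
        sel, _ = select_by_delta_rule(HD_LADDER_AICS)
        assert sel == 2

    def test_full_tie_takes_least_complex(self):
        sel, _ = select_by_delta_rule({o: 100.0 for o in range(5)})
        assert sel == 0

    def test_unique_best(self):
        sel, reason = select_by_delta_rule({0: 10.0, 1: 20.0, 2: 30.0})
        assert sel == 0
        assert reason == "unique best by delta rule"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_by_delta_rule({})


class TestAkaikeWeights:
    def test_delta_zero_two(self):
        w = akaike_weights([100.0, 102.0])
        np.testing.assert_allclose(w, [0.7311, 0.2689], atol=5e-5)

    def test_equal_pair_splits_evenly(self):
        np.testing.assert_allclose(akaike_weights([5.0, 5.0]), [0.5, 0.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8),
           st.floats(-100, 100))
    def test_sum_one_and_shift_invariant(self, ics, shift):
        w = akaike_weights(ics)
        assert np.sum(w) == pytest.approx(1.0)
        np.testing.assert_allclose(
            akaike_weights([v + shift for v in ics]), w, atol=1e-9
        )


class TestPolynomialLadder:
    def test_selected_order_never_trails_close_set(self, rng):
        df, _ = simulate_response_table(SimConfig(), 3)
        lad = polynomial_ladder(df["pi"].to_numpy(), df["band"].to_numpy(),
                                groups=df["species_id"].to_numpy())
        aics = {int(r["order"]): r["AIC"] for _, r in lad.rows.iterrows()
                if r["converged"]}
        best = min(aics.values())
        assert aics[lad.selected_order] - best < 2.0
        assert all(aics[o] >= aics[lad.selected_order] - 2.0
                   for o in aics if o < lad.selected_order)

    def test_quadratic_truth_selects_at_least_two(self):
        # strong curvature relative to the variance components, so the
        # ladder has unambiguous evidence for a non-linear term
        df, _ = simulate_response_table(
            SimConfig(beta_pi=(0.012, 0.0, -0.02)), 42
        )
        lad = polynomial_ladder(df["pi"].to_numpy(), df["band"].to_numpy(),
                                groups=df["species_id"].to_numpy())
        assert lad.selected_order >= 2
        assert lad.fits[lad.selected_order].beta[2] < 0

    def test_ols_mode_without_groups(self, rng):
        x = rng.uniform(-30, 30, 40)
        y = 0.5 - 0.01 * (x / 15) ** 2 + rng.normal(0, 0.01, 40)
        lad = polynomial_ladder(y, x, mixed=False)
        assert lad.selected_order >= 1
        assert not lad.mixed


class TestCollinearityScreen:
    def test_env_pair_yields_two_candidate_sets(self):
        env = simulate_env_fields(SimConfig(), 5)
        env_vars = env.drop(columns=["band", "lat", "lon"])
        scaled = (env_vars - env_vars.mean()) / env_vars.std()
        report = collinearity_screen(scaled)
        assert report.flagged_pairs == [("BO_sstmean", "BO_dissox")]
        assert len(report.candidate_sets) == 2
        assert all(len(s) == 5 for s in report.candidate_sets)
        with_do = [s for s in report.candidate_sets if "BO_dissox" in s][0]
        with_sst = [s for s in report.candidate_sets if "BO_sstmean" in s][0]
        assert "BO_sstmean" not in with_do and "BO_dissox" not in with_sst

    def test_orthogonal_variables_single_set(self, rng):
        n = 200
        env = pd.DataFrame({f"v{i}": rng.normal(size=n) for i in range(4)})
        report = collinearity_screen(env)
        assert report.candidate_sets == [list(env.columns)]
        assert all(v < 1.2 for v in report.vif.values())

    def test_two_predictor_vif_closed_form(self, rng):
        a = rng.normal(size=5000)
        b = 0.8 * a + math.sqrt(1 - 0.64) * rng.normal(size=5000)
        env = pd.DataFrame({"a": a, "b": b})
        report = collinearity_screen(env)
        r2 = report.pearson.loc["a", "b"] ** 2
        expected = 1.0 / (1.0 - r2)
        assert report.vif["a"] == pytest.approx(expected, rel=1e-9)
        assert report.vif["b"] == pytest.approx(expected, rel=1e-9)
        assert report.flagged_pairs == [("a", "b")]
        assert not report.flagged_vars  # VIF ~2.8 is under the threshold

    def test_perfect_collinearity_infinite_vif(self, rng):
        a = rng.normal(size=50)
        env = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=50)})
        report = collinearity_screen(env)
        assert math.isinf(report.vif["a"])
        assert ("a", "b") in report.flagged_pairs


def _fake_fit(loglik, k=7):
    return LMMFit(beta=np.zeros(1), se_beta=np.zeros(1), t_values=np.zeros(1),
                  sigma2_alpha=0.0, sigma2_eps=1.0, loglik=loglik, k=k,
                  N=100, converged=True, names=["intercept"])


class TestCompareGlobalSets:
    def test_clear_winner_retained_alone(self):
        fits = [("setA", _fake_fit(-43.0)), ("setB", _fake_fit(-48.0))]
        assert compare_global_sets(fits) == ["setA"]

    def test_close_sets_both_retained(self):
        fits = [("setA", _fake_fit(-43.0)), ("setB", _fake_fit(-43.75))]
        assert compare_global_sets(fits) == ["setA", "setB"]

    def test_single_set_is_itself(self):
        assert compare_global_sets([("only", _fake_fit(-5.0))]) == ["only"]


@pytest.fixture(scope="module")
def driver_data():
    cfg = SimConfig(env_effects={"BO_chlomean": 0.0065})
    df, _ = simulate_response_table(cfg, 9)
    env_vars = ["BO_dissox", "BO_salinity", "BO2_curvelmean_bdmean",
                "BO_chlomean", "BO22_ph"]
    scaled = df[env_vars].apply(lambda c: (c - c.mean()) / c.std())
    return df, scaled, env_vars


class TestAllSubsets:
    def test_counts_all_subsets_including_null(self, driver_data):
        df, scaled, _ = driver_data
        ranking = all_subsets(df["pi"].to_numpy(), scaled,
                              df["species_id"].to_numpy())
        assert len(ranking.table) == 32
        assert () in set(ranking.table["terms"])
        assert ranking.table["weight"].sum() == pytest.approx(1.0)
        assert (ranking.table["AICc"].diff().dropna() >= 0).all()

    def test_ranking_agrees_with_independent_refits(self, driver_data):
        df, scaled, _ = driver_data
        y = df["pi"].to_numpy()
        groups = df["species_id"].to_numpy()
        ranking = all_subsets(y, scaled, groups)
        for _, row in ranking.table.head(5).iterrows():
            terms = row["terms"]
            X = np.column_stack([np.ones(len(y))]
                                + [scaled[t].to_numpy() for t in terms])
            refit = fit_lmm_ml(DesignSpec(y, X, groups))
            aicc = information_criteria(refit.loglik, refit.k, len(y))["AICc"]
            assert row["AICc"] == pytest.approx(aicc, abs=1e-8)

    def test_matches_statsmodels_global_model(self, driver_data):
        sm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        df, scaled, env_vars = driver_data
        y = df["pi"].to_numpy()
        groups = df["species_id"].to_numpy()
        X = np.column_stack([np.ones(len(y)), scaled.to_numpy()])
        fit = fit_lmm_ml(DesignSpec(y, X, groups))
        ref = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)


class TestModelAverage:
    def test_two_model_hand_example(self):
        table = average_terms([0.6, 0.4], [{"x": (1.0, 0.1)}, {}], terms=["x"])
        row = table.iloc[0]
        assert row["estimate"] == pytest.approx(0.6)
        assert row["se"] == pytest.approx(math.sqrt(0.246))
        assert row["se"] == pytest.approx(0.4960, abs=5e-5)
        assert row["importance"] == pytest.approx(0.6)

    def test_single_model_identity(self, rng):
        df, _ = simulate_response_table(SimConfig(), 17)
        scaled = df[["BO_chlomean"]].apply(lambda c: (c - c.mean()) / c.std())
        ranking = all_subsets(df["pi"].to_numpy(), scaled,
                              df["species_id"].to_numpy())
        top = ranking.table[ranking.table["delta_AICc"] < 2.0]
        if len(top) == 1:
            avg = model_average(ranking)
            fit = ranking.fits[top.iloc[0]["terms"]]
            for name, b, s in zip(fit.names, fit.beta, fit.se_beta):
                if name == "intercept":
                    continue
                row = avg.table.set_index("term").loc[name]
                assert row["estimate"] == pytest.approx(b)
                assert row["se"] == pytest.approx(s)
                assert row["importance"] == pytest.approx(1.0)

    def test_term_in_every_top_model_has_unit_importance(self):
        table = average_terms(
            [0.5, 0.3, 0.2],
            [{"x": (1.0, 0.1)}, {"x": (0.8, 0.2)}, {"x": (1.2, 0.15)}],
        )
        assert table.iloc[0]["importance"] == pytest.approx(1.0)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError):
            average_terms([0.5, 0.2], [{"x": (1.0, 0.1)}, {}])


class TestDriverAnalysis:
    def test_known_chlorophyll_driver_is_detected(self):
        detected = 0
        for seed in range(15):
            cfg = SimConfig(env_effects={"BO_chlomean": 0.0065})
            df, _ = simulate_response_table(cfg, seed)
            env = df[["band", "BO_sstmean", "BO_dissox", "BO_salinity",
                      "BO2_curvelmean_bdmean", "BO_chlomean", "BO22_ph"]] \
                .drop_duplicates("band")
            report = driver_analysis(df, env, "pi")
            ok = True
            for avg in report.averaged.values():
                row = avg.table.set_index("term").loc["BO_chlomean"]
                ok &= bool(row["ci_excludes_zero"]) and row["importance"] > 0.8
            if ok and report.retained_sets:
                detected += 1
        assert detected >= 13

    def test_pure_noise_rarely_excludes_zero(self):
        flags, total = 0, 0
        for seed in range(10):
            df, _ = simulate_response_table(SimConfig(), 100 + seed)
            env = df[["band", "BO_sstmean", "BO_dissox", "BO_salinity",
                      "BO2_curvelmean_bdmean", "BO_chlomean", "BO22_ph"]] \
                .drop_duplicates("band")
            report = driver_analysis(df, env, "pi")
            for avg in report.averaged.values():
                flags += int(avg.table["ci_excludes_zero"].sum())
                total += len(avg.table)
        assert flags / total <= 0.2

    def test_single_variable_reduces_to_identity_average(self):
        cfg = SimConfig(env_effects={"BO_chlomean": 0.01})
        df, _ = simulate_response_table(cfg, 23)
        env = df[["band", "BO_chlomean", "BO_salinity"]].drop_duplicates("band")
        report = driver_analysis(df, env, "pi")
        assert report.retained_sets
        for avg in report.averaged.values():
            assert set(avg.table["term"]) <= {"BO_chlomean", "BO_salinity"}


class TestIntraspecificTrends:
    def _table(self, rng, n_bands=12, quad=-0.02, noise=0.002):
        bands = np.arange(-n_bands // 2, n_bands - n_bands // 2)
        z = (bands - bands.mean()) / bands.std(ddof=1)
        rows = []
        for sp in ("spA", "spB"):
            pi = 0.02 + quad * z**2 + rng.normal(0, noise, n_bands)
            hd = 0.8 + 10 * quad * z**2 + rng.normal(0, 10 * noise, n_bands)
            for b, p, h in zip(bands, pi, hd):
                rows.append((sp, b, p, h))
        return pd.DataFrame(rows, columns=["species_id", "band", "pi", "hd"])

    def test_hump_detected_in_most_seeds(self):
        hits = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            out = intraspecific_trends(self._table(rng))
            sub = out[out["metric"] == "pi"]
            hits += int((sub["selected_order"] >= 2).sum())
            total += len(sub)
        assert hits / total >= 0.8

    def test_flat_diversity_selects_null_without_r2(self, rng):
        out = intraspecific_trends(self._table(rng, quad=0.0, noise=0.001))
        nulls = out[out["selected_order"] == 0]
        assert len(nulls) > 0
        assert nulls["adj_r2"].isna().all()

    def test_four_bands_caps_order(self, rng):
        df = self._table(rng, n_bands=4)
        out = intraspecific_trends(df)
        assert (out["selected_order"] <= 2).all()
        assert len(out) == 4  # 2 species x 2 metrics
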