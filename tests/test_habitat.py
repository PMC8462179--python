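"""Use-availability selection model: table building, VIF, fit, selection, maps."""

import numpy as np
import pandas as pd
import pytest

import sealforage as sf
from sealforage.habitat import HabitatSelectionModel


def logistic_table(n, rng, beta_bathy=-0.05, beta_tidal=0.0, intercept=2.0,
                   n_individuals=6, extra_covs=()):
    """Rows sampled from a known logistic law (synthetic use-availability data)."""
    bathy = rng.uniform(0, 120, n)
    tidal = rng.uniform(0, 1.5, n)
    eta = intercept + beta_bathy * bathy + beta_tidal * tidal
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    df = pd.DataFrame({"response": y, "bathy": bathy, "tidal": tidal,
                       "individual": rng.choice([f"i{k}" for k in range(n_individuals)], n)})
    for name in extra_covs:
        df[name] = rng.uniform(0, 10, n)
    return df


class TestBuildTable:
    @staticmethod
    def inputs(rng, n_dives=100, ratio=2):
        f = pd.DataFrame({"individual": "a", "dive_id": [f"d{i}" for i in range(n_dives)],
                          "bathy": rng.uniform(0, 50, n_dives)})
        a = pd.DataFrame({"individual": "a",
                          "bathy": rng.uniform(0, 50, ratio * n_dives)})
        return f, a

    def test_row_count(self):
        f, a = self.inputs(np.random.default_rng(0))
        assert len(sf.build_table(f, a)) == 300

    def test_column_means_preserved(self):
        f, a = self.inputs(np.random.default_rng(1))
        t = sf.build_table(f, a)
        assert t.loc[t.response == 1, "bathy"].mean() == pytest.approx(f["bathy"].mean())
        assert t.loc[t.response == 0, "bathy"].mean() == pytest.approx(a["bathy"].mean())

    def test_row_shuffle_leaves_fit_invariant(self):
        rng = np.random.default_rng(2)
        tab = logistic_table(800, rng)
        fit1 = HabitatSelectionModel(tab, smooths=("bathy", "tidal"),
                                     sediment=None).fit(lambdas=[1.0, 1.0, 1.0])
        shuffled = tab.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = HabitatSelectionModel(shuffled, smooths=("bathy", "tidal"),
                                     sediment=None).fit(lambdas=[1.0, 1.0, 1.0])
        assert fit1.deviance == pytest.approx(fit2.deviance, abs=1e-6)

    def test_single_class_individual_rejected(self):
        f = pd.DataFrame({"individual": ["a", "b"], "dive_id": ["d0", "d1"],
                          "bathy": [1.0, 2.0]})
        a = pd.DataFrame({"individual": ["a", "a"], "bathy": [3.0, 4.0]})
        with pytest.raises(ValueError, match="one response class|pseudo-absences"):
            sf.build_table(f, a)


class TestVif:
    def test_independent_covariates_near_one(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame({"bathy": rng.normal(size=5000),
                            "tidal": rng.normal(size=5000),
                            "dist_shore": rng.normal(size=5000)})
        v = sf.vif_screen(tab, covariates=("bathy", "tidal", "dist_shore"),
                          categorical=None)
        assert (v < 1.1).all()

    def test_duplicated_covariate_infinite(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=500)
        tab = pd.DataFrame({"bathy": x, "tidal": x.copy()})
        with pytest.warns(UserWarning, match="collinear"):
            v = sf.vif_screen(tab, covariates=("bathy", "tidal"), categorical=None)
        assert np.isinf(v).all()

    def test_correlated_pair_matches_closed_form(self):
        rng = np.random.default_rng(5)
        n = 40000
        x = rng.normal(size=n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
        tab = pd.DataFrame({"bathy": x, "tidal": y})
        with pytest.warns(UserWarning):
            v = sf.vif_screen(tab, covariates=("bathy", "tidal"), categorical=None)
        assert v["bathy"] == pytest.approx(1 / (1 - 0.81), rel=0.05)


class TestFit:
    def test_linear_effect_recovered_within_ci(self):
        rng = np.random.default_rng(6)
        tab = logistic_table(6000, rng, beta_bathy=-0.05)
        m = HabitatSelectionModel(tab, smooths=("bathy", "tidal"), sediment=None,
                                  linear=True)
        res = m.fit()
        sl = m.slices["bathy"]
        est = res.params[sl][0]
        se = np.sqrt(res.cov_params[sl, sl][0, 0])
        truth = -0.05 * tab["bathy"].std()
        assert abs(est - truth) < 1.96 * se
        # fitted smooth is monotone decreasing in bathymetry
        grid = pd.DataFrame({"bathy": np.linspace(5, 115, 40),
                             "tidal": np.full(40, 0.7)})
        mu = res.predict(grid)
        assert (np.diff(mu) < 0).all()

    def test_null_data_low_explained_deviance(self):
        rng = np.random.default_rng(7)
        tab = logistic_table(6000, rng, beta_bathy=0.0, intercept=-0.7)
        res = HabitatSelectionModel(tab, smooths=("bathy", "tidal"), sediment=None).fit()
        assert res.explained_deviance < 2.0

    def test_refit_identical_aic(self):
        rng = np.random.default_rng(8)
        tab = logistic_table(2000, rng)
        a = HabitatSelectionModel(tab, smooths=("bathy", "tidal"), sediment=None).fit()
        b = HabitatSelectionModel(tab, smooths=("bathy", "tidal"), sediment=None).fit()
        assert a.aic == pytest.approx(b.aic, abs=1e-8)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(9)
        tab = logistic_table(1500, rng)
        lam = [0.5, 0.5, 2.0]
        res = HabitatSelectionModel(tab, smooths=("bathy", "tidal"),
                                    sediment=None).fit(lambdas=lam)
        swapped = tab.assign(response=1 - tab["response"])
        res2 = HabitatSelectionModel(swapped, smooths=("bathy", "tidal"),
                                     sediment=None).fit(lambdas=lam)
        np.testing.assert_allclose(res.params, -res2.params, atol=1e-6)

    def test_deviance_non_increasing_with_extra_term(self):
        rng = np.random.default_rng(10)
        tab = logistic_table(3000, rng)
        small = HabitatSelectionModel(tab, smooths=("bathy",),
                                      sediment=None).fit(lambdas=[1.0, 1.0])
        large = HabitatSelectionModel(tab, smooths=("bathy", "tidal"),
                                      sediment=None).fit(lambdas=[1.0, 1.0, 1.0])
        assert large.deviance <= small.deviance + 1e-6 * abs(small.deviance)

    def test_sign_recovery_over_replicates(self):
        """Both effect signs recovered in >= 90% of 10 quick replicates."""
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            tab = logistic_table(3000, rng, beta_bathy=-0.05, beta_tidal=1.5)
            m = HabitatSelectionModel(tab, smooths=("bathy", "tidal"), sediment=None,
                                      linear=True)
            res = m.fit()
            b = res.params[m.slices["bathy"]][0]
            t = res.params[m.slices["tidal"]][0]
            hits += int(b < 0 and t > 0)
        assert hits >= 9

    def test_separation_guard_raises_or_converges(self):
        # a covariate perfectly separating the classes must not crash the fit
        rng = np.random.default_rng(11)
        n = 400
        x = rng.uniform(-1, 1, n)
        tab = pd.DataFrame({"response": (x > 0).astype(int), "bathy": x,
                            "tidal": rng.normal(size=n), "individual": "a"})
        try:
            res = HabitatSelectionModel(tab, smooths=("bathy", "tidal"), sediment=None).fit()
            assert np.isfinite(res.aic)
        except RuntimeError:
            pass  # an explicit failure is acceptable; a hang or crash is not


class TestSelection:
    def test_ledger_delta_aic_zero_at_winner(self):
        rng = np.random.default_rng(12)
        tab = logistic_table(1500, rng)
        best, ledger = sf.select_model(tab, smooths=("bathy", "tidal"),
                                       include_sediment=False)
        assert ledger.loc[ledger["ok"], "delta_aic"].min() == 0.0

    def test_exact_tie_resolved_deterministically(self):
        rng = np.random.default_rng(13)
        tab = logistic_table(1200, rng)
        best, ledger = sf.select_model(tab, candidates=[["bathy"], ["bathy"]],
                                       include_sediment=False)
        # duplicate candidates tie exactly: the stable sort keeps the first
        assert ledger["aic"].iloc[0] == ledger["aic"].iloc[1]
        assert best.model.smooth_names == ["bathy"]
        assert ledger.loc[ledger["ok"], "delta_aic"].min() == 0.0

    def test_noise_covariate_usually_excluded(self):
        """True model bathy-only; AIC keeps the pure-noise smooth out.

        With one noise smooth costing ~1 effective df, AIC admits it when the
        deviance drop exceeds 2, i.e. with probability ~P(chi2_1 > 2) ~ 0.16
        per replicate; 12 replicates should see >= 8 exclusions.
        """
        wins = 0
        for rep in range(12):
            rng = np.random.default_rng(300 + rep)
            tab = logistic_table(2000, rng, beta_bathy=-0.06)
            best, _ = sf.select_model(tab, smooths=("bathy", "tidal"),
                                      include_sediment=False)
            sel = set(best.model.smooth_names)
            assert "bathy" in sel            # the real effect is never dropped
            wins += int(sel == {"bathy"})
        assert wins >= 8


class TestDevianceAndImportance:
    def test_hand_computed_deviance_ten_rows(self):
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0])
        x = np.linspace(-1, 1, 10)
        tab = pd.DataFrame({"response": y, "bathy": x, "individual": "a"})
        m = HabitatSelectionModel(tab, smooths=("bathy",), sediment=None, linear=True)
        res = m.fit(lambdas=[])
        mu = res.fittedvalues()
        dev_hand = -2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        assert res.deviance == pytest.approx(dev_hand, abs=1e-10)
        p0 = y.mean()
        null_hand = -2 * np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0))
        assert res.explained_deviance == pytest.approx(
            100 * (1 - dev_hand / null_hand), abs=1e-10)

    def test_intercept_only_zero_explained_deviance(self):
        rng = np.random.default_rng(14)
        tab = pd.DataFrame({"response": rng.integers(0, 2, 200),
                            "individual": "a"})
        res = HabitatSelectionModel(tab, smooths=(), sediment=None).fit()
        assert res.explained_deviance == pytest.approx(0.0, abs=1e-8)

    def test_single_covariate_importance_100(self):
        rng = np.random.default_rng(15)
        tab = logistic_table(1200, rng)
        res = HabitatSelectionModel(tab, smooths=("bathy",), sediment=None).fit()
        imp = res.term_importance()
        assert imp["bathy"] == pytest.approx(100.0)

    def test_equal_effects_give_equal_shares(self):
        rng = np.random.default_rng(16)
        n = 6000
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        eta = a + b
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        tab = pd.DataFrame({"response": y, "bathy": a, "tidal": b, "individual": "z"})
        res = HabitatSelectionModel(tab, smooths=("bathy", "tidal"), sediment=None).fit()
        imp = res.term_importance()
        assert imp.sum() == pytest.approx(100.0, abs=0.5)
        assert abs(imp["bathy"] - 50.0) < 10.0

    def test_shares_sum_to_100(self, ua_table):
        res = HabitatSelectionModel(ua_table).fit()
        assert res.term_importance().sum() == pytest.approx(100.0, abs=0.5)


class TestGlobalMode:
    def test_one_in_three_row_counts(self, ua_table):
        sub = sf.subsample_one_in_three(ua_table)
        n_dives_full = (ua_table["response"] == 1).sum()
        n_dives_sub = (sub["response"] == 1).sum()
        per_ind = ua_table.loc[ua_table.response == 1].groupby("individual").size()
        expect = int(sum(int(np.ceil(c / 3)) for c in per_ind))
        assert n_dives_sub == expect
        # absences follow their dives
        assert set(sub.loc[sub.response == 0, "dive_ref"]) <= \
            set(sub.loc[sub.response == 1, "dive_ref"])

    def test_subsampling_changes_coefficients_less_than_one_se(self):
        rng = np.random.default_rng(17)
        n = 30000
        tab = logistic_table(n, rng, beta_bathy=-0.05)
        tab["dive_ref"] = [f"d{i}" for i in range(n)]  # treat rows as independent dives
        full = HabitatSelectionModel(tab, smooths=("bathy", "tidal"), sediment=None,
                                     linear=True)
        rf = full.fit()
        sub_tab = tab.iloc[::3].reset_index(drop=True)
        sub = HabitatSelectionModel(sub_tab, smooths=("bathy", "tidal"), sediment=None,
                                    linear=True)
        rs = sub.fit()
        sl = full.slices["bathy"]
        se_sub = np.sqrt(rs.cov_params[sub.slices["bathy"], sub.slices["bathy"]][0, 0])
        assert abs(rf.params[sl][0] - rs.params[sub.slices["bathy"]][0]) < se_sub

    def test_global_mode_adds_site_intercepts(self, ua_table):
        tab = ua_table.copy()
        tab["site"] = np.where(tab.index % 2 == 0, "sA", "sB")
        m = HabitatSelectionModel(tab, mode="global")
        assert "re_site" in m.slices


class TestPredictMap:
    def test_intercept_only_constant_map(self, small_seascape):
        rng = np.random.default_rng(18)
        tab = pd.DataFrame({"response": rng.integers(0, 2, 300), "individual": "a"})
        res = HabitatSelectionModel(tab, smooths=(), sediment=None).fit()
        maps = res.predict_map(small_seascape)
        vals = maps["probability"][small_seascape.sea]
        expect = 1 / (1 + np.exp(-res.params[0]))
        np.testing.assert_allclose(vals, expect, atol=1e-9)

    def test_probabilities_in_unit_interval(self, ua_table, small_seascape):
        res = HabitatSelectionModel(ua_table).fit()
        maps = res.predict_map(small_seascape)
        v = maps["probability"][np.isfinite(maps["probability"])]
        assert ((v >= 0) & (v <= 1)).all()
        assert np.isnan(maps["probability"][small_seascape.land]).all()


def test_summary_mentions_key_quantities(ua_table):
    res = HabitatSelectionModel(ua_table).fit()
    text = res.summary()
    assert "AIC" in text and "explained" in text and "dist_haulout" in text


def test_matches_mgcv_reference_fit(tmp_path):
    """Cross-check against an mgcv binomial GAM on the same data.

    The reference fit uses thin-plate smooths without random effects;
    agreement is checked on fitted probabilities and explained deviance.
    """
    import subprocess

    rng = np.random.default_rng(19)
    tab = logistic_table(3000, rng, beta_bathy=-0.05, beta_tidal=1.0)
    csv = tmp_path / "tab.csv"
    tab.to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(f"""
library(mgcv)
d <- read.csv("{csv}")
m <- gam(response ~ s(bathy, k=5) + s(tidal, k=5), family=binomial, data=d)
ed <- 100 * (1 - m$deviance / m$null.deviance)
write.csv(data.frame(mu=fitted(m), ed=ed), "{tmp_path / 'out.csv'}", row.names=FALSE)
""")
    subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "out.csv")
    res = HabitatSelectionModel(tab, smooths=("bathy", "tidal"), sediment=None).fit()
    mine = res.fittedvalues()
    assert np.corrcoef(mine, ref["mu"])[0, 1] > 0.98
    assert abs(res.explained_deviance - ref["ed"].iloc[0]) < 3.0
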