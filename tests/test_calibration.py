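import datetime as dt

import numpy as np
import pandas as pd
import pytest

import cgmtap
from cgmtap.calibration import (MCMCConfig, ParameterEstimates, _HAVE_NUMBA,
                                gbm_predict_params, mcmc_estimate)
from cgmtap.markers import MarkerMatrix, compute_kinship
from cgmtap.phenology import WeatherSeries, predict_heading_batch
from cgmtap.simulate import calibration_design_weathers
from _oracles import founder_panel

FAST = MCMCConfig(n_iter=1500, burn_in=400, thin=5, rng_seed=7)


def _hd_table(weathers, P, S, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for e, w in weathers.items():
        d = predict_heading_batch(P, S, w)
        d = d + noise_sd * rng.standard_normal(len(P))
        rows += [(f"V{v:03d}", e, d[v]) for v in range(len(P))]
    return pd.DataFrame(rows, columns=["variety_id", "env_id", "hd"])


class TestMCMC:
    def test_zero_noise_recovery(self):
        """Noise-free heading dates pin the parameters: posterior means
        land within (±2 °C·d, ±0.05) of truth for ≥90% of varieties."""
        weathers = calibration_design_weathers(8, seed=1)
        n = 30
        P_t, S_t = np.full(n, 100.0), np.full(n, 0.5)
        df = _hd_table(weathers, P_t, S_t)
        est = mcmc_estimate(df, weathers, cfg=MCMCConfig(rng_seed=3))
        ok = (((est.table["P_mean"] - 100).abs() <= 2)
              & ((est.table["SLDL_mean"] - 0.5).abs() <= 0.05))
        assert ok.mean() >= 0.9

    def test_flat_sldl_when_days_long(self):
        """With long days at the leaf-number-fixing stage the likelihood
        is flat in SLDL: its posterior stays prior-wide while P is
        still recovered."""
        sow = dt.date(2012, 5, 1)  # late-spring sowing at high latitude
        weathers = {
            f"L{i}": WeatherSeries(f"L{i}", sow, np.full(300, 14.0 + 2 * i),
                                   latitude=62.0)
            for i in range(4)
        }
        for w in weathers.values():
            # the leaf-number-fixing stage falls in this saturated window
            assert w.daylength_h[10:60].min() > 15.0
        n = 20
        df = _hd_table(weathers, np.full(n, 95.0), np.full(n, 0.7))
        est = mcmc_estimate(df, weathers, cfg=MCMCConfig(rng_seed=5))
        assert est.table["SLDL_sd"].median() > 0.3          # ~ prior width
        assert (est.table["P_mean"] - 95).abs().median() < 2.0

    def test_same_seed_identical_chains(self):
        weathers = calibration_design_weathers(4, seed=2)
        df = _hd_table(weathers, np.full(8, 110.0), np.full(8, 0.9), 1.0, seed=4)
        a = mcmc_estimate(df, weathers, cfg=FAST)
        b = mcmc_estimate(df, weathers, cfg=FAST)
        pd.testing.assert_frame_equal(a.table, b.table)

    @pytest.mark.skipif(not _HAVE_NUMBA, reason="numba not installed")
    def test_numba_and_numpy_kernels_bit_identical(self):
        weathers = calibration_design_weathers(4, seed=2)
        df = _hd_table(weathers, np.full(6, 120.0), np.full(6, 0.4), 1.0, seed=9)
        cfg = MCMCConfig(n_iter=400, burn_in=100, thin=2, rng_seed=11,
                         sample_sigma=True)
        a = mcmc_estimate(df, weathers, cfg=cfg, use_numba=True)
        b = mcmc_estimate(df, weathers, cfg=cfg, use_numba=False)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_posterior_sd_shrinks_with_observation_sd(self):
        weathers = calibration_design_weathers(8, seed=3)
        df = _hd_table(weathers, np.full(10, 100.0), np.full(10, 0.5))
        sd_tight = mcmc_estimate(
            df, weathers, cfg=MCMCConfig(hd_noise_sd=0.1, rng_seed=1)
        ).table["P_sd"].median()
        sd_wide = mcmc_estimate(
            df, weathers, cfg=MCMCConfig(hd_noise_sd=3.0, rng_seed=1)
        ).table["P_sd"].median()
        assert sd_tight < sd_wide

    def test_single_environment_varieties_excluded(self):
        weathers = calibration_design_weathers(3, seed=4)
        df = _hd_table(weathers, np.full(5, 100.0), np.full(5, 0.5))
        envs = list(weathers)
        df = df[~((df["variety_id"] == "V000") & (df["env_id"] != envs[0]))]
        est = mcmc_estimate(df, weathers, cfg=FAST)
        assert est.excluded == ["V000"]
        assert "V000" not in est.table.index

    def test_acceptance_rates_in_open_interval(self):
        weathers = calibration_design_weathers(4, seed=6)
        df = _hd_table(weathers, np.full(6, 100.0), np.full(6, 0.5), 1.0, seed=2)
        est = mcmc_estimate(df, weathers, cfg=FAST)
        assert ((est.table["accept_rate"] > 0) & (est.table["accept_rate"] < 1)).all()
        assert est.table["P_mean"].between(60, 160).all()
        assert est.table["SLDL_mean"].between(0, 2).all()


def _marker_matrix(g):
    n, L = g.shape
    return MarkerMatrix(g, [f"V{i}" for i in range(n)], [f"M{l}" for l in range(L)])


def _estimates(ids, P, SLDL):
    return ParameterEstimates(pd.DataFrame(
        {"P_mean": P, "P_sd": 0.0, "SLDL_mean": SLDL, "SLDL_sd": 0.0,
         "accept_rate": 0.2, "n_environments": 8},
        index=pd.Index(ids, name="variety_id")), [])


class TestGBM:
    def test_heritability_one_panel_predicts_accurately(self):
        g = founder_panel(200, 500, seed=9)
        m = _marker_matrix(g)
        K = compute_kinship(m)
        rng = np.random.default_rng(9)
        eff = rng.standard_normal(500) / np.sqrt(500)
        raw = g @ eff
        P_true = 100 + 10 * (raw - raw.mean()) / raw.std()
        S_true = np.clip(0.6 + 0.03 * (raw - raw.mean()), 0, 2)
        ids = m.variety_ids
        est = _estimates(ids[:150], P_true[:150], S_true[:150])
        pred = gbm_predict_params(est, K, ids[150:])
        assert np.corrcoef(pred.table["P_mean"], P_true[150:])[0, 1] > 0.95

    def test_zero_genetic_variance_gives_fixed_part_only(self, rng):
        g = founder_panel(60, 200, seed=3)
        m = _marker_matrix(g)
        K = compute_kinship(m)
        ids = m.variety_ids
        # response = intercept + major-marker effect exactly, plus iid noise
        # unrelated to K (gamma -> 0)
        major = "M0"
        codes = m.to_frame()[major].to_numpy()
        y = 100 + 6 * codes[:40] + 0.5 * rng.standard_normal(40)
        est = _estimates(ids[:40], y, np.full(40, 0.5))
        pred = gbm_predict_params(est, K, ids[40:], markers=m,
                                  major_marker_ids=(major,), clip_to_range=False)
        info = pred.fit_info["P"]
        expected = info["beta"][0] + info["beta"][1] * codes[40:]
        ratio = info["gamma"]
        assert ratio < 0.5
        shrunk = pred.table["P_mean"].to_numpy()
        assert np.abs(shrunk - expected).max() < 1.5  # residual BLUP is small

    def test_major_locus_effect_recovered(self, rng):
        g = founder_panel(120, 300, seed=5)
        m = _marker_matrix(g)
        K = compute_kinship(m)
        ids = m.variety_ids
        codes = m.to_frame()["M7"].to_numpy()
        true_eff = 12.0
        y = 100 + true_eff * codes + rng.standard_normal(120)
        est = _estimates(ids[:90], y[:90], np.full(90, 0.5))
        pred = gbm_predict_params(est, K, ids[90:], markers=m,
                                  major_marker_ids=("M7",), clip_to_range=False)
        info = pred.fit_info["P"]
        assert info["beta"][1] == pytest.approx(true_eff, abs=2 * 1.0)

    def test_equals_ridge_when_k_from_same_markers(self, rng):
        g = (rng.random((30, 200)) < rng.uniform(0.1, 0.9, 200)).astype(float)
        m = _marker_matrix(g)
        K = compute_kinship(m)
        ids = m.variety_ids
        y = 100 + 5 * rng.standard_normal(30)
        est = _estimates(ids[:22], y[:22], np.full(22, 0.5))
        pred = gbm_predict_params(est, K, ids[22:], clip_to_range=False)
        info = pred.fit_info["P"]
        gamma = info["gamma"]
        # ridge on centered marker codes with the matched penalty
        C = g - g.mean(axis=0)
        b = K.scale_b
        lam = b / gamma
        tr, te = slice(0, 22), slice(22, 30)
        Ktt = C[tr] @ C[tr].T
        Vi = np.linalg.inv(Ktt + lam * np.eye(22))
        one = np.ones(22)
        mu = (one @ Vi @ y[:22]) / (one @ Vi @ one)
        alpha = C[tr].T @ Vi @ (y[:22] - mu)
        ridge_pred = mu + C[te] @ alpha
        assert np.abs(pred.table["P_mean"].to_numpy() - ridge_pred).max() < 1e-6

    def test_missing_variety_in_kinship_rejected(self, rng):
        g = (rng.random((10, 50)) < 0.5).astype(float)
        m = _marker_matrix(g)
        K = compute_kinship(m)
        est = _estimates(m.variety_ids[:5], np.full(5, 100.0), np.full(5, 0.5))
        with pytest.raises(KeyError):
            gbm_predict_params(est, K, ["VX"])
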