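import numpy as np
import pandas as pd
import pytest

from cgmtap.envs import EnvCovariance, bend_to_psd
from cgmtap.gei import (HDScaling, METData, MODEL_NAMES, ModelSpec,
                        build_covariates, fit_gei_model, predict_cells)
from conftest import random_psd_kinship, small_met
from _oracles import dense_gei


def _w_obj(rng, E, ids=None):
    B = rng.standard_normal((E, max(E, 6)))
    D = np.sqrt(((B[:, None, :] - B[None, :, :]) ** 2).sum(-1))
    W = 1 - D / D.max()
    return EnvCovariance(D, W, ids or [f"E{j}" for j in range(E)])


class TestModelSpec:
    def test_nine_names(self):
        assert len(MODEL_NAMES) == 9
        assert set(MODEL_NAMES) == {
            "EG", "EG_GxE", "EG_GxW", "EG_HD", "EG_GxE_HD", "EG_GxW_HD",
            "EG_HD2", "EG_GxE_HD2", "EG_GxW_HD2"}
        for name in MODEL_NAMES:
            assert ModelSpec.from_name(name).name == name

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec.from_name("EG_GxZ")


class TestBuildCovariates:
    def test_symmetric_pattern_gives_z_scores(self):
        hd = np.array([90.0, 100.0, 110.0] * 4)
        met = METData(pd.DataFrame({
            "variety_id": [f"V{i}" for i in range(12)], "env_id": "E1",
            "gy": 0.0, "hd": hd}))
        h, h2, sc = build_covariates(met, ModelSpec("none", "quadratic"))
        np.testing.assert_allclose(h, (hd - hd.mean()) / hd.std(ddof=1))
        assert h2.mean() == pytest.approx(0.0, abs=1e-12)
        assert h2.std(ddof=1) == pytest.approx(1.0)

    def test_test_records_use_training_constants(self):
        sc = HDScaling.fit(np.array([90.0, 100, 110, 95, 105]))
        h_new, _ = sc.transform(np.array([120.0]))
        assert h_new[0] == pytest.approx((120 - sc.mean_h) / sc.sd_h)

    def test_constant_hd_rejected(self):
        with pytest.raises(ValueError, match="zero HD variance"):
            HDScaling.fit(np.full(10, 100.0))


class TestFitAgainstDenseOracle:
    def test_incomplete_grid_all_structures(self, rng):
        """Spectral REML path equals explicit dense V + GLS at the
        fitted variance ratios (subset of specs; the full nine-spec
        sweep lives in the acceptance suite)."""
        K = random_psd_kinship(10, rng)
        W = _w_obj(rng, 4)
        rec = small_met(rng, n=10, E=4, alpha=[0.5, -0.3, 0.2, 0.0])
        rec = rec[rng.random(len(rec)) > 0.2].reset_index(drop=True)
        met = METData(rec)
        for name in ("EG", "EG_GxE_HD", "EG_GxW_HD2"):
            spec = ModelSpec.from_name(name)
            fit = fit_gei_model(met, spec, K, W=W if spec.gxe_structure == "W" else None)
            Sigma = (np.eye(4) if spec.gxe_structure == "identity"
                     else bend_to_psd(W.values) if spec.gxe_structure == "W" else None)
            ref = dense_gei(rec, rec.head(5), spec, K.values, K.variety_ids,
                            Sigma, W.env_ids if spec.gxe_structure == "W" else None,
                            fit.gamma_g, fit.gamma_ge, fit.sigma2_e,
                            hd_scaling=fit.hd_scaling)
            assert fit.loglik == pytest.approx(ref["loglik"], abs=1e-6)
            mine = np.concatenate(
                [fit.blues["mu"]]
                + ([fit.blues["alpha"]] if spec.hd_covariate != "none" else [])
                + ([fit.blues["beta"]] if spec.hd_covariate == "quadratic" else []))
            np.testing.assert_allclose(mine, ref["bhat"], atol=1e-6)
            np.testing.assert_allclose(
                fit.blups_g.loc[ref["var_ids"]].to_numpy(), ref["G"], atol=1e-6)
            preds = predict_cells(fit, rec.head(5), K,
                                  W=W if spec.gxe_structure == "W" else None)
            np.testing.assert_allclose(preds, ref["preds"], atol=1e-6)


class TestClosedFormLimits:
    def test_identity_kinship_single_env_is_ridge_shrinkage(self, rng):
        from cgmtap.markers import KinshipMatrix

        n = 15
        K = KinshipMatrix(np.eye(n), [f"V{i}" for i in range(n)], 1.0)
        y = 5 + rng.standard_normal(n)
        rec = pd.DataFrame({"variety_id": K.variety_ids, "env_id": "E1",
                            "gy": y, "hd": 100.0})
        s2g, s2e = 0.8, 0.4
        fit = fit_gei_model(METData(rec), ModelSpec.from_name("EG"), K,
                            fixed_components=(s2g, 0.0, s2e))
        # GLS mean with V = s2g I + s2e I is the plain mean; BLUP shrinks
        lam = 1.0 / (1.0 + s2e / s2g)
        np.testing.assert_allclose(fit.blups_g.to_numpy(),
                                   lam * (y - y.mean()), atol=1e-8)

    def test_zero_genetic_variances_give_env_means(self, rng):
        K = random_psd_kinship(12, rng)
        rec = small_met(rng, n=12, E=3)
        met = METData(rec)
        fit = fit_gei_model(met, ModelSpec.from_name("EG_GxE"), K,
                            fixed_components=(0.0, 0.0, 1.0))
        means = rec.groupby("env_id", sort=False)["gy"].mean()
        np.testing.assert_allclose(fit.blues["mu"], means[fit.train_envs], atol=1e-8)
        preds = predict_cells(fit, rec, K)
        np.testing.assert_allclose(
            preds, rec["env_id"].map(means).to_numpy(), atol=1e-8)


class TestPredictCells:
    def test_unrelated_variety_gets_fixed_part_only(self, rng):
        from cgmtap.markers import KinshipMatrix

        n = 10
        Kv = np.eye(n + 1)
        Kv[:n, :n] = random_psd_kinship(n, rng).values
        K = KinshipMatrix(Kv, [f"V{i}" for i in range(n + 1)], 1.0)
        rec = small_met(rng, n=10, E=3)
        met = METData(rec)
        fit = fit_gei_model(met, ModelSpec.from_name("EG_GxE"), K)
        cell = pd.DataFrame({"variety_id": [f"V{n}"], "env_id": ["E1"], "hd": [100.0]})
        pred = predict_cells(fit, cell, K)
        mu = fit.blues.set_index("env_id").loc["E1", "mu"]
        assert pred[0] == pytest.approx(mu, abs=1e-10)

    def test_duplicate_of_training_cell_matches_fitted_value(self, rng):
        K = random_psd_kinship(10, rng)
        W = _w_obj(rng, 3)
        rec = small_met(rng, n=10, E=3, alpha=[0.4, 0.1, -0.2])
        met = METData(rec)
        fit = fit_gei_model(met, ModelSpec.from_name("EG_GxW_HD"), K, W=W)
        env_map = fit.blues.set_index("env_id")
        h, _ = fit.hd_scaling.transform(rec["hd"].to_numpy())
        fitted = (env_map.loc[rec["env_id"], "mu"].to_numpy()
                  + env_map.loc[rec["env_id"], "alpha"].to_numpy() * h
                  + fit.blups_g.loc[rec["variety_id"]].to_numpy()
                  + fit.blups_ge["ge"].to_numpy())
        preds = predict_cells(fit, rec, K, W=W)
        np.testing.assert_allclose(preds, fitted, atol=1e-8)

    def test_new_env_conditional_gaussian_oracle(self, rng):
        """Predictions in a training-absent environment equal the dense
        conditional-expectation formula."""
        K = random_psd_kinship(15, rng)
        W = _w_obj(rng, 4)
        rec = small_met(rng, n=15, E=4)
        train = rec[rec["env_id"] != "E3"].reset_index(drop=True)
        test = rec[rec["env_id"] == "E3"].reset_index(drop=True)
        met = METData(train)
        fit = fit_gei_model(met, ModelSpec.from_name("EG_GxW"), K, W=W)
        preds = predict_cells(fit, test, K, W=W)
        ref = dense_gei(train, test, ModelSpec.from_name("EG_GxW"),
                        K.values, K.variety_ids, bend_to_psd(W.values), W.env_ids,
                        fit.gamma_g, fit.gamma_ge, fit.sigma2_e)
        np.testing.assert_allclose(preds, ref["preds"], atol=1e-6)

    def test_identity_structure_refuses_new_env(self, rng):
        K = random_psd_kinship(8, rng)
        rec = small_met(rng, n=8, E=3)
        met = METData(rec[rec["env_id"] != "E2"].reset_index(drop=True))
        fit = fit_gei_model(met, ModelSpec.from_name("EG_GxE"), K)
        cell = pd.DataFrame({"variety_id": ["V0"], "env_id": ["E2"], "hd": [100.0]})
        with pytest.raises(ValueError, match="new-environment"):
            predict_cells(fit, cell, K)


class TestInvariants:
    def test_gxe_nests_main_effect_loglik(self, rng):
        K = random_psd_kinship(12, rng)
        rec = small_met(rng, n=12, E=4)
        met = METData(rec)
        ll_eg = fit_gei_model(met, ModelSpec.from_name("EG"), K).loglik
        ll_gxe = fit_gei_model(met, ModelSpec.from_name("EG_GxE"), K).loglik
        assert ll_gxe >= ll_eg - 1e-6

    def test_variety_relabeling_equivariance(self, rng):
        from cgmtap.markers import KinshipMatrix

        K = random_psd_kinship(9, rng)
        rec = small_met(rng, n=9, E=3)
        fit1 = fit_gei_model(METData(rec), ModelSpec.from_name("EG"), K)
        p1 = predict_cells(fit1, rec, K)
        perm = np.random.default_rng(0).permutation(9)
        relabel = {f"V{i}": f"X{i}" for i in range(9)}
        K2 = KinshipMatrix(K.values[np.ix_(perm, perm)],
                           [relabel[f"V{i}"] for i in perm], 1.0)
        rec2 = rec.assign(variety_id=rec["variety_id"].map(relabel))
        fit2 = fit_gei_model(METData(rec2), ModelSpec.from_name("EG"), K2)
        p2 = predict_cells(fit2, rec2, K2)
        np.testing.assert_allclose(p1, p2, atol=1e-7)

    def test_env_with_constant_hd_named_in_error(self, rng):
        K = random_psd_kinship(8, rng)
        rec = small_met(rng, n=8, E=2)
        rec.loc[rec["env_id"] == "E1", "hd"] = 100.0
        with pytest.raises(ValueError, match="E1"):
            fit_gei_model(METData(rec), ModelSpec.from_name("EG_HD"), K)

    def test_w_spec_requires_w(self, rng):
        K = random_psd_kinship(6, rng)
        with pytest.raises(ValueError, match="W"):
            fit_gei_model(METData(small_met(rng, n=6, E=3)),
                          ModelSpec.from_name("EG_GxW"), K)

    def test_duplicate_cells_rejected(self):
        rec = pd.DataFrame({"variety_id": ["V1", "V1"], "env_id": ["E1", "E1"],
                            "gy": [1.0, 2.0], "hd": [100.0, 101.0]})
        with pytest.raises(ValueError, match="duplicate"):
            METData(rec)
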