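"""Cross-validation scenarios for trait-assisted GEI prediction.

Three prediction objectives, each with its own fold structure:

* CVrandom — sparse testing: random cells of the variety × environment
  table are hidden (6 folds, repeated).
* CVnewG — new varieties: variety groups are hidden entirely (6 folds,
  repeated).
* CVnewE — new environments: leave-one-environment-out.

Each fold runs the two-step procedure: (1) the secondary trait (heading
date) of the test cells is predicted with the phenology model — its
genetic parameters estimated by MCMC from the test varieties' heading
observed in training cells (CVrandom, CVnewE) or genomically predicted
(CVnewG); (2) each requested GEI model is fitted on the training cells
with observed heading and used to predict the test cells with the
model-predicted heading as covariate.  For CVnewE the env-specific
covariate slopes of the hidden environment are first predicted from
environmental covariates by stepwise regression.

Predictive ability is the Pearson correlation between adjusted means and
predictions, per environment within each fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import MCMCConfig, ParameterEstimates, gbm_predict_params, mcmc_estimate
from .envcoef import K_ALPHA, K_BETA, estimate_env_coefficients, stepwise_ec_predict
from .envs import ECMatrix, EnvCovariance, classify_environments
from .gei import METData, ModelSpec, fit_gei_model, predict_cells
from .markers import KinshipMatrix, MarkerMatrix
from .phenology import CGMConfig, WeatherSeries, predict_heading_batch

logger = logging.getLogger(__name__)

__all__ = ["CVPlan", "EvaluationResult", "make_folds", "run_scenario",
           "predictive_ability", "rmse", "SCENARIOS"]

SCENARIOS = ("CVrandom", "CVnewG", "CVnewE")


def predictive_ability(pred, obs) -> float:
    """Pearson correlation between predictions and adjusted means;
    nan (with a warning) when fewer than 3 pairs or constant obs."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if len(pred) < 3 or len(pred) != len(obs):
        warnings.warn("predictive ability needs >=3 aligned pairs; returning nan")
        return float("nan")
    if np.std(obs) == 0 or np.std(pred) == 0:
        warnings.warn("constant vector; predictive ability undefined")
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1])


def rmse(pred, obs) -> float:
    """Root mean squared error in trait units."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


@dataclass
class CVPlan:
    """Test-cell folds (record indices into met.records) for one repeat."""

    scenario: str
    folds: list[np.ndarray]
    n_repeats: int
    rng_seed: int

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        all_idx = np.concatenate(self.folds) if self.folds else np.array([])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("folds overlap")


def make_folds(met: METData, scenario: str, n_folds: int = 6, seed: int = 0) -> CVPlan:
    """Partition the prediction target units into folds.

    CVrandom partitions observed cells, CVnewG partitions varieties
    (a fold's test set is all cells of its varieties), CVnewE is one
    fold per environment.  Deterministic given the seed.
    """
    rec = met.records
    rng = np.random.default_rng(seed)
    if scenario == "CVrandom":
        if n_folds > len(rec):
            raise ValueError("more folds than cells")
        perm = rng.permutation(len(rec))
        folds = [np.sort(f) for f in np.array_split(perm, n_folds)]
    elif scenario == "CVnewG":
        varieties = list(pd.unique(rec["variety_id"]))
        if n_folds > len(varieties):
            raise ValueError("more folds than varieties")
        perm = rng.permutation(len(varieties))
        groups = np.array_split(perm, n_folds)
        folds = []
        for grp in groups:
            vset = {varieties[i] for i in grp}
            folds.append(np.flatnonzero(rec["variety_id"].isin(vset).to_numpy()))
    elif scenario == "CVnewE":
        folds = [np.flatnonzero((rec["env_id"] == e).to_numpy())
                 for e in pd.unique(rec["env_id"])]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    default_rep = 1 if scenario == "CVnewE" else 10
    return CVPlan(scenario=scenario, folds=folds, n_repeats=default_rep, rng_seed=seed)


@dataclass
class EvaluationResult:
    """Tidy result tables of a cross-validation run."""

    gy: pd.DataFrame   # scenario, model, repeat, fold, env_id, env_class, ability, n_cells
    hd: pd.DataFrame   # scenario, repeat, fold, hd_ability, hd_rmse, n_cells
    notices: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean predictive ability per model and environment class."""
        return (self.gy.groupby(["model", "env_class"])["ability"]
                .mean().unstack("env_class"))

    def model_class_mean(self, model: str, env_class: str) -> float:
        sub = self.gy[(self.gy["model"] == model) & (self.gy["env_class"] == env_class)]
        return float(sub["ability"].mean())


def _fold_seed(master: int, repeat: int, fold: int) -> int:
    return int(np.random.SeedSequence([master, repeat, fold]).generate_state(1)[0]
               % (2**31))


def _predict_hd_step(scenario, rec, test_idx, train_met, K, markers, major_ids,
                     weathers, mcmc_cfg, cgm_cfg, seed):
    """Step 1: phenology-model heading predictions for the test cells.
    Returns (hd_pred per test record, diagnostics dict)."""
    test = rec.iloc[test_idx]
    test_vars = list(pd.unique(test["variety_id"]))
    train_rec = train_met.records

    if scenario in ("CVrandom", "CVnewE"):
        calib = train_rec[train_rec["variety_id"].isin(test_vars)][
            ["variety_id", "env_id", "hd"]]
        est = mcmc_estimate(calib, weathers,
                            cfg=_reseed(mcmc_cfg, seed), cgm_cfg=cgm_cfg)
    else:  # CVnewG: genomic prediction of the parameters
        train_vars = [v for v in pd.unique(train_rec["variety_id"])]
        calib = train_rec[["variety_id", "env_id", "hd"]]
        est_train = mcmc_estimate(calib, weathers,
                                  cfg=_reseed(mcmc_cfg, seed), cgm_cfg=cgm_cfg)
        est = gbm_predict_params(est_train, K, test_ids=test_vars,
                                 markers=markers, major_marker_ids=tuple(major_ids))

    # evaluate the phenology model at the point estimates, per environment
    hd_pred = np.full(len(test), np.nan)
    tab = est.table
    for env, sub in test.groupby("env_id"):
        ok_vars = [v for v in sub["variety_id"] if v in tab.index]
        if not ok_vars:
            continue
        P = tab.loc[ok_vars, "P_mean"].to_numpy()
        S = tab.loc[ok_vars, "SLDL_mean"].to_numpy()
        days = predict_heading_batch(P, S, weathers[env], cgm_cfg, continuous=True)
        sel = sub["variety_id"].isin(ok_vars).to_numpy()
        pos = {v: i for i, v in enumerate(ok_vars)}
        hd_pred[np.flatnonzero(test["env_id"].to_numpy() == env)[sel]] = (
            days[[pos[v] for v in sub["variety_id"][sel]]])
    return hd_pred, est


def _reseed(cfg: MCMCConfig, seed: int) -> MCMCConfig:
    from dataclasses import replace
    return replace(cfg, rng_seed=seed)


def run_scenario(
    met: METData,
    scenario: str,
    model_specs: list[ModelSpec | str],
    K: KinshipMatrix,
    W: EnvCovariance | None = None,
    omega: ECMatrix | None = None,
    weathers: dict[str, WeatherSeries] | None = None,
    mcmc_cfg: MCMCConfig = MCMCConfig(),
    cgm_cfg: CGMConfig = CGMConfig(),
    seed: int = 0,
    n_folds: int = 6,
    n_repeats: int | None = None,
    markers: MarkerMatrix | None = None,
    major_marker_ids: tuple[str, ...] = (),
    env_classes: dict[str, str] | None = None,
    min_cells_per_env: int = 3,
) -> EvaluationResult:
    """Run one cross-validation scenario end-to-end over the requested
    GEI models and return tidy per-(repeat, fold, environment, model)
    predictive abilities plus per-fold heading-date metrics."""
    specs = [ModelSpec.from_name(s) if isinstance(s, str) else s for s in model_specs]
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    rec = met.records
    if weathers is None:
        raise ValueError("weather series are required for the phenology step")
    missing_w = set(rec["env_id"]) - set(weathers)
    if missing_w:
        raise ValueError(f"missing weather for environments {sorted(missing_w)}")
    needs_coef_pred = scenario == "CVnewE" and any(s.hd_covariate != "none" for s in specs)
    if needs_coef_pred and omega is None:
        raise ValueError("CVnewE with HD-covariate models needs the EC matrix")
    if scenario == "CVnewG" and markers is None and major_marker_ids:
        raise ValueError("major markers requested but no marker matrix given")
    if env_classes is None:
        env_classes = classify_environments(met).classes()

    if n_repeats is None:
        n_repeats = 1 if scenario == "CVnewE" else 10
    if scenario == "CVnewE":
        n_repeats = 1

    notices = []
    run_specs = []
    for s in specs:
        if scenario == "CVnewE" and s.gxe_structure == "identity":
            msg = (f"{s.name} skipped for CVnewE: a K ⊗ I interaction cannot "
                   "predict an unobserved environment")
            logger.info(msg)
            notices.append(msg)
        else:
            run_specs.append(s)

    gy_rows, hd_rows = [], []
    warm: dict[str, tuple[float, float]] = {}
    for rep in range(n_repeats):
        plan = make_folds(met, scenario, n_folds, seed=_fold_seed(seed, rep, 10**6))
        for f, test_idx in enumerate(plan.folds):
            fold_seed = _fold_seed(seed, rep, f)
            mask = np.ones(len(rec), dtype=bool)
            mask[test_idx] = False
            train_met = METData(rec.iloc[np.flatnonzero(mask)].reset_index(drop=True))
            test = rec.iloc[test_idx]

            hd_pred, _ = _predict_hd_step(
                scenario, rec, test_idx, train_met, K, markers, major_marker_ids,
                weathers, mcmc_cfg, cgm_cfg, fold_seed)
            ok_hd = ~np.isnan(hd_pred)
            obs_hd = test["hd"].to_numpy(float)
            if ok_hd.sum() >= 3:
                hd_rows.append((scenario, rep, f,
                                predictive_ability(hd_pred[ok_hd], obs_hd[ok_hd]),
                                rmse(hd_pred[ok_hd], obs_hd[ok_hd]), int(ok_hd.sum())))

            # reusable pieces of step 2 for this fold
            train_vars = [v for v in K.variety_ids
                          if v in set(train_met.records["variety_id"])]
            idx = K.index_of(train_vars)
            K_tt = K.values[np.ix_(idx, idx)]
            lam, U = np.linalg.eigh(K_tt)
            k_eig = (np.clip(lam, 0.0, None), U)

            coef_cache: dict[int, dict] = {}
            for s in run_specs:
                fit = fit_gei_model(train_met, s, K,
                                    W=W if s.gxe_structure == "W" else None,
                                    k_eig=k_eig, warm_start=warm.get(s.name))
                warm[s.name] = (max(fit.sigma2_g / fit.sigma2_e, 1e-6),
                                max(fit.sigma2_ge / fit.sigma2_e, 1e-6))
                new_env_coefs = None
                if scenario == "CVnewE" and s.hd_covariate != "none":
                    target = test["env_id"].iloc[0]
                    degree = 2 if s.hd_covariate == "quadratic" else 1
                    if degree not in coef_cache:
                        coefs = estimate_env_coefficients(train_met, degree=degree)
                        a_hat, _ = stepwise_ec_predict(coefs, omega, target, k=K_ALPHA,
                                                       coefficient="alpha")
                        b_hat = np.nan
                        if degree == 2:
                            b_hat, _ = stepwise_ec_predict(coefs, omega, target,
                                                           k=K_BETA, coefficient="beta")
                        coef_cache[degree] = {target: (a_hat, b_hat)}
                    new_env_coefs = coef_cache[degree]

                cells = test.assign(hd=hd_pred)
                use = ok_hd if s.hd_covariate != "none" else np.ones(len(test), bool)
                preds = predict_cells(fit, cells.iloc[np.flatnonzero(use)], K,
                                      W=W if s.gxe_structure == "W" else None,
                                      new_env_coefs=new_env_coefs)
                sub = test.iloc[np.flatnonzero(use)].assign(pred=preds)
                for env, env_sub in sub.groupby("env_id"):
                    if len(env_sub) < min_cells_per_env:
                        notices.append(f"rep {rep} fold {f} env {env}: "
                                       f"only {len(env_sub)} test cells, skipped")
                        continue
                    gy_rows.append((scenario, s.name, rep, f, env,
                                    env_classes.get(env, "unknown"),
                                    predictive_ability(env_sub["pred"], env_sub["gy"]),
                                    len(env_sub)))

    gy = pd.DataFrame(gy_rows, columns=["scenario", "model", "repeat", "fold",
                                        "env_id", "env_class", "ability", "n_cells"])
    hd = pd.DataFrame(hd_rows, columns=["scenario", "repeat", "fold",
                                        "hd_ability", "hd_rmse", "n_cells"])
    return EvaluationResult(gy=gy, hd=hd, notices=notices)
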