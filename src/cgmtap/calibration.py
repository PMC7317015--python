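"""Estimating phenology-model genetic parameters.

Two routes, matching the two prediction settings:

* ``mcmc_estimate`` — per-variety Bayesian calibration from observed
  heading dates in at least two environments.  Each variety gets an
  independent chain over (P, SLDL) with coordinate-wise
  Metropolis-Hastings updates (Gaussian proposal centered on the current
  value, uniform prior over the valid parameter ranges) under a Gaussian
  observation model for heading date.  The observation SD can be fixed
  or given an inverse-gamma prior and sampled by Gibbs.
* ``gbm_predict_params`` — gene-based prediction for varieties with no
  phenotype: a GBLUP mixed model (optionally with major phenology
  markers as fixed effects) is fitted per parameter on the calibrated
  varieties and evaluated for the test varieties.

Chains are vectorized across varieties; all randomness is pre-generated
from one numpy Generator so the optional numba-compiled kernel and the
pure-numpy kernel produce bit-identical chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .markers import KinshipMatrix, MarkerMatrix
from .phenology import CGMConfig, P_RANGE, SLDL_RANGE, WeatherSeries

logger = logging.getLogger(__name__)

__all__ = ["MCMCConfig", "ParameterEstimates", "mcmc_estimate", "gbm_predict_params"]

try:  # numba is optional; the numpy kernel is bit-identical
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class MCMCConfig:
    """Settings of the Metropolis-within-Gibbs calibration sampler."""

    n_iter: int = 10000
    burn_in: int = 2000
    thin: int = 10
    prop_sd_p: float = 3.0        # °C·d proposal SD for the phyllochron
    prop_sd_sldl: float = 0.05    # proposal SD for photoperiod sensitivity
    hd_noise_sd: float = 1.5      # days; fixed observation SD unless sampled
    sample_sigma: bool = False
    sigma_prior_shape: float = 2.0
    sigma_prior_scale: float = 2.0
    continuous_hd: bool = True    # interpolate the heading crossing day
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.prop_sd_p <= 0 or self.prop_sd_sldl <= 0:
            raise ValueError("proposal SDs must be positive")


@dataclass
class ParameterEstimates:
    """Per-variety point estimates (posterior means or GBLUP
    predictions) of the phenology genetic parameters."""

    table: pd.DataFrame  # index variety_id; P_mean, P_sd, SLDL_mean, SLDL_sd,
    #                      accept_rate, n_environments
    excluded: list[str]

    def params(self, variety_id: str) -> tuple[float, float]:
        row = self.table.loc[variety_id]
        return float(row["P_mean"]), float(row["SLDL_mean"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="variety_id")

    @classmethod
    def from_csv(cls, path) -> "ParameterEstimates":
        return cls(pd.read_csv(path, index_col="variety_id"), [])


def _day_py(cum, thr, continuous):
    """Crossing day (1-based) of thermal thresholds; vectorized twin of
    the compiled scalar search.  Returns day even when the series ends
    first; reachability is checked by the caller."""
    T = len(cum)
    j = np.searchsorted(cum, thr, side="left")
    reach = j < T
    if continuous:
        j_safe = np.minimum(np.maximum(j, 1), T - 1)
        day = np.where(thr <= cum[0], 1.0,
                       j_safe + (thr - cum[j_safe - 1]) / (cum[j_safe] - cum[j_safe - 1]))
    else:
        day = (np.minimum(j, T - 1) + 1).astype(float)
    return day, reach


def _eval_full(cum_cat, dl_cat, starts, hd, obs, P, S, cfg_vec, continuous):
    """SS of predicted vs observed heading per variety, plus the
    flag-stage daylength per (variety, environment).  Unreachable
    heading gives inf; the daylength falls back to the last day."""
    tt_e, hs_flag, dl_sat, l_min, l_max, k_head = cfg_vec
    n, E = hd.shape
    ss = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    DL = np.empty((n, E))
    for e in range(E):
        sel = obs[:, e]
        s0, s1 = starts[e], starts[e + 1]
        cum = cum_cat[s0:s1]
        T = s1 - s0
        i = np.searchsorted(cum, tt_e + hs_flag * P, side="left")
        reach_f = i < T
        dl_star = dl_cat[s0 + np.minimum(i, T - 1)]
        DL[:, e] = dl_star
        lf = l_min + S * np.maximum(0.0, dl_sat - dl_star)
        lf = np.minimum(np.maximum(lf, l_min), l_max)
        day, reach_h = _day_py(cum, tt_e + (lf + k_head) * P, continuous)
        reach = reach_f & reach_h
        resid = hd[:, e] - day
        ss += np.where(sel & reach, resid * resid, 0.0)
        bad |= sel & ~reach
    ss[bad] = np.inf
    return ss, DL


def _eval_sldl(cum_cat, dl_cat, starts, hd, obs, P, S, DL, cfg_vec, continuous):
    """SS at new photoperiod sensitivities, reusing the cached
    flag-stage daylength (which depends on P only)."""
    tt_e, hs_flag, dl_sat, l_min, l_max, k_head = cfg_vec
    n, E = hd.shape
    ss = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for e in range(E):
        sel = obs[:, e]
        s0, s1 = starts[e], starts[e + 1]
        cum = cum_cat[s0:s1]
        lf = l_min + S * np.maximum(0.0, dl_sat - DL[:, e])
        lf = np.minimum(np.maximum(lf, l_min), l_max)
        day, reach = _day_py(cum, tt_e + (lf + k_head) * P, continuous)
        resid = hd[:, e] - day
        ss += np.where(sel & reach, resid * resid, 0.0)
        bad |= sel & ~reach
    ss[bad] = np.inf
    return ss


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _day_nb(cum_cat, s0, s1, thr, continuous):  # pragma: no cover - parity-tested
        T = s1 - s0
        j = np.searchsorted(cum_cat[s0:s1], thr)
        if j >= T:
            return np.nan
        if continuous:
            if thr <= cum_cat[s0]:
                return 1.0
            jj = min(max(j, 1), T - 1)
            return jj + (thr - cum_cat[s0 + jj - 1]) / (
                cum_cat[s0 + jj] - cum_cat[s0 + jj - 1])
        return float(min(j, T - 1) + 1)

    @numba.njit(cache=True)
    def _chains_nb(cum_cat, dl_cat, starts, hd, obs, n_iter, burn, thin,
                   sd_p, sd_s, p0, s0_, sig2_0, sample_sigma, prior_scale,
                   prop, log_unif, gam, cfg_vec, continuous,
                   samples, sig_samples, acc):  # pragma: no cover - parity-tested
        tt_e, hs_flag, dl_sat, l_min, l_max, k_head = (
            cfg_vec[0], cfg_vec[1], cfg_vec[2], cfg_vec[3], cfg_vec[4], cfg_vec[5])
        p_lo, p_hi = P_RANGE
        s_lo, s_hi = SLDL_RANGE
        n, E = hd.shape
        dl_cache = np.empty(E)
        dl_tmp = np.empty(E)

        for v in range(n):
            P = p0
            S = s0_
            sig2 = sig2_0
            # current state: dl* per env (depends on P only) and SS
            ss_cur = 0.0
            for e in range(E):
                if not obs[v, e]:
                    continue
                s0, s1 = starts[e], starts[e + 1]
                i = np.searchsorted(cum_cat[s0:s1], tt_e + hs_flag * P)
                if i >= s1 - s0:
                    dl_cache[e] = dl_cat[s1 - 1]
                    ss_cur = np.inf
                    continue
                dl_cache[e] = dl_cat[s0 + i]
                lf = min(max(l_min + S * max(0.0, dl_sat - dl_cache[e]), l_min), l_max)
                day = _day_nb(cum_cat, s0, s1, tt_e + (lf + k_head) * P, continuous)
                if np.isnan(day):
                    ss_cur = np.inf
                else:
                    r = hd[v, e] - day
                    ss_cur += r * r
            k = 0
            for it in range(n_iter):
                # phyllochron update (re-derives the flag-stage daylength)
                cand = P + sd_p * prop[it, 0, v]
                if p_lo <= cand <= p_hi:
                    ss_new = 0.0
                    for e in range(E):
                        if not obs[v, e]:
                            continue
                        s0, s1 = starts[e], starts[e + 1]
                        i = np.searchsorted(cum_cat[s0:s1], tt_e + hs_flag * cand)
                        if i >= s1 - s0:
                            ss_new = np.inf
                            break
                        dl_tmp[e] = dl_cat[s0 + i]
                        lf = min(max(l_min + S * max(0.0, dl_sat - dl_tmp[e]),
                                     l_min), l_max)
                        day = _day_nb(cum_cat, s0, s1,
                                      tt_e + (lf + k_head) * cand, continuous)
                        if np.isnan(day):
                            ss_new = np.inf
                            break
                        r = hd[v, e] - day
                        ss_new += r * r
                    if log_unif[it, 0, v] < -0.5 * (ss_new - ss_cur) / sig2:
                        P = cand
                        ss_cur = ss_new
                        acc[v] += 1.0
                        for e in range(E):
                            dl_cache[e] = dl_tmp[e]
                # photoperiod-sensitivity update (flag daylength cached)
                cand = S + sd_s * prop[it, 1, v]
                if s_lo <= cand <= s_hi:
                    ss_new = 0.0
                    for e in range(E):
                        if not obs[v, e]:
                            continue
                        s0, s1 = starts[e], starts[e + 1]
                        lf = min(max(l_min + cand * max(0.0, dl_sat - dl_cache[e]),
                                     l_min), l_max)
                        day = _day_nb(cum_cat, s0, s1,
                                      tt_e + (lf + k_head) * P, continuous)
                        if np.isnan(day):
                            ss_new = np.inf
                            break
                        r = hd[v, e] - day
                        ss_new += r * r
                    if log_unif[it, 1, v] < -0.5 * (ss_new - ss_cur) / sig2:
                        S = cand
                        ss_cur = ss_new
                        acc[v] += 1.0
                if sample_sigma:
                    sig2 = (prior_scale + 0.5 * ss_cur) / gam[it, v]
                if it >= burn and (it - burn) % thin == 0:
                    samples[k, 0, v] = P
                    samples[k, 1, v] = S
                    sig_samples[k, v] = np.sqrt(sig2)
                    k += 1


def _run_chains(cum_cat, dl_cat, starts, hd, obs, cfg: MCMCConfig, cgm: CGMConfig,
                rng: np.random.Generator, use_numba: bool):
    n, E = hd.shape
    n_obs = obs.sum(axis=1).astype(float)
    cfg_vec = np.array([cgm.tt_emergence, cgm.hs_flag, cgm.dl_sat,
                        cgm.l_min, cgm.l_max, cgm.k_head])

    # pre-generated randomness makes the two kernels bit-identical
    prop = rng.standard_normal((cfg.n_iter, 2, n))
    log_unif = np.log(rng.random((cfg.n_iter, 2, n)))
    if cfg.sample_sigma:
        gam = rng.gamma(cfg.sigma_prior_shape + n_obs / 2.0, size=(cfg.n_iter, n))
    else:
        gam = np.ones((1, n))

    p0 = 0.5 * (P_RANGE[0] + P_RANGE[1])
    s0 = 0.5 * (SLDL_RANGE[0] + SLDL_RANGE[1])
    sig2_0 = cfg.hd_noise_sd**2
    n_keep = len(range(cfg.burn_in, cfg.n_iter, cfg.thin))
    samples = np.empty((n_keep, 2, n))
    sig_samples = np.empty((n_keep, n))
    acc = np.zeros(n)

    if use_numba and _HAVE_NUMBA:
        _chains_nb(cum_cat, dl_cat, starts, hd, obs, cfg.n_iter, cfg.burn_in,
                   cfg.thin, cfg.prop_sd_p, cfg.prop_sd_sldl, p0, s0, sig2_0,
                   cfg.sample_sigma, cfg.sigma_prior_scale, prop, log_unif, gam,
                   cfg_vec, cfg.continuous_hd, samples, sig_samples, acc)
        return samples, sig_samples, acc / (2.0 * cfg.n_iter)

    P = np.full(n, p0)
    S = np.full(n, s0)
    sig2 = np.full(n, sig2_0)
    with np.errstate(invalid="ignore"):
        ss_cur, DL = _eval_full(cum_cat, dl_cat, starts, hd, obs, P, S,
                                cfg_vec, cfg.continuous_hd)
        k = 0
        for it in range(cfg.n_iter):
            cand = P + cfg.prop_sd_p * prop[it, 0]
            in_rng = (cand >= P_RANGE[0]) & (cand <= P_RANGE[1])
            cand = np.where(in_rng, cand, P)
            ss_new, DL_new = _eval_full(cum_cat, dl_cat, starts, hd, obs, cand, S,
                                        cfg_vec, cfg.continuous_hd)
            take = in_rng & (log_unif[it, 0] < -0.5 * (ss_new - ss_cur) / sig2)
            P = np.where(take, cand, P)
            ss_cur = np.where(take, ss_new, ss_cur)
            DL[take] = DL_new[take]
            acc += take

            cand = S + cfg.prop_sd_sldl * prop[it, 1]
            in_rng = (cand >= SLDL_RANGE[0]) & (cand <= SLDL_RANGE[1])
            cand = np.where(in_rng, cand, S)
            ss_new = _eval_sldl(cum_cat, dl_cat, starts, hd, obs, P, cand, DL,
                                cfg_vec, cfg.continuous_hd)
            take = in_rng & (log_unif[it, 1] < -0.5 * (ss_new - ss_cur) / sig2)
            S = np.where(take, cand, S)
            ss_cur = np.where(take, ss_new, ss_cur)
            acc += take

            if cfg.sample_sigma:
                sig2 = (cfg.sigma_prior_scale + 0.5 * ss_cur) / gam[it]
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                samples[k, 0] = P
                samples[k, 1] = S
                sig_samples[k] = np.sqrt(sig2)
                k += 1
    return samples, sig_samples, acc / (2.0 * cfg.n_iter)


def _as_hd_table(hd_obs) -> pd.DataFrame:
    if isinstance(hd_obs, pd.DataFrame):
        return hd_obs
    rows = [(v, e, hd) for v, envs in hd_obs.items() for e, hd in envs.items()]
    return pd.DataFrame(rows, columns=["variety_id", "env_id", "hd"])


def mcmc_estimate(
    hd_obs,
    weathers: dict[str, WeatherSeries],
    cfg: MCMCConfig = MCMCConfig(),
    cgm_cfg: CGMConfig = CGMConfig(),
    use_numba: bool = True,
) -> ParameterEstimates:
    """Posterior-mean phenology parameters per variety from observed
    heading dates.

    ``hd_obs``: mapping variety → {env: HD days after sowing}, or a long
    DataFrame (variety_id, env_id, hd).  Varieties observed in fewer
    than two environments are excluded with a warning.
    """
    df = _as_hd_table(hd_obs).dropna(subset=["hd"])
    counts = df.groupby("variety_id")["env_id"].nunique()
    excluded = sorted(counts.index[counts < 2].astype(str))
    if excluded:
        logger.warning("excluding %d varieties observed in <2 environments: %s",
                       len(excluded), excluded[:5])
    keep = [v for v in pd.unique(df["variety_id"]) if v not in set(excluded)]
    if not keep:
        raise ValueError("no variety has heading observations in >=2 environments")
    env_ids = [e for e in weathers if e in set(df["env_id"])]
    pos_v = {v: i for i, v in enumerate(keep)}
    pos_e = {e: j for j, e in enumerate(env_ids)}

    hd = np.full((len(keep), len(env_ids)), np.nan)
    for _, r in df.iterrows():
        if r["variety_id"] in pos_v and r["env_id"] in pos_e:
            hd[pos_v[r["variety_id"]], pos_e[r["env_id"]]] = r["hd"]
    obs = ~np.isnan(hd)
    hd = np.nan_to_num(hd)

    cums = [weathers[e].cumulative_tt(cgm_cfg.t_base) for e in env_ids]
    dls = [weathers[e].daylength_h for e in env_ids]
    starts = np.concatenate([[0], np.cumsum([len(c) for c in cums])]).astype(np.int64)
    cum_cat = np.concatenate(cums)
    dl_cat = np.concatenate(dls)

    rng = np.random.default_rng(cfg.rng_seed)
    samples, sig_samples, acc = _run_chains(
        cum_cat, dl_cat, starts, hd, obs, cfg, cgm_cfg, rng, use_numba)

    table = pd.DataFrame({
        "P_mean": samples[:, 0, :].mean(axis=0),
        "P_sd": samples[:, 0, :].std(axis=0, ddof=1),
        "SLDL_mean": samples[:, 1, :].mean(axis=0),
        "SLDL_sd": samples[:, 1, :].std(axis=0, ddof=1),
        "accept_rate": acc,
        "n_environments": obs.sum(axis=1),
        "sigma_hd": sig_samples.mean(axis=0),
    }, index=pd.Index(keep, name="variety_id"))
    return ParameterEstimates(table=table, excluded=excluded)


# ------------------------------------------------------------------- GBM

def _gblup_single(y, X_tr, X_te, K_tt, K_et):
    """REML fit of y = Xb + u, u ~ N(0, K s2u), e ~ N(0, I s2e) via the
    eigendecomposition of K; returns test predictions and fit info."""
    lam, U = eigh(K_tt)
    lam = np.clip(lam, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X_tr
    n, p = X_tr.shape

    def negll(t):
        g = np.exp(t)
        w = g * lam + 1.0
        Xw = Xr / w[:, None]
        Cxx = Xr.T @ Xw
        cxy = Xw.T @ yr
        bhat = np.linalg.solve(Cxx, cxy)
        yPy = float(yr @ (yr / w) - cxy @ bhat)
        s2e = max(yPy, 1e-300) / (n - p)
        _, ld = np.linalg.slogdet(Cxx)
        return 0.5 * ((n - p) * np.log(s2e) + np.log(w).sum() + ld), bhat, s2e

    res = minimize_scalar(lambda t: negll(t)[0], bounds=(-16, 16), method="bounded",
                          options={"xatol": 1e-8})
    g = float(np.exp(res.x))
    _, bhat, s2e = negll(res.x)
    w = g * lam + 1.0
    r = y - X_tr @ bhat
    Ai_r = U @ ((U.T @ r) / w)
    u_te = g * (K_et @ Ai_r)
    return X_te @ bhat + u_te, {"gamma": g, "sigma2_e": s2e, "beta": bhat}


def gbm_predict_params(
    estimates_train: ParameterEstimates,
    K: KinshipMatrix,
    test_ids: list[str],
    markers: MarkerMatrix | None = None,
    major_marker_ids: tuple[str, ...] = (),
    clip_to_range: bool = True,
) -> ParameterEstimates:
    """Predict (P, SLDL) for unphenotyped varieties by genomic
    prediction, with major phenology markers (if any) as fixed effects.

    Each parameter is modeled independently as intercept + major-marker
    fixed effects + polygenic effect with covariance K, variance
    components by REML.  Predictions are clipped to the valid parameter
    ranges by default (they feed the phenology model, whose priors the
    ranges define).
    """
    train_ids = [str(v) for v in estimates_train.table.index]
    missing = set(train_ids + list(test_ids)) - set(K.variety_ids)
    if missing:
        raise KeyError(f"varieties absent from kinship: {sorted(missing)[:5]}")
    tr = K.index_of(train_ids)
    te = K.index_of(list(test_ids))
    K_tt = K.values[np.ix_(tr, tr)]
    K_et = K.values[np.ix_(te, tr)]

    def fixed_design(ids):
        cols = [np.ones(len(ids))]
        if major_marker_ids:
            if markers is None:
                raise ValueError("major markers requested but no marker matrix given")
            g = markers.to_frame().loc[list(ids), list(major_marker_ids)].to_numpy(float)
            if np.isnan(g).any():
                col_means = np.nanmean(g, axis=0)
                idx = np.where(np.isnan(g))
                g[idx] = col_means[idx[1]]
            cols.append(g)
        return np.column_stack(cols)

    X_tr = fixed_design(train_ids)
    X_te = fixed_design(list(test_ids))

    out = {}
    info = {}
    for name, col, rng_ in (("P", "P_mean", P_RANGE), ("SLDL", "SLDL_mean", SLDL_RANGE)):
        y = estimates_train.table[col].to_numpy(float)
        pred, fit_info = _gblup_single(y, X_tr, X_te, K_tt, K_et)
        if clip_to_range:
            pred = np.clip(pred, rng_[0], rng_[1])
        out[f"{name}_mean"] = pred
        out[f"{name}_sd"] = np.full(len(test_ids), np.nan)
        info[name] = fit_info
    table = pd.DataFrame(out, index=pd.Index(list(test_ids), name="variety_id"))
    table["accept_rate"] = np.nan
    table["n_environments"] = 0
    est = ParameterEstimates(table=table, excluded=[])
    est.fit_info = info
    return est
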