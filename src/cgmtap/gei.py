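"""Multi-environment GBLUP models of genotype-by-environment interaction.

Nine model specifications form a 3×3 grid: the genotype-by-environment
term is absent, has an independent-environments covariance (K ⊗ I), or an
environmental-covariate-derived covariance (K ⊗ W); and the secondary
trait (heading date, HD) enters the fixed part not at all, linearly, or
quadratically with environment-specific slopes:

    y_ij = mu_j + alpha_j h_ij + beta_j h_ij^2 + G_i + GE_ij + e_ij
    G ~ N(0, K sigma_g^2),  GE ~ N(0, (K ⊗ Sigma_E) sigma_ge^2),
    e ~ N(0, I sigma_e^2)

Variance components are estimated by REML.  The implementation exploits
the exact spectral structure of the marginal covariance: on the full
variety × environment grid,

    V = K ⊗ (sigma_g^2 J + sigma_ge^2 Sigma_E) + sigma_e^2 I
      = (U ⊗ Q) diag(lambda_k d_j + sigma_e^2) (U ⊗ Q)'

with K = U Λ U' and M = sigma_g^2 J + sigma_ge^2 Sigma_E = Q D Q'.
Unobserved grid cells are handled exactly through a Schur-complement
correction of the full-grid inverse, so each likelihood evaluation costs
O(nE·m) instead of O(N^3).  The residual variance is profiled out and
the two variance ratios are maximized directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize, minimize_scalar

from .envs import EnvCovariance, bend_to_psd
from .markers import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "METData",
    "ModelSpec",
    "MODEL_NAMES",
    "HDScaling",
    "FittedGEIModel",
    "build_covariates",
    "fit_gei_model",
    "predict_cells",
]

_GAMMA_FLOOR = 1e-8
_GAMMA_CEIL = 1e6


@dataclass
class METData:
    """Long-format multi-environment-trial records.

    ``records`` columns: variety_id, env_id, gy, hd and optionally
    hd_source in {"observed", "cgm_predicted"}.  At most one record per
    (variety, environment).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"variety_id", "env_id"}
        if not req <= set(self.records.columns):
            raise ValueError(f"records must have columns {req}")
        if "hd_source" not in self.records.columns:
            self.records = self.records.assign(hd_source="observed")
        dup = self.records.duplicated(subset=["variety_id", "env_id"])
        if dup.any():
            raise ValueError("duplicate (variety, environment) records")

    @property
    def variety_ids(self) -> list[str]:
        return list(pd.unique(self.records["variety_id"]))

    @property
    def env_ids(self) -> list[str]:
        return list(pd.unique(self.records["env_id"]))

    def subset(self, mask) -> "METData":
        return METData(self.records.loc[mask].reset_index(drop=True))

    @classmethod
    def from_csv(cls, path) -> "METData":
        df = pd.read_csv(path)
        df["variety_id"] = df["variety_id"].astype(str)
        df["env_id"] = df["env_id"].astype(str)
        return cls(df)


_STRUCTURES = {"none": "", "identity": "_GxE", "W": "_GxW"}
_COVARIATES = {"none": "", "linear": "_HD", "quadratic": "_HD2"}


@dataclass(frozen=True)
class ModelSpec:
    """One of the nine model specifications."""

    gxe_structure: str = "none"   # none | identity | W
    hd_covariate: str = "none"    # none | linear | quadratic

    def __post_init__(self) -> None:
        if self.gxe_structure not in _STRUCTURES:
            raise ValueError(f"gxe_structure must be one of {set(_STRUCTURES)}")
        if self.hd_covariate not in _COVARIATES:
            raise ValueError(f"hd_covariate must be one of {set(_COVARIATES)}")

    @property
    def name(self) -> str:
        return "EG" + _STRUCTURES[self.gxe_structure] + _COVARIATES[self.hd_covariate]

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        for gxe in _STRUCTURES:
            for cov in _COVARIATES:
                spec = cls(gxe, cov)
                if spec.name == name:
                    return spec
        raise ValueError(f"unknown model name {name!r}; valid: {MODEL_NAMES}")

    @property
    def has_ge(self) -> bool:
        return self.gxe_structure != "none"


MODEL_NAMES = tuple(
    ModelSpec(g, c).name for g in _STRUCTURES for c in _COVARIATES
)


@dataclass
class HDScaling:
    """Standardization constants for the HD covariates, estimated on the
    training records and reused unchanged on test records."""

    mean_h: float
    sd_h: float
    mean_h2: float
    sd_h2: float

    @classmethod
    def fit(cls, hd: np.ndarray) -> "HDScaling":
        hd = np.asarray(hd, float)
        sd = hd.std(ddof=1)
        if sd < 1e-10:
            raise ValueError("zero HD variance; covariate undefined")
        h = (hd - hd.mean()) / sd
        h2 = h**2
        sd2 = h2.std(ddof=1)
        if sd2 < 1e-10:
            raise ValueError("zero variance of squared HD")
        return cls(float(hd.mean()), float(sd), float(h2.mean()), float(sd2))

    def transform(self, hd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (h, h2) columns for raw HD values."""
        h = (np.asarray(hd, float) - self.mean_h) / self.sd_h
        h2 = (h**2 - self.mean_h2) / self.sd_h2
        return h, h2


def build_covariates(met: METData, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray | None, HDScaling]:
    """Standardized HD covariates for the training records.

    h is centered and scaled to unit SD over the training records; h² is
    the square of standardized h, itself then centered and scaled.
    Returns (h, h2, constants); h2 is None when the spec has no
    quadratic term.
    """
    if spec.hd_covariate == "none":
        raise ValueError("spec has no HD covariate")
    hd = met.records["hd"].to_numpy(float)
    if np.isnan(hd).any():
        raise ValueError("HD missing for some training records")
    scaling = HDScaling.fit(hd)
    h, h2 = scaling.transform(hd)
    return h, (h2 if spec.hd_covariate == "quadratic" else None), scaling


# ------------------------------------------------------------------ REML

class _GridProblem:
    """REML machinery on the variety × environment grid (see module
    docstring).  All quantities are in residual-variance units: the
    covariance is sigma_e^2 * ([K ⊗ (g_g J + g_ge Sigma)]_grid + I)."""

    def __init__(self, y, X, var_idx, env_idx, K_tt, Sigma, k_eig=None):
        self.y = y
        self.X = X
        self.N, self.p = X.shape
        self.n, self.E = K_tt.shape[0], (Sigma.shape[0] if Sigma is not None else int(env_idx.max()) + 1)
        self.Sigma = Sigma
        self.J = np.ones((self.E, self.E))
        if k_eig is None:
            lam, U = eigh(K_tt)
            lam = np.clip(lam, 0.0, None)
        else:
            lam, U = k_eig
        self.lam, self.U = lam, U
        self.grid_idx = var_idx * self.E + env_idx
        obs = np.zeros(self.n * self.E, dtype=bool)
        obs[self.grid_idx] = True
        self.miss_idx = np.flatnonzero(~obs)
        self.i_m = self.miss_idx // self.E
        self.e_m = self.miss_idx % self.E
        # fixed rotation by U' of the zero-padded [y, X] block
        cols = 1 + self.p
        Yg = np.zeros((cols, self.n, self.E))
        Y = np.column_stack([y, X])
        for c in range(cols):
            flat = np.zeros(self.n * self.E)
            flat[self.grid_idx] = Y[:, c]
            Yg[c] = flat.reshape(self.n, self.E)
        self.B = np.matmul(self.U.T[None, :, :], Yg)  # (cols, n, E)
        self._cache = {}

    def _M(self, g_g: float, g_ge: float) -> np.ndarray:
        M = g_g * self.J
        if self.Sigma is not None:
            M = M + g_ge * self.Sigma
        return M

    def evaluate(self, g_g: float, g_ge: float):
        """REML profile quantities at variance ratios (g_g, g_ge)."""
        M = self._M(g_g, g_ge)
        d, Q = eigh(M)
        d = np.clip(d, 0.0, None)
        w = self.lam[:, None] * d[None, :] + 1.0   # (n, E)
        cols = 1 + self.p

        T1 = np.matmul(self.B, Q)                  # (cols, n, E)
        S = T1 / w[None, :, :]
        back = np.matmul(S, Q.T)
        u = np.matmul(self.U[None, :, :], back)    # (cols, n, E) full-grid Ainv of padding
        u_flat = u.reshape(cols, -1)
        logdet = float(np.log(w).sum())

        if self.miss_idx.size:
            m = self.miss_idx.size
            Fm = (self.U[self.i_m, :, None] * Q[self.e_m, None, :]).reshape(m, -1)
            w_flat = w.reshape(-1)
            Gm = (Fm / w_flat[None, :]) @ Fm.T
            cf = cho_factor(Gm, lower=True)
            logdet += 2.0 * float(np.log(np.diag(cf[0])).sum())
            u_m = u_flat[:, self.miss_idx]                      # (cols, m)
            z = cho_solve(cf, u_m.T)                            # (m, cols)
            # apply full-grid inverse to the miss-padded correction block
            Zg = np.zeros((cols, self.n, self.E))
            Zg[:, self.i_m, self.e_m] = z.T
            B2 = np.matmul(self.U.T[None, :, :], Zg)
            T2 = np.matmul(B2, Q) / w[None, :, :]
            u2 = np.matmul(self.U[None, :, :], np.matmul(T2, Q.T)).reshape(cols, -1)
            AiY = (u_flat - u2)[:, self.grid_idx].T             # (N, cols)
        else:
            AiY = u_flat[:, self.grid_idx].T

        C = np.column_stack([self.y, self.X]).T @ AiY           # (cols, cols)
        cyy = C[0, 0]
        cxy = C[1:, 0]
        Cxx = 0.5 * (C[1:, 1:] + C[1:, 1:].T)
        cfx = cho_factor(Cxx, lower=True)
        bhat = cho_solve(cfx, cxy)
        yPy = float(cyy - cxy @ bhat)
        logdet_cxx = 2.0 * float(np.log(np.diag(cfx[0])).sum())
        return {
            "logdet_A": logdet, "logdet_Cxx": logdet_cxx, "yPy": yPy,
            "bhat": bhat, "AiY": AiY, "Q": Q, "d": d, "w": w,
        }

    def reml_loglik(self, g_g, g_ge, sigma_e2=None):
        ev = self.evaluate(g_g, g_ge)
        N, p = self.N, self.p
        if sigma_e2 is None:
            sigma_e2 = ev["yPy"] / (N - p)
            quad = N - p
        else:
            quad = ev["yPy"] / sigma_e2
        ll = -0.5 * ((N - p) * np.log(sigma_e2) + ev["logdet_A"]
                     + ev["logdet_Cxx"] + quad + (N - p) * np.log(2 * np.pi))
        return float(ll), float(sigma_e2), ev


@dataclass
class FittedGEIModel:
    """A fitted GEI model: variance components, BLUEs, BLUPs and the
    state needed to predict unobserved cells."""

    spec: ModelSpec
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    blues: pd.DataFrame                 # env_id, mu, alpha, beta
    blups_g: pd.Series                  # G_i for training varieties
    blups_ge: pd.DataFrame              # variety_id, env_id, ge (observed cells)
    loglik: float
    converged: bool
    hd_scaling: HDScaling | None
    # prediction state
    train_varieties: list[str] = field(repr=False, default=None)
    train_envs: list[str] = field(repr=False, default=None)
    Ra: np.ndarray = field(repr=False, default=None)   # padded Ainv residual, (n_t, E_t), residual units
    Sigma_train: np.ndarray | None = field(repr=False, default=None)
    gamma_g: float = field(repr=False, default=0.0)    # fitted ratios (pre-flooring)
    gamma_ge: float = field(repr=False, default=0.0)

    @property
    def mu_new_env(self) -> float:
        """Fixed environment mean used for environments never observed
        in training (the mean of the training-environment BLUEs)."""
        return float(self.blues["mu"].mean())


def _design(met: METData, spec: ModelSpec, env_ids: list[str]):
    """Fixed-effect design: a full environment factor (no global
    intercept) plus env-specific HD slopes per the spec."""
    env_pos = {e: i for i, e in enumerate(env_ids)}
    env_idx = met.records["env_id"].map(env_pos).to_numpy()
    E = len(env_ids)
    N = len(met.records)
    blocks = [np.zeros((N, E))]
    blocks[0][np.arange(N), env_idx] = 1.0
    scaling = None
    h = h2 = None
    if spec.hd_covariate != "none":
        h, h2, scaling = build_covariates(met, spec)
        Zh = np.zeros((N, E))
        Zh[np.arange(N), env_idx] = h
        blocks.append(Zh)
        for e in range(E):
            vals = h[env_idx == e]
            if np.unique(np.round(vals, 12)).size < 2:
                raise ValueError(
                    f"environment {env_ids[e]!r} has fewer than 2 distinct HD values; "
                    f"env-specific slope not estimable")
        if spec.hd_covariate == "quadratic":
            Z2 = np.zeros((N, E))
            Z2[np.arange(N), env_idx] = h2
            blocks.append(Z2)
            for e in range(E):
                if np.unique(np.round(h[env_idx == e], 12)).size < 3:
                    raise ValueError(
                        f"environment {env_ids[e]!r} has fewer than 3 distinct HD values; "
                        f"quadratic term not estimable")
    return np.column_stack(blocks), env_idx, scaling


def fit_gei_model(
    met: METData,
    spec: ModelSpec,
    K: KinshipMatrix,
    W: EnvCovariance | None = None,
    fixed_components: tuple[float, float, float] | None = None,
    k_eig=None,
    warm_start: tuple[float, float] | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> FittedGEIModel:
    """Fit one GEI model specification by REML on the training records.

    ``fixed_components`` (sigma2_g, sigma2_ge, sigma2_e) skips variance
    estimation and evaluates BLUE/BLUP at the given components.
    ``k_eig`` optionally supplies a precomputed eigendecomposition
    (lam, U) of the training block of K; ``warm_start`` an initial
    (gamma_g, gamma_ge) ratio pair.
    """
    rec = met.records
    if spec.gxe_structure == "W" and W is None:
        raise ValueError("spec requires an environment covariance W")
    env_ids = met.env_ids
    var_ids = [v for v in K.variety_ids if v in set(rec["variety_id"])]
    if set(rec["variety_id"]) - set(var_ids):
        raise KeyError("records contain varieties absent from K")
    y = rec["gy"].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("missing GY in training records")
    X, env_idx, scaling = _design(met, spec, env_ids)
    var_pos = {v: i for i, v in enumerate(var_ids)}
    var_idx = rec["variety_id"].map(var_pos).to_numpy()
    K_tt = K.values[np.ix_(K.index_of(var_ids), K.index_of(var_ids))]

    Sigma = None
    if spec.gxe_structure == "identity":
        Sigma = np.eye(len(env_ids))
    elif spec.gxe_structure == "W":
        Wb = bend_to_psd(W.values)
        sub = W.index_of(env_ids)
        Sigma = Wb[np.ix_(sub, sub)]

    prob = _GridProblem(y, X, var_idx, env_idx, K_tt, Sigma, k_eig=k_eig)

    vary = float(np.var(y))
    converged = True
    if fixed_components is not None:
        s2g, s2ge, s2e = fixed_components
        if s2e <= 0:
            raise ValueError("fixed residual variance must be positive")
        g_g = s2g / s2e
        g_ge = s2ge / s2e if spec.has_ge else 0.0
        ll, s2e, ev = prob.reml_loglik(g_g, g_ge, sigma_e2=s2e)
    else:
        lo, hi = np.log(_GAMMA_FLOOR), np.log(_GAMMA_CEIL)

        if spec.has_ge:
            # gamma_ge is optimized on the square-root scale so that the
            # zero-variance boundary is an ordinary interior point
            def nll(t):
                return -prob.reml_loglik(np.exp(np.clip(t[0], lo, hi)),
                                         min(t[1] * t[1], _GAMMA_CEIL))[0]
            if warm_start is not None:
                # keep the sqrt coordinate away from the flat origin so the
                # initial simplex spans a usable scale
                t0 = np.array([np.log(warm_start[0]),
                               max(np.sqrt(warm_start[1]), 0.07)])
            else:
                t0 = np.array([0.0, 0.55])
            simplex = np.array([t0, t0 + [0.25, 0.0], t0 + [0.0, 0.12]])
            res = minimize(nll, t0, method="Nelder-Mead",
                           options={"fatol": tol * 0.1, "xatol": 2e-3,
                                    "maxfev": max_iter * 4,
                                    "initial_simplex": simplex})
            # converged when the REML log-likelihood has stabilized to
            # within tol across the final simplex
            converged = bool(res.success) or float(np.ptp(res.final_simplex[1])) < tol
            g_g = float(np.exp(np.clip(res.x[0], lo, hi)))
            g_ge = float(min(res.x[1] * res.x[1], _GAMMA_CEIL))
        else:
            def nll1(t):
                return -prob.reml_loglik(np.exp(t), 0.0)[0]
            res = minimize_scalar(nll1, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-6, "maxiter": max_iter})
            converged = bool(res.success)
            g_g, g_ge = float(np.exp(res.x)), 0.0
        if not converged:
            raise RuntimeError(f"REML did not converge for {spec.name}: {res}")
        ll, s2e, ev = prob.reml_loglik(g_g, g_ge)

    floor = _GAMMA_FLOOR * vary
    s2g = max(g_g * s2e, 0.0)
    s2ge = max(g_ge * s2e, 0.0) if spec.has_ge else 0.0
    if 0 < s2g < floor:
        s2g = floor
    if spec.has_ge and 0 < s2ge < floor:
        s2ge = floor

    bhat = ev["bhat"]
    AiY = ev["AiY"]
    Air = AiY[:, 0] - AiY[:, 1:] @ bhat       # Ainv residual, residual units
    n_t, E_t = len(var_ids), len(env_ids)
    Ra = np.zeros(n_t * E_t)
    Ra[prob.grid_idx] = Air
    Ra = Ra.reshape(n_t, E_t)

    G = g_g * (K_tt @ Ra.sum(axis=1))
    if spec.has_ge:
        GE_grid = g_ge * (K_tt @ Ra @ Sigma)
        ge_obs = GE_grid.reshape(-1)[prob.grid_idx]
    else:
        ge_obs = np.zeros(len(rec))

    E = len(env_ids)
    mu = bhat[:E]
    alpha = bhat[E:2 * E] if spec.hd_covariate != "none" else np.full(E, np.nan)
    beta = bhat[2 * E:3 * E] if spec.hd_covariate == "quadratic" else np.full(E, np.nan)
    blues = pd.DataFrame({"env_id": env_ids, "mu": mu, "alpha": alpha, "beta": beta})

    return FittedGEIModel(
        spec=spec, sigma2_g=s2g, sigma2_ge=s2ge, sigma2_e=s2e,
        blues=blues,
        blups_g=pd.Series(G, index=var_ids, name="G"),
        blups_ge=pd.DataFrame({"variety_id": rec["variety_id"].to_numpy(),
                               "env_id": rec["env_id"].to_numpy(), "ge": ge_obs}),
        loglik=ll, converged=converged, hd_scaling=scaling,
        train_varieties=var_ids, train_envs=env_ids, Ra=Ra, Sigma_train=Sigma,
        gamma_g=g_g, gamma_ge=g_ge,
    )


def predict_cells(
    fit: FittedGEIModel,
    test_cells: pd.DataFrame,
    K: KinshipMatrix,
    W: EnvCovariance | None = None,
    new_env_coefs: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Predict genotype × environment cells as BLUE(fixed) + BLUP(random).

    ``test_cells`` columns: variety_id, env_id and (for HD-covariate
    specs) hd, transformed with the training standardization constants.
    BLUPs of unobserved random effects come from their covariance with
    the training cells.  For environments never observed in training:
    the fixed environment mean is the average of training BLUEs, the
    HD slopes must be supplied via ``new_env_coefs`` ({env: (alpha,
    beta)}), and a K ⊗ I interaction structure is refused since it
    carries no information across environments.
    """
    spec = fit.spec
    env_set = set(fit.train_envs)
    new_envs = [e for e in pd.unique(test_cells["env_id"]) if e not in env_set]
    if new_envs and spec.gxe_structure == "identity":
        raise ValueError(
            f"model {spec.name} cannot predict unobserved environments {new_envs} "
            "(K ⊗ I shares no information between environments; "
            "not applicable to the new-environment scenario)")
    if new_envs and spec.hd_covariate != "none" and not new_env_coefs:
        raise ValueError(f"HD slopes for new environments {new_envs} must be supplied")

    g_g, g_ge = fit.gamma_g, fit.gamma_ge
    tr_idx = K.index_of(fit.train_varieties)
    te_idx = K.index_of(list(test_cells["variety_id"]))
    K_cross = K.values[np.ix_(te_idx, tr_idx)]            # (n_test_cells, n_t)
    row_sum = fit.Ra.sum(axis=1)
    G_test = g_g * (K_cross @ row_sum)

    env_pos = {e: i for i, e in enumerate(fit.train_envs)}
    mu_map = dict(zip(fit.blues["env_id"], fit.blues["mu"]))
    alpha_map = dict(zip(fit.blues["env_id"], fit.blues["alpha"]))
    beta_map = dict(zip(fit.blues["env_id"], fit.blues["beta"]))

    if spec.has_ge:
        if spec.gxe_structure == "W":
            Wb = bend_to_psd(W.values)
            w_tr = W.index_of(fit.train_envs)
            RaS_base = fit.Ra @ Wb[np.ix_(w_tr, np.arange(Wb.shape[0]))]  # (n_t, E_all)
            col_of = {e: j for j, e in enumerate(W.env_ids)}
        else:
            RaS_base = fit.Ra @ fit.Sigma_train
            col_of = env_pos

    h_arr = h2_arr = None
    if spec.hd_covariate != "none":
        if "hd" not in test_cells.columns or test_cells["hd"].isna().any():
            raise ValueError("test cells need HD values for an HD-covariate spec")
        h_arr, h2_arr = fit.hd_scaling.transform(test_cells["hd"].to_numpy(float))

    preds = np.empty(len(test_cells))
    for r, (_, row) in enumerate(test_cells.iterrows()):
        env = row["env_id"]
        if env in env_set:
            val = mu_map[env]
            a_j, b_j = alpha_map[env], beta_map[env]
        else:
            val = fit.mu_new_env
            a_j, b_j = (new_env_coefs or {}).get(env, (np.nan, np.nan))
        if spec.hd_covariate != "none":
            val += a_j * h_arr[r]
            if spec.hd_covariate == "quadratic":
                val += b_j * h2_arr[r]
        val += G_test[r]
        if spec.has_ge:
            j = col_of.get(env)
            if j is None:
                raise KeyError(f"environment {env!r} absent from W")
            val += g_ge * float(K_cross[r] @ RaS_base[:, j])
        preds[r] = val
    return preds
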