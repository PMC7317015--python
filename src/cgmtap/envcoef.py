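"""Per-environment HD→GY regression coefficients and their prediction
in new environments from environmental covariates.

When predicting a completely unobserved environment, the
environment-specific slopes of the secondary-trait covariate (alpha_j,
and beta_j for the quadratic term) cannot be estimated — no GY or HD is
observed there.  They are instead (1) estimated in every training
environment by per-environment OLS of GY on the standardized secondary
trait, then (2) regressed on environmental covariates with a stepwise
variable selection under a generalized-AIC criterion

    crit = n log(RSS/n) + k p

(p counts estimated coefficients including the intercept), and (3) the
selected model is evaluated at the target environment's covariates.
Default penalties: k = 3.7 for alpha, k = 8 for beta.  Because the
number of candidate covariates can exceed the number of environments,
candidates are first screened to the min(10, E_train/2) covariates most
correlated with the response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .gei import HDScaling, METData

logger = logging.getLogger(__name__)

__all__ = [
    "EnvCoefficients",
    "StepwiseModel",
    "estimate_env_coefficients",
    "stepwise_ec_predict",
    "K_ALPHA",
    "K_BETA",
]

K_ALPHA = 3.7
K_BETA = 8.0


@dataclass
class EnvCoefficients:
    """Estimated HD→GY slopes per environment.

    ``table`` columns: env_id, alpha, beta (nan unless degree 2),
    resid_sd, n_used.  Environments with singular designs are flagged
    with nan coefficients.
    """

    table: pd.DataFrame
    degree: int
    scaling: HDScaling

    def response(self, name: str) -> pd.Series:
        return self.table.set_index("env_id")[name]


@dataclass
class StepwiseModel:
    """Result of a penalized stepwise EC selection."""

    selected: list[str]
    intercept: float
    coefficients: dict[str, float]
    k: float
    criterion: float
    screened: list[str]

    def predict(self, ec_row: pd.Series | dict) -> float:
        val = self.intercept
        for name, c in self.coefficients.items():
            val += c * float(ec_row[name])
        return val


def estimate_env_coefficients(met: METData, degree: int = 1,
                              min_pairs: int = 10) -> EnvCoefficients:
    """OLS slopes of GY on the standardized secondary trait, per
    environment.

    HD is standardized over all records exactly as in the GEI model
    covariates (global mean/SD; the squared term re-centered and
    rescaled), so the slopes are on the same scale as the fitted
    env-specific fixed effects.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    rec = met.records.dropna(subset=["hd", "gy"])
    scaling = HDScaling.fit(rec["hd"].to_numpy(float))
    h_all, h2_all = scaling.transform(rec["hd"].to_numpy(float))
    rec = rec.assign(_h=h_all, _h2=h2_all)
    rows = []
    for env, sub in rec.groupby("env_id", sort=False):
        n = len(sub)
        if n < min_pairs:
            rows.append((env, np.nan, np.nan, np.nan, n))
            continue
        y = sub["gy"].to_numpy(float)
        cols = [np.ones(n), sub["_h"].to_numpy()]
        if degree == 2:
            cols.append(sub["_h2"].to_numpy())
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            logger.warning("environment %s: singular HD design, flagged", env)
            rows.append((env, np.nan, np.nan, np.nan, n))
            continue
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(n - X.shape[1], 1)
        rows.append((env, beta[1], beta[2] if degree == 2 else np.nan,
                     float(np.sqrt(resid @ resid / dof)), n))
    table = pd.DataFrame(rows, columns=["env_id", "alpha", "beta", "resid_sd", "n_used"])
    return EnvCoefficients(table=table, degree=degree, scaling=scaling)


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(res[0]) if res.size else float(np.sum((y - X @ beta) ** 2))
    return beta, rss


def _criterion(n: int, rss: float, p: int, k: float) -> float:
    return n * np.log(max(rss, 1e-300) / n) + k * p


def stepwise_ec_predict(
    coefs: EnvCoefficients,
    omega,
    target_env: str,
    k: float = K_ALPHA,
    coefficient: str = "alpha",
    max_candidates: int = 10,
) -> tuple[float, StepwiseModel]:
    """Predict one regression coefficient in ``target_env`` from the
    environmental covariates of the remaining environments.

    The target environment is excluded from the training rows; the
    candidate covariates are screened to the ``min(max_candidates,
    E_train // 2)`` with the largest absolute marginal correlation with
    the response.  Because the screen caps the candidate set at ten
    covariates, the penalized criterion is minimized *exactly* by
    enumerating all candidate subsets rather than by the
    forward-backward walk the criterion derives from — the heuristic
    can stall in local optima on correlated candidates, while the
    search space here is at most 2¹⁰ tiny regressions.  Ties prefer the
    smaller model, then lexicographic order.
    """
    if k <= 0:
        raise ValueError("penalty k must be positive")
    resp = coefs.response(coefficient).dropna()
    train_envs = [e for e in resp.index if e != target_env]
    if len(train_envs) < 5:
        raise ValueError(f"too few training environments ({len(train_envs)} < 5)")
    y = resp.loc[train_envs].to_numpy(float)
    n = len(y)

    om = omega.to_frame()
    missing = set(train_envs + [target_env]) - set(om.index)
    if missing:
        raise KeyError(f"environments absent from EC matrix: {sorted(missing)}")
    X_all = om.loc[train_envs]
    target_row = om.loc[target_env]

    # deterministic marginal screen
    sd = X_all.std(ddof=0)
    usable = sd.index[sd > 0]
    cors = {c: abs(float(np.corrcoef(X_all[c], y)[0, 1])) for c in usable}
    m = min(max_candidates, n // 2)
    screened = sorted(sorted(cors), key=lambda c: -cors[c])[:m]

    ones = np.ones((n, 1))
    _, rss0 = _ols_rss(y, ones)
    best_crit = _criterion(n, rss0, 1, k)
    selected: list[str] = []
    for size in range(1, len(screened) + 1):
        for sub in combinations(screened, size):
            X = np.column_stack([ones, X_all[list(sub)].to_numpy()])
            _, rss = _ols_rss(y, X)
            crit = _criterion(n, rss, size + 1, k)
            if crit < best_crit - 1e-12:
                best_crit = crit
                selected = list(sub)

    X = np.column_stack([ones] + ([X_all[selected].to_numpy()] if selected else []))
    beta, rss = _ols_rss(y, X)
    model = StepwiseModel(
        selected=list(selected), intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(selected, beta[1:])},
        k=k, criterion=best_crit, screened=screened,
    )
    return model.predict(target_row), model
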