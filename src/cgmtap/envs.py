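"""Environmental characterization: standardized covariates, the
environment covariance matrix W, and HD–GY relationship classes.

Environments are characterized by a matrix Ω (environments × covariates)
of standardized environmental covariates.  The covariance between
environments is derived from the Euclidean distances between the rows of
Ω:

    W = 1 − D_Ω / max(D_Ω)

so identical environments have covariance 1 and the most dissimilar pair
has covariance 0.  Environments are also classified by the shape and
strength of the within-environment relationship between the secondary
trait (heading date, HD) and the target trait (grain yield, GY): low,
medium or high absolute linear correlation, or quadratic when a
second-degree fit explains clearly more than a linear one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ECMatrix",
    "EnvCovariance",
    "EnvClassification",
    "standardize_ec",
    "env_covariance",
    "classify_environments",
    "bend_to_psd",
]


@dataclass
class ECMatrix:
    """Standardized environment × covariate matrix Ω."""

    omega: np.ndarray
    env_ids: list[str]
    ec_ids: list[str]

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != (len(self.env_ids), len(self.ec_ids)):
            raise ValueError("omega shape does not match labels")
        if np.isnan(self.omega).any():
            raise ValueError("omega contains missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.omega, index=self.env_ids, columns=self.ec_ids)

    def row(self, env_id: str) -> np.ndarray:
        return self.omega[self.env_ids.index(env_id)]

    @classmethod
    def from_csv(cls, path) -> "ECMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), list(df.index.astype(str)),
                   list(df.columns.astype(str)))


@dataclass
class EnvCovariance:
    """Pairwise environment distances D_Ω and covariance W = 1 − D/max."""

    distances: np.ndarray
    values: np.ndarray
    env_ids: list[str]

    def __post_init__(self) -> None:
        E = len(self.env_ids)
        if self.distances.shape != (E, E) or self.values.shape != (E, E):
            raise ValueError("matrix shapes do not match env_ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.env_ids, columns=self.env_ids)

    def bent(self) -> np.ndarray:
        """W adjusted to positive semidefiniteness (see bend_to_psd)."""
        return bend_to_psd(self.values)

    def index_of(self, ids) -> np.ndarray:
        lookup = {e: i for i, e in enumerate(self.env_ids)}
        missing = [e for e in ids if e not in lookup]
        if missing:
            raise KeyError(f"environments absent from W: {missing}")
        return np.array([lookup[e] for e in ids], dtype=int)

    @classmethod
    def from_csv(cls, path) -> "EnvCovariance":
        df = pd.read_csv(path, index_col=0)
        W = df.to_numpy(float)
        env_ids = list(df.index.astype(str))
        # distances are recoverable only up to the unknown max; store 1-W
        return cls(1.0 - W, W, env_ids)


CLASS_LABELS = ("low", "medium", "high", "quadratic")


@dataclass
class EnvClassification:
    """Per-environment HD–GY relationship summary and class label."""

    table: pd.DataFrame  # columns: env_id, r, adj_r2_lin, adj_r2_quad, env_class

    def classes(self) -> dict[str, str]:
        return dict(zip(self.table["env_id"], self.table["env_class"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def standardize_ec(raw: pd.DataFrame, method: str = "inverse_normal") -> ECMatrix:
    """Standardize each covariate column across environments.

    ``inverse_normal`` (default): rank-based inverse normal transform
    value → Φ⁻¹((rank − 0.5)/E) with average ranks for ties, yielding
    (approximate) standard-normal scores.  ``zscore``: plain centering
    and scaling.
    """
    if raw.shape[0] < 3:
        raise ValueError("need at least 3 environments")
    X = raw.to_numpy(float)
    for j, col in enumerate(raw.columns):
        if np.nanstd(X[:, j]) == 0:
            raise ValueError(f"covariate {col!r} is constant across environments")
    E = X.shape[0]
    if method == "inverse_normal":
        ranks = np.apply_along_axis(stats.rankdata, 0, X)  # average ranks for ties
        out = stats.norm.ppf((ranks - 0.5) / E)
    elif method == "zscore":
        out = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ECMatrix(out, list(raw.index.astype(str)), list(raw.columns.astype(str)))


def env_covariance(omega: ECMatrix) -> EnvCovariance:
    """Build D_Ω (Euclidean distances between environment rows of Ω)
    and W = 1 − D_Ω / max(D_Ω)."""
    if len(omega.env_ids) < 2:
        raise ValueError("need at least 2 environments")
    D = squareform(pdist(omega.omega, metric="euclidean"))
    dmax = D.max()
    if dmax == 0.0:
        raise ValueError("all environments identical (max distance 0)")
    W = 1.0 - D / dmax
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 1.0)
    return EnvCovariance(distances=D, values=W, env_ids=list(omega.env_ids))


def bend_to_psd(W: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Make a covariance-like matrix positive semidefinite by adding
    δ = max(0, −λ_min) + eps to the diagonal, then renormalize the
    diagonal back to 1."""
    lam_min = float(np.linalg.eigvalsh(W).min())
    delta = max(0.0, -lam_min) + eps
    Wb = (W + delta * np.eye(W.shape[0])) / (1.0 + delta)
    return 0.5 * (Wb + Wb.T)


def _adj_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted R² of an OLS fit with intercept; X excludes the intercept."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    p = X.shape[1]
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    rss = float(np.sum((y - Xd @ beta) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def classify_environments(met, quad_margin: float = 0.05,
                          low_cut: float = 0.3, high_cut: float = 0.6) -> EnvClassification:
    """Classify each environment by its HD–GY relationship.

    Per environment an OLS of GY on HD and on (HD, HD²) is fitted.  The
    class is ``quadratic`` when the quadratic fit improves the adjusted
    R² by more than ``quad_margin``; otherwise ``low`` / ``medium`` /
    ``high`` according to the absolute Pearson correlation (<0.3,
    0.3–0.6, >0.6).  The margin keeps chance fluctuations of the
    quadratic term (which improve adjusted R² with sizeable probability
    under a purely linear relationship) from producing spurious
    quadratic labels.

    Environments with fewer than 10 complete (HD, GY) pairs are flagged
    ``unclassifiable``.
    """
    df = met.records if hasattr(met, "records") else met
    rows = []
    for env, sub in df.groupby("env_id", sort=False):
        ok = sub[["hd", "gy"]].dropna()
        if len(ok) < 10:
            rows.append((env, np.nan, np.nan, np.nan, "unclassifiable"))
            continue
        h = ok["hd"].to_numpy(float)
        y = ok["gy"].to_numpy(float)
        hc = (h - h.mean()) / (h.std() if h.std() > 0 else 1.0)
        r = float(np.corrcoef(h, y)[0, 1]) if h.std() > 0 else np.nan
        a_lin = _adj_r2(y, hc[:, None])
        a_quad = _adj_r2(y, np.column_stack([hc, hc**2]))
        if a_quad > a_lin + quad_margin:
            label = "quadratic"
        elif abs(r) < low_cut:
            label = "low"
        elif abs(r) <= high_cut:
            label = "medium"
        else:
            label = "high"
        rows.append((env, r, a_lin, a_quad, label))
    table = pd.DataFrame(rows, columns=["env_id", "r", "adj_r2_lin", "adj_r2_quad", "env_class"])
    return EnvClassification(table)
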