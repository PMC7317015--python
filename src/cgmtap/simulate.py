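"""Synthetic multi-environment trial generator.

Generates a complete MET with the statistical structure the prediction
models assume: a panel of inbred varieties with SNP genotypes, per-variety
phenology parameters (one major phyllochron locus, two major photoperiod
loci, plus polygenic background), daily weather per environment, heading
dates produced by the phenology model plus observation noise, a set of
deterministic weather-summary environmental covariates (plus pure-noise
distractors for the stepwise selection), and grain yield built as

    GY_ij = mu_j + alpha_j h~_ij + beta_j h~_ij^2 + G_i + GE_ij + e_ij

with G ~ N(0, K sigma_g^2) drawn through marker effects and
GE ~ N(0, (K ⊗ W_true) sigma_ge^2) with W_true derived from the true
covariates.  Environments are assigned to four designed classes of
HD–GY relationship (low / medium / high linear correlation, quadratic),
with alpha/beta drawn from per-class ranges.

The covariate h~ used in generation is the heading date centered per
environment and scaled by a single pooled within-environment SD, so the
per-class alpha ranges translate directly into the intended within-
environment correlation strengths (environment means absorb the
centering when models are fitted).
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .envs import ECMatrix, bend_to_psd, env_covariance, standardize_ec
from .gei import METData
from .markers import MarkerMatrix
from .phenology import CGMConfig, WeatherSeries, daylength, predict_heading_batch

__all__ = ["SimConfig", "SyntheticTruth", "SimResult", "simulate",
           "export_fixture", "pinned_fixture", "PINNED_FIXTURE_SEED"]

PINNED_FIXTURE_SEED = 20200619

_CLASS_ORDER = ("low", "medium", "high", "quadratic")


@dataclass
class SimConfig:
    """Study design of the synthetic MET (defaults emulate a 220-variety
    by 16-environment winter-wheat trial network)."""

    n_varieties: int = 220
    n_markers: int = 2000
    n_major_p: int = 1            # major phyllochron loci
    n_major_sldl: int = 2         # major photoperiod loci
    n_small_effect: int = 200     # polygenic background loci per parameter
    n_environments: int = 16
    class_counts: tuple[int, int, int, int] = (4, 4, 4, 4)  # low/medium/high/quadratic
    alpha_low: float = 0.2        # |alpha| <= 0.2, sign random
    alpha_medium: tuple[float, float] = (0.35, 0.6)
    alpha_high: tuple[float, float] = (0.7, 1.1)
    alpha_quadratic: float = 0.3  # |alpha| <= 0.3 in quadratic envs
    beta_quadratic: tuple[float, float] = (-2.2, -1.0)
    sigma2_g: float = 0.5
    sigma2_ge: float = 0.3
    sigma2_e: float = 0.5
    sigma_hd: float = 1.0         # days of HD observation noise
    latitude_range: tuple[float, float] = (43.0, 50.0)
    sowing_window: tuple[str, str] = ("10-10", "11-05")  # month-day, autumn sowing
    n_weather_days: int = 330
    winter_tmean: tuple[float, float] = (3.0, 12.0)
    summer_tmean: tuple[float, float] = (16.0, 22.0)
    ar1_rho: float = 0.7
    ar1_sd: float = 2.0           # marginal SD of daily temperature noise
    maf_range: tuple[float, float] = (0.05, 0.5)
    het_rate: float = 0.02
    missing_rate: float = 0.01
    n_noise_ec: int = 5
    mu_gy: float = 8.0            # t/ha scale of environment means
    mu_gy_sd: float = 1.0
    p_center: float = 100.0
    p_major_effect: float = 8.0   # °C·d per major allele substitution
    p_polygenic_sd: float = 6.0
    sldl_center: float = 0.6
    sldl_major_effect: float = 0.15
    sldl_polygenic_sd: float = 0.15
    # explicit per-environment overrides (arrays of length n_environments)
    alphas: tuple | None = None
    betas: tuple | None = None

    def __post_init__(self) -> None:
        if sum(self.class_counts) != self.n_environments:
            raise ValueError("class counts must sum to n_environments")
        for v in (self.sigma2_g, self.sigma2_ge, self.sigma2_e):
            if v < 0:
                raise ValueError("variance components must be nonnegative")


@dataclass
class SyntheticTruth:
    """Everything the generator knows that an analyst would not."""

    params: pd.DataFrame          # variety_id-indexed P, SLDL
    env_table: pd.DataFrame       # env_id, class, mu, alpha, beta, latitude, sowing_doy
    G: pd.Series
    GE: pd.DataFrame              # varieties × environments
    hd_noiseless: pd.DataFrame    # varieties × environments, whole days after sowing
    h_center: pd.Series           # per-env HD mean used in the covariate
    h_scale: float                # pooled within-env HD SD
    major_p: list[str]
    major_sldl: list[str]


@dataclass
class SimResult:
    markers: MarkerMatrix
    met: METData
    weathers: dict[str, WeatherSeries]
    ec_raw: pd.DataFrame
    omega: ECMatrix
    truth: SyntheticTruth
    config: SimConfig


def _simulate_weather(cfg: SimConfig, rng: np.random.Generator, env_id: str):
    lat = rng.uniform(*cfg.latitude_range)
    m0, d0 = map(int, cfg.sowing_window[0].split("-"))
    m1, d1 = map(int, cfg.sowing_window[1].split("-"))
    year = 2012
    lo = dt.date(year, m0, d0).toordinal()
    hi = dt.date(year, m1, d1).toordinal()
    sowing = dt.date.fromordinal(int(rng.integers(lo, hi + 1)))
    winter = rng.uniform(*cfg.winter_tmean)
    summer = rng.uniform(*cfg.summer_tmean)
    mid, amp = 0.5 * (winter + summer), 0.5 * (summer - winter)
    doy = (sowing.timetuple().tm_yday - 1 + np.arange(cfg.n_weather_days)) % 365 + 1
    seasonal = mid + amp * np.cos(2.0 * np.pi * (doy - 196) / 365.0)
    innov_sd = cfg.ar1_sd * np.sqrt(1.0 - cfg.ar1_rho**2)
    eps = rng.standard_normal(cfg.n_weather_days)
    noise = np.empty(cfg.n_weather_days)
    noise[0] = cfg.ar1_sd * eps[0]
    for t in range(1, cfg.n_weather_days):
        noise[t] = cfg.ar1_rho * noise[t - 1] + innov_sd * eps[t]
    tmean = seasonal + noise
    return WeatherSeries(env_id, sowing, tmean, latitude=lat), lat, sowing


def _draw_alpha_beta(cfg: SimConfig, env_class: str, rng: np.random.Generator):
    sign = rng.choice([-1.0, 1.0])
    if env_class == "low":
        return sign * rng.uniform(0.0, cfg.alpha_low), 0.0
    if env_class == "medium":
        return sign * rng.uniform(*cfg.alpha_medium), 0.0
    if env_class == "high":
        return sign * rng.uniform(*cfg.alpha_high), 0.0
    return (sign * rng.uniform(0.0, cfg.alpha_quadratic),
            rng.uniform(*cfg.beta_quadratic))


def _weather_summaries(w: WeatherSeries) -> dict[str, float]:
    """Twenty deterministic covariates summarizing one environment's
    weather (window temperature means, daylength at milestones, thermal
    sums, heat load, site geometry)."""
    cum = w.cumulative_tt(0.0)
    out = {}
    for i in range(6):  # mean temperature of 45-day windows after sowing
        a, b = 45 * i, 45 * (i + 1)
        out[f"tmean_w{i + 1}"] = float(w.tmean[a:b].mean())
    for d in (60, 120, 180, 240):
        out[f"daylength_d{d}"] = float(w.daylength_h[d - 1])
    for d in (90, 150, 210, 270):
        out[f"tt_d{d}"] = float(cum[d - 1])
    # threshold sums (always interior to the simulated temperature range,
    # so never constant across environments)
    out["warm_sum"] = float(np.maximum(w.tmean - 16.0, 0.0).sum())
    out["cold_sum"] = float(np.maximum(12.0 - w.tmean, 0.0).sum())
    out["tmean_spring"] = float(w.tmean[150:240].mean())
    out["tt_total"] = float(cum[-1])
    out["latitude"] = float(w.latitude)
    out["sowing_doy"] = float(w.sowing_date.timetuple().tm_yday)
    return out


def calibration_design_weathers(n_envs: int = 8, seed: int = 0,
                                cfg: SimConfig = SimConfig()) -> dict[str, WeatherSeries]:
    """Weather for a calibration-optimized trial design.

    Sowing dates are staggered from early October to late March (and
    latitudes spread over the configured range), so the daylength
    perceived at the leaf-number-fixing stage varies strongly between
    environments.  This is the kind of design that makes the two
    phenology parameters separately identifiable: in an all-autumn-sown
    network every environment perceives nearly the same short winter
    daylength and only a combination of phyllochron and photoperiod
    sensitivity is determined by the data.
    """
    rng = np.random.default_rng(seed)
    year = 2012
    start = dt.date(year, 10, 1).toordinal()
    span = (dt.date(year + 1, 3, 25).toordinal() - start)
    out = {}
    for i in range(n_envs):
        env = f"C{i + 1:02d}"
        sow = dt.date.fromordinal(start + round(span * i / max(n_envs - 1, 1)))
        lat = float(rng.uniform(*cfg.latitude_range))
        winter = rng.uniform(*cfg.winter_tmean)
        summer = rng.uniform(*cfg.summer_tmean)
        mid, amp = 0.5 * (winter + summer), 0.5 * (summer - winter)
        doy = (sow.timetuple().tm_yday - 1 + np.arange(cfg.n_weather_days)) % 365 + 1
        seasonal = mid + amp * np.cos(2.0 * np.pi * (doy - 196) / 365.0)
        eps = rng.standard_normal(cfg.n_weather_days)
        noise = np.empty(cfg.n_weather_days)
        noise[0] = cfg.ar1_sd * eps[0]
        innov = cfg.ar1_sd * np.sqrt(1.0 - cfg.ar1_rho**2)
        for t in range(1, cfg.n_weather_days):
            noise[t] = cfg.ar1_rho * noise[t - 1] + innov * eps[t]
        out[env] = WeatherSeries(env, sow, seasonal + noise, latitude=lat)
    return out


def simulate(cfg: SimConfig = SimConfig(), seed: int = 0) -> SimResult:
    """Generate a full synthetic MET; bit-reproducible from (cfg, seed)."""
    rng = np.random.default_rng(seed)
    n, L, E = cfg.n_varieties, cfg.n_markers, cfg.n_environments
    variety_ids = [f"V{i + 1:03d}" for i in range(n)]
    marker_ids = [f"M{l + 1:05d}" for l in range(L)]
    env_ids = [f"E{j + 1:02d}" for j in range(E)]

    # --- genotypes: inbred panel with a little residual heterozygosity
    p = rng.uniform(*cfg.maf_range, size=L)
    g = (rng.random((n, L)) < p).astype(float)
    het = rng.random((n, L)) < cfg.het_rate
    g[het] = 0.5
    full = g.copy()  # complete codes for the genetic truth
    miss = rng.random((n, L)) < cfg.missing_rate
    g[miss] = np.nan
    chrom = np.repeat(np.arange(1, 8), int(np.ceil(L / 7)))[:L]
    bp = np.concatenate([np.sort(rng.integers(1, 10**8, size=(chrom == c).sum()))
                         for c in np.unique(chrom)])
    markers = MarkerMatrix(g, variety_ids, marker_ids, np.column_stack([chrom, bp]))

    # --- genetic parameters of the phenology model
    loci = rng.choice(L, size=cfg.n_major_p + cfg.n_major_sldl + cfg.n_small_effect,
                      replace=False)
    major_p = loci[:cfg.n_major_p]
    major_sldl = loci[cfg.n_major_p:cfg.n_major_p + cfg.n_major_sldl]
    poly = loci[cfg.n_major_p + cfg.n_major_sldl:]
    centered = full - p
    poly_w_p = rng.standard_normal(cfg.n_small_effect)
    poly_w_s = rng.standard_normal(cfg.n_small_effect)

    def _polygenic(wts, sd_target):
        raw = centered[:, poly] @ wts
        s = raw.std()
        return raw * (sd_target / s if s > 0 else 0.0)

    P = (cfg.p_center
         + 2.0 * cfg.p_major_effect * centered[:, major_p].sum(axis=1)
         + _polygenic(poly_w_p, cfg.p_polygenic_sd))
    SLDL = (cfg.sldl_center
            + 2.0 * cfg.sldl_major_effect * centered[:, major_sldl].sum(axis=1)
            + _polygenic(poly_w_s, cfg.sldl_polygenic_sd))
    P = np.clip(P, 60.0, 160.0)
    SLDL = np.clip(SLDL, 0.0, 2.0)

    # --- weather and heading dates
    weathers, lat_l, sow_l = {}, [], []
    hd_true = np.empty((n, E))
    cgm = CGMConfig()
    for j, env in enumerate(env_ids):
        w, lat, sowing = _simulate_weather(cfg, rng, env)
        weathers[env] = w
        lat_l.append(lat)
        sow_l.append(sowing.timetuple().tm_yday)
        hd_true[:, j] = predict_heading_batch(P, SLDL, w, cgm, continuous=False)
    if np.isnan(hd_true).any():
        bad = [env_ids[j] for j in np.unique(np.where(np.isnan(hd_true))[1])]
        raise RuntimeError(f"heading not reached in environments {bad}; "
                           "weather series too short or too cold")
    hd_obs = hd_true + cfg.sigma_hd * rng.standard_normal((n, E))

    # --- environmental covariates and the true environment covariance
    ec_raw = pd.DataFrame([_weather_summaries(weathers[e]) for e in env_ids],
                          index=env_ids)
    noise_ec = rng.standard_normal((E, cfg.n_noise_ec))
    for q in range(cfg.n_noise_ec):
        ec_raw[f"noise_ec{q + 1}"] = noise_ec[:, q]
    omega = standardize_ec(ec_raw)
    W_true = bend_to_psd(env_covariance(omega).values)

    # --- environment classes and fixed effects
    classes = np.repeat(_CLASS_ORDER, cfg.class_counts)
    classes = classes[rng.permutation(E)]
    mu = cfg.mu_gy + cfg.mu_gy_sd * rng.standard_normal(E)
    ab = [_draw_alpha_beta(cfg, c, rng) for c in classes]
    alpha = np.array([a for a, _ in ab])
    beta = np.array([b for _, b in ab])
    if cfg.alphas is not None:
        alpha = np.asarray(cfg.alphas, float)
    if cfg.betas is not None:
        beta = np.asarray(cfg.betas, float)

    # --- genetic main effect and GEI through K and W_true
    b_scale = float(np.sum(p * (1.0 - p)))
    K = centered @ centered.T / b_scale
    gamma = rng.standard_normal(L) * np.sqrt(cfg.sigma2_g / b_scale)
    G = centered @ gamma
    LK = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    LW = np.linalg.cholesky(W_true + 1e-10 * np.eye(E))
    GE = np.sqrt(cfg.sigma2_ge) * (LK @ rng.standard_normal((n, E)) @ LW.T)

    # --- grain yield through the secondary-trait reaction norm
    h_center = hd_obs.mean(axis=0)
    s_pooled = float(np.sqrt(np.mean(hd_obs.var(axis=0, ddof=1))))
    h = (hd_obs - h_center) / s_pooled
    eps = np.sqrt(cfg.sigma2_e) * rng.standard_normal((n, E))
    gy = mu + alpha * h + beta * h**2 + G[:, None] + GE + eps

    met = METData(pd.DataFrame({
        "variety_id": np.repeat(variety_ids, E),
        "env_id": np.tile(env_ids, n),
        "gy": gy.reshape(-1),
        "hd": hd_obs.reshape(-1),
        "hd_source": "observed",
    }))

    truth = SyntheticTruth(
        params=pd.DataFrame({"P": P, "SLDL": SLDL},
                            index=pd.Index(variety_ids, name="variety_id")),
        env_table=pd.DataFrame({
            "env_id": env_ids, "env_class": classes, "mu": mu,
            "alpha": alpha, "beta": beta, "latitude": lat_l, "sowing_doy": sow_l,
        }),
        G=pd.Series(G, index=variety_ids, name="G"),
        GE=pd.DataFrame(GE, index=variety_ids, columns=env_ids),
        hd_noiseless=pd.DataFrame(hd_true, index=variety_ids, columns=env_ids),
        h_center=pd.Series(h_center, index=env_ids),
        h_scale=s_pooled,
        major_p=[marker_ids[l] for l in major_p],
        major_sldl=[marker_ids[l] for l in major_sldl],
    )
    return SimResult(markers=markers, met=met, weathers=weathers,
                     ec_raw=ec_raw, omega=omega, truth=truth, config=cfg)


def export_fixture(sim: SimResult, out_dir) -> dict[str, Path]:
    """Write the simulated tables to ``out_dir`` in the package's
    standard plain-text formats; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["genotypes"] = out / "genotypes.csv"
    sim.markers.to_frame().to_csv(paths["genotypes"])
    pos = pd.DataFrame(sim.markers.positions, columns=["chrom", "pos"],
                       index=sim.markers.marker_ids)
    paths["marker_map"] = out / "marker_map.csv"
    pos.to_csv(paths["marker_map"], index_label="marker_id")

    paths["pheno"] = out / "pheno.csv"
    sim.met.records.to_csv(paths["pheno"], index=False)

    rows = []
    for env, w in sim.weathers.items():
        dates = pd.date_range(w.sowing_date, periods=len(w), freq="D")
        rows.append(pd.DataFrame({"env_id": env, "date": dates.strftime("%Y-%m-%d"),
                                  "tmean": w.tmean, "daylength": w.daylength_h}))
    paths["weather"] = out / "weather.csv"
    pd.concat(rows).to_csv(paths["weather"], index=False)

    meta = pd.DataFrame({
        "env_id": list(sim.weathers),
        "latitude": [w.latitude for w in sim.weathers.values()],
        "sowing_date": [w.sowing_date.isoformat() for w in sim.weathers.values()],
    })
    paths["env_meta"] = out / "env_meta.csv"
    meta.to_csv(paths["env_meta"], index=False)

    paths["ec"] = out / "ec.csv"
    sim.ec_raw.to_csv(paths["ec"], index_label="env_id")

    paths["truth_params"] = out / "truth_params.csv"
    sim.truth.params.to_csv(paths["truth_params"])
    paths["truth_env"] = out / "truth_env.csv"
    sim.truth.env_table.to_csv(paths["truth_env"], index=False)
    return paths


def fixture_checksum(sim: SimResult) -> str:
    """Stable digest of the exported tables (used to pin the fixture)."""
    h = hashlib.sha256()
    h.update(sim.markers.to_frame().round(6).to_csv().encode())
    h.update(sim.met.records.round(6).to_csv(index=False).encode())
    h.update(sim.ec_raw.round(6).to_csv().encode())
    return h.hexdigest()


def pinned_fixture() -> SimResult:
    """The small pinned fixture used throughout the test-suite:
    40 varieties × 6 environments × 300 markers, fixed seed."""
    cfg = SimConfig(n_varieties=40, n_markers=300, n_environments=6,
                    class_counts=(2, 1, 2, 1), n_small_effect=60)
    return simulate(cfg, seed=PINNED_FIXTURE_SEED)
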