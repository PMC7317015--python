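"""A minimal deterministic wheat phenology model.

The model predicts heading date from daily weather given two genetic
parameters: the phyllochron P (°C·day of thermal time per leaf) and the
photoperiod sensitivity SLDL (extra leaves per hour of daylength
shortfall below a saturating daylength).  Development is driven by
cumulative thermal time above a base temperature; the final leaf number
is set by the daylength perceived at an early Haun stage, so short days
delay heading in sensitive genotypes.  Vernalization is deliberately
omitted: the intended material is autumn-sown winter wheat assumed fully
vernalized by the time photoperiod becomes limiting.

The simulation is exact and cheap: with cumulative thermal time
precomputed, a heading prediction is two binary searches, which makes
the model usable inside MCMC calibration loops.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenologyParams",
    "WeatherSeries",
    "CGMConfig",
    "daylength",
    "predict_heading",
    "predict_heading_batch",
    "HeadingNotReached",
    "P_RANGE",
    "SLDL_RANGE",
]

P_RANGE = (60.0, 160.0)
SLDL_RANGE = (0.0, 2.0)


class HeadingNotReached(RuntimeError):
    """Raised when the weather series ends before predicted heading."""


@dataclass(frozen=True)
class PhenologyParams:
    """Genetic parameters of the phenology model.

    P : phyllochron, °C·day per leaf, valid range [60, 160].
    SLDL : daylength sensitivity, leaves per hour below saturation,
        valid range [0, 2].
    """

    P: float
    SLDL: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.P) and P_RANGE[0] <= self.P <= P_RANGE[1]):
            raise ValueError(f"P={self.P} outside valid range {P_RANGE}")
        if not (np.isfinite(self.SLDL) and SLDL_RANGE[0] <= self.SLDL <= SLDL_RANGE[1]):
            raise ValueError(f"SLDL={self.SLDL} outside valid range {SLDL_RANGE}")


@dataclass(frozen=True)
class CGMConfig:
    """Fixed (non-genetic) constants of the phenology model."""

    t_base: float = 0.0          # °C, base temperature for thermal time
    tt_emergence: float = 120.0  # °C·d from sowing to emergence
    hs_flag: float = 4.0         # Haun stage at which final leaf number is set
    dl_sat: float = 15.0         # h, saturating daylength
    l_min: float = 8.0           # minimum final leaf number
    l_max: float = 24.0          # maximum final leaf number
    k_head: float = 2.5          # phyllochrons from final-leaf stage to heading

    def __post_init__(self) -> None:
        if self.l_min >= self.l_max:
            raise ValueError("l_min must be < l_max")
        if not 0 < self.dl_sat <= 24:
            raise ValueError("dl_sat must be in (0, 24]")
        for name in ("tt_emergence", "hs_flag", "l_min", "k_head"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def daylength(latitude: float, day_of_year) -> np.ndarray | float:
    """Astronomical daylength (hours) from solar declination.

    δ = −23.44° · cos(2π (J + 10) / 365); daylength =
    (24/π) · arccos(−tan φ · tan δ), with the arccos argument clipped
    to [−1, 1].  Valid for |latitude| < 66.5° (no polar day/night).
    """
    if abs(latitude) >= 66.5:
        raise ValueError("polar latitudes not supported")
    J = np.asarray(day_of_year, dtype=float)
    decl = np.deg2rad(-23.44) * np.cos(2.0 * np.pi * (J + 10.0) / 365.0)
    phi = np.deg2rad(latitude)
    arg = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    out = (24.0 / np.pi) * np.arccos(arg)
    return float(out) if np.isscalar(day_of_year) else out


@dataclass
class WeatherSeries:
    """Daily weather for one environment, starting at sowing.

    ``tmean`` and ``daylength_h`` are aligned daily arrays whose first
    entry is the sowing date (day 1 after sowing).  Daylength is derived
    from ``latitude`` when not supplied.
    """

    env_id: str
    sowing_date: dt.date
    tmean: np.ndarray
    daylength_h: np.ndarray | None = None
    latitude: float | None = None
    _cum_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.tmean = np.asarray(self.tmean, dtype=float)
        if self.tmean.ndim != 1 or len(self.tmean) < 250:
            raise ValueError("weather series must be 1-D with at least 250 daily records")
        if self.daylength_h is None:
            if self.latitude is None:
                raise ValueError("need daylength_h or latitude")
            doy = self.day_of_year()
            self.daylength_h = daylength(self.latitude, doy)
        self.daylength_h = np.asarray(self.daylength_h, dtype=float)
        if self.daylength_h.shape != self.tmean.shape:
            raise ValueError("daylength and tmean must be aligned")
        if not ((self.daylength_h > 0) & (self.daylength_h < 24)).all():
            raise ValueError("daylength must be in (0, 24) hours")

    def __len__(self) -> int:
        return len(self.tmean)

    def day_of_year(self) -> np.ndarray:
        start = self.sowing_date.timetuple().tm_yday
        return (start - 1 + np.arange(len(self.tmean))) % 365 + 1

    def cumulative_tt(self, t_base: float) -> np.ndarray:
        """Cumulative thermal time Σ max(0, tmean − t_base), cached."""
        key = float(t_base)
        if key not in self._cum_cache:
            self._cum_cache[key] = np.cumsum(np.maximum(0.0, self.tmean - t_base))
        return self._cum_cache[key]

    @classmethod
    def from_frame(cls, env_id: str, df: pd.DataFrame, sowing_date=None,
                   latitude: float | None = None) -> "WeatherSeries":
        """Build from a daily table with columns date, tmean and
        optionally daylength."""
        df = df.sort_values("date")
        dates = pd.to_datetime(df["date"])
        if not (dates.diff().dropna() == pd.Timedelta(days=1)).all():
            raise ValueError(f"{env_id}: dates must be strictly daily")
        sow = sowing_date or dates.iloc[0].date()
        dl = df["daylength"].to_numpy(float) if "daylength" in df.columns else None
        return cls(env_id, sow, df["tmean"].to_numpy(float), dl, latitude)


def _heading_from_cum(cum: np.ndarray, dl: np.ndarray, P: np.ndarray,
                      SLDL: np.ndarray, cfg: CGMConfig, continuous: bool):
    """Vectorized core: heading day (1-based days after sowing) for
    parameter vectors, given precomputed cumulative thermal time.
    Returns nan where heading is not reached within the series."""
    T = len(cum)
    thr_flag = cfg.tt_emergence + cfg.hs_flag * P
    i_flag = np.searchsorted(cum, thr_flag, side="left")
    reached_flag = i_flag < T
    i_safe = np.minimum(i_flag, T - 1)
    dl_star = dl[i_safe]
    lf = np.clip(cfg.l_min + SLDL * np.maximum(0.0, cfg.dl_sat - dl_star),
                 cfg.l_min, cfg.l_max)
    thr_head = cfg.tt_emergence + (lf + cfg.k_head) * P
    if continuous:
        days = np.arange(1, T + 1, dtype=float)
        day = np.interp(thr_head, cum, days)
        reached = thr_head <= cum[-1]
    else:
        i_head = np.searchsorted(cum, thr_head, side="left")
        reached = i_head < T
        day = (np.minimum(i_head, T - 1) + 1).astype(float)
    out = np.where(reached_flag & reached, day, np.nan)
    return out


def predict_heading(params: PhenologyParams, weather: WeatherSeries,
                    cfg: CGMConfig = CGMConfig(), continuous: bool = False):
    """Predict heading for one variety in one environment.

    Simulation: thermal time accumulates as Σ max(0, tmean − t_base);
    emergence occurs when it reaches ``tt_emergence``; the Haun stage is
    then (TT − tt_emergence)/P; on the first day the Haun stage reaches
    ``hs_flag`` the perceived daylength DL* fixes the final leaf number
    L_f = clip(l_min + SLDL·max(0, dl_sat − DL*), l_min, l_max); heading
    is the first day with Haun stage ≥ L_f + k_head.

    Returns ``(days_after_sowing, day_of_year)``.  With
    ``continuous=True`` the crossing day is linearly interpolated (used
    for smoother MCMC likelihoods); day_of_year is then fractional too.

    Raises HeadingNotReached when the series ends first.
    """
    cum = weather.cumulative_tt(cfg.t_base)
    day = _heading_from_cum(cum, weather.daylength_h,
                            np.asarray([params.P]), np.asarray([params.SLDL]),
                            cfg, continuous)[0]
    if np.isnan(day):
        raise HeadingNotReached(
            f"heading not reached in {weather.env_id} within {len(weather)} days "
            f"(P={params.P}, SLDL={params.SLDL})")
    if not continuous:
        day = int(day)
    sow_doy = weather.sowing_date.timetuple().tm_yday
    doy = (sow_doy - 1 + day - 1) % 365 + 1
    return day, doy


def predict_heading_batch(P: np.ndarray, SLDL: np.ndarray, weather: WeatherSeries,
                          cfg: CGMConfig = CGMConfig(),
                          continuous: bool = False) -> np.ndarray:
    """Heading days after sowing for vectors of (P, SLDL); nan where
    heading is not reached."""
    cum = weather.cumulative_tt(cfg.t_base)
    return _heading_from_cum(cum, weather.daylength_h, np.asarray(P, float),
                             np.asarray(SLDL, float), cfg, continuous)
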