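"""Synthetic weather, counts and case records for the case-crossover DLNM.

The real inputs of the analysis — an emergency-department registry of
intentional self-harm visits, a national cause-of-death registry, and a
single-station meteorological series — are restricted-access.  This module
generates stand-ins with the statistical structure the analysis assumes:

* a gap-free daily temperature series with an annual cycle, AR(1) noise and
  a correlated dewpoint series, on the Seoul scale (annual mean ~13 degC,
  SD ~10-11 degC);
* daily event counts drawn from a known exposure-lag-response surface with
  day-of-week, seasonal and holiday log-rate offsets and overdispersion;
* individual-level visit records carrying the registry schema fields that
  the inclusion/exclusion filters and subgroup assignment consume, with a
  parallel death-registry record (ICD-10 X60-X84) for each fatal case.

Every generator is a pure function of its parameters and seed, so the
ground truth behind any simulated dataset is known exactly and downstream
estimates can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "WeatherParams",
    "RiskSurface",
    "CaseSchema",
    "simulate_weather",
    "simulate_counts",
    "simulate_case_records",
    "linear_exposure",
    "null_exposure",
    "DEFAULT_DEMOGRAPHICS",
]

SEXES = ("female", "male")
AGE_BANDS = ("0-34", "35-64", "65+")
_AGE_RANGES = {"0-34": (10, 34), "35-64": (35, 64), "65+": (65, 90)}

#: sex x age-band mixing proportions (emergency self-harm visit composition)
DEFAULT_DEMOGRAPHICS: dict[tuple[str, str], float] = {
    ("female", "0-34"): 0.257,
    ("female", "35-64"): 0.276,
    ("female", "65+"): 0.061,
    ("male", "0-34"): 0.144,
    ("male", "35-64"): 0.200,
    ("male", "65+"): 0.062,
}

MECHANISMS = ("poisoning", "drowning", "hanging", "jumping", "sharp objects", "others")

#: ICD-10 intentional self-harm categories per mechanism (X60-X84)
MECHANISM_ICD10 = {
    "poisoning": [f"X{c}" for c in range(60, 70)],
    "drowning": ["X71"],
    "hanging": ["X70"],
    "jumping": ["X80"],
    "sharp objects": ["X78"],
    "others": ["X75", "X76", "X81", "X82", "X83", "X84"],
}


def linear_exposure(slope: float, reference: float) -> Callable[[np.ndarray], np.ndarray]:
    """Linear log-RR in temperature, zero at the reference."""

    def fn(x: np.ndarray) -> np.ndarray:
        return slope * (np.asarray(x, float) - reference)

    return fn


def null_exposure(reference: float = 0.0) -> Callable[[np.ndarray], np.ndarray]:
    """No temperature effect."""

    def fn(x: np.ndarray) -> np.ndarray:
        return np.zeros_like(np.asarray(x, float))

    return fn


@dataclass(frozen=True)
class WeatherParams:
    """Parameters of the simulated single-station meteorological series.

    The deterministic annual cycle is a cosine completing exactly
    ``n_years`` cycles over the series (period ~365.25 d), coldest at the
    configurable start date, so whole-series means are exact.  AR(1) noise
    with stationary SD ``noise_sd`` is superposed.  Min/max temperatures sit
    half a diurnal range below/above the mean; dewpoint tracks the mean
    temperature minus an offset plus independent noise.
    """

    n_years: int = 6
    annual_mean: float = 13.4  # degC
    annual_amplitude: float = 14.0  # degC
    noise_sd: float = 3.0  # degC
    ar1_coef: float = 0.6
    dewpoint_offset: float = 8.7  # degC
    dewpoint_noise_sd: float = 5.0  # degC
    diurnal_range: float = 9.0  # degC, tmax - tmin
    diurnal_noise_sd: float = 1.0  # degC
    start: str = "2014-01-01"
    holidays_per_year: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError(f"n_years must be >= 1, got {self.n_years}")
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not abs(self.ar1_coef) < 1:
            raise ValueError(f"ar1_coef must satisfy |ar1_coef| < 1, got {self.ar1_coef}")
        if self.diurnal_range <= 0:
            raise ValueError(f"diurnal_range must be > 0, got {self.diurnal_range}")


def simulate_weather(params: WeatherParams) -> pd.DataFrame:
    """Simulate the daily series: one row per calendar day, no gaps.

    Returns columns date, tmean, tmin, tmax, dewpoint, holiday.
    """
    start = pd.Timestamp(params.start)
    end = start + pd.DateOffset(years=params.n_years) - pd.Timedelta(days=1)
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)
    rng = np.random.default_rng(params.seed)

    t = np.arange(n)
    seasonal = params.annual_mean - params.annual_amplitude * np.cos(2 * np.pi * params.n_years * t / n)
    innov = rng.normal(0.0, params.noise_sd * np.sqrt(1 - params.ar1_coef**2), n)
    e0 = rng.normal(0.0, params.noise_sd)
    noise = lfilter([1.0], [1.0, -params.ar1_coef], innov, zi=[params.ar1_coef * e0])[0]
    tmean = seasonal + noise

    half = params.diurnal_range / 2
    tmin = tmean - half + rng.normal(0.0, params.diurnal_noise_sd, n)
    tmax = tmean + half + rng.normal(0.0, params.diurnal_noise_sd, n)
    dew = tmean - params.dewpoint_offset + rng.normal(0.0, params.dewpoint_noise_sd, n)

    holiday = np.zeros(n, dtype=bool)
    holiday[(dates.month == 1) & (dates.day == 1)] = True
    extra = max(params.holidays_per_year - 1, 0)
    for year in dates.year.unique():
        iyr = np.flatnonzero(dates.year == year)
        pick = rng.choice(iyr, size=min(extra, iyr.size), replace=False)
        holiday[pick] = True

    return pd.DataFrame(
        {
            "date": dates,
            "tmean": tmean,
            "tmin": tmin,
            "tmax": tmax,
            "dewpoint": dew,
            "holiday": holiday,
        }
    )


@dataclass(frozen=True)
class RiskSurface:
    """Ground-truth exposure-lag-response surface behind simulated counts.

    ``exposure_fn`` maps temperature (degC) to the lag-0 log-RR contribution
    and must be exactly zero at ``reference``; ``lag_weights`` spread that
    contribution over lags 0..L and sum to one.  Baseline, day-of-week,
    seasonal and holiday terms act on the log rate; ``overdispersion`` is
    the variance/mean ratio of the count draw (1 = Poisson, >1 via a
    gamma-Poisson mixture, i.e. negative binomial with matched moments).
    """

    exposure_fn: Callable[[np.ndarray], np.ndarray]
    reference: float
    lag_weights: tuple[float, ...] = (1.0, 0.0, 0.0)
    baseline_log_rate: float = float(np.log(16.2))
    dow_effects: tuple[float, ...] = (0.05, 0.02, 0.0, 0.0, 0.02, -0.04, -0.05)
    season_amplitude: float = 0.10
    holiday_effect: float = 0.10
    overdispersion: float = 1.5

    def __post_init__(self) -> None:
        w = np.asarray(self.lag_weights, dtype=float)
        if np.any(w < 0):
            raise ValueError(f"lag_weights must be non-negative, got {self.lag_weights}")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"lag_weights must sum to 1 within 1e-12, got sum {w.sum()!r}")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")
        if self.overdispersion < 1:
            raise ValueError(f"overdispersion must be >= 1, got {self.overdispersion}")
        ref_val = float(np.asarray(self.exposure_fn(np.array([self.reference])))[0])
        if ref_val != 0.0:
            raise ValueError(f"exposure_fn(reference) must be exactly 0, got {ref_val}")

    @property
    def max_lag(self) -> int:
        return len(self.lag_weights) - 1

    @classmethod
    def null(cls, reference: float = 14.8, **kwargs) -> "RiskSurface":
        return cls(exposure_fn=null_exposure(reference), reference=reference, **kwargs)

    def log_mu(self, weather: pd.DataFrame) -> pd.Series:
        """Deterministic log expected count for each day with full lag history."""
        dates = pd.DatetimeIndex(weather["date"])
        gaps = np.flatnonzero(np.diff(dates.values) != np.timedelta64(1, "D"))
        if gaps.size:
            missing = [str(dates[g].date()) for g in gaps[:5]]
            raise ValueError(f"weather series has gaps after: {missing}")
        L = self.max_lag
        if len(weather) < L + 1:
            raise ValueError(f"weather must cover at least {L + 1} days, got {len(weather)}")
        fx = np.asarray(self.exposure_fn(weather["tmean"].to_numpy()), dtype=float)
        w = np.asarray(self.lag_weights, dtype=float)
        contrib = np.convolve(fx, w)[: len(fx)]  # contrib[t] = sum_l w[l] fx[t-l]
        doy = dates.dayofyear.to_numpy()
        season = self.season_amplitude * (-np.cos(2 * np.pi * doy / 365.25))
        dow = np.asarray(self.dow_effects)[dates.weekday.to_numpy()]
        hol = self.holiday_effect * weather["holiday"].to_numpy().astype(float)
        log_mu = self.baseline_log_rate + dow + season + hol + contrib
        return pd.Series(log_mu[L:], index=dates[L:], name="log_mu")

    def grid_evaluation(self, lo: float, hi: float, step: float = 0.1) -> pd.DataFrame:
        """Evaluate the true cumulative log-RR on a temperature grid (test oracle)."""
        grid = np.arange(lo, hi + step / 2, step)
        return pd.DataFrame({"temperature": grid, "cumulative_log_rr": self.exposure_fn(grid)})


def simulate_counts(weather: pd.DataFrame, surface: RiskSurface, seed: int) -> pd.Series:
    """Draw daily counts from the surface; indexed by date, first L days dropped.

    Poisson when ``overdispersion == 1``; otherwise gamma-Poisson with
    variance ``overdispersion * mu`` (negative-binomial parameterization).
    Deterministic given the seed.
    """
    log_mu = surface.log_mu(weather)
    mu = np.exp(log_mu.to_numpy())
    rng = np.random.default_rng(seed)
    phi = surface.overdispersion
    if phi == 1.0:
        y = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=mu / (phi - 1.0), scale=phi - 1.0)
        y = rng.poisson(lam)
    return pd.Series(y, index=log_mu.index, name="count")


@dataclass(frozen=True)
class CaseSchema:
    """Categorical composition of simulated emergency visit records."""

    mechanism_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "poisoning": 0.529,
            "sharp objects": 0.276,
            "others": 0.118,
            "hanging": 0.038,
            "jumping": 0.020,
            "drowning": 0.019,
        }
    )
    intentionality_probs: Mapping[str, float] = field(
        default_factory=lambda: {"intentional self-harm": 0.7, "suicide": 0.3}
    )
    er_death_fraction: float = 0.038
    posthosp_death_fraction: float = 0.011

    def __post_init__(self) -> None:
        for name, probs in (
            ("mechanism_probs", self.mechanism_probs),
            ("intentionality_probs", self.intentionality_probs),
        ):
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9, got {total!r}")
        for name, f in (
            ("er_death_fraction", self.er_death_fraction),
            ("posthosp_death_fraction", self.posthosp_death_fraction),
        ):
            if not 0 <= f <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {f}")


def simulate_case_records(
    weather: pd.DataFrame,
    surface: RiskSurface,
    demographics: Mapping[tuple[str, str], float] | None = None,
    schema: CaseSchema | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Individual-level visit records plus the parallel death registry.

    Per-day record counts follow :func:`simulate_counts`; each record draws
    sex/age band, mechanism, intentionality and outcome fields
    independently.  A fraction ``er_death_fraction`` die in the emergency
    room (death level in ``er_result``) and, among the rest,
    ``posthosp_death_fraction`` die after admission (death level in
    ``posthosp_result``).  Every ER death also yields a death-registry row
    with an ICD-10 code in X60-X84 matched to its mechanism.

    Returns ``(records, deaths)`` DataFrames.
    """
    demographics = dict(DEFAULT_DEMOGRAPHICS if demographics is None else demographics)
    total = float(sum(demographics.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"demographic proportions must sum to 1 within 1e-9, got {total!r}")
    schema = schema or CaseSchema()
    counts = simulate_counts(weather, surface, seed)
    rng = np.random.default_rng(seed + 1)

    n = int(counts.sum())
    dates = np.repeat(counts.index.to_numpy(), counts.to_numpy())

    cells = list(demographics.keys())
    cell_idx = rng.choice(len(cells), size=n, p=list(demographics.values()))
    sex = np.array([cells[i][0] for i in cell_idx])
    band = np.array([cells[i][1] for i in cell_idx])
    age = np.empty(n, dtype=int)
    for b, (lo, hi) in _AGE_RANGES.items():
        m = band == b
        age[m] = rng.integers(lo, hi + 1, size=int(m.sum()))

    mech_levels = list(schema.mechanism_probs.keys())
    mech = rng.choice(mech_levels, size=n, p=list(schema.mechanism_probs.values()))
    intent_levels = list(schema.intentionality_probs.keys())
    intent = rng.choice(intent_levels, size=n, p=list(schema.intentionality_probs.values()))

    er_death = rng.random(n) < schema.er_death_fraction
    posthosp_death = (~er_death) & (rng.random(n) < schema.posthosp_death_fraction)
    er_result = np.where(er_death, "death", rng.choice(["discharge", "admission"], size=n))
    posthosp_result = np.where(posthosp_death, "death", "normal discharge")
    posthosp_result = np.where(er_death, "not applicable", posthosp_result)

    records = pd.DataFrame(
        {
            "record_id": np.arange(n),
            "event_date": dates,
            "sex": sex,
            "age": age,
            "intentionality": intent,
            "mechanism": mech,
            "er_result": er_result,
            "posthosp_result": posthosp_result,
        }
    )

    dead = records[er_death]
    icd = [rng.choice(MECHANISM_ICD10[m]) for m in dead["mechanism"]]
    deaths = pd.DataFrame(
        {
            "date": dead["event_date"].to_numpy(),
            "sex": dead["sex"].to_numpy(),
            "age": dead["age"].to_numpy(),
            "icd10": icd,
        }
    )
    return records, deaths


def write_synthetic_inputs(
    out_dir: str | Path,
    weather_params: WeatherParams | None = None,
    surface: RiskSurface | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Write weather, records, deaths and the true-surface grid as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = weather_params or WeatherParams(seed=seed)
    weather = simulate_weather(params)
    surface = surface or RiskSurface(
        exposure_fn=linear_exposure(0.02, float(np.percentile(weather["tmean"], 50))),
        reference=float(np.percentile(weather["tmean"], 50)),
    )
    records, deaths = simulate_case_records(weather, surface, seed=seed)
    paths = {
        "weather": out / "weather.csv",
        "records": out / "records.csv",
        "deaths": out / "deaths.csv",
        "surface": out / "true_surface.csv",
    }
    weather.assign(date=weather["date"].dt.date).to_csv(paths["weather"], index=False)
    records.assign(event_date=pd.DatetimeIndex(records["event_date"]).date).to_csv(paths["records"], index=False)
    deaths.assign(date=pd.DatetimeIndex(deaths["date"]).date).to_csv(paths["deaths"], index=False)
    surface.grid_evaluation(float(weather["tmean"].min()), float(weather["tmean"].max())).to_csv(
        paths["surface"], index=False
    )
    return paths
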