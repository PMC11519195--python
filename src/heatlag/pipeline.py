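"""End-to-end orchestration: cohort build, per-subgroup DLNM fits, effects.

One config drives the whole study: for each outcome x subgroup the pipeline
aggregates daily counts, builds the case-crossover strata and the
cross-basis with outcome-specific exposure knots (P50 for suicide deaths,
P25/50/75 for self-harm visits), fits the conditional quasi-Poisson model,
and extracts the cumulative RR curve, MaxRT and the P99-vs-P50 contrast.
The sensitivity suite repeats the primary contrast for maximum lags 2/3/6
and for minimum/maximum instead of mean temperature.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basis import build_cross_basis, log_lag_knots, percentile_knots
from .cohort import Subgroup, aggregate_daily, select_ish, select_suicide_deaths
from .effects import find_maxrt, predict_rr, rr_at_percentile
from .model import fit_conditional_quasipoisson, humidity_covariates
from .strata import build_strata, informative_strata

__all__ = ["AnalysisConfig", "run_analysis", "run_sensitivity", "DEFAULT_SUBGROUPS"]

logger = logging.getLogger(__name__)

DEFAULT_SUBGROUPS: tuple[Subgroup, ...] = (
    Subgroup(),
    Subgroup(sex="female"),
    Subgroup(sex="male"),
    Subgroup(age_band="0-34"),
    Subgroup(age_band="35-64"),
    Subgroup(age_band="65+"),
    Subgroup(sex="female", age_band="0-34"),
    Subgroup(sex="female", age_band="35-64"),
    Subgroup(sex="female", age_band="65+"),
    Subgroup(sex="male", age_band="0-34"),
    Subgroup(sex="male", age_band="35-64"),
    Subgroup(sex="male", age_band="65+"),
)

DEFAULT_KNOT_PERCENTILES = {
    "ish_nonfatal": (25.0, 50.0, 75.0),
    "ish_total": (25.0, 50.0, 75.0),
    "suicide_death": (50.0,),
}

_OUTCOMES = ("ish_nonfatal", "ish_total", "suicide_death")
_EXPOSURES = ("tmean", "tmin", "tmax")


@dataclass
class AnalysisConfig:
    """Configuration of one full study run."""

    weather_csv: str | None = None
    records_csv: str | None = None
    deaths_csv: str | None = None
    output_dir: str = "results"
    outcomes: tuple[str, ...] = ("ish_nonfatal", "suicide_death")
    exposure: str = "tmean"
    max_lag: int = 2
    lag_knots: int = 1
    knot_percentiles: dict = field(default_factory=lambda: dict(DEFAULT_KNOT_PERCENTILES))
    subgroups: tuple[Subgroup, ...] = DEFAULT_SUBGROUPS
    ci_level: float = 0.95
    seed: int = 0
    qaic_variant: str = "scaled_deviance"
    dewpoint_df: int = 3

    def __post_init__(self) -> None:
        if self.max_lag not in (2, 3, 6):
            raise ValueError(f"max_lag must be one of 2, 3, 6; got {self.max_lag}")
        if self.exposure not in _EXPOSURES:
            raise ValueError(f"exposure must be one of {_EXPOSURES}, got {self.exposure!r}")
        for outcome in self.outcomes:
            if outcome not in _OUTCOMES:
                raise ValueError(f"unknown outcome {outcome!r}; expected one of {_OUTCOMES}")
            pcts = self.knot_percentiles.get(outcome)
            if not pcts or any(not 0 < p < 100 for p in pcts):
                raise ValueError(f"invalid knot percentiles for {outcome!r}: {pcts}")
        self.subgroups = tuple(Subgroup(*s) if not isinstance(s, Subgroup) else s for s in self.subgroups)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "subgroups" in raw:
            raw["subgroups"] = tuple(Subgroup(**s) if isinstance(s, dict) else Subgroup(*s) for s in raw["subgroups"])
        if "knot_percentiles" in raw:
            raw["knot_percentiles"] = {k: tuple(v) for k, v in raw["knot_percentiles"].items()}
        if "outcomes" in raw:
            raw["outcomes"] = tuple(raw["outcomes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subgroups"] = [list(s) for s in self.subgroups]
        d["knot_percentiles"] = {k: list(v) for k, v in self.knot_percentiles.items()}
        d["outcomes"] = list(self.outcomes)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _load_inputs(config, weather, records, deaths):
    if weather is None:
        if config.weather_csv is None:
            raise ValueError("no weather input: pass a DataFrame or set weather_csv")
        weather = pd.read_csv(config.weather_csv, parse_dates=["date"])
    needs_records = any(o.startswith("ish") for o in config.outcomes)
    if records is None and needs_records:
        if config.records_csv is None:
            raise ValueError("no case-record input: pass a DataFrame or set records_csv")
        records = pd.read_csv(config.records_csv, parse_dates=["event_date"])
    needs_deaths = "suicide_death" in config.outcomes
    if deaths is None and needs_deaths:
        if config.deaths_csv is None:
            raise ValueError("no death-record input: pass a DataFrame or set deaths_csv")
        deaths = pd.read_csv(config.deaths_csv, parse_dates=["date"])
    return weather, records, deaths


def _outcome_records(outcome: str, records: pd.DataFrame | None, deaths: pd.DataFrame | None) -> pd.DataFrame:
    if outcome == "ish_nonfatal":
        return select_ish(records, include_fatal=False)
    if outcome == "ish_total":
        return select_ish(records, include_fatal=True)
    if outcome == "suicide_death":
        return select_suicide_deaths(deaths)
    raise ValueError(f"unknown outcome {outcome!r}")


def _analyze_one(
    weather: pd.DataFrame,
    counts: pd.Series,
    exposure: str,
    max_lag: int,
    lag_knots: int,
    pcts: tuple[float, ...],
    ci_level: float,
    qaic_variant: str,
    dewpoint_df: int,
) -> dict:
    """Fit one outcome/subgroup series and extract all effect summaries."""
    calendar = pd.DatetimeIndex(weather["date"])
    x = weather[exposure].to_numpy(dtype=float)
    strata = build_strata(calendar)
    exposure_spec = percentile_knots(x, pcts)
    lag_spec = log_lag_knots(max_lag, lag_knots)
    cb = build_cross_basis(x, exposure_spec, lag_spec, max_lag, exposure_name=exposure)
    dew_X, dew_names = humidity_covariates(weather["dewpoint"].to_numpy(), df=dewpoint_df)
    cov = np.column_stack([dew_X, weather["holiday"].to_numpy(dtype=float)])
    fit = fit_conditional_quasipoisson(
        cb, counts.to_numpy(), strata, cov, dew_names + ["holiday"], qaic_variant=qaic_variant
    )
    curve = predict_rr(fit, cb, exposure_sample=x, ci_level=ci_level)
    maxrt = find_maxrt(curve, x)
    rr99 = rr_at_percentile(curve, x, 99)
    informative = informative_strata(counts.to_numpy()[cb.complete], _restrict(strata, cb.complete))
    return {
        "fit": fit,
        "curve": curve,
        "maxrt": maxrt,
        "rr99": rr99,
        "n_events": int(counts.sum()),
        "n_strata_informative": informative.n_strata,
    }


def _restrict(strata, mask):
    from .strata import StratumIndex

    codes_sub = strata.codes[mask]
    keep = np.unique(codes_sub)
    recode = {c: i for i, c in enumerate(keep)}
    return StratumIndex(
        dates=strata.dates[mask],
        codes=np.array([recode[c] for c in codes_sub]),
        labels=[strata.labels[c] for c in keep],
    )


def run_analysis(
    config: AnalysisConfig,
    weather: pd.DataFrame | None = None,
    records: pd.DataFrame | None = None,
    deaths: pd.DataFrame | None = None,
    write: bool = True,
) -> dict:
    """Run every outcome x subgroup analysis of the config.

    Returns ``{"summary": DataFrame, "analyses": {(outcome, subgroup): ...}}``
    and, when ``write`` is true, writes ``summary.csv`` plus per-analysis
    JSON bundles under ``config.output_dir``.
    """
    weather, records, deaths = _load_inputs(config, weather, records, deaths)
    calendar = pd.DatetimeIndex(weather["date"])
    logger.info("run %s: seed=%d, %d days, exposure=%s, L=%d",
                config.config_hash, config.seed, len(calendar), config.exposure, config.max_lag)

    rows = []
    analyses: dict = {}
    for outcome in config.outcomes:
        recs = _outcome_records(outcome, records, deaths)
        pcts = tuple(config.knot_percentiles[outcome])
        for sg in config.subgroups:
            counts = aggregate_daily(recs, calendar, sg)
            if counts.sum() == 0:
                logger.warning("skipping %s / %s: zero events", outcome, sg.label)
                continue
            res = _analyze_one(
                weather, counts, config.exposure, config.max_lag, config.lag_knots,
                pcts, config.ci_level, config.qaic_variant, config.dewpoint_df,
            )
            analyses[(outcome, sg)] = res
            rows.append(
                {
                    "outcome": outcome,
                    "sex": sg.sex,
                    "age_band": sg.age_band,
                    "exposure": config.exposure,
                    "max_lag": config.max_lag,
                    "n_events": res["n_events"],
                    "maxrt": res["maxrt"].maxrt,
                    "rr_maxrt": res["maxrt"].rr_at_maxrt,
                    "rr_maxrt_lo": res["maxrt"].lo,
                    "rr_maxrt_hi": res["maxrt"].hi,
                    "rr_p99": res["rr99"].rr,
                    "rr_p99_lo": res["rr99"].lo,
                    "rr_p99_hi": res["rr99"].hi,
                    "qaic": res["fit"].qaic,
                    "dispersion": res["fit"].dispersion,
                    "converged": res["fit"].converged,
                }
            )
    summary = pd.DataFrame(rows)
    out = {"summary": summary, "analyses": analyses, "config_hash": config.config_hash}
    if write:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "summary.csv", index=False)
        for (outcome, sg), res in analyses.items():
            name = f"{outcome}_{sg.sex}_{sg.age_band.replace('+', 'plus')}"
            bundle = {
                "outcome": outcome,
                "subgroup": {"sex": sg.sex, "age_band": sg.age_band},
                "config_hash": config.config_hash,
                "seed": config.seed,
                "fit": res["fit"].to_dict(),
                "maxrt": dataclasses.asdict(res["maxrt"]),
                "rr_p99": res["rr99"]._asdict(),
                "n_strata_informative": res["n_strata_informative"],
            }
            (out_dir / f"{name}.json").write_text(json.dumps(bundle, indent=2))
            res["curve"].to_frame().to_csv(out_dir / f"{name}_curve.csv", index=False)
        logger.info("wrote %d summary rows to %s", len(summary), out_dir / "summary.csv")
    return out


def run_sensitivity(
    config: AnalysisConfig,
    weather: pd.DataFrame | None = None,
    records: pd.DataFrame | None = None,
    deaths: pd.DataFrame | None = None,
    max_lags: tuple[int, ...] = (2, 3, 6),
    exposures: tuple[str, ...] = ("tmean", "tmin", "tmax"),
    write: bool = True,
) -> pd.DataFrame:
    """P99-vs-P50 contrast of the all-group series across lag/exposure variants."""
    weather, records, deaths = _load_inputs(config, weather, records, deaths)
    calendar = pd.DatetimeIndex(weather["date"])
    rows = []
    for outcome in config.outcomes:
        recs = _outcome_records(outcome, records, deaths)
        counts = aggregate_daily(recs, calendar, Subgroup())
        if counts.sum() == 0:
            logger.warning("sensitivity: skipping %s, zero events", outcome)
            continue
        pcts = tuple(config.knot_percentiles[outcome])
        for exposure in exposures:
            for L in max_lags:
                res = _analyze_one(
                    weather, counts, exposure, L, config.lag_knots,
                    pcts, config.ci_level, config.qaic_variant, config.dewpoint_df,
                )
                rows.append(
                    {
                        "outcome": outcome,
                        "exposure": exposure,
                        "max_lag": L,
                        "rr_p99": res["rr99"].rr,
                        "rr_p99_lo": res["rr99"].lo,
                        "rr_p99_hi": res["rr99"].hi,
                        "maxrt": res["maxrt"].maxrt,
                        "qaic": res["fit"].qaic,
                    }
                )
    table = pd.DataFrame(rows)
    if write:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "sensitivity.csv", index=False)
    return table
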