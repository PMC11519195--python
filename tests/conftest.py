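import numpy as np
import pandas as pd
import pytest

import heatlag as hl


@pytest.fixture(scope="session")
def weather6y() -> pd.DataFrame:
    """Six years of synthetic Seoul-scale daily weather."""
    return hl.simulate_weather(hl.WeatherParams(seed=11))


def run_single(
    weather: pd.DataFrame,
    surface: hl.RiskSurface,
    seed: int,
    max_lag: int = 2,
    knot_percentiles=(50,),
    lag_knots: int = 1,
):
    """One full single-series analysis: counts -> strata -> cross-basis -> fit -> curve.

    Returns (fit, crossbasis, curve, exposure array).
    """
    x = weather["tmean"].to_numpy()
    counts = hl.simulate_counts(weather, surface, seed)
    y = np.zeros(len(weather))
    y[surface.max_lag:] = counts.to_numpy()
    espec = hl.percentile_knots(x, knot_percentiles)
    lspec = hl.log_lag_knots(max_lag, lag_knots)
    cb = hl.build_cross_basis(x, espec, lspec, max_lag)
    strata = hl.build_strata(pd.DatetimeIndex(weather["date"]))
    dew_X, dew_names = hl.humidity_covariates(weather["dewpoint"].to_numpy())
    cov = np.column_stack([dew_X, weather["holiday"].to_numpy(float)])
    fit = hl.fit_conditional_quasipoisson(cb, y, strata, cov, dew_names + ["holiday"])
    curve = hl.predict_rr(fit, cb, exposure_sample=x)
    return fit, cb, curve, x


def calibration_surface(x: np.ndarray, slope: float, lag_weights=(1.0, 0.0, 0.0)) -> hl.RiskSurface:
    """Surface for estimator-calibration runs: linear log-RR, no within-month
    seasonal trend (month strata only absorb monthly means, so an aligned
    seasonal trend would be genuine residual confounding, not estimator error)."""
    ref = float(np.percentile(x, 50))
    fn = hl.linear_exposure(slope, ref) if slope else hl.null_exposure(ref)
    return hl.RiskSurface(
        exposure_fn=fn, reference=ref, lag_weights=lag_weights, season_amplitude=0.0
    )


@pytest.fixture(scope="session")
def replicate_study():
    """200 replicates each of an effect (slope 0.02/degC at lag 0, L=2) and a
    null surface on ~2,000-day series; shared by recovery, coverage and
    type-I checks."""

    def one(seed: int, slope: float):
        w = hl.simulate_weather(hl.WeatherParams(seed=seed)).iloc[:2002].reset_index(drop=True)
        x = w["tmean"].to_numpy()
        surf = calibration_surface(x, slope)
        fit, cb, curve, _ = run_single(w, surf, seed + 10_000)
        x50, x99 = np.percentile(x, [50, 99])
        log_rr, se = curve.log_rr_at(x99)
        rr = hl.rr_at_percentile(curve, x, 99)
        true_rr = float(np.exp(slope * (x99 - x50)))
        return {
            "slope_hat": log_rr / (x99 - x50),
            "covered": rr.lo <= true_rr <= rr.hi,
            "rejected": (rr.lo > 1.0) or (rr.hi < 1.0),
        }

    effect = [one(1000 + r, 0.02) for r in range(200)]
    null = [one(5000 + r, 0.0) for r in range(200)]
    return {"effect": effect, "null": null, "true_slope": 0.02, "n_reps": 200}
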