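"""Conditional quasi-Poisson regression with absorbed case-crossover strata.

The model for daily counts is

    Y_t ~ quasi-Poisson(mu_t)
    log(mu_t) = alpha_s(t) + beta' T_t + gamma' S(DT_t) + eta * Holiday_t

with one nuisance intercept ``alpha_s`` per (year, month, weekday) stratum.
The stratum intercepts are eliminated by conditioning on stratum totals:
the conditional likelihood is multinomial within each stratum, and its
maximizer coincides with the fixed-effects Poisson MLE.  Fitting absorbs
the strata by profiling (closed-form intercept update plus within-stratum
weighted centering in the IRLS step) rather than estimating dense dummy
columns, which keeps memory O(strata).  Overdispersion is estimated by
Pearson chi-square over residual degrees of freedom and scales the
covariance (quasi-likelihood).  Estimates are equivalent to conditional
logistic regression when strata contain a single binary case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import CrossBasis, SplineSpec, ns_basis, percentile_knots
from .strata import StratumIndex

__all__ = [
    "FitResult",
    "fit_conditional_quasipoisson",
    "qaic",
    "select_exposure_knots",
    "humidity_covariates",
]

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """One converged conditional quasi-Poisson fit."""

    coefficients: np.ndarray
    names: list[str]
    vcov: np.ndarray  # scaled by dispersion
    dispersion: float
    loglik: float  # conditional (multinomial) log-likelihood, constants dropped
    n_params: int
    converged: bool
    n_strata_used: int
    n_obs: int
    deviance: float
    pearson_chi2: float
    df_resid: int
    cb_slice: slice = field(default_factory=lambda: slice(0, 0))
    qaic_variant: str = "scaled_deviance"
    n_iter: int = 0
    score_norm: float = np.nan

    @property
    def qaic(self) -> float:
        return qaic(self, self.qaic_variant)

    def cb_coefficients(self) -> np.ndarray:
        return self.coefficients[self.cb_slice]

    def cb_vcov(self) -> np.ndarray:
        return self.vcov[self.cb_slice, self.cb_slice]

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(self.names, map(float, self.coefficients))),
            "vcov": self.vcov.tolist(),
            "dispersion": float(self.dispersion),
            "loglik": float(self.loglik),
            "n_params": self.n_params,
            "qaic": float(self.qaic),
            "qaic_variant": self.qaic_variant,
            "converged": self.converged,
            "n_strata_used": self.n_strata_used,
            "n_obs": self.n_obs,
            "deviance": float(self.deviance),
            "pearson_chi2": float(self.pearson_chi2),
            "df_resid": self.df_resid,
        }


def humidity_covariates(dewpoint: np.ndarray | pd.Series, df: int = 3) -> tuple[np.ndarray, list[str]]:
    """Natural cubic spline of daily mean dewpoint temperature, S(DT_t, df).

    ``df`` columns (no intercept): ``df - 1`` interior knots at equally
    spaced quantiles of the dewpoint series, boundary knots at min/max.
    """
    dew = np.asarray(dewpoint, dtype=float)
    if df < 2:
        raise ValueError(f"dewpoint spline df must be >= 2, got {df}")
    probs = np.linspace(0, 100, df + 1)[1:-1]
    spec = percentile_knots(dew, probs)
    X = ns_basis(dew, spec)
    return X, [f"dew_{i+1}" for i in range(X.shape[1])]


def _stratum_mean(values: np.ndarray, weights: np.ndarray, codes: np.ndarray, n_strata: int) -> np.ndarray:
    wsum = np.bincount(codes, weights=weights, minlength=n_strata)
    if values.ndim == 1:
        num = np.bincount(codes, weights=weights * values, minlength=n_strata)
        return (num / wsum)[codes]
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        num = np.bincount(codes, weights=weights * values[:, j], minlength=n_strata)
        out[:, j] = (num / wsum)[codes]
    return out


def fit_conditional_quasipoisson(
    crossbasis: CrossBasis,
    counts: np.ndarray | pd.Series,
    strata: StratumIndex,
    covariates: np.ndarray | pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
    max_iter: int = 50,
    deviance_rtol: float = 1e-9,
    score_tol: float = 1e-6,
    qaic_variant: str = "scaled_deviance",
) -> FitResult:
    """Fit the conditional quasi-Poisson model.

    ``crossbasis.matrix``, ``counts``, ``covariates`` and ``strata.dates``
    must be row-aligned on the same calendar.  Days without a full lag
    history and days in uninformative (all-zero) strata are excluded from
    the likelihood.
    """
    y_all = np.asarray(counts, dtype=float)
    n_all = y_all.size
    if crossbasis.matrix.shape[0] != n_all or len(strata.dates) != n_all:
        raise ValueError(
            f"row mismatch: crossbasis {crossbasis.matrix.shape[0]}, counts {n_all}, "
            f"strata {len(strata.dates)}"
        )
    X_all = crossbasis.matrix
    n_cb = X_all.shape[1]
    names = list(crossbasis.column_names)
    if len(names) != n_cb:
        names = [f"cb_{j}" for j in range(n_cb)]
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            covariate_names = covariate_names or list(covariates.columns)
            covariates = covariates.to_numpy(dtype=float)
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariate_names is None:
            covariate_names = [f"z_{j}" for j in range(covariates.shape[1])]
        X_all = np.column_stack([X_all, covariates])
        names += list(covariate_names)

    mask = crossbasis.complete.copy()
    codes_full = strata.codes[mask]
    y = y_all[mask]
    X = X_all[mask]

    # restrict to informative strata (all-zero strata contribute constants)
    totals = np.bincount(codes_full, weights=y)
    keep = np.flatnonzero(totals > 0)
    if keep.size == 0:
        raise ValueError("no informative strata: all counts are zero")
    dropped = (np.bincount(codes_full).size if codes_full.size else 0) - keep.size
    obs_keep = np.isin(codes_full, keep)
    recode = -np.ones(codes_full.max() + 1, dtype=int)
    recode[keep] = np.arange(keep.size)
    codes = recode[codes_full[obs_keep]]
    y = y[obs_keep]
    X = X[obs_keep]
    S = keep.size
    n, k = X.shape
    logger.debug("fitting on %d days, %d strata (%d uninformative dropped), %d params", n, S, max(dropped, 0), k)

    # collinearity check on the within-stratum centered design
    Xc0 = X - _stratum_mean(X, np.ones(n), codes, S)
    r = np.abs(np.diag(np.linalg.qr(Xc0, mode="r")))
    bad = np.flatnonzero(r < 1e-8 * max(r.max(), 1.0))
    if bad.size:
        raise ValueError(f"collinear design columns after stratum absorption: {[names[j] for j in bad]}")

    beta = np.zeros(k)
    dev = np.inf
    converged = False
    XtWX = np.eye(k)
    n_iter = 0
    score_norm = np.inf
    ysum = np.bincount(codes, weights=y, minlength=S)
    for n_iter in range(1, max_iter + 1):
        eta_x = X @ beta
        m = np.exp(eta_x - eta_x.max())  # stabilized; scale absorbed in alpha
        msum = np.bincount(codes, weights=m, minlength=S)
        mu = m * (ysum / msum)[codes]  # profiled stratum intercepts
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0)
        new_dev = 2.0 * dev_terms.sum()  # sum(y - mu) = 0 within strata
        score = X.T @ (y - mu)
        score_norm = float(np.linalg.norm(score))
        rel = abs(new_dev - dev) / (abs(new_dev) + 0.1)
        dev = new_dev
        if rel < deviance_rtol and score_norm < score_tol:
            converged = True
            break
        w = mu
        z = np.log(mu) + (y - mu) / mu
        Xc = X - _stratum_mean(X, w, codes, S)
        zc = z - _stratum_mean(z, w, codes, S)
        XtWX = (Xc * w[:, None]).T @ Xc
        XtWz = (Xc * w[:, None]).T @ zc
        beta = np.linalg.solve(XtWX, XtWz)

    if not converged:
        logger.warning(
            "conditional quasi-Poisson did not converge in %d iterations (score norm %.3g)",
            max_iter,
            score_norm,
        )

    # final quantities at beta-hat
    eta_x = X @ beta
    m = np.exp(eta_x - eta_x.max())
    msum = np.bincount(codes, weights=m, minlength=S)
    mu = m * (ysum / msum)[codes]
    w = mu
    Xc = X - _stratum_mean(X, w, codes, S)
    XtWX = (Xc * w[:, None]).T @ Xc
    info_inv = np.linalg.inv(XtWX)
    pearson = float(np.sum((y - mu) ** 2 / mu))
    df_resid = n - k - S
    dispersion = pearson / df_resid if df_resid > 0 else np.nan
    if df_resid <= 0:
        logger.warning("non-positive residual df (%d); dispersion undefined", df_resid)
    vcov = dispersion * info_inv if df_resid > 0 else info_inv
    vcov = 0.5 * (vcov + vcov.T)
    # conditional multinomial log-likelihood, multinomial coefficient dropped
    p = mu / np.bincount(codes, weights=mu, minlength=S)[codes]
    loglik = float(np.sum(y * np.log(p)))

    return FitResult(
        coefficients=beta,
        names=names,
        vcov=vcov,
        dispersion=float(dispersion),
        loglik=loglik,
        n_params=k,
        converged=converged,
        n_strata_used=S,
        n_obs=n,
        deviance=float(dev),
        pearson_chi2=pearson,
        df_resid=df_resid,
        cb_slice=slice(0, n_cb),
        qaic_variant=qaic_variant,
        n_iter=n_iter,
        score_norm=score_norm,
    )


def qaic(fit: FitResult, variant: str = "scaled_deviance") -> float:
    """Quasi-AIC of a fit.

    Default ``scaled_deviance``: QAIC = -2*loglik/phi + 2k.  The alternative
    ``scaled_penalty`` convention, QAIC = -2*loglik + 2*phi*k, is available
    because the literature uses both.  ``k`` counts estimated slope
    parameters; absorbed stratum intercepts are excluded.
    """
    if not np.isfinite(fit.dispersion) or fit.dispersion <= 0:
        raise ValueError(f"dispersion must be positive and finite, got {fit.dispersion}")
    if variant == "scaled_deviance":
        return -2.0 * fit.loglik / fit.dispersion + 2.0 * fit.n_params
    if variant == "scaled_penalty":
        return -2.0 * fit.loglik + 2.0 * fit.dispersion * fit.n_params
    raise ValueError(f"unknown QAIC variant {variant!r}")


def select_exposure_knots(
    candidates: list[tuple[float, ...]],
    exposure: np.ndarray | pd.Series,
    counts: np.ndarray | pd.Series,
    strata: StratumIndex,
    lag_spec: SplineSpec | None,
    max_lag: int,
    covariates: np.ndarray | pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
    qaic_variant: str = "scaled_deviance",
) -> tuple[SplineSpec, pd.DataFrame]:
    """Pick exposure knot percentiles by QAIC over a candidate list.

    Fits the full model once per candidate percentile set and returns the
    minimizer together with the comparison table.  Ties break toward fewer
    knots, then toward earlier position in the list.  A candidate that fails
    to fit is recorded with a NaN QAIC rather than aborting the search.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate percentile set")
    from .basis import build_cross_basis

    x = np.asarray(exposure, dtype=float)
    rows = []
    specs: list[SplineSpec | None] = []
    for pcts in candidates:
        try:
            spec = percentile_knots(x, pcts)
            cb = build_cross_basis(x, spec, lag_spec, max_lag)
            fit = fit_conditional_quasipoisson(
                cb, counts, strata, covariates, covariate_names, qaic_variant=qaic_variant
            )
            rows.append(
                {
                    "percentiles": "/".join(str(p) for p in pcts),
                    "n_knots": len(pcts),
                    "qaic": fit.qaic,
                    "dispersion": fit.dispersion,
                    "converged": fit.converged,
                }
            )
            specs.append(spec)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("candidate %s failed to fit: %s", pcts, exc)
            rows.append(
                {
                    "percentiles": "/".join(str(p) for p in pcts),
                    "n_knots": len(pcts),
                    "qaic": np.nan,
                    "dispersion": np.nan,
                    "converged": False,
                }
            )
            specs.append(None)
    table = pd.DataFrame(rows)
    ok = table["qaic"].notna()
    if not ok.any():
        raise ValueError("no candidate knot set could be fitted")
    order = table[ok].sort_values(["qaic", "n_knots"], kind="stable")
    best = int(order.index[0])
    return specs[best], table  # type: ignore[return-value]
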