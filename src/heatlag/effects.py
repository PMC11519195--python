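"""Relative-risk curves, MaxRT and percentile contrasts from a DLNM fit.

All contrasts are linear in the cross-basis coefficients: the cumulative
log-RR at temperature ``x`` versus the reference is ``(b(x) - b(ref))' beta``
where ``b(x)`` stacks ``sum_l R_i(x) C_j(l)`` in cross-basis column order,
and its variance follows by the delta method, ``c' V c`` with
``c = b(x) - b(ref)``.  Lag-specific contrasts use ``R_i(x) C_j(l)`` for a
single lag.  Confidence intervals are Wald on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

from .basis import CrossBasis, ns_basis
from .model import FitResult

__all__ = ["RRCurve", "MaxRTResult", "RREstimate", "predict_rr", "find_maxrt", "rr_at_percentile"]


class RREstimate(NamedTuple):
    rr: float
    lo: float
    hi: float


@dataclass
class RRCurve:
    """Cumulative and lag-specific relative risks over an exposure grid."""

    grid: np.ndarray  # degC, sorted, contains the reference exactly
    reference: float
    cumulative_rr: np.ndarray
    cumulative_lo: np.ndarray
    cumulative_hi: np.ndarray
    lag_rr: np.ndarray  # (L+1, n_grid)
    lag_lo: np.ndarray
    lag_hi: np.ndarray
    ci_level: float = 0.95
    # contrast machinery kept for exact interpolation of off-grid queries
    _basis_rows: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _ref_row: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _beta: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _vcov: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def z(self) -> float:
        return float(norm.ppf(0.5 + self.ci_level / 2))

    def log_rr_at(self, x: float) -> tuple[float, float]:
        """Cumulative log-RR and its SE at ``x``.

        Between grid points the cumulative-contrast vector is interpolated
        linearly (hence log-RR is piecewise linear in the stored rows).
        """
        g = self.grid
        if x <= g[0]:
            row = self._basis_rows[0]
        elif x >= g[-1]:
            row = self._basis_rows[-1]
        else:
            i = int(np.searchsorted(g, x, side="right")) - 1
            t = (x - g[i]) / (g[i + 1] - g[i]) if g[i + 1] > g[i] else 0.0
            row = (1 - t) * self._basis_rows[i] + t * self._basis_rows[i + 1]
        c = row - self._ref_row
        est = float(c @ self._beta)
        se = float(np.sqrt(max(c @ self._vcov @ c, 0.0)))
        return est, se

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "temperature": self.grid,
                "cumulative_rr": self.cumulative_rr,
                "cumulative_lo": self.cumulative_lo,
                "cumulative_hi": self.cumulative_hi,
            }
        )


@dataclass
class MaxRTResult:
    """Maximum-risk temperature within the 1st-99th exposure percentiles."""

    maxrt: float
    rr_at_maxrt: float
    lo: float
    hi: float
    search_bounds: tuple[float, float]


def _default_grid(exposure_sample: np.ndarray, step: float = 0.1) -> np.ndarray:
    x = np.asarray(exposure_sample, dtype=float)
    lo, hi = x.min(), x.max()
    base = np.arange(lo, hi + step / 2, step)
    pct = np.percentile(x, np.arange(1, 100), method="linear")
    return np.unique(np.round(np.concatenate([base, pct, [hi]]), 10))


def predict_rr(
    fit: FitResult,
    crossbasis: CrossBasis,
    exposure_sample: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    reference: float | None = None,
    ci_level: float = 0.95,
) -> RRCurve:
    """Cumulative and lag-specific RR curves for a fitted cross-basis.

    ``reference`` defaults to the 50th percentile of ``exposure_sample``;
    the default grid spans the observed range at 0.1 degC resolution with
    the exact 1st-99th percentile points appended.
    """
    if grid is None:
        if exposure_sample is None:
            raise ValueError("provide either a grid or an exposure sample")
        grid = _default_grid(np.asarray(exposure_sample, float))
    grid = np.sort(np.asarray(grid, dtype=float))
    if reference is None:
        if exposure_sample is None:
            raise ValueError("provide either a reference or an exposure sample")
        reference = float(np.percentile(np.asarray(exposure_sample, float), 50, method="linear"))
    if not (grid[0] <= reference <= grid[-1]):
        raise ValueError(f"reference {reference} lies outside the grid [{grid[0]}, {grid[-1]}]")
    if reference not in grid:
        grid = np.sort(np.append(grid, reference))

    beta = fit.cb_coefficients()
    V = fit.cb_vcov()
    R = ns_basis(grid, crossbasis.exposure_spec)  # (G, v)
    C = crossbasis.lag_basis_matrix()  # (L+1, w)
    v, w = R.shape[1], C.shape[1]
    if beta.size != v * w:
        raise ValueError(f"fit has {beta.size} cross-basis coefficients, specs imply {v * w}")
    z = float(norm.ppf(0.5 + ci_level / 2))

    csum = C.sum(axis=0)  # (w,)
    rows = (R[:, :, None] * csum[None, None, :]).reshape(len(grid), v * w)  # b(x)
    iref = int(np.flatnonzero(grid == reference)[0])
    ref_row = rows[iref]
    contrasts = rows - ref_row
    est = contrasts @ beta
    var = np.einsum("gi,ij,gj->g", contrasts, V, contrasts)
    se = np.sqrt(np.clip(var, 0.0, None))
    cum_rr = np.exp(est)
    cum_lo = np.exp(est - z * se)
    cum_hi = np.exp(est + z * se)
    # exact null contrast at the reference
    cum_rr[iref] = cum_lo[iref] = cum_hi[iref] = 1.0

    L1 = C.shape[0]
    lag_rr = np.empty((L1, len(grid)))
    lag_lo = np.empty_like(lag_rr)
    lag_hi = np.empty_like(lag_rr)
    for lag in range(L1):
        rows_l = (R[:, :, None] * C[lag][None, None, :]).reshape(len(grid), v * w)
        c_l = rows_l - rows_l[iref]
        e_l = c_l @ beta
        s_l = np.sqrt(np.clip(np.einsum("gi,ij,gj->g", c_l, V, c_l), 0.0, None))
        lag_rr[lag] = np.exp(e_l)
        lag_lo[lag] = np.exp(e_l - z * s_l)
        lag_hi[lag] = np.exp(e_l + z * s_l)

    return RRCurve(
        grid=grid,
        reference=float(reference),
        cumulative_rr=cum_rr,
        cumulative_lo=cum_lo,
        cumulative_hi=cum_hi,
        lag_rr=lag_rr,
        lag_lo=lag_lo,
        lag_hi=lag_hi,
        ci_level=ci_level,
        _basis_rows=rows,
        _ref_row=ref_row,
        _beta=beta,
        _vcov=V,
    )


def find_maxrt(curve: RRCurve, exposure_sample: np.ndarray) -> MaxRTResult:
    """Locate the maximum-risk temperature within the 1st-99th percentiles.

    The argmax of the cumulative RR is taken over grid points inside
    [P1, P99]; ties break toward the lower temperature.  A flat curve
    returns the lower bound with a warning.
    """
    x = np.asarray(exposure_sample, dtype=float)
    p1, p99 = np.percentile(x, [1, 99], method="linear")
    mask = (curve.grid >= p1) & (curve.grid <= p99)
    if not mask.any():
        raise ValueError(f"grid does not cover the percentile window [{p1}, {p99}]")
    g = curve.grid[mask]
    rr = curve.cumulative_rr[mask]
    lo = curve.cumulative_lo[mask]
    hi = curve.cumulative_hi[mask]
    if rr.max() - rr.min() < 1e-12:
        warnings.warn("cumulative RR curve is flat over the search window; returning the lower bound")
        i = 0
    else:
        i = int(np.argmax(rr))  # first max = lowest temperature on a sorted grid
    return MaxRTResult(
        maxrt=float(g[i]),
        rr_at_maxrt=float(rr[i]),
        lo=float(lo[i]),
        hi=float(hi[i]),
        search_bounds=(float(p1), float(p99)),
    )


def rr_at_percentile(curve: RRCurve, exposure_sample: np.ndarray, p: float) -> RREstimate:
    """Cumulative RR (with CI) at the empirical p-th exposure percentile."""
    if not 0 < p < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {p}")
    xp = float(np.percentile(np.asarray(exposure_sample, float), p, method="linear"))
    est, se = curve.log_rr_at(xp)
    z = curve.z
    return RREstimate(rr=float(np.exp(est)), lo=float(np.exp(est - z * se)), hi=float(np.exp(est + z * se)))
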