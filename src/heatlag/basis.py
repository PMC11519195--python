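"""Natural cubic spline bases and the DLNM cross-basis.

The distributed lag nonlinear model represents the exposure-response and the
lag-response shapes with two spline bases, combined as a tensor product: the
"cross-basis" design matrix whose entry for day ``t`` and column ``(i, j)``
is ``sum_l R_i(x_{t-l}) * C_j(l)`` for exposure basis ``R`` and lag basis
``C``.

The natural cubic spline basis used here is the *cardinal* basis over the
knot sequence (boundary + interior knots): basis function ``j`` is the
natural cubic interpolating spline through the unit vector ``e_j`` on the
knots.  Natural splines are linear beyond the boundary knots; evaluation
outside the boundaries therefore continues along the tangent line at the
boundary.  The span of the basis is exactly the space of natural cubic
splines on those knots, which contains all linear functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SplineSpec",
    "CrossBasis",
    "ns_basis",
    "percentile_knots",
    "log_lag_knots",
    "build_cross_basis",
]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of one natural cubic spline basis.

    Parameters
    ----------
    interior_knots : tuple of float
        Strictly increasing knots strictly inside the boundary interval.
    boundary_knots : (low, high)
        Interval on which the spline is cubic; linear beyond it.
    intercept : bool
        If True the basis spans constants (dimension ``n_interior + 2``),
        otherwise the constant direction is dropped
        (dimension ``n_interior + 1``).
    """

    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    intercept: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError(f"boundary_knots must satisfy low < high, got ({lo}, {hi})")
        kn = np.asarray(self.interior_knots, dtype=float)
        if kn.size and (np.any(np.diff(kn) <= 0)):
            raise ValueError(f"interior_knots must be strictly increasing, got {self.interior_knots}")
        if kn.size and (kn[0] <= lo or kn[-1] >= hi):
            raise ValueError(
                f"interior_knots {self.interior_knots} must lie strictly inside boundary ({lo}, {hi})"
            )

    @property
    def all_knots(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        return np.concatenate([[lo], np.asarray(self.interior_knots, float), [hi]])

    @property
    def df(self) -> int:
        """Basis dimension."""
        return len(self.interior_knots) + 1 + (1 if self.intercept else 0)

    def to_dict(self) -> dict:
        return {
            "interior_knots": list(self.interior_knots),
            "boundary_knots": list(self.boundary_knots),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            interior_knots=tuple(d["interior_knots"]),
            boundary_knots=tuple(d["boundary_knots"]),
            intercept=bool(d["intercept"]),
        )


def ns_basis(x: Sequence[float] | np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Returns an ``(len(x), spec.df)`` matrix.  Second derivatives vanish at
    (and beyond) the boundary knots; values outside the boundaries lie on the
    tangent line from the nearest boundary.  Without an intercept the first
    cardinal column is dropped: together with an external model intercept the
    remaining columns span the same natural-spline space.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    kn = spec.all_knots
    K = kn.size
    lo, hi = spec.boundary_knots

    if K == 2:
        # no interior knots: the natural-spline space is the linear functions
        B = np.column_stack([(hi - x) / (hi - lo), (x - lo) / (hi - lo)])
    else:
        B = np.empty((x.size, K))
        below = x < lo
        above = x > hi
        inside = ~(below | above)
        for j in range(K):
            e = np.zeros(K)
            e[j] = 1.0
            cs = CubicSpline(kn, e, bc_type="natural")
            col = np.empty_like(x)
            col[inside] = cs(x[inside])
            if below.any():
                col[below] = cs(lo) + cs(lo, 1) * (x[below] - lo)
            if above.any():
                col[above] = cs(hi) + cs(hi, 1) * (x[above] - hi)
            B[:, j] = col

    if not spec.intercept:
        B = B[:, 1:]
    return B


def percentile_knots(x: Sequence[float] | np.ndarray, percentiles: Sequence[float]) -> SplineSpec:
    """Interior knots at empirical percentiles of an exposure series.

    Quantiles use linear interpolation between order statistics; boundary
    knots sit at the observed minimum and maximum.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    p = np.asarray(percentiles, dtype=float)
    if p.size == 0:
        raise ValueError("percentiles must be non-empty")
    if np.any((p <= 0) | (p >= 100)):
        raise ValueError(f"percentiles must lie in (0, 100), got {list(p)}")
    if np.any(np.diff(p) <= 0):
        raise ValueError(f"percentiles must be strictly increasing, got {list(p)}")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("exposure series is constant; percentile knots are degenerate")
    kn = np.percentile(x, p, method="linear")
    vals = np.concatenate([[lo], kn, [hi]])
    if np.any(np.diff(vals) <= 0):
        raise ValueError(f"duplicate knot values after quantile computation: {list(np.round(vals, 6))}")
    return SplineSpec(interior_knots=tuple(float(v) for v in kn), boundary_knots=(lo, hi), intercept=False)


def log_lag_knots(max_lag: int, n_knots: int = 1) -> SplineSpec:
    """Lag-dimension spline with knots evenly spaced on the log-lag scale.

    ``n_knots`` interior knots at ``max_lag ** (i / (n_knots + 1))`` for
    ``i = 1..n_knots``; boundary knots at 0 and ``max_lag``.  The lag basis
    carries an intercept (the standard DLNM identifiability convention: the
    exposure basis does not).  For ``max_lag == 1`` every log-spaced knot
    collides with the upper boundary, so the basis degrades to the linear
    (intercept + slope) space with no interior knot.
    """
    if max_lag < 1:
        raise ValueError(f"max_lag must be >= 1, got {max_lag}")
    if n_knots < 1:
        raise ValueError(f"n_knots must be >= 1, got {n_knots}")
    if max_lag == 1:
        return SplineSpec(interior_knots=(), boundary_knots=(0.0, 1.0), intercept=True)
    i = np.arange(1, n_knots + 1)
    kn = np.power(float(max_lag), i / (n_knots + 1))
    if np.unique(np.round(kn, 12)).size < kn.size or kn[0] <= 0 or kn[-1] >= max_lag:
        raise ValueError(
            f"{n_knots} log-spaced knots collide within lag window (0, {max_lag}): {list(kn)}"
        )
    return SplineSpec(
        interior_knots=tuple(float(v) for v in kn),
        boundary_knots=(0.0, float(max_lag)),
        intercept=True,
    )


@dataclass
class CrossBasis:
    """DLNM cross-basis matrix plus the metadata needed to reconstruct it.

    ``matrix`` has one row per day and ``v * w`` columns where ``v`` is the
    exposure-basis dimension and ``w`` the lag-basis dimension; column
    ``i * w + j`` pairs exposure-basis function ``i`` with lag-basis function
    ``j``.  Rows without a full lag history (the first ``max_lag`` days) are
    NaN and flagged False in ``complete``.
    """

    matrix: np.ndarray
    exposure_spec: SplineSpec
    lag_spec: SplineSpec | None
    max_lag: int
    exposure_name: str = "tmean"
    complete: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_exposure_basis(self) -> int:
        return self.exposure_spec.df

    @property
    def n_lag_basis(self) -> int:
        return 1 if self.lag_spec is None else self.lag_spec.df

    @property
    def column_names(self) -> list[str]:
        return [f"cb_{i}_{j}" for i in range(self.n_exposure_basis) for j in range(self.n_lag_basis)]

    def lag_basis_matrix(self) -> np.ndarray:
        """Lag basis evaluated at integer lags ``0..max_lag``: shape (L+1, w)."""
        lags = np.arange(self.max_lag + 1, dtype=float)
        if self.lag_spec is None:
            return np.ones((self.max_lag + 1, 1))
        return ns_basis(lags, self.lag_spec)

    def to_csv(self, path: str | Path, dates=None) -> None:
        """Write the matrix as CSV with a JSON sidecar recording the specs."""
        import pandas as pd

        path = Path(path)
        df = pd.DataFrame(self.matrix, columns=self.column_names)
        if dates is not None:
            df.insert(0, "date", dates)
        df.to_csv(path, index=False)
        meta = {
            "exposure_spec": self.exposure_spec.to_dict(),
            "lag_spec": None if self.lag_spec is None else self.lag_spec.to_dict(),
            "max_lag": self.max_lag,
            "exposure_name": self.exposure_name,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def build_cross_basis(
    exposure: Sequence[float] | np.ndarray,
    exposure_spec: SplineSpec,
    lag_spec: SplineSpec | None,
    max_lag: int,
    exposure_name: str = "tmean",
) -> CrossBasis:
    """Tensor-contract exposure history with the lag basis.

    Row ``t``, column ``(i, j)`` is ``sum_{l=0..L} R_i(x_{t-l}) * C_j(l)``.
    ``lag_spec=None`` means an intercept-only lag basis (required when
    ``max_lag == 0``, allowed for any L as a constant-weight lag shape).
    """
    x = np.asarray(exposure, dtype=float)
    n = x.size
    if max_lag < 0:
        raise ValueError(f"max_lag must be >= 0, got {max_lag}")
    if max_lag >= n:
        raise ValueError(f"max_lag={max_lag} >= series length {n}")
    if np.isnan(x).any():
        raise ValueError("exposure series contains missing values inside the window")
    if lag_spec is not None and lag_spec.boundary_knots != (0.0, float(max_lag)):
        raise ValueError(
            f"lag_spec boundary {lag_spec.boundary_knots} does not match lag window (0, {max_lag})"
        )

    R = ns_basis(x, exposure_spec)  # (n, v)
    if lag_spec is None:
        C = np.ones((max_lag + 1, 1))
    else:
        C = ns_basis(np.arange(max_lag + 1, dtype=float), lag_spec)  # (L+1, w)
    v, w = R.shape[1], C.shape[1]

    M = np.zeros((n, v * w))
    for lag in range(max_lag + 1):
        Rs = np.zeros_like(R)
        Rs[lag:] = R[: n - lag]
        M += (Rs[:, :, None] * C[lag][None, None, :]).reshape(n, v * w)
    complete = np.arange(n) >= max_lag
    M[~complete] = np.nan
    return CrossBasis(
        matrix=M,
        exposure_spec=exposure_spec,
        lag_spec=lag_spec,
        max_lag=max_lag,
        exposure_name=exposure_name,
        complete=complete,
    )
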