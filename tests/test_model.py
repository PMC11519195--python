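"""Conditional quasi-Poisson fitting, dispersion, QAIC and knot selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import heatlag as hl
from heatlag.basis import CrossBasis, SplineSpec
from heatlag.strata import StratumIndex

from conftest import calibration_surface, run_single


def identity_crossbasis(X: np.ndarray) -> CrossBasis:
    """Wrap a plain design matrix as a lag-free cross-basis (test plumbing)."""
    X = np.asarray(X, float)
    return CrossBasis(
        matrix=X.copy(),
        exposure_spec=SplineSpec((), (0.0, 1.0), intercept=True),
        lag_spec=None,
        max_lag=0,
        complete=np.ones(X.shape[0], dtype=bool),
    )


def flat_strata(n_strata: int, size: int) -> StratumIndex:
    dates = pd.date_range("2015-01-01", periods=n_strata * size)
    return StratumIndex(
        dates=pd.DatetimeIndex(dates),
        codes=np.repeat(np.arange(n_strata), size),
        labels=[(0, 0, i) for i in range(n_strata)],
    )


def matched_binary_data(seed: int = 5, n_strata: int = 120):
    """1 case + 3 control days per stratum with a known binary outcome law."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(4 * n_strata, 2))
    beta = np.array([0.5, -0.3])
    y = np.zeros(4 * n_strata)
    for s in range(n_strata):
        idx = np.arange(4 * s, 4 * s + 4)
        p = np.exp(X[idx] @ beta)
        y[rng.choice(idx, p=p / p.sum())] = 1.0
    return X, y, flat_strata(n_strata, 4)


class TestConditionalFit:
    def test_matches_conditional_logistic_oracle(self):
        """On 1:3 matched binary case-crossover data the conditional Poisson
        MLE coincides with conditional logistic regression."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        X, y, strata = matched_binary_data()
        fit = hl.fit_conditional_quasipoisson(identity_crossbasis(X), y, strata)
        oracle = ConditionalLogit(y, X, groups=strata.codes).fit(method="newton", tol=1e-12, disp=0)
        rel = np.abs(fit.coefficients - oracle.params) / np.abs(oracle.params)
        assert rel.max() < 1e-6

    def test_matches_dense_dummy_glm(self, weather6y):
        """Absorbed-strata fitting equals the fixed-effects Poisson GLM with
        one dummy per stratum, in both coefficients and scaled covariance."""
        import statsmodels.api as sm

        w = weather6y.iloc[:731].reset_index(drop=True)
        x = w["tmean"].to_numpy()
        surf = calibration_surface(x, 0.03)
        fit, cb, _, _ = run_single(w, surf, seed=3, knot_percentiles=(25, 50, 75))

        counts = hl.simulate_counts(w, surf, 3)
        y = np.zeros(len(w))
        y[2:] = counts.to_numpy()
        dew_X, _ = hl.humidity_covariates(w["dewpoint"].to_numpy())
        cov = np.column_stack([dew_X, w["holiday"].to_numpy(float)])
        mask = cb.complete
        Xf = np.column_stack([cb.matrix[mask], cov[mask]])
        codes = hl.build_strata(pd.DatetimeIndex(w["date"])).codes[mask]
        informative = np.bincount(codes, weights=y[mask]) > 0
        obs = informative[codes]
        D = pd.get_dummies(codes[obs]).to_numpy(float)
        glm = sm.GLM(y[mask][obs], np.column_stack([Xf[obs], D]), family=sm.families.Poisson()).fit(
            scale="X2"
        )
        k = Xf.shape[1]
        assert np.abs(glm.params[:k] - fit.coefficients).max() < 1e-8
        assert np.abs(glm.cov_params()[:k, :k] - fit.vcov).max() < 1e-8
        assert glm.scale == pytest.approx(fit.dispersion, rel=1e-8)

    def test_stratum_baseline_rescaling_leaves_beta_unchanged(self):
        """Adding an arbitrary per-stratum log-rate offset (rescaling each
        stratum's baseline) does not move the conditional estimate."""
        import statsmodels.api as sm

        X, y, strata = matched_binary_data(seed=9, n_strata=60)
        fit = hl.fit_conditional_quasipoisson(identity_crossbasis(X), y, strata)
        rng = np.random.default_rng(0)
        offsets = rng.normal(0, 2.0, strata.n_strata)[strata.codes]
        D = pd.get_dummies(strata.codes).to_numpy(float)
        glm = sm.GLM(y, np.column_stack([X, D]), family=sm.families.Poisson(), offset=offsets).fit()
        assert np.abs(glm.params[:2] - fit.coefficients).max() < 1e-6

    def test_dispersion_recovered_under_poisson(self, weather6y):
        """Data generated with phi = 1 yield a Pearson dispersion near 1."""
        w = weather6y.iloc[:2002].reset_index(drop=True)
        x = w["tmean"].to_numpy()
        surf = calibration_surface(x, 0.0)
        surf = hl.RiskSurface(
            exposure_fn=surf.exposure_fn, reference=surf.reference,
            season_amplitude=0.0, overdispersion=1.0,
        )
        fit, *_ = run_single(w, surf, seed=21)
        assert 0.8 < fit.dispersion < 1.2

    def test_score_norm_small_at_optimum(self, weather6y):
        w = weather6y.iloc[:1500].reset_index(drop=True)
        surf = calibration_surface(w["tmean"].to_numpy(), 0.02)
        fit, *_ = run_single(w, surf, seed=4)
        assert fit.converged
        assert fit.score_norm < 1e-6

    def test_vcov_is_dispersion_times_information_inverse(self):
        """Symmetry/PSD, and the covariance divided by phi-hat equals the
        unscaled (phi = 1) information inverse from the dense-dummy GLM."""
        import statsmodels.api as sm

        X, y, strata = matched_binary_data(seed=2, n_strata=80)
        fit = hl.fit_conditional_quasipoisson(identity_crossbasis(X), y, strata)
        assert np.allclose(fit.vcov, fit.vcov.T)
        assert np.all(np.linalg.eigvalsh(fit.vcov) > -1e-12)
        D = pd.get_dummies(strata.codes).to_numpy(float)
        glm = sm.GLM(y, np.column_stack([X, D]), family=sm.families.Poisson()).fit(scale=1.0)
        assert np.abs(glm.cov_params()[:2, :2] - fit.vcov / fit.dispersion).max() < 1e-8

    def test_uninformative_strata_do_not_affect_fit(self, weather6y):
        """Appending a stretch of all-zero days (new strata, no events)
        leaves coefficients identical."""
        w = weather6y.iloc[:400].reset_index(drop=True)
        x = w["tmean"].to_numpy()
        surf = calibration_surface(x, 0.05)
        counts = hl.simulate_counts(w, surf, 13)
        y = np.zeros(len(w))
        y[2:] = counts.to_numpy()
        y[200:] = 0.0  # silence later strata entirely
        espec = hl.percentile_knots(x, (50,))
        cb = hl.build_cross_basis(x, espec, hl.log_lag_knots(2, 1), 2)
        strata = hl.build_strata(pd.DatetimeIndex(w["date"]))
        fit_full = hl.fit_conditional_quasipoisson(cb, y, strata)

        w2 = w.iloc[:231].reset_index(drop=True)  # keep only months covering the events
        x2 = w2["tmean"].to_numpy()
        cb2 = hl.build_cross_basis(x2, espec, hl.log_lag_knots(2, 1), 2)
        fit_trim = hl.fit_conditional_quasipoisson(
            cb2, y[:231], hl.build_strata(pd.DatetimeIndex(w2["date"]))
        )
        assert np.abs(fit_full.coefficients - fit_trim.coefficients).max() < 1e-8

    def test_collinear_columns_named(self):
        X, y, strata = matched_binary_data(seed=3, n_strata=40)
        X = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.raises(ValueError, match="collinear"):
            hl.fit_conditional_quasipoisson(identity_crossbasis(X), y, strata)

    def test_all_zero_counts_rejected(self):
        X, y, strata = matched_binary_data(seed=3, n_strata=20)
        with pytest.raises(ValueError, match="informative"):
            hl.fit_conditional_quasipoisson(identity_crossbasis(X), np.zeros_like(y), strata)


# small fixed dataset for the hand-checked QAIC computation
_TINY_X = np.array([0.2, -1.1, 0.8, 1.5, -0.4, 0.9, -1.3, 0.1])
_TINY_Y = np.array([3.0, 1.0, 2.0, 5.0, 1.0, 4.0, 0.0, 2.0])


class TestQaic:
    def _tiny_fit(self):
        return hl.fit_conditional_quasipoisson(
            identity_crossbasis(_TINY_X[:, None]), _TINY_Y, flat_strata(2, 4)
        )

    def test_tiny_dataset_matches_hand_computation(self):
        """Independent recomputation: maximize the conditional log-likelihood
        directly, profile the stratum intercepts, form Pearson chi-square and
        the QAIC formula by hand."""
        fit = self._tiny_fit()
        codes = np.repeat([0, 1], 4)
        ysum = np.array([_TINY_Y[:4].sum(), _TINY_Y[4:].sum()])

        def nll(b):
            eta = _TINY_X * b
            ll = 0.0
            for s in (0, 1):
                m = codes == s
                ll += eta[m] @ _TINY_Y[m] - ysum[s] * np.log(np.exp(eta[m]).sum())
            return -ll

        opt = minimize_scalar(nll, bounds=(-5, 5), method="bounded", options={"xatol": 1e-12})
        beta = opt.x
        assert fit.coefficients[0] == pytest.approx(beta, abs=1e-7)
        eta = _TINY_X * beta
        mu = np.concatenate(
            [
                ysum[0] * np.exp(eta[:4]) / np.exp(eta[:4]).sum(),
                ysum[1] * np.exp(eta[4:]) / np.exp(eta[4:]).sum(),
            ]
        )
        loglik = float(np.sum(_TINY_Y * np.log(mu / np.repeat(ysum, 4))))
        pearson = float(np.sum((_TINY_Y - mu) ** 2 / mu))
        phi = pearson / (8 - 1 - 2)
        assert fit.loglik == pytest.approx(loglik, abs=1e-8)
        assert fit.dispersion == pytest.approx(phi, abs=1e-8)
        assert fit.qaic == pytest.approx(-2 * loglik / phi + 2 * 1, abs=1e-6)

    def test_poisson_limit_equals_aic(self):
        fit = self._tiny_fit()
        fit.dispersion = 1.0
        assert hl.qaic(fit) == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)

    def test_doubling_dispersion_halves_deviance_term(self):
        fit = self._tiny_fit()
        q1 = hl.qaic(fit)
        fit2 = self._tiny_fit()
        fit2.dispersion = 2 * fit.dispersion
        q2 = hl.qaic(fit2)
        assert q2 - 2 * fit.n_params == pytest.approx((q1 - 2 * fit.n_params) / 2)

    def test_alternative_variant(self):
        fit = self._tiny_fit()
        assert hl.qaic(fit, "scaled_penalty") == pytest.approx(
            -2 * fit.loglik + 2 * fit.dispersion * fit.n_params
        )
        with pytest.raises(ValueError, match="variant"):
            hl.qaic(fit, "nonsense")

    def test_zero_dispersion_rejected(self):
        fit = self._tiny_fit()
        fit.dispersion = 0.0
        with pytest.raises(ValueError, match="dispersion"):
            hl.qaic(fit)


class TestKnotSelection:
    @staticmethod
    def _setup(seed, bend=True, n_days=731):
        w = hl.simulate_weather(hl.WeatherParams(seed=seed)).iloc[:n_days].reset_index(drop=True)
        x = w["tmean"].to_numpy()
        ref = float(np.percentile(x, 50))
        if bend:
            fn = lambda t: 0.08 * np.clip(np.asarray(t, float) - ref, 0, None)  # noqa: E731
        else:
            fn = hl.null_exposure(ref)
        surf = hl.RiskSurface(exposure_fn=fn, reference=ref, season_amplitude=0.0)
        y = np.zeros(len(w))
        y[2:] = hl.simulate_counts(w, surf, seed + 50).to_numpy()
        return x, y, hl.build_strata(pd.DatetimeIndex(w["date"]))

    def test_single_bend_prefers_one_knot_in_median(self):
        """A single-bend exposure response should not reward three knots:
        the 1-knot candidate wins the QAIC comparison in the median."""
        lspec = hl.log_lag_knots(2, 1)
        wins = []
        for r in range(20):
            x, y, strata = self._setup(400 + r)
            table = hl.select_exposure_knots([(50,), (25, 50, 75)], x, y, strata, lspec, 2)[1]
            wins.append(table.loc[0, "qaic"] - table.loc[1, "qaic"])
        assert np.median(wins) < 0

    def test_duplicate_candidates_first_wins(self):
        x, y, strata = self._setup(7, n_days=400)
        lspec = hl.log_lag_knots(2, 1)
        spec, table = hl.select_exposure_knots([(50,), (50,)], x, y, strata, lspec, 2)
        assert table.loc[0, "qaic"] == table.loc[1, "qaic"]
        assert spec == hl.percentile_knots(x, (50,))

    def test_single_candidate_returned(self):
        x, y, strata = self._setup(8, n_days=400)
        spec, table = hl.select_exposure_knots([(50,)], x, y, strata, hl.log_lag_knots(2, 1), 2)
        assert len(table) == 1 and np.isfinite(table.loc[0, "qaic"])
        assert spec.interior_knots == hl.percentile_knots(x, (50,)).interior_knots

    def test_failing_candidate_recorded_not_fatal(self):
        x, y, strata = self._setup(9, n_days=400)
        # an absurd percentile pair that collides -> recorded as NaN
        xx = x.copy()
        table = hl.select_exposure_knots(
            [(50,), (50.0, 50.000001)], xx, y, strata, hl.log_lag_knots(2, 1), 2
        )[1]
        assert np.isfinite(table.loc[0, "qaic"])
        assert not table.loc[1, "converged"]
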