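"""Log10-log10 allometric regression with bootstrap uncertainty.

The allometric model is a power law ``y = 10**a * x**b``, which is linear on
log10-log10 axes:

    log10(y) = a + b * log10(x)

:class:`LogLogRegression` fits ``a`` (intercept) and ``b`` (slope) by ordinary
least squares on the log10-transformed data, the standard choice when the goal
is to *predict* ``y`` from ``x`` rather than to describe a symmetric
structural relationship. Coefficient uncertainty is quantified by a
nonparametric case-resampling bootstrap: data pairs are resampled with
replacement, the OLS fit is repeated per replicate, the standard error is the
standard deviation of the replicate coefficients and the confidence interval
is the percentile interval. This makes no distributional assumption and is
well suited to the small calibration panels typical of comparative
morphometrics.

Prediction limits for a *new individual* at predictor value ``x0`` use the
classical t-based OLS prediction interval on the log10 scale,

    a + b*log10(x0)  +/-  t(level, n-2) * s * sqrt(1 + 1/n + (log10(x0) - mx)^2 / Sxx)

(``s`` the residual standard deviation with ``n-2`` denominator, ``mx`` the
mean and ``Sxx`` the centred sum of squares of the log10 predictor), then
back-transformed with ``10**``. Back-transformation makes every interval
multiplicatively (log-) symmetric about its point estimate:
``upper/point == point/lower``.

The estimator follows scikit-learn conventions (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and composes with
sklearn pipelines; a model may also be constructed directly from published
coefficients, in which case it predicts but cannot produce analytic intervals
(it lacks fit diagnostics) and says so explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "LogLogRegression",
    "BootstrapConfig",
    "PredictionResult",
    "fit_loglog",
    "bootstrap_fit",
    "predict_point",
    "prediction_interval",
    "pearson_r",
]

#: Default bootstrap replication count.
DEFAULT_N_REPS = 1000
#: Default coverage of confidence and prediction intervals.
DEFAULT_CI_LEVEL = 0.95
#: Default seed, recorded in all outputs.
DEFAULT_SEED = 20150217

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for the case-resampling bootstrap.

    Attributes
    ----------
    n_reps:
        Number of bootstrap replicates.
    seed:
        Integer seed making every replicate sequence reproducible.
    ci_level:
        Two-sided coverage of the percentile confidence intervals.
    """

    n_reps: int = DEFAULT_N_REPS
    seed: int = DEFAULT_SEED
    ci_level: float = DEFAULT_CI_LEVEL

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class PredictionResult:
    """A natural-scale point prediction with multiplicative 95% limits.

    Invariants: ``0 < lower <= point <= upper`` and
    ``upper/point == point/lower`` (log-symmetry). ``log10_halfwidth`` is the
    half-width of the interval on the log10 scale.
    """

    x0: float
    point: float
    lower: float
    upper: float
    log10_halfwidth: float

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.point <= self.upper):
            raise ValueError(
                f"invalid prediction interval: ({self.lower}, {self.point}, "
                f"{self.upper})"
            )


def _validate_pairs(pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must have shape (n, 2)")
    if arr.shape[0] < 3:
        raise ValueError(f"need at least 3 pairs, got {arr.shape[0]}")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("all values must be strictly positive and finite")
    return arr[:, 0], arr[:, 1]


def _ols_log10(lx: np.ndarray, ly: np.ndarray) -> tuple[float, float]:
    """Closed-form normal-equations OLS of ly on lx."""
    mx = lx.mean()
    my = ly.mean()
    sxx = float(np.sum((lx - mx) ** 2))
    if sxx <= 0:
        raise ValueError("constant predictor: zero centred sum of squares")
    sxy = float(np.sum((lx - mx) * (ly - my)))
    b = sxy / sxx
    a = my - b * mx
    return a, b


class LogLogRegression(RegressorMixin, BaseEstimator):
    """Power-law regression fitted by OLS on log10-transformed data.

    Parameters
    ----------
    n_boot:
        Bootstrap replication count used during :meth:`fit`; ``0`` disables
        the bootstrap (standard errors and confidence intervals stay unset).
    ci_level:
        Coverage of bootstrap percentile confidence intervals.
    random_state:
        Seed for the bootstrap resampling.
    x_role, y_role:
        Measurement-role labels of the predictor and response (documentation
        and chain-linkage metadata; not used numerically).

    Attributes
    ----------
    intercept_ : float
        ``a``, the additive constant on the log10 scale.
    slope_ : float
        ``b``, the allometric exponent.
    n_ : int
        Calibration sample size.
    r_ : float
        Pearson correlation of the log10 pairs.
    residual_sd_ : float
        Standard deviation of log10 residuals (``n - 2`` denominator).
    mean_log_x_, ss_log_x_ : float
        Mean and centred sum of squares of the log10 predictor.
    intercept_ci_, slope_ci_ : tuple[float, float]
        Bootstrap percentile confidence intervals (when ``n_boot > 0``).
    intercept_se_, slope_se_ : float
        Bootstrap standard errors (when ``n_boot > 0``).
    boot_intercepts_, boot_slopes_ : ndarray
        The replicate coefficients, kept for audit and Monte-Carlo use.
    """

    def __init__(
        self,
        n_boot: int = DEFAULT_N_REPS,
        ci_level: float = DEFAULT_CI_LEVEL,
        random_state: int | None = DEFAULT_SEED,
        x_role: str = "x",
        y_role: str = "y",
    ) -> None:
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.random_state = random_state
        self.x_role = x_role
        self.y_role = y_role

    # ------------------------------------------------------------------ fit

    def fit(self, X, y) -> "LogLogRegression":
        """Fit the power law to positive data.

        ``X`` is a 1-d array or an ``(n, 1)`` column of positive predictor
        values on the natural scale; ``y`` the positive responses.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be 1-d or a single column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        x, yv = _validate_pairs(np.column_stack([X, y]))
        lx = np.log10(x)
        ly = np.log10(yv)

        a, b = _ols_log10(lx, ly)
        n = lx.size
        resid = ly - (a + b * lx)
        self.intercept_ = a
        self.slope_ = b
        self.n_ = int(n)
        self.mean_log_x_ = float(lx.mean())
        self.ss_log_x_ = float(np.sum((lx - lx.mean()) ** 2))
        self.residual_sd_ = float(np.sqrt(np.sum(resid**2) / (n - 2)))
        if np.ptp(ly) == 0:
            self.r_ = 0.0  # flat response: correlation undefined, slope 0
        else:
            self.r_ = float(np.corrcoef(lx, ly)[0, 1])
        self._log_x = lx
        self._log_y = ly
        self.intercept_ci_ = None
        self.slope_ci_ = None
        self.intercept_se_ = None
        self.slope_se_ = None
        self.boot_intercepts_ = None
        self.boot_slopes_ = None
        if self.n_boot:
            self._run_bootstrap()
        return self

    def _run_bootstrap(self) -> None:
        lx, ly = self._log_x, self._log_y
        n = self.n_
        rng = np.random.default_rng(self.random_state)
        idx = rng.integers(0, n, size=(self.n_boot, n))
        for _ in range(_MAX_REDRAWS):
            bx = lx[idx]
            sxx = ((bx - bx.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            bad = sxx <= 0
            if not bad.any():
                break
            # a resample drew a constant predictor: redraw those replicates
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
        else:
            raise ValueError(
                "bootstrap failed: constant-predictor resamples persisted "
                f"after {_MAX_REDRAWS} redraws"
            )
        by = ly[idx]
        mx = bx.mean(axis=1, keepdims=True)
        my = by.mean(axis=1, keepdims=True)
        sxy = ((bx - mx) * (by - my)).sum(axis=1)
        slopes = sxy / sxx
        intercepts = my[:, 0] - slopes * mx[:, 0]
        alpha = 1.0 - self.ci_level
        qs = [alpha / 2, 1 - alpha / 2]
        self.boot_intercepts_ = intercepts
        self.boot_slopes_ = slopes
        self.intercept_ci_ = tuple(np.quantile(intercepts, qs))
        self.slope_ci_ = tuple(np.quantile(slopes, qs))
        ddof = 1 if self.n_boot > 1 else 0
        self.intercept_se_ = float(np.std(intercepts, ddof=ddof))
        self.slope_se_ = float(np.std(slopes, ddof=ddof))

    # ------------------------------------------------------- published mode

    @classmethod
    def from_coefficients(
        cls,
        intercept: float,
        slope: float,
        *,
        intercept_ci: tuple[float, float] | None = None,
        slope_ci: tuple[float, float] | None = None,
        intercept_se: float | None = None,
        slope_se: float | None = None,
        r: float | None = None,
        x_role: str = "x",
        y_role: str = "y",
    ) -> "LogLogRegression":
        """Build a model from published coefficients.

        The model predicts, but carries no fit diagnostics: analytic
        prediction intervals are unavailable and requesting one raises.
        Published intervals/SEs, if supplied, are attached as metadata.
        """
        model = cls(n_boot=0, x_role=x_role, y_role=y_role)
        model.intercept_ = float(intercept)
        model.slope_ = float(slope)
        model.n_ = None
        model.r_ = r
        model.residual_sd_ = None
        model.mean_log_x_ = None
        model.ss_log_x_ = None
        model.intercept_ci_ = intercept_ci
        model.slope_ci_ = slope_ci
        model.intercept_se_ = intercept_se
        model.slope_se_ = slope_se
        model.boot_intercepts_ = None
        model.boot_slopes_ = None
        return model

    # ------------------------------------------------------------- predict

    @property
    def has_diagnostics(self) -> bool:
        """Whether the model was fitted to data (enables prediction limits)."""
        return getattr(self, "residual_sd_", None) is not None

    def predict(self, X) -> np.ndarray:
        """Natural-scale prediction ``10**(a + b*log10(x))`` for each x."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 0
        if X.ndim == 2:
            X = X[:, 0]
        X = np.atleast_1d(X)
        if np.any(X <= 0) or not np.all(np.isfinite(X)):
            raise ValueError("predictor values must be strictly positive")
        out = 10.0 ** (self.intercept_ + self.slope_ * np.log10(X))
        return float(out[0]) if squeeze else out

    def predict_point(self, x0: float) -> float:
        """Scalar convenience wrapper around :meth:`predict`."""
        return float(self.predict(np.asarray(x0)))

    def prediction_interval(
        self,
        x0: float,
        level: float = DEFAULT_CI_LEVEL,
        method: str = "analytic",
        random_state: int | None = None,
    ) -> PredictionResult:
        """95% (by default) limits for a new observation at ``x0``.

        ``method="analytic"`` uses the t-based OLS prediction interval on the
        log10 scale. ``method="bootstrap"`` resamples a fitted line from the
        bootstrap replicates and adds a resampled log10 residual, taking a
        symmetric quantile of the absolute log10 deviation so that the
        log-symmetry contract holds for both methods.
        """
        self._check_fitted()
        if not self.has_diagnostics:
            raise ValueError(
                "model was built from published coefficients and carries no "
                "fit diagnostics; prediction limits are unavailable"
            )
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        x0 = float(x0)
        if x0 <= 0:
            raise ValueError("x0 must be strictly positive")
        lx0 = np.log10(x0)
        log_point = self.intercept_ + self.slope_ * lx0
        if method == "analytic":
            tcrit = stats.t.ppf(1 - (1 - level) / 2, self.n_ - 2)
            half = (
                tcrit
                * self.residual_sd_
                * np.sqrt(
                    1.0
                    + 1.0 / self.n_
                    + (lx0 - self.mean_log_x_) ** 2 / self.ss_log_x_
                )
            )
        elif method == "bootstrap":
            if self.boot_slopes_ is None:
                raise ValueError(
                    "bootstrap prediction interval requires a bootstrapped "
                    "fit (n_boot > 0)"
                )
            rng = np.random.default_rng(
                self.random_state if random_state is None else random_state
            )
            resid = self._log_y - (self.intercept_ + self.slope_ * self._log_x)
            draws = (
                self.boot_intercepts_
                + self.boot_slopes_ * lx0
                + rng.choice(resid, size=self.boot_slopes_.size, replace=True)
            )
            half = float(np.quantile(np.abs(draws - log_point), level))
        else:
            raise ValueError(f"unknown prediction-interval method {method!r}")
        half = float(half)
        return PredictionResult(
            x0=x0,
            point=10.0**log_point,
            lower=10.0 ** (log_point - half),
            upper=10.0 ** (log_point + half),
            log10_halfwidth=half,
        )

    # ----------------------------------------------------------- utilities

    def _check_fitted(self) -> None:
        if getattr(self, "intercept_", None) is None:
            raise ValueError("model is not fitted")

    def to_dict(self) -> dict:
        """Flat serializable record of coefficients, diagnostics and config."""
        self._check_fitted()
        return {
            "x_role": self.x_role,
            "y_role": self.y_role,
            "intercept": self.intercept_,
            "slope": self.slope_,
            "n": self.n_,
            "r": self.r_,
            "residual_sd": self.residual_sd_,
            "mean_log_x": self.mean_log_x_,
            "ss_log_x": self.ss_log_x_,
            "intercept_ci": list(self.intercept_ci_)
            if self.intercept_ci_ is not None
            else None,
            "slope_ci": list(self.slope_ci_)
            if self.slope_ci_ is not None
            else None,
            "intercept_se": self.intercept_se_,
            "slope_se": self.slope_se_,
            "n_boot": self.n_boot,
            "ci_level": self.ci_level,
            "random_state": self.random_state,
        }


# --------------------------------------------------------------------------
# Functional wrappers


def fit_loglog(pairs, x_role: str = "x", y_role: str = "y") -> LogLogRegression:
    """OLS fit of ``log10 y = a + b log10 x`` to positive (x, y) pairs.

    The returned model has coefficients and diagnostics populated but no
    bootstrap fields (use :func:`bootstrap_fit` for those).
    """
    x, y = _validate_pairs(np.asarray(pairs, dtype=float))
    return LogLogRegression(n_boot=0, x_role=x_role, y_role=y_role).fit(x, y)


def bootstrap_fit(
    pairs,
    config: BootstrapConfig | None = None,
    x_role: str = "x",
    y_role: str = "y",
) -> LogLogRegression:
    """Fit plus case-resampling bootstrap SEs and percentile CIs."""
    config = config or BootstrapConfig()
    x, y = _validate_pairs(np.asarray(pairs, dtype=float))
    model = LogLogRegression(
        n_boot=config.n_reps,
        ci_level=config.ci_level,
        random_state=config.seed,
        x_role=x_role,
        y_role=y_role,
    )
    return model.fit(x, y)


def predict_point(model: LogLogRegression, x0: float) -> float:
    """Natural-scale point prediction ``10**(a + b*log10(x0))``."""
    return model.predict_point(x0)


def prediction_interval(
    model: LogLogRegression, x0: float, level: float = DEFAULT_CI_LEVEL
) -> PredictionResult:
    """Analytic t-based prediction limits at ``x0`` (see the estimator)."""
    return model.prediction_interval(x0, level=level)


def pearson_r(pairs) -> float:
    """Pearson product-moment correlation of the log10-transformed pairs."""
    x, y = _validate_pairs(np.asarray(pairs, dtype=float))
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        raise ValueError("correlation undefined for a constant variate")
    return float(np.corrcoef(lx, ly)[0, 1])
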