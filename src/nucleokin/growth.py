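"""Tumour growth-curve inference from caliper measurements.

Volumes are the standard caliper approximation V = L * W^2 * 0.52 (mm^3).
Growth is modelled on the log scale with Gaussian errors (multiplicative
lognormal noise on volume):

* single exponential:   ln V = ln V0 + r * t
* biexponential:        ln V = ln V0 + r_early * min(t, t_b) + r_late * max(0, t - t_b)

i.e. a continuous piecewise log-linear curve with early- and late-time growth
rates and a breakpoint t_b. The breakpoint is profiled over a fixed 0.1-day
grid spanning the observed days (conditional fits are closed-form OLS), and
the exact maximized Gaussian log-likelihood, including the sigma MLE term, is
returned. Nested models on the same data are compared with a likelihood-ratio
test against chi-squared with df = 2 (extra rate + breakpoint); because the
breakpoint is absent under the null, the chi-squared reference is approximate
and its calibration is checked by simulation in the test suite.

A sum-of-two-exponentials variant, V(t) = V0 * (w e^{r1 t} + (1-w) e^{r2 t}),
is available via ``model="sum_exponential"`` for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares

from .datatypes import GrowthCurve

__all__ = [
    "caliper_volume",
    "GrowthModel",
    "GrowthResults",
    "GrowthTestResult",
    "fit_growth",
    "growth_lrt",
]

BREAKPOINT_STEP = 0.1  # days; profile-grid resolution of the breakpoint


def caliper_volume(length, width):
    """Caliper tumour volume, mm^3: length * width^2 * 0.52.

    Warns (does not fail) if width exceeds length — calipers are conventionally
    read with length as the longer axis.
    """
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(length < 0) or np.any(width < 0):
        raise ValueError("caliper measurements must be non-negative")
    if np.any(width > length):
        warnings.warn("width > length: check caliper axis convention", stacklevel=2)
    v = length * width**2 * 0.52
    return float(v) if v.ndim == 0 else v


def _gaussian_loglik(sse: float, n: int) -> tuple[float, float]:
    """Maximized Gaussian log-likelihood and sigma-hat for an OLS residual SSE."""
    sigma2 = max(sse / n, 1e-300)
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return float(ll), float(np.sqrt(sigma2))


class GrowthModel:
    """Exponential / piecewise-exponential growth model for one arm.

    Parameters
    ----------
    curves
        The arm's :class:`GrowthCurve` list (pooled fit: shared rates; a shared
        intercept by default, per-animal intercepts with
        ``per_animal_intercepts=True``).
    model
        ``"single"``, ``"biexponential"`` (continuous piecewise log-linear,
        free breakpoint) or ``"sum_exponential"``.
    """

    def __init__(self, curves, model: str = "single", per_animal_intercepts: bool = False):
        if model not in ("single", "biexponential", "sum_exponential"):
            raise ValueError(f"unknown growth model: {model}")
        curves = list(curves)
        if not curves:
            raise ValueError("no growth curves supplied")
        self.curves = curves
        self.model = model
        self.per_animal_intercepts = per_animal_intercepts
        self.days = np.concatenate([c.days for c in curves])
        self.log_volumes = np.log(np.concatenate([c.volumes for c in curves]))
        self.animals = np.concatenate([[c.animal_id] * len(c.days) for c in curves])
        if np.unique(self.days).size < 2:
            raise ValueError("need observations on at least two distinct days")
        n_params = {"single": 2, "biexponential": 4, "sum_exponential": 4}[model]
        if self.per_animal_intercepts:
            n_params += len(curves) - 1
        if self.days.size < n_params + 2:
            raise ValueError("too few observations for the requested model")
        self._n_mean_params = n_params

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, arm: str | None = None, **kwargs) -> "GrowthModel":
        """Build from a tidy table with columns ``animal_id, arm, day`` and
        either ``volume_mm3`` or ``length_mm``/``width_mm``."""
        df = df.copy()
        if arm is not None:
            df = df[df["arm"] == arm]
        if "volume_mm3" not in df.columns:
            df["volume_mm3"] = caliper_volume(df["length_mm"].to_numpy(),
                                              df["width_mm"].to_numpy())
        curves = []
        for animal, g in df.sort_values("day").groupby("animal_id", sort=True):
            curves.append(GrowthCurve(str(animal), str(g["arm"].iloc[0]),
                                      g["day"].to_numpy(), g["volume_mm3"].to_numpy()))
        return cls(curves, **kwargs)

    # -- design matrices -------------------------------------------------
    def _intercept_columns(self) -> np.ndarray:
        if not self.per_animal_intercepts:
            return np.ones((self.days.size, 1))
        ids = sorted({c.animal_id for c in self.curves})
        cols = [np.ones(self.days.size)]
        cols += [(self.animals == a).astype(float) for a in ids[1:]]
        return np.column_stack(cols)

    def _ols(self, X: np.ndarray):
        coef, _, _, _ = np.linalg.lstsq(X, self.log_volumes, rcond=None)
        resid = self.log_volumes - X @ coef
        return coef, float(resid @ resid)

    def _breakpoint_grid(self) -> np.ndarray:
        lo, hi = float(self.days.min()), float(self.days.max())
        grid = np.arange(lo + BREAKPOINT_STEP, hi - BREAKPOINT_STEP / 2, BREAKPOINT_STEP)
        if grid.size == 0:
            raise ValueError("day range too short to profile a breakpoint")
        return grid

    # -- fitting ---------------------------------------------------------
    def fit(self) -> "GrowthResults":
        if self.model == "single":
            return self._fit_single()
        if self.model == "biexponential":
            return self._fit_biexponential()
        return self._fit_sum_exponential()

    def _fit_single(self) -> "GrowthResults":
        X = np.column_stack([self._intercept_columns(), self.days])
        coef, sse = self._ols(X)
        ll, sigma = _gaussian_loglik(sse, self.days.size)
        rate = float(coef[-1])
        return GrowthResults(
            model="single", log_v0=float(coef[0]), rate_early=rate, rate_late=rate,
            breakpoint=None, sigma=sigma, log_likelihood=ll, sse=sse,
            nobs=self.days.size, n_mean_params=self._n_mean_params,
            converged=True, model_obj=self,
        )

    def _fit_biexponential(self) -> "GrowthResults":
        Z = self._intercept_columns()
        best = None
        for tb in self._breakpoint_grid():
            X = np.column_stack([Z, np.minimum(self.days, tb),
                                 np.maximum(0.0, self.days - tb)])
            coef, sse = self._ols(X)
            if best is None or sse < best[1]:
                best = (coef, sse, tb)
        coef, sse, tb = best
        ll, sigma = _gaussian_loglik(sse, self.days.size)
        return GrowthResults(
            model="biexponential", log_v0=float(coef[0]),
            rate_early=float(coef[-2]), rate_late=float(coef[-1]),
            breakpoint=float(tb), sigma=sigma, log_likelihood=ll, sse=sse,
            nobs=self.days.size, n_mean_params=self._n_mean_params,
            converged=True, model_obj=self,
        )

    def _fit_sum_exponential(self) -> "GrowthResults":
        t, y = self.days, self.log_volumes

        def mean_fn(p):
            log_v0, r1, r2, logit_w = p
            w = 1.0 / (1.0 + np.exp(-logit_w))
            return log_v0 + np.log(w * np.exp(r1 * t) + (1 - w) * np.exp(r2 * t))

        slope0 = np.polyfit(t, y, 1)[0]
        best = None
        for f1, f2 in ((1.5, 0.5), (2.0, 0.25), (1.0, 1.0)):
            x0 = np.array([y[t == t.min()].mean(), slope0 * f1, slope0 * f2, 0.0])
            try:
                sol = least_squares(lambda p: mean_fn(p) - y, x0)
            except Exception:
                continue
            sse = float(2.0 * sol.cost)
            if best is None or sse < best[1]:
                best = (sol, sse)
        if best is None:
            raise RuntimeError("sum-of-exponentials fit failed from every start")
        sol, sse = best
        log_v0, r1, r2, logit_w = sol.x
        ll, sigma = _gaussian_loglik(sse, t.size)
        r_early, r_late = (r1, r2) if r1 >= r2 else (r2, r1)
        return GrowthResults(
            model="sum_exponential", log_v0=float(log_v0),
            rate_early=float(r_early), rate_late=float(r_late),
            breakpoint=None, sigma=sigma, log_likelihood=ll, sse=sse,
            nobs=t.size, n_mean_params=self._n_mean_params,
            converged=bool(sol.success), model_obj=self,
            extra={"weight_fast": float(1.0 / (1.0 + np.exp(-logit_w)))},
        )


@dataclass
class GrowthResults:
    """Fitted growth model: rates (day^-1), intercept, breakpoint, exact
    maximized Gaussian log-likelihood, and the ln-scale residual SD."""

    model: str
    log_v0: float
    rate_early: float
    rate_late: float
    breakpoint: float | None
    sigma: float
    log_likelihood: float
    sse: float
    nobs: int
    n_mean_params: int
    converged: bool
    model_obj: GrowthModel | None = None
    extra: dict = field(default_factory=dict)

    def predict_log_volume(self, days) -> np.ndarray:
        t = np.asarray(days, dtype=float)
        if self.model == "single":
            return self.log_v0 + self.rate_early * t
        if self.model == "biexponential":
            tb = self.breakpoint
            return self.log_v0 + self.rate_early * np.minimum(t, tb) \
                + self.rate_late * np.maximum(0.0, t - tb)
        w = self.extra["weight_fast"]
        return self.log_v0 + np.log(w * np.exp(self.rate_early * t)
                                    + (1 - w) * np.exp(self.rate_late * t))

    def compare_lr_test(self, null_results: "GrowthResults") -> "GrowthTestResult":
        return growth_lrt(null_results, self)

    def summary(self) -> str:
        lines = [
            f"Growth model: {self.model}   (n = {self.nobs} observations)",
            f"  ln V0            {self.log_v0:9.4f}   (V0 = {np.exp(self.log_v0):.1f} mm^3)",
            f"  rate_early       {self.rate_early:9.4f} / day",
            f"  rate_late        {self.rate_late:9.4f} / day",
        ]
        if self.breakpoint is not None:
            lines.append(f"  breakpoint       {self.breakpoint:9.1f} day")
        lines += [
            f"  sigma (ln scale) {self.sigma:9.4f}",
            f"  log-likelihood   {self.log_likelihood:9.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed volumes (log scale) with the fitted mean curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model_obj is not None:
            for c in self.model_obj.curves:
                ax.semilogy(c.days, c.volumes, "o-", ms=3, lw=0.5, alpha=0.4)
            tt = np.linspace(self.model_obj.days.min(), self.model_obj.days.max(), 200)
            ax.semilogy(tt, np.exp(self.predict_log_volume(tt)), "k-", lw=2,
                        label=f"{self.model} fit")
            ax.legend()
        ax.set_xlabel("day")
        ax.set_ylabel("tumour volume (mm$^3$)")
        return ax


@dataclass
class GrowthTestResult:
    """Likelihood-ratio comparison of nested growth models."""

    statistic: float  # 2 * (ll_alt - ll_null)
    df: int
    p_value: float


_NESTING = {"single": {"biexponential", "sum_exponential"}}


def fit_growth(curves, model: str = "single", **kwargs) -> GrowthResults:
    """Convenience wrapper: ``GrowthModel(curves, model=model).fit()``."""
    return GrowthModel(curves, model=model, **kwargs).fit()


def growth_lrt(null_fit: GrowthResults, alt_fit: GrowthResults,
               tol: float = 1e-6) -> GrowthTestResult:
    """Likelihood-ratio test of nested growth fits on the same data.

    df is the difference in free mean parameters (2 for single vs
    biexponential: the extra rate plus the breakpoint).
    """
    if alt_fit.model not in _NESTING.get(null_fit.model, set()):
        raise ValueError(f"{null_fit.model!r} is not nested in {alt_fit.model!r}")
    if null_fit.nobs != alt_fit.nobs:
        raise ValueError("fits are not on the same data (observation counts differ)")
    lam = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)
    if lam < -tol:
        raise RuntimeError(f"negative LR statistic ({lam:.3g}): alternative fit failed")
    lam = max(lam, 0.0)
    df = 2
    return GrowthTestResult(statistic=float(lam), df=df,
                            p_value=float(sps.chi2.sf(lam, df)))
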