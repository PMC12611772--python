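"""Two-pool FRAP recovery analysis.

A bleached nuclear region's fluorescence recovery F(t) is modelled as the sum
of a fast- and a slow-exchanging pool:

    F(t) = y0 + A_fast (1 - exp(-t / tau_fast)) + A_slow (1 - exp(-t / tau_slow))

where ``y0`` is the fluorescence immediately after photobleaching (relative to
the pre-bleach level) and the two amplitudes/time constants describe transient
versus longer-lived chromatin interactions of the tagged protein. Derived pool
fractions:

* mobile fraction  = (A_fast + A_slow) / (1 - y0)  — the share of the bleached
  pool that exchanges by the end of recovery; its complement is stably bound;
* slow fraction    = A_slow / (A_fast + A_slow)    — the share of the mobile
  pool in the slow component (fast fraction is its complement).

The pipeline is normalize -> bleach-depth QC -> fit -> fractions. Fitting uses
variable projection (the model is linear in y0 and the amplitudes given the
time constants) over a log-spaced multi-start grid of (tau_fast, tau_slow)
pairs, followed by a bounded trust-region polish of all five parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datatypes import DegenerateInputError, FrapCurve
from .stats import TestResult, two_sample_t

__all__ = [
    "normalize_recovery",
    "qc_bleach_depth",
    "QcDecision",
    "TwoComponentRecovery",
    "FrapFitResults",
    "PoolFractions",
    "fit_two_component",
    "pool_fractions",
    "analyze_cohort",
    "compare_fractions",
]

MIN_POSTBLEACH_SAMPLES = 10


def normalize_recovery(curve: FrapCurve) -> FrapCurve:
    """Normalize a recovery trace to its pre-bleach sample.

    Every intensity is divided by the pre-bleach value (which becomes exactly
    1.0) and the time origin is shifted so the first post-bleach sample sits at
    t = 0. Scale-invariant: ``normalize(k * curve) == normalize(curve)``.
    """
    if curve.normalized:
        raise ValueError(f"curve {curve.cell_id} is already normalized")
    pre = curve.prebleach_intensity
    if pre <= 0:
        raise ValueError(f"curve {curve.cell_id}: non-positive pre-bleach intensity")
    t0 = curve.postbleach_times[0]
    return curve.replace(
        times=curve.times - t0,
        intensities=curve.intensities / pre,
        normalized=True,
    )


@dataclass
class QcDecision:
    cell_id: str
    accepted: bool
    reason: str | None = None
    first_postbleach: float | None = None


def qc_bleach_depth(curve: FrapCurve, max_postbleach: float = 0.25) -> QcDecision:
    """Accept a curve only if the bleach was deep enough.

    A curve passes when its first post-bleach sample is at or below
    ``max_postbleach`` of the pre-bleach value (boundary inclusive). Shallow
    bleaches leave too little recovery dynamic range to constrain the fit.
    """
    if not curve.normalized:
        raise ValueError("qc_bleach_depth requires a normalized curve")
    first = float(curve.postbleach_intensities[0])
    if first <= max_postbleach:
        return QcDecision(curve.cell_id, True, first_postbleach=first)
    return QcDecision(curve.cell_id, False, reason="insufficient_bleach_depth",
                      first_postbleach=first)


def _model(t, y0, a_fast, tau_fast, a_slow, tau_slow):
    return (y0
            + a_fast * (1.0 - np.exp(-t / tau_fast))
            + a_slow * (1.0 - np.exp(-t / tau_slow)))


def _varpro_sse(t, f, tau1, tau2):
    """Given the two time constants, solve (y0, A1, A2) by linear least squares.

    Returns (sse, y0, a1, a2). The design is [1, 1-e^-t/tau1, 1-e^-t/tau2].
    """
    X = np.column_stack([
        np.ones_like(t),
        1.0 - np.exp(-t / tau1),
        1.0 - np.exp(-t / tau2),
    ])
    coef, _, _, _ = np.linalg.lstsq(X, f, rcond=None)
    resid = f - X @ coef
    return float(resid @ resid), coef


@dataclass
class PoolFractions:
    mobile_fraction: float
    slow_fraction: float
    fast_fraction: float


class TwoComponentRecovery:
    """Two-component exponential recovery model for a single normalized,
    QC-passed :class:`FrapCurve`.

    Parameters
    ----------
    curve
        Normalized recovery trace with at least 10 post-bleach samples.
    tau_bounds
        Allowed range for both time constants, seconds.
    n_starts
        Grid size per time constant for the multi-start (n_starts ** 2 pairs,
        log-spaced; only tau1 < tau2 pairs are evaluated).
    """

    def __init__(self, curve: FrapCurve, tau_bounds=(0.05, 100.0), n_starts: int = 5,
                 y0_bounds=(0.0, 1.0), amp_bounds=(0.0, 2.0)):
        if not curve.normalized:
            raise ValueError("fit requires a normalized curve")
        if curve.n_postbleach < MIN_POSTBLEACH_SAMPLES:
            raise ValueError(
                f"curve {curve.cell_id}: need >= {MIN_POSTBLEACH_SAMPLES} post-bleach samples")
        self.curve = curve
        self.tau_bounds = tau_bounds
        self.n_starts = n_starts
        self.y0_bounds = y0_bounds
        self.amp_bounds = amp_bounds

    def fit(self) -> "FrapFitResults":
        t = self.curve.postbleach_times
        f = self.curve.postbleach_intensities
        sst = float(((f - f.mean()) ** 2).sum())
        if np.ptp(f) <= 1e-12 * max(1.0, float(np.abs(f).max())):
            raise DegenerateInputError(
                f"curve {self.curve.cell_id}: constant trace, nothing to fit")

        lo, hi = self.tau_bounds
        grid = np.geomspace(lo, hi, self.n_starts)
        best = None
        for i, tau1 in enumerate(grid):
            for tau2 in grid[i + 1:]:
                sse, coef = _varpro_sse(t, f, tau1, tau2)
                if best is None or sse < best[0]:
                    best = (sse, coef, tau1, tau2)
        sse0, coef0, tau1_0, tau2_0 = best

        # bounded trust-region polish of all five parameters from the best
        # variable-projection candidate
        y0_lo, y0_hi = self.y0_bounds
        a_lo, a_hi = self.amp_bounds
        x0 = np.array([
            np.clip(coef0[0], y0_lo, y0_hi),
            np.clip(coef0[1], a_lo, a_hi),
            tau1_0,
            np.clip(coef0[2], a_lo, a_hi),
            tau2_0,
        ])
        lower = [y0_lo, a_lo, lo, a_lo, lo]
        upper = [y0_hi, a_hi, hi, a_hi, hi]

        def resid(p):
            return _model(t, *p) - f

        converged = True
        try:
            sol = least_squares(resid, x0, bounds=(lower, upper), method="trf")
            converged = bool(sol.success)
            params = sol.x
            sse = float(2.0 * sol.cost)
        except Exception:
            converged = False
            params, sse = x0, sse0
        # polish must never lose to its own starting point
        sse_start = float((resid(x0) ** 2).sum())
        if sse_start < sse:
            params, sse = x0, sse_start

        y0, a1, tau1, a2, tau2 = params
        # relabel so the fast component is the smaller time constant;
        # ties broken toward the first slot
        if tau1 <= tau2:
            a_fast, tau_fast, a_slow, tau_slow = a1, tau1, a2, tau2
        else:
            a_fast, tau_fast, a_slow, tau_slow = a2, tau2, a1, tau1
        r_squared = 1.0 - sse / sst
        return FrapFitResults(
            cell_id=self.curve.cell_id,
            y0=float(y0), a_fast=float(a_fast), tau_fast=float(tau_fast),
            a_slow=float(a_slow), tau_slow=float(tau_slow),
            sse=sse, sst=sst, r_squared=float(np.clip(r_squared, 0.0, 1.0)),
            converged=converged, n_postbleach=t.size,
        )


@dataclass
class FrapFitResults:
    """Fitted two-component recovery parameters for one cell.

    R^2 is computed on post-bleach samples only (the pre-bleach anchor is a
    normalization constant, not a fitted point).
    """

    cell_id: str
    y0: float
    a_fast: float
    tau_fast: float
    a_slow: float
    tau_slow: float
    sse: float
    sst: float
    r_squared: float
    converged: bool
    n_postbleach: int

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return _model(t, self.y0, self.a_fast, self.tau_fast, self.a_slow, self.tau_slow)

    def pool_fractions(self) -> PoolFractions:
        return pool_fractions(self)

    def summary(self) -> str:
        frac = self.pool_fractions()
        lines = [
            f"Two-component FRAP recovery fit — cell {self.cell_id}",
            f"  y0 (post-bleach floor)   {self.y0:8.4f}",
            f"  A_fast                   {self.a_fast:8.4f}   tau_fast {self.tau_fast:7.3f} s",
            f"  A_slow                   {self.a_slow:8.4f}   tau_slow {self.tau_slow:7.3f} s",
            f"  R^2 (post-bleach)        {self.r_squared:8.4f}   SSE {self.sse:.3e}",
            f"  mobile fraction          {frac.mobile_fraction:8.4f}",
            f"  slow / fast (of mobile)  {frac.slow_fraction:.4f} / {frac.fast_fraction:.4f}",
            f"  converged                {self.converged}",
        ]
        return "\n".join(lines)

    def plot(self, curve: FrapCurve | None = None, ax=None):
        """Overlay the fitted recovery on the measured trace."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if curve is not None:
            ax.plot(curve.postbleach_times, curve.postbleach_intensities,
                    ".", ms=3, alpha=0.6, label="data")
            tt = np.linspace(curve.postbleach_times[0], curve.postbleach_times[-1], 400)
        else:
            tt = np.linspace(0, 5 * self.tau_slow, 400)
        ax.plot(tt, self.predict(tt), "-", label="two-component fit")
        ax.set_xlabel("time after bleach (s)")
        ax.set_ylabel("normalized fluorescence")
        ax.legend()
        return ax


def fit_two_component(curve: FrapCurve, **kwargs) -> FrapFitResults:
    """Convenience wrapper: ``TwoComponentRecovery(curve, **kwargs).fit()``."""
    return TwoComponentRecovery(curve, **kwargs).fit()


def is_resolved(fit: FrapFitResults, curve: FrapCurve,
                min_tau_ratio: float = 3.0, min_dt_multiple: float = 10.0) -> bool:
    """Whether the fit genuinely resolved two kinetic pools.

    A two-component fit only supports a slow-pool interpretation when the slow
    time constant is measurable on the acquisition: at least
    ``min_dt_multiple`` sampling intervals long, no longer than the recovery
    window, and separated from the fast time constant by at least
    ``min_tau_ratio``. Fits violating this (e.g. two merged fast components, or
    a pseudo-linear ramp slower than the window) carry no pool-fraction
    information and are excluded from cohort summaries.
    """
    t = curve.postbleach_times
    dt = float(np.median(np.diff(t)))
    window = float(t[-1] - t[0])
    return (fit.tau_slow >= min_dt_multiple * dt
            and fit.tau_slow <= window
            and fit.tau_slow >= min_tau_ratio * fit.tau_fast)


def pool_fractions(fit: FrapFitResults) -> PoolFractions:
    """Derive mobile/slow/fast pool fractions from a converged fit.

    mobile = (A_fast + A_slow) / (1 - y0); the slow and fast fractions
    partition the mobile pool and sum to 1 exactly.
    """
    if fit.y0 >= 1.0:
        raise ValueError("y0 >= 1: no bleach depth, fractions undefined")
    total = fit.a_fast + fit.a_slow
    if total <= 0:
        raise ValueError("zero total amplitude: fractions undefined")
    mobile = total / (1.0 - fit.y0)
    slow = fit.a_slow / total
    return PoolFractions(mobile_fraction=float(mobile),
                         slow_fraction=float(slow),
                         fast_fraction=float(1.0 - slow))


def analyze_cohort(curves, max_postbleach: float = 0.25, **fit_kwargs):
    """Run the full pipeline (normalize -> QC -> fit -> fractions) on a cohort.

    Returns ``(table, summary)``: a per-cell DataFrame (including rejected and
    non-converged cells, flagged) and a cohort summary dict with mean ± SEM of
    mobile fraction, slow fraction and R^2 over converged, QC-passed cells.
    """
    rows = []
    for curve in curves:
        c = curve if curve.normalized else normalize_recovery(curve)
        qc = qc_bleach_depth(c, max_postbleach=max_postbleach)
        row = {"cell_id": c.cell_id, "qc_pass": qc.accepted, "qc_reason": qc.reason,
               "converged": False}
        row["resolved"] = False
        if qc.accepted:
            try:
                fit = fit_two_component(c, **fit_kwargs)
            except DegenerateInputError:
                row["qc_reason"] = "degenerate_trace"
            else:
                row.update(
                    y0=fit.y0, a_fast=fit.a_fast, tau_fast=fit.tau_fast,
                    a_slow=fit.a_slow, tau_slow=fit.tau_slow,
                    r_squared=fit.r_squared, sse=fit.sse, converged=fit.converged,
                    resolved=fit.converged and is_resolved(fit, c),
                )
                if fit.converged:
                    frac = fit.pool_fractions()
                    row.update(mobile_fraction=frac.mobile_fraction,
                               slow_fraction=frac.slow_fraction,
                               fast_fraction=frac.fast_fraction)
        rows.append(row)
    table = pd.DataFrame(rows)
    fitted = table[table.get("converged", False) & table["qc_pass"]]
    resolved = fitted[fitted["resolved"]]

    def _ms(frame, col):
        if col not in frame or frame[col].dropna().empty:
            return {"mean": float("nan"), "sem": float("nan")}
        v = frame[col].dropna()
        return {"mean": float(v.mean()),
                "sem": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")}

    summary = {
        "n_input": len(table),
        "n_qc_pass": int(table["qc_pass"].sum()),
        "n_converged": int(len(fitted)),
        "n_resolved": int(len(resolved)),
        "mobile_fraction": _ms(resolved, "mobile_fraction"),
        "slow_fraction": _ms(resolved, "slow_fraction"),
        "fast_fraction": _ms(resolved, "fast_fraction"),
        "r_squared": _ms(fitted, "r_squared"),
    }
    return table, summary


def compare_fractions(group_a, group_b, variant: str = "pooled",
                      labels=("a", "b")) -> TestResult:
    """Two-sided two-sample t-test between per-cell fraction samples."""
    return two_sample_t(group_a, group_b, variant=variant, labels=labels)
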