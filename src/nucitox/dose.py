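"""Dose-response metrics: normalization, constrained 4PL IC50, trapezoidal AUC.

Viability is expressed in percent of the vehicle (DMSO) control. The IC50 is
the concentration at which the fitted four-parameter logistic crosses 50%,
with the top and bottom asymptotes fixed at 100 and 0 so only the midpoint
and the hill slope are free:

    V(c) = 100 / (1 + (c / IC50)^h)

The fit is performed on x = log10(c). AUC is the trapezoidal integral of
mean viability over the tested log10-concentration range, divided by the
range width, i.e. the mean viability over the tested range on a 0-100 scale.
Because the top/bottom are fixed, a drug whose fitted midpoint lies beyond
the largest tested concentration is censored at "> c_max" rather than
reported as a numeric IC50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "normalize_to_control",
    "fit_4pl",
    "four_pl",
    "compute_auc",
    "normalize_dynamics",
    "classify_growth",
]


@dataclass(frozen=True)
class FitResult:
    """Constrained 4PL fit summary for one (method, cell line, drug) series."""

    ic50: float  # µM; when censored, equals c_max and `censored` is True
    hill: float
    rss: float
    status: str  # "converged" | "not_reached" | "failed"

    @property
    def censored(self) -> bool:
        return self.status == "not_reached"


def normalize_to_control(values, control_values, blank_values=None) -> np.ndarray:
    """Percent viability: 100 * (value - blank) / (control_mean - blank).

    `blank_values` are no-cell wells (required for absorbance assays such as
    XTT, where medium + reagent has nonzero signal); omit them for direct
    counts. Values above 100% are retained — metabolic assays genuinely
    over-report at some sub-toxic doses — but negative viabilities are floored
    at 0 and logged.
    """
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if control.size < 2:
        raise ValueError("need at least 2 control replicates")
    blank_mean = float(np.mean(blank_values)) if blank_values is not None else 0.0
    control_mean = float(control.mean())
    if control_mean <= blank_mean:
        raise ValueError(
            f"control mean ({control_mean:g}) must exceed blank mean ({blank_mean:g})"
        )
    v = 100.0 * (values - blank_mean) / (control_mean - blank_mean)
    n_neg = int((v < 0).sum())
    if n_neg:
        logger.info("floored %d negative viability value(s) at 0", n_neg)
        v = np.maximum(v, 0.0)
    return v


def four_pl(conc, ic50: float, hill: float) -> np.ndarray:
    """Constrained logistic V(c) = 100 / (1 + (c/IC50)^h)."""
    conc = np.asarray(conc, dtype=float)
    return 100.0 / (1.0 + (conc / ic50) ** hill)


def fit_4pl(concentrations, viability) -> FitResult:
    """Least-squares 4PL fit with fixed asymptotes (top 100, bottom 0).

    Accepts replicate observations (repeated concentrations allowed). Fitting
    runs on log10 concentration with multi-start initialisation — the midpoint
    is started at every distinct tested concentration — to avoid local minima
    on shallow or noisy curves. If the fitted midpoint exceeds the largest
    tested concentration the IC50 is censored ("> c_max", status
    ``not_reached``).
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(viability, dtype=float)
    keep = ~np.isnan(v)
    c, v = c[keep], v[keep]
    if c.size == 0:
        raise ValueError("no viability observations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive (drop the control point)")
    distinct = np.unique(c)
    if distinct.size < 4:
        raise ValueError("need >= 4 distinct nonzero concentrations")
    x = np.log10(c)
    x_max = float(np.log10(distinct.max()))
    ln10 = np.log(10.0)

    def resid(theta):
        x50, h = theta
        return 100.0 / (1.0 + 10.0 ** (h * (x - x50))) - v

    def jac(theta):
        x50, h = theta
        u = 10.0 ** (h * (x - x50))
        g = 100.0 * u / (1.0 + u) ** 2 * ln10
        return np.column_stack([g * h, -g * (x - x50)])

    lo = [x.min() - 6.0, 1e-3]
    hi = [x.max() + 6.0, 50.0]
    # screen a grid of starts by RSS, polish the best few with least_squares
    starts = [(x0, h0) for x0 in np.log10(distinct) for h0 in (0.5, 1.0, 2.0)]
    screened = sorted(starts, key=lambda th: float((resid(th) ** 2).sum()))[:3]
    best = None
    for th0 in screened:
        try:
            sol = least_squares(
                resid, th0, jac=jac, bounds=(lo, hi), xtol=1e-12, ftol=1e-10, gtol=1e-10
            )
        except Exception:  # pragma: no cover - optimizer failure is exotic
            continue
        rss = float((sol.fun**2).sum())
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol.x)
    if best is None:
        return FitResult(np.nan, np.nan, np.nan, "failed")
    rss, (x50, h) = best
    if not np.isfinite(x50) or not np.isfinite(h):
        return FitResult(np.nan, np.nan, rss, "failed")
    if x50 > x_max:
        # curve does not reach 50% inside the tested range
        return FitResult(float(distinct.max()), float(h), rss, "not_reached")
    return FitResult(float(10.0**x50), float(h), rss, "converged")


def compute_auc(concentrations, viability) -> float:
    """Range-normalized trapezoidal AUC over log10 concentration, in percent.

    Replicates at the same concentration are averaged first; the control
    (c = 0) must be excluded by the caller since log10(0) is undefined.
    Result is the mean viability over [log10 c_min, log10 c_max]: 100 for a
    flat fully-viable curve, 0 for complete kill everywhere.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(viability, dtype=float)
    keep = ~np.isnan(v)
    c, v = c[keep], v[keep]
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive (control excluded)")
    distinct = np.unique(c)
    if distinct.size < 2:
        raise ValueError("AUC needs >= 2 distinct nonzero concentrations")
    mean_v = np.array([v[c == ci].mean() for ci in distinct])
    x = np.log10(distinct)
    return float(np.trapezoid(mean_v, x) / (x[-1] - x[0]))


def normalize_dynamics(times, counts) -> np.ndarray:
    """Fold-change of one replicate's counts relative to its t = 0 count."""
    t = np.asarray(times, dtype=float)
    n = np.asarray(counts, dtype=float)
    at0 = n[t == 0]
    if at0.size == 0 or np.isnan(at0[0]) or at0[0] <= 0:
        raise ValueError("t = 0 count must be present and positive")
    return n / at0[0]


def classify_growth(treated_fold, control_fold, tol: float = 0.1) -> str:
    """Label a treated growth curve relative to its starting count and control.

    Rules on the final fold-change F (start = 1.0):
      * cytotoxic          — F < 1 - tol (net cell loss)
      * cytostatic         — F within [1 - tol, 1 + tol] (numbers held flat)
      * partial_inhibition — growth, but final F < control * (1 - tol)
      * no_effect          — otherwise
    """
    treated = np.asarray(treated_fold, dtype=float)
    control = np.asarray(control_fold, dtype=float)
    if control.size == 0:
        raise ValueError("control series required")
    if treated.size != control.size:
        raise ValueError("treated and control series must share timepoints")
    f = float(treated[-1])
    f_ctrl = float(control[-1])
    if f < 1.0 - tol:
        return "cytotoxic"
    if f <= 1.0 + tol:
        return "cytostatic"
    if f < f_ctrl * (1.0 - tol):
        return "partial_inhibition"
    return "no_effect"
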