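"""Summary statistics for labeling efficiency, kinetics and specificity.

Covers the ensemble-level quantifications of the labeling reaction:

* pseudo-first-order kinetics, N(t) = N_inf * (1 - exp(-k' t)), fitted by
  nonlinear least squares to per-time mean label counts;
* the Poisson zero-class bound turning "fraction of molecules with zero
  labels" into kb of DNA per (non-specific) fluorophore;
* fold change between mean label counts of two labeling chemistries;
* the site-titration regression relating mean labels per plasmid to the
  number of recognition sites (slope = per-site efficiency, intercept =
  off-target labels per plasmid).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "KineticsFit",
    "TitrationFit",
    "fit_pseudo_first_order",
    "poisson_zero_bound",
    "fold_change",
    "titration_regression",
    "FitError",
]


class FitError(RuntimeError):
    """Nonlinear fit failed; carries initialization and residual context."""


@dataclass
class KineticsFit:
    k_prime: float            # min^-1
    plateau: float            # labels per molecule at saturation
    residual_norm: float
    covariance: np.ndarray    # 2x2, order (plateau, k_prime)

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.plateau * (1.0 - np.exp(-self.k_prime * t))


@dataclass
class TitrationFit:
    slope: float              # labels per site (per-site efficiency)
    intercept: float          # labels per plasmid (off-target estimate)
    slope_se: float
    intercept_se: float


def fit_pseudo_first_order(
    times: Sequence[float], means: Sequence[float], baseline: bool = False
) -> KineticsFit:
    """Fit N(t) = plateau * (1 - exp(-k' t)) to per-time mean counts.

    With ``baseline=True`` the model gains an additive constant b,
    N(t) = b + plateau * (1 - exp(-k' t)), which absorbs the
    time-independent off-target label count when the means come from data
    that include non-specific labeling.

    Initialization: plateau from the largest observed mean; k' from a
    log-linear regression of 1 - N/plateau against t.  Raises
    :class:`FitError` on degenerate input or non-convergence.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(means, dtype=float)
    if len(np.unique(t)) < (4 if baseline else 3):
        raise FitError("too few distinct time points for the model")
    if np.any(t < 0):
        raise ValueError("negative reaction time")
    if np.all(y <= 0):
        raise FitError("all mean counts are zero; kinetics undefined")

    b0 = float(np.min(y)) if baseline else 0.0
    plateau0 = float(np.max(y)) - b0
    if plateau0 <= 0:
        raise FitError("no increase over time; kinetics undefined")
    # log-linear initial rate: 1 - (N-b)/plateau0 = exp(-k t)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - (y - b0) / (plateau0 * 1.05)
        ok = (frac > 1e-9) & (t > 0)
    if ok.sum() >= 2:
        k0 = max(1e-3, float(-np.polyfit(t[ok], np.log(frac[ok]), 1)[0]))
    else:
        k0 = 1.0 / max(t[t > 0].min(), 1e-6)

    if baseline:
        def model(tt, plateau, k, b):
            return b + plateau * (1.0 - np.exp(-k * tt))

        p0 = (plateau0, k0, b0)
        bounds = ((0, 1e-9, 0), (np.inf, np.inf, np.inf))
    else:
        def model(tt, plateau, k):
            return plateau * (1.0 - np.exp(-k * tt))

        p0 = (plateau0, k0)
        bounds = ((0, 1e-9), (np.inf, np.inf))

    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0, maxfev=20000, bounds=bounds,
            xtol=1e-10, ftol=1e-10)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(
            f"kinetics fit did not converge (p0={p0}): {exc}") from exc
    resid = y - model(t, *popt)
    return KineticsFit(
        k_prime=float(popt[1]),
        plateau=float(popt[0]),
        residual_norm=float(np.linalg.norm(resid)),
        covariance=np.asarray(pcov),
    )


def poisson_zero_bound(
    f_zero: float, length_kb: float, method: str = "poisson"
) -> float:
    """Kb of DNA per non-specific label from the zero-label fraction.

    Under a Poisson count model, a fraction ``f_zero`` of molecules with
    zero labels implies a mean of lambda = -ln(f_zero) labels per molecule;
    the result is ``length_kb / lambda`` kb per label.  ``method="odds"``
    uses the naive (1 - f_zero)/f_zero mean instead; both agree to leading
    order when labels are rare.  ``f_zero = 1`` returns +inf (no labels
    observed at all).
    """
    if not 0 < f_zero <= 1:
        raise ValueError("f_zero must be in (0, 1]")
    if length_kb <= 0:
        raise ValueError("length_kb must be positive")
    if f_zero == 1.0:
        return float("inf")
    if method == "poisson":
        lam = -np.log(f_zero)
    elif method == "odds":
        lam = (1.0 - f_zero) / f_zero
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(length_kb / lam)


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of two mean label counts (e.g. one-pot vs two-step chemistry)."""
    if mean_b <= 0:
        raise ValueError("reference mean must be positive")
    return float(mean_a) / float(mean_b)


def titration_regression(
    site_counts: Sequence[float],
    mean_labels: Sequence[float],
    sems: Sequence[float] | None = None,
) -> TitrationFit:
    """OLS of mean labels per plasmid against recognition-site count.

    The slope estimates per-site labeling efficiency; the intercept the mean
    number of off-target labels per plasmid ("sites plus one" when both are
    about 1).  When per-group standard errors ``sems`` are supplied, the
    parameter standard errors are propagated from them instead of being
    estimated from the (few) regression residuals.
    """
    x = np.asarray(site_counts, dtype=float)
    y = np.asarray(mean_labels, dtype=float)
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct site counts (design is rank deficient)")
    X = np.column_stack([x, np.ones_like(x)])
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    xtx_inv = np.linalg.inv(X.T @ X)
    if sems is not None:
        V = np.diag(np.asarray(sems, dtype=float) ** 2)
        cov = xtx_inv @ X.T @ V @ X @ xtx_inv
    else:
        dof = max(len(x) - 2, 1)
        s2 = float(np.sum((y - fitted) ** 2)) / dof
        cov = s2 * xtx_inv
    return TitrationFit(
        slope=float(coef[0]),
        intercept=float(coef[1]),
        slope_se=float(np.sqrt(cov[0, 0])),
        intercept_se=float(np.sqrt(cov[1, 1])),
    )
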