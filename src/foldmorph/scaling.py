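"""Fitting the cortical folding scaling law.

In log space the scaling law ``At * sqrt(T) = k * Ae^alpha`` is linear:

    log At + (1/4) log T^2 = alpha * log Ae + log k

with the folding model predicting ``alpha = 5/4``.  The fit regresses
``y = logAt + 0.25 logT2`` on ``logAe`` by ordinary least squares, so the
reported confidence interval is the usual t-based slope CI with ``n - 2``
degrees of freedom.  A total-least-squares option (orthogonal regression
in the (logAe, y) plane) is provided for users who prefer a symmetric
error model; the default stays with OLS, whose slope CIs are the ones
conventionally reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm

from .components import Basis, DEFAULT_BASIS, compute_components
from .errors import DegenerateFitError, DomainError

__all__ = ["ScalingFit", "fit_scaling_law", "plane_residual", "implied_fractal_dimension"]


@dataclass(frozen=True)
class ScalingFit:
    """Result of a scaling-law fit.

    alpha is the fitted area exponent, log_k the offset (log10 of the
    scaling constant), alpha_ci the two-sided 95% interval for alpha.
    """

    alpha: float
    log_k: float
    alpha_ci: tuple[float, float]
    r_squared: float
    n: int

    def to_json(self) -> str:
        d = asdict(self)
        d["alpha_ci"] = list(d["alpha_ci"])
        return json.dumps(d, indent=2)


def fit_scaling_law(points, method: str = "ols") -> ScalingFit:
    """Fit ``logAt + 0.25 logT2 = alpha logAe + log_k`` to log points.

    Parameters
    ----------
    points
        Array of shape (n, 3) of (logAt, logAe, logT2) triples, n >= 3.
    method
        "ols" (default) or "tls" (orthogonal regression; CI still from the
        OLS formula applied at the TLS slope is not meaningful, so TLS
        reports the OLS interval width centered on the TLS slope only as a
        rough guide).
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise DomainError("points must have shape (n, 3)")
    n = X.shape[0]
    if n < 3:
        raise DegenerateFitError("need at least 3 points to fit the scaling law")
    y = X[:, 0] + 0.25 * X[:, 2]
    x = X[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in log Ae; slope is undefined")

    if method == "ols":
        res = sm.OLS(y, sm.add_constant(x)).fit()
        lo, hi = res.conf_int(alpha=0.05)[1]
        return ScalingFit(
            alpha=float(res.params[1]),
            log_k=float(res.params[0]),
            alpha_ci=(float(lo), float(hi)),
            r_squared=float(res.rsquared),
            n=n,
        )
    if method == "tls":
        xy = np.column_stack([x, y])
        xy0 = xy - xy.mean(axis=0)
        _, _, vt = np.linalg.svd(xy0, full_matrices=False)
        dx, dy = vt[0]
        if dx == 0:
            raise DegenerateFitError("TLS direction is vertical; slope undefined")
        slope = dy / dx
        intercept = y.mean() - slope * x.mean()
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        ci_lo, ci_hi = ols.conf_int(alpha=0.05)[1]
        half = float(ci_hi - ci_lo) / 2.0
        resid = y - (intercept + slope * x)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
        return ScalingFit(slope, intercept, (slope - half, slope + half), r2, n)
    raise DomainError(f"unknown method {method!r}")


def plane_residual(p, log_k: float, basis: Basis = DEFAULT_BASIS) -> np.ndarray:
    """Signed offset of log points from the theoretical plane: K(p) - log_k.

    Zero exactly when a point satisfies the scaling law with constant
    10**log_k.  This is a residual along the kappa direction, i.e. a
    distance surrogate (true Euclidean distance would divide by |kappa|).
    """
    return compute_components(p, basis).K - log_k


def implied_fractal_dimension(alpha: float) -> float:
    """Self-similar surface dimension implied by an area exponent.

    An exponent alpha relating folded to exposed area corresponds to a
    surface of fractal dimension 2*alpha; the theoretical alpha = 5/4
    gives the 5/2 of a statistically self-similar cortex, and alpha = 1 is
    the smooth (unfolded) limit with dimension 2.
    """
    if not alpha > 0:
        raise DomainError("alpha must be positive")
    return 2.0 * alpha
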