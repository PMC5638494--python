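"""Shared nonlinear least-squares machinery.

All model fits in the package go through :func:`multistart_least_squares`,
a thin wrapper around ``scipy.optimize.least_squares`` that adds
multi-start initialisation, asymptotic parameter covariance and a uniform
convergence report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

# Convergence follows damped least squares practice: stop on relative
# parameter / cost change below 1e-8, cap iterations at 500 per start.
_XTOL = 1e-8
_MAX_NFEV = 500


@dataclass
class LsqResult:
    params: np.ndarray
    params_sd: np.ndarray
    residuals: np.ndarray
    chi_sq_reduced: float
    n_iterations: int
    converged: bool
    cost: float = 0.0
    flags: list[str] = field(default_factory=list)


def _asymptotic_sd(jac: np.ndarray, residuals: np.ndarray, n_params: int) -> np.ndarray:
    """Standard deviations from the Gauss-Newton approximation (J^T J)^-1 s^2."""
    dof = max(residuals.size - n_params, 1)
    s_sq = float(residuals @ residuals) / dof
    jtj = jac.T @ jac
    try:
        cov = np.linalg.pinv(jtj) * s_sq
        sd = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        sd = np.full(n_params, np.nan)
    return sd


def multistart_least_squares(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> LsqResult:
    """Run ``least_squares`` from each start and keep the lowest-cost solution.

    Parameters are compared in the caller's parameterisation; callers that
    need positivity should pass log-scale parameters or explicit bounds.
    """
    best = None
    total_nfev = 0
    kwargs: dict = {"xtol": _XTOL, "ftol": _XTOL, "gtol": 1e-12, "max_nfev": _MAX_NFEV}
    if bounds is not None:
        kwargs["bounds"] = bounds
    for x0 in starts:
        try:
            sol = least_squares(residual_fn, np.asarray(x0, dtype=float), **kwargs)
        except Exception:
            continue
        total_nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-24:  # exact fit; further starts cannot improve
            break
    if best is None:
        n = len(starts[0])
        return LsqResult(
            params=np.full(n, np.nan),
            params_sd=np.full(n, np.nan),
            residuals=np.array([]),
            chi_sq_reduced=np.inf,
            n_iterations=total_nfev,
            converged=False,
            flags=["all starts failed"],
        )
    res = best.fun
    n_params = best.x.size
    dof = max(res.size - n_params, 1)
    return LsqResult(
        params=best.x,
        params_sd=_asymptotic_sd(best.jac, res, n_params),
        residuals=res,
        chi_sq_reduced=float(res @ res) / dof,
        n_iterations=total_nfev,
        converged=bool(best.success),
        cost=float(best.cost),
    )


def ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Ordinary least squares line fit.

    Returns ``(slope, intercept, slope_sd, intercept_sd, r_squared)`` with
    the classical homoscedastic standard errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two points for a line fit")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("degenerate x values: zero variance")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - ym) ** 2).sum())
    r_sq = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    dof = max(n - 2, 1)
    s_sq = ss_res / dof
    slope_sd = float(np.sqrt(s_sq / sxx))
    intercept_sd = float(np.sqrt(s_sq * (1.0 / n + xm**2 / sxx)))
    return slope, intercept, slope_sd, intercept_sd, r_sq
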