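"""Cosedimentation binding isotherms and stopped-flow binding kinetics.

High-speed cosedimentation quantifies side binding: filament-bound
protein pellets with F-actin, gel band volumes are corrected for
molecular weight (and optionally staining efficiency), and the pelleted
leiomodin-to-actin molar ratio y is fit against total leiomodin x with
the empirical sigmoid

    y(x) = (y_min - y_max) / (1 + exp((x - x0) / dx)) + y_max

whose inflection x0 is the half-saturation concentration and dx the
transition width.

Stopped-flow pyrene transients after mixing leiomodin with F-actin rise
as a double exponential

    y(t) = A1 (1 - exp(-t / t1)) + A2 (1 - exp(-t / t2)),  t1 <= t2,

falling back to a single exponential when the slow amplitude is not
resolved (SD exceeding the estimate).  The concentration dependence of
the fast observed rate 1/t1 is summarised by a straight line, whose
slope reports on a second-order binding step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from actospec._fitting import multistart_least_squares, ols_line
from actospec.decay import FitReport

if TYPE_CHECKING:  # pragma: no cover
    from actospec.synthetic import DensitometryTable, StoppedFlowTrace


@dataclass(frozen=True)
class SigmoidModel:
    """Empirical bound-ratio sigmoid."""

    y_min: float
    y_max: float
    x0_um: float
    dx_um: float

    def __post_init__(self) -> None:
        if self.y_max < self.y_min:
            raise ValueError("y_max must be >= y_min")
        if self.dx_um <= 0:
            raise ValueError("dx must be positive")

    def ratio(self, x_um: np.ndarray) -> np.ndarray:
        x = np.asarray(x_um, dtype=float)
        return (self.y_min - self.y_max) / (
            1.0 + np.exp((x - self.x0_um) / self.dx_um)
        ) + self.y_max


@dataclass(frozen=True)
class BiexpModel:
    """Rising biexponential transient; time constants sorted t1 <= t2."""

    a1: float
    a2: float
    t1_s: float
    t2_s: float

    def __post_init__(self) -> None:
        if self.t1_s <= 0 or self.t2_s <= 0:
            raise ValueError("time constants must be positive")
        if self.t1_s > self.t2_s:
            # enforce ordering by swapping component labels
            a1, a2, t1, t2 = self.a2, self.a1, self.t2_s, self.t1_s
            object.__setattr__(self, "a1", a1)
            object.__setattr__(self, "a2", a2)
            object.__setattr__(self, "t1_s", t1)
            object.__setattr__(self, "t2_s", t2)

    def signal(self, time_s: np.ndarray) -> np.ndarray:
        t = np.asarray(time_s, dtype=float)
        return self.a1 * (1.0 - np.exp(-t / self.t1_s)) + self.a2 * (
            1.0 - np.exp(-t / self.t2_s)
        )


def densitometry_ratio(
    table: "DensitometryTable",
    stain_actin: float = 1.0,
    stain_lmod: float = 1.0,
) -> pd.DataFrame:
    """Molecular-weight-corrected pelleted protein ratio per lane.

    ratio = (V_lmod / MW_lmod / stain_lmod) / (V_actin / MW_actin / stain_actin)

    Staining-efficiency coefficients default to 1 (equal dye binding per
    unit mass).  Lanes with a zero actin band are dropped with a warning
    flag in the returned frame's ``attrs``.
    """
    ok = table.band_volume_actin > 0
    dropped = int((~ok).sum())
    ratio = (table.band_volume_lmod[ok] / table.mw_lmod_kda / stain_lmod) / (
        table.band_volume_actin[ok] / table.mw_actin_kda / stain_actin
    )
    out = pd.DataFrame(
        {"lmod_total_um": table.lmod_total_um[ok], "bound_ratio": ratio}
    )
    out.attrs["dropped_lanes"] = dropped
    if dropped:
        out.attrs["warning"] = f"{dropped} lane(s) dropped: zero actin band"
    return out


def fit_sigmoid(x: Sequence[float], y: Sequence[float]) -> FitReport:
    """Least-squares fit of the bound-ratio sigmoid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need at least 5 matched (x, y) points")

    span = float(y.max() - y.min())
    flags: list[str] = []
    if span < 1e-12:
        model = SigmoidModel(float(y.mean()), float(y.mean()) + 1e-12, float(x.mean()), 1.0)
        return FitReport(
            parameters=model,
            parameter_sd={},
            chi_sq_reduced=0.0,
            n_iterations=0,
            converged=False,
            residuals=np.zeros_like(y),
            flags=["flat data: sigmoid unidentifiable"],
        )

    def residual(p: np.ndarray) -> np.ndarray:
        y_min, y_max, x0, log_dx = p
        dx = np.exp(log_dx)
        return (y_min - y_max) / (1.0 + np.exp((x - x0) / dx)) + y_max - y

    x_span = float(x.max() - x.min())
    starts = [
        np.array([y.min(), y.max(), x0_guess, np.log(dx_guess)])
        for x0_guess in np.quantile(x, [0.25, 0.5, 0.75])
        for dx_guess in (0.1 * x_span, 0.3 * x_span)
    ]
    res = multistart_least_squares(residual, starts)
    y_min, y_max, x0, log_dx = res.params
    if y_max < y_min:
        y_min, y_max = y_max, y_min
        flags.append("plateaus swapped to enforce y_max >= y_min")
    model = SigmoidModel(float(y_min), float(y_max), float(x0), float(np.exp(log_dx)))
    sd = {
        "y_min": float(res.params_sd[0]),
        "y_max": float(res.params_sd[1]),
        "x0_um": float(res.params_sd[2]),
        "dx_um": float(res.params_sd[3] * np.exp(log_dx)),
    }
    return FitReport(
        parameters=model,
        parameter_sd=sd,
        chi_sq_reduced=res.chi_sq_reduced,
        n_iterations=res.n_iterations,
        converged=res.converged,
        residuals=res.residuals,
        flags=flags + res.flags,
    )


def fit_biexponential(trace: "StoppedFlowTrace") -> FitReport:
    """Fit a rising biexponential to a stopped-flow transient.

    When the second amplitude is not resolved (its SD exceeds |a2|), the
    trace is refit with a single exponential and the fallback noted.
    """
    t = trace.time_s
    y = trace.signal_au

    def residual2(p: np.ndarray) -> np.ndarray:
        a1, a2, log_t1, log_t2 = p
        t1, t2 = np.exp(log_t1), np.exp(log_t2)
        return (
            a1 * (1.0 - np.exp(-t / t1)) + a2 * (1.0 - np.exp(-t / t2)) - y
        )

    y_inf = float(y[-5:].mean()) if y.size >= 5 else float(y[-1])
    t_span = float(t[-1] - t[0]) if t[-1] > t[0] else 1.0
    starts = [
        np.array([0.7 * y_inf, 0.3 * y_inf, np.log(f1 * t_span), np.log(f2 * t_span)])
        for f1, f2 in [(0.01, 0.2), (0.05, 0.5), (0.02, 1.0), (0.1, 0.3)]
    ]
    res = multistart_least_squares(residual2, starts)
    a1, a2, log_t1, log_t2 = res.params
    t1, t2 = float(np.exp(log_t1)), float(np.exp(log_t2))
    sd_a2 = float(res.params_sd[1])
    flags = list(res.flags)

    if not res.converged or (abs(a2) > 0 and sd_a2 > abs(a2)):
        flags.append("second amplitude unresolved: single-exponential fallback")

        def residual1(p: np.ndarray) -> np.ndarray:
            a, log_tc = p
            return a * (1.0 - np.exp(-t / np.exp(log_tc))) - y

        starts1 = [
            np.array([y_inf, np.log(f * t_span)]) for f in (0.02, 0.1, 0.5)
        ]
        res1 = multistart_least_squares(residual1, starts1)
        a, log_tc = res1.params
        tc = float(np.exp(log_tc))
        model = BiexpModel(a1=float(a), a2=0.0, t1_s=tc, t2_s=tc)
        return FitReport(
            parameters=model,
            parameter_sd={
                "a1": float(res1.params_sd[0]),
                "t1_s": float(res1.params_sd[1] * tc),
            },
            chi_sq_reduced=res1.chi_sq_reduced,
            n_iterations=res.n_iterations + res1.n_iterations,
            converged=res1.converged,
            residuals=res1.residuals,
            flags=flags,
        )

    # order components so t1 <= t2
    if t1 > t2:
        a1, a2, t1, t2 = a2, a1, t2, t1
        res.params_sd = res.params_sd[[1, 0, 3, 2]]
    model = BiexpModel(a1=float(a1), a2=float(a2), t1_s=t1, t2_s=t2)
    sd = {
        "a1": float(res.params_sd[0]),
        "a2": float(res.params_sd[1]),
        "t1_s": float(res.params_sd[2] * t1),
        "t2_s": float(res.params_sd[3] * t2),
    }
    return FitReport(
        parameters=model,
        parameter_sd=sd,
        chi_sq_reduced=res.chi_sq_reduced,
        n_iterations=res.n_iterations,
        converged=res.converged,
        residuals=res.residuals,
        flags=flags,
    )


def rate_vs_concentration(
    fits: Sequence[tuple[float, BiexpModel]],
) -> dict[str, float]:
    """Straight-line summary of the fast observed rate versus concentration.

    Returns slope (per uM per s), intercept (per s) and their SDs from an
    ordinary least-squares fit of 1/t1 against concentration.
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 concentrations")
    conc = np.array([c for c, _ in fits], dtype=float)
    kobs = np.array([1.0 / m.t1_s for _, m in fits], dtype=float)
    slope, intercept, slope_sd, intercept_sd, r_sq = ols_line(conc, kobs)
    return {
        "slope_per_um_s": slope,
        "intercept_per_s": intercept,
        "slope_sd": slope_sd,
        "intercept_sd": intercept_sd,
        "r_squared": r_sq,
    }
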