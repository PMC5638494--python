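"""Pyrene polymerisation-rate and critical-concentration analysis.

Pyrene-labelled actin reports filament mass through its fluorescence
quantum yield, so the time course of pyrene emission traces actin
assembly.  The polymerisation rate is taken as the slope of the pyrene
curve at 50% of the maximal fluorescence change, normalised by the slope
of the spontaneous (no-regulator) assembly measured under the same
conditions.

The critical concentration cc - the free G-actin concentration at steady
state - is the breakpoint of the steady-state pyrene emission F versus
total actin [a], modelled as the continuous two-segment (hinge) line

    F([a]) = F_c + L_s ([a] - cc)   for [a] <= cc
    F([a]) = F_c + R_s ([a] - cc)   for [a] >  cc

with slopes L_s below and R_s above the break and emission F_c at the
break.  Ionic strength is computed from salt composition with fixed
dissociation stoichiometry; the conventional 1/2 sum c_i z_i^2 form is
the default and the unsquared 1/2 sum c_i |z_i| variant is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal

import numpy as np
from scipy.optimize import minimize_scalar

from actospec._fitting import ols_line
from actospec.decay import FitReport

if TYPE_CHECKING:  # pragma: no cover
    from actospec.synthetic import ConcentrationSeries, PyreneTrace

# salt -> [(ion, count, charge)]
_SALT_TABLE: dict[str, list[tuple[str, int, int]]] = {
    "KCl": [("K+", 1, +1), ("Cl-", 1, -1)],
    "NaCl": [("Na+", 1, +1), ("Cl-", 1, -1)],
    "MgCl2": [("Mg2+", 1, +2), ("Cl-", 2, -1)],
    "CaCl2": [("Ca2+", 1, +2), ("Cl-", 2, -1)],
}

#: Buffer compositions used for the three standard screening conditions
#: (molar concentrations).
SALT_PRESETS: dict[str, list[tuple[str, float]]] = {
    "low": [("KCl", 0.010), ("MgCl2", 0.0005)],
    "medium": [("KCl", 0.050), ("MgCl2", 0.001)],
    "high": [("KCl", 0.100), ("MgCl2", 0.002)],
}


@dataclass(frozen=True)
class SaltCondition:
    """Salt composition of a polymerisation buffer."""

    species: tuple[tuple[str, float], ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        for salt, conc in self.species:
            if salt not in _SALT_TABLE:
                raise ValueError(
                    f"unknown salt {salt!r}; supported: {sorted(_SALT_TABLE)}"
                )
            if conc < 0:
                raise ValueError(f"negative concentration for {salt}")

    @classmethod
    def preset(cls, label: Literal["low", "medium", "high"]) -> "SaltCondition":
        return cls(tuple(SALT_PRESETS[label]), label=label)


@dataclass
class RateResult:
    """Polymerisation rate extracted at half-maximal change."""

    slope_au_per_s: float
    t_half_s: float
    f_min: float
    f_max: float
    normalised_rate: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class BreakpointModel:
    """Two-segment critical-concentration model (continuous at the break)."""

    f_c: float
    l_s: float
    r_s: float
    cc_um: float

    def __post_init__(self) -> None:
        if self.cc_um <= 0:
            raise ValueError("critical concentration must be positive")

    def intensity(self, conc_um: np.ndarray) -> np.ndarray:
        a = np.asarray(conc_um, dtype=float)
        d = a - self.cc_um
        return self.f_c + np.where(d <= 0, self.l_s * d, self.r_s * d)


def ionic_strength(
    cond: SaltCondition, convention: Literal["squared", "as_printed"] = "squared"
) -> float:
    """Ionic strength in molar units.

    ``squared`` is the conventional 1/2 sum c_i z_i^2 over all dissociated
    ions; ``as_printed`` uses |z_i| in place of z_i^2.
    """
    total = 0.0
    for salt, conc in cond.species:
        for _ion, count, charge in _SALT_TABLE[salt]:
            c_i = conc * count
            if convention == "squared":
                total += c_i * charge**2
            elif convention == "as_printed":
                total += c_i * abs(charge)
            else:
                raise ValueError("convention must be 'squared' or 'as_printed'")
    return 0.5 * total


def extract_rate(trace: "PyreneTrace", window_frac: float = 0.05) -> RateResult:
    """Slope of a pyrene trace at 50% of its maximal change.

    The half-maximal time is located by linear interpolation of the first
    crossing of (f_min + f_max)/2; the slope is an ordinary least-squares
    fit over the points whose intensity lies within ``window_frac`` of the
    total amplitude on either side of the half-maximal level.
    """
    t = trace.time_s
    y = trace.intensity_au
    f_min = float(y.min())
    f_max = float(y.max())
    amplitude = f_max - f_min
    if amplitude <= 0:
        raise ValueError("trace has no amplitude change")
    flags: list[str] = []
    # crude noise estimate from first differences (robust to the trend)
    noise = float(np.median(np.abs(np.diff(y)))) / 0.6745
    if amplitude < 5 * noise:
        raise ValueError(
            f"amplitude {amplitude:.3g} below 5x the noise estimate {noise:.3g}"
        )

    half = 0.5 * (f_min + f_max)
    above = y >= half
    crossings = np.nonzero(above[1:] != above[:-1])[0]
    if crossings.size == 0:
        raise ValueError("trace never crosses its half-maximal level")
    if crossings.size > 1:
        flags.append(
            f"{crossings.size} half-maximal crossings; first crossing used"
        )
    i = int(crossings[0])
    # linear interpolation between the bracketing samples
    t_half = float(
        t[i] + (half - y[i]) * (t[i + 1] - t[i]) / (y[i + 1] - y[i])
    )

    lo, hi = half - window_frac * amplitude, half + window_frac * amplitude
    # contiguous block around the crossing whose intensity stays in-window
    left = i
    while left > 0 and lo <= y[left - 1] <= hi:
        left -= 1
    right = i + 1
    while right < y.size - 1 and lo <= y[right + 1] <= hi:
        right += 1
    sel_t, sel_y = t[left : right + 1], y[left : right + 1]
    if sel_t.size < 2:
        sel_t, sel_y = t[i : i + 2], y[i : i + 2]
    slope, _inter, _ssd, _isd, _r2 = ols_line(sel_t, sel_y)
    return RateResult(
        slope_au_per_s=float(slope),
        t_half_s=t_half,
        f_min=f_min,
        f_max=f_max,
        flags=flags,
    )


def normalise_rate(sample: RateResult, spontaneous: RateResult) -> float:
    """Fold rate: sample slope over the spontaneous-assembly slope."""
    if spontaneous.slope_au_per_s <= 0:
        raise ValueError("spontaneous slope must be positive")
    return sample.slope_au_per_s / spontaneous.slope_au_per_s


def _hinge_lstsq(
    conc: np.ndarray, f: np.ndarray, cc: float
) -> tuple[np.ndarray, float]:
    """Linear least squares for (f_c, l_s, r_s) at fixed breakpoint cc."""
    d = conc - cc
    design = np.column_stack(
        [np.ones_like(conc), np.minimum(d, 0.0), np.maximum(d, 0.0)]
    )
    coef, *_ = np.linalg.lstsq(design, f, rcond=None)
    resid = f - design @ coef
    return coef, float(resid @ resid)


def fit_critical_concentration(series: "ConcentrationSeries") -> FitReport:
    """Fit the two-segment breakpoint model by profiling the break position.

    For each candidate cc the remaining parameters are linear and solved
    exactly; the profile sum of squares is scanned on a dense grid over
    the interior of the concentration span and the best bracket is refined
    by bounded scalar minimisation.
    """
    conc = series.conc_um
    f = series.intensity_au
    if conc.size < 5:
        raise ValueError("need at least 5 concentrations to fit a breakpoint")

    lo, hi = float(conc[1]), float(conc[-2])
    grid = np.linspace(lo, hi, 512)
    sse = np.array([_hinge_lstsq(conc, f, cc)[1] for cc in grid])
    k = int(np.argmin(sse))
    b_lo = grid[max(k - 1, 0)]
    b_hi = grid[min(k + 1, grid.size - 1)]
    refine = minimize_scalar(
        lambda cc: _hinge_lstsq(conc, f, cc)[1],
        bounds=(b_lo, b_hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    cc_hat = float(refine.x)
    coef, best_sse = _hinge_lstsq(conc, f, cc_hat)
    f_c, l_s, r_s = map(float, coef)

    flags: list[str] = []
    if abs(l_s - r_s) < 0.05 * abs(r_s):
        flags.append("slopes differ by <5%: breakpoint unidentifiable")
    if cc_hat <= lo * 1.0000001 or cc_hat >= hi * 0.9999999:
        flags.append("breakpoint estimate at the edge of the data span")

    model = BreakpointModel(f_c=f_c, l_s=l_s, r_s=r_s, cc_um=cc_hat)
    resid = f - model.intensity(conc)
    dof = max(conc.size - 4, 1)
    # cc uncertainty from the profile curvature; linear parameters from OLS
    d2 = _profile_curvature(conc, f, cc_hat, best_sse)
    sd = {
        "f_c": float(np.sqrt(best_sse / dof)),
        "cc_um": d2,
    }
    return FitReport(
        parameters=model,
        parameter_sd=sd,
        chi_sq_reduced=float(resid @ resid) / dof,
        n_iterations=grid.size,
        converged=True,
        residuals=resid,
        flags=flags,
    )


def _profile_curvature(
    conc: np.ndarray, f: np.ndarray, cc: float, sse0: float
) -> float:
    """Approximate SD of cc from the second derivative of the profile SSE."""
    h = max(1e-4 * cc, 1e-6)
    s_plus = _hinge_lstsq(conc, f, cc + h)[1]
    s_minus = _hinge_lstsq(conc, f, cc - h)[1]
    d2 = (s_plus - 2.0 * sse0 + s_minus) / h**2
    if d2 <= 0:
        return float("nan")
    dof = max(conc.size - 4, 1)
    sigma_sq = sse0 / dof
    return float(np.sqrt(2.0 * sigma_sq / d2))
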