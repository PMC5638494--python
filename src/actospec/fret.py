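"""Inter-monomer FRET efficiency and temperature-dependent flexibility.

Donor (IAEDANS) and acceptor (IAF) labelled actin monomers are
co-polymerised so that energy transfer between neighbouring protomers
reports on filament structure.  The transfer efficiency is

    E = 1 - F_DA / F_D

where F_D and F_DA are the donor emissions integrated over the
435-485 nm band without and with acceptor present.  Because one donor
may couple to several acceptors, absolute distances are not computed;
instead the normalised transfer

    f' = E / F_DA

is followed as a function of temperature.  Relative f' (each series
normalised to its lowest temperature) rises more steeply with
temperature the more flexible the protein matrix separating the dyes is,
so comparing the slopes of relative f' versus temperature between two
conditions ranks their filament flexibility.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

from actospec._fitting import ols_line

if TYPE_CHECKING:  # pragma: no cover
    from actospec.synthetic import EmissionSpectrum

DONOR_BAND_NM = (435.0, 485.0)


@dataclass(frozen=True)
class FretRecord:
    """Donor emissions and transfer efficiency at one temperature."""

    temperature_c: float
    f_d: float
    f_da: float
    efficiency: float
    f_prime: float

    def __post_init__(self) -> None:
        if self.f_d <= 0:
            raise ValueError("donor-only emission must be positive")


@dataclass(frozen=True)
class FretSeries:
    """Temperature series of FRET records with relative f'."""

    records: tuple[FretRecord, ...]
    relative_f_prime: tuple[float, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        temps = [r.temperature_c for r in self.records]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")

    @property
    def temperatures_c(self) -> np.ndarray:
        return np.array([r.temperature_c for r in self.records])


def inner_filter_correct(
    spectrum: "EmissionSpectrum", a_ex: float = 0.0, a_em: float = 0.0
) -> "EmissionSpectrum":
    """Inner-filter correction: intensities scaled by 10^((A_ex + A_em)/2).

    A_ex and A_em are the sample absorbances at the excitation and
    emission wavelengths.  Zero absorbances (the default, for
    pre-corrected data) leave the spectrum unchanged.
    """
    if a_ex < 0 or a_em < 0:
        raise ValueError("absorbances must be non-negative")
    factor = 10.0 ** ((a_ex + a_em) / 2.0)
    return replace(spectrum, intensity_au=spectrum.intensity_au * factor)


def integrate_band(
    spectrum: "EmissionSpectrum",
    lo_nm: float = DONOR_BAND_NM[0],
    hi_nm: float = DONOR_BAND_NM[1],
) -> float:
    """Trapezoidal area under the spectrum over the closed band [lo, hi].

    The band edges are reached by linear interpolation, so the result is
    independent of how the wavelength grid is registered to the band.
    """
    wl = spectrum.wavelength_nm
    inten = spectrum.intensity_au
    if lo_nm < wl[0] or hi_nm > wl[-1]:
        raise ValueError(
            f"band [{lo_nm}, {hi_nm}] nm not covered by the grid "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    inside = (wl > lo_nm) & (wl < hi_nm)
    xs = np.concatenate(([lo_nm], wl[inside], [hi_nm]))
    ys = np.concatenate(
        (
            [np.interp(lo_nm, wl, inten)],
            inten[inside],
            [np.interp(hi_nm, wl, inten)],
        )
    )
    return float(np.trapezoid(ys, xs))


def fret_efficiency(f_d: float, f_da: float) -> float:
    """E = 1 - F_DA / F_D.

    Slightly negative values can arise from noise and are returned as-is
    (never clipped) so that averaging over replicates stays unbiased.
    """
    if f_d <= 0:
        raise ValueError("donor-only emission must be positive")
    return 1.0 - f_da / f_d


def make_record(temperature_c: float, f_d: float, f_da: float) -> FretRecord:
    """Build a FretRecord computing E and f' from the band integrals."""
    e = fret_efficiency(f_d, f_da)
    if f_da <= 0:
        raise ValueError("donor emission with acceptor must be positive")
    return FretRecord(
        temperature_c=temperature_c,
        f_d=f_d,
        f_da=f_da,
        efficiency=e,
        f_prime=e / f_da,
    )


def f_prime_series(
    records: Sequence[FretRecord], condition: str = ""
) -> FretSeries:
    """Assemble a temperature series and normalise f' to its lowest T."""
    if len(records) < 2:
        raise ValueError("need at least 2 temperatures")
    recs = tuple(sorted(records, key=lambda r: r.temperature_c))
    ref = recs[0].f_prime
    if ref == 0:
        raise ValueError("f' at the lowest temperature is zero; cannot normalise")
    rel = tuple(r.f_prime / ref for r in recs)
    return FretSeries(records=recs, relative_f_prime=rel, condition=condition)


def temperature_slope(series: FretSeries) -> dict[str, float]:
    """OLS slope of relative f' versus temperature, with SD."""
    if len(series.records) < 3:
        raise ValueError("need at least 3 temperatures for a slope")
    slope, intercept, slope_sd, intercept_sd, r_sq = ols_line(
        series.temperatures_c, np.asarray(series.relative_f_prime)
    )
    return {
        "slope_per_c": slope,
        "intercept": intercept,
        "slope_sd": slope_sd,
        "intercept_sd": intercept_sd,
        "r_squared": r_sq,
    }


def compare_slopes(series_a: FretSeries, series_b: FretSeries) -> dict[str, float]:
    """Difference of temperature slopes (a - b) with propagated SD."""
    sa = temperature_slope(series_a)
    sb = temperature_slope(series_b)
    diff = sa["slope_per_c"] - sb["slope_per_c"]
    sd = float(np.hypot(sa["slope_sd"], sb["slope_sd"]))
    return {"delta_slope_per_c": diff, "delta_slope_sd": sd}
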