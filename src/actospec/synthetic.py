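"""Seeded generators for every raw-data type the pipeline consumes.

Each generator starts from a known ground-truth parameter set, evaluates
the corresponding forward model on a sampling grid and adds i.i.d.
Gaussian noise from a seeded stream, so that every analysis stage can be
validated by forward-inverse (parameter-recovery) testing: generate with
known truth, analyse, compare.

Forward models
--------------
* polarized decays: I_VV = I (1 + 2 r)/3 and I_VH = I (1 - r)/(3 G)
  from a multi-exponential intensity decay I(t) and anisotropy decay
  r(t), so that I_VV + 2 G I_VH reconstructs I(t) exactly;
* frequency sweeps: analytic phase/modulation transforms of the decay;
* pyrene polymerisation: generalized logistic with an independent
  plateau scale (emulating the regulator-dependent saturation
  intensity); mechanistic nucleation-elongation kinetics are out of
  scope;
* critical-concentration series: continuous two-segment line;
* cosedimentation tables: band volumes back-computed from a bound-ratio
  sigmoid with molecular-weight correction;
* stopped-flow: rising biexponential;
* FRET spectra: Gaussian donor emission band; the acceptor-present
  spectrum is the donor spectrum scaled by (1 - E);
* NADH traces: straight line with slope -k [HMM] eps l.

Default grids (0-50 ns / 1024 points for decays, 0-2000 s for
polymerisation, 0-5 s for stopped flow) resolve the parameter scales of
the measurements being emulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from actospec.binding import BiexpModel, SigmoidModel
from actospec.decay import (
    FUNDAMENTAL_ANISOTROPY,
    AnisotropyDecayModel,
    DecayModel,
    phase_modulation,
)
from actospec.polymerisation import BreakpointModel

DEFAULT_DECAY_GRID_NS = np.linspace(0.0, 50.0, 1024)
DEFAULT_PYRENE_GRID_S = np.linspace(0.0, 2000.0, 600)
DEFAULT_STOPFLOW_GRID_S = np.linspace(0.0, 5.0, 1000)

#: Gaussian stand-in for the IAEDANS donor emission band (nm); only the
#: 435-485 nm integral matters downstream.
DONOR_PEAK_NM = 475.0
DONOR_WIDTH_NM = 35.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: standard deviation and stream seed."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def add(self, y: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if self.sigma == 0.0:
            return np.asarray(y, dtype=float).copy()
        r = rng if rng is not None else self.rng()
        return y + r.normal(0.0, self.sigma, size=np.shape(y))


def _check_grid(grid: np.ndarray, name: str = "grid") -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 2 or np.any(np.diff(g) <= 0):
        raise ValueError(f"{name} must be a strictly increasing 1-D array")
    return g


@dataclass(frozen=True)
class PolarizedDecayTraces:
    """Time-resolved polarized intensity pair with its G factor."""

    time_ns: np.ndarray
    i_vv: np.ndarray
    i_vh: np.ndarray
    g_factor: float = 1.0

    def __post_init__(self) -> None:
        t = _check_grid(self.time_ns, "time_ns")
        if not (self.i_vv.size == self.i_vh.size == t.size):
            raise ValueError("trace columns must have equal length")
        if self.g_factor <= 0:
            raise ValueError("G factor must be positive")
        if not (np.all(np.isfinite(self.i_vv)) and np.all(np.isfinite(self.i_vh))):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class FrequencySweep:
    """Phase-modulation sweep: frequency (MHz), phase (deg), modulation."""

    freq_mhz: np.ndarray
    phase_deg: np.ndarray
    modulation: np.ndarray

    def __post_init__(self) -> None:
        f = _check_grid(self.freq_mhz, "freq_mhz")
        if not (self.phase_deg.size == self.modulation.size == f.size):
            raise ValueError("sweep columns must have equal length")
        if np.any(self.phase_deg < 0) or np.any(self.phase_deg >= 90):
            raise ValueError("phase must lie in [0, 90) degrees")
        if np.any(self.modulation <= 0) or np.any(self.modulation > 1):
            raise ValueError("modulation must lie in (0, 1]")


@dataclass(frozen=True)
class PyreneTrace:
    """Pyrene fluorescence time course for one condition."""

    time_s: np.ndarray
    intensity_au: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = _check_grid(self.time_s, "time_s")
        if self.intensity_au.size != t.size:
            raise ValueError("trace columns must have equal length")
        if not np.all(np.isfinite(self.intensity_au)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class ConcentrationSeries:
    """Steady-state pyrene emission versus total actin concentration."""

    conc_um: np.ndarray
    intensity_au: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = _check_grid(self.conc_um, "conc_um")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if self.intensity_au.size != c.size:
            raise ValueError("series columns must have equal length")


@dataclass(frozen=True)
class DensitometryTable:
    """Per-lane gel band volumes for a cosedimentation titration."""

    lmod_total_um: np.ndarray
    band_volume_actin: np.ndarray
    band_volume_lmod: np.ndarray
    mw_actin_kda: float = 42.0
    mw_lmod_kda: float = 62.0

    def __post_init__(self) -> None:
        n = self.lmod_total_um.size
        if not (self.band_volume_actin.size == self.band_volume_lmod.size == n):
            raise ValueError("table columns must have equal length")
        if np.any(self.band_volume_actin < 0) or np.any(self.band_volume_lmod < 0):
            raise ValueError("band volumes must be non-negative")


@dataclass(frozen=True)
class StoppedFlowTrace:
    """Pyrene fluorescence change after stopped-flow mixing."""

    time_s: np.ndarray
    signal_au: np.ndarray

    def __post_init__(self) -> None:
        t = _check_grid(self.time_s, "time_s")
        if self.signal_au.size != t.size:
            raise ValueError("trace columns must have equal length")
        if not np.all(np.isfinite(self.signal_au)):
            raise ValueError("signal must be finite")


@dataclass(frozen=True)
class EmissionSpectrum:
    """Emission spectrum at one temperature and labelling condition."""

    wavelength_nm: np.ndarray
    intensity_au: np.ndarray
    temperature_c: float = 25.0
    condition: str = "donor-only"
    lmod_um: float = 0.0

    def __post_init__(self) -> None:
        wl = _check_grid(self.wavelength_nm, "wavelength_nm")
        if self.intensity_au.size != wl.size:
            raise ValueError("spectrum columns must have equal length")


@dataclass(frozen=True)
class AbsorbanceTrace:
    """A340 time course of the NADH-coupled assay."""

    time_s: np.ndarray
    a340: np.ndarray

    def __post_init__(self) -> None:
        t = _check_grid(self.time_s, "time_s")
        if self.a340.size != t.size:
            raise ValueError("trace columns must have equal length")


# ---------------------------------------------------------------------------
# generators


def gen_polarized_decay(
    decay: DecayModel,
    aniso: AnisotropyDecayModel | None,
    g_factor: float = 1.0,
    grid_ns: np.ndarray = DEFAULT_DECAY_GRID_NS,
    noise: NoiseSpec = NoiseSpec(),
) -> PolarizedDecayTraces:
    """Polarized decay pair from intensity and anisotropy models.

    The noiseless traces satisfy I_VV + 2 G I_VH = I(t) exactly, with
    I_VV = I (1 + 2 r)/3 and I_VH = I (1 - r)/(3 G).  ``aniso=None``
    generates isotropic emission (r = 0).
    """
    t = _check_grid(grid_ns, "grid_ns")
    if g_factor <= 0:
        raise ValueError("G factor must be positive")
    if aniso is not None and sum(aniso.fractional_anisotropies) > FUNDAMENTAL_ANISOTROPY + 1e-12:
        raise ValueError(
            "total fractional anisotropy exceeds the fundamental limit 0.4"
        )
    intensity = decay.intensity(t)
    r = aniso.anisotropy(t) if aniso is not None else np.zeros_like(t)
    i_vv = intensity * (1.0 + 2.0 * r) / 3.0
    i_vh = intensity * (1.0 - r) / (3.0 * g_factor)
    rng = noise.rng()
    return PolarizedDecayTraces(
        time_ns=t,
        i_vv=noise.add(i_vv, rng),
        i_vh=noise.add(i_vh, rng),
        g_factor=g_factor,
    )


def gen_frequency_sweep(
    decay: DecayModel,
    freqs_mhz: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
) -> FrequencySweep:
    """Phase/modulation sweep from the analytic transforms of the decay.

    Noise is added to phase (degrees) and modulation with the same sigma;
    results are clipped to the physical ranges so the sweep stays valid.
    """
    f = _check_grid(np.asarray(freqs_mhz, dtype=float), "freqs_mhz")
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    phase, mod = phase_modulation(decay, f)
    rng = noise.rng()
    phase = np.clip(noise.add(phase, rng), 0.0, 90.0 - 1e-9)
    mod = np.clip(noise.add(mod, rng), 1e-9, 1.0)
    return FrequencySweep(freq_mhz=f, phase_deg=phase, modulation=mod)


def logistic_pyrene(
    t: np.ndarray,
    f0: float,
    fmax: float,
    t_half_s: float,
    steepness: float,
    plateau_scale: float = 1.0,
) -> np.ndarray:
    """Generalized logistic polymerisation curve.

    Plateau = f0 + plateau_scale (fmax - f0); the maximal slope
    plateau_scale (fmax - f0) steepness / 4 occurs at ``t_half_s``.
    """
    amplitude = plateau_scale * (fmax - f0)
    return f0 + amplitude / (1.0 + np.exp(-steepness * (t - t_half_s)))


def gen_pyrene_curve(
    f0: float,
    fmax: float,
    t_half_s: float,
    steepness: float,
    plateau_scale: float = 1.0,
    grid_s: np.ndarray = DEFAULT_PYRENE_GRID_S,
    noise: NoiseSpec = NoiseSpec(),
    label: str = "",
) -> PyreneTrace:
    """Sigmoidal pyrene polymerisation trace.

    ``plateau_scale`` scales the saturation intensity independently of
    the kinetics, emulating the regulator-concentration-dependent pyrene
    quantum-yield increase on filament binding.
    """
    if fmax <= f0:
        raise ValueError("fmax must exceed f0")
    if steepness <= 0:
        raise ValueError("steepness must be positive")
    if plateau_scale < 1.0:
        raise ValueError("plateau_scale must be >= 1")
    t = _check_grid(grid_s, "grid_s")
    if not (t[0] <= t_half_s <= t[-1]):
        raise ValueError("t_half must lie within the time grid")
    if t.size < 50:
        raise ValueError("grid must have at least 50 points")
    y = logistic_pyrene(t, f0, fmax, t_half_s, steepness, plateau_scale)
    return PyreneTrace(time_s=t, intensity_au=noise.add(y), label=label)


def gen_cc_series(
    model: BreakpointModel,
    concs_um: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
) -> ConcentrationSeries:
    """Two-segment piecewise-linear concentration series.

    A breakpoint outside the concentration span does not abort
    generation but flags the series (the downstream fit will be
    unidentifiable).
    """
    c = _check_grid(np.asarray(concs_um, dtype=float), "concs_um")
    if c.size < 5:
        raise ValueError("need at least 5 concentrations")
    flags: tuple[str, ...] = ()
    if not (c[0] < model.cc_um < c[-1]):
        flags = ("breakpoint outside the concentration span: fit unidentifiable",)
    y = model.intensity(c)
    return ConcentrationSeries(conc_um=c, intensity_au=noise.add(y), flags=flags)


def gen_cosed_table(
    iso: SigmoidModel,
    lmod_concs_um: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
    actin_band_volume: float = 1000.0,
    mw_actin_kda: float = 42.0,
    mw_lmod_kda: float = 62.0,
) -> DensitometryTable:
    """Densitometry table realising a bound-ratio sigmoid.

    Actin band volumes are constant (saturating F-actin pellets fully);
    leiomodin band volumes are back-computed so that the MW-corrected
    ratio reproduces the sigmoid.  Noise is applied to the band volumes.
    """
    x = np.asarray(lmod_concs_um, dtype=float)
    ratios = iso.ratio(x)
    v_actin = np.full_like(x, actin_band_volume)
    v_lmod = ratios * actin_band_volume * mw_lmod_kda / mw_actin_kda
    rng = noise.rng()
    return DensitometryTable(
        lmod_total_um=x,
        band_volume_actin=np.clip(noise.add(v_actin, rng), 0.0, None),
        band_volume_lmod=np.clip(noise.add(v_lmod, rng), 0.0, None),
        mw_actin_kda=mw_actin_kda,
        mw_lmod_kda=mw_lmod_kda,
    )


def gen_stopped_flow(
    model: BiexpModel,
    grid_s: np.ndarray = DEFAULT_STOPFLOW_GRID_S,
    noise: NoiseSpec = NoiseSpec(),
) -> StoppedFlowTrace:
    """Rising biexponential stopped-flow transient starting at zero."""
    t = _check_grid(grid_s, "grid_s")
    if t[0] < 0:
        raise ValueError("stopped-flow time must start at or after zero")
    y = model.signal(t)
    return StoppedFlowTrace(time_s=t, signal_au=noise.add(y))


def donor_spectrum_shape(
    wavelength_nm: np.ndarray,
    peak_nm: float = DONOR_PEAK_NM,
    width_nm: float = DONOR_WIDTH_NM,
    amplitude: float = 100.0,
) -> np.ndarray:
    """Gaussian donor emission band (arbitrary units)."""
    wl = np.asarray(wavelength_nm, dtype=float)
    return amplitude * np.exp(-0.5 * ((wl - peak_nm) / width_nm) ** 2)


def gen_fret_spectra(
    e_by_temperature: Sequence[tuple[float, float]],
    wavelength_nm: np.ndarray | None = None,
    peak_nm: float = DONOR_PEAK_NM,
    width_nm: float = DONOR_WIDTH_NM,
    amplitude: float = 100.0,
    lmod_um: float = 0.0,
    noise: NoiseSpec = NoiseSpec(),
) -> list[tuple[EmissionSpectrum, EmissionSpectrum]]:
    """Donor-only / donor+acceptor spectrum pairs per temperature.

    The acceptor-present spectrum equals the donor-only spectrum scaled
    by (1 - E), so the 435-485 nm band integrals satisfy
    F_DA / F_D = 1 - E exactly in the noiseless case.
    """
    if wavelength_nm is None:
        wavelength_nm = np.arange(380.0, 600.0 + 1e-9, 1.0)
    wl = _check_grid(wavelength_nm, "wavelength_nm")
    step = float(np.max(np.diff(wl)))
    if step > 2.0:
        raise ValueError("grid step must be <= 2 nm across the donor band")
    rng = noise.rng()
    out: list[tuple[EmissionSpectrum, EmissionSpectrum]] = []
    for temp_c, e in e_by_temperature:
        if not 0.0 <= e < 1.0:
            raise ValueError(f"transfer efficiency {e} outside [0, 1)")
        donor = donor_spectrum_shape(wl, peak_nm, width_nm, amplitude)
        da = donor * (1.0 - e)
        out.append(
            (
                EmissionSpectrum(
                    wavelength_nm=wl,
                    intensity_au=np.clip(noise.add(donor, rng), 0.0, None),
                    temperature_c=temp_c,
                    condition="donor-only",
                    lmod_um=lmod_um,
                ),
                EmissionSpectrum(
                    wavelength_nm=wl,
                    intensity_au=np.clip(noise.add(da, rng), 0.0, None),
                    temperature_c=temp_c,
                    condition="donor+acceptor",
                    lmod_um=lmod_um,
                ),
            )
        )
    return out


def gen_nadh_trace(
    k_target: float,
    hmm_um: float,
    eps_path_per_m: float = 6220.0,
    duration_s: float = 300.0,
    n_points: int = 300,
    a340_start: float = 0.93,
    noise: NoiseSpec = NoiseSpec(),
) -> AbsorbanceTrace:
    """Linearly decreasing A340 trace for a given ATPase activity.

    The noiseless slope is -k [HMM] eps l with [HMM] converted to molar,
    so the downstream rate computation recovers ``k_target`` exactly.
    The default initial absorbance corresponds to 0.15 mM NADH in a 1 cm
    cuvette.
    """
    if k_target < 0:
        raise ValueError("k_target must be non-negative")
    if eps_path_per_m <= 0:
        raise ValueError("eps * path must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    t = np.linspace(0.0, duration_s, n_points)
    slope = -k_target * hmm_um * 1e-6 * eps_path_per_m
    a = a340_start + slope * t
    return AbsorbanceTrace(time_s=t, a340=np.clip(noise.add(a), 0.0, None))
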