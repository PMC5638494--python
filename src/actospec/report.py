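"""End-to-end demo pipeline: generate, analyse, tabulate recovery.

``run_demo`` generates one synthetic dataset per assay at reference
parameter values typical of cardiac-leiomodin characterisation
(lifetime 2.92 ns, slow correlation time
35.9 ns, steady-state anisotropy 0.083, critical concentration 0.12 uM,
FRET efficiencies 26% / 32%, polymerisation fold rates 12 and 4, ATPase
rates 0.04 / 0.164 uM_ATP s^-1 uM_protein^-1, 40% residual activity at
3 uM regulator), runs the matching analysis stage on each, and tabulates
recovered versus true values.  With the default zero noise every row
recovers its truth to numerical precision; with noise the table shows
the realised errors.  Reports are deterministic for a fixed config+seed
and carry a provenance block (config hash, seed, version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

import actospec
from actospec import synthetic
from actospec.atpase import activity_profile, rate_from_trace
from actospec.binding import SigmoidModel, densitometry_ratio, fit_sigmoid
from actospec.decay import (
    AnisotropyDecayModel,
    DecayModel,
    PolarizedIntensities,
    average_lifetime,
    compute_anisotropy_trace,
    fit_anisotropy_decay,
    fit_intensity_decay,
    steady_state_anisotropy,
)
from actospec.fret import fret_efficiency, integrate_band
from actospec.polymerisation import (
    BreakpointModel,
    extract_rate,
    fit_critical_concentration,
    normalise_rate,
)

#: actin concentration grid (uM) of the critical-concentration assay
CC_GRID_UM = (0.03, 0.05, 0.1, 0.3, 0.5, 0.7, 1.0, 3.0, 5.0)


@dataclass
class RunConfig:
    """Demo-run configuration; every field has a default.

    ``sigma_*`` are per-assay additive noise SDs in the trace's own
    intensity units (zero = noiseless recovery check).
    """

    seed: int = 0
    sigma_decay: float = 0.0
    sigma_sweep: float = 0.0
    sigma_pyrene: float = 0.0
    sigma_cc: float = 0.0
    sigma_cosed: float = 0.0
    sigma_fret: float = 0.0
    sigma_nadh: float = 0.0
    lifetime_ns: float = 2.92
    correlation_times_ns: tuple[float, float] = (0.5, 35.9)
    fractional_anisotropies: tuple[float, float] = (0.1, 0.15)
    steady_state_r: float = 0.083
    g_factor: float = 1.1
    cc_um: float = 0.12
    fret_e_bare: float = 0.26
    fret_e_lmod: float = 0.32
    fold_rate_max: float = 12.0
    fold_rate_high_salt: float = 4.0
    atpase_basal: float = 0.04
    atpase_activated: float = 0.164
    atpase_residual_fraction: float = 0.4
    hmm_um: float = 0.5

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        clean = dict(data)
        for key in ("correlation_times_ns", "fractional_anisotropies"):
            if key in clean and isinstance(clean[key], list):
                clean[key] = tuple(clean[key])
        return cls(**clean)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Report:
    """Recovery table plus provenance."""

    rows: pd.DataFrame
    config_hash: str
    seed: int
    version: str = actospec.__version__
    errors: list[str] = field(default_factory=list)

    def body_text(self) -> str:
        lines = [
            "actospec demo report",
            f"version: {self.version}",
            f"config_hash: {self.config_hash}",
            f"seed: {self.seed}",
            "",
            self.rows.to_string(
                index=False,
                float_format=lambda v: f"{v:.6g}",
            ),
        ]
        if self.errors:
            lines += ["", "stage errors:"] + [f"  - {e}" for e in self.errors]
        return "\n".join(lines) + "\n"


def _row(stage, quantity, truth, recovered, units=""):
    rel = abs(recovered - truth) / abs(truth) if truth != 0 else abs(recovered)
    return {
        "stage": stage,
        "quantity": quantity,
        "truth": float(truth),
        "recovered": float(recovered),
        "rel_error": float(rel),
        "units": units,
    }


def run_demo(config: RunConfig | None = None) -> Report:
    """Generate every synthetic assay, analyse it, tabulate recovery."""
    cfg = config or RunConfig()
    rows: list[dict] = []
    errors: list[str] = []
    seed = cfg.seed

    def noise(sigma: float, offset: int) -> synthetic.NoiseSpec:
        return synthetic.NoiseSpec(sigma=sigma, seed=(seed + offset) % 2**31)

    # --- lifetime via frequency-domain fit
    try:
        decay_true = DecayModel((1.0,), (cfg.lifetime_ns,))
        sweep = synthetic.gen_frequency_sweep(
            decay_true, np.geomspace(5.0, 200.0, 10), noise(cfg.sigma_sweep, 1)
        )
        fit = fit_intensity_decay(sweep, n_components=1)
        rows.append(
            _row(
                "decay",
                "average lifetime",
                cfg.lifetime_ns,
                average_lifetime(fit.require_converged()),
                "ns",
            )
        )
    except Exception as exc:  # noqa: BLE001 - stage failures recorded, run continues
        errors.append(f"decay/lifetime: {exc}")

    # --- slow rotational correlation time via anisotropy decay
    try:
        aniso_true = AnisotropyDecayModel(
            cfg.fractional_anisotropies, cfg.correlation_times_ns
        )
        traces = synthetic.gen_polarized_decay(
            decay_true,
            aniso_true,
            g_factor=1.0,
            grid_ns=np.linspace(0.0, 150.0, 2048),
            noise=noise(cfg.sigma_decay, 2),
        )
        atrace = compute_anisotropy_trace(traces)
        afit = fit_anisotropy_decay(
            atrace.time_ns, atrace.r, n_components=2, weights=atrace.total_intensity
        )
        slow = afit.require_converged().correlation_times_ns[-1]
        rows.append(
            _row(
                "decay",
                "slow rotational correlation time",
                cfg.correlation_times_ns[-1],
                slow,
                "ns",
            )
        )
    except Exception as exc:  # noqa: BLE001
        errors.append(f"decay/anisotropy: {exc}")

    # --- steady-state anisotropy with G correction
    try:
        r_true = cfg.steady_state_r
        g = cfg.g_factor
        pol = PolarizedIntensities(
            i_vv=(1.0 + 2.0 * r_true) / 3.0,
            i_vh=(1.0 - r_true) / (3.0 * g),
        )
        rows.append(
            _row(
                "decay",
                "steady-state anisotropy",
                r_true,
                steady_state_anisotropy(pol, g),
            )
        )
    except Exception as exc:  # noqa: BLE001
        errors.append(f"decay/steady-state: {exc}")

    # --- critical concentration
    try:
        bp_true = BreakpointModel(f_c=10.0, l_s=4.0, r_s=80.0, cc_um=cfg.cc_um)
        series = synthetic.gen_cc_series(bp_true, CC_GRID_UM, noise(cfg.sigma_cc, 3))
        cc_fit = fit_critical_concentration(series)
        rows.append(
            _row(
                "polymerisation",
                "critical concentration",
                cfg.cc_um,
                cc_fit.require_converged().cc_um,
                "uM",
            )
        )
    except Exception as exc:  # noqa: BLE001
        errors.append(f"polymerisation/cc: {exc}")

    # --- fold polymerisation rates
    try:
        for name, fold in (
            ("max fold rate", cfg.fold_rate_max),
            ("high-salt fold rate", cfg.fold_rate_high_salt),
        ):
            spont = synthetic.gen_pyrene_curve(
                f0=0.0,
                fmax=1.0,
                t_half_s=1000.0,
                steepness=0.004,
                noise=noise(cfg.sigma_pyrene, 4),
            )
            fast = synthetic.gen_pyrene_curve(
                f0=0.0,
                fmax=1.0,
                t_half_s=300.0,
                steepness=0.004 * fold,
                noise=noise(cfg.sigma_pyrene, 5),
            )
            rows.append(
                _row(
                    "polymerisation",
                    name,
                    fold,
                    normalise_rate(extract_rate(fast), extract_rate(spont)),
                    "fold",
                )
            )
    except Exception as exc:  # noqa: BLE001
        errors.append(f"polymerisation/rate: {exc}")

    # --- cosedimentation sigmoid recovery
    try:
        iso_true = SigmoidModel(y_min=0.0, y_max=0.5, x0_um=1.5, dx_um=0.4)
        table = synthetic.gen_cosed_table(
            iso_true, np.linspace(0.05, 5.0, 12), noise(cfg.sigma_cosed, 6)
        )
        ratios = densitometry_ratio(table)
        sfit = fit_sigmoid(ratios["lmod_total_um"], ratios["bound_ratio"])
        rows.append(
            _row(
                "binding",
                "half-saturation x0",
                iso_true.x0_um,
                sfit.require_converged().x0_um,
                "uM",
            )
        )
    except Exception as exc:  # noqa: BLE001
        errors.append(f"binding/cosed: {exc}")

    # --- FRET efficiencies
    try:
        for name, e_true, lmod in (
            ("FRET efficiency bare filaments", cfg.fret_e_bare, 0.0),
            ("FRET efficiency with Lmod2", cfg.fret_e_lmod, 5.0),
        ):
            (donor, da), = synthetic.gen_fret_spectra(
                [(25.0, e_true)], lmod_um=lmod, noise=noise(cfg.sigma_fret, 7)
            )
            e_hat = fret_efficiency(integrate_band(donor), integrate_band(da))
            rows.append(_row("fret", name, e_true, e_hat))
    except Exception as exc:  # noqa: BLE001
        errors.append(f"fret/efficiency: {exc}")

    # --- ATPase rates and inhibition profile
    try:
        for name, k_true in (
            ("basal ATPase rate", cfg.atpase_basal),
            ("actin-activated ATPase rate", cfg.atpase_activated),
        ):
            trace = synthetic.gen_nadh_trace(
                k_true, cfg.hmm_um, noise=noise(cfg.sigma_nadh, 8)
            )
            res = rate_from_trace(trace, cfg.hmm_um)
            rows.append(_row("atpase", name, k_true, res.rate_k, "uM_ATP/s/uM"))
        k0 = cfg.atpase_activated
        results = []
        for lmod, k in ((0.0, k0), (3.0, cfg.atpase_residual_fraction * k0)):
            tr = synthetic.gen_nadh_trace(k, cfg.hmm_um, noise=noise(cfg.sigma_nadh, 9))
            results.append((lmod, rate_from_trace(tr, cfg.hmm_um)))
        prof = activity_profile(results)
        rows.append(
            _row(
                "atpase",
                "fraction of control at 3 uM",
                cfg.atpase_residual_fraction,
                float(prof.fraction_of_control[prof.lmod_um == 3.0][0]),
            )
        )
    except Exception as exc:  # noqa: BLE001
        errors.append(f"atpase: {exc}")

    return Report(
        rows=pd.DataFrame(rows),
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        errors=errors,
    )


def write_report(report: Report, out_dir: str | Path, fmt: str = "text") -> list[Path]:
    """Serialize a report as plain text and/or machine-readable YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    if fmt in ("text", "both"):
        p = out / "report.txt"
        p.write_text(report.body_text(), encoding="utf-8")
        paths.append(p)
    if fmt in ("structured", "both"):
        p = out / "report.yaml"
        payload = {
            "version": report.version,
            "config_hash": report.config_hash,
            "seed": report.seed,
            "errors": report.errors,
            "rows": report.rows.to_dict(orient="records"),
        }
        p.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
        paths.append(p)
    if not paths:
        raise ValueError("fmt must be 'text', 'structured' or 'both'")
    return paths
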