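"""Delimited-text I/O for every trace/table type in the pipeline.

All interchange formats are comma-separated UTF-8 with a header row and
'.' decimal separator.  Units are fixed at the interface and declared in
the headers: time in ns (decays) or s (kinetic traces), concentrations
in uM, wavelengths in nm.  Schemas are matched by column name,
order-insensitively; extra columns are preserved.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from actospec.synthetic import (
    AbsorbanceTrace,
    ConcentrationSeries,
    DensitometryTable,
    EmissionSpectrum,
    FrequencySweep,
    PolarizedDecayTraces,
    PyreneTrace,
    StoppedFlowTrace,
)

#: canonical column names per trace type
SCHEMAS: dict[str, tuple[str, ...]] = {
    "polarized_decay": ("time_ns", "i_vv", "i_vh"),
    "frequency_sweep": ("freq_mhz", "phase_deg", "modulation"),
    "pyrene_trace": ("time_s", "intensity_au"),
    "concentration_series": ("conc_um", "intensity_au"),
    "densitometry": ("lmod_total_um", "band_volume_actin", "band_volume_lmod"),
    "stopped_flow": ("time_s", "signal_au"),
    "spectrum": ("wavelength_nm", "intensity_au"),
    "absorbance": ("time_s", "a340"),
}


def read_table(path: str | Path, schema: str | Sequence[str]) -> pd.DataFrame:
    """Read and validate a delimited table against a schema.

    ``schema`` is either a key of :data:`SCHEMAS` or an explicit column
    list.  Missing columns, non-numeric cells and empty files raise with
    row/column context; extra columns are kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    required = SCHEMAS[schema] if isinstance(schema, str) else tuple(schema)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2} "
                f"(1-based, counting the header)"
            )
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0])
            raise ValueError(f"{path}: missing value in column {col!r}, row {row + 2}")
        df[col] = coerced
    return df


def _col(df: pd.DataFrame, name: str) -> np.ndarray:
    return df[name].to_numpy(dtype=float)


def read_polarized_decay(path: str | Path, g_factor: float = 1.0) -> PolarizedDecayTraces:
    df = read_table(path, "polarized_decay")
    return PolarizedDecayTraces(
        time_ns=_col(df, "time_ns"),
        i_vv=_col(df, "i_vv"),
        i_vh=_col(df, "i_vh"),
        g_factor=g_factor,
    )


def read_frequency_sweep(path: str | Path) -> FrequencySweep:
    df = read_table(path, "frequency_sweep")
    return FrequencySweep(
        freq_mhz=_col(df, "freq_mhz"),
        phase_deg=_col(df, "phase_deg"),
        modulation=_col(df, "modulation"),
    )


def read_pyrene_trace(path: str | Path, label: str = "") -> PyreneTrace:
    df = read_table(path, "pyrene_trace")
    return PyreneTrace(
        time_s=_col(df, "time_s"), intensity_au=_col(df, "intensity_au"), label=label
    )


def read_concentration_series(path: str | Path) -> ConcentrationSeries:
    df = read_table(path, "concentration_series")
    return ConcentrationSeries(
        conc_um=_col(df, "conc_um"), intensity_au=_col(df, "intensity_au")
    )


def read_densitometry(path: str | Path) -> DensitometryTable:
    df = read_table(path, "densitometry")
    kwargs = {}
    if "mw_actin_kda" in df.columns:
        kwargs["mw_actin_kda"] = float(df["mw_actin_kda"].iloc[0])
    if "mw_lmod_kda" in df.columns:
        kwargs["mw_lmod_kda"] = float(df["mw_lmod_kda"].iloc[0])
    return DensitometryTable(
        lmod_total_um=_col(df, "lmod_total_um"),
        band_volume_actin=_col(df, "band_volume_actin"),
        band_volume_lmod=_col(df, "band_volume_lmod"),
        **kwargs,
    )


def read_stopped_flow(path: str | Path) -> StoppedFlowTrace:
    df = read_table(path, "stopped_flow")
    return StoppedFlowTrace(time_s=_col(df, "time_s"), signal_au=_col(df, "signal_au"))


def read_spectrum(
    path: str | Path,
    temperature_c: float = 25.0,
    condition: str = "donor-only",
    lmod_um: float = 0.0,
) -> EmissionSpectrum:
    df = read_table(path, "spectrum")
    if "temperature_c" in df.columns:
        temperature_c = float(df["temperature_c"].iloc[0])
    return EmissionSpectrum(
        wavelength_nm=_col(df, "wavelength_nm"),
        intensity_au=_col(df, "intensity_au"),
        temperature_c=temperature_c,
        condition=condition,
        lmod_um=lmod_um,
    )


def read_absorbance(path: str | Path) -> AbsorbanceTrace:
    df = read_table(path, "absorbance")
    return AbsorbanceTrace(time_s=_col(df, "time_s"), a340=_col(df, "a340"))


# ---------------------------------------------------------------------------
# writers


def _write_csv(path: Path, data: dict[str, np.ndarray]) -> None:
    pd.DataFrame(data).to_csv(path, index=False)


def write_trace(obj, path: str | Path) -> Path:
    """Write any trace/table type to CSV, dispatching on its type."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, PolarizedDecayTraces):
        _write_csv(path, {"time_ns": obj.time_ns, "i_vv": obj.i_vv, "i_vh": obj.i_vh})
    elif isinstance(obj, FrequencySweep):
        _write_csv(
            path,
            {
                "freq_mhz": obj.freq_mhz,
                "phase_deg": obj.phase_deg,
                "modulation": obj.modulation,
            },
        )
    elif isinstance(obj, PyreneTrace):
        _write_csv(path, {"time_s": obj.time_s, "intensity_au": obj.intensity_au})
    elif isinstance(obj, ConcentrationSeries):
        _write_csv(path, {"conc_um": obj.conc_um, "intensity_au": obj.intensity_au})
    elif isinstance(obj, DensitometryTable):
        _write_csv(
            path,
            {
                "lmod_total_um": obj.lmod_total_um,
                "band_volume_actin": obj.band_volume_actin,
                "band_volume_lmod": obj.band_volume_lmod,
            },
        )
    elif isinstance(obj, StoppedFlowTrace):
        _write_csv(path, {"time_s": obj.time_s, "signal_au": obj.signal_au})
    elif isinstance(obj, EmissionSpectrum):
        _write_csv(
            path, {"wavelength_nm": obj.wavelength_nm, "intensity_au": obj.intensity_au}
        )
    elif isinstance(obj, AbsorbanceTrace):
        _write_csv(path, {"time_s": obj.time_s, "a340": obj.a340})
    else:
        raise TypeError(f"no CSV writer for {type(obj).__name__}")
    return path


def write_sidecar(path: str | Path, ground_truth: dict, seed: int) -> Path:
    """YAML sidecar carrying ground-truth parameters and the noise seed."""
    path = Path(path)
    path.write_text(
        yaml.safe_dump({"ground_truth": ground_truth, "seed": seed}, sort_keys=True),
        encoding="utf-8",
    )
    return path


def read_sidecar(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8"))
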