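"""File formats: RMM time-series CSV, cell-summary CSV, and run config.

The RMM CSV is a deliberately open stand-in for proprietary
rhinomanometer exports: comma-separated, UTF-8, '.' decimals, mandatory
header.  The flow column name declares its unit (``flow_mL_s`` or
``flow_m3_s``); values are normalised to strict SI on read.  Floats are
written in shortest round-trip representation so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import core
from .core import DuctModel, FluidProperties, FrictionPolicy, FrictionRegime
from .errors import OrderingError, SchemaError
from .waveforms import (
    BreathingProtocol,
    NoiseModel,
    Phase,
    RmmTimeSeries,
    Side,
    WaveformKind,
    label_phases,
)

FLOW_COLUMNS = {"flow_mL_s": 1e-6, "flow_m3_s": 1.0}
REQUIRED_COLUMNS = ("time_s", "pressure_Pa", "side", "phase")


def _fmt(x: float) -> str:
    """Shortest representation that round-trips the float exactly."""
    return repr(float(x))


def write_rmm_csv(series: RmmTimeSeries, path: "str | Path", flow_unit: str = "mL_per_s") -> None:
    """Write an RMM series to CSV with the declared flow unit."""
    if flow_unit == "mL_per_s":
        col, scale = "flow_mL_s", 1e6
    elif flow_unit == "m3_per_s":
        col, scale = "flow_m3_s", 1.0
    else:
        raise SchemaError(f"unknown flow unit {flow_unit!r}")
    phases = series.phase_labels()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"time_s,{col},pressure_Pa,side,phase\n")
        for t, q, p, ph in zip(series.time, series.flowrate, series.pressure, phases):
            fh.write(f"{_fmt(t)},{_fmt(q * scale)},{_fmt(p)},{series.side.value},{ph}\n")


def _finite_difference(t: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Central differences of Q(t), one-sided at the edges."""
    return np.gradient(q, t, edge_order=1)


def read_rmm_csv(path: "str | Path") -> RmmTimeSeries:
    """Read an RMM series from CSV, normalising units to SI.

    The flow derivative is reconstructed by central finite differences
    (one-sided at the edges).  ``phase=auto`` rows are labelled from
    the flow sign (positive = inspiration).  Malformed rows and
    non-monotone time stamps are reported with their line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    flow_cols = [c for c in df.columns if c in FLOW_COLUMNS]
    if not flow_cols:
        raise SchemaError(
            f"{path}: missing flow column (expected one of {sorted(FLOW_COLUMNS)})"
        )
    missing = [c for c in ("time_s", "pressure_Pa", "side") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    flow_col = flow_cols[0]
    for col in ("time_s", flow_col, "pressure_Pa"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.where(bad)[0][0]) + 2  # +1 header, +1 one-based
            raise SchemaError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col])
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.where(dt <= 0)[0][0]) + 3  # offending (second) row
        raise OrderingError(f"{path}: time not strictly increasing at line {line}")
    q = df[flow_col].to_numpy(dtype=float) * FLOW_COLUMNS[flow_col]
    p = df["pressure_Pa"].to_numpy(dtype=float)
    sides = set(df["side"].astype(str))
    if not sides <= {"left", "right"}:
        raise SchemaError(f"{path}: side must be left/right, got {sorted(sides)}")
    if len(sides) != 1:
        raise SchemaError(f"{path}: one series per file; found sides {sorted(sides)}")
    side = Side(sides.pop())
    if "phase" in df.columns:
        raw = df["phase"].astype(str).to_numpy()
        if np.all(raw == "auto"):
            phase = label_phases(q, inspiration_sign=1)
        else:
            valid = {Phase.INSPIRATION.value, Phase.EXPIRATION.value}
            bad = ~np.isin(raw, sorted(valid))
            if bad.any():
                line = int(np.where(bad)[0][0]) + 2
                raise SchemaError(f"{path}: invalid phase label at line {line}")
            phase = raw.astype(object)
    else:
        phase = label_phases(q, inspiration_sign=1)
    return RmmTimeSeries(
        time=t, flowrate=q, flow_derivative=_finite_difference(t, q),
        pressure=p, side=side, phase=phase, provenance=str(path),
    )


def read_cell_csv(path: "str | Path") -> pd.DataFrame:
    """Read a per-cell CFD summary CSV (u, y, cell_volume|dx, epsilon[, tau_w])."""
    df = pd.read_csv(path)
    if "cell_volume" not in df.columns and "dx" not in df.columns:
        raise SchemaError(f"{path}: need a cell_volume or dx column")
    missing = [c for c in ("u", "y", "epsilon") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat, serialisable description of a full synthetic run.

    A run is fully reproducible from (config, seed): the config
    round-trips losslessly through YAML, and its SHA-256 hash is logged
    by every CLI stage.
    """

    fluid_preset: str = "standard"          # standard | rounded_nu | explicit
    density: Optional[float] = None
    dynamic_viscosity: Optional[float] = None
    hydraulic_diameter: float = 10e-3
    length: float = 0.1
    relative_roughness: float = 0.0
    waveform: str = "sine"
    peak_flowrate: float = 600e-6
    period: float = 5.0
    phase_offset: float = 0.0
    n_cycles: int = 1
    friction: str = "blended"               # laminar | haaland | blended
    sampling_rate: Optional[float] = None
    pressure_noise_sd: float = 0.0
    dh_jitter_cv: float = 0.0
    seed: int = 0
    side: str = "right"
    fit_phase_scope: str = "both"
    fit_fixed_length: float = 0.1
    diag_time_step: float = 1e-5
    diag_bin_width: float = 0.1

    def fluid(self) -> FluidProperties:
        if self.fluid_preset == "standard":
            return core.AIR_STANDARD
        if self.fluid_preset == "rounded_nu":
            return core.AIR_ROUNDED_NU
        if self.fluid_preset == "explicit":
            if self.density is None or self.dynamic_viscosity is None:
                raise SchemaError("explicit fluid preset needs density and dynamic_viscosity")
            return FluidProperties(self.density, self.dynamic_viscosity)
        raise SchemaError(f"unknown fluid preset {self.fluid_preset!r}")

    def duct(self) -> DuctModel:
        return DuctModel(self.hydraulic_diameter, self.length, self.relative_roughness)

    def protocol(self) -> BreathingProtocol:
        return BreathingProtocol(
            peak_flowrate=self.peak_flowrate, period=self.period,
            phase_offset=self.phase_offset, n_cycles=self.n_cycles,
            waveform_kind=WaveformKind(self.waveform),
        )

    def friction_policy(self) -> FrictionPolicy:
        return friction_policy_from_name(self.friction)

    def noise(self) -> NoiseModel:
        return NoiseModel(
            pressure_noise_sd=self.pressure_noise_sd,
            dh_jitter_cv=self.dh_jitter_cv,
            random_seed=self.seed,
        )

    def to_yaml(self, path: "str | Path") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def friction_policy_from_name(name: str) -> FrictionPolicy:
    mapping = {
        "laminar": core.LAMINAR,
        "haaland": core.HAALAND,
        "turbulent": core.HAALAND,
        "blended": core.BLENDED,
    }
    try:
        return mapping[name]
    except KeyError:
        raise SchemaError(
            f"unknown friction policy {name!r} (expected laminar/haaland/blended)"
        ) from None
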