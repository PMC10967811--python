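"""Dimensionless resolution diagnostics for nasal-airflow CFD fields.

Operates on tabular per-cell summaries exported from a solver (velocity
magnitude, wall distance, cell volume, turbulent dissipation rate, wall
shear stress) — never on the solution fields themselves.  The battery
covers wall units and the law of the wall, the CFL number, Kolmogorov
microscales, the WALE subgrid mixing length, and histograms of the
resolution ratios l_LES/eta and dt/tau_eta with their exceedance
fractions (the share of cells coarser than the Kolmogorov scales).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .core import VON_KARMAN, FluidProperties
from .errors import (
    EmptyReportError,
    InvalidParameterError,
    ScalesUndefinedError,
)

#: Coefficient capping the WALE mixing length at 0.325 * Delta.
WALE_CAP = 0.325
#: Log-law constants: u+ = ln(y+)/KAPPA_LOG + B_LOG in the log layer.
KAPPA_LOG = 0.41
B_LOG = 5.0
#: Layer bounds in wall units.
VISCOUS_SUBLAYER_MAX = 5.0
LOG_LAYER_MIN = 35.0


@dataclass(frozen=True)
class WallSample:
    """Near-wall sample: wall shear stress tau_w (Pa) and distance y (m)."""

    wall_shear_stress: float
    wall_distance: float

    def __post_init__(self) -> None:
        if self.wall_shear_stress < 0:
            raise InvalidParameterError("wall_shear_stress must be >= 0")
        if self.wall_distance < 0:
            raise InvalidParameterError("wall_distance must be >= 0")

    def shear_velocity(self, fluid: FluidProperties) -> float:
        """u_tau = sqrt(tau_w / rho)."""
        return math.sqrt(self.wall_shear_stress / fluid.density)


@dataclass(frozen=True)
class CellSample:
    """Per-cell CFD summary feeding the resolution diagnostics."""

    velocity: float
    wall_distance: float
    cell_volume: Optional[float] = None
    grid_size: Optional[float] = None
    dissipation_rate: float = 0.0
    wall_shear_stress: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cell_volume is None and self.grid_size is None:
            raise InvalidParameterError("need cell_volume or grid_size")
        for name in ("velocity", "wall_distance", "dissipation_rate"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @property
    def delta(self) -> float:
        """Characteristic grid size: cube root of cell volume if given."""
        if self.cell_volume is not None:
            return self.cell_volume ** (1.0 / 3.0)
        return self.grid_size


@dataclass(frozen=True)
class TurbulenceScales:
    """Kolmogorov microscales and the WALE mixing length at one cell."""

    kolmogorov_length: float
    kolmogorov_time: float
    les_mixing_length: float
    von_karman: float = VON_KARMAN


def y_plus(sample: WallSample, fluid: FluidProperties) -> float:
    """Dimensionless wall distance y+ = u_tau y / nu."""
    return (
        sample.shear_velocity(fluid) * sample.wall_distance
        / fluid.kinematic_viscosity
    )


def law_of_wall(yp: float) -> Tuple[float, str]:
    """Law-of-the-wall velocity u+ with a layer classification.

    Viscous sublayer (y+ <= 5): u+ = y+.  Log layer (y+ >= 35):
    u+ = ln(y+)/0.41 + 5.  The buffer layer in between is interpolated
    linearly in ln(y+) between the laws' endpoint values and flagged
    'buffer' — no universal profile exists there, so the value is a
    bracketed estimate only.
    """
    if yp < 0:
        raise InvalidParameterError("y+ must be >= 0")
    if yp <= VISCOUS_SUBLAYER_MAX:
        return yp, "viscous"
    log_law = lambda y: math.log(y) / KAPPA_LOG + B_LOG
    if yp >= LOG_LAYER_MIN:
        return log_law(yp), "log"
    u_lo = VISCOUS_SUBLAYER_MAX
    u_hi = log_law(LOG_LAYER_MIN)
    frac = (math.log(yp) - math.log(VISCOUS_SUBLAYER_MAX)) / (
        math.log(LOG_LAYER_MIN) - math.log(VISCOUS_SUBLAYER_MAX)
    )
    return u_lo + frac * (u_hi - u_lo), "buffer"


def cfl_number(velocity: float, time_step: float, grid_size: float) -> float:
    """Courant-Friedrichs-Lewy number CFL = u dt / dx."""
    if grid_size <= 0:
        raise InvalidParameterError("grid_size must be > 0")
    if time_step <= 0:
        raise InvalidParameterError("time_step must be > 0")
    if velocity < 0:
        raise InvalidParameterError("velocity magnitude must be >= 0")
    return velocity * time_step / grid_size


def kolmogorov_scales(
    dissipation_rate: float, fluid: FluidProperties
) -> Tuple[float, float]:
    """Kolmogorov length and time scales (eta, tau_eta).

    eta = (nu^3/eps)^(1/4), tau_eta = (nu/eps)^(1/2); the identity
    tau_eta = eta^2/nu follows.  eps <= 0 (laminar, non-dissipating
    cells) has no defined microscale.
    """
    if dissipation_rate <= 0:
        raise ScalesUndefinedError(
            "Kolmogorov scales undefined for dissipation rate <= 0 (laminar cell)"
        )
    nu = fluid.kinematic_viscosity
    eta = (nu**3 / dissipation_rate) ** 0.25
    tau = (nu / dissipation_rate) ** 0.5
    return eta, tau


def les_mixing_length(wall_distance: float, cell_volume: float) -> float:
    """WALE subgrid mixing length l_LES = min(kappa y, 0.325 Delta).

    Delta is the cube root of the cell volume; near walls the
    kappa*y bound governs, in the interior the grid-size cap does.
    """
    if wall_distance < 0:
        raise InvalidParameterError("wall_distance must be >= 0")
    if cell_volume <= 0:
        raise InvalidParameterError("cell_volume must be > 0")
    delta = cell_volume ** (1.0 / 3.0)
    return min(VON_KARMAN * wall_distance, WALE_CAP * delta)


@dataclass
class ResolutionReport:
    """Histograms and exceedance fractions of the resolution ratios."""

    length_ratio_edges: np.ndarray
    length_ratio_counts: np.ndarray
    time_ratio_edges: np.ndarray
    time_ratio_counts: np.ndarray
    length_exceedance_fraction: float
    time_exceedance_fraction: float
    n_cells: int
    n_laminar_excluded: int
    bin_width: float

    def summary(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_laminar_excluded": self.n_laminar_excluded,
            "length_exceedance_fraction": self.length_exceedance_fraction,
            "time_exceedance_fraction": self.time_exceedance_fraction,
            "bin_width": self.bin_width,
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-form table of both histograms (one row per bin)."""
        rows = []
        for name, edges, counts in (
            ("l_les_over_eta", self.length_ratio_edges, self.length_ratio_counts),
            ("dt_over_tau_eta", self.time_ratio_edges, self.time_ratio_counts),
        ):
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                rows.append({"ratio": name, "bin_lo": lo, "bin_hi": hi, "count": int(c)})
        return pd.DataFrame(rows)


def _histogram(values: np.ndarray, bin_width: float) -> Tuple[np.ndarray, np.ndarray]:
    top = max(float(values.max()), bin_width)
    n_bins = int(math.ceil(top / bin_width + 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    if edges[-1] < top:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts


def resolution_report(
    cells: pd.DataFrame,
    time_step: float,
    fluid: FluidProperties,
    bin_width: float = 0.1,
) -> ResolutionReport:
    """Audit LES spatial/temporal resolution against Kolmogorov scales.

    ``cells`` needs columns ``y`` (wall distance, m), ``cell_volume``
    (m^3) or ``dx`` (m), and ``epsilon`` (dissipation rate, m^2/s^3).
    Cells with epsilon <= 0 are excluded from the ratios and counted
    separately.  The exceedance fractions report the share of included
    cells with l_LES/eta > 1 and dt/tau_eta > 1 — the under-resolution
    metric.
    """
    if len(cells) == 0:
        raise EmptyReportError("no cells supplied")
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    if time_step <= 0:
        raise InvalidParameterError("time_step must be > 0")
    eps = cells["epsilon"].to_numpy(dtype=float)
    turb = eps > 0
    n_lam = int((~turb).sum())
    if not turb.any():
        raise EmptyReportError("no cells with positive dissipation rate")
    y = cells["y"].to_numpy(dtype=float)[turb]
    if "cell_volume" in cells.columns:
        delta = cells["cell_volume"].to_numpy(dtype=float)[turb] ** (1.0 / 3.0)
    elif "dx" in cells.columns:
        delta = cells["dx"].to_numpy(dtype=float)[turb]
    else:
        raise InvalidParameterError("cells need a cell_volume or dx column")
    eps = eps[turb]
    nu = fluid.kinematic_viscosity
    l_les = np.minimum(VON_KARMAN * y, WALE_CAP * delta)
    eta = (nu**3 / eps) ** 0.25
    tau_eta = (nu / eps) ** 0.5
    length_ratio = l_les / eta
    time_ratio = time_step / tau_eta
    le_edges, le_counts = _histogram(length_ratio, bin_width)
    te_edges, te_counts = _histogram(time_ratio, bin_width)
    return ResolutionReport(
        length_ratio_edges=le_edges,
        length_ratio_counts=le_counts,
        time_ratio_edges=te_edges,
        time_ratio_counts=te_counts,
        length_exceedance_fraction=float(np.mean(length_ratio > 1.0)),
        time_exceedance_fraction=float(np.mean(time_ratio > 1.0)),
        n_cells=int(turb.sum()),
        n_laminar_excluded=n_lam,
        bin_width=bin_width,
    )


def hydraulic_diameter(area: float, perimeter: float) -> float:
    """Hydraulic diameter of a cross-section, Dh = 4A/O."""
    if area <= 0 or perimeter <= 0:
        raise InvalidParameterError("area and perimeter must be > 0")
    return 4.0 * area / perimeter
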