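"""Respiratory waveforms and the synthetic rhinomanometry generator.

Two tidal-breathing waveforms are supported: the plain sinusoid
``Q = Qmax sin(omega t)`` and the negative cosine
``Q = -Qmax cos(2 pi (t - t0)/tau)`` used as the transient-simulation
boundary condition, which starts at peak inspiration after an
initialisation interval ``t0`` and counts inspiration as negative flow.

The generator drives the unsteady Bernoulli duct model with the analytic
(Q, dQ/dt) pair to produce rhinomanometry (RMM) time series, optionally
corrupted by additive Gaussian pressure noise and by breath-to-breath
jitter of the hydraulic diameter — a crude stand-in for in vivo
variability such as the nasal cycle and measurement scatter.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from . import core
from .core import DuctModel, FluidProperties, FrictionPolicy
from .errors import (
    InvalidParameterError,
    LabellingError,
    SamplingResolutionError,
)


class WaveformKind(str, enum.Enum):
    SINE = "sine"
    NEGATIVE_COSINE = "negative_cosine"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Phase(str, enum.Enum):
    INSPIRATION = "inspiration"
    EXPIRATION = "expiration"


@dataclass(frozen=True)
class BreathingProtocol:
    """Tidal-breathing boundary condition.

    Parameters
    ----------
    peak_flowrate : float
        Qmax in m^3/s (amplitude of the flow oscillation).
    period : float
        Breathing period tau in seconds.
    phase_offset : float
        t0 in seconds; the negative-cosine waveform starts at peak
        inspiration at t = t0.  Ignored by the sine kind.
    n_cycles : int
        Number of breathing cycles to generate.
    waveform_kind : WaveformKind
        ``sine`` (inspiration = positive flow) or ``negative_cosine``
        (inspiration = negative flow).
    """

    peak_flowrate: float
    period: float
    phase_offset: float = 0.0
    n_cycles: int = 1
    waveform_kind: WaveformKind = WaveformKind.SINE

    def __post_init__(self) -> None:
        if self.peak_flowrate < 0:
            raise InvalidParameterError("peak_flowrate must be >= 0")
        if self.period <= 0:
            raise InvalidParameterError("period must be > 0")
        if self.n_cycles < 1:
            raise InvalidParameterError("n_cycles must be >= 1")

    @property
    def angular_frequency(self) -> float:
        """omega = 2 pi / tau in rad/s."""
        return 2.0 * math.pi / self.period

    @property
    def frequency(self) -> float:
        """Breathing frequency f = 1/tau in Hz."""
        return 1.0 / self.period

    @property
    def start_time(self) -> float:
        """First instant of the generated waveform."""
        return self.phase_offset if self.waveform_kind is WaveformKind.NEGATIVE_COSINE else 0.0

    @property
    def inspiration_sign(self) -> int:
        """Sign of Q during inspiration (+1 sine, -1 negative cosine)."""
        return -1 if self.waveform_kind is WaveformKind.NEGATIVE_COSINE else 1


#: Reference sinusoidal protocol: Qmax = 600 mL/s, tau = 5 s.
PROTOCOL_SINE_REFERENCE = BreathingProtocol(peak_flowrate=600e-6, period=5.0)

#: Transient-simulation protocol: negative cosine, Qmax = 600 mL/s,
#: tau = 5 s, t0 = 1 s, three cycles.
PROTOCOL_SIMULATION = BreathingProtocol(
    peak_flowrate=600e-6, period=5.0, phase_offset=1.0, n_cycles=3,
    waveform_kind=WaveformKind.NEGATIVE_COSINE,
)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise surrogate for synthetic RMM series.

    pressure_noise_sd adds i.i.d. Gaussian noise (Pa) to each pressure
    sample; dh_jitter_cv resamples the duct's hydraulic diameter once
    per breath with the given coefficient of variation.  Identical
    (seed, parameters) always reproduce the same series.
    """

    pressure_noise_sd: float = 0.0
    dh_jitter_cv: float = 0.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.pressure_noise_sd < 0 or self.dh_jitter_cv < 0:
            raise InvalidParameterError("noise magnitudes must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.pressure_noise_sd > 0 or self.dh_jitter_cv > 0


NOISE_OFF = NoiseModel()


@dataclass
class RmmTimeSeries:
    """Ordered rhinomanometry samples (strict SI).

    Arrays ``time``, ``flowrate``, ``flow_derivative``, ``pressure``
    share one length >= 2 and strictly increasing time.  ``phase`` is a
    per-sample label array ('inspiration'/'expiration').
    """

    time: np.ndarray
    flowrate: np.ndarray
    flow_derivative: np.ndarray
    pressure: np.ndarray
    side: Side = Side.RIGHT
    phase: Optional[np.ndarray] = None
    protocol: Optional[BreathingProtocol] = None
    duct: Optional[DuctModel] = None
    fluid: Optional[FluidProperties] = None
    noise: Optional[NoiseModel] = None
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flowrate = np.asarray(self.flowrate, dtype=float)
        self.flow_derivative = np.asarray(self.flow_derivative, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        n = self.time.size
        if n < 2:
            raise InvalidParameterError("series needs at least 2 samples")
        if any(a.size != n for a in (self.flowrate, self.flow_derivative, self.pressure)):
            raise InvalidParameterError("series arrays must share one length")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidParameterError("time must be strictly increasing")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=object)
            if self.phase.size != n:
                raise InvalidParameterError("phase labels must match series length")

    def __len__(self) -> int:
        return self.time.size

    def phase_labels(self) -> np.ndarray:
        """Per-sample phase labels, deriving them from flow sign if absent."""
        if self.phase is not None:
            return self.phase
        insp_sign = self.protocol.inspiration_sign if self.protocol is not None else 1
        return label_phases(self.flowrate, insp_sign)


@dataclass(frozen=True)
class PressureFlowCurve:
    """Four-quadrant chart representation of an RMM series.

    x carries |dP| signed by phase (inspiration positive), y carries
    |Q| signed by side and phase, so each (side, phase) pair lands in
    its clinical quadrant: right/left inspiration in the upper/lower
    right, right/left expiration in the lower/upper left.
    """

    x: np.ndarray
    y: np.ndarray
    phase: np.ndarray
    subphase: np.ndarray
    side: Side


def waveform_flow(
    t: "np.ndarray | float", protocol: BreathingProtocol
) -> Tuple["np.ndarray | float", "np.ndarray | float"]:
    """Analytic flowrate and its time derivative at time(s) ``t``.

    sine:            Q =  Qmax sin(omega t)
    negative_cosine: Q = -Qmax cos(omega (t - t0))
    """
    t = np.asarray(t, dtype=float)
    omega, qmax = protocol.angular_frequency, protocol.peak_flowrate
    if protocol.waveform_kind is WaveformKind.SINE:
        q = qmax * np.sin(omega * t)
        dq = qmax * omega * np.cos(omega * t)
    else:
        arg = omega * (t - protocol.phase_offset)
        q = -qmax * np.cos(arg)
        dq = qmax * omega * np.sin(arg)
    if t.ndim == 0:
        return float(q), float(dq)
    return q, dq


def tidal_volume(protocol: BreathingProtocol) -> float:
    """Inspired volume per breathing cycle, in m^3.

    The integral of |Q| over the inspiratory half-cycle of either
    waveform: V = Qmax * tau / pi.
    """
    return protocol.peak_flowrate * protocol.period / math.pi


def label_phases(flowrate: np.ndarray, inspiration_sign: int) -> np.ndarray:
    """Label samples inspiration/expiration from the sign of Q.

    Zero-flow samples inherit the label of the upcoming half-cycle
    (the sign of the next non-zero sample) so phase runs are contiguous.
    """
    q = np.asarray(flowrate, dtype=float)
    sign = np.sign(q).astype(int)
    # propagate the next non-zero sign backwards onto exact zeros
    nz = sign != 0
    if not nz.any():
        raise LabellingError("cannot label phases of an all-zero flow series")
    idx = np.where(nz, np.arange(q.size), q.size)
    nxt = np.minimum.accumulate(idx[::-1])[::-1]
    nxt = np.where(nxt < q.size, nxt, np.max(np.where(nz)[0]))
    sign = np.where(sign == 0, sign[nxt], sign)
    return np.where(
        sign == inspiration_sign, Phase.INSPIRATION.value, Phase.EXPIRATION.value
    ).astype(object)


def label_subphases(
    flowrate: np.ndarray, flow_derivative: np.ndarray
) -> np.ndarray:
    """Label samples accelerating/decelerating from d|Q|/dt = sign(Q)*dQ/dt."""
    q = np.asarray(flowrate, dtype=float)
    dq = np.asarray(flow_derivative, dtype=float)
    speed_rate = np.sign(q) * dq
    # at Q = 0 the magnitude is momentarily increasing in the new direction
    return np.where(speed_rate >= 0, "accelerating", "decelerating").astype(object)


def generate_rmm_timeseries(
    duct: DuctModel,
    fluid: FluidProperties,
    protocol: BreathingProtocol,
    policy: FrictionPolicy = core.BLENDED,
    sampling_rate: float = None,
    noise: NoiseModel = NOISE_OFF,
    side: Side = Side.RIGHT,
) -> RmmTimeSeries:
    """Generate a synthetic RMM time series from the duct model.

    Each sample's pressure is the unsteady Bernoulli pressure drop at
    the analytic (Q, dQ/dt).  Default sampling is 1000 samples per
    cycle; fewer than 50 per cycle is rejected.  With noise disabled
    the series is deterministic and each full period closes into a
    loop; with noise enabled it is reproducible from the seed.
    """
    if sampling_rate is None:
        sampling_rate = 1000.0 / protocol.period
    if sampling_rate * protocol.period < 50:
        raise SamplingResolutionError(
            "need at least 50 samples per breathing cycle, got "
            f"{sampling_rate * protocol.period:.1f}"
        )
    n = int(round(sampling_rate * protocol.period * protocol.n_cycles))
    t = protocol.start_time + np.arange(n + 1) / sampling_rate
    q, dq = waveform_flow(t, protocol)

    if noise.dh_jitter_cv > 0:
        rng = np.random.default_rng(noise.random_seed)
        breath = np.minimum(
            ((t - protocol.start_time) / protocol.period).astype(int),
            protocol.n_cycles - 1,
        )
        factors = 1.0 + noise.dh_jitter_cv * rng.standard_normal(protocol.n_cycles)
        factors = np.maximum(factors, 0.1)  # keep Dh physical under large CV
        pressure = np.empty_like(q)
        for b in range(protocol.n_cycles):
            mask = breath == b
            jittered = replace(
                duct, hydraulic_diameter=duct.hydraulic_diameter * factors[b]
            )
            pressure[mask] = core.pressure_drop(q[mask], dq[mask], jittered, fluid, policy)
    else:
        rng = np.random.default_rng(noise.random_seed)
        pressure = core.pressure_drop(q, dq, duct, fluid, policy)

    if noise.pressure_noise_sd > 0:
        if noise.dh_jitter_cv == 0:
            rng = np.random.default_rng(noise.random_seed)
        pressure = pressure + noise.pressure_noise_sd * rng.standard_normal(t.size)

    return RmmTimeSeries(
        time=t,
        flowrate=q,
        flow_derivative=dq,
        pressure=pressure,
        side=side,
        phase=label_phases(q, protocol.inspiration_sign),
        protocol=protocol,
        duct=duct,
        fluid=fluid,
        noise=noise if noise.enabled else None,
    )


def to_clinical_quadrants(series: RmmTimeSeries) -> PressureFlowCurve:
    """Map an RMM series into the clinical four-quadrant chart.

    x = phase_sign * |dP| with inspiration positive; y = side_sign *
    phase_sign * |Q| with the right side positive, so the four (side,
    phase) combinations occupy their conventional quadrants and the
    magnitudes |Q|, |dP| are preserved.
    """
    if series.side is None:
        raise LabellingError("series has no side label")
    phases = series.phase_labels()
    phase_sign = np.where(phases == Phase.INSPIRATION.value, 1.0, -1.0)
    side_sign = 1.0 if series.side is Side.RIGHT else -1.0
    x = phase_sign * np.abs(series.pressure)
    y = side_sign * phase_sign * np.abs(series.flowrate)
    sub = label_subphases(series.flowrate, series.flow_derivative)
    return PressureFlowCurve(x=x, y=y, phase=phases, subphase=sub, side=series.side)
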