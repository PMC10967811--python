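import numpy as np
import pytest

import rhinoflow as rf


@pytest.fixture
def air():
    """Standard-condition air (rho=1.225 kg/m^3, mu=1.7894e-5 Pa s)."""
    return rf.AIR_STANDARD


@pytest.fixture
def air_rounded():
    """Air with the rounded kinematic viscosity nu=1.5e-5 m^2/s."""
    return rf.AIR_ROUNDED_NU


@pytest.fixture
def duct_10mm():
    """Reference duct: Dh=10 mm, L=0.1 m, smooth."""
    return rf.DuctModel(10e-3, 0.1)


@pytest.fixture
def sine_protocol():
    """Reference sinusoidal breathing: Qmax=600 mL/s, tau=5 s."""
    return rf.PROTOCOL_SINE_REFERENCE


def make_loop(duct, fluid, protocol, policy=rf.LAMINAR, samples_per_cycle=1000,
              noise=rf.NOISE_OFF):
    """Synthetic closed pressure-flow loop."""
    return rf.generate_rmm_timeseries(
        duct, fluid, protocol, policy,
        sampling_rate=samples_per_cycle / protocol.period, noise=noise,
    )


def make_steady_curve(duct, fluid, protocol, policy=rf.LAMINAR,
                      samples_per_cycle=1000):
    """Single-valued curve with the unsteady term suppressed (dQ/dt=0)."""
    loop = make_loop(duct, fluid, protocol, policy, samples_per_cycle)
    return rf.RmmTimeSeries(
        time=loop.time,
        flowrate=loop.flowrate,
        flow_derivative=np.zeros_like(loop.time),
        pressure=rf.pressure_drop(loop.flowrate, 0.0, duct, fluid, policy),
        side=loop.side,
        phase=loop.phase,
        protocol=protocol,
        duct=duct,
        fluid=fluid,
    )
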