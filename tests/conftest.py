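"""Shared fixtures: default components and session-scoped ensembles.

The heavy transport ensembles are session-scoped so the acceptance tests
and property tests reuse the same simulated data instead of re-running
multi-second simulations per test.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kinesim as ks

settings.register_profile(
    "suite", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def motor() -> ks.MotorParams:
    return ks.MotorParams()


@pytest.fixture(scope="session")
def profile(motor) -> ks.DetachmentProfile:
    return ks.make_profile("measured", motor)


def transport_ensemble(eta_rel, n, seed, stride=0, variant="measured",
                       diffusion=True, v0=800.0, d=500.0):
    """Run a transport ensemble at the given condition (helper, not a test)."""
    import dataclasses

    motor = ks.MotorParams(v0=v0)
    profile = ks.make_profile(variant, motor)
    fluid = ks.FluidCargo.from_water_multiple(eta_rel, d=d)
    cfg = ks.SimulationConfig(n_replicates=n, seed=seed, record_stride=stride,
                              diffusion=diffusion)
    return ks.simulate_ensemble(cfg, motor, fluid, profile)


@pytest.fixture(scope="session")
def water_ensemble():
    """N=1500 runs at 1x water, d=0.5 um, v0=0.8 um/s."""
    return transport_ensemble(1.0, 1500, seed=101)


@pytest.fixture(scope="session")
def visc22_ensemble():
    """N=1500 runs at 22x water (characteristic drag ~0.25 pN)."""
    return transport_ensemble(22.0, 1500, seed=202)


@pytest.fixture(scope="session")
def visc500_ensemble():
    """N=400 runs at 500x water (drag ~5.7 pN, strongly hindered)."""
    return transport_ensemble(500.0, 400, seed=303)


@pytest.fixture(scope="session")
def drag02_ensemble():
    """N=400 recorded runs at drag ~0.2 pN (17.68x water)."""
    return transport_ensemble(17.684, 400, seed=404, stride=10)


@pytest.fixture(scope="session")
def lowdrag_ensembles(drag02_ensemble):
    """Recorded ensembles spanning characteristic drag 0.01-0.2 pN."""
    return [
        transport_ensemble(1.0, 200, seed=505, stride=10),
        transport_ensemble(4.0, 200, seed=606, stride=10),
        drag02_ensemble,
    ]


@pytest.fixture(scope="session")
def zero_drag_pool(motor):
    """Stationary displacement samples pooled over the zero-drag grid
    (viscosity 1-1000x water, diameter 0.1-1 um)."""
    pools = []
    for i, eta in enumerate((1.0, 10.0, 100.0, 1000.0)):
        for j, d in enumerate((100.0, 320.0, 1000.0)):
            fluid = ks.FluidCargo.from_water_multiple(eta, d=d)
            pools.append(ks.stationary_displacement_sample(
                motor, fluid, seed=1000 + 10 * i + j))
    return np.concatenate(pools)


@pytest.fixture(scope="session")
def stiffness_sweep():
    """Zero-drag equilibrium displacement samples over a 100-fold
    stiffness range around 0.32 pN/nm; returns (kappas, samples list)."""
    import dataclasses

    base = ks.MotorParams()
    fluid = ks.FluidCargo.from_water_multiple(1.0)
    kappas = 0.32 * np.logspace(-1, 1, 7)
    samples = []
    for i, k in enumerate(kappas):
        m = dataclasses.replace(base, kappa=float(k))
        samples.append(ks.stationary_displacement_sample(
            m, fluid, seed=2000 + i, samples_per_chain=40_000,
            span_crossings=120.0))
    return kappas, samples
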