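"""Monte Carlo time-stepping simulator of single-motor cargo transport.

Each run couples a stochastic stepper (the motor) to an overdamped bead
(the cargo) through a slack-then-Hookean tether.  Per time step ``dt``, in
this order:

1. the cargo-motor displacement sets the signed load F on the motor;
2. the motor detaches with probability epsilon(F) * dt (run ends);
3. the motor advances one 8-nm step with probability k_step(F) * dt;
4. the cargo moves by deterministic drift (-F / xi) * dt plus a Gaussian
   (Euler-Maruyama) diffusion increment sqrt(2 D dt) * N(0, 1);
5. time advances by dt.

Stepping and detachment are independent Bernoulli trials per step, valid
while rate * dt stays small (a warning is emitted above 0.1).  The inner
loops are compiled with numba; a trajectory is fully determined by its seed.

``equilibrium`` mode holds the motor still and disables detachment, which
samples the stationary cargo-motor displacement distribution in the
flat-bottomed harmonic tether potential.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import CorruptedStateError, InvalidParameterError
from .kinetics import DetachmentProfile, MotorParams, ProfileVariant, stepping_rate
from .mechanics import FluidCargo, tether_load_on_motor

_VARIANT_CODE = {
    ProfileVariant.MEASURED: 0,
    ProfileVariant.SYMMETRIC_HINDERING: 1,
    ProfileVariant.SYMMETRIC_ASSISTING: 2,
    ProfileVariant.REVERSED: 3,
}

#: Stiffness above which the default time step drops from 10 us to 1 us.
_STIFF_KAPPA = 0.32


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level numerical settings.

    ``dt=None`` resolves to 1e-5 s, or 1e-6 s for motors stiffer than
    0.32 pN/nm (the finer step is needed to track the cargo in the steeper
    tether potential).  ``record_stride=0`` disables trajectory sampling;
    a positive stride records time, motor and cargo positions every that
    many steps.
    """

    dt: float | None = None
    n_replicates: int = 1000
    max_steps: int = 10_000_000
    seed: int = 0
    mode: str = "transport"
    equilibrium_steps: int = 20_000
    burn_in: int = 0
    record_stride: int = 0
    include_binding_wait: bool = False
    diffusion: bool = True

    def __post_init__(self) -> None:
        if self.dt is not None and self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if self.mode not in ("transport", "equilibrium"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.record_stride < 0 or self.burn_in < 0:
            raise InvalidParameterError("record_stride and burn_in must be >= 0")

    def resolve_dt(self, motor: MotorParams) -> float:
        if self.dt is not None:
            return self.dt
        return 1e-6 if motor.kappa > _STIFF_KAPPA else 1e-5


@dataclass
class TrajectoryRecord:
    """One simulated cargo run.

    ``times``/``motor``/``cargo`` are sampled every ``record_stride`` steps
    (empty arrays when recording was off).  ``run_length`` is the total
    distance the motor travelled before detaching, i.e.
    ``n_motor_steps * step_size``.
    """

    seed: int
    dt: float
    run_length: float
    duration: float
    n_motor_steps: int
    termination: str
    times: np.ndarray = field(repr=False)
    motor: np.ndarray = field(repr=False)
    cargo: np.ndarray = field(repr=False)
    binding_wait: float = 0.0

    def displacements(self) -> np.ndarray:
        """Sampled cargo - motor displacements, nm."""
        return self.cargo - self.motor

    def loads(self, kappa: float, L0: float) -> np.ndarray:
        """Sampled signed tether loads on the motor, pN."""
        d = self.displacements()
        out = np.zeros_like(d)
        lead = d > L0
        lag = d < -L0
        out[lead] = kappa * (d[lead] - L0)
        out[lag] = -kappa * (-d[lag] - L0)
        return out


# ---------------------------------------------------------------------------
# compiled kernels


@njit(cache=True, inline="always")
def _eps_measured(F, eps0, Fdm, Fdp, slope, prefac, bend):
    if F <= 0.0:
        return eps0 * math.exp(-F / Fdm)
    if F <= bend:
        return eps0 * (1.0 + slope * F)
    return eps0 * prefac * math.exp(F / Fdp)


@njit(cache=True, inline="always")
def _eps(F, code, eps0, Fdm, Fdp, slope, prefac, bend):
    if code == 0:
        return _eps_measured(F, eps0, Fdm, Fdp, slope, prefac, bend)
    if code == 1:
        return eps0 * math.exp(abs(F) / Fdm)
    if code == 2:
        return _eps_measured(abs(F), eps0, Fdm, Fdp, slope, prefac, bend)
    return _eps_measured(-F, eps0, Fdm, Fdp, slope, prefac, bend)


@njit(cache=True)
def _transport_core(seed, dt, max_steps, dx, Fs, k0, kappa, L0, xi, D,
                    code, eps0, Fdm, Fdp, slope, prefac, bend,
                    stride, cap):
    np.random.seed(seed)
    motor = 0.0
    cargo = 0.0
    t = 0.0
    n_steps = 0
    noise = math.sqrt(2.0 * D * dt)
    times = np.empty(cap)
    motors = np.empty(cap)
    cargos = np.empty(cap)
    nsamp = 0
    detached = False
    for i in range(max_steps):
        delta = cargo - motor
        if delta > L0:
            F = kappa * (delta - L0)
        elif delta < -L0:
            F = -kappa * (-delta - L0)
        else:
            F = 0.0
        if stride > 0 and i % stride == 0 and nsamp < cap:
            times[nsamp] = t
            motors[nsamp] = motor
            cargos[nsamp] = cargo
            nsamp += 1
        eps = _eps(F, code, eps0, Fdm, Fdp, slope, prefac, bend)
        if np.random.random() < eps * dt:
            detached = True
            t += dt
            break
        if F > 0.0:
            k = k0
        elif F <= -Fs:
            k = 0.0
        else:
            k = k0 * (1.0 - (F / Fs) ** 2)
        if k > 0.0 and np.random.random() < k * dt:
            motor += dx
            n_steps += 1
        cargo += (-F / xi) * dt
        if noise > 0.0:
            cargo += noise * np.random.normal()
        t += dt
    return (motor, cargo, n_steps, t, detached,
            times[:nsamp], motors[:nsamp], cargos[:nsamp])


@njit(cache=True)
def _equilibrium_core(seed, dt, n_steps, burn_in, stride, kappa, L0, xi, D):
    np.random.seed(seed)
    cargo = 0.0
    noise = math.sqrt(2.0 * D * dt)
    out = np.empty(n_steps // stride)
    nsamp = 0
    for i in range(burn_in + n_steps):
        if cargo > L0:
            Fc = -kappa * (cargo - L0)
        elif cargo < -L0:
            Fc = kappa * (-cargo - L0)
        else:
            Fc = 0.0
        cargo += (Fc / xi) * dt + noise * np.random.normal()
        if i >= burn_in and (i - burn_in) % stride == 0 and nsamp < out.size:
            out[nsamp] = cargo
            nsamp += 1
    return out[:nsamp]


# ---------------------------------------------------------------------------
# python-level API


@dataclass
class SimState:
    """Mutable per-step state used by :func:`advance_one_step`."""

    motor: float = 0.0
    cargo: float = 0.0
    t: float = 0.0
    n_motor_steps: int = 0
    attached: bool = True


def advance_one_step(
    state: SimState,
    rng: np.random.Generator,
    motor: MotorParams,
    fluid: FluidCargo,
    profile: DetachmentProfile,
    dt: float,
) -> SimState:
    """Advance one transport time step in place (reference implementation).

    Implements exactly the update cycle of the compiled kernel: load
    evaluation, Bernoulli detachment, Bernoulli stepping, cargo drift +
    diffusion.  Used for small-n oracle tests; ensembles go through the
    compiled :func:`simulate_run`.
    """
    if not (math.isfinite(state.motor) and math.isfinite(state.cargo)):
        raise CorruptedStateError(f"non-finite state {state}")
    if not state.attached:
        raise InvalidParameterError("motor already detached")
    F = tether_load_on_motor(state.cargo - state.motor, motor.kappa, motor.L0)
    if rng.random() < profile.rate(F) * dt:
        state.attached = False
        state.t += dt
        return state
    if rng.random() < stepping_rate(F, motor) * dt:
        state.motor += motor.step_size
        state.n_motor_steps += 1
    state.cargo += (-F / fluid.xi) * dt + math.sqrt(2.0 * fluid.D * dt) * rng.standard_normal()
    state.t += dt
    if not (math.isfinite(state.motor) and math.isfinite(state.cargo)):
        raise CorruptedStateError("state became non-finite; reduce dt")
    return state


def _check_bernoulli(dt: float, motor: MotorParams, profile: DetachmentProfile) -> None:
    worst = max(motor.k0, profile.eps0) * dt
    if worst > 0.1:
        warnings.warn(
            f"rate*dt = {worst:.3g} > 0.1; Bernoulli per-step probabilities "
            "are inaccurate, reduce dt", stacklevel=3)


def _check_stability(dt: float, motor: MotorParams, fluid: FluidCargo) -> None:
    # explicit Euler relaxation of the taut tether is unstable beyond
    # kappa*dt/xi = 2 (oscillatory already beyond 1)
    a = motor.kappa * dt / fluid.xi
    if a > 2.0:
        warnings.warn(
            f"kappa*dt/xi = {a:.3g} > 2: the tether relaxation is unresolved "
            "and the cargo update is unstable; reduce dt", stacklevel=3)


def simulate_run(
    config: SimulationConfig,
    motor: MotorParams,
    fluid: FluidCargo,
    profile: DetachmentProfile,
    seed: int | None = None,
) -> TrajectoryRecord:
    """Simulate one cargo run until detachment (or the step cap).

    The run starts with the cargo at the motor position (zero tether
    extension).  With ``include_binding_wait`` an exponential waiting time
    at rate ``k_on`` is drawn and reported in ``binding_wait``; it does not
    affect the run itself.
    """
    dt = config.resolve_dt(motor)
    _check_bernoulli(dt, motor, profile)
    _check_stability(dt, motor, fluid)
    if seed is None:
        seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0])
    stride = config.record_stride
    cap = (config.max_steps // stride + 1) if stride > 0 else 1
    D = fluid.D if config.diffusion else 0.0
    (mpos, cpos, n_steps, t, detached, times, motors, cargos) = _transport_core(
        seed, dt, config.max_steps,
        motor.step_size, motor.Fs, motor.k0, motor.kappa, motor.L0,
        fluid.xi, D,
        _VARIANT_CODE[profile.variant], profile.eps0, profile.Fd_minus,
        profile.Fd_plus, profile.bridge_slope, profile.bridge_prefactor,
        profile.bridge_end,
        stride, cap,
    )
    if not (math.isfinite(mpos) and math.isfinite(cpos)):
        raise CorruptedStateError("simulation state became non-finite; reduce dt")
    wait = 0.0
    if config.include_binding_wait:
        wait = float(np.random.default_rng(seed).exponential(1.0 / motor.k_on))
    return TrajectoryRecord(
        seed=seed, dt=dt, run_length=mpos, duration=t, n_motor_steps=n_steps,
        termination="detached" if detached else "max_steps",
        times=times, motor=motors, cargo=cargos, binding_wait=wait,
    )


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic, order-independent per-replicate seeds (uint32)."""
    return np.random.SeedSequence(master_seed).generate_state(n)


def simulate_ensemble(
    config: SimulationConfig,
    motor: MotorParams,
    fluid: FluidCargo,
    profile: DetachmentProfile,
) -> list[TrajectoryRecord]:
    """Simulate ``config.n_replicates`` independent runs.

    Replicate seeds are spawned from the master seed, so the ensemble is
    reproducible and independent of evaluation order.
    """
    seeds = replicate_seeds(config.seed, config.n_replicates)
    return [
        simulate_run(config, motor, fluid, profile, seed=int(s)) for s in seeds
    ]


def simulate_equilibrium(
    config: SimulationConfig,
    motor: MotorParams,
    fluid: FluidCargo,
) -> np.ndarray:
    """Sample cargo-motor displacements with the motor held still.

    Runs ``n_replicates`` independent chains of ``equilibrium_steps`` steps
    each (after ``burn_in`` unrecorded steps) with detachment disabled, and
    returns the pooled displacement samples in nm, recorded every
    ``record_stride`` steps (every step by default).  In the continuum
    limit the samples follow the Boltzmann distribution of the
    flat-bottomed harmonic tether potential.
    """
    if config.mode != "equilibrium":
        config = replace(config, mode="equilibrium")
    dt = config.resolve_dt(motor)
    _check_stability(dt, motor, fluid)
    stride = max(config.record_stride, 1)
    seeds = replicate_seeds(config.seed, config.n_replicates)
    chunks = [
        _equilibrium_core(int(s), dt, config.equilibrium_steps, config.burn_in,
                          stride, motor.kappa, motor.L0, fluid.xi, fluid.D)
        for s in seeds
    ]
    out = np.concatenate(chunks)
    if not np.all(np.isfinite(out)):
        raise CorruptedStateError("equilibrium sampling became non-finite; reduce dt")
    return out
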