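"""Closed-form diffusion-free transport model.

Without cargo diffusion the only load on the motor is the viscous drag
|F| = 9*pi*eta*d*v, always hindering.  Combining this with the quadratic
force-velocity relation v = v0 * (1 - (F/Fs)^2) gives a self-consistent
velocity, and the run length follows from l = v / epsilon with the Bell
hindering detachment law:

    l = (v / eps0) * exp(-9*pi*eta*d*v / Fd_minus)

These curves are the reference against which diffusion-enabled ensembles
are compared, and they define the drag threshold at which viscous load
alone shortens runs by a given fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import InvalidParameterError
from .kinetics import DetachmentProfile, MotorParams
from .mechanics import FluidCargo


@dataclass(frozen=True)
class AnalyticInputs:
    """Parameters of the diffusion-free model (units as elsewhere)."""

    eta: float
    d: float
    v0: float
    Fs: float
    Fd_minus: float
    eps0: float

    def __post_init__(self) -> None:
        for name in ("eta", "d", "v0", "Fs", "Fd_minus", "eps0"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"AnalyticInputs.{name} must be positive")

    @classmethod
    def from_components(
        cls, motor: MotorParams, fluid: FluidCargo, profile: DetachmentProfile
    ) -> "AnalyticInputs":
        """Share numbers with the simulation components (no separate defaults)."""
        return cls(eta=fluid.eta, d=fluid.d, v0=motor.v0, Fs=motor.Fs,
                   Fd_minus=profile.Fd_minus, eps0=profile.eps0)


def diffusion_free_velocity(inputs: AnalyticInputs) -> float:
    """Self-consistent velocity (nm/s) under the motor's own viscous drag.

    Solves v = v0 * (1 - (9*pi*eta*d*v / Fs)^2) in closed form:

        v = (v0/2) * (Fs / (9*pi*eta*d*v0))^2 * (-1 + sqrt(1 + 4*(9*pi*eta*d*v0/Fs)^2))

    evaluated in the rationalized form v = 2*v0 / (1 + sqrt(1 + 4*g^2))
    with g = 9*pi*eta*d*v0/Fs, which is algebraically identical but avoids
    the catastrophic cancellation of the 0/0 form as drag vanishes
    (v -> v0 smoothly).
    """
    g = 9.0 * math.pi * inputs.eta * inputs.d * inputs.v0 / inputs.Fs
    return 2.0 * inputs.v0 / (1.0 + math.sqrt(1.0 + 4.0 * g * g))


def diffusion_free_run_length(inputs: AnalyticInputs) -> float:
    """Run length l = (v / eps0) * exp(-9*pi*eta*d*v / Fd_minus), nm.

    Monotonically decreasing in the viscosity-diameter product eta*d.
    """
    v = diffusion_free_velocity(inputs)
    drag = 9.0 * math.pi * inputs.eta * inputs.d * v
    return v / inputs.eps0 * math.exp(-drag / inputs.Fd_minus)


def drag_threshold(
    reduction_fraction: float,
    Fs: float = 7.0,
    Fd_minus: float = 4.11 / 0.60,
) -> float:
    """Drag (pN) at which the diffusion-free run length drops by a fraction.

    At drag force F the normalized run length is
    (v/v0) * exp(-F/Fd_minus) = (1 - (F/Fs)^2) * exp(-F/Fd_minus); the
    threshold is the root of that expression equalling
    1 - reduction_fraction, found by bracketed root search on (0, Fs) to
    1e-6 pN.
    """
    if not 0.0 < reduction_fraction < 1.0:
        raise InvalidParameterError("reduction_fraction must be in (0, 1)")

    def shortfall(F: float) -> float:
        return (1.0 - (F / Fs) ** 2) * math.exp(-F / Fd_minus) - (1.0 - reduction_fraction)

    lo, hi = 1e-12, Fs * (1.0 - 1e-12)
    if shortfall(lo) < 0.0 or shortfall(hi) > 0.0:
        raise InvalidParameterError("no root in (0, Fs) for this reduction fraction")
    return float(brentq(shortfall, lo, hi, xtol=1e-6))
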