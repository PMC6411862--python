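"""Cargo-fluid coupling and the motor-tether force law.

Internal unit system: pN, nm, s.  Viscosity is expressed in pN*s/nm^2;
water at room temperature (1e-3 Pa*s) is ``ETA_WATER`` = 1e-9 in these
units, so a solution "22x water" has eta = 22 * ETA_WATER.

The cargo is treated as a point particle in one dimension whose diameter
enters only through the Stokes friction coefficient.  Experiments on beads
near a coverslip see roughly threefold the free-space friction, so the
wall-correction multiplier ``chi`` defaults to 3, making the effective
friction 9*pi*eta*d.  With that default the steady-state tether load on a
motor moving at v equals the characteristic drag 9*pi*eta*d*v, the single
control parameter that collapses viscosity, cargo-size and velocity sweeps.
``chi = 1`` recovers the uncorrected free-space Stokes law 3*pi*eta*d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError
from .kinetics import KBT

#: Viscosity of water, pN*s/nm^2 (= 1e-3 Pa*s).
ETA_WATER = 1.0e-9


def friction_coefficient(eta: float, d: float, chi: float = 3.0) -> float:
    """Friction coefficient xi = chi * 3*pi*eta*d, pN*s/nm.

    Parameters
    ----------
    eta : float
        Solution viscosity, pN*s/nm^2.
    d : float
        Cargo diameter, nm.
    chi : float
        Wall-correction multiplier on the free-space Stokes friction.
    """
    if eta <= 0 or d <= 0 or chi <= 0:
        raise InvalidParameterError(f"eta, d, chi must be positive (got {eta}, {d}, {chi})")
    return chi * 3.0 * math.pi * eta * d


def diffusion_coefficient(xi: float, kBT: float = KBT) -> float:
    """Einstein diffusion coefficient D = kBT / xi, nm^2/s."""
    if xi <= 0:
        raise InvalidParameterError(f"xi must be positive (got {xi})")
    return kBT / xi


def characteristic_drag(eta: float, d: float, v: float) -> float:
    """Viscous drag 9*pi*eta*d*v (pN) on a cargo moving at velocity v.

    This near-wall Stokes drag is the single control parameter against
    which run-length sweeps over viscosity, cargo size and motor velocity
    collapse.
    """
    if v < 0:
        raise InvalidParameterError(f"v must be non-negative (got {v})")
    return 9.0 * math.pi * eta * d * v


def tether_load_on_motor(delta: float, kappa: float, L0: float) -> float:
    """Signed load (pN) transmitted to the motor by the cargo tether.

    ``delta`` is cargo position minus motor position (nm).  The tether is a
    linear spring of stiffness ``kappa`` that is slack below the rest length
    ``L0``: no force inside |delta| <= L0, Hookean beyond.  A cargo leading
    the motor (delta > L0) assists (+); a lagging cargo hinders (-).  The
    force on the cargo is the negation.
    """
    if kappa <= 0:
        raise InvalidParameterError(f"kappa must be positive (got {kappa})")
    if L0 < 0:
        raise InvalidParameterError(f"L0 must be non-negative (got {L0})")
    if delta > L0:
        return kappa * (delta - L0)
    if delta < -L0:
        return -kappa * (-delta - L0)
    return 0.0


@dataclass(frozen=True)
class FluidCargo:
    """A spherical cargo in a viscous solution.

    Attributes
    ----------
    d : float
        Cargo diameter, nm.
    eta : float
        Solution viscosity, pN*s/nm^2 (``ETA_WATER`` = water).
    chi : float
        Wall-correction multiplier on the free-space friction (default 3).
    kBT : float
        Thermal energy, pN*nm.
    """

    d: float = 500.0
    eta: float = ETA_WATER
    chi: float = 3.0
    kBT: float = KBT

    def __post_init__(self) -> None:
        if self.d <= 0 or self.eta <= 0 or self.chi <= 0 or self.kBT <= 0:
            raise InvalidParameterError("FluidCargo fields must be positive")

    @classmethod
    def from_water_multiple(cls, eta_rel: float, d: float = 500.0, **kw) -> "FluidCargo":
        """Construct from a viscosity expressed in multiples of water."""
        return cls(d=d, eta=eta_rel * ETA_WATER, **kw)

    @property
    def eta_rel(self) -> float:
        """Viscosity in multiples of water."""
        return self.eta / ETA_WATER

    @property
    def xi(self) -> float:
        """Friction coefficient chi * 3*pi*eta*d, pN*s/nm."""
        return friction_coefficient(self.eta, self.d, self.chi)

    @property
    def D(self) -> float:
        """Diffusion coefficient kBT / xi, nm^2/s (fluctuation-dissipation)."""
        return diffusion_coefficient(self.xi, self.kBT)

    def drag_at(self, v: float) -> float:
        """Characteristic drag 9*pi*eta*d*v at velocity v, pN."""
        return characteristic_drag(self.eta, self.d, v)
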