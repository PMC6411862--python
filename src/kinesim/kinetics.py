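"""Load-dependent stepping and detachment kinetics of kinesin-1.

Sign convention used throughout the package: a positive force on the motor
acts in the direction of motor motion ("assisting"); a negative force opposes
it ("hindering").

The motor steps 8 nm per mechanochemical cycle at an unloaded rate
``v0 / step_size``.  Hindering load slows stepping quadratically up to the
stall force; assisting load leaves the stepping rate unchanged.  Detachment
from the microtubule follows Bell-type (exponential) load dependence with a
pronounced asymmetry: the characteristic detachment distance is larger for
assisting load, so assisting forces strip the motor off its track far more
effectively than hindering forces of equal magnitude.  Because the assisting
branch was measured only above +2 pN, the 0 to +2 pN gap is bridged by a
linear interpolation constructed to meet the exponential branch at +2 pN.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields

import numpy as np

from .errors import InvalidParameterError

#: Thermal energy at room temperature, pN * nm.
KBT = 4.11


class ProfileVariant(str, enum.Enum):
    """Shape of the load-detachment rate law epsilon(F).

    ``MEASURED`` is the experimentally determined asymmetric profile.  The
    other three are synthetic controls used to probe which features of the
    asymmetry matter for transport:

    * ``SYMMETRIC_HINDERING`` -- the hindering branch mirrored onto F > 0.
    * ``SYMMETRIC_ASSISTING`` -- the assisting branch (linear bridge plus
      exponential) applied to |F| in both directions.
    * ``REVERSED`` -- the measured profile with the force axis flipped,
      epsilon_rev(F) = epsilon_meas(-F).
    """

    MEASURED = "measured"
    SYMMETRIC_HINDERING = "symmetric_hindering"
    SYMMETRIC_ASSISTING = "symmetric_assisting"
    REVERSED = "reversed"


def detachment_force(delta: float, kBT: float = KBT) -> float:
    """Detachment force F_d = kBT / delta for a Bell detachment distance.

    Parameters
    ----------
    delta : float
        Characteristic distance between attached and detached states, nm.
    kBT : float
        Thermal energy, pN * nm.
    """
    if delta <= 0 or kBT <= 0:
        raise InvalidParameterError(f"delta and kBT must be positive (got {delta}, {kBT})")
    return kBT / delta


def unloaded_detachment_rate(v0: float, l0: float) -> float:
    """Unloaded detachment rate eps0 = v0 / l0 (1/s).

    The mean unloaded run length of a motor detaching at constant rate eps0
    while moving at v0 is v0 / eps0, so eps0 = v0 / l0 reproduces the
    observed unloaded run length l0.
    """
    if l0 <= 0:
        raise InvalidParameterError(f"l0 must be positive (got {l0})")
    if v0 < 0:
        raise InvalidParameterError(f"v0 must be non-negative (got {v0})")
    return v0 / l0


@dataclass(frozen=True)
class MotorParams:
    """Kinetic and mechanical constants of a single kinesin motor.

    Attributes
    ----------
    v0 : float
        Unloaded velocity, nm/s.
    l0 : float
        Unloaded run length, nm.
    step_size : float
        Lattice step, nm.
    Fs : float
        Stall force, pN (hindering load at which stepping stops).
    kappa : float
        Motor-tether stiffness, pN/nm.
    L0 : float
        Tether rest length, nm; no load is transmitted below this extension.
    k_on : float
        Microtubule binding rate, 1/s.
    """

    v0: float = 800.0
    l0: float = 1500.0
    step_size: float = 8.0
    Fs: float = 7.0
    kappa: float = 0.32
    L0: float = 40.0
    k_on: float = 5.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise InvalidParameterError(f"MotorParams.{f.name} must be positive")

    @property
    def eps0(self) -> float:
        """Unloaded detachment rate v0 / l0, 1/s."""
        return unloaded_detachment_rate(self.v0, self.l0)

    @property
    def k0(self) -> float:
        """Unloaded stepping rate v0 / step_size, 1/s."""
        return self.v0 / self.step_size


def stepping_rate(F: float, motor: MotorParams) -> float:
    """Load-dependent stepping rate k_step(F), 1/s.

    Zero at and beyond stall (F <= -Fs); a quadratic force-velocity relation
    (v0/dx) * (1 - (F/Fs)^2) under sub-stall hindering load; the unloaded
    rate v0/dx under any assisting load.
    """
    k0 = motor.k0
    if F > 0:
        return k0
    if F <= -motor.Fs:
        return 0.0
    return k0 * (1.0 - (F / motor.Fs) ** 2)


@dataclass(frozen=True)
class DetachmentProfile:
    """Piecewise load-detachment rate law epsilon(F) and its variants.

    For the measured profile::

        epsilon(F) = eps0 * exp(|F| / Fd_minus)            F <= 0
                     eps0 * (1 + bridge_slope * F)         0 < F <= 2 pN
                     eps0 * bridge_prefactor * exp(F / Fd_plus)   F > 2 pN

    The bridge constants are chosen so the linear segment joins the
    assisting exponential at +2 pN to within 0.1%.
    """

    variant: ProfileVariant = ProfileVariant.MEASURED
    v0: float = 800.0
    l0: float = 1500.0
    kBT: float = KBT
    delta_minus: float = 0.60
    delta_plus: float = 0.32
    bridge_slope: float = 3.8247
    bridge_prefactor: float = 7.4
    bridge_end: float = 2.0
    Fd_minus: float = field(init=False)
    Fd_plus: float = field(init=False)
    eps0: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("v0", "l0", "kBT", "delta_minus", "delta_plus",
                     "bridge_slope", "bridge_prefactor", "bridge_end"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"DetachmentProfile.{name} must be positive")
        object.__setattr__(self, "Fd_minus", detachment_force(self.delta_minus, self.kBT))
        object.__setattr__(self, "Fd_plus", detachment_force(self.delta_plus, self.kBT))
        object.__setattr__(self, "eps0", unloaded_detachment_rate(self.v0, self.l0))

    # -- rate evaluation ---------------------------------------------------

    def _measured(self, F: float) -> float:
        if F <= 0:
            return self.eps0 * math.exp(abs(F) / self.Fd_minus)
        if F <= self.bridge_end:
            return self.eps0 * (1.0 + self.bridge_slope * F)
        return self.eps0 * self.bridge_prefactor * math.exp(F / self.Fd_plus)

    def rate(self, F: float) -> float:
        """Detachment rate at signed load F (pN), 1/s."""
        v = self.variant
        if v is ProfileVariant.MEASURED:
            return self._measured(F)
        if v is ProfileVariant.SYMMETRIC_HINDERING:
            return self.eps0 * math.exp(abs(F) / self.Fd_minus)
        if v is ProfileVariant.SYMMETRIC_ASSISTING:
            a = abs(F)
            if a <= self.bridge_end:
                return self.eps0 * (1.0 + self.bridge_slope * a)
            return self.eps0 * self.bridge_prefactor * math.exp(a / self.Fd_plus)
        if v is ProfileVariant.REVERSED:
            return self._measured(-F)
        raise InvalidParameterError(f"unknown profile variant {v!r}")

    def rates(self, F: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`rate` over an array of signed loads."""
        F = np.asarray(F, dtype=float)
        v = self.variant
        if v is ProfileVariant.REVERSED:
            F = -F
            v = ProfileVariant.MEASURED
        a = np.abs(F)
        hind = self.eps0 * np.exp(a / self.Fd_minus)
        lin = self.eps0 * (1.0 + self.bridge_slope * a)
        expo = self.eps0 * self.bridge_prefactor * np.exp(a / self.Fd_plus)
        assist = np.where(a <= self.bridge_end, lin, expo)
        if v is ProfileVariant.MEASURED:
            return np.where(F <= 0, hind, assist)
        if v is ProfileVariant.SYMMETRIC_HINDERING:
            return hind
        if v is ProfileVariant.SYMMETRIC_ASSISTING:
            return assist
        raise InvalidParameterError(f"unknown profile variant {v!r}")


def detachment_rate(F: float, profile: DetachmentProfile) -> float:
    """Detachment rate epsilon(F) for a signed load F (pN), 1/s."""
    return profile.rate(F)


def make_profile(
    variant: ProfileVariant | str = ProfileVariant.MEASURED,
    motor: MotorParams | None = None,
    **overrides: float,
) -> DetachmentProfile:
    """Build a :class:`DetachmentProfile` consistent with a motor's kinetics.

    The unloaded detachment rate is tied to the motor through
    eps0 = v0 / l0; keyword overrides reach any remaining profile field.
    """
    try:
        variant = ProfileVariant(variant)
    except ValueError as exc:
        raise InvalidParameterError(f"unknown profile variant {variant!r}") from exc
    motor = motor or MotorParams()
    return DetachmentProfile(variant=variant, v0=motor.v0, l0=motor.l0, **overrides)
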