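"""Configuration files: parsing, validation, defaults, serialization.

A run configuration is a single YAML file with flat key-value sections
``motor``, ``detachment``, ``fluid``, ``simulation`` and (optionally)
``sweep``.  An empty file resolves to the default parameter set.  Every
resolved configuration can be echoed back as a JSON sidecar so a run is
reproducible bit-for-bit from its output directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .engine import SimulationConfig
from .errors import ConfigValidationError, InvalidParameterError
from .kinetics import DetachmentProfile, MotorParams, ProfileVariant
from .mechanics import ETA_WATER, FluidCargo

_MOTOR_KEYS = {"v0", "l0", "step_size", "Fs", "kappa", "L0", "k_on"}
_DETACH_KEYS = {"variant", "kBT", "delta_minus", "delta_plus",
                "bridge_slope", "bridge_prefactor", "bridge_end"}
_FLUID_KEYS = {"d", "eta_rel", "eta", "chi"}
_SIM_KEYS = {"dt", "n_replicates", "max_steps", "seed", "mode",
             "equilibrium_steps", "burn_in", "record_stride",
             "include_binding_wait", "diffusion"}
_SWEEP_KEYS = {"eta_rel", "d", "v0", "kappa", "variants", "diffusion",
               "replicates", "seed", "mode", "record_stride", "burn_in"}
_SECTIONS = {"motor": _MOTOR_KEYS, "detachment": _DETACH_KEYS,
             "fluid": _FLUID_KEYS, "simulation": _SIM_KEYS, "sweep": _SWEEP_KEYS}


@dataclass(frozen=True)
class SweepSpec:
    """A grid of simulation conditions (outer product of the axes).

    Axes are viscosity in multiples of water, cargo diameter (nm), unloaded
    velocity (nm/s), motor stiffness (pN/nm), detachment-profile variant and
    the diffusion on/off switch.  ``mode`` selects transport ensembles or
    equilibrium displacement sampling.
    """

    eta_rel: tuple[float, ...] = (1.0,)
    d: tuple[float, ...] = (500.0,)
    v0: tuple[float, ...] = (800.0,)
    kappa: tuple[float, ...] = (0.32,)
    variants: tuple[str, ...] = ("measured",)
    diffusion: tuple[bool, ...] = (True,)
    replicates: int = 1000
    seed: int = 0
    mode: str = "transport"
    record_stride: int = 0
    burn_in: int = 0

    def __post_init__(self) -> None:
        for axis in ("eta_rel", "d", "v0", "kappa", "variants", "diffusion"):
            if len(getattr(self, axis)) == 0:
                raise InvalidParameterError(f"sweep axis {axis} must be nonempty")
        if self.mode not in ("transport", "equilibrium"):
            raise InvalidParameterError(f"unknown sweep mode {self.mode!r}")

    @property
    def n_cells(self) -> int:
        return (len(self.eta_rel) * len(self.d) * len(self.v0)
                * len(self.kappa) * len(self.variants) * len(self.diffusion))


@dataclass(frozen=True)
class ResolvedConfig:
    """A fully validated configuration bundle."""

    motor: MotorParams
    profile: DetachmentProfile
    fluid: FluidCargo
    sim: SimulationConfig
    sweep: SweepSpec | None = None

    @property
    def resolved_dt(self) -> float:
        """Time step after the stiffness-dependent default is applied."""
        return self.sim.resolve_dt(self.motor)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "motor": dataclasses.asdict(self.motor),
            "detachment": dataclasses.asdict(self.profile),
            "fluid": dataclasses.asdict(self.fluid),
            "simulation": dataclasses.asdict(self.sim),
        }
        d["detachment"]["variant"] = self.profile.variant.value
        d["simulation"]["dt"] = self.resolved_dt
        d["fluid"]["eta_rel"] = self.fluid.eta_rel
        if self.sweep is not None:
            d["sweep"] = dataclasses.asdict(self.sweep)
        return d

    def write_sidecar(self, path: str | Path) -> Path:
        """Echo the resolved configuration as a JSON reproducibility record."""
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


def _check_positive(errors: list[str], section: str, data: dict, keys: set[str]) -> None:
    for k in keys:
        if k in data and not (isinstance(data[k], (int, float)) and data[k] > 0):
            errors.append(f"{section}.{k}: must be a positive number (got {data[k]!r})")


def resolve_config(raw: dict[str, Any] | None) -> ResolvedConfig:
    """Validate a parsed configuration mapping and apply defaults.

    All offending keys are collected and reported together in a single
    :class:`ConfigValidationError`.
    """
    raw = raw or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigValidationError(["top level must be a mapping of sections"])
    for section in raw:
        if section not in _SECTIONS:
            errors.append(f"unknown section {section!r}")
    sections = {name: dict(raw.get(name) or {}) for name in _SECTIONS}
    for name, allowed in _SECTIONS.items():
        for key in sections[name]:
            if key not in allowed:
                errors.append(f"unknown key {name}.{key}")
        sections[name] = {k: v for k, v in sections[name].items() if k in allowed}

    m, det, fl, sim, sw = (sections[s] for s in
                           ("motor", "detachment", "fluid", "simulation", "sweep"))
    _check_positive(errors, "motor", m, _MOTOR_KEYS)
    _check_positive(errors, "detachment", det, _DETACH_KEYS - {"variant"})
    _check_positive(errors, "fluid", fl, _FLUID_KEYS)
    _check_positive(errors, "simulation", sim,
                    {"dt", "n_replicates", "max_steps", "equilibrium_steps"})
    variant = det.pop("variant", "measured")
    try:
        variant = ProfileVariant(variant)
    except ValueError:
        errors.append(f"detachment.variant: unknown variant {variant!r}")
        variant = ProfileVariant.MEASURED
    if "eta" in fl and "eta_rel" in fl:
        errors.append("fluid: give either eta or eta_rel, not both")
    if errors:
        raise ConfigValidationError(sorted(errors))

    motor = MotorParams(**m)
    profile = DetachmentProfile(variant=variant, v0=motor.v0, l0=motor.l0, **det)
    eta = fl.pop("eta", None)
    eta_rel = fl.pop("eta_rel", None)
    if eta is None:
        eta = (eta_rel if eta_rel is not None else 1.0) * ETA_WATER
    fluid = FluidCargo(eta=eta, **fl)
    simcfg = SimulationConfig(**sim)
    sweep = None
    if sw:
        for axis in ("eta_rel", "d", "v0", "kappa", "variants", "diffusion"):
            if axis in sw and not isinstance(sw[axis], (list, tuple)):
                sw[axis] = [sw[axis]]
        sweep = SweepSpec(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in sw.items()})
    return ResolvedConfig(motor=motor, profile=profile, fluid=fluid,
                          sim=simcfg, sweep=sweep)


def load_config(path: str | Path) -> ResolvedConfig:
    """Read and validate a YAML configuration file.

    An empty file yields the default configuration.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigValidationError([f"could not parse {path}: {exc}"]) from exc
    return resolve_config(raw)
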