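"""Sweep orchestration over viscosity, cargo size, velocity and stiffness.

A sweep executes the outer product of the grid axes in a
:class:`~kinesim.config.SweepSpec`.  Transport cells produce a run-length
ensemble that is fitted and summarized; equilibrium cells sample the
cargo-motor displacement distribution.  One summary row per cell, sorted
by characteristic drag, is written as CSV together with a JSON sidecar of
the resolved grid so every number can be regenerated from the seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .config import SweepSpec
from .engine import SimulationConfig, simulate_ensemble, simulate_equilibrium
from .kinetics import KBT, MotorParams, make_profile
from .mechanics import ETA_WATER, FluidCargo

log = logging.getLogger("kinesim")

SUMMARY_COLUMNS = [
    "eta_rel", "d_nm", "v0_nm_s", "kappa_pN_nm", "variant", "diffusion",
    "drag_pN", "eta_d", "norm_run_length", "norm_run_length_sem",
    "mean_velocity_nm_s", "velocity_sem_nm_s", "p_assisting", "p_hindering",
    "mean_excursion_assisting_nm", "mean_excursion_hindering_nm",
    "eff_detachment_rel", "n", "error",
]


@dataclass
class SummaryRow:
    """One sweep cell: condition identifiers plus summary statistics.

    ``drag_pN`` is the characteristic drag 9*pi*eta*d*v0 recomputed from
    the row's own fields; ``eta_d`` the viscosity-diameter product in
    pN*s/nm.  Fields that do not apply to a cell's mode are NaN.
    """

    eta_rel: float
    d_nm: float
    v0_nm_s: float
    kappa_pN_nm: float
    variant: str
    diffusion: bool
    drag_pN: float = np.nan
    eta_d: float = np.nan
    norm_run_length: float = np.nan
    norm_run_length_sem: float = np.nan
    mean_velocity_nm_s: float = np.nan
    velocity_sem_nm_s: float = np.nan
    p_assisting: float = np.nan
    p_hindering: float = np.nan
    mean_excursion_assisting_nm: float = np.nan
    mean_excursion_hindering_nm: float = np.nan
    eff_detachment_rel: float = np.nan
    n: int = 0
    error: str = ""


def _cells(spec: SweepSpec):
    return itertools.product(spec.eta_rel, spec.d, spec.v0, spec.kappa,
                             spec.variants, spec.diffusion)


def run_cell(
    spec: SweepSpec,
    cell_index: int,
    eta_rel: float,
    d: float,
    v0: float,
    kappa: float,
    variant: str,
    diffusion: bool,
    base_motor: MotorParams | None = None,
) -> tuple[SummaryRow, list | np.ndarray]:
    """Run one grid cell and summarize it.

    The cell seed is ``spec.seed + cell_index`` so a one-cell sweep is
    identical to a direct ensemble call with the master seed.
    """
    base = base_motor or MotorParams()
    motor = dataclasses.replace(base, v0=v0, kappa=kappa) if v0 > 0 else \
        dataclasses.replace(base, kappa=kappa)
    fluid = FluidCargo.from_water_multiple(eta_rel, d=d)
    profile = make_profile(variant, motor)
    row = SummaryRow(eta_rel=eta_rel, d_nm=d, v0_nm_s=v0, kappa_pN_nm=kappa,
                     variant=variant, diffusion=diffusion,
                     drag_pN=fluid.drag_at(v0), eta_d=fluid.eta * d)
    seed = spec.seed + cell_index
    if spec.mode == "equilibrium":
        cfg = SimulationConfig(n_replicates=spec.replicates, seed=seed,
                               mode="equilibrium", diffusion=diffusion,
                               burn_in=spec.burn_in)
        samples = simulate_equilibrium(cfg, motor, fluid)
        stats = analysis.displacement_stats(samples, motor.L0)
        row.p_assisting = stats.p_assisting
        row.p_hindering = stats.p_hindering
        row.mean_excursion_assisting_nm = stats.mean_excursion_assisting
        row.mean_excursion_hindering_nm = stats.mean_excursion_hindering
        row.eff_detachment_rel = analysis.effective_detachment_rate(
            samples, profile, motor.kappa, motor.L0) / profile.eps0
        row.n = stats.n
        return row, samples

    cfg = SimulationConfig(n_replicates=spec.replicates, seed=seed,
                           record_stride=spec.record_stride, diffusion=diffusion)
    records = simulate_ensemble(cfg, motor, fluid, profile)
    est = analysis.fit_run_length([r.run_length for r in records], seed=seed)
    row.norm_run_length, row.norm_run_length_sem = analysis.normalized_run_length(
        est, motor.l0)
    row.n = est.n
    if spec.record_stride > 0:
        try:
            v, vsem, _ = analysis.ensemble_velocity(records, seed=seed)
            row.mean_velocity_nm_s, row.velocity_sem_nm_s = v, vsem
        except analysis.InsufficientDataError:
            pass
        pooled = analysis.pooled_displacements(records)
        stats = analysis.displacement_stats(pooled, motor.L0)
        row.p_assisting = stats.p_assisting
        row.p_hindering = stats.p_hindering
        row.mean_excursion_assisting_nm = stats.mean_excursion_assisting
        row.mean_excursion_hindering_nm = stats.mean_excursion_hindering
        row.eff_detachment_rel = analysis.effective_detachment_rate(
            pooled, profile, motor.kappa, motor.L0) / profile.eps0
    return row, records


def run_sweep(
    spec: SweepSpec,
    out_dir: str | Path | None = None,
    base_motor: MotorParams | None = None,
    write_runs: bool = False,
) -> pd.DataFrame:
    """Execute every cell of a sweep and return the summary table.

    Cells that fail are recorded with their error message and the sweep
    continues.  When ``out_dir`` is given, writes ``summary.csv`` (sorted
    by characteristic drag), a JSON sidecar of the spec, and optionally a
    per-run CSV per cell.
    """
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for idx, (eta_rel, d, v0, kappa, variant, diffusion) in enumerate(_cells(spec)):
        try:
            row, payload = run_cell(spec, idx, eta_rel, d, v0, kappa, variant,
                                    diffusion, base_motor=base_motor)
        except Exception as exc:  # noqa: BLE001 - per-cell isolation is the contract
            log.error("cell %d (%s) failed: %s", idx,
                      (eta_rel, d, v0, kappa, variant, diffusion), exc)
            row = SummaryRow(eta_rel=eta_rel, d_nm=d, v0_nm_s=v0,
                             kappa_pN_nm=kappa, variant=variant,
                             diffusion=diffusion, error=str(exc),
                             drag_pN=9.0 * np.pi * eta_rel * ETA_WATER * d * v0,
                             eta_d=eta_rel * ETA_WATER * d)
            payload = None
        rows.append(row)
        if write_runs and out_dir is not None and spec.mode == "transport" \
                and payload is not None:
            runs = pd.DataFrame({
                "replicate": np.arange(len(payload)),
                "seed": [r.seed for r in payload],
                "run_length_nm": [r.run_length for r in payload],
                "duration_s": [r.duration for r in payload],
                "n_steps": [r.n_motor_steps for r in payload],
                "mean_load_pN": [
                    float(np.mean(r.loads(row.kappa_pN_nm, 40.0)))
                    if r.times.size else np.nan for r in payload],
            })
            runs.to_csv(out_dir / f"runs_cell{idx:04d}.csv", index=False)
    table = pd.DataFrame([dataclasses.asdict(r) for r in rows],
                         columns=SUMMARY_COLUMNS)
    table = table.sort_values("drag_pN", kind="stable").reset_index(drop=True)
    if out_dir is not None:
        table.to_csv(out_dir / "summary.csv", index=False)
        (out_dir / "sweep.json").write_text(
            json.dumps(dataclasses.asdict(spec), indent=2) + "\n")
    return table


# -- presets mirroring the published experiment designs ---------------------

_ETA_GRID = (1.0, 2.2, 4.6, 10.0, 22.0, 46.0, 100.0, 220.0, 460.0, 1000.0)


PRESETS = ("viscosity_sweep", "size_velocity_sweep", "zero_drag_equilibrium",
           "stiffness_sweep", "detachment_variants")


def preset(name: str, replicates: int = 1000, seed: int = 0) -> SweepSpec:
    """Named sweep presets for the headline experiment designs.

    ``viscosity_sweep``: 1-1000x water at d = 0.5 um, v0 = 0.8 um/s, with
    and without cargo diffusion.  ``size_velocity_sweep``: cargo-size and
    velocity grid for the drag-collapse analysis.
    ``zero_drag_equilibrium``: displacement sampling at v = 0 over the
    viscosity/size grid.  ``stiffness_sweep``: equilibrium sampling over a
    100-fold tether-stiffness range.  ``detachment_variants``: the four
    detachment-profile variants over a drag grid.
    """
    if name == "viscosity_sweep":
        return SweepSpec(eta_rel=_ETA_GRID, diffusion=(True, False),
                         replicates=replicates, seed=seed)
    if name == "size_velocity_sweep":
        return SweepSpec(eta_rel=_ETA_GRID, d=(100.0, 320.0, 1000.0),
                         v0=(400.0, 800.0, 1600.0),
                         replicates=replicates, seed=seed)
    if name == "zero_drag_equilibrium":
        return SweepSpec(eta_rel=(1.0, 10.0, 100.0, 1000.0),
                         d=(100.0, 500.0, 1000.0), v0=(0.0,),
                         replicates=10, seed=seed, mode="equilibrium")
    if name == "stiffness_sweep":
        return SweepSpec(eta_rel=(1.0,), v0=(0.0,),
                         kappa=tuple(np.round(0.32 * np.logspace(-1, 1, 7), 5)),
                         replicates=10, seed=seed, mode="equilibrium")
    if name == "detachment_variants":
        return SweepSpec(eta_rel=(0.1, 1.0, 10.0, 22.0, 100.0, 500.0),
                         variants=("measured", "symmetric_hindering",
                                   "symmetric_assisting", "reversed"),
                         replicates=replicates, seed=seed)
    raise KeyError(f"unknown preset {name!r}")


# -- Boltzmann stationary distribution of the tethered cargo ----------------


def boltzmann_sigma(kappa: float = 0.32, kBT: float = KBT) -> float:
    """Gaussian width sqrt(kBT / kappa) of the tethered tail, nm."""
    return float(np.sqrt(kBT / kappa))


def boltzmann_tail_probability(kappa: float = 0.32, L0: float = 40.0,
                               kBT: float = KBT) -> float:
    """Per-side stationary probability of |delta| > L0.

    The tether potential is flat inside +/-L0 and harmonic outside, so the
    stationary density is uniform inside and half-Gaussian (width
    sigma = sqrt(kBT/kappa)) outside; each tail carries mass
    sigma*sqrt(pi/2) relative to the flat region's 2*L0.
    """
    s = boltzmann_sigma(kappa, kBT) * np.sqrt(np.pi / 2.0)
    return float(s / (2.0 * L0 + 2.0 * s))


def boltzmann_mean_excursion(kappa: float = 0.32, kBT: float = KBT) -> float:
    """Mean excursion beyond the rest length, sigma*sqrt(2/pi), nm."""
    return float(boltzmann_sigma(kappa, kBT) * np.sqrt(2.0 / np.pi))


def boltzmann_displacement_sample(
    n: int,
    kappa: float = 0.32,
    L0: float = 40.0,
    kBT: float = KBT,
    seed: int = 0,
) -> np.ndarray:
    """Draw displacements from the stationary density by inverse CDF.

    Independent of the simulation engine; serves as the continuum oracle
    for equilibrium-mode sampling.
    """
    from scipy.special import erfinv

    rng = np.random.default_rng(seed)
    sigma = boltzmann_sigma(kappa, kBT)
    p_tail = boltzmann_tail_probability(kappa, L0, kBT)
    u = rng.random(n)
    w = rng.random(n)
    # half-normal inverse CDF for the tail excursion
    exc = sigma * np.sqrt(2.0) * erfinv(w)
    out = np.empty(n)
    lo = u < p_tail
    hi = u > 1.0 - p_tail
    mid = ~(lo | hi)
    out[lo] = -(L0 + exc[lo])
    out[hi] = L0 + exc[hi]
    out[mid] = -L0 + 2.0 * L0 * (u[mid] - p_tail) / (1.0 - 2.0 * p_tail)
    return out


def stationary_displacement_sample(
    motor: MotorParams,
    fluid: FluidCargo,
    n_chains: int = 10,
    samples_per_chain: int = 20_000,
    seed: int = 0,
    dt: float | None = None,
    span_crossings: float = 10.0,
) -> np.ndarray:
    """Equilibrium displacement samples with stationarity safeguards.

    The slow time scale of the tethered cargo is the diffusive crossing of
    the 2*L0 free range, t_cross = (2*L0)^2 / (2*D), which grows linearly
    with viscosity and cargo size.  Each chain discards a burn-in of
    5*t_cross (at least 20 tether relaxation times) and records
    ``samples_per_chain`` displacements strided so the recorded window
    spans at least ``span_crossings``*t_cross, keeping the pooled sample
    representative of the stationary distribution at every viscosity.
    Raise ``span_crossings`` when a small per-cell standard error matters
    more than run time (the effective sample size grows with the span, not
    with the raw sample count).

    When ``dt`` is not given it is scaled inversely with the diffusion
    coefficient (relative to the default 0.5-um cargo in water), which
    keeps the dimensionless discretization — per-step diffusive jump over
    rest length and relaxation fraction kappa*dt/xi — identical for every
    viscosity and cargo size, so cells are directly comparable and the
    cost per cell is viscosity-independent.
    """
    from .engine import SimulationConfig, simulate_equilibrium
    from .mechanics import diffusion_coefficient, friction_coefficient

    cfg0 = SimulationConfig(mode="equilibrium")
    if dt is None:
        d_ref = diffusion_coefficient(friction_coefficient(ETA_WATER, 500.0, 3.0))
        dt = cfg0.resolve_dt(motor) * d_ref / fluid.D
    t_cross = (2.0 * motor.L0) ** 2 / (2.0 * fluid.D)
    t_relax = fluid.xi / motor.kappa
    burn = int(np.ceil(max(5.0 * t_cross, 20.0 * t_relax) / dt))
    stride = max(1, int(np.ceil(span_crossings * t_cross / (samples_per_chain * dt))))
    cfg = SimulationConfig(
        mode="equilibrium", n_replicates=n_chains, seed=seed, dt=dt,
        equilibrium_steps=samples_per_chain * stride,
        record_stride=stride, burn_in=burn,
    )
    return simulate_equilibrium(cfg, motor, fluid)


# -- deterministic fixtures for analysis tests ------------------------------


def generate_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write small deterministic artifacts for analysis unit tests.

    (a) 500 exponential run lengths with mean 1500 nm; (b) 10^4 Boltzmann
    displacement samples at default stiffness; (c) a noiseless linear
    trajectory at 800 nm/s.  Byte-identical for a given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    runs = rng.exponential(1500.0, size=500)
    p_runs = out / "exponential_run_lengths.csv"
    np.savetxt(p_runs, runs, fmt="%.6f", header="run_length_nm", comments="")

    disp = boltzmann_displacement_sample(10_000, seed=seed + 1)
    p_disp = out / "boltzmann_displacements.csv"
    np.savetxt(p_disp, disp, fmt="%.6f", header="displacement_nm", comments="")

    t = np.arange(0.0, 1.0, 1e-3)
    traj = np.column_stack([t, 800.0 * t])
    p_traj = out / "linear_trajectory.csv"
    np.savetxt(p_traj, traj, fmt="%.6f", header="time_s,cargo_nm",
               delimiter=",", comments="")
    return {"run_lengths": p_runs, "displacements": p_disp, "trajectory": p_traj}
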