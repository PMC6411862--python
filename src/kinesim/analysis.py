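"""Estimation procedures applied to simulated ensembles.

Run lengths of a single motor detaching at a (load-averaged) constant rate
are exponentially distributed; the mean run length is estimated as the
decay constant of an exponential CDF fitted to the empirical cumulative
distribution, with a bootstrap standard error.  Velocities come from the
least-squares slope of sampled trajectories, subject to the standard
single-molecule screening filters (minimum duration and travel).  The
displacement statistics quantify tethered excursions of the cargo beyond
the 40-nm rest length, from which a frequency-weighted effective
detachment rate — and hence an implied run length v / epsilon — follows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .engine import TrajectoryRecord
from .errors import FitFailureError, InsufficientDataError, InvalidParameterError
from .kinetics import DetachmentProfile, MotorParams, stepping_rate
from .mechanics import tether_load_on_motor

# -- run length -------------------------------------------------------------


@dataclass(frozen=True)
class RunLengthEstimate:
    """Exponential-CDF fit of an ensemble of run lengths.

    ``l`` is the decay constant (nm, the mean run length), ``A`` the fitted
    amplitude, ``sem`` the bootstrap standard error of ``l``.
    """

    l: float
    A: float
    sem: float
    n: int


def _ecdf(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(x)
    return xs, np.arange(1, xs.size + 1) / xs.size


def _fit_exponential_cdf(x: np.ndarray) -> tuple[float, float]:
    xs, ys = _ecdf(x)
    mean = float(np.mean(xs))
    popt, _ = optimize.curve_fit(
        lambda t, A, l: 1.0 - A * np.exp(-t / l),
        xs, ys, p0=(1.0, mean), maxfev=10_000,
    )
    return float(popt[1]), float(popt[0])


def fit_run_length(
    run_lengths: Sequence[float] | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> RunLengthEstimate:
    """Fit 1 - A*exp(-x/l) to the empirical run-length CDF.

    Unweighted nonlinear least squares over all empirical points with free
    (A, l); the SEM is the standard deviation of ``l`` over ``n_boot``
    resamples with replacement.

    Raises
    ------
    InsufficientDataError
        Fewer than 10 finite positive run lengths.
    FitFailureError
        Degenerate input (no spread) or non-convergence.
    """
    x = np.asarray(run_lengths, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 10:
        raise InsufficientDataError(f"need >= 10 positive run lengths, got {x.size}")
    if np.ptp(x) == 0.0:
        raise FitFailureError("all run lengths identical; exponential fit is degenerate")
    try:
        l, A = _fit_exponential_cdf(x)
    except RuntimeError as exc:
        raise FitFailureError(f"exponential CDF fit did not converge: {exc}") from exc
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        resampled = rng.choice(x, size=x.size, replace=True)
        try:
            boot[b], _ = _fit_exponential_cdf(resampled)
        except RuntimeError:
            boot[b] = np.nan
    sem = float(np.nanstd(boot, ddof=1))
    return RunLengthEstimate(l=l, A=A, sem=sem, n=int(x.size))


def normalized_run_length(estimate: RunLengthEstimate, l0: float) -> tuple[float, float]:
    """(l / l0, sem / l0): run length as a fraction of the unloaded value."""
    if l0 <= 0:
        raise InvalidParameterError("l0 must be positive")
    return estimate.l / l0, estimate.sem / l0


# -- velocity ---------------------------------------------------------------


@dataclass(frozen=True)
class VelocityResult:
    """Slope estimate for one trajectory; ``accepted`` is False when the
    trajectory fails a screening filter (reason recorded)."""

    velocity: float
    accepted: bool
    reason: str = ""


def trajectory_velocity(
    record: TrajectoryRecord,
    min_duration: float = 0.2,
    min_displacement: float = 100.0,
    use: str = "cargo",
) -> VelocityResult:
    """Least-squares slope (nm/s) of a sampled trajectory.

    Trajectories shorter than ``min_duration`` seconds, or that travelled
    less than ``min_displacement`` nm, are rejected (typed outcome, not an
    exception).  ``use`` selects cargo (bead-tracking convention) or motor
    positions.
    """
    pos = record.cargo if use == "cargo" else record.motor
    if record.times.size < 2:
        return VelocityResult(np.nan, False, "too few samples")
    if record.duration < min_duration:
        return VelocityResult(np.nan, False, f"duration < {min_duration} s")
    if abs(pos[-1] - pos[0]) < min_displacement:
        return VelocityResult(np.nan, False, f"displacement < {min_displacement} nm")
    slope = np.polyfit(record.times, pos, 1)[0]
    return VelocityResult(float(slope), True)


def ensemble_velocity(
    records: Iterable[TrajectoryRecord],
    n_boot: int = 1000,
    seed: int = 0,
    **filters,
) -> tuple[float, float, int]:
    """Mean of accepted trajectory velocities with bootstrap SEM.

    Returns (mean, sem, n_accepted).
    """
    v = np.array([r.velocity for rec in records
                  if (r := trajectory_velocity(rec, **filters)).accepted])
    if v.size < 2:
        raise InsufficientDataError("fewer than 2 trajectories passed the velocity filters")
    rng = np.random.default_rng(seed)
    boot = [np.mean(rng.choice(v, v.size, replace=True)) for _ in range(n_boot)]
    return float(np.mean(v)), float(np.std(boot, ddof=1)), int(v.size)


# -- displacement and load statistics ---------------------------------------


@dataclass(frozen=True)
class DisplacementStats:
    """Occupancy of the free- and tethered-diffusion ranges.

    Probabilities are fractions of samples with the cargo inside the rest
    length (``p_free``), leading beyond it (``p_assisting``), or lagging
    beyond it (``p_hindering``); they sum to 1.  Mean excursions are
    |delta| - L0 averaged over the respective tethered samples, nm.
    """

    p_free: float
    p_assisting: float
    p_hindering: float
    mean_excursion_assisting: float
    mean_excursion_hindering: float
    n: int


def displacement_stats(samples: np.ndarray, L0: float = 40.0) -> DisplacementStats:
    """Classify cargo-motor displacements against the tether rest length."""
    d = np.asarray(samples, dtype=float)
    if d.size == 0:
        raise InsufficientDataError("no displacement samples")
    lead = d > L0
    lag = d < -L0
    n = d.size
    exc_a = float(np.mean(d[lead] - L0)) if lead.any() else 0.0
    exc_h = float(np.mean(-d[lag] - L0)) if lag.any() else 0.0
    return DisplacementStats(
        p_free=float(np.mean(~lead & ~lag)),
        p_assisting=float(np.mean(lead)),
        p_hindering=float(np.mean(lag)),
        mean_excursion_assisting=exc_a,
        mean_excursion_hindering=exc_h,
        n=n,
    )


def load_histogram(
    records: Iterable[TrajectoryRecord],
    bin_width: float,
    motor: MotorParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of sampled signed loads pooled across runs.

    Returns (bin_edges, frequency); frequencies sum to 1.
    """
    loads = [r.loads(motor.kappa, motor.L0) for r in records if r.times.size]
    if not loads:
        raise InsufficientDataError("no sampled loads in the records")
    pooled = np.concatenate(loads)
    lo = np.floor(pooled.min() / bin_width) * bin_width
    hi = np.ceil(pooled.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(pooled, bins=edges)
    return edges, counts / counts.sum()


def pooled_displacements(records: Iterable[TrajectoryRecord]) -> np.ndarray:
    """Concatenate sampled cargo-motor displacements across runs."""
    chunks = [r.displacements() for r in records if r.times.size]
    if not chunks:
        raise InsufficientDataError("no sampled positions in the records")
    return np.concatenate(chunks)


# -- effective rates and implied run length ---------------------------------


def sample_loads(samples: np.ndarray, kappa: float, L0: float) -> np.ndarray:
    """Signed tether loads for an array of displacements."""
    d = np.asarray(samples, dtype=float)
    out = np.zeros_like(d)
    lead = d > L0
    lag = d < -L0
    out[lead] = kappa * (d[lead] - L0)
    out[lag] = -kappa * (-d[lag] - L0)
    return out


def effective_detachment_rate(
    samples: np.ndarray,
    profile: DetachmentProfile,
    kappa: float,
    L0: float,
) -> float:
    """Frequency-weighted detachment rate (1/s) over a displacement sample.

    The mean of epsilon(F(delta)) over the sampled displacements; equals
    eps0 when every sample lies in the free range, and exceeds it otherwise
    since epsilon is minimized at zero load.
    """
    F = sample_loads(samples, kappa, L0)
    return float(np.mean(profile.rates(F)))


def effective_stepping_rate(samples: np.ndarray, motor: MotorParams) -> float:
    """Frequency-weighted stepping rate (1/s) over a displacement sample."""
    F = sample_loads(samples, motor.kappa, motor.L0)
    k = np.array([stepping_rate(f, motor) for f in np.nditer(F)]) if F.size else np.array([])
    return float(np.mean(k))


def predicted_run_length(velocity: float, detachment_rate: float) -> float:
    """Run length (nm) implied by a velocity and a detachment rate, v / eps."""
    if detachment_rate <= 0:
        raise InvalidParameterError("detachment rate must be positive")
    return velocity / detachment_rate


def implied_normalized_run_length(
    samples: np.ndarray,
    motor: MotorParams,
    profile: DetachmentProfile,
) -> float:
    """Implied run length from a displacement distribution, as a fraction
    of the unloaded value.

    The velocity is the unloaded velocity scaled by the weighted stepping
    rate, the detachment rate the weighted epsilon; the ratio
    (k_eff / k0) / (eps_eff / eps0) is the normalized v / epsilon.
    """
    eps_eff = effective_detachment_rate(samples, profile, motor.kappa, motor.L0)
    k_eff = effective_stepping_rate(samples, motor)
    return (k_eff / motor.k0) / (eps_eff / profile.eps0)


# -- stiffness scaling ------------------------------------------------------


def stiffness_scaling_slope(
    stiffnesses: Sequence[float],
    mean_loads: Sequence[float],
) -> tuple[float, float]:
    """Log-log slope of conditional mean load magnitude versus stiffness.

    Fits log10(mean load among load-bearing samples) against log10(kappa)
    by least squares and returns (slope, stderr).  Equipartition in the
    harmonic tail predicts mean load ~ sqrt(kappa * kBT), i.e. slope 1/2.
    """
    k = np.asarray(stiffnesses, dtype=float)
    m = np.asarray(mean_loads, dtype=float)
    if k.size < 3:
        raise InsufficientDataError("need >= 3 stiffness points")
    if k.max() / k.min() < 10.0:
        raise InsufficientDataError("stiffness range must span >= 10-fold")
    res = stats.linregress(np.log10(k), np.log10(m))
    return float(res.slope), float(res.stderr)
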