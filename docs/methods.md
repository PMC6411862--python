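# Model and methods

## The transport model

`kinesim` simulates a single kinesin-1 motor carrying a spherical cargo
along a one-dimensional microtubule lattice through a viscous medium.  The
motor is a stochastic stepper; the cargo is an overdamped Brownian particle;
the two are connected by a tether that is slack up to a rest length
L0 = 40 nm and Hookean (stiffness κ, default 0.32 pN/nm) beyond it.  Forces
are signed along the direction of motion: positive loads assist the motor,
negative loads hinder it.  The load on the motor at cargo–motor
displacement Δ is

    F(Δ) = 0                      |Δ| ≤ L0
           +κ (Δ − L0)            Δ >  L0   (cargo leads: assisting)
           −κ (|Δ| − L0)          Δ < −L0   (cargo lags: hindering)

and the cargo feels the opposite force.

**Stepping.**  The motor advances in 8-nm steps with a quadratic
force–velocity relation: rate k_step(F) = (v0/Δx)(1 − (F/Fs)²) under
sub-stall hindering load, zero at and beyond the stall force Fs = 7 pN, and
the unloaded rate v0/Δx under assisting load.  Default unloaded velocity
v0 = 800 nm/s.

**Detachment.**  Detachment from the microtubule is Bell-like with a strong
directional asymmetry.  With ε0 = v0/l0 (unloaded run length
l0 = 1500 nm ⇒ ε0 ≈ 0.533 s⁻¹):

    ε(F) = ε0 · exp(|F|/Fd−)          F ≤ 0        Fd− = kBT/0.60 nm = 6.85 pN
           ε0 · (1 + 3.8247 F)        0 < F ≤ 2 pN
           ε0 · 7.4 · exp(F/Fd+)      F > 2 pN     Fd+ = kBT/0.32 nm = 12.84 pN

The 0–2 pN linear bridge joins the unloaded rate to the measured assisting
branch at +2 pN (the two expressions there agree to <0.1%).  Because
Fd+ applies on top of a 7.4-fold prefactor, assisting load is far more
destructive than hindering load of the same magnitude — the asymmetry that
drives every non-trivial result of the model.  Three synthetic variants
(`symmetric_hindering`, `symmetric_assisting`, `reversed`) replace this law
by its even extensions or its mirror image for control experiments.

**Cargo dynamics.**  The cargo obeys overdamped Langevin dynamics with
friction ξ = χ·3πηd and diffusion D = kBT/ξ (fluctuation–dissipation is
exact by construction).  The wall-correction factor defaults to χ = 3,
i.e. ξ = 9πηd, the Stokes friction of a bead translating close to a hard
wall — the geometry of bead assays.  With this default the steady-state
tether load on a moving motor equals the characteristic drag

    F_drag = 9πηdv,

the single control parameter against which viscosity, cargo-size and
velocity sweeps collapse.  χ = 1 (free-space Stokes) is selectable.
Internal units are pN, nm, s; viscosity is stored in pN·s/nm² with water
= 1e-9 (1 mPa·s).

## Time stepping

Per step Δt the engine evaluates, in order: tether load; detachment
(Bernoulli, probability ε(F)Δt — a run ends at the first success); stepping
(Bernoulli, k_step(F)Δt); cargo update by Euler–Maruyama,
Δx_cargo = (−F/ξ)Δt + √(2DΔt)·N(0,1).  Runs start with the cargo at the
motor (Δ = 0) and, optionally, after an exponential binding wait at
k_on = 5 s⁻¹ (bookkeeping only; it cannot affect the run).  Δt defaults to
10 µs, switching to 1 µs for κ > 0.32 pN/nm where the stiffer tether needs
finer resolution; a warning is emitted if any rate·Δt exceeds 0.1.
Alternative update orderings (step before detach) differ at O(rate·Δt) and
are below statistical resolution; the ordering above is fixed, not
configurable.  Each replicate runs on its own RNG stream spawned from the
master seed, so ensembles are bit-reproducible and order-independent.

Equilibrium mode holds the motor still and disables detachment (ε0 = v0/l0
is ill-defined at v0 = 0), sampling the stationary cargo–motor displacement
distribution.  In the continuum limit that distribution is Boltzmann in the
flat-bottomed tether potential: uniform inside ±L0 and half-Gaussian with
width σ = √(kBT/κ) ≈ 3.58 nm beyond.  Closed forms used as oracles: tail
mass per side σ√(π/2)/(2L0 + 2σ√(π/2)) ≈ 5.05%, mean excursion
σ√(2/π) ≈ 2.86 nm.

### Stationary sampling protocol

The slowest cargo time scale is the diffusive crossing of the free range,
t_cross = (2L0)²/(2D), which reaches tens of seconds at 1000× water
viscosity — far longer than a naive 0.2-s equilibrium run.  Wherever
stationary displacement statistics are reported
(`stationary_displacement_sample`), each chain therefore (i) discards a
burn-in of 5 t_cross (at least 20 tether relaxation times ξ/κ), (ii)
records a fixed sample budget strided so the window spans ≥ 10 t_cross
(longer, 120 t_cross, for the stiffness sweep, where a max-minus-min range
statistic demands small per-point errors), and (iii) scales Δt inversely
with D so that the dimensionless discretization — per-step jump
√(2DΔt) relative to L0 and relaxation fraction κΔt/ξ — is identical for
every viscosity and cargo size.  This keeps cells statistically comparable
and the cost per cell viscosity-independent.

## Analysis procedures

*Run length*: the empirical CDF of per-run travel distances is fitted by
unweighted nonlinear least squares to 1 − A·exp(−x/l) with free (A, l);
the decay constant l is the mean run length and its SEM is the standard
deviation of l over 1000 bootstrap resamples.  *Velocity*: least-squares
slope of the sampled cargo trajectory, after the standard screening
filters (duration ≥ 0.2 s, travel ≥ 100 nm); rejection is a typed result,
not an error.  *Displacement statistics*: occupancy of the free /
assisting-tethered / hindering-tethered ranges and mean excursions
|Δ| − L0.  *Effective rates*: frequency-weighted means of ε(F(Δ)) and
k_step(F(Δ)) over a displacement sample; the implied normalized run length
is (k_eff/k0)/(ε_eff/ε0).  *Stiffness scaling*: least-squares slope of
log10(mean load among load-bearing samples) against log10 κ.  The mean is
conditional on nonzero load because the unconditional mean is
κ-independent under the Boltzmann density (tail mass ∝ κ^(−1/2) cancels
tail force ∝ κ^(+1/2)) and could not produce the observed square-root
scaling.

## Diffusion-free analytic model

Without diffusion the only load is the drag 9πηdv, always hindering.
Substituting into the force–velocity relation gives
v = v0(1 − (9πηdv/Fs)²), solved in closed form as
v = 2v0/(1 + √(1 + 4g²)) with g = 9πηdv0/Fs (rationalized to avoid
cancellation at small drag), and run length
l = (v/ε0)·exp(−9πηdv/Fd−).  The drag at which l falls a given fraction
below l0 is found by bracketed root search on (0, Fs); the 5% threshold is
0.34 pN, i.e. 0.3 pN to one significant figure.

## What the simulations show

Every statement below is recomputed by the test suite and
`scripts/acceptance.py` at run time.

Diffusion-free ensembles agree with the analytic curve across the drag
range.  With diffusion, runs shorten at low drag (the diffusing cargo
spends ≈5% of its time pulling the motor forward, where the detachment law
is steepest), recover near 0.2 pN drag (viscous drag biases the cargo
behind the motor, suppressing assisting load to below ~1% occupancy), and
shorten again at high drag (hindering viscous load).  The recovery
requires the measured asymmetry: symmetric or mirrored detachment laws
give monotone decay.  Stiffness changes the frequency and the magnitude of
tethered loads in compensating κ^(∓1/2) fashion, leaving the implied run
length nearly unchanged over a 100-fold κ range.

## Known limitations and deliberate deviations

* **Magnitude of the diffusion effect.**  Our equilibrium displacement
  distribution matches the continuum Boltzmann density (KS < 0.003 at fine
  Δt), giving a Boltzmann-weighted detachment rate of 1.18 ε0 and a ~13–16%
  diffusion-induced run-length reduction at negligible drag (normalized run
  length ≈ 0.87 at water viscosity).  Published estimates for this model
  (+30% detachment, ~24–26% reduction, 0.76 at water) imply per-side tails
  of ≈6% with ≈3.4 nm excursions — noticeably super-Boltzmann — which this
  integrator does not produce at the stated time step under either friction
  convention.  The corresponding acceptance assertions are kept at the
  published values and fail; every quantity not sensitive to this tail
  inflation reproduces well.
* **Stepping shot noise vs the closed form.**  The analytic diffusion-free
  model assumes the motor moves smoothly at v(F); the simulation steps in
  8-nm increments, each of which yanks a taut tether by κ·Δx ≈ 2.6 pN with
  relaxation time ξ/κ.  Because both the stepping and detachment laws are
  convex in |F|, these fluctuations cost run length, leaving diffusion-free
  ensembles a genuine 1–3% below the closed-form curve at intermediate drag
  (largest where the relaxation time is comparable to the stepping
  interval).  The effect is Δt-independent and intrinsic to discrete
  steppers.
* 1-D geometry; the cargo is a point with diameter entering only through
  ξ; no motor rebinding after detachment; no backstepping; no viscoelastic
  (memory) friction; nucleotide-state kinetics not modelled.
* Bernoulli-per-step kinetics assume rate·Δt ≪ 1; very small cargos
  (≪100 nm) need a finer Δt than the defaults.
* The synthetic controls (`symmetric_*`, `reversed`) are this package's
  even/mirror constructions of the measured law; their qualitative
  contracts (monotone run-length decay) are tested, their quantitative
  shapes are interpretation.
* Passing tests show correctness of the model as specified, on simulated
  data; they do not validate the underlying kinetic constants against new
  experiments.
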