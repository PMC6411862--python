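# kinesim

Monte Carlo simulation of cargo transport by a single kinesin-1 motor in a
viscous medium, for single-molecule biophysicists studying how thermal
diffusion of the cargo and viscous drag shape motor run length.

A kinesin walks in 8-nm steps along a microtubule while its cargo — a
bead of diameter d in a solution of viscosity η — diffuses and drifts at
the end of a tether that is slack below a 40-nm rest length and Hookean
(κ = 0.32 pN/nm) beyond it.  The motor steps with the quadratic
force–velocity law k_step(F) = (v0/Δx)(1 − (F/Fs)²) (stall force
Fs = 7 pN) and detaches at the Bell-type, directionally *asymmetric* rate

    ε(F) = ε0·exp(|F|/Fd−)        F ≤ 0          (hindering, Fd− = 6.85 pN)
           ε0·(1 + 3.8247·F)      0 < F ≤ 2 pN   (linear bridge)
           ε0·7.4·exp(F/Fd+)      F > 2 pN       (assisting, Fd+ = 12.84 pN)

with ε0 = v0/l0.  Assisting load is much more destructive than hindering
load, so a cargo that diffuses *ahead* of its motor shortens runs; viscous
drag (9πηdv) biases the cargo behind the motor and suppresses that effect,
producing a non-monotonic dependence of run length on drag.  The package
bundles the stochastic engine, the diffusion-free closed-form model, the
estimation procedures (exponential-CDF run-length fits with bootstrap
errors, velocity filters, displacement/load statistics, effective
detachment rates), a sweep orchestrator with YAML configuration, and a CLI.

## Worked example

```python
import kinesim as ks

motor   = ks.MotorParams()                      # v0=800 nm/s, l0=1500 nm, ...
profile = ks.make_profile("measured", motor)
fluid   = ks.FluidCargo.from_water_multiple(22.0)   # 22x water, d=0.5 um

cfg  = ks.SimulationConfig(n_replicates=1000, seed=1)
runs = ks.simulate_ensemble(cfg, motor, fluid, profile)
est  = ks.fit_run_length([r.run_length for r in runs], seed=1)
frac, sem = ks.normalized_run_length(est, motor.l0)
print(f"drag {fluid.drag_at(motor.v0):.3f} pN -> "
      f"run length {est.l:.0f} +/- {est.sem:.0f} nm "
      f"({100*frac:.1f} +/- {100*sem:.1f} % of unloaded)")

ai = ks.AnalyticInputs.from_components(motor, fluid, profile)
print(f"diffusion-free model: {ks.diffusion_free_run_length(ai):.0f} nm")
```

prints

```
drag 0.249 pN -> run length 1445 +/- 55 nm (96.3 +/- 3.7 % of unloaded)
diffusion-free model: 1445 nm
```

At 0.25 pN of drag the diffusing cargo almost never pulls the motor
forward, so the simulated run length sits on the diffusion-free curve and
within a few percent of the unloaded 1500 nm.  Repeating at 1× water
viscosity (drag 0.011 pN) gives ≈ 87% of the unloaded value — thermal
diffusion alone shortens runs — and at 500× water (drag 5.7 pN) runs
collapse to ≈ 40%: the non-monotonic signature.  The same sweep from the
shell:

```
kinesim sweep --preset viscosity_sweep --replicates 200 --out-dir scratch/sweep
kinesim rates --fmin -8 --fmax 8 --n 9        # ε(F), k_step(F) tables
```

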