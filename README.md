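# nestedfsi

Nested fluid–structure interaction analysis of fetal brain cushioning
during maternal convulsive motion.

During maternal trauma — here, simulated tonic–clonic seizure movements —
forces reach the fetal brain only after crossing two protective fluid
layers: the amniotic fluid between the uterine wall and the fetal body, and
the cerebrospinal fluid (CSF) between the skull and the brain.  `nestedfsi`
is a desk-scale computational model of that nested architecture for
researchers in prenatal biomechanics: a weakly compressible
smoothed-particle-hydrodynamics (SPH) fluid model coupled to explicit
viscoelastic finite-element solids through penalty contact, driven by
synthesised seizure roll kinematics, with the cushioning observables of the
analysis — normalised landmark separations, brain stress invariants, and
protected-vs-unprotected attenuation — as outputs.

## Model

Fluids follow the SPH discretisation with kernel interpolation
`A(r) = Σ_j (m_j/ρ_j) A_j W(|r−r_j|, h)`, the continuity equation
`Dρ_i/Dt = Σ_j m_j (v_i − v_j)·∇_i W_ij`, the momentum equation with
Monaghan artificial viscosity
`Dv_i/Dt = −Σ_j m_j (p_i/ρ_i² + p_j/ρ_j² + Π_ij) ∇_i W_ij + g`, and the
weakly compressible equation of state `p = c0²(ρ − ρ0)`.  Solids integrate
`M ü + C u̇ + K u = F_ext + F_FSI` explicitly with a generalized-Maxwell
deviatoric law `G(t) = G∞ + Σ_k G_k e^{−t/τ_k}` (stress split
`σ = σ_eq + Σ_k σ_k`).  Fluid and solid exchange forces through normal
penalty contact `F_c = k_c δ n` against the deformed surfaces.  The seizure
boundary condition is a calibrated stochastic roll signal (peak angular
velocity 9.5 ± 1.1 rad/s, excursion 0.50 ± 0.10 rad peak-to-peak, dominant
frequency 0.5 ± 0.1 Hz) prescribed as a rigid rotation of the uterine outer
wall; a complementary filter
`θ_fused = α(θ_prev + ωΔt) + (1−α) θ_accel` is included for processing raw
IMU recordings.  Stress reporting uses the standard invariants: von Mises
stress `σ_VM = √(½[(σ1−σ2)² + (σ2−σ3)² + (σ3−σ1)²])`, mean stress
`σ_m = (σ1+σ2+σ3)/3`, triaxiality `T_σ = σ_m/σ_VM`, and the first
deviatoric principal stress.

See `docs/methods.md` for assumptions, parameter defaults (and which are
placeholders), and known limitations.

## Worked example

```python
from nestedfsi import SimulationConfig, run_simulation
from nestedfsi.metrics import attenuation_percent

cfg = SimulationConfig(total_time=6.0, seed=0)          # 3 convulsion cycles
nested = run_simulation(cfg, outdir="out/nested")

from dataclasses import replace
bare = run_simulation(replace(cfg, scenario="no_fluids"), outdir="out/bare")

s = nested.summary()
print(f"inner (brain-skull) max |d/d0 - 1|: {s['inner_max_abs_deviation']:.3f}")
print(f"outer (uterus-fetus) normalized range: {s['outer_normalized_range']}")
print(f"peak brain-skull relative displacement: {s['peak_brain_skull_rel_disp_m']*1e3:.2f} mm")
print(f"peak brain von Mises: nested {nested.peak_brain_vm:.0f} Pa, "
      f"unprotected {bare.peak_brain_vm:.0f} Pa")
print(f"stress attenuation: "
      f"{attenuation_percent(nested.peak_brain_vm, bare.peak_brain_vm):.1f} %")
```

prints (seed 0, default desk-scale configuration):

```
inner (brain-skull) max |d/d0 - 1|: 0.060
outer (uterus-fetus) normalized range: [0.7357767703380295, 1.229665205944205]
peak brain-skull relative displacement: 0.39 mm
peak brain von Mises: nested 77 Pa, unprotected 1202 Pa
stress attenuation: 93.6 %
```

Reading: the outer amniotic layer absorbs the convulsive motion — the
uterus-fetus separations swing to ~0.74–1.23× baseline (mean absolute
deviation 6.7 %) — while the brain-skull separations stay near baseline
(mean absolute deviation 0.8 %, single-landmark excursions up to ~6 %, an
outer-to-inner deviation ratio of ~8) and the brain moves less than half a
millimetre relative to the skull.  Removing the fluid layers (direct
contact) raises peak brain von Mises stress ~16-fold: the nested fluid
architecture attenuates ~94 % of it.  Stress magnitudes are
order-of-magnitude only (fetal tissue moduli are placeholders); the ratios
are the supported result.

The same runs are available from a shell:

```bash
nestedfsi gen-kinematics --seed 0 --out trace.csv
nestedfsi run --seed 0 --outdir out/nested --duration 6
nestedfsi compare --seed 0 --outdir out/cmp --duration 6
```

Each run directory contains `distances.csv` (tidy per-landmark separations,
raw and normalised), `stress.csv` (brain stress invariants and brain-skull
relative displacement over time), `summary.json`, a `model/` directory with
VTK-legacy snapshots of every component, and optional time-resolved VTK
snapshots (`snapshot_interval` in the config).

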