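# ttrstab

Analytics for transthyretin (TTR) tetramer-stability studies: chemical
denaturation modelling, fluorescence observables, resveratrol-based
tetramer quantification, analytical-ultracentrifugation (AUC) reductions,
and trajectory/crystal flexibility metrics — with synthetic-data
generators that make every stage testable against known ground truth.

## The scientific problem

TTR is a homotetrameric transport protein whose dissociation into
aggregation-prone monomers is the rate-limiting step of amyloid formation.
Comparing disease-associated variants (such as substitutions at R34/K35 at
the end of β-strand B) requires a consistent quantitative pipeline over
several kinds of measurement:

* **Urea/GdmHCl denaturation curves** followed by tryptophan fluorescence.
  A spectrum is condensed into the centre of spectral mass,
  `CSM = Σ(ν_i F_i)/Σ F_i` with `ν_i = 10⁷/λ_i` (cm⁻¹), or the 355/335 nm
  intensity ratio.  Curves are biphasic: a first equilibrium transition
  reflecting dissociation of *non-stabilized* tetramers linked to monomer
  unfolding, and a second *apparent* transition from a kinetically
  stabilized tetramer population that does not equilibrate on the
  experimental timescale.
* **The two-population model.** For the dissociating population, mass
  action in protomer units (`C` = protomer concentration) gives
  `K_D = 4C³ fM⁴ / fT` with `fT + fM = 1`; free energies follow the linear
  extrapolation model `ΔG(D) = ΔG(0) − m·D`.  The stabilized fraction
  `α_stab` follows an empirical two-state sigmoid (`ΔG₂_app, m₂_app`).
  Transition midpoints `Cm1` (where `fT = 0.5`) and `Cm2` are the summary
  statistics; `Cm1` rises with protein concentration, the signature of a
  dissociation process.
* **Resveratrol binding** reports tetramer directly (monomers do not
  bind): a linear F394-vs-concentration calibration converts fluorescence
  into percent tetramer along the curve.
* **AUC sedimentation velocity.**  Observed `s` values are standardized to
  water/20 °C, `s20,w = s·(η_b/η_w,20)·(1−v̄₂₀ρ_w,20)/(1−v̄_Tρ_b)`, using
  buffer density/viscosity correlations; frictional ratios
  `f/f0 = s_max/s20,w` compare each species with its anhydrous sphere; and
  c(s) distributions are integrated into monomer (< 2 S), tetramer
  (2–5 S) and higher-order (> 5 S) classes.
* **Structure and dynamics.**  Kabsch superposition RMSD between variant
  crystal models, per-residue Cα RMSF over 10 ns windows of a trajectory,
  side-chain contact persistence (fraction of frames with any side-chain
  heavy-atom pair within 4.5 Å, sequence separation ≥ 2), main-chain
  N···O hydrogen-bond distances, and Cα B-factor profiles over named loop
  regions (BC 36–40, DE 55–64, ...).

## Worked example

```python
import numpy as np
import ttrstab as t
from ttrstab.hydro import vbar_at_temperature

# AUC reduction: 2.5 M urea + 0.1 M KCl + 50 mM phosphate at 25 degC
buf = t.SolventConditions(temperature=25.0, urea=2.5, kcl=0.1, phosphate=0.05)
rho, eta = t.solvent_properties(buf)
print(f"buffer density  = {rho:.4f} g/mL, viscosity = {eta:.4f} cP")
print(f"s20,w(3.5 S)    = {t.s20w(3.5, buf):.2f} S")
M = t.monomer_mass()                        # mature 127-residue chain
print(f"monomer mass    = {M:.1f} g/mol")
print(f"f/f0(1.66 S)    = {t.frictional_ratio(1.66, M, vbar_at_temperature(20.0)):.2f}")

# denaturation curve: simulate at 1.5 uM tetramer (6 uM protomer), refit
params = t.params_from_midpoints(6e-6, cm1=3.2, m_diss=2.0, cm_unf=15.0,
                                 s_T0=1.0, s_M0=2.0, s_U0=2.0)
curve = t.gen_denaturation_curve(params, 6e-6, np.linspace(0, 9, 40),
                                 noise_sd=0.02, seed=7)
res = t.fit_curve(curve, "one_population", params,
                  fixed=("dG_unf", "m_unf", "s_U0", "s_U1", "s_T1", "s_M1"),
                  n_boot=0, n_starts=2, seed=0)
print(f"fitted Cm1      = {res.midpoints[0]:.2f} M (truth 3.2 M)")

# c(s) species accounting
dist = t.gen_cs_distribution([(1.4, 0.2, 0.12), (4.1, 0.6, 0.2), (6.5, 0.2, 0.25)],
                             np.linspace(0.1, 10, 600))
pct = t.integrate_species(dist)
print("species %       =", {k: round(v, 1) for k, v in pct.items()})
```

prints

```
buffer density  = 1.0473 g/mL, viscosity = 1.0155 cP
s20,w(3.5 S)    = 4.13 S
monomer mass    = 13761.2 g/mol
f/f0(1.66 S)    = 1.23
fitted Cm1      = 3.17 M (truth 3.2 M)
species %       = {'monomer': 20.0, 'tetramer': 60.0, 'higher-order': 20.0}
```

The standardized 3.5 S → 4.13 S is the globular tetramer; 1.66 S with
f/f0 ≈ 1.23 is a compact globular monomer.  The fitted `Cm1` recovers the
generating midpoint within the noise-limited uncertainty, and the c(s)
mixture integrates back to its constructed 20/60/20 species split.

A `ttrstab` console command exposes the same operations
(`ttrstab s20w --s 3.5 --temp 25 --urea 2.5 --kcl 0.1 --phosphate 0.05`,
`ttrstab fit-denat`, `ttrstab traj-rmsf`, `ttrstab traj-contacts`,
`ttrstab struct-rmsd`, `ttrstab report --config run.yaml`, ...).

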