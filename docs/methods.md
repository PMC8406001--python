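# Methods

This note documents the models, conventions and design choices behind
`ttrstab`, what the synthetic-data generators do and do not emulate, and
the package's known limitations.

## Two-population dissociation/unfolding model

Urea denaturation of transthyretin is treated as the superposition of two
tetramer populations:

* **Non-stabilized tetramers** (fraction `1 − α_stab`) equilibrate within
  the incubation time.  Dissociation to monomers obeys mass action in
  protomer units: with `C` the protomer concentration,
  `[T4] = C·fT/4`, `[M] = C·fM`,

      K_D = [M]⁴ / [T4] = 4 C³ fM⁴ / fT,   fT + fM = 1.

  The quartic closure has a unique root `fM ∈ (0,1)`, found by Brent's
  method to 1e-15.  Free monomers unfold in a two-state step with
  constant `K_U`.  Both steps follow the linear extrapolation model,
  `ΔG(D) = ΔG(0) − m·D`, the standard convention for chemical
  denaturation.
* **Stabilized tetramers** (fraction `α_stab`, e.g. anion-loaded or
  sequence-stabilized species) do not reach equilibrium; their late
  transition is *apparent*.  It is modelled as an empirical two-state
  sigmoid with parameters `ΔG₂_app, m₂_app`, deliberately not as a
  mechanistic tetramer model — equilibrium data cannot constrain a
  kinetic barrier.  Oligomer assembly is likewise excluded from the
  signal model (no spectral signature is available); oligomers are
  accounted for only in the AUC species percentages.

The observable is a population-weighted sum of linear baselines
`S_T, S_M, S_U` (folded tetramer, intermediate/partially folded monomer,
unfolded monomer):

    S(D) = (1−α)[fT·S_T + fM·(fU·S_U + (1−fU)·S_M)] + α[S_T + f₂·(S_U−S_T)]

with `fU = K_U/(1+K_U)` and `f₂ = K₂/(1+K₂)` evaluated in overflow-safe
logistic form.  Because monomer unfolding does not feed back into the
dissociation equilibrium, the model with `α = 0` and well-separated
transitions is algebraically a product of two independent sigmoids; the
test suite asserts this against an independently coded oracle.

The intermediate baseline `S_M` is a free parameter: whether the
first-transition monomer is partially folded or unfolded is
probe-dependent, so the data decide.

**Midpoints.**  `Cm1` is the denaturant concentration where `fT = 0.5`
(root-found on the closure); at that point `K_D = 0.5 C³`, which makes
`Cm1` increase with protein concentration — the diagnostic of a
dissociation-driven transition.  `Cm2 = ΔG₂_app/m₂_app`.  A population
that is absent (`α_stab` = 0 or 1) has its midpoint reported as `None`.

**Fitting.**  Nonlinear least squares (lmfit/`least_squares`) in an
internal *midpoint parametrization* `(cm1, m_diss, cm_unf, m_unf, α,
cm2, m₂, baselines)`.  The raw `(ΔG, m)` space is badly conditioned for
intermolecular steps: `ΔG_diss` carries the concentration offset
`−RT ln(0.5 C³) ≈ +22 kcal/mol` at micromolar concentrations, so a small
relative error in `ΔG` throws the transition out of the data window.
Midpoints are what the data constrain.  Multi-start restarts scatter the
free midpoints uniformly over the sampled denaturant window (local minima
of sigmoid fits live in midpoint space); the lowest residual norm wins,
with ties broken by the smallest parameter shift from the initial guess.
Uncertainties: asymptotic standard errors from the Jacobian, and 95%
bootstrap confidence intervals by residual resampling (default 200
replicates, seed-controlled; `n_boot=0` skips).

Fixing `dG_diss`/`dG_unf`/`dG2_app` by name clamps the corresponding
midpoint.  RT is fixed at 25 °C (0.5925 kcal/mol).

## Spectral observables

* CSM uses `ν = 10⁷/λ` (λ in nm, ν in cm⁻¹) and weights the *raw*
  intensities — no Jacobian (λ²) re-weighting on the wavelength→
  wavenumber conversion, matching how the statistic is conventionally
  quoted.  The full acquired window (310–410 nm) is used.
* The 355/335 ratio linearly interpolates off-grid wavelengths; grids are
  expected at 1 nm spacing.
* Background subtraction requires identical grids — no silent
  interpolation.

## Resveratrol tetramer quantification

F394 is assumed proportional to tetramer concentration with a linear
calibration `F = slope·[T4] + intercept` (OLS over the 0–2 µM design);
binding is treated as stoichiometrically saturating at 18 µM resveratrol,
so no binding-constant model is attempted.  Percent tetramer is clipped
to [0, 100] (denaturation-curve tails routinely give small negative
estimates); clipping is logged, and values below the intercept beyond a
noise tolerance are flagged.  Synthetic tests use a single calibration;
per-variant quantum-yield differences only matter for real data.

## AUC reductions

* **Solvent properties.**  Water density from the Kell (1975) polynomial;
  water viscosity from the CRC log-ratio correlation anchored at
  1.002 cP/20 °C.  Cosolute increments are additive: urea relative
  viscosity `1 + 0.0378c + 0.000644c³` (Kawahara–Tanford-style) and a
  density increment from its apparent molal volume (44.24 mL/mol, weak
  linear concentration dependence); KCl density from its apparent molal
  volume (26.85 mL/mol) with Jones–Dole viscosity
  (`A = 0.0052, B = −0.014`); sodium phosphate (treated as Na₂HPO₄ at
  pH ≈ 7) density increment 0.129 g/mL per M with Jones–Dole
  `A = 0.02, B = 0.554 L/mol`.  Additivity is adequate at ≤ 2.5 M urea
  and ≤ 0.1 M salts; each correlation raises a named error outside its
  validity range.
* **s20,w.**  The correction factor
  `(η_b/η_w,20)·(1−v̄₂₀ρ_w,20)/(1−v̄_Tρ_b)` is species-independent for
  fixed conditions — one factor applies to every species in a run.  The
  water reference state is computed from the same property tables, so
  water/20 °C conditions return `s` unchanged exactly.
* **Partial specific volume.**  v̄₂₅ = 0.7346 mL/g, the Cohn–Edsall
  sequence-based value for the mature 127-residue chain (the package
  stores the sequence and derives the monomer mass, 13 761.2 g/mol, from
  it); temperature shifted by the standard 4.25×10⁻⁴ mL g⁻¹ °C⁻¹.
  Config-overridable and logged in every report.
* **Frictional ratio.**  `f/f0 = s_max/s20,w` with
  `s_max = M(1−v̄ρ)/(N_A·6πη·R_min)`, `R_min = (3Mv̄/4πN_A)^{1/3}` — the
  anhydrous-sphere convention, so hydration contributes to `f/f0`.
* **c(s) classes.**  Monomer < 2 S, tetramer 2–5 S, higher-order > 5 S
  (config-overridable).  Trapezoidal integration with the distribution
  interpolated at interior class edges, so percentages sum to exactly
  100 and are invariant under rescaling of c(s).  The 2–5 S class is
  labelled "tetramer" even though it would include dimers.

## Trajectory and structure analytics

* **Superposition.**  Kabsch least-squares rigid fit (SVD with the
  standard sign flip to exclude reflections); atoms matched by
  (chain, residue number, atom name), unmatched residues skipped with a
  logged list, never imputed.  Crystal models routinely miss terminal
  and disordered residues; intersection matching handles that.
* **Windowed RMSF.**  Within each window, frames are superposed onto the
  window-average structure with the fit iterated once
  (fit → recompute mean → fit); `RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩`; the
  profile is the mean over complete windows (trailing partial window
  discarded).  Per-window superposition (rather than one whole-trajectory
  fit) is a deliberate choice: it removes slow inter-window drift from
  the fluctuation estimate.  Removing the six rigid degrees of freedom
  biases RMSF low by ≈ `√(1 − 6/3N)`; with ≥ 60 selected atoms this is
  under 2%, within the tolerances used in testing.
* **Contacts.**  Side-chain atoms are all heavy atoms minus the backbone
  set {N, CA, C, O, OXT}; hydrogens are excluded (heavy-atom analysis is
  the norm and the generator is heavy-atom only).  Two residues are in
  contact in a frame if any side-chain heavy-atom pair is within 4.5 Å
  and they are on different chains or ≥ 2 apart in sequence ("sequence
  distance greater than 1").  Persistence = contact frames / total
  frames; zero-persistence pairs are omitted; records are canonically
  ordered and duplicate-free.  Glycine has no side-chain heavy atoms and
  therefore contributes no contacts (the strict reading; logged once).
* **H-bond distances.**  Main-chain N···O cross distances between two
  residues, per chain, sorted ascending with atom labels; like-atom
  pairs are excluded by default (`cross_only`), zero-distance self pairs
  always.  Only distances are reported — no angular H-bond criterion, as
  the quantities being reproduced are distances.
* **B-factors.**  Per-residue Cα B values per chain, with region means
  and region/chain-mean ratios over the named loop table
  (AB 18–28, BC 36–40, CD 49–53, DE 55–64, EF 74–90, FG 98–104,
  GH 105–122 — one table in `config.py`, not scattered constants).

PDB I/O (single- and multi-model) goes through Biopython behind the
module surface; structures live in flat per-atom arrays.

## Synthetic-data generators

Every generator is a pure function of (spec, seed); random streams are
split per observable from a master `SeedSequence`, so adding one
generator call does not shift another's draws.  Zero-noise outputs equal
the deterministic model predictions pointwise.

* **Spectra.**  Folded/unfolded basis spectra are Gaussians in wavelength
  (centres 335/355 nm, width 25 nm, the simplest shapes preserving the
  355/335 ratio and CSM behaviour); the intermediate state has no basis
  of its own but is a fixed 50/50 mixture of the two.  Noise is
  homoscedastic Gaussian on intensities — no photophysical model of
  tryptophan quenching is attempted, and no experimental noise model was
  available to emulate.
* **Curves.**  Model prediction plus i.i.d. Gaussian noise.  The default
  "wild-type-like" conditions used in tests are 1.5 µM tetramer (6 µM
  protomer — concentration bookkeeping is in protomer units, converted
  at the I/O boundary), `Cm1 = 3.2 M`, and `m_diss = 2.0 kcal/mol/M`,
  the steepness that reproduces a first transition spanning roughly
  1.5–4.5 M urea with a clear pretransition baseline; the two-population
  fixture uses `α_stab = 0.4`, `Cm2 = 6.5 M`.  Noise is 2% of the signal
  span, a typical fluorescence plate precision — no measurement SDs were
  available to infer it from.
* **Trajectories.**  Reference coordinates (an extended synthetic chain
  with N/CA/C/O/CB/CG per residue) plus independent per-coordinate
  Gaussian displacements of SD `σ_i` per residue, giving the analytic
  Cα RMSF `σ_i√3`.  Scheduled contacts displace one designated
  side-chain atom (CG) along a fixed outward axis to exactly 3.0 Å
  ("on") or 8.0 Å ("off") from its partner in a Bernoulli(persistence)
  pattern, making the contact statistic exactly controllable; a pair
  already within the cutoff by fixed geometry alone is rejected as
  contradictory.  This is harmonic plumbing, not physics: no force
  field, no correlated motions, no solvent.
* **c(s).**  Gaussian peak mixtures, area-normalized to the loading
  signal; fractions must sum to 1.

Passing tests on these synthetics demonstrate the *analysis* machinery —
estimator correctness, oracle agreement, statistical calibration — not
that real TTR data obey the generating assumptions (homoscedastic noise,
harmonic fluctuations, Gaussian peaks).

## Monte-Carlo recovery design

The recovery suite uses 100 curves per condition on 40-point 0–9 M grids
at 2% noise, initial guesses perturbed ±10%, and two fit starts.  The
fits use the correctly specified model family: the unobserved unfolded
baseline (the single-transition fixture's monomer never unfolds
in-window, so `S_U` is unidentifiable there) and the generating model's
zero baseline slopes are clamped.  With slopes left free, the slope
parameters partially absorb the broad dissociation transition and the
midpoint error roughly quadruples; the free-slope protocol remains
exercised in the unit tests.

## Pipeline

`RunConfig` (YAML/JSON) names stages (simulate, csm, fit_denat, s20w,
cs_integrate, traj_rmsf, traj_contacts, struct_rmsd) and their options;
`run()` executes them in dependency order, writes per-stage TSV/JSON and
a single `summary.json` carrying provenance (tool version, config hash,
master seed).  Per-stage seeds are derived by hashing (master seed,
stage name), so toggling one stage never shifts another's stream; reruns
are byte-identical.  Stage failures preserve partial results and record
the cause.  The CLI is a thin layer over the library.

## Known limitations

* The stabilized population is phenomenological: no anion-binding model,
  no kinetics (dissociation rates, freeze–thaw), no global multi-curve
  linkage fits.
* Oligomer assembly enters only through AUC species accounting.
* Solvent-property additivity and the fixed v̄ temperature coefficient
  are conventions, accurate at the compositions used here but not
  general.
* Deposited crystal structures are required for the structure-comparison
  checks; in an offline environment those tests report the missing
  inputs rather than computing on substitutes.
* The c(s) distributions are consumed as given — no Lamm-equation
  modelling or regularization is performed.
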