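# Methods

This note documents the models, algorithms, numerical choices and
limitations of `saisolv`.  Units throughout: Å for length, kcal/mol for
energy, e for charge, K for temperature, atm for pressure.

## The alchemical model

An absolute solvation free energy is computed as
`ASFE = dG_vac − dG_aq + dG_LRC`, where both legs annihilate *all*
nonbonded interactions of the solute (intermolecular and intramolecular),
so an explicit vacuum leg is required and no gas-phase correction ever is.

### The SAI ladder (`schedule`)

States are emitted in three blocks, each state a full per-atom set of
`charge_scale` and `lj_scale` factors (LJ scaling multiplies both `r_min`
and `epsilon`):

1. **charge block** — uniform charge factors `(1.0, 0.6, 0.3, 0.0)`; the
   first state is the physical system, and uniform scaling keeps a neutral
   solute exactly neutral in every state;
2. **hydrogen block** — all hydrogens jointly at LJ factors `(0.5, 0.0)`
   (skipped for hydrogen-free solutes);
3. **heavy-atom block** — one state per heavy atom turning it into a
   dummy, except the last heavy atom, which fades in two states
   `(0.5, 0.0)`.

A terminal all-zero bookkeeping state is appended by default.  It
duplicates the previous endpoint and is free for MBAR, but it makes the
emitted state count match the convention in which a 7-heavy-atom solute
with hydrogens uses 15 states:
`|charge| + |hydrogen| + (n_heavy − 1) + |last heavy| + 1 = 4 + 2 + 6 + 2 + 1`.

**Heavy-atom removal order.**  The design intent of SAI is that the
still-interacting core stays connected, so no dummy atom ever bridges two
live fragments.  The rule implemented: an atom is preferred while it was
*terminal in the original heavy-atom skeleton* (degree ≤ 1 counting bonds
to already-removed atoms), lowest index first; when no such atom remains
(rings), the lowest-index remaining atom of minimal degree is taken.  In
both branches, articulation points of the remaining graph are never
eligible, which guarantees connectivity after every removal.  For a chain
C1–C2–C3 this yields (C1, C3, C2) — the interior atom goes last even after
it becomes a leaf — and for a six-ring it yields ring order by index.

### Coupling semantics

`apply_state` multiplies per-atom charge by `charge_scale` and both LJ
parameters by `lj_scale`; solvent parameters are never touched.  Because
pair `epsilon` combines geometrically, a per-atom factor s scales a
solute–solvent pair well depth by √s — monotone and zero at s = 0, which
is all the ladder requires.

## The toy system (`chem_system`, `fixtures`)

* **Solutes** are generated with connected chain / ring / star heavy-atom
  skeletons (a ring request beyond 6 atoms grows a substituent chain, e.g.
  7 heavy atoms → six-ring + methyl), hydrogens attached round-robin to
  free valence (4 minus heavy degree), ε ∈ [0.02, 0.2], r_min ∈ [2.0, 4.5]
  (hydrogens at the small end).  Partial charges are drawn on a dyadic
  grid (multiples of 2⁻¹² e, up to ±0.5 e) so that they sum to *exactly*
  zero in floating point, mirroring the neutral compounds of hydration
  benchmarks.
* **Geometry** is grown breadth-first along bonds (heavy bonds 1.5 Å, X–H
  1.1 Å) choosing directions from a fixed icosahedral candidate set under
  minimum-separation constraints; ring-closure bonds end up longer than
  ideal, which is harmless because bonds are restrained to the *embedded*
  lengths.
* **Bonds** are harmonic restraints, `U = k (d − d₀)²` with
  k = 300 kcal/mol/Å² and d₀ from the embedded geometry.  There are no
  angle or torsion terms; intramolecular nonbonded pairs separated by one
  or two bonds (1-2, 1-3) are excluded.
* **Water** is a rigid 3-site monomer (O at −0.80 e with ε = 0.152,
  r_min = 3.54; H at +0.40 e with a small core ε = 0.046, r_min = 0.45;
  r(OH) = 0.9572 Å, HOH = 104.52°).  It is intentionally *not* TIP3P: only
  the estimators built on top are under test, not water thermodynamics.
  The small H core prevents charge fusion in the absence of Ewald
  electrostatics.
* Baths are placed clash-free (site–site > 2 Å, O–O > 2.8 Å), giving
  densities well below liquid water — a deliberate desk-scale choice that
  keeps sampling cheap while exercising every code path.

The system file format is YAML with an explicit unit header; writing is
molecule-wise wrapped and deterministic, so write→load→write is
byte-identical, and each intermediate state can be written out as a
self-contained `intstN/` directory (scaled system + metadata), runnable or
re-derivable in isolation.

## Energetics (`engine`)

Minimum-image pair sums in a cubic box.  LJ uses the CHARMM convention
`U = ε[(r_min/r)¹² − 2(r_min/r)⁶]` with Lorentz–Berthelot combination on
(r_min, ε).  Cutoff treatments between `r_on` (default 10) and `r_off`
(default 12; tests and examples use a scaled-down 6/8 window with ≥16.5 Å
boxes):

* `OMM_VSWI` — quintic smoothstep potential switch
  `S = 1 − 10x³ + 15x⁴ − 6x⁵`, `x = (r − r_on)/(r_off − r_on)`;
* `VSWI` — the classic quadratic-in-r² potential switch;
* `VFSW` — the force-switch form: the r⁻¹² and r⁻⁶ terms are replaced
  beyond `r_on` by `A k₁₂ (r⁻⁶ − r_off⁻⁶)²` and `B k₆ (r⁻³ − r_off⁻³)²`
  and constant-shifted inside, making the *force* continuous at `r_on` and
  zero at `r_off` (verified against finite differences in the tests rather
  than trusted as transcribed);
* `NONE` — hard truncation.

Coulomb interactions in periodic systems always use the quintic potential
switch regardless of the LJ kind, so switch-kind comparisons isolate the
LJ treatment (production codes likewise share one Ewald electrostatics
across LJ options).  Non-periodic (vacuum) systems are evaluated with no
truncation at all.  There is no Ewald/PME summation anywhere: toy boxes
are small and the estimators, not the electrostatics model, are under
test.

**Soft-core path.**  The reference route couples the solute through a
separation-shifted soft core,
`U(r, λ) = λ S(r) U_LJ(√(r² + α(1−λ)))` with α = 5 Å², and scales solute
charges linearly by λ (so solute–solvent Coulomb terms go as λ and
intra-solute ones as λ²).  λ = 1 is exactly the physical switched system
and λ = 0 the fully decoupled solute — the same endpoints as the SAI
ladder, which is what makes the two-route comparison meaningful.  dU/dλ is
analytic.

**Sampling** is Metropolis Monte Carlo: one attempted translation per
solute atom and one rigid translation+rotation per water per sweep, with
optional molecular-scaling volume moves at constant pressure
(N_mol ln V term included).  Step sizes auto-tune toward ~40% acceptance
during the first 20% of the sweeps (inside the later-discarded
equilibration span, so production obeys detailed balance with fixed
steps).  Frames are saved every `save_every` sweeps, molecule-wise
wrapped, with per-frame box edges.  A fixed seed gives a bit-identical
trajectory.  The two pair-energy inner loops are JIT-compiled (numba); a
vectorized numpy implementation of the same sums remains in the module and
the suite asserts both paths agree to 1e-9.

Defaults: T = 303.15 K, p = 1 atm, Coulomb constant 332.0637 kcal·Å/(mol·e²).

## Estimation (`estimators`)

* **Discard**: the first ⌊fraction·n⌋ frames of each trajectory are
  dropped (default 25%; the TI route uses 10% burn-in).
* **Reduced potentials**: every retained frame is re-evaluated under every
  state; `u = βU`, plus `βpV` only for frames from constant-pressure
  trajectories (never for vacuum/NVT).  Solvent–solvent and bond terms are
  state-independent and enter as per-frame constants, to which MBAR is
  invariant.
* **MBAR**: log-sum-exp-stabilized self-consistent iteration, then Newton
  polishing on the convex objective (gradient `N_k(Σ_n W_nk − 1)`, Hessian
  `diag(ΣWN) − (WN)ᵀ(WN)` with f₁ pinned), certified by a final
  self-consistent sweep to max|Δf| < 1e-10; iteration cap 10⁵, failure
  raises with the overlap matrix attached.  The overlap matrix
  `O = Wᵀ(W diag(N))` is row-stochastic; adjacent-state overlap below 0.03
  emits a warning that propagates into run reports.  An asymptotic
  covariance (SVD form, zero-shift mode projected out at rcond 1e-10) is
  available as a secondary diagnostic; headline error bars are standard
  deviations over independently seeded repeats (default 4; repeat r uses
  base_seed + r, with states and legs on disjoint sub-streams).
* **TI**: ⟨dU/dλ⟩ at 21 equidistant λ, cubic-spline interpolated and
  integrated segment-by-segment in closed form.  Not-a-knot boundary
  conditions were chosen over natural ones because they reproduce
  polynomial integrands up to cubic order exactly (a natural spline's
  forced zero end-curvature biases even a quadratic ⟨dU/dλ⟩ profile); the
  per-λ standard errors propagate through the (linear) quadrature weights.
* **Combination**: `ASFE = dG_vac − dG_aq + dG_LRC`, uncertainties in
  quadrature; legs must belong to the same solute.

## Long-range correction (`lrc`)

The energy missing beyond (and inside) the switching region is, per
ordered pair of atom types,
`E_LRC = (2π/V) Σ_ab C_ab ∫ [U_ab − U_ab^sw] r² dr`, with the beyond-cutoff
part in closed form (`−2εr_min⁶/(3r_off³)` plus the r⁻¹² term) and the
switch deficit on [r_on, r_off] by adaptive quadrature (rel. tol. 1e-10;
the force-switch adds its constant inner shift analytically).

**Pair counts are exact**: `C_ab = N_a N_b` for unlike types and
`N_a(N_a − 1)` within a type.  The familiar N² self-density convention is
only the large-N limit; at 10–20 particles it disagrees with a brute-force
periodic-image pair sum by several percent, which the test oracle (image
sum to a large spherical radius plus a closed-form remainder, ensemble
averaged over ideal-gas configurations) resolves clearly.

The correction to the ASFE is the full-box value minus that of the
matching solute-free water box.  At fixed volume this is a constant
(`asfe_lrc_analytic`); for constant-pressure trajectories the a-posteriori
route applies `C/V` per frame, discards the first third of each
trajectory, averages, differences full − water, and repeats the whole
procedure (default 3 repetitions) for the error bar.  The virial
contribution of the tail is ignored; the constant-volume limit (where the
a-posteriori estimate must equal the analytic difference exactly) is the
regression test standing in for a production-scale comparison.

## Benchmark statistics (`stats`)

FreeSolv-style semicolon-delimited files with `#` comments; the column
layout is a configurable mapping because upstream layouts have changed
across releases.  Metrics: RMSE, MAE, Pearson r, Spearman ρ (average-rank
ties), each with a nonparametric bootstrap 95% percentile interval
(molecule-level resampling, B = 10,000 by default, seeded).  Deviation
count tables use thresholds (2, 3, 4, 6) kcal/mol.  Group summaries assign
each compound only its *first* listed category (avoiding double counting
of polyfunctional compounds) and summarize only groups with ≥ 10 members;
size profiles bin by heavy-atom count (from SMILES via rdkit, halogens
included) with bootstrap bands, single-member bins reported without one.

## Problem sizes used by the test suite

Chosen as the package's own desk-scale working points: harmonic MBAR
recovery at 5,000 samples/state over 10 random force-constant pairs;
two-route agreement on a 3-heavy-atom chain solute in 40 waters
(16.5 Å box, 6/8 Å switch, 700 sweeps × 3 repeats per state, 21 λ for TI);
switch-kind robustness on a 2-heavy-atom solute in 24 waters
(500 sweeps × 3 repeats); the image-sum oracle on a 20-particle two-type
box averaged over 220 ideal-gas configurations.

## Known limitations

* The solute has no angle/torsion terms and bonds restrain to the embedded
  geometry; conformational free energy contributions of real molecules are
  out of scope.
* Minimum-image switched Coulomb is not Ewald; charged solutes are warned
  about and not meaningfully supported (uniform charge scaling would
  change the net charge along the ladder).
* The toy water and dilute baths do not reproduce liquid-water structure;
  passing tests validate the estimators and bookkeeping, not hydration
  thermodynamics of real compounds.
* The a-posteriori LRC ignores the tail's virial contribution, so NPT
  densities are those of the truncated potential.
* Per-state sampling starts every state from the same packed
  configuration; the discarded 25% must cover relaxation, which the
  repeat-based error bars make visible when it does not.
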