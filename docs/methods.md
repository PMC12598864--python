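# Methods

## The problem

The pH scale of a nonaqueous solvent read off a meter calibrated with
aqueous buffers (pH_app) is not the solvent's intrinsic ideal-dilute scale
(pH*); the two differ by a solvent-specific offset δ, pH* = pH_app + δ.
Because the autoprotolysis constant K_ap of a solvent is measured on the
apparent scale, every quantity derived from it — the solvent's acidity in
itself, its pKa, and the solvation free energies of its own anion and
cation — inherits the offset.  For methanol, δ ≈ 2.3, so the corrected
constant is K_ap* = 10^(−2δ) K_ap and the acidity shifts by
2δRT ln 10 ≈ 6.3 kcal/mol.  `pkasolv` implements the cycle algebra that
carries this correction through to ion solvation free energies, with
quadrature error propagation, plus two supporting computational pieces: a
desk-scale free-energy-perturbation Monte Carlo (FEP-MC) engine and a
running-average convergence analyser for cluster-configuration energies.

## Cycle algebra (`thermochem`, `cycles`)

For a solvent SH of molarity [SH]:

    ΔG_sol(1) = −RT ln(K_ap/[SH])            solution acidity, SH → S⁻ + H⁺
    ΔG_sol(2) = −RT ln(K_ap/[SH]²)           heterolytic, 2 SH → S⁻ + SH₂⁺
    ΔG_sol(3) = ΔG_sol(1) − ΔG_sol(2) = −RT ln[SH]
    pKa(1)    = ΔG_sol(1)/(RT ln 10)
    pKa(2)    = ΔG_sol(2)/(RT ln 10) − log₁₀[SH]

    ΔG_sol*(S⁻)   = −ΔG_gas(1) + ΔG_sol*(SH) − ΔG_sol*(H⁺) + ΔG_sol(1)
    ΔG_sol*(SH₂⁺) =  ΔG_gas(3) + ΔG_sol*(SH) + ΔG_sol*(H⁺) − ΔG_sol(3)

pKa(1) and pKa(2) are algebraically identical (both reduce to
pK_ap + log₁₀[SH]); the identity is asserted, not merely tested
numerically.  Every value is a `Quantity` (value, optional 1σ, unit tag);
uncertainties combine in independent quadrature, σ = √Σσᵢ².  Covariances
are deliberately out of scope: the experimental inputs come from unrelated
measurements.

Choices:

- **RT = 0.5926 kcal/mol** at 298.15 K, configurable via
  `ThermoConstants`.  Published tables in this area are rounded to two
  decimals and are internally consistent only to ~0.03 kcal/mol, so all
  comparisons against tabulated values use a ±0.05 band.
- **δ(methanol) = 2.30**, the average of the two literature determinations
  2.34 and 2.25; both ship as presets in `synthetic.DELTA_PRESETS`.
- Inputs with no stated uncertainty (K_ap, [SH], δ) are treated as exact;
  consequently ΔG_sol(1) and ΔG_sol(3) carry σ = 0 into the ion cycles.
  The larger σ values sometimes attached to experimental acidities
  (±1.94 water, ±4.00 methanol) are not derivable from the tabulated
  inputs; they are carried as literal pass-through display constants in
  `io.TABLE3_ACIDITY_SIGMA` and never recomputed.
- Both K_ap conventions are first-class: reports are tagged
  `original`/`corrected` and rendered side by side (braces for the
  original), because the difference between them is the point of the
  analysis.
- The cation cycle is implemented from its defining relation
  ΔG_sol*(SH₂⁺) = ΔG_gas(3) + ΔG_sol*(SH) + ΔG_sol*(H⁺) − ΔG_sol(3),
  i.e. through the solution basicity, which is convention-independent.

## FEP Monte Carlo engine (`fepmc`)

Rigid molecules interact through site-site Lennard-Jones + Coulomb with
geometric-mean combination rules (ε_ij = √(ε_i ε_j), σ_ij = √(σ_i σ_j)),
Coulomb constant 332.06 kcal·Å/(mol·e²).  Sampling is Metropolis NPT:
per-sweep rigid translation+rotation trials for every molecule and one
volume trial accepted with weight exp(−β(ΔU + PΔV) + N ln(V′/V)).  The
volume proposal is uniform in V with a *fixed* half-width (5% of the
system's reference volume by default): a width tied to the current volume
would make the proposal asymmetric and bias ⟨V⟩ upward — this was measured
at about +2% on the ideal gas before being fixed.  Note the N ln(V′/V)
weight makes the ideal-gas density N/⟨V⟩ = (N/(N+1))·P/kT; tests use
N = 150 where the bias is 0.7%.

Energetics: minimum-image convention in a cubic box, molecule-centre
cutoff r_c = L/2 maintained through volume moves, and the standard
isotropic LJ tail correction beyond r_c assuming unit pair correlation.
Electrostatics use a plain cutoff — no Ewald — matching the minimum-image
scheme of classical liquid-simulation practice at this scale; net-charged
solutes therefore carry a finite-size caveat at small N.  There is no
Coulomb tail term.  Total energy is maintained incrementally and must
agree with a from-scratch recompute to 1e-6 kcal/mol (tested after every
kind of move).

Solvation free energies are assembled from a staged annihilation of the
solute, each stage a ladder of coupling values λ from 1 to 0:

1. **charges** (λ scales the solute Coulomb term), double-wide sampling:
   each simulation point estimates both its backward and forward window;
2. **attractive LJ** (the −r⁻⁶ term), double-wide;
3. **repulsive LJ** (the r⁻¹² term), forward-only windows.

Each window uses the Zwanzig estimator ΔG = −RT ln⟨exp(−ΔU/RT)⟩ with
log-sum-exp stabilisation; standard errors come from the spread over
independent replicates (block averages within a single replicate).
Replicate RNGs are spawned deterministically from one master seed.  The
final assembly is

    ΔG_sol*(X) = −ΔG_ele − ΔG_nonele − RT ln 24.46 + ΔG_pol,

where RT ln 24.46 converts an ideal gas at 1 atm to the 1 mol/L standard
state and ΔG_pol is an optional user-supplied solute-polarization
correction (default 0; its evaluation requires electronic-structure input
that is outside this package's scope).

The repulsive term is scaled linearly in λ with no soft-core modification;
at the desk-scale densities and ε values used here the λ→0 endpoint is
benign (the final window's ΔU is bounded by the remaining repulsion).
This is a known limitation for dense fluids, where a soft-core form would
be required.

Two schedule families ship: `default_lambda_schedules()` (2 double-wide
charge simulations over a 5-value list, 1 double-wide attractive, 2
forward repulsive — desk scale) and `production_lambda_schedules()` (a
25-value charge list spanned by 12 double-wide simulations at alternating
interior points, a 9-value attractive list spanned by 4, a 5-value
repulsive list spanned by 4).  The alternating-interior-point convention
for choosing double-wide simulation points is a documented convention of
this package, overridable by constructing `LambdaSchedule` directly.

**What desk scale means.**  Defaults are N ≤ 50 molecules and 10³–10⁵
sweeps.  Production protocols of the scale used to obtain published
FEP-MC ion solvation values (500 solvent molecules, ~10⁸ steps per window,
5 replicates) are expressible through the same interfaces but are far
outside test scope; the engine's correctness is instead established by
analytic and statistical oracles: exact zero for a null perturbation,
forward/backward window cancellation, the closed-form harmonic
free-energy difference (RT/2) ln(k′/k), ideal-gas NPT density, Boltzmann
occupation of radial bins for a two-molecule system, and
schedule-refinement invariance of stage sums.  Passing these shows the
estimator and sampler are implemented correctly; it says nothing about
force-field accuracy or finite-size effects in real solvents.

## Convergence analysis (`convergence`)

For an ordered stream of per-configuration energies (as produced by
hybrid explicit/implicit cluster-solvation averaging), `running_stats`
computes prefix means and standard errors SE_k = sd_k/√k (SE₁ reported as
absent), and the convergence index: the smallest k such that the running
mean stays within a tolerance band around the final mean for all j ≥ k.
The default tolerance is one final SE — the literature states convergence
visually, so the band is explicit, configurable, and echoed in output.
Streams are treated as exchangeable with no autocorrelation correction,
consistent with plain averaging over Monte-Carlo-sampled configurations.
Reported ± values on such cluster averages are interpreted as standard
errors of the mean (consistent with n = 200 and sd = SE·√n); this is an
assumption, stated here once.

## Synthetic data (`synthetic`)

All pipeline inputs are generated, seeded and pure:

- `make_solvent_table` — the canonical water/methanol thermochemistry
  records (duplicated digit-for-digit in `data/solvents.csv`, which the
  tests cross-check), optionally Gaussian-perturbed for round-trip tests.
- `make_energy_stream` — i.i.d. normal energies with recorded truth.  To
  emulate a reported cluster average μ ± SE at n = 200, sd = SE·√200 (e.g.
  −110.50 ± 0.20 → sd 2.83).  Gaussianity is a modelling choice: only
  means and SEs are consumed downstream, and no distributional information
  is available for the real streams.
- `make_toy_fluid` — monatomic LJ or dipolar-LJ baths with non-overlapping
  starting configurations (minimum-distance rejection sampling).  The
  dipolar template (±0.25 e, 1 Å apart) exists so charge annihilation has
  an electrostatic response to measure.
- `make_harmonic_system` — the analytic FEP oracle with truth
  (RT/2) ln(k_final/k_initial).
- `spc_water` / `opls_methanol` — force-field fixtures.  The methanol
  fixture is the canonical 3-site united-atom OPLS model used as a
  geometry/parameter placeholder; all-atom variants can be supplied as
  site tables via `io.read_molecule_csv`.

## Numerical notes

- Quadrature treats absent σ as exactly zero; a result built only from
  exact inputs has an absent σ, not σ = 0 — the distinction survives I/O.
- `fep_window` requires ≥ 2 samples; SE uses 5 contiguous blocks by
  default and degrades gracefully for short sample sets.
- Tables accept the typographic minus variants (−, –, —) on input and
  always emit ASCII hyphens.
- Degenerate inputs are rejected loudly by constructor validation:
  nonpositive concentrations, negative δ, negative σ, λ ladders that do
  not run 1 → 0 or whose simulation points fail to tile the window list.

## Problem sizes used in tests

Cycle algebra is closed-form (instant).  Engine tests use 2–16 interacting
molecules (16-molecule dipolar bath for annihilation, 150 non-interacting
for the NPT ideal gas, 2 for detailed balance at 10⁵ sweeps), chosen as
the smallest systems in which each property is statistically decidable at
3σ with fixed seeds.  Convergence checks use 1000 replicates of n = 200
streams and one n = 5000 stream for the SE ∝ n^(−1/2) regression.
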