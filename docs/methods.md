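# Methods

`crownbind` analyses the thermodynamics of two potassium ions binding
consecutively to a rigid ditopic receptor carrying two identical
crown-ether sites (a bis(18-crown-6) analogue of Tröger's base,
"BCETB"), in water, with attention to the counterintuitive observation
that the second binding step is *enthalpically favoured* over the first
(ΔΔH° = ΔH°₂ − ΔH°₁ < 0) while being disfavoured in free energy
(ΔΔG° > 0). The package covers four computational layers: titration
calorimetry, binding-polynomial thermodynamics, continuum
electrostatics, and configuration-ensemble decomposition, each backed
by a ground-truth-known synthetic generator.

Units throughout: energies kcal/mol, temperatures K, distances Å,
concentrations mM at the interface and mol/L internally. Binding
constants are dimensionless on the 1 M standard-concentration scale so
that ΔG° = −RT ln K directly, with R = 1.98720425×10⁻³ kcal/(mol·K).

## ITC forward model and fitting (`crownbind.itc`)

Two models describe a ditopic receptor M titrated by a cation L:

* **Sequential two-site model.** Stepwise constants K₁ (empty →
  singly occupied) and K₂ (singly → doubly occupied) define the
  binding polynomial ζ = 1 + K₁L + K₁K₂L², occupancy fractions
  F₁ = K₁L/ζ, F₂ = K₁K₂L²/ζ, and the cell heat content
  Q = V₀·Mₜ·(F₁ΔH₁ + F₂(ΔH₁+ΔH₂)).
* **Single set of identical sites.** Stoichiometry n, one constant K,
  one per-site enthalpy ΔH; the free ligand solves a quadratic in
  closed form and Q = V₀·n·Mₜ·ΔH·KL/(1+KL).

At statistical binding (K₁ = 2k, K₂ = k/2, ΔH₁ = ΔH₂) the two
partition functions coincide and the models agree injection by
injection; this algebraic identity is a standing regression test.

Concentration bookkeeping uses the perfusion-cell displacement
convention of the instrument class the data come from: with v the
cumulative injected volume, Mₜ = M₀(1−v/2V₀)/(1+v/2V₀) and
Lₜ = L_syr(v/V₀)/(1+v/2V₀). An exponential-dilution convention is
available behind `convention="exponential"`. The per-injection heat is
ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ+Qᵢ₋₁)/2, normalized by the moles of
injectant in injection i. The first, deliberately small injection is
simulated for bookkeeping but excluded from fitted residuals, matching
standard practice of discarding it.

The free-ligand concentration solves the mass balance
Lₜ = L + Mₜ(K₁L + 2K₁K₂L²)/ζ, which is strictly increasing in L; a
Brent bracket on [0, Lₜ] converges to machine precision (relative
tolerance 8.9×10⁻¹⁶, guarded at 200 iterations). An independent plain
bisection oracle in the test suite agrees to 10⁻¹⁰ relative over 10³
random draws spanning eight orders of magnitude in the constants.

Fitting minimizes Σ((y_obs − y_model)/σᵢ)² with `lmfit`
(Levenberg–Marquardt), parameterizing ln K to enforce positivity
(bounds ln K ∈ [−25, 40] keep exp() representable in flat directions;
enthalpies bounded at ±500 kcal/mol for the same reason). Goodness of
fit is the reduced chi-squared χ²/ν with ν = N_fitted − n_params; a
value ≪ 1 signals overfitting, ≫ 1 model misfit beyond measurement
error.

**Weighting.** Measurement σᵢ is the per-injection SD across
replicates. With only three replicates these SD estimates are
heavy-tailed downward (the expectation of 1/s² diverges at two degrees
of freedom), and raw 1/SD² weights let single lucky injections dominate
— in experiments we observed the weighted optimum running away along a
K₂→0, ΔH₂→−∞ valley while scoring *better* than the truth. Fit sigmas
are therefore floored at the median replicate SD; this also covers
exactly-zero SDs. Parameter uncertainties follow the replicate
convention: each replicate is refit independently and the SD of the
per-replicate parameters is reported (covariance-matrix errors are also
available from single-series fits).

**Identifiability of the study conditions.** The experimental protocol
(1.4631 mL cell, 0.39 mM receptor, 247 mM titrant, 4 µL discarded +
28×10 µL) is a low-c titration: c = K₁·M₀ ≈ 0.05, so the normalized
heats span only about −0.17 to −0.015 kcal/mol. The Fisher information
of the 4-parameter sequential fit is correspondingly low: per-injection
noise of 0.05 kcal/mol would put the Cramér–Rao parameter bounds at
several hundred percent, irrecoverable by any estimator. The
experiment's reported reproducibility (K₁ to ~8%, ΔH₂ to ~1% across
replicates) is only attainable if the effective per-injection noise on
the integrated, normalized heats is of order 5×10⁻⁴ kcal/mol — the
synthetic generator therefore uses σ = 5×10⁻⁴ kcal/mol as its default
(dilution-blank noise 10⁻⁴), which reproduces replicate-SD parameter
errors of the observed order. Physically this reflects that integrated
heats of smooth, slowly decaying thermograms average over raw power
noise, and replicate-to-replicate agreement is limited by preparation,
not detector noise. Both noise levels are plain keyword arguments.

## Binding-polynomial thermodynamics (`crownbind.thermo`)

* ΔG° = −RT ln K and its inverse (round-trips to 10⁻¹² relative).
* Cooperativity: ρ = 4β₂/β₁² with β₁ = K₁, β₂ = K₁K₂, equal to
  4K₂/K₁. Two identical independent sites give K₁ = 4K₂ exactly (two
  ways in, one way out for the first ion; one way in, two ways out for
  the second), hence ρ = 1 at statistical binding and ρ < 1 for
  negative cooperativity.
* The purely combinatorial contribution to ΔΔG° is RT ln 4
  (≈ 0.82 kcal/mol at 298.15 K).
* Degeneracy corrections convert site-resolved simulated binding free
  energies to standard stepwise values: +RT ln(1/2) on the first step,
  +RT ln 2 on the second; the net ΔΔG° shift is RT ln 4.
* Van't Hoff analysis: unweighted OLS of ln K on 1/T (the slope's
  standard error is available per point count); ΔH° = −slope·R. The
  linear (ΔCp = 0) form is deliberate — the package does not fit
  heat-capacity models. Whether the source analysis weighted the
  points is unknown; unweighted OLS is the assumption, and a shift of
  all ln K values changes only the intercept.
* TΔS = ΔH − ΔG reconstructs ΔG = ΔH − TΔS exactly.

## Continuum electrostatics (`crownbind.continuum`)

Two monovalent cations at separation r in a dielectric continuum
interact with the screened Coulomb free energy
G(r,T) = e²N_Av/(4πε₀ε_r(T)r) — a *free* energy because ε_r(T)
contains the solvent's orientational degrees of freedom. The
Gibbs–Helmholtz transform at fixed r gives
H = G·(1 + (T/ε_r)·dε_r/dT) and TΔS = H − G.

The Coulomb prefactor is e²N_Av/4πε₀ = 332.06 kcal·Å/mol. The default
water model is a quadratic in T anchored at ε_r(298.15 K) = 78.4 with
slope −0.360 K⁻¹ and curvature 8.0×10⁻⁴ K⁻², valid 273–373 K; it
tracks experimental liquid water to ~0.3 across the range (87.95 at
0 °C, 55.9 at 100 °C). Any parameterization matching ε_r and its slope
at 25 °C to ~1% reproduces the same two-decimal results: at r = 11.5 Å
(the mean K⁺···K⁺ distance in the doubly occupied receptor) and
298.15 K, G = 0.37, H = −0.14, H/G = −0.37, −TΔΔS = 0.51 kcal/mol.
Because (T/ε_r)·dε_r/dT ≈ −1.37 < −1 for water, the enthalpy takes the
*opposite* sign to the free energy: the cation pair attracts
enthalpically while paying a larger entropic penalty. Solvents with a
milder dielectric temperature response (the derivative factor in
(−1, 0]) keep sign(H) = sign(G), and a temperature-independent
dielectric gives H = G exactly; both regimes are property-tested, as is
thermodynamic consistency H − G = −T·∂G/∂T against a finite difference.

The Bjerrum length λ_B = e²/(4πε₀ε_r k_B T) (≈ 7.15 Å for water at
25 °C) marks where the pair energy equals k_BT; the 11.5 Å site
separation sits comfortably beyond it, which is why the continuum
enthalpy term is small.

## Ensemble analysis (`crownbind.ensemble`)

Configuration ensembles arrive as fixed-length per-frame descriptor
vectors with per-frame internal energies of the complex (solvent and
counterions excluded) and a bound-state label (0/1/2 cations). The
descriptor choice is left to the data producer; the synthetic generator
uses a 2-D conformational plane padded with low-variance noise
dimensions.

* **PCA** is a mean-centered covariance eigendecomposition with
  components in decreasing-eigenvalue order and a deterministic sign
  convention (largest-magnitude loading positive). Zero-variance input
  is rejected rather than silently projected.
* **Ellipse gating.** Conformational states (extended EXT, collapsed
  COL, skewed SK1/SK2) are regions of the projected plane bounded by
  user-supplied ellipses; a helper seeds 2σ ellipses from a Gaussian
  mixture fit. Gate probabilities are weighted frame fractions;
  pairwise gate overlap is checked by Monte-Carlo area sampling (warn
  above 0.1%). Standard errors come from 10 contiguous-block
  averaging (the estimator behind published probability error bars is
  not documented; block averaging is robust to the autocorrelation
  real trajectories have, and on exchangeable frames it agrees with
  the multinomial SE within a factor of two — property-tested).
  Probabilities plus the ungated remainder sum to one exactly.
* **Energy decomposition.** With p_ij the probability and U_ij the mean
  energy of conformation j in bound state i (ungated frames forming the
  pseudo-conformation "rest"), Uᵢ = Σⱼ p_ij·U_ij holds exactly by
  construction; ΔU₀₋₁, ΔU₁₋₂, ΔΔU and the per-conformation
  ΔΔ(pU) with its running sum telescope to machine precision. The
  decomposition is pure bookkeeping — all statistical content is in the
  gate probabilities and state means.
* **Solvation-shell dipole correlation.** For each binding site the k
  (default 4) nearest waters by minimum-image distance define a
  cluster; the angle between the two cluster dipole sums is histogrammed
  in ±15° windows, with densities normalized to integrate to one over
  [0, π] radians so an isotropic ensemble shows the sin θ solid-angle
  measure. Zero-magnitude cluster dipoles give an undefined (NaN) angle
  and are excluded from densities.
* **Ion partitioning.** K_p(d) = (⟨n_ion(d)⟩/N_ion)/(⟨n_water(d)⟩/N_water)
  counts species within [0, d] of the receptor surface, where "surface"
  means distance to the nearest receptor atom center (simplest reading;
  a van-der-Waals offset is available via `surface_offset`). Water is
  referenced by its oxygen. K_p is exactly 1 at any box-spanning d and
  exactly invariant under duplication of all ions and waters. Regions
  containing no water are reported as NaN, never as infinities.

Periodic boundaries use the minimum-image convention; orthorhombic
boxes only.

## Synthetic generators (`crownbind.synth`)

All generators are deterministic under a fixed seed (one
`numpy.random.default_rng` stream each) and emit truth records;
downstream tests compare against those records, never against
hard-coded copies.

* **Titrations** simulate the sequential model on the experimental KCl
  protocol with truth K₁ = 119, K₂ = 17.2, ΔH₁ = −4.12, ΔH₂ = −6.76,
  add a constant dilution heat (−0.02 kcal/mol) plus i.i.d. Gaussian
  noise per injection, and emit three replicates and a dilution blank,
  so the full pipeline (blank subtraction, replicate averaging,
  weighted fitting, replicate-SD errors) is exercised end to end. What
  the generator does *not* emulate: baseline integration artifacts,
  drift, correlated injection errors, and concentration mis-weighing —
  so passing recovery tests demonstrate estimator correctness under the
  stated noise model, not robustness to systematic ITC pathologies.
* **Conformational ensembles** are four-cluster 2-D Gaussian mixtures
  (cluster SD 0.6 around centers at (−6,0), (0,±2.5), (6,0)) embedded
  in 5-D, one ensemble per bound state. Default weights move the
  collapsed-analog population 0.10 → 0.20 → 0.34 as ions bind while its
  energy drops faster than the others', so ΔΔU < 0 arises from a large
  negative collapsed-state term overcompensating positive terms — the
  qualitative mechanism under study, reproduced by construction, with
  per-frame energy noise of 2 kcal/mol (the order of simulation error
  bars on such averages). The truth record carries the exact mixture
  expectations.
* **Particle frames** hold a fixed 8-atom receptor cluster at the box
  center, uniform waters, two site references 11.5 Å apart, and ions
  drawn from a mixture of a uniform background and a near-surface shell.
  The shell weight q is chosen so the expected K_p at the shell
  distance equals the requested enrichment, using a seeded Monte-Carlo
  estimate (2×10⁵ points) of the shell volume fraction — the union of
  spheres around the atom cluster has no convenient closed form — and
  both q and the volume fraction are recorded. Water dipoles are unit
  vectors tilted toward the site axis by an alignment parameter in
  [0, 1] (0 = isotropic). Dipole-correlation checks need enough waters
  that the two 4-nearest clusters are disjoint (≥ ~150 waters in a
  30 Å box at 11.5 Å site separation); with sparse water the clusters
  share members and the angle distribution is genuinely biased toward
  0°, which is a property of the observable, not an artifact.

## Problem sizes used in the shipped checks

Recovery studies run 20 seeds × 3 replicates on the 29-injection
protocol; ensemble identities use 2×10⁴ frames per bound state; dipole
isotropy uses 10⁵ frames of 250 waters; partitioning uses 400 frames of
60 ions + 600 waters; the solver cross-check uses 10³ random draws.
These sizes put Monte-Carlo standard errors comfortably below the
assertion tolerances while keeping the whole suite under a minute of
compute.

## Known limitations

* The ITC layer starts from integrated, normalized heats; raw power
  traces, baseline integration and vendor binary formats are out of
  scope, as are global multi-temperature fits.
* χ²/ν values depend on the weighting convention; with replicate-SD
  weights from three replicates they are comparable *between models on
  the same data* (the use made of them here) but not across weighting
  conventions or laboratories.
* The continuum layer is unscreened Coulomb in a uniform dielectric: no
  ionic-strength screening, Born/self terms, or dielectric saturation.
* Ensemble energetics arrive precomputed; the package neither runs nor
  parses molecular-dynamics trajectories, and the linear van't Hoff
  form assumes ΔCp = 0 over the 20 K ladder it is meant for.
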