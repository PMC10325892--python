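# Methods

## The exchange model

All kinetic analyses assume two-site chemical exchange between a dominant
ground state (GS) and a minor excited state (ES),

    GS  ⇌  ES,     k_GE = k_ex·p_ES,   k_EG = k_ex·(1 − p_ES),

with total exchange rate k_ex (s⁻¹), excited-state population p_ES (bounded
to ≤ 0.5 to fix the labelling ambiguity), and a per-residue ¹⁵N chemical
shift difference Δω = δ_ES − δ_GS.  ppm↔rad/s conversion uses the ¹⁵N
Larmor frequency, (¹H MHz)·0.10136901; the default spectrometer field is
800.13 MHz.

## CPMG relaxation dispersion

R₂,eff is computed from constant-time intensity ratios,
R₂,eff = −ln(I/I₀)/T_CP with T_CP = 40 ms by default; non-positive
intensities are censored with a warning.  The refocusing-pulse convention
is n = 2·ν_CPMG·T_CP evenly spaced 180° pulses (n = 4 at 50 Hz and
n = 160 at 2000 Hz), rounded to the nearest even integer when ν·T_CP is
not an integer (the deviation is logged).

**Errors.**  The only error source in the data design is the repeated
acquisition of the 750 and 50 Hz points.  Each duplicate pair contributes
d²/2 to a pooled variance; the pooled σ is applied uniformly to all points
of the residue, with a configurable floor.  Because two pairs give a very
noisy χ²₂-distributed estimate, `profiles_from_dataset` by default pools
the pairs of *all* residues of a dataset into one σ (still applied
uniformly per residue); the per-residue estimator remains available.

**Forward models.**  Three routes evaluate R₂,eff(ν):

1. `r2eff_exact` — the exact closed-form solution of the even echo train.
   The coupled GS/ES transverse magnetization evolves under a 2×2 complex
   matrix whose exponential is analytic; a pair of echoes has propagator
   U U* U* U, and its integer powers follow from the eigenvalues via the
   Cayley–Hamilton identity.  This keeps the projection of the initial
   condition onto both eigenmodes and is therefore valid at any exchange
   regime.  It is the model used by all fits.
2. `r2eff_propagated` — an independent numerical propagator (scipy matrix
   exponential + matrix powers) used for cross-validation; agrees with
   (1) to machine precision.
3. `carver_richards` — the classical approximation, retained for
   reference.  It effectively reports the decay of the dominant eigenmode
   only and deviates from the exact result by up to a few s⁻¹ for
   excited-state populations near 10% outside fast exchange, which is why
   it is not used for fitting.

R₂,₀ is assumed state-independent in the closed-form fits (the standard
identifiability compromise), which also makes it exactly additive in the
model — exploited by the fitters below.  Δω ≥ 0 is enforced: its sign is
not identifiable from CPMG and is deferred to CEST.

**Per-residue analysis** fits a no-exchange model (weighted mean) and a
two-site model (weighted least squares, 20 seeded starts log-uniform in
k_ex over [50, 10⁴] s⁻¹ to escape the fast/slow local-minimum trap) and
selects by the corrected Akaike information criterion
AICc = N·ln(χ²/N) + 2k + 2k(k+1)/(N−k−1) with k = 1 and 4.  R_ex is
reported as the model-predicted R₂,eff at the lowest measured frequency
minus that at the highest.

**Global fits** share (k_ex, p_ES) across a residue set with per-residue
(Δω, R₂,₀).  The search is nested: for fixed shared kinetics, R₂,₀ is
profiled in closed form (weighted mean of the residual) and Δω located on
a dense grid with parabolic refinement; the outer 2-parameter problem is
scanned from the multi-start grid and polished by Nelder–Mead, followed by
a full joint least-squares refinement that also provides the covariance
(scaled by reduced χ²).  A switch shares k_ex only, giving each residue
its own population.

## CEST

The forward model propagates the 6-component magnetization (x, y, z of
both states) under the homogeneous Bloch–McConnell generator — offset
precession, B₁ nutation about x, R₁/R₂ relaxation, and exchange — for the
saturation time T_sat via a matrix exponential (batched eigendecomposition
with a per-offset `expm` fallback), starting from z-magnetization
partitioned (p_GS, p_ES).  The reported profile is GS z-magnetization
normalized to the no-saturation reference, so at B₁ = 0 it is flat at
exp(−R₁·T_sat).  Conventions and defaults:

* offsets: 64 points from 134 to 99 ppm; B₁ = 15 and 30 Hz, treated as
  nominal single values (no inhomogeneity distribution);
* T_sat = 0.4 s — long enough to develop dips at B₁ = 15 Hz, typical for
  ¹⁵N CEST; configurable;
* R₁ state-independent; R₂ shared between states by default (per-state R₂
  available on the model object).

**Dip detection** finds local minima deeper than 3σ of the baseline
scatter (σ from the stored errors, else a robust first-difference
estimate), requires the deeper flanking point to dip as well (saturation
dips span several offsets, single-point excursions are noise), refines
positions by parabolic interpolation, and returns candidates deepest
first.

**Fitting** is joint weighted least squares over all provided B₁ fields
with parameters (δ_GS, δ_ES, ln k_ex, p_ES, R₁, R₂).  Initial shifts come
from dip detection; because the second-deepest dip may be an artifact (or
buried), excited-state starts are tried at the detected candidate, its
mirror image about δ_GS, and generic ±2 ppm offsets, combined with four
k_ex starts.  Single-dip data are fitted but flagged: k_ex and p_ES are
then only weakly identifiable.  Group fits share (k_ex, p_ES) across
residues, start from the individual fits, and report per-residue χ² so a
residue inconsistent with the shared kinetics is visible rather than
silently averaged.

## Spin relaxation

T₁/T₂ series are fitted with the two-parameter model I(t) = A·exp(−R·t);
constant-time baselines are assumed subtracted upstream, keeping the model
identifiable with 6–8 delays.  Intensities are normalized internally so
the fit is exactly scale-invariant.  Parameter errors come from the
covariance scaled by reduced χ² (per-point errors are typically not
available for these experiments).  A fitted decay of less than 0.1% over
the sampled window is flagged as non-converged rather than reported as a
rate.  The heteronuclear NOE is I_sat/I_ref with first-order error
propagation; negative values pass through.

## Thermokinetics

Rates decompose exactly as k_GE = k_ex·p_ES and k_EG = k_ex − k_GE; the
exchange timescale is τ_ex = 10⁶/k_ex μs; the excited-state free energy is
ΔG = −RT·ln(p_ES/(1−p_ES)) with R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹ and
temperatures in K as given.  Arrhenius analysis regresses ln k on 1/T
(equal weights by default, optional rate errors mapped to ln-space);
Ea = −slope·R.  Two temperatures give an exact line with undefined error,
flagged as such.

## Chemical-shift analytics

CSP combines amide changes as √(Δδ_H² + (Δδ_N/10)²) — the 1/10 nitrogen
scaling, not gyromagnetic-ratio variants.  The display threshold of
0.2 ppm is a plotting convention only and never filters tables.
Temperature coefficients are per-residue linear regressions of shift on
temperature (ppb/K), requiring ≥ 3 temperatures.  State correlations are
ordinary least squares with R² and per-residue residuals for outlier
mapping.  Secondary shifts are δ_obs − δ_rc against a packaged table of
standard random-coil values (Cα, Cβ, CO, N, Hα per residue type);
additive nearest-neighbour corrections are accepted as a configurable
table because published correction sets differ, and none is applied by
default.  The combined propensity score is a weighted sum
(Cα +1, Cβ −1, CO +1, N −0.25, Hα −4, normalized by the weight sum) with
positive values indicating helical propensity; the Hα and N weights
compensate for their smaller/noisier secondary-shift ranges.

## RDC alignment tensors

Measured ¹H–¹⁵N couplings are fitted to a structure by direct linear least
squares for the five independent Saupe elements (SVD of the
direction-cosine design matrix), requiring ≥ 5 couplings of rank-5
geometry — the exact solution of the fitting problem, replacing any
steric-prediction step, which is out of scope.  The N–H dipolar constant
is fixed at 21.7 kHz (r_NH = 1.04 Å); only relative agreement statistics
(R², Q = rms(D_meas − D_pred)/rms(D_meas)) matter for structural
conclusions.  Ensembles are fitted against a chosen model (default: the
first, i.e. lowest-energy) and per-subset R²/Q can be computed for named
residue groups; subsets with < 3 couplings are reported as undersized.

## Ensemble metrics

Superposition is the Kabsch algorithm (SVD with determinant correction).
Ensemble precision is the mean RMSD of models to their iteratively refined
mean structure (≥ 2 refinement passes, converged to 10⁻⁶ Å); a
pairwise-RMSD alternative is provided since deposition statistics do not
always state the convention — for two models the two coincide.  Backbone
means {N, Cα, C, O}; heavy atoms all non-hydrogens.  RMSF superposes onto
the mean first, so rigid-body motion does not register; note that with few
atoms the superposition necessarily absorbs a small part of a localized
fluctuation into the 6 rigid-body degrees of freedom.  Distance
distributions are per-model Euclidean distances with normalized
histograms; distance-only criteria (no angles) are used for H-bond-style
contacts.

## Synthetic data

The generators emulate the acquisition design: nine ν_CPMG values
{50, 100, 200, 350, 500, 750, 1000, 1500, 2000} Hz (the nine values are a
package choice spanning the stated 50–2000 Hz range) with repeats at 750
and 50 Hz; T_CP = 40 ms; 64 CEST offsets 134→99 ppm at B₁ ∈ {15, 30} Hz;
eight T₁ delays evenly spanning 50–1100 ms (the even grid is a documented
choice; the exact delays are configurable); T₂ delays
{5, 20, 35, 50, 70, 90} ms.  Per-residue Δω magnitudes are drawn
log-uniform from 0.5–6 ppm by default so both dispersive and near-flat
residues occur (the wt scenario uses 1–4 ppm, the CEST scenarios random
signs), ground-state shifts uniform in 108–126 ppm, R₂,₀ in 8–15 s⁻¹ and
R₁ in 1.2–2.0 s⁻¹ — typical amide values at these fields.

Noise is additive Gaussian on intensities with σ proportional to the local
peak intensity (default 1%), which makes the duplicate-derived σ(R₂,eff)
roughly uniform at ~0.25–0.5 s⁻¹ across the grid; CEST noise is additive
on the normalized profile.  A separate noise-stream seed allows repeated
noise realizations of one fixed ground truth.  With noise = 0 every
pipeline is an exact inverse problem and fits recover the generator to
solver tolerance.  Multi-temperature series scale k_ex by an Arrhenius law
(default Ea = 9.5 kcal/mol) anchored at the scenario temperature, with
populations held fixed.

Registered scenarios pin the reference conditions: `wt-291K`
(k_ex = 5207 s⁻¹, p_ES = 0.02, the 6-residue wild-type global set),
`tan-291K` (1240 s⁻¹, 0.03, the 31-residue set), `tan-283K` (458 s⁻¹,
0.03), and `tan-cest-283K` (572 s⁻¹, 0.03, five residues, both B₁
fields).

**What the generator does not emulate:** peak overlap and assignment
errors, spectrometer drift, B₁ inhomogeneity, off-resonance and pulse
imperfections in the CPMG train, temperature-dependent shifts or
populations, and three-site or concerted exchange.  Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
noise model, not robustness to all artifacts of real spectra.

## Numerical choices and degenerate inputs

* Fit bounds: k_ex ∈ [1, 5×10⁴] s⁻¹ (CPMG) / [1, 2×10⁴] (CEST), p_ES ∈
  (10⁻⁶, 0.5]; parameters pinned at bounds are flagged.
* Covariances are scaled by reduced χ²; singular Jacobians yield NaN
  errors with a warning rather than failure.
* The exact CPMG closed form guards the degenerate cases Δω = 0, p_ES = 0
  (flat curve) and coincident pair-propagator eigenvalues (L'Hôpital
  branch).
* AICc is undefined for N − k − 1 ≤ 0 and raises.
* Global fits with one residue warn (degenerate) but reduce exactly to the
  per-residue two-site fit.

## Known limitations

* Only two-site exchange; no R₁ρ, no ¹³C CEST, no multi-quantum models.
* CPMG fits assume equal state baselines R₂,₀; the numerical propagator
  accepts per-state values for simulation.
* The statistical-precision window of the fast-exchange wild-type scenario
  is intrinsically wide: with six residues at 1% noise the global k_ex has
  a 1σ spread of several hundred s⁻¹, so single-realization recoveries
  scatter accordingly.
* NMR-STAR support covers the atom-chemical-shift loop only.
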