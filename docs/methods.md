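# Methods

## The reaction and the model

Sesamin (A), a furofuran lignan of sesame oil, isomerizes reversibly to its
epimer asarinin (B) over a solid acid catalyst (citric-acid-loaded Hβ
zeolite) at 70–90 °C. The mechanism — ring opening on an acid site, surface
rearrangement, desorption — reduces under the quasi-equilibrium
approximation (surface rearrangement rate-determining, adsorption and
desorption equilibrated) and a site balance to a Langmuir–Hinshelwood rate
law:

    R = k(T) · w_cat · ([A] − [B]/K(T)) / (1 + K1·[A] + K2·[B])

with batch material balances d[A]/dt = −R, d[B]/dt = +R. `K1` and `K2` are
the adsorption constants of the two epimers and are tied (`K2 = K1`) by
default — chemically motivated (the epimers differ only in one ring-fusion
configuration) and structurally consequential (see *Identifiability*).

Temperature dependence is parameterized at a reference temperature
T_ref = 353.15 K (the 80 °C design centre) to decorrelate the
pre-exponential factor from the activation energy:

    k(T) = exp[ ln k_ref + (Ea/(R·T_ref)) · (1 − T_ref/T) ]
    K(T) = exp[ ln K_ref + (ΔH_r/(R·T_ref)) · (1 − T_ref/T) ]

R = 8.314 J·mol⁻¹·K⁻¹. A positive ΔH_r means the isomerization is
endothermic, i.e. the equilibrium shifts toward asarinin with temperature.

Default (reference) parameter set: ln k_ref = 9.74, Ea/(R·T_ref) = 21.4
(Ea ≈ 62.8 kJ/mol), K_ref = 0.536, ΔH_r = 34 578 J/mol, K1 = K2 = 4029.99.

## Units

The kinetic functions are unit-agnostic; the package-wide convention,
enforced at the I/O boundary, is: concentrations in mmol/L, time in
minutes, temperature in K, catalyst amount `w_cat` as a mass fraction
(g catalyst per g oil, i.e. wt.%/100), `K1`/`K2` in L/mmol. This convention
was chosen because under it the reference parameter set reproduces the
experimentally observed time scale: simulated 240-min conversions of
21.2 / 30.9 / 40.8 % at 70/80/90 °C (1.6 wt.%, 21.47 mmol/L), against
reported values of 23.72 / 35.78 / 40.09 %, and a relaxation constant of
λ ≈ 9×10⁻³ min⁻¹ at 80 °C that is well resolved by the 3–240 min sampling
grid. Conventions that put the transient at sub-second scale make every
profile a step to equilibrium at the first sample point and destroy the
identifiability of the rate parameters; they were rejected for that reason.
CSV files use seconds, °C and wt.% (converted at the boundary) so they read
like the experimental tables.

## Closed-form oracle

With `K1 = K2` the total lignan concentration C_tot = [A]+[B] is conserved,
so the adsorption denominator 1 + K1·C_tot is constant along a trajectory
and the ODE is linear:

    [A](t) = A_eq + ([A]₀ − A_eq)·e^(−λt),  A_eq = C_tot/(1+K),
    λ = k_eff·(1 + 1/K),  k_eff = k·w_cat/(1 + K1·C_tot).

This analytic solution is the independent oracle for the numerical
integrator (LSODA, rtol 1e-9 / atol 1e-12); agreement to 1e-8 absolute is
asserted across a parameter sweep. Concentrations are clipped to zero only
at output, never inside the integrator.

## Estimation

Both responses are fitted jointly with the determinant criterion
S(θ) = (n+m+1)·ln|υ(θ)|, υ_ij = Σ_u r_iu·r_ju, where m = 2 responses and
n counts events per response (all sampled points pooled across runs; t = 0
points included by default — they carry zero residual for noise-free data
and only inflate n; this is configurable). A ridge ε = 1e-12·max(1, tr υ/m)
regularizes the perfect-fit singularity so self-consistency fits have a
finite floor. The criterion self-weights the responses; no additional
weighting is applied. Rescaling one response by a constant c shifts S by
the additive constant (n+m+1)·2·ln c and leaves the argmin unchanged.

The optimization vector is (ln k_ref, Ea/(R·T_ref), ln K_ref, ΔH_r/(R·T_ref),
ln K1): logarithms keep positive parameters positive, and the dimensionless
enthalpy group puts all coordinates on a common O(10) scale. A Nelder–Mead
search (xatol 1e-5, fatol 1e-7, adaptive) is followed by a BFGS refinement
accepted only on improvement; the procedure is deterministic given
(dataset, initial guess, frozen set). Non-convergence returns the best
point found with a flag rather than raising. ln K_ref and ΔH_r are fitted
jointly by default; a separate two-stage route (per-temperature equilibrium
constants, then the Van't Hoff regression of ln K on (1/R)(1/T − 1/T_ref),
slope = −ΔH_r) is provided and recovers the same enthalpy exactly on
noise-free data.

### Uncertainty

95% marginal HPD half-widths are a first-order curvature approximation:
t₀.₉₇₅,df·SE with df = n·m − p and SE from the inverse of the Gauss–Newton
Hessian of S/2,

    H_ab = (n+m+1) · Σ_ij (υ⁻¹)_ij · G_ia·G_jb,

where G are prediction sensitivities obtained by central differences of the
simulated responses (relative step 1e-4). Building the curvature from
prediction sensitivities rather than second differences of the
log-determinant objective matters: the latter has a finite-difference noise
floor around 1e-3 of the leading curvature and cannot resolve near-null
directions, while sensitivity collinearity is resolved to ~1e-8. Half-widths
for K_ref, ΔH_r and K1 are delta-method rescales of the internal log /
dimensionless coordinates.

A parameter is flagged **indeterminate** when (a) its curvature diagonal is
≤ 1e-10 of the largest (no sensitivity at all — e.g. the activation-energy
group under a single-temperature design, where the reference-temperature
parameterization makes the sensitivity exactly zero at T = T_ref), (b) it
is the dominant component of a curvature eigendirection whose eigenvalue is
< 1e-6 of the largest after diagonal scaling (collinear sensitivities; the
threshold is set by the finite-difference accuracy of the sensitivities),
or (c) its implied HPD exceeds 10³ % of the estimate. Flagged parameters
carry no interval and their correlation rows are zeroed; the remaining
covariance is computed on the informative subspace, i.e. conditional on the
flagged parameters' values.

### Identifiability of K1

With `K2 = K1`, K1 enters a trajectory only through the constant
1 + K1·C_tot, which the rate constant can absorb almost exactly; the only
leverage is the spread of initial concentrations across runs (21.47–23.83
mmol/L, ≈ 11%). Re-optimizing the other parameters after halving or
doubling K1 leaves residuals of order 1e-7 mmol/L — invisible under any
realistic noise (the objective moves by < 1e-3 against a 2%-noise floor).
K1 is therefore reported as indeterminate when freed, and frozen at its
reference value for the recovery studies. Note that the objective's
logarithmic form *does* resolve this compensation residual on exactly
noise-free data, so flatness of the K1 profile is a statement about noisy
data, and is tested as such.

## Synthetic data

The generator emulates the nine-run experimental matrix (initial sesamin
21.47–23.83 mmol/L, 70–90 °C, 1.0–3.0 wt.% catalyst, 200–400 rpm, zero
initial asarinin) on the sampling grid 0, 3, 5, 10, 20, 30, 60, 120, 180,
240 min. The default noise model is multiplicative Gaussian with cv = 2%,
a plausible figure for triplicate HPLC-UV quantification; additive Gaussian
and noise-free modes are available, negative draws are truncated at zero,
and replicate campaigns get suffixed run ids. What the generator does *not*
emulate: temperature dependence of the oil density, intermediate species,
catalyst deactivation across reuses, mass-transfer effects (stirring speed
is metadata with no kinetic role, consistent with the experimental
finding), or the mg/100 g ↔ mmol/L conversion of the original assay
(concentrations are defined directly in mmol/L). Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to these real-data effects.

## Problem sizes and numerical choices

The recovery studies use the five concentration/temperature runs
(the runs the original fit presents) with 10 time points each — 100
observations over two responses — for the deterministic loop, and the full
nine-run design for the noisy replicates (20 seeded replicates at cv = 2%).
These sizes are the study's own design; the deterministic loop recovers the
generating parameters to ~1e-10 relative, far inside the 0.1% acceptance
band. Degenerate inputs are handled explicitly: `ln k_ref = −∞` is a dead-
catalyst flag short-circuiting to a constant profile; `K1 ≠ K2` makes the
closed form refuse (the simulator still integrates it); empty designs,
duplicate run ids, non-increasing time grids, negative concentrations and
malformed CSVs raise validation errors naming the offending field or row.

## Known limitations

- The HPD intervals are curvature-based (local, Gaussian); no posterior
  sampling is performed, and coverage claims are verified only under the
  generator's noise model.
- The rate law assumes the surface rearrangement is rate-determining;
  competing mechanisms are not discriminated.
- Catalyst loading enters linearly through w_cat; site-count changes from
  recycling/calcination are out of scope.
- The experimental 240-min conversions at 1.0 and 3.0 wt.% loading
  (16.38% / 54.78%) bracket the model's equilibrium cap (34.9% at 80 °C)
  and cannot be reproduced quantitatively by any parameterization of this
  rate law; the loading effect is reproduced qualitatively only.
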