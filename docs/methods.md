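# Methods

This note records the models phenolflux implements, the assumptions they
make, the numerical choices behind them, and what the synthetic data do and
do not establish.

## Diffusion model

**Physical picture.** Monodisperse spherical particles (default radius
24.50 µm, half the volume-weighted mean diameter D[2,3] = 49.00 µm of the
motivating hull powder) carry an initially uniform phenolic load *C*ₛ₀ and
sit in a finite, well-mixed solvent bath that starts empty. Intra-particle
transport is Fickian with a constant effective diffusivity *D*ₑ; external
film resistance is neglected (ultrasonic micro-mixing), the particle
surface is in instantaneous partition equilibrium with the bath
(*C*ₛ(*r*,*t*) = *K·C*L(*t*)), and there is no swelling, degradation or
time-varying *D*ₑ. These assumptions are hard-coded; polydispersity,
non-spherical geometry and cavitation physics are out of scope.

**Dimensionless core.** The solver works exclusively in ξ = *x*/*r*,
τ = *D*ₑ*t*/*r*², *u* = *C*ₛ/*C*ₛ₀ and the bath-capacity number
α = *V*L/(*K·V*ₛ). Two parameterisations with equal dimensionless groups
produce identical solutions (tested). This matters because reported *D*ₑ
magnitudes in this literature are often dimensionally inconsistent with the
quoted particle radii and extraction times; a dimensionless core is correct
under any unit reading, and results are reported both as *D*ₑ in user units
and as the r²-normalised rate *D*ₑ/*r*² (1/min), which is the quantity the
kinetics actually identify.

**Discretisation.** Conservative finite volumes on a uniform ξ-grid
(default 101 nodes): cell-integrated masses advance via face fluxes
ξ²∂ξ*u*, the centre cell uses the symmetric zero-flux limit, and the
surface half-cell is lumped with the bath (which is algebraically slaved to
it through the partition condition) into a single state of capacity
*V*cell + α/3. Total mass is then conserved *exactly* at the spatial level;
the only drift comes from time integration (LSODA, rtol 1e-8, atol 1e-10,
tridiagonal bands), observed at ~1e-15 relative. Doubling the grid changes
the bath series by < 1e-4 relative. The incompatible initial data (*u* ≡ 1
but *C*L(0) = 0) are handled by letting the surface half-cell's load
redistribute instantly over (half-cell + bath) — an O(h) mass fraction —
while the profile reports the nominal initial condition at *t* = 0.

**Oracle.** `crank_series_fraction` implements the classical eigenfunction
series for a sphere in a stirred bath of limited volume:
*M*ₜ/*M*∞ = 1 − Σₙ 6α(α+1)e^(−qₙ²τ)/(9+9α+qₙ²α²), with qₙ the nonzero
roots of tan *q* = 3*q*/(3+α*q*²), each bracketed in (nπ, nπ+π/2) and
located by bisection to 1e-13. Solver and series agree to |Δ| < 1e-3 for
α ∈ {1, 5, 10, 50} and τ ∈ [1e-3, 5]; the series is used only as a test
oracle, never inside the fitting path. Note the series is normalised by the
equilibrium uptake *M*∞, whereas the profile's extracted fraction is
normalised by the initial load and tends to α/(1+α).

**A note on surface monotonicity.** With a finite bath the surface
concentration *C*ₛ(*r*,*t*) = *K·C*L(*t*) *rises* from zero toward
equilibrium, so pointwise-in-time monotonicity of *C*ₛ holds in the
interior but not at the surface. The tested invariants are the physically
correct set: *C*L nondecreasing, volume-mean *C*ₛ nonincreasing, radial
profiles nonincreasing from centre to surface, and 0 ≤ *C*ₛ ≤ *C*ₛ₀.

## Diffusivity estimation

The fit minimises the unweighted RMSE between the simulated and observed
liquid-phase yield curve over log₁₀(*D*ₑ/*r*²) with a bounded scalar
optimiser (tolerance 1e-3 log units). By the closed mass balance this is
equivalent, up to the constant *V*ₛ/*V*L factor, to fitting the solid-phase
residual content. Bounds default to ±3 decades around a Fourier-matched
initial guess rate₀ ≈ 0.03/*t*½ (τ at half-extraction is O(0.03) for a
sphere); a 20-point bound scan guards against multimodality and a scan
minimum at the upper bound (zero-residual plateau) marks the rate as
unidentifiable (`converged=False`) — this is what flat, already-equilibrated
data produce. R² is reported as NaN when the observations are constant,
where it is undefined.

The extractable load defaults to the measured total phenolic content
(7.90 mg GAE/g); with the 1:10 solid-to-liquid ratio and unit densities
this implies α = 10 and an equilibrium yield of 7.90·α/(1+α) ≈ 7.18 mg/g.
Observed plateaus well below that imply an effective partition *K* ≠ 1 or
partial extractability; *K* is therefore configurable, and the synthetic
generator instead encodes each condition's plateau as an extractable
content (plateau × (1+α)/α), which the fitting layer accepts per condition.
Replicate SDs, when present, are *not* used as weights (the reference
metric is unweighted).

Recovery behaviour under the design's noise model: exact (< 0.05%) on
noiseless curves, median error ~3% at SD 0.05 mg/g and ~11% at the design
maximum SD 0.150 mg/g (20 seeds, 8 time points).

## ANFIS yield model

Standard five-layer first-order Takagi–Sugeno system over temperature
(°C), time (min) and enzyme concentration (% w/v), all min–max scaled to
[0, 1] internally. Grid partitioning with 2 membership functions per input
gives 2³ = 8 rules and 32 consequent coefficients. The default membership
family is the difference of sigmoids (dsigmf), which expresses
interval-shaped ("optimal within a range") responses; Gaussians are
available. Initial sets are centred at the domain ends with half-width
step/2 and slope 7/step: adjacent sets cross within 1e-3 of 0.5, and the
substantial overlap lets rules share data — important because a 6:4 split
of 48 runs leaves 29 training samples against 32 coefficients. That LSE
system is necessarily rank-deficient; it is solved by a ridge fallback
(λ = 1e-8) with a warning, and the overlap (not the tiny ridge) is what
controls the generalisation of the resulting minimum-norm-like solution.

Hybrid training per epoch: (1) forward pass — consequents solved exactly by
least squares on the normalised-firing design matrix, train/test RMSE
recorded; (2) backward pass — premise parameters take one normalised
gradient step of length lr (default 0.01, halved whenever train RMSE
rises). The model snapshot at the epoch with minimum test RMSE is retained
(early-stopping-by-selection). Training is fully deterministic given the
split; the 30-epoch default follows the reference protocol.

The train/test split is stratified: the global train size is
round(0.6·48) = 29, allocated across the six (temperature, enzyme) cells by
largest remainder, and *within* each cell the test picks are spread
systematically over the time axis (one random draw per quantile block).
Without the within-cell balancing, splits that put all of a cell's early
steep-phase or final plateau points in the test set force the first-order
consequents to extrapolate and occasionally collapse the held-out R².

On the default synthetic design (noise SD 0.05 mg/g) the held-out R² is
0.96–0.995 across seeds (median ~0.985).

## Compositional analytics

The packaged fixture transcribes the published 17-compound quantification
table (compound, category, retention time, mean ± SD per condition; "-" =
not detected). Category shares treat non-detected compounds as zero mass.
Because the raw triplicates are unpublished, PCA samples are *simulated*:
three replicates per condition drawn from Normal(mean, SD) clipped at zero,
missing entries as 0 µg/g. This is an explicit approximation — it assumes
independent Gaussian replicate error and cannot recover any replicate
correlation structure the real data had.

PCA autoscales by default (centre, unit variance, ddof = 1) because
compound abundances span ~1.5–856 µg/g; covariance-mode is available by
flag. All min(n−1, p) components are kept so explained-variance percentages
sum to 100 and scores·loadingsᵀ reproduces the preprocessed matrix
(1e-8). On the fixture the replicate-expanded PC1 share is 65.3 ± 1.4%
(PC1+PC2 ≈ 81.4%) across seeds, versus 68.1% for the PCA of the six
condition means alone; the confidence ellipses in the biplot are 95% normal
ellipses per condition group, cosmetic only.

## Synthetic data: what it establishes

The generator reproduces the *design* of the motivating experiment — 2
temperatures × 3 enzyme levels × 8 front-loaded sampling times within the
30-minute extraction window, triplicates, per-point SDs in
[0.002, 0.150] mg/g — and phenomenological truth maps with the qualitative
structure of the fitted kinetics: rate = 0.008·e^(−0.06(T−40))·(1+0.55·E)
per minute (falling with temperature, rising with enzyme dose; magnetic
stirring ×0.62), plateau = (2.3 + 0.19(T−40))·(1+0.05·E) mg/g (strongly
higher at 50 °C, nearly enzyme-flat). The absolute rate scale puts
half-extraction at 2–10 min, consistent with ~70% extraction inside
10 minutes. Mean curves come from the forward solver itself, so
generator/fitter recovery tests certify the estimation machinery, not the
physics; passing them says nothing about whether real hull extraction is
Fickian. The reported SD column carries the generating per-point SD (the
3-sample SD would be chi-inflated far outside the design range).

Compound-table simulation mirrors the fixture's schema (category sizes
9/2/3/3, abundances ~3–630 µg/g, structured 40 °C missingness) with a
configurable 40-vs-50 °C contrast so PCA separation is testable under the
null (PC1 ≈ random-matrix level) and under strong signal (PC1 > 50%).

## Reproducibility and sizes

One master seed drives everything: the pipeline derives per-stage seeds via
`SeedSequence` (all < 2³¹), reruns are byte-identical, and `manifest.json`
echoes every defaulted parameter. Default problem sizes — 101 radial nodes,
48-run design, 30 training epochs, 10 PCA seeds in the acceptance script —
keep the full test suite under ~2 minutes and any single analysis under a
few seconds while leaving all reported tolerances met with margin.

## Known limitations

* Constant *D*ₑ and monodisperse spheres; no washing/diffusion two-phase
  decomposition (the fast initial phase is absorbed into the fitted rate).
* The plateau/partition ambiguity (*K* vs extractable fraction) is not
  resolvable from yield curves alone; co-fitting both is deliberately off
  by default.
* ANFIS consequents outnumber the 6:4 training split of 48 runs; outside
  heavily overlapping membership initialisations the model can interpolate.
  More data, fewer rules (zero-order consequents) or stronger
  regularisation are the remedies.
* PCA replicates are simulated from summary statistics, so score-cloud
  shapes (not the variance shares) should be read qualitatively.
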