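# Methods

This note documents the models, numerical choices and known limitations of
the `landgen` pipeline.

## Genetic distances

**Relatedness.** For a dyad, the likelihood of the two multilocus genotypes
is a mixture over the number of alleles shared identical-by-descent,
weighted by the Cotterman coefficients (k₀, k₁, k₂):
Pr(G₁,G₂ | k) = k₀S₀ + k₁S₁ + k₂S₂ per locus, with S₀ = Pr(G₁)Pr(G₂),
S₂ = Pr(G₁)·1[G₁=G₂], and S₁ the one-shared-gene term (the IBD copy is
equally likely either gene of G₁; the partner's second gene is a fresh
population draw).  The product over loci is maximized over the k-simplex
subject to the genetic feasibility constraint k₁² ≥ 4k₀k₂ by SLSQP started
from the four canonical relationships (unrelated, half-sib, full-sib,
parent–offspring); r̂ = k₂ + k₁/2 ∈ [0,1] by construction.  Allele
frequencies are the sample frequencies, so r̂ is accurate only when the
table is a reasonable frequency sample; with very small samples r̂ is biased
(the shared alleles are over-represented in the frequency estimates).
Per-dyad missing loci are dropped from that dyad's likelihood only.

**Kin filtering.** Dyads with r̂ strictly above the threshold (default 0.5,
so r = 0.5 parent–offspring/full-sib dyads are retained) are broken by
greedily removing the individual with the most above-threshold partners,
ties to the lexicographically smallest id.  Greedy max-degree removal keeps
the most individuals; the removal order is a convention, not an inference.

**Rousset's â.** Per locus, Q_ij is the probability that one gene drawn
from each individual matches (mean over the four cross draws) and Q̄w the
mean within-individual identity over the sample;
â = Σ_l (Q̄w,l − Q_ij,l) / Σ_l (1 − Q̄w,l) — a multilocus ratio of sums, the
convention of the FST-analogue estimator family this statistic belongs to.
The alternative (mean of per-locus ratios) weights low-diversity loci more
heavily; the ratio-of-sums form is stable when some loci are nearly fixed.

**D_PS.** Proportion of shared alleles: per locus shared = Σ_a min(cᵢ(a),
cⱼ(a))/2, averaged over loci typed in both members; ∈ [0,1].

## Terrain and density surfaces

TRI uses the squared-difference convention, √Σ(z_c − z_n)² over the eight
neighbors (the mean-absolute variant is selectable); TPI is z_c minus the
eight-neighbor mean.  Border cells use the neighbors that exist rather than
padded elevations — padding would invent terrain.  Point density is a
truncated-kernel sum (quartic by default, matching GIS heatmap tools),
with cells beyond every point's radius set to 0 ("no events here" is data,
not missing data).  Density is linear in point multiplicity by
construction.

## Resistance surfaces

Continuous rasters are affinely rescaled to [0, 10]; the transformation
then applies a base curve — Monomolecular g(x) = 1 − e^(−x/s) (saturating)
or Ricker g(x) = x·e^(−x/s) (humped, peak at x = s) — with "Reverse"
evaluating at 10 − x and "Inverse" reflecting the achieved curve
vertically, and finally rescales resistance onto [1, maximum].  Bounds
follow the optimization framework's convention: maximum ≤ 5000 for single
surfaces and ≤ 10000 inside composites.  "Distance" is the flat surface
(resistance 1 everywhere): commute distance then degenerates to a pure
isolation-by-distance null.  Composites are cell-wise sums re-anchored so
min = 1; resistances are additive costs, and re-anchoring keeps composite
and single surfaces on the same floor (whether to re-anchor is not
observable from the model fit — commute distances are invariant to a
common scale, and the fit standardizes the predictor — so the choice is
cosmetic; a sensitivity test in the suite verifies a flat component leaves
the composite ordering unchanged).

### Transformation-family aliasing (important caveat)

A Ricker curve whose peak sits at or beyond the top of the rescaled domain
(shape ≳ 9 on [0, 10]) is monotone-saturating and, after the affine
[1, max] rescale, approximates a Monomolecular curve closely.  The
deterministic likelihood separation between the two family labels is then
of the same order as (or smaller than) the ~3-parameter overfitting gain
of the search itself, which is scale-free in the noise variance.  The
practical consequence: the *resistance pattern* and its likelihood are
recoverable, but the *family label* of a monotone transformation is not a
reliably identifiable quantity, at any noise level.  Reported families for
monotone optima should be read as "monotone saturating", not as evidence
for a specific functional form.  Search ranges are deliberately left at
the field-standard shape ∈ [0.01, 100].

## Circuit theory

Resistance rasters become undirected conductance graphs (8-neighbor by
default): edge conductance 1/mean(Rᵢ, Rⱼ), diagonal edges divided by √2
for the longer step (the convention of the commute-distance tooling this
mirrors; 4-neighbor graphs need no correction).  Commute distance is
vol(G)·R_eff(i,j) — the expected round-trip steps of the weighted random
walk — computed by grounding one query node and solving the reduced SPD
Laplacian with a single sparse LU factorization; this agrees with the
dense pseudoinverse formula to 1e-8 (tested) and is O(solve) per query
node instead of O(n³).  Query coordinates snap to the nearest non-missing
cell center, ties toward lower row then column; row 0 is the northernmost
row, cell-center registration.  Current maps solve the Kirchhoff system
per source/sink pair and accumulate per-cell current magnitude (half the
summed absolute incident edge currents; the injected 1 A at terminals).

## MLPE mixed model

y᷉ᵢⱼ = β₀ + βᵀxᵢⱼ + uᵢ + uⱼ + εᵢⱼ, u ~ N(0, σ²_u) iid per individual.  With
Z the dyad×individual incidence matrix, V = σ²_u ZZᵀ + σ²_ε I.  The
likelihood is profiled: for a variance ratio γ = σ²_u/σ²_ε, GLS gives β̂ and
σ̂²_ε in closed form through the Woodbury identity (only n-individual-sized
solves), and log|I + γZZᵀ| = log|I_n + γZᵀZ|; a bounded 1-D search over
log γ (γ ∈ [e⁻¹², e¹²], xatol 1e-10, γ = 0 boundary checked explicitly)
maximizes ML or REML.  The implementation is verified against a dense
multivariate-normal log-density at the optimum (agreement to 1e-6) and
against OLS in the σ²_u = 0 limit.  Predictors are z-scored before fitting
so slopes are comparable across candidate distance matrices.

Information criteria: AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with **n = the
number of genotyped individuals**, the conservative effective sample size
for dyadic data (n = number of dyads would overstate the information), and
k the per-surface parameter count (2 for the distance null, 3 for a
two-class categorical surface, 4 for a transformed continuous surface).
This (n, k) convention reproduces the published surface model tables it
mirrors to the printed precision; two printed rows of the categorical
table are mutually inconsistent with every other row under any single
convention and are treated as typos.

## GA optimization

Objective: ML log-likelihood of MLPE(genetic ~ commute(transform(raw, θ))).
Defaults: population 30, tournament size 3, uniform crossover (p = 0.7),
Gaussian mutation (sd 0.6) on log-shape and log-maximum, family resampled
with p = 0.15, 15% random immigrants per generation, elitism of one, stop
after 25 generations without a ≥ 0.1 logL improvement (cap 100).  The
initial population is stratified so every family is represented.  Each run
ends with a Nelder–Mead polish of the continuous parameters (family fixed),
so independent runs converge to their basin's optimum rather than the GA's
last step.  Runs are repeated ≥ 2 times from independent seeds;
disagreement beyond 0.5 logL is flagged, never silently merged.  Commute
matrices are cached by a hash of the transformed surface, which is what
keeps desk-scale runtimes to seconds per evaluation batch.  For composites
the genome concatenates per-component transformations ("Distance" is
available per component, so a non-influential component can be selected
away), and the report includes each component's percent contribution
(range of its transformed values over the total).

## Bootstrap model selection

Each iteration draws ⌈frac·n⌉ individuals without replacement (default
frac = 0.75), restricts every matrix to the retained dyads, refits the
MLPE model per candidate surface **without re-optimizing transformations**,
and ranks by AICc (n = subsample size).  Ranks accumulate average rank;
per-iteration Akaike weights w_m = exp(−Δ_m/2)/Σexp(−Δ/2) accumulate ω̄;
the top-ranked candidate increments π̂ (reported as a percentage, the
bootstrap analogue of ω).  Subsampling operates on individuals — the
natural unit when genetic distances are individual-based.  Ties: fewer
parameters rank first; candidates with *exactly* equal AICc and k are
permuted randomly within the iteration so symmetric candidates receive
symmetric expected ranks (a deterministic name-order tie-break would give
two identical candidates ranks 1 and 2 forever).  Iterations whose
subsample is too small to fit are resampled and logged.  A fixed seed
reproduces the summary bit-for-bit.

## Gravity model

Singly-constrained gravity models on the saturated ordered-dyad network:
log D_PS regressed on log distance, log within-site covariates (attached
to the destination node — attraction), and log resistance distances, with
a random intercept per origin node as the single constraint (destination
constraint selectable).  Fits use REML through a standard linear
mixed-model solver; ML refits are available for nested comparisons, since
REML log-likelihoods are only comparable at a fixed fixed-effects design.
AIC = 2k_eff − 2ℓ with k_eff = (covariates beyond distance) + 4, the four
covering intercept, distance, origin variance and residual variance; this
convention reproduces the published gravity model tables it mirrors to
±0.001.  Zero responses receive a configurable offset (default half the
minimum positive value) and a loud log message.  Degrees of freedom are
conventions, not likelihood quantities: edge-level covariates use
n_dyads − p, node-level covariates n_nodes − 2 (site-level covariates
carry site-level information; using dyad counts would wildly overstate
significance).

## Synthetic data

`make_landscape` produces Gaussian-filtered noise fields (continuous),
multiscale ridged fields (DEM-like), or quantile-thresholded class maps;
autocorrelation range grows with the smoothing length (tested via lag
correlations).  `simulate_genetic_distances` draws directly from the MLPE
generative model on the true surface's standardized commute distances.
`simulate_genotypes` gives each site logistic-normal allele-frequency
deviates whose between-site correlation decays as exp(−decay·commute/
median commute) — a Gaussian-type kernel in the commute embedding, hence a
valid covariance — then draws two alleles per locus per individual; clones
and Mendelian parent–offspring dyads can be planted.
`simulate_gravity_network` builds a saturated network with log-normal site
attributes and a known linear predictor plus origin random effect.

Default noise for the MLPE estimator recovery suite: β₁ = 1, σ²_u = 0.5,
σ²_ε = 1 at n = 40 individuals (a low-signal regime, R² ≈ 0.33, that
stresses the variance-component machinery).  The GA-optimizer and
bootstrap-selection recovery suites instead use a high-signal
self-consistency regime, σ²_u = 0.01, σ²_ε = 0.02 (R² ≈ 0.97) on a 40×40
landscape with 30–50 sampled locations: these suites validate search and
selection machinery, which requires the planted structure to be
statistically identifiable; at the low-signal regime the data carry no
information about the transformation, and no optimizer could recover it.
Even in the high-signal regime the family *label* of a monotone optimum
remains a coin flip between aliases (see above) — the recovery suites
therefore treat the attained likelihood (within 0.5 logL of the truth) and
run-to-run agreement as the primary evidence of correct optimization.

What the generators do **not** emulate: linkage, null alleles and
genotyping error, mutation, drift/coalescent genealogies (frequency
correlations stand in for forward-time demography), anisotropic movement,
temporal environmental change, and observation error in rasters.  Passing
recovery tests therefore demonstrates that the inference chain is
self-consistent and numerically correct — not that real microsatellite
data meet the model's assumptions.

## Problem sizes and determinism

The test and acceptance suites run on 24×24–40×40 landscapes, 12–50
sampling locations, 40–62 individuals, 100–500 bootstrap iterations and
200 Monte-Carlo replicates — sizes chosen so the full chain (including two
GA runs with polish, ~1000–1400 objective evaluations) completes in about
a minute while leaving Monte-Carlo errors small relative to the tested
effects.  Every stochastic component takes an explicit integer seed;
repeated runs are bit-identical, and the pipeline runner refuses to
overwrite a non-empty artifact directory.
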