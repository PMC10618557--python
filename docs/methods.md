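# Methods

This note records the model, the sampler, the synthetic-data generator and
the numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model

Two-level hierarchy on images `Y (n × p)` and a standardized design matrix
`S (n × m)` of genotypes and covariates:

* Level 1: `y_ij ~ N(μ_i · δ{φ(v_j) > 0}, σ_i²)`. The mean outside the
  region is exactly zero (no intercept), and σ_i² is a single per-subject
  variance shared inside and outside the region. The level-set field φ has a
  mean-zero GP prior with squared-exponential kernel
  `κ(v,v′) = exp(−c‖v−v′‖²)`.
* Level 2: `μ_i ~ N(s_iᵀη, τ_μ²)`; η carries a continuous spike-and-slab
  prior `η_k | γ_k, τ_k² ~ N(0, γ_k τ_k²)`, `γ_k | w ~ (1−w)δ_{ν₀} + w δ_1`,
  `w ~ Uniform(0,1)`, or the non-sparse alternative `η ~ N(0, τ_η² I)`.
* Conjugate inverse-gamma priors on all variances.

For computation φ is replaced by its truncated Karhunen–Loève expansion
`φ = Ψβ`, `β ~ N(0, diag(λ))`, and the indicator by the smoothed step
`H_ε(x) = ½(1 + (2/π) arctan(x/ε))`.

### Basis construction

Voxel centers are mapped affinely to `[−1,1]` per axis
(`c_i = −1 + (2i+1)/n`, C-order voxel scan). On a regular grid the
squared-exponential kernel is separable, so the p×p kernel matrix is a
Kronecker product of small per-axis matrices; its eigenpairs are computed
exactly as products/Kronecker factors of the per-axis eigenpairs. Irregular
voxel sets (e.g., masked anatomical regions) use a dense symmetric
eigendecomposition up to p = 10,000 and a Nyström approximation with 2,000
landmark voxels above that. Eigenvalues below `1e-10 × λ_1` are clipped.
The truncation order L is minimal with cumulative eigenvalue share ≥ α.
On the 20³ grid with inverse scale 10 and α = 0.75 this gives L = 127.

Truncating at share α bounds the relative *trace-norm* reconstruction error
of the kernel by 1 − α (the Frobenius ratio is not bounded by 1 − α in
general; the tests check the trace-norm form).

## Posterior computation

One systematic scan updates β → μ → (η, γ, w, τ²) → (σ², τ_μ²).

**β (MMALA).** Proposal `β′ = β + (h/2)G⁻¹∇ + √h G^{−1/2}ξ` with the
position-dependent metric

    G(β) = (Σ_i μ_i²/σ_i²) · Ψᵀ diag(H′_ε(Ψβ)²) Ψ + Λ⁻¹,

the expected Fisher information of the β-likelihood plus the prior
precision (simplified-manifold MALA: the metric enters the proposal and its
MH correction, derivative-of-metric terms are omitted — the accept step
remains exact). Because `H′_ε² ∝ (ε/x)⁴` for `|x| ≫ ε`, the metric is
assembled only over voxels with `|φ_j| ≤ 100ε` (relative truncation error
≤ ~1e−8; G stays a deterministic function of β, so MH exactness is
unaffected). A fixed preconditioner `G = Λ⁻¹` is available as
`metric="fixed"`; it cannot track the boundary curvature and mixes far
worse on sharp-ε problems.

* Step size: adapted during burn-in by constant-gain (0.15) stochastic
  approximation toward the MALA-optimal acceptance 0.574, frozen afterward.
  A decaying-gain schedule collapses irrecoverably when early proposals are
  all rejected (before the level set has been located).
* ε annealing: during the first half of burn-in ε decays geometrically from
  0.3 to its target (1e−3 for the 2D and the segmentation-only 3D settings,
  1e−4 for the 3D selection settings). With a wide H_ε the likelihood is
  smooth in φ and the region migrates freely; the width is back to its
  target well before any draw is saved, so the sampled posterior is the
  target one. Disable with `anneal_eps0=0`.

**μ, σ², τ_μ².** Standard conjugate draws (normal and inverse gamma); the
exact conditional parameters are validated against quadrature oracles in
the test suite.

**Spike-and-slab block.** Two kernels, both invariant for the same
posterior:

* the standard blocking — η jointly from its multivariate-normal
  conditional, then γ_k element-wise given η_k, then w | γ and
  τ_k² | η_k, γ_k;
* a collapsed single-site scan — γ_k drawn with η_k integrated out of the
  two-point odds, η_k refreshed immediately, followed by a joint η refresh.

Conditioning γ_k on the current η_k makes whichever state the variant is in
nearly absorbing (flipping requires a tail draw of η_k), so a cold start can
leave true effects undetected for thousands of scans. `run_chain` therefore
uses the collapsed kernel for the first half of burn-in and the standard
blocking afterwards; the saved-phase dynamics are those of the standard
sampler.

**Initialization.** β from a 0.1× prior draw (β = 0 is degenerate: H ≡ ½
everywhere); μ_i from the mean of subject i's top-decile voxel intensities;
η = 0 with all indicators in the slab (the slab→spike direction mixes in a
few scans, the reverse does not); variances by method of moments.

## Key hyperparameters

| parameter | default | meaning / rationale |
|---|---|---|
| ε | 1e−4 (3D selection), 1e−3 (2D, segmentation-only) | smoothing width of H_ε, in φ units |
| α | 0.75 (0.8 segmentation-only) | basis variance share; L = 127 on the 20³ grid |
| kernel inverse scale c | 10 | prior correlation exp(−c h²) between voxels at distance h |
| ν₀ | 0.05 | spike/slab variance ratio; see below |
| c1, c2 | 2, 1 | IG prior on the slab variance τ_k², prior mean 1 |
| a1,a2,b1,b2,d1,d2 | 0.01 | vague IG priors (their conditionals are dominated by p/2-, n/2- or m/2-sized shape updates) |
| step size h | 0.1 initial, adapted | MMALA step, tuned to acceptance 0.574 |

Two hyperparameter choices deserve emphasis because the selection behavior
depends on them qualitatively:

* **Slab variance prior (c1 = 2, c2 = 1, informative unit scale).** Under a
  vague IG prior the conditional `τ_k² ~ IG(c1 + ½, c2 + η_k²/(2γ_k))` has
  shape ≈ ½ and routinely draws τ_k² ~ 1e4; the "spike" `ν₀τ_k²` then
  becomes unit-width, true effects migrate into it, and that representation
  is absorbing — variable selection silently inverts. A unit-scale slab
  (prior mean 1, matching unit-sized effects on standardized genotypes)
  removes the degeneracy.
* **Spike width (ν₀ = 0.05).** The two-point odds put the slab/spike
  crossover at `|η| ≈ √(2 ν₀τ² [ln((1−w)/w) + ½ln(1/ν₀)])` ≈ 0.7 on a unit
  slab. Chance genotype–intensity correlations produce apparent null
  effects up to |η| ≈ 0.25 in the simulated designs, well below the
  crossover, while unit true effects sit well above it: selection is then
  sharp in both directions. With a near-point spike (ν₀ ≤ 1e−4) the spike
  evidence converges to the point-null evidence, null inclusion
  probabilities become ν₀-invariant at the few-percent level, and
  specificity at small PIP thresholds degrades.

## Selection rules

* Voxels: posterior inclusion probability `z̄_j` = share of saved draws with
  `(Ψβ)_j > 0`; select `z̄_j > 0.5` (strict comparator; the inclusive `≥`
  variant used for real-data maps is a flag).
* Variants, spike-and-slab: PIP `γ̄_k` = share of saved draws with γ_k = 1;
  select `γ̄_k > 0.02` (simulation profile) or `> 0.5` (stringent profile).
* Variants, normal prior: one equal-tailed 99% credible interval per
  variant from all saved draws; select when the interval **excludes** zero.
  (The source formulation assigns the indicator when zero *is* included,
  which would select exactly the null variants; this is read as a typo and
  inverted — the result tables are only consistent with the inverted rule.)
  With a single interval the PIP is binary, so the companion 0.01 PIP
  threshold reduces to the exclusion test itself.

## Synthetic-data generator

Each dataset consists of a level-set field on a regular grid in `[−1,1]^d`
(closed-form circle/square/sphere/diamond bumps, or a seeded draw from the
GP prior), per-subject intensities, standardized Binomial(2, MAF) genotype
columns with MAF ~ Uniform(0.05, 0.5), five active variants with η_k = 1,
and Gaussian image noise. Two signal-to-noise ratios calibrate the design
exactly (not by Monte-Carlo matching):

    SNR(β) = (1/n) Σ_i |μ_i|/σ_i      — image contrast
    SNR(η) = Var(Sη) / τ_μ²           — genetic effect strength

given targets, `τ_μ² = Var(Sη)/SNR(η)` (population variance over the n
subjects) and a single noise scale `σ = mean|μ_i| / SNR(β)`; with
μ = Sη + ε this reproduces both targets identically. The
segmentation-only designs instead draw `μ_i ~ N(mean, sd²)` directly with a
fixed σ.

Random GP regions are drawn from the truncated expansion at the *analysis*
share (α = 0.75). Fields drawn at a near-complete share (α = 0.99) carry
structure below the analysis resolution and cap achievable voxel label
agreement near 0.84 on the 20³ grid, which is incompatible with the
classification accuracies this class of design is known to exhibit; the
well-specified convention is adopted once and documented here.

What the generator does **not** emulate: linkage-disequilibrium structure
between variants (columns are independent), registration error and spatial
noise correlation in real PET, region-specific intensities μ_{i,r}, and
longitudinal correlation across time points. Passing tests therefore show
correct inference under the model's own assumptions at realistic sizes —
not robustness to the ways real imaging data violate them.

## Problem sizes used in tests and the acceptance script

The replication experiments run the full study layout (n = 235 subjects,
20³ = 8,000 voxels, m = 200 variants with 5 true effects, all nine
shape-by-SNR cells) at reduced Monte-Carlo scale: 5 datasets per cell and
2,000 MCMC iterations (1,000 burn-in, thinning 2), the package's chosen
desk-scale defaults; the segmentation-only study uses its stated 5,000
iterations. A single chain at this size takes ~12 s on one CPU.

## Known limitations

* The label-sign symmetry (negative μ with flipped region) is not
  post-processed; μ is monitored instead. All study designs keep positive
  mean intensity, where this is a non-issue.
* The sampler is exact but local: multimodal level-set posteriors (e.g.,
  topologically distinct segmentations of very noisy data) are explored
  only through the ε-annealed burn-in, not between saved draws.
* PIPs for marginally-correlated null variants are genuine few-percent
  posterior quantities; specificity at the 0.02 threshold reflects the
  spike-width calibration above rather than a universal property of the
  model.
* The normal-prior credible-interval rule is approximately calibrated
  (~1–2% null exclusions at the 99% level), so its specificity is high;
  sources reporting materially lower specificity for this rule are
  reporting under-dispersed interval estimates, which this implementation
  does not reproduce.
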