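# bnls — Bayesian nonparametric level-set modeling for imaging genetics

`bnls` jointly estimates **where** a brain activation region sits and
**which genetic variants** drive the activation intensity inside it, from
multi-subject imaging data (e.g., FDG-PET) plus a subjects × variants
genotype/covariate matrix.

It is aimed at statisticians and imaging-genetics analysts who want fully
Bayesian inference on both the region shape and the variant effects, with
uncertainty expressed as posterior inclusion probabilities for voxels and
variants alike.

## Model

Let `y_ij` be the image intensity of subject `i` at voxel `v_j` and `S_ik`
the (standardized) genotype of subject `i` at variant `k`.

**Level 1 — region shape.** A shared level-set function φ defines the
region: voxels with φ(v) > 0 are inside. Intensities follow a two-component
normal mixture,

    y_ij ~ N( μ_i · δ{φ(v_j) > 0}, σ_i² ),

with per-subject activation intensity μ_i and noise variance σ_i². φ has a
mean-zero Gaussian-process prior with squared-exponential kernel
κ(v, v′) = exp(−c‖v − v′‖²), represented by its truncated Karhunen–Loève
expansion φ = Σ_l β_l ψ_l, β_l ~ N(0, λ_l); the truncation order L is the
smallest number of eigenpairs capturing a share α (default 0.75) of the
kernel variance.

**Level 2 — genetic effects.** Intensities regress on genotypes,
μ_i ~ N(s_iᵀη, τ_μ²). The effect vector η carries either a continuous
spike-and-slab prior, η_k | γ_k, τ_k² ~ N(0, γ_k τ_k²) with
γ_k ∈ {ν₀, 1} and prior inclusion probability w ~ Uniform(0, 1)
(variable selection), or a plain normal prior η ~ N(0, τ_η² I) (a faster
non-sparse variant).

**Computation.** The hard indicator is smoothed to
H_ε(x) = ½(1 + (2/π) arctan(x/ε)), making the likelihood differentiable in
β. Posterior sampling is a systematic-scan Gibbs sampler: a
manifold-preconditioned Metropolis-adjusted Langevin (MMALA) step for β,
conjugate draws for everything else, and stochastic search variable
selection (SSVS) for (γ, w). Voxels are selected where the posterior
probability of φ_j > 0 exceeds 0.5; variants where the posterior inclusion
probability exceeds 0.02 (or, for the normal prior, where the 99% credible
interval excludes zero).

## Worked example

```python
import numpy as np
from bnls import (SimConfig, simulate_dataset, build_basis, RunConfig,
                  HyperParams, run_chain, voxel_inclusion_map, select_voxels,
                  select_snps_ssvs, confusion_metrics)

# 235 subjects, 20x20x20 images, spherical activation region, 200 variants
# with 5 true unit effects; image SNR 8, genetic SNR 8.
cfg = SimConfig(shape_kind="sphere", snr_beta=8.0, snr_eta=8.0, seed=3)
data, truth = simulate_dataset(cfg)

basis = build_basis(data.grid, cfg.kernel, alpha=0.75)        # L = 127
draws = run_chain(data, basis, RunConfig(n_iter=2000, n_burnin=1000,
                                         thin=2, seed=4))

inc = voxel_inclusion_map(draws, basis)
vox = select_voxels(inc)                      # PIP > 0.5
sel = select_snps_ssvs(draws)                 # PIP > 0.02
print("beta acceptance:", round(draws.accept_rate, 2))
print("voxel ACC/TPR/TNR:",
      [round(x, 3) for x in confusion_metrics(
          vox, np.flatnonzero(truth.labels), data.p)])
print("selected variants:", sel.selected.tolist(),
      " true:", truth.active.tolist())
```

Output:

```
beta acceptance: 0.62
voxel ACC/TPR/TNR: [1.0, 1.0, 1.0]
selected variants: [16, 106, 111, 126, 165]  true: [16, 106, 111, 126, 165]
```

All 8,000 voxels are classified correctly and exactly the five true
variants are recovered. A run takes ~12 s on one CPU.

The same pipeline is available from the shell:

```bash
bnls simulate --config sim.yaml --out data/
bnls fit --images data/images.nii.gz --genotypes data/genotypes.tsv \
         --out chain.h5 --seed 4
bnls summarize --chain chain.h5 --grid-shape 20,20,20 --out summary/
bnls evaluate --scenarios scenarios.yaml --out metrics.tsv
```

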