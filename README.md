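# dirgmm — directional Gaussian mixture models for spatial microbiome data

MaPS-seq and similar droplet technologies sample the gut microbiome at
~20-μm resolution: every barcode groups the reads of one local community,
but the position of each droplet along the gut is lost in the process.
`dirgmm` recovers the *relative* spatial arrangement of those communities.
It is written for computational microbiologists who have a barcode × taxon
table (and optionally a phylogeny) and want to know whether their samples
line up along one spatial axis, two, or none.

## The model

After an isometric log-ratio transform of the relative abundances
(x_b ∈ ℝ^(D−1) for D taxa), barcodes are modeled as a Gaussian mixture
whose latent cluster means — archetypal community states — are chained by
spatial dependencies instead of being independent:

    μ₁ ~ N(μ̄₀, Q₀)
    μᵢ | μᵢ₋₁ ~ N(μᵢ₋₁ + Δ, Q)                      (K × 1 chain)

    μ₂₁ | μ₁₁ ~ N(μ₁₁ + Δ⊥, Q),  Δ·Δ⊥ = 0
    μ₂ᵢ | μ₁ᵢ, μ₂(ᵢ₋₁) ~ N(½(μ₁ᵢ + μ₂(ᵢ₋₁) + Δ + Δ⊥), Q)   (K × 2 grid)

    z_b ~ Categorical(π),   x_b | z_b = s ~ N(μ_s, Σ_s)

Δ is the average compositional change between spatially adjacent states
along the longitudinal axis, Δ⊥ the orthogonal (radial) change, and Q the
covariance of deviations from that trend. Inference is MAP
expectation–maximization with restarts; candidate arrangements (2×1 … 8×1,
2×2 … 4×2) are compared by AIC with the complete log-likelihood as the
likelihood surrogate. A matching synthetic-data generator (Pareto-derived
sorted mean compositions, inverse-Wishart cluster covariances, evenly
drawn samples) and the associated evaluation statistics (label-matched
RMSE against a naive GMM, Wilcoxon comparison, Δ-axis projections, KL
divergence with a permutation test) are included. Details and design
rationale are in [`docs/methods.md`](docs/methods.md).

## Worked example

Simulate 360 barcodes from a 4-state chain with step magnitude |Δ| = 5 and
unit within-cluster standard deviation, fit the chain model, and compare
the learned community states with the generating truth:

```console
$ dirgmm simulate --grid 4x1 --delta 5 --n 360 --seed 11 --out data.tsv --truth truth.json
wrote 360 samples from a 4x1 truth to data.tsv

$ dirgmm fit --data data.tsv --grid 4x1 --n-init 20 --seed 7 --out fit.json
4x1 fit: ECLL -9522.39 after 9 iterations

$ dirgmm evaluate --fit fit.json --truth truth.json --out eval.json
grid-matched RMSE: 0.0359

$ dirgmm project --fit fit.json --data data.tsv --out proj.tsv
wrote projections for 360 barcodes to proj.tsv
```

The fit converged in 9 EM iterations to an expected complete
log-likelihood of −9522.4. The grid-matched RMSE of 0.036 means the four
learned state means each sit about 0.04 ILR units from the truth — far
below both the within-state noise (sd 1) and the state spacing (5), i.e.
the spatial arrangement was recovered essentially exactly. `proj.tsv`
holds each barcode's scalar coordinate along the unit Δ axis together with
its hard cluster assignment (`fit.json`/`proj.tsv.means.tsv` carry the
state coordinates), which is the standard one-dimensional visualization of
the recovered axis.

Real count tables enter through `dirgmm transform`:

```bash
dirgmm transform --counts counts.tsv --tree tree.nwk --coverage 0.95 --out ilr.tsv
dirgmm select --data ilr.tsv --n-init 200 --seed 7 --out report.json
```

`select` fits every candidate arrangement and reports per-candidate AIC
scores, the winning grid, and the AIC score difference against a naive
(spatially independent) GMM with the same number of clusters — a
difference above 10 means the unstructured model has essentially no
support. Library users can do the same through `dirgmm.fit`,
`dirgmm.select_model`, `dirgmm.generate_dataset` and the
`dirgmm.evaluate` statistics.

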