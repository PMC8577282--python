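# Methods

## The model

MaPS-seq measures local gut microbial communities: each barcoded droplet
captures one ~20-μm plot, but the positions of the plots along the gut are
lost. `dirgmm` models the barcodes as draws from `K` (or `2K`) latent
*community states* whose means are linked by spatial dependencies, so that
the relative arrangement of the states — and with it the global spatial
axis (or axes) of the community — can be recovered from unordered samples.

Observations are compositional. Read counts are closed to relative
abundances, the most abundant taxa jointly covering 95% of total abundance
are retained and renormalized, zeros are imputed by multiplicative
replacement with δ = 1/D² for D taxa, and the result is mapped to ℝ^(D−1)
by an isometric log-ratio (ILR) transform. The ILR basis is a sequential
binary partition — from a rooted phylogeny when one is supplied (one
balance per internal node, the PhILR construction, unweighted), otherwise a
balanced bisection of the taxon order. Non-binary nodes are resolved by
deterministic left-to-right caterpillar expansion.

In ILR space, cluster means form a linear-Gaussian network. For a chain
(one-dimensional model) with states S = {1..K}:

    μ₁ ~ N(μ̄₀, Q₀)
    μᵢ | μᵢ₋₁ ~ N(μᵢ₋₁ + Δ, Q)        i = 2..K

For a K × 2 grid, the second row shifts by a radial step Δ⊥ ⊥ Δ:

    μ₂₁ | μ₁₁ ~ N(μ₁₁ + Δ⊥, Q)
    μ₂ᵢ | μ₁ᵢ, μ₂(ᵢ₋₁) ~ N(½(μ₁ᵢ + μ₂(ᵢ₋₁) + Δ + Δ⊥), Q)

Barcode b belongs to state z_b ~ Categorical(π) and is observed as
x_b | z_b = s ~ N(μ_s, Σ_s) with a full per-state covariance Σ_s. The
complete likelihood p(μ_S, z_B, x_B) multiplies the spatial prior factors,
the categorical assignments and the Gaussian observations.

## Inference

Fitting is MAP expectation–maximization: the E-step computes
responsibilities r_bs ∝ π_s N(x_b | μ_s, Σ_s) (log-sum-exp normalized);
the M-step is one pass of block coordinate ascent:

1. **Means** — the maximum a posteriori μ_S solve a single sparse
   block-linear system (the objective is jointly quadratic because the
   prior is linear-Gaussian); the solution zeroes the analytic gradient to
   machine precision.
2. **Steps** — for chains, Δ is the average successive difference, which
   telescopes to (μ_K − μ₁)/(K − 1). For grids, (Δ, Δ⊥) are maximized by
   exact alternating closed-form solves of the edge objective under the
   linear constraint Δ·Δ⊥ = 0, starting from the previous feasible pair,
   so the constraint holds exactly and the objective never decreases.
3. **Remaining parameters** — π is the mean responsibility;
   Σ_s = (N_s·scatter_s + κ τ² I)/(N_s + κ) with κ = 10 pseudo-observations
   and τ² the overall mean per-coordinate data variance;
   Q = (edge scatter + r τ² I)/(m + 1) with r = 10⁻⁶ and m edges.

The covariance shrinkage is essential, not cosmetic. With D = 47 taxa and
a few hundred barcodes, per-cluster maximum-likelihood covariances are
estimated from fewer points than dimensions; unregularized EM reliably
drifts to degenerate partitions whose collapsed log-determinants dominate
the likelihood, while the generating arrangement scores worse. With the
weak conjugate penalty the generating basin had the highest objective in
every simulated dataset we examined. Q needs its own floor because its
scatter has at most one rank per grid edge and collapses without bound
once the fitted means sit exactly on the grid. Both penalties are part of
the optimized objective, so every M-step block is an exact maximizer and
the recorded objective trace (expected complete log-likelihood plus
penalties) is non-decreasing; the plain expected complete log-likelihood
of the final state is reported separately and used for model selection.

The root hyperprior is fixed, not optimized: μ̄₀ is the data mean and
Q₀ = 10³·τ²·I, effectively uninformative. Its maximum-likelihood update
from the single root draw would be degenerate (Q₀ → 0).

**Initialization and restarts.** Each fit runs `n_init` independent
initializations (default 200; the bundled experiments use 20) on
deterministic substreams of the seed. An initialization seeds a basic
independent-cluster GMM by k-means in the leading principal subspace —
columns along the first principal axis, where the longitudinal spread
lives, and for grids a two-means row split along one of the five leading
principal axes of the within-column residuals, cycled across restarts to
explore candidate radial directions. The full-space metric is useless for
seeding here: with heavy-tailed inverse-Wishart-like within-cluster
covariances the states overlap in Euclidean distance and separate only in
Mahalanobis distance. The seeded template is then aligned by a short
burn-in (≤ 40 EM iterations with uniform weights, one shared spherical
covariance and Q clamped small) in which effectively only the grid
geometry adapts, before the full model is released. An initialization
converges when the objective's relative increase stays below 10⁻⁴ for 5
consecutive iterations; one exceeding 500 iterations is discarded and
replaced. The converged fit with the highest objective wins and is
reported in the canonical gauge Δ[0] ≥ 0 (a chain read backwards with −Δ
is the same model).

## Model selection

Candidates are chains 2×1 … 8×1 and grids 2×2 … 4×2, dropping any
arrangement whose average state would hold fewer than 50 samples. Each is
scored by AIC = −2 ln L̂ + 2 p_k with the expected complete log-likelihood
as L̂; candidates with the same number of states are compared by complete
likelihood directly, and residual ties break toward fewer parameters, then
chains. A naive GMM with the winner's cluster count — fitted with the
same seeding and the same covariance shrinkage, so the comparison isolates
the spatial prior — provides the AIC score difference; differences above
10 indicate essentially no support for the weaker model.

p_k counts the mixture weights (|S|−1), Δ (d), Δ⊥ (d−1, grids only), and
each shrinkage-regularized covariance at d effective scales (|S|·d for the
Σ_s, d for Q). The fixed root hyperprior is not counted, and the cluster
means are latent states under the spatial prior rather than free
parameters. Counting covariances at their nominal d(d+1)/2 entries would
put the penalty above the total information in the sample (p_k > n at
d = 46) and make the criterion prefer ever-smaller models regardless of
fit; the effective count reflects what the shrunk estimators can actually
adapt.

**Known limitation.** The complete-likelihood surrogate rewards splitting
even unstructured data: in high dimension each additional cluster can gain
on the order of d²/2 nats purely from covariance adaptation, which is more
than true spatial structure gains per cluster. No cluster-count-linear
penalty can therefore both detect real grids and refuse to split a
structureless blob; on featureless data the criterion will drift toward
the largest candidate. In the regimes studied here the practical guard is
different: on sharply separated data, over-sized candidates cannot keep
every state populated, fail their initializations, and are recorded as
failed rather than scored.

## The synthetic-data generator

The generator reproduces the simulation protocol exactly. Two anchor
compositions are built from D = 47 i.i.d. standard Pareto(α = 1) draws,
closed to the simplex and sorted in decreasing abundance before the ILR
transform (using the balanced default basis; the simulation involves no
phylogeny); their ILR difference, rescaled to the requested magnitude
(default |Δ| = 5), is the longitudinal step. Sorting concentrates the
step on balances of abundant taxa, mimicking the larger dynamics visible
on abundant taxa in real data. For grids, Δ⊥ is a standard normal draw
orthogonalized against Δ and rescaled (default |Δ⊥| = 5). The remaining
means are laid out exactly on the chain/grid from the first anchor.
Per-state covariances are independent inverse-Wishart(ν = D + 1,
Ψ = I/(D−1)) draws; with the default `sd_scale = 1` each draw is rescaled
so its mean diagonal is 1 (the stated within-cluster standard deviation of
the benchmark regime; `sd_scale = None` keeps the raw draws, whose mean is
Ψ itself). 360 samples are drawn evenly and independently across states,
the remainder round-robin from the first state. Everything is
deterministic under the seed.

What the generator does *not* emulate: sequencing counts and their
sampling noise (data are drawn directly in ILR space), barcode collisions,
read-depth variation, zero inflation, or phylogenetic structure in the
basis. Passing the bundled benchmarks therefore demonstrates recovery of
spatial structure under the model's own noise assumptions, not robustness
to the full messiness of real MaPS-seq libraries.

## Evaluation statistics

* **Label-matched RMSE** — per state, the root mean squared coordinate
  error of the learned mean; averaged over states. Directional fits are
  matched under the grid labeling minimized over its order-reversal
  symmetries; naive GMMs, whose labels are arbitrary, get the best of all
  |S|! label permutations (exhaustive, |S| ≤ 8).
* **Paired comparison** — a one-sided Wilcoxon signed-rank test that the
  directional RMSE is smaller, paired per simulated dataset.
* **Projections** — scalar coordinates of data and means on the unit Δ
  (and Δ⊥) axes, for the standard one- and two-dimensional visualization.
* **KL divergence** — KL(observed ‖ proposed), natural log, between a
  state's observed mean composition (hard-assigned barcodes) and its
  proposed composition (inverse-ILR of the fitted mean). Significance via
  a permutation test (default 10,000 coordinate permutations of the
  observed vector) with the add-one estimator; *small* p means the two
  compositions are closer than random coordinate matching would produce.
* **Assigned-versus-best-other test** — per barcode, the fitted
  log-density in its assigned state against the best log-density among the
  other states, compared by a paired one-sided t-test.

A further limitation concerns 2 × 2 grids with equal step magnitudes:
the arrangement is a square, so the two axes are interchangeable (the
model is symmetric under transposing rows and columns) and the spatial
prior has only one longitudinal edge per row to lean on. Restarted EM
reliably picks the right model *size* there, but the recovered vertex
means are noticeably further from the truth (roughly 3–4× the
mean-recovery error of larger grids in the bundled benchmarks), reflecting
local optima of the harder search geometry rather than a defect of any
single update.

## Numerical choices and degenerate inputs

Responsibilities are normalized in log space; an all-underflow row raises
with the barcode index. A cluster whose responsibility mass falls below
10·machine-epsilon aborts that initialization (counted against `n_init`);
in the naive baseline a starved component is instead frozen, so the
restart scores poorly rather than dying. K = 1 chains have no edges: Δ is
returned as zeros with a warning. Taxon-ranking ties in the abundance
filter break by input order; k-means seeds derive from the fit seed, so
identical seeds give bitwise-identical fits. Filtering at a fixed coverage
is not idempotent — renormalization inflates the survivors' shares, so a
second pass can retain a shorter prefix; this is a property of the
renormalize-then-rank rule itself.

## Problem sizes of the bundled experiments

The test suite and `scripts/acceptance.py` run the benchmark regime
(D = 47, n = 360, |Δ| = |Δ⊥| = 5, unit within-cluster sd) with 20 EM
initializations per fit, 30 paired datasets per configuration for the RMSE
comparison, and 10 seeds per configuration for model-selection accuracy —
the package's chosen desk scale; full-scale runs use 200 initializations.
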