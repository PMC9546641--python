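# Methods

This note records the models implemented in `vmgcaps`, the assumptions and
numerical choices behind them, and what the synthetic experiments do and do
not demonstrate.

## Variational Bayesian Gaussian mixture (`vmgcaps.vbgmm`)

The core model is a finite mixture of K Gaussians over points x_n in R^D
with latent one-hot assignments z_n, a symmetric Dirichlet(α₀) prior on the
mixing weights π, and an independent Gaussian–Wishart prior on each
component's mean and precision:

    π ~ Dir(α₀, …, α₀)
    Λ_k ~ Wishart(W₀, ν₀)
    μ_k | Λ_k ~ N(μ₀, (β₀ Λ_k)⁻¹)
    x_n | z_nk = 1 ~ N(μ_k, Λ_k⁻¹)

Inference is mean-field coordinate ascent with the factorization
q(Z) q(π) q(μ, Λ). The E-step computes log-domain responsibilities

    ln ρ_nk = E[ln π_k] + ½ E[ln|Λ_k|] − (D/2) ln 2π
              − ½ ( D/β_k + ν_k (x_n − m_k)ᵀ W_k (x_n − m_k) ),

row-normalized by log-sum-exp (direct exponentiation overflows for modest
|ln ρ|). The M-step applies the conjugate updates
α_k = α₀ + y_k, β_k = β₀ + y_k, ν_k = ν₀ + y_k,
m_k = (β₀ μ₀ + y_k x̄_k)/β_k and
W_k⁻¹ = W₀⁻¹ + y_k S_k + β₀ y_k/(β₀+y_k) (x̄_k−μ₀)(x̄_k−μ₀)ᵀ, with
y_k, x̄_k, S_k the responsibility-weighted counts, means and scatters. The
evidence lower bound is assembled from its seven expectation terms (each
retrievable individually via `elbo_terms` for diagnostics) and is
non-decreasing under these updates; the test suite asserts this on dozens of
random fixtures at a 1e-8 relative tolerance, which absorbs benign
floating-point cancellation in a quantity of magnitude 10²–10⁴.

**Covariance modes.** A 1-D `W0` selects diagonal mode: scatters keep only
their diagonal and all Wishart normalizers retain the full multivariate
form, so diagonal and full mode coincide exactly whenever the scatter
matrices are diagonal. Diagonal mode is the default and the only mode used
inside routing — a mean-field-style constraint that also limits the damage
of nearly collinear features.

**Degenerate inputs.** 0·ln 0 := 0 in every entropy-like term. A component
with y_k < 1e-12 receives x̄_k := μ₀ and S_k := 0, which makes its M-step
return the prior exactly (no 0/0). Duplicated data cannot collapse a
variance to zero because W₀⁻¹ > 0 bounds every posterior precision.

**Initialization and restarts.** Responsibilities are seeded by
kmeans++-style point spreading (first provisional center uniform, later ones
with probability proportional to squared distance; one-hot assignment to the
nearest center), followed by one M-step. A symmetric Dirichlet(1,…,1) draw
per row is available as `init_method="random"`, but random responsibilities
concentrate all components near the global mean and measurably often merge
well-separated clusters, so point seeding is the default. `fit` restarts
from `n_init = 4` seeded initializations and keeps the highest-ELBO run;
coordinate ascent only finds local optima and the merged-cluster optimum is
clearly separated in ELBO, so best-of-n restarts make recovery stable in
seed sweeps. Convergence is declared when the relative ELBO change drops
below `tol = 1e-6` (cap `max_iter = 200`).

**Default priors.** α₀ = 1/K (uniform mixing in expectation), β₀ = 1,
μ₀ = data mean (zero for routing), W₀ = I, ν₀ = D + 1 (the smallest integer
degrees of freedom giving a proper, weakly informative Wishart).

## VMG routing (`vmgcaps.routing`)

Routing-by-agreement between capsule layers is the same variational mixture
run on votes: lower capsule n casts a vote x_{k|n} ∈ R¹⁶ (a flattened 4×4
pose prediction) for each higher capsule k, and higher capsule k is mixture
component k with diagonal precision λ_k. Iteration alternates the E-step
over higher capsules with an activation-weighted M-step (point weights
a_n · r_nk, so inactive lower capsules contribute nothing), starting from
the prior state; symmetry between components is broken by the votes
themselves, which differ per target capsule. Three iterations are the
default.

After the last update the bound is split into per-capsule shares L_k: every
term of the seven-term ELBO either carries an index k or (the two Dirichlet
normalizers and the Wishart prior constant) is divided evenly over K, so
Σ_k L_k equals the full activation-weighted ELBO exactly — a property the
tests check against the standalone mixture core. The activation is

    a_k = σ( τ (L_k − β_a,k) ),

with β_a a trainable per-capsule-type cost (initialized at 0) and τ an
inverse temperature (fixed at 1 in the standalone router, configurable).
Inside the network τ = exp(s)/√(nD) for a layer with n lower capsules and
D = 16, where s is a trainable per-layer log-temperature initialized at 0:
the spread of L_k across inputs grows with the evidence a capsule can
absorb, and without the 1/√(nD) scaling the sigmoid is either saturated
(τ = 1) or flat at 0.5 (τ = 1/(nD)), both of which stall learning; the
learned refinement lets each layer find its useful operating range.

The M-step is written in raw-moment form,
W_k⁻¹ = W₀⁻¹ + Σ_n w_nk v² + β₀μ₀² − (β₀μ₀ + t_k)²/(β₀ + y_k) with
t_k = Σ_n w_nk v, algebraically identical to the scatter form but free of
divisions by y_k, so empty capsules revert to the prior with finite
gradients. Everything — digamma and log-gamma terms included — is
differentiable end-to-end; routing runs on the package's reverse-mode
autodiff core (`vmgcaps.autodiff`, a small numpy tensor/graph engine with
the polygamma-family derivatives and fused kernels for the large vote
reductions). Finite-difference checks on 3-lower/2-higher fixtures agree
with the autodiff gradients to ~1e-10.

**Posterior sampling.** For stochastic predictive runs the class layer
draws its output poses from N(m_k, (β_k ν_k w_kd)⁻¹) — the Gaussian part of
the Gaussian–Wishart posterior at the posterior-mean precision — and the
per-capsule ELBO (hence the activation) is evaluated at the sampled pose.
The convolutional capsule layers stay at their posterior means: most of
their spatial positions receive almost no effective evidence, so their
posteriors are essentially the prior, and sampling them injects
input-independent noise (sd (β₀ν₀w₀)^(-1/2) ≈ 0.24 per pose entry) that
measurably destroys the mean prediction.

## The capsule classifier (`vmgcaps.network`)

Architecture [f, p1, p2, p3, p4] on a 32×32×1 input (28×28 inputs are
zero-padded; color is collapsed to luminance):

- conv stem: f filters, 2×2, stride 2, rectifier, **no bias** (the
  threshold is absorbed by the primary heads), → 16×16×f;
- primary capsules: 1×1 convs giving p1 pose matrices (4×4) and p1 sigmoid
  activations per position;
- two convolutional capsule layers (p2, p3 types): 3×3 windows, stride 2,
  padding 1 (16×16 → 8×8 → 4×4), VMG routing over the 9·p_in votes per
  window;
- class capsules: one set of per-(input-type, class) transform matrices
  broadcast over the 4×4 grid, global routing into p4 = #classes capsules.

Transform matrices are shared across window offsets. Spatial identity is
restored by a learned 4-vector per (offset, input-type, output-type) added
to the translation column of the vote — a fraction of the cost of
per-offset matrices — and the class layer analogously adds a per-position
vote bias under its broadcast matrices. The two middle layers also learn a
per-output-type routing prior mean (the class layer keeps μ₀ = 0), and
every routed layer owns a trainable scalar log-temperature for its
activation sigmoid (initialized at zero, i.e. at the fixed 1/√(nD) scale;
the useful temperature varies across layers and a poorly scaled one
measurably stalls training). These choices fix the parameter counts at
14,049 (14.0 K) for {32, 4, 8, 8, 10} and 10,203 (10.2 K) for
{32, 4, 8, 8, 4}.

Transforms initialize at identity + N(0, 0.5²): near-identical capsule
types within a layer make routing responsibilities uniform and gradients
through them tiny, and the 0.5 perturbation removes that plateau. Conv and
head weights use fan-in scaled Gaussians.

**Losses.** Spread loss on class activations,
L = Σ_{i≠t} max(0, m − (a_t − a_i))², plus negative log likelihood on the
activations normalized to a simplex; the two are summed unweighted. The
margin m ramps linearly from 0.2 during training (see below).

## Uncertainty (`vmgcaps.uncertainty`)

N stochastic forward passes give class distributions p⁽¹⁾…p⁽ᴺ⁾. The report
contains their mean p*, the argmax class (ties to the lowest index),
NLL* = −ln max p*, the entropy of p* (natural log, 0·ln 0 := 0), and the
per-class population variances (1/N convention) whose sum is the total
variance σ_T². A deterministic pass has σ_T² = 0 identically — the
epistemic component vanishes and only the aleatoric entropy remains. The
mean is computed anchored at the first run so that identical runs give
σ_T² = 0 exactly rather than ~1e-17.

## Synthetic data (`vmgcaps.data`)

- **Gaussian clusters**: K unit-covariance clusters whose means form a
  regular simplex with edge `separation` (randomly rotated, centered at the
  origin; repulsion sampling when K > D+1). The simplex keeps the
  constellation compact, so the weakly informative prior shrinks recovered
  means by only ~|μ₀−x̄|/y_k ≈ 0.05 at 100 points per cluster.
- **Vote fixtures**: votes around `n_clusters` centers in R¹⁶, expressed
  relative to each higher capsule's reference pose (capsule k's reference is
  cluster k's center), the geometry a trained transform layer produces.
  Identical absolute votes across capsules would make the mixture
  components exactly interchangeable — a symmetric fixed point of routing.
- **Shapes**: 32×32 grayscale images of a disk, square or triangle (cross
  held out as the out-of-distribution class) at random position (±1/5 of
  the image), scale (radius 4.9–8.9 px), and rotation, with additive
  Gaussian pixel noise (σ = 0.05) clipped to [0, 1] and never denoised. The
  default training counts (60, 40, 20) are deliberately imbalanced (3:2:1),
  echoing a small, skewed medical-image collection; validation and test
  take ~a third of each class, and the OOD split has 30 cross images.
  Datasets persist as IDX files plus a JSON manifest, and the same IDX
  reader loads real MNIST-format files.

What the shapes data does *not* emulate: anatomical texture, acquisition
artifacts beyond Gaussian noise, label noise, and domain shift within a
class. Passing the desk-scale study shows the training loop, routing and
uncertainty machinery behave as designed — not that the model reaches any
particular accuracy on radiographs.

## Desk-scale training recipe

The full-scale defaults follow the published recipe (adaptive-moment
descent at lr 0.001, up to 100 epochs, batches of 16–32 shuffled per epoch,
3 routing iterations, early stopping on 10,000 steps without validation
improvement — "patience" is read as optimizer steps, since 10,000 epochs
would be meaningless against a 100-epoch budget; an optional halving
schedule is behind `lr_halve_every`). The best-validation checkpoint is
kept (weights as `.npz`, architecture/seed/config in a JSON sidecar).

The desk-scale study (reduced architecture {8, 2, 2, 2, 3}, 120 training
images, 30 epochs, one CPU) uses lr 3e-3, batch 16, and a spread margin
ramped 0.2 → 0.5 over the first 70% of steps. The differences from the
full-scale recipe are deliberate: at ~8 optimizer steps per epoch a larger
step size compensates for the 30× shorter schedule, and the lower margin
ceiling suits ELBO-driven sigmoid activations, which concentrate between
0.4 and 0.95 rather than spanning [0, 1] — a 0.9 margin saturates the loss
early and stalls progress (measured: the 0.9/20% schedule plateaus near
75–85% training accuracy at 30 epochs, while the same model fits to >99%
given more epochs).

## Known limitations

- The autodiff core is eager and unoptimized beyond a few fused kernels;
  training beyond desk scale is slow.
- Routing from the cold (prior) start can merge clusters when votes carry
  no per-capsule structure; inside the network the learned transforms
  provide that structure, but the standalone router is not a general-purpose
  clustering tool.
- Per-capsule ELBO shares split the Dirichlet normalizers evenly across K;
  other splits would shift all activations by a common amount absorbed by
  β_a, but are not explored.
- Diagonal mode drops scatter cross-terms rather than refactorizing the
  Wishart per dimension; this is what makes diagonal and full modes agree
  on diagonal scatters, but it is not a per-dimension conjugate model.
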