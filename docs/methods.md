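# Methods

## Problem setting

A point distribution model (PDM) represents an anatomical shape as an
ordered list of N landmark points, X(0) = (x_1, …, x_N), x_i ∈ R³, where
index i marks the same anatomical locus in every subject of a population.
Correspondence is what makes PDMs useful for morphometry: per-index group
statistics localize effects such as hippocampal atrophy in Alzheimer's
disease. Unordered point-cloud generators discard exactly this structure.
`pdmdiff` implements a denoising diffusion probabilistic model (DDPM) whose
samples *preserve* correspondence: generated point i lies at the locus that
index i occupies in the training population.

## Diffusion model

Forward process (1-based timesteps t = 1..T):

    q(X(t) | X(t-1)) = N( sqrt(1 - β_t) X(t-1), β_t I ),

with variance schedule β_1..β_T, α_t = 1 − β_t, ᾱ_t = Π_{s≤t} α_s
(ᾱ_0 ≡ 1). The t-step marginal has the closed form

    X(t) = sqrt(ᾱ_t) X(0) + sqrt(1 − ᾱ_t) ε,  ε ~ N(0, I),

which the test suite verifies against sequential simulation of the one-step
kernel. A network ε_θ(X(t), t[, class]) is trained to predict ε with the
plain L2 objective ‖ε − ε_θ‖², reduced by the mean over batch, points and
coordinates so the loss scale is independent of N and T. Ancestral
sampling runs the learned reverse transitions

    p(X(t-1) | X(t)) = N( μ_θ, β_t I ),
    μ_θ = ( X(t) − β_t / sqrt(1 − ᾱ_t) · ε_θ ) / sqrt(α_t),

with the reverse variance fixed to β_t I (not the ᾱ-tilde variant) and no
noise added at the final t = 1 → 0 step.

**Schedule defaults.** Linear β from 1e-4 to 0.02 with T = 1000 (the
standard DDPM operating point). At desk scale we run T = 100 and scale the
β range by 1000/T (to 1e-3..0.2) so that ᾱ_T ≈ 2e-5 — without this
rescaling ᾱ_T ≈ 0.36 at T = 100 and the N(0, I) sampling start is far
from the forward marginal. A squared-cosine ᾱ schedule is available as
`schedule_kind="cosine"`.

## Backbone

The noise predictor is a U-Net-like stack of row-wise feature
transformation (RFT) blocks: a *shared* linear map applied to every
point's feature row, modulated FiLM-style by `h·(1+scale)+shift` with
scale/shift projected from a sinusoidal timestep embedding (plus a learned
class embedding when conditional), followed by SiLU. Weight sharing makes
a lone RFT block permutation equivariant.

Three additions give the network its correspondence behavior:

* **Correspondence embeddings** — a learned N×z matrix E added row-wise to
  the activations of the deepest encoder level (the level whose width
  equals z, immediately before the bottleneck). This is the only component
  that breaks permutation equivariance; it ties index i to a consistent
  locus, playing the role positional embeddings play in transformers but
  learned, because index order carries no spatial meaning.
  `use_correspondence_embeddings=False` is the ablation model, identical in
  every other respect.
* **Masked self-attention** at the bottleneck — multi-head scaled
  dot-product attention with a residual connection, restricted to a fixed
  (not learned) k-nearest-neighbor graph built from the training mean
  shape (default k = 50; self always allowed; ties broken by lower index).
  Forbidden logits get an additive −1e30 so their weight is exactly 0.
* **Skip connections** — encoder features are concatenated (not added)
  into the mirrored decoder levels.

Default widths are 3→64→128→256 with z = 256 and 4 heads; the desk-scale
profile used throughout the tests is 3→32→64 (z = 64, 4 heads), ~58k
parameters, which trains on one CPU in a couple of minutes. Exact widths,
activation (SiLU) and the injection level are free design choices exposed
in `NetworkConfig`.

**Training.** Adam (lr 2e-3, cosine-decayed to 10%), batch 32–64, uniform
t ~ U{1..T}, fresh Gaussian noise per step; datasets are globally
normalized first (grand-centroid centering, division by the RMS point
norm — one set of parameters for the whole population so correspondence
and relative geometry are untouched; parameters are stored with the
checkpoint and inverted on sampling).

## Synthetic populations

Real PDM cohorts are not redistributable, so all tests run on a synthetic
generator with exact ground truth. The template is an ellipsoid (default
semi-axes 1.0, 0.7, 0.5 — elongated, loosely hippocampus-like) sampled at
N points by a deterministic Fibonacci sphere lattice, giving every index a
fixed direction d_i (correspondence by construction; indices are ordered
by latitude, so a contiguous index range is a contiguous surface band).
Per subject the three semi-axes are scaled by independent log-normals
(`radii_sd = 0.1`, anatomy-scale variation that keeps radii positive); the
affected class receives a signed radial offset `effect_magnitude = −0.3`
(inward = atrophy) on a contiguous patch of N/8 indices; finally isotropic
Gaussian noise `noise_sd = 0.02` is added per point. Default cohort sizes
are 717 healthy / 208 affected, mirroring a typical dementia-cohort
imbalance; desk-scale tests use a few hundred subjects.

Because the class effect is additive along fixed directions, the
difference between class templates is exactly `effect_magnitude · d_i` on
the patch and zero elsewhere — the recorded `ground_truth_effect` against
which group-difference maps and counterfactual displacements are checked.

What the generator does *not* emulate: realistic hippocampal geometry
(curvature, medial structure), correspondence error from an actual
correspondence-optimization pipeline, non-Gaussian segmentation artifacts,
covariance between neighboring landmarks beyond the three global scale
factors. Passing tests therefore demonstrate that the machinery recovers
planted, well-specified structure — not that it matches real-data effect
sizes.

## Evaluation metrics

Pairwise shape distances:

* `L2` — index-wise RMS distance ‖a − b‖_F / √N; order-sensitive by
  design (the correspondence-aware distance).
* `CD` — Chamfer: sum of the two directed means of squared
  nearest-neighbor distances; permutation-invariant.
* `EMD` — mean Euclidean cost of the exact optimal assignment
  (Hungarian algorithm via `scipy.optimize.linear_sum_assignment`);
  permutation-invariant. Ground cost is unsquared Euclidean, mean-reduced.

The L2 normalization (÷√N) puts L2 and EMD on the same per-point scale,
so for a correspondence-preserving generator L2 ≈ EMD, while destroying
index order inflates L2 only. CD uses squared distances (the common
convention); absolute CD values are therefore not comparable across
conventions, and published absolute numbers are not reproduction targets.

Set-level metrics between a real and generated sample: MMD (mean over
real shapes of the distance to the nearest generated shape), and the
k-NN-ball coverage and density (k = 7): each real sample gets a ball whose
radius is the distance to its k-th nearest other real sample (self
excluded, containment uses ≤); coverage is the fraction of balls holding
at least one generated sample, density the total number of containments
divided by k·M. Between two samples of one distribution both approach 1
as sample size grows; the acceptance script measures this calibration at
1000 shapes per side.

Large pairwise Chamfer matrices are computed blockwise in float32 via the
‖a‖² + ‖b‖² − 2ab expansion (one GEMM per block); the ~1e-6 relative
error is negligible at shape-distance scale.

## Downstream analyses

* **Group difference maps**: per-index mean difference between two
  populations, plus its projection on the outward direction from the
  pooled-mean centroid (negative = inward = atrophy; surface normals are
  unavailable without meshes, so the centroid ray is the outward proxy).
* **Classifier**: per-point shared two-layer feature map, mean pooling,
  two-layer head; mean pooling keeps it order-robust on purpose so that
  counterfactual guidance cannot exploit index artifacts.
* **Counterfactual generation**: the original shape is re-noised to
  t₀ = T/4 (partial re-noising preserves subject identity) and denoised
  with the conditional model under the target class. At each step the
  denoised estimate x̂₀ = (x − sqrt(1−ᾱ_t)·ε_θ)/sqrt(ᾱ_t) is nudged by
  (1−ᾱ_t)·guidance_scale·∇ log p(target | x̂₀) (classifier gradient via
  backprop to the input), then pulled toward the original by the *exact
  proximal map* of similarity_weight·‖x − original‖² with step (1−ᾱ_t):
  x̂₀ ← (x̂₀ + λ·original)/(1 + λ), λ = 2·similarity_weight·(1−ᾱ_t).
  The proximal form is stable for arbitrarily large similarity weights
  (weight → ∞ returns the original exactly). The adjusted x̂₀ is converted
  back to an ε estimate and the standard reverse step proceeds. Defaults:
  guidance_scale 1.0, similarity_weight 0.1.
* **Correspondence color maps and score**: deterministic RGB per index
  from the min-max-normalized reference coordinates; the quantitative
  score is the Pearson correlation between flattened per-index mean
  positions of two populations (1.0 = indices at the right loci; a fixed
  index permutation of good samples collapses it).

## Numerical and design choices

* Reverse variance β_t I; final reverse step noiseless.
* Attention mask value −1e30 (not −inf) to avoid NaNs in degenerate rows.
* Normalization scale floor 1e-12 with a warning on degenerate data.
* PCA: SVD on mean-centered flattened shapes; deterministic sign
  convention (largest-magnitude entry of each component positive);
  sampling draws scores with the empirical eigenvalue variances (no
  whitening), so the retained covariance is reproduced exactly in
  expectation.
* `.particles` output uses 9 significant digits; `#` comment lines are
  skipped on read; parse errors name the offending line.
* All randomness flows through `numpy.random.Generator` seeds; training,
  sampling and the CLI are reproducible bit-for-bit on one platform.
* The backbone runs on a small reverse-mode autodiff engine over numpy
  written for this package (float64, tape-based); with the desk-scale
  profile a training step on one CPU takes ~60 ms, so the end-to-end
  tests train real models rather than stubs.

## Known limitations

* The ablation model (no correspondence embeddings) not only loses
  correspondence but also produces poor *unordered* geometry on this task:
  with an exchangeable input and only the fixed index-based attention
  graph to coordinate points, the learned reverse process approximates
  per-point marginal denoising, and sampled clouds do not tighten onto the
  population manifold (EMD-MMD stays ~10x the full model's). Its L2/EMD
  ratio therefore stays near 1; the large-L2-only signature of unordered
  generators appears when good samples are index-shuffled, which the test
  suite demonstrates explicitly.
* Exact EMD is O(N³) per pair; pairwise EMD matrices beyond a few hundred
  shapes of ~100 points become slow.
* Conditional generation and counterfactual guidance are validated on the
  synthetic family only; no claim is made about real hippocampal data.
* No DDIM/accelerated samplers, learned variances, or latent diffusion.
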