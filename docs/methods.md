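# Methods

This note documents the model implemented by `v1sal`, its assumptions, the
parameters that matter, the synthetic data the tests run on, and the
numerical choices made where the design was genuinely open.

## Model overview

The pipeline has four stages:

1. **Color decomposition.** An RGB image (floats in [0, 1]) is expanded
   into 13 single-channel images: NTSC luminance (gray) plus the channels
   of RGB, CIELAB, HSI and YIQ. Each channel is min-max rescaled to [0, 1]
   so that one receptive-field set trained on gray-scale patches can encode
   every channel.
2. **Sparse spike coding.** Patches around every pixel are whitened and
   encoded by a population of K leaky integrate-and-fire neurons; the
   per-pixel code is the vector of spike counts.
3. **Self-information saliency.** Per response dimension, a probability
   model is fitted *on the current image*; pixel saliency is the summed
   self-information of its responses (natural log).
4. **Entropy selection and fusion.** Per color space the sub-map with the
   lowest quantized-histogram entropy is selected; the four winners plus
   the gray sub-map are min-max normalized and summed with weights
   proportional to reciprocal entropies, then the result is normalized to
   [0, 1].

The key assumption in stage 3 is independence of response dimensions,
which holds approximately for sparse codes; self-information is then
additive across dimensions. The rationale for stage 4 is that a useful
saliency map concentrates mass on a small focus, which shows up as low
entropy of its value histogram.

## The spiking network

Dynamics per patch (T steps, leak η, whitened input x):

    u_i(t+1) = (1 − η) u_i(t) + η (Q_i·x − Σ_j W_ij s_j(t))

with spike and reset to 0 when u_i > θ_i. The code is the count vector n.
Learning uses local batch rules with target rate p:

    ΔW_ij ∝ α (⟨n_i n_j⟩ − p²)   (clipped at W ≥ 0, zero diagonal)
    ΔQ_i  ∝ β n_i (x − n_i Q_i)
    Δθ_i  ∝ γ (⟨n_i⟩ − p)

Inhibition decorrelates neuron pairs, the threshold rule enforces the
target rate per neuron, and the Hebbian rule pulls each row of Q toward
the count-weighted input average.

Numerical choices:

* **Preconditioned Hebbian step.** The raw rule's decay term β n² Q makes
  the update stiff once counts exceed one. The implementation uses the
  fixed-point form `Q_i += β (⟨n_i x⟩/⟨n_i²⟩ − Q_i)`, which has the same
  fixed point `Q_i = E[n_i x]/E[n_i²]` and is stable for β < 1.
* **Annealing.** α and β decay by `lr_decay = 0.9` per epoch so the
  stochastic updates settle; γ stays constant so the thresholds keep
  tracking the target rate. Without annealing the dictionary-recovery
  score jitters around a plateau instead of converging.
* **Divergence guard.** Training aborts if any |Q| exceeds 100 in
  whitened units.

### Parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| K (`n_neurons`) | 128 | population size |
| `patch_side` | 14 | patch side, so 196 input dimensions |
| T (`lif_steps`) | 50 | integration steps per patch |
| η (`lif_leak`) | 0.2 | membrane leak per step |
| p (`target_rate`) | 0.05 | spikes per patch per neuron |
| α, β, γ | 0.1, 0.3, 0.05 | learning rates (α is divided by p²) |
| `lr_decay` | 0.9 | per-epoch annealing of α, β |
| epochs × batch | 25 × 200 | training schedule |

The target rate is the load-bearing parameter. p = 0.05 spikes/patch is
the classic sparse regime: most counts are zero, code distributions are
zero-peaked with heavy tails (positive excess kurtosis in ≥ 90% of
dimensions on natural-statistics input), and neurons specialize to single
generative causes. Raising p toward one spike per patch or more forces
neurons to fire on nearly every patch; the codes lose their sparsity and
dictionary recovery collapses (measured: ~30% of atoms recovered at
p = 2.5 versus ~100% at p = 0.05).

### Whitening

Patches are mean-centered and ZCA-whitened; the transform (matrix + mean)
is stored with the trained weights and reused at inference for every
channel, so the code is stationary across inputs. Eigenvalues are floored
at 1e-8 of the largest to bound the transform on ill-conditioned data.
On rank-deficient input (e.g. patches synthesized from a small
dictionary) the floor determines how much pure-noise subspace is
amplified; the dictionary-recovery experiments fit the whitener on the
same data they train on, which is the intended usage.

### Reconstruction and its baseline

A patch is reconstructed as `gain · n @ Q`, un-whitened; a whole image is
the overlap-average of per-pixel patch reconstructions. The scalar gain is
a least-squares fit on a fixed probe set, performed in pixel space.

Training progress is logged as the relative L2 probe reconstruction error,
with entry 0 the error of a *rate-matched* untrained network (random unit
rows Q, thresholds bisected so its mean count equals p). Rate-matching is
essential: an untrained network with θ = 1 fires ~50× more spikes and
reconstructs *better* than the trained sparse code simply because more
spikes carry more linear information. Note also that on Gaussian input
(e.g. the pink-noise surrogates) sparse coding cannot beat a rate-matched
random code at reconstruction — there is no sparse structure to find — so
training-progress claims are evaluated on sparse-dictionary data, where
the improvement is real and large (≈ 0.93 → 0.83 relative error).

## Probability models and saliency

* **Histograms** (default): per dimension, 1000 equal-width bins over that
  image's observed [min, max]; probability `(count + ε)/(n + ε·bins)` with
  add-one smoothing ε = 1 so self-information stays finite. A degenerate
  dimension (min = max) contributes probability 1, i.e. zero
  self-information.
* **Generalized Gaussian** (optional): moment-matched per dimension — β
  solved from the sample kurtosis by bisection on the GGD kurtosis ratio
  Γ(5/β)Γ(1/β)/Γ(3/β)², α from the variance, μ from the mean. Densities
  are multiplied by the histogram bin width so both models live on the
  same probability scale. β = 2 recovers the Gaussian, β = 1 the
  Laplacian; simulation recovery is within 0.3 of both at n = 10⁵.

Probability models are fitted per image and per channel: rarity is defined
by the current scene. Natural logarithm throughout; the base only scales
S and E jointly and cancels in the normalized fusion weights.

### Entropy

A sub-map is min-max normalized and quantized to m = 256 levels by
rounding to `(m−1)·s`; the entropy is the Shannon entropy of the level
histogram. A constant map has entropy 0 by convention; a map hitting all
m levels equally gives exactly log m. This quantity is exactly invariant
to positive affine rescaling (the normalization absorbs it) but not to
arbitrary nonlinear monotone maps, which move values across quantization
levels.

Fusion degeneracies: if any selected sub-map has zero entropy (constant
map), reciprocal weighting is undefined; all weight goes uniformly to the
zero-entropy maps. Ties in the per-space argmin go to the first channel
in the frozen order (gray, R, G, B, L, a, b, H, S, I, Y, Iq, Q).

### Stride

`compute_response_map` accepts a stride; responses are then computed on a
subsampled pixel grid and each self-information sub-map is bilinearly
upsampled to image size before fusion. Upsampling the *saliency* rather
than the response grid keeps the spike counts integral and the histograms
exact. Stride 1 is the default; the tests use stride 2 on 96×96 scenes.

## Evaluation metrics

ROC sweeps thresholds over the unique saliency values with a ≥ call
convention (ties counted together), always including (0,0) and (1,1); AUC
is the trapezoidal area and equals the Mann-Whitney statistic with ties
counted half. CC is the Pearson correlation against a continuous map; NSS
the mean z-scored saliency at fixated pixels. Continuous ground truths are
binarized at > 0 for ROC/NSS unless a threshold is supplied. Degenerate
cases (single-class ground truth, constant map for CC/NSS) raise errors
rather than returning silent placeholders.

## Synthetic data

The generators define the study conditions; all are pure functions of
their parameters and a seed.

* **Pink noise** (`make_pink_noise_images`): Gaussian white noise shaped
  to a 1/f amplitude spectrum (exponent 1 by default), the canonical
  second-order statistics of natural scenes. What it does *not* emulate:
  natural images' sparse, non-Gaussian structure (edges, contours). Hence
  trained receptive fields on this surrogate are less cleanly Gabor-like
  than on photographs, and reconstruction gains over a rate-matched random
  code are absent by construction. A directory of real photographs can be
  substituted via `v1sal train --images DIR`.
* **Pop-out scenes** (`make_popout_scene`): a base-color background with
  shared pink-noise luminance texture and one disk target (6% of the image
  area by default) whose color is displaced toward a distinct hue by a
  contrast parameter; contrast 0 is the no-signal control. The mask marks
  the target exactly. These scenes test feature pop-out only — no
  objectness, occlusion or center bias.
* **Sparse dictionary** (`make_sparse_patch_set`): 64 random Gabor atoms
  (unit norm) on 10×10 patches; each patch combines exactly 4 atoms with
  Laplacian coefficients plus Gaussian pixel noise (σ = 0.02). Used for
  the dictionary-recovery check: learned fields are matched to atoms by
  Hungarian assignment on |correlation| (sign-blind, since rectified
  neurons specialize per sign; the 2× overcomplete default K = 128 gives
  the population room to cover both signs).

Passing tests on these fixtures show that the mechanism works where its
assumptions hold; they do not certify benchmark performance on
photographic datasets, which depends on training data and parameters not
exercised here.

## Problem sizes used by the tests and acceptance script

Training runs use 20,000 patches (15 epochs for the pink-noise network,
25 for dictionary recovery); saliency experiments use 20 pop-out scenes
at 96×96 with stride 2 plus 5 zero-contrast controls. These sizes give
stable statistics (recovery and pop-out AUC vary by a few percent across
seeds) while keeping a full run in the minutes range on one CPU.

## Known limitations

* The single-population network with symmetric inhibition is the simplest
  mechanism that yields sparse codes and Gabor-like fields; a two-
  population excitatory/inhibitory variant is a possible extension and
  would change no downstream interface.
* Per-image histograms make saliency scene-relative; a cross-image
  ensemble model is not implemented.
* No center-bias term, top-down priors, or object-level grouping; scores
  on fixation datasets that reward center bias will underrate the model.
* Color channels are encoded with the gray-trained whitener and weights;
  channels whose statistics differ strongly from luminance (e.g. hue) are
  therefore encoded in a mismatched basis. This mirrors the design it
  implements but is a real approximation.
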