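# v1sal

Bottom-up visual saliency from the self-information of V1-like sparse
spike codes, with entropy-weighted fusion across four color spaces.

## The problem

Bottom-up visual attention selects image regions that differ from their
context before any task knowledge is applied. `v1sal` implements a
biologically grounded saliency model built on three ideas:

1. **Sparse spike coding.** A population of K leaky integrate-and-fire
   neurons with feedforward weights Q (the receptive fields), non-negative
   lateral inhibition W and adaptive thresholds θ encodes whitened image
   patches into spike counts. The weights are learned with purely local
   plasticity rules, so on natural-statistics input the receptive fields
   become localized and oriented (Gabor-like) and the spike-count
   distributions become zero-peaked and heavy-tailed.
2. **Saliency as self-information.** With per-dimension probability models
   p_k estimated from the current image (1000-bin histograms by default, a
   moment-matched generalized Gaussian as an alternative), the saliency of
   a pixel is the summed self-information of its responses:

       S(x, y) = Σ_k  −log p_k( r_k(x, y) )

   Rare responses — produced by regions unlike the rest of the scene —
   yield high saliency.
3. **Entropy-based fusion.** One saliency sub-map is computed for the
   gray-scale image and for each channel of RGB, CIELAB, HSI and YIQ
   (13 in all). Within each color space the sub-map with the lowest
   quantized-histogram entropy — the most concentrated focus — is selected,
   and the four winners plus the gray sub-map are combined with weights
   O_j = (1/E_j) / Σ_i (1/E_i).

Evaluation against ground-truth masks or fixation maps uses the standard
scores: ROC/AUC (threshold sweep with ties counted together; 1 = perfect,
0.5 = chance), Pearson CC, and NSS (mean z-scored saliency at fixations).

## Worked example

```python
import numpy as np
from v1sal import (SparseCodingModel, TrainingConfig, sample_patches,
                   make_pink_noise_images, make_popout_scene,
                   compute_saliency, evaluate)

# 1. learn receptive fields from 20k whitened 14x14 patches
images = make_pink_noise_images(n=20, size=128, seed=0)
patches = sample_patches(images, 20_000, side=14, seed=0)
results = SparseCodingModel(patches, TrainingConfig(seed=0, n_epochs=15)).fit()
print(results.summary())

# 2. saliency of a color pop-out scene with known target mask
rf = results.receptive_fields
scene, mask = make_popout_scene(seed=3)
sal = compute_saliency(scene, rf, stride=2)
print("selected channels:", sal.combination.channels)
print("fusion weights:   ", np.round(sal.combination.weights, 3))
scores = evaluate(sal.saliency, mask.astype(float))
print(f"AUC = {scores.auc:.3f}   CC = {scores.cc:.3f}   NSS = {scores.nss:.3f}")
```

Output:

```
Sparse-coding network fit
======================================================
neurons (K)                       128
patch side / dim                  14 / 196
LIF steps / leak                  50 / 0.2
target rate p (spikes/patch)      0.05
epochs x batch                    15 x 200
final mean rate                   0.0373
final rel. recon error            0.2553
reconstruction gain               0.3695
mean threshold                    2.3552
mean lateral weight               28.30540

selected channels: ['gray', 'R', 'b', 'S', 'Iq']
fusion weights:    [0.061 0.241 0.234 0.237 0.226]
AUC = 0.940   CC = 0.566   NSS = 2.239
```

The network fires ~0.04 spikes per patch per neuron (the sparse regime),
reconstructs a held-out image to a relative error of 0.26, and the fused
map ranks the pop-out target above the background almost perfectly
(AUC 0.94). The entropy selection picked the red-green-sensitive channels
(R, CIELAB b, HSI S, YIQ I) that isolate the red target.

The same pipeline is available from the shell:

```bash
v1sal train --out rf.npz                       # pink-noise surrogate training
v1sal fixtures --kind popout --n 5 --out fx/   # synthetic scenes + masks
v1sal saliency --image fx/popout_000.png --weights rf.npz \
      --out map.png --out-npz map.npz
v1sal evaluate --map map.npz --truth fx/popout_000_mask.png
```

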