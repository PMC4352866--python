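"""Synthetic inputs for training, testing and desk-scale experiments.

Three generators, all pure functions of their parameters and seed:

* pink-noise images — gray-scale surrogates for natural photographs, with
  the approximately 1/f amplitude spectrum that drives whitening and
  sparse-coding behaviour;
* pop-out scenes — a textured background with one region of distinct color,
  plus the exact binary mask of that region, for end-to-end saliency
  evaluation with known ground truth;
* sparse-dictionary patch sets — patches synthesized as sparse combinations
  of known Gabor atoms, for dictionary-recovery checks on the learner.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "make_pink_noise_images",
    "make_popout_scene",
    "make_sparse_patch_set",
    "make_gabor_dictionary",
    "dictionary_recovery",
]


def make_pink_noise_images(
    n: int = 10,
    size: int = 128,
    exponent: float = 1.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Gray-scale noise images with amplitude spectrum ~ 1/f**exponent.

    White Gaussian noise is shaped in the frequency domain (the DC gain is
    zero), inverse-transformed and min-max normalized to [0, 1].
    ``exponent = 0`` gives flat-spectrum white noise, ``exponent = 1`` the
    natural-image-like pink spectrum.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    gain = np.zeros_like(f)
    nz = f > 0
    gain[nz] = 1.0 / f[nz] ** exponent
    images = []
    for _ in range(n):
        spectrum = np.fft.fft2(rng.standard_normal((size, size))) * gain
        img = np.real(np.fft.ifft2(spectrum))
        lo, hi = img.min(), img.max()
        images.append((img - lo) / (hi - lo))
    return images


def make_popout_scene(
    size: int = 96,
    target_fraction: float = 0.06,
    contrast: float = 1.0,
    texture_amplitude: float = 0.08,
    background_rgb: tuple[float, float, float] = (0.35, 0.45, 0.35),
    target_rgb: tuple[float, float, float] = (0.75, 0.25, 0.25),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A color pop-out scene and the exact binary mask of its target.

    The background is a base color modulated by shared pink-noise luminance
    texture; the target is a disk whose color is moved from the background
    color toward ``target_rgb`` by ``contrast`` (0 = identical to the
    background: the no-signal control).  Returns (rgb image in [0, 1],
    boolean mask).
    """
    rng = np.random.default_rng(seed)
    texture = make_pink_noise_images(1, size, exponent=1.0, seed=rng.integers(2**31))[0]
    texture = (texture - 0.5) * 2.0 * texture_amplitude

    radius = np.sqrt(target_fraction * size * size / np.pi)
    margin = int(np.ceil(radius)) + 2
    cy = rng.integers(margin, size - margin)
    cx = rng.integers(margin, size - margin)
    yy, xx = np.mgrid[:size, :size]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2

    bg = np.asarray(background_rgb)
    tg = bg + contrast * (np.asarray(target_rgb) - bg)
    img = np.where(mask[..., None], tg, bg) + texture[..., None]
    return np.clip(img, 0.0, 1.0), mask


def make_gabor_dictionary(
    n_atoms: int, side: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Unit-norm dictionary of randomly parameterized Gabor atoms, (K, side^2)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    yy, xx = np.mgrid[:side, :side] - (side - 1) / 2.0
    atoms = np.empty((n_atoms, side * side))
    for k in range(n_atoms):
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(1.0, 2.5) / side      # cycles per pixel
        phase = rng.uniform(0, 2 * np.pi)
        sigma = rng.uniform(0.15, 0.3) * side
        cy, cx = rng.uniform(-side / 5, side / 5, size=2)
        xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        env = np.exp(-(xr ** 2 + (0.6 * yr) ** 2) / (2 * sigma ** 2))
        atom = env * np.cos(2 * np.pi * freq * xr + phase)
        atom -= atom.mean()
        atoms[k] = atom.ravel() / np.linalg.norm(atom)
    return atoms


def make_sparse_patch_set(
    n_patches: int = 20_000,
    n_atoms: int = 64,
    side: int = 10,
    sparsity: int = 4,
    noise_sigma: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Patches synthesized from a known sparse dictionary, plus the dictionary.

    Each patch is a combination of exactly ``sparsity`` atoms with Laplacian
    coefficients plus Gaussian pixel noise of scale ``noise_sigma``:
    x = c . D + noise.  Returns (patch matrix (n, side^2), dictionary
    (n_atoms, side^2)).
    """
    rng = np.random.default_rng(seed)
    D = make_gabor_dictionary(n_atoms, side, rng)
    coeffs = np.zeros((n_patches, n_atoms))
    for i in range(n_patches):
        support = rng.choice(n_atoms, size=sparsity, replace=False)
        coeffs[i, support] = rng.laplace(scale=1.0, size=sparsity)
    patches = coeffs @ D
    if noise_sigma > 0:
        patches += rng.normal(scale=noise_sigma, size=patches.shape)
    return patches, D


def dictionary_recovery(learned: np.ndarray, dictionary: np.ndarray) -> np.ndarray:
    """Best one-to-one |correlation| match of dictionary atoms to learned fields.

    Rows of both arrays are vectorized patches.  Each true atom is assigned a
    distinct learned field by Hungarian matching on absolute Pearson
    correlation (sign-blind: a field tuned to -atom counts as recovered).
    Returns the matched |correlation| per atom, shape (n_atoms,).
    """
    from scipy.optimize import linear_sum_assignment

    A = learned - learned.mean(axis=1, keepdims=True)
    B = dictionary - dictionary.mean(axis=1, keepdims=True)
    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    B = B / np.linalg.norm(B, axis=1, keepdims=True)
    C = np.abs(B @ A.T)  # atoms x learned
    rows, cols = linear_sum_assignment(-C)
    return C[rows, cols]
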