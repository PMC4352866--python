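"""Self-information saliency and entropy-based sub-map fusion.

Rare neuron responses mark salient locations: for each response dimension k
a probability model p_k is estimated from the current image, and the
saliency of a pixel is the summed self-information of its responses,

    S(x, y) = sum_k  -log p_k( r_k(x, y) )

(natural log; the dimensions are treated as independent, which holds
approximately for sparse codes).  One saliency sub-map is computed for the
gray-scale image and for each of the twelve color channels.  Within each
color space the sub-map with the lowest entropy — the most concentrated
focus against a suppressed background — is selected, and the four winners
plus the gray sub-map are combined linearly with weights proportional to
the reciprocals of their entropies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, zoom
from scipy.optimize import brentq
from scipy.special import gammaln

from .colorspace import CHANNEL_ORDER, SPACE_GROUPS, normalize01, split_channels
from .sparse_net import ReceptiveFieldSet, compute_response_map

__all__ = [
    "HistogramModel",
    "GGDModel",
    "fit_histogram_model",
    "fit_ggd_model",
    "self_information_map",
    "map_entropy",
    "select_and_combine",
    "compute_saliency",
    "SaliencyResult",
]


# ---------------------------------------------------------------------------
# probability models over per-dimension responses
# ---------------------------------------------------------------------------

class HistogramModel:
    """Per-dimension histogram estimator of response probabilities.

    Each dimension gets equal-width bins spanning that dimension's observed
    [min, max]; a degenerate dimension (min == max) collapses to a single
    bin with probability 1.  Additive smoothing eps bounds self-information:
    p = (count + eps) / (n + eps * bins).
    """

    def __init__(self, responses: np.ndarray, bins: int = 1000, eps: float = 1.0):
        if bins < 1:
            raise ValueError("bins must be >= 1")
        R = responses.reshape(-1, responses.shape[-1]).astype(np.float64)
        if R.size == 0:
            raise ValueError("empty response map")
        self.bins = bins
        self.eps = float(eps)
        self.n_total = R.shape[0]
        self.n_dims = R.shape[1]
        self.lo = R.min(axis=0)
        self.hi = R.max(axis=0)
        self.degenerate = self.hi <= self.lo
        width = np.where(self.degenerate, 1.0, (self.hi - self.lo) / bins)
        self.width = width
        idx = self._bin_index(R)
        self.counts = np.zeros((self.n_dims, bins), dtype=np.int64)
        for k in range(self.n_dims):
            np.add.at(self.counts[k], idx[:, k], 1)

    def _bin_index(self, R: np.ndarray) -> np.ndarray:
        rel = (R - self.lo) / (self.width * np.where(self.degenerate, np.inf, 1.0))
        idx = np.floor(rel).astype(np.int64)
        return np.clip(idx, 0, self.bins - 1)

    def prob(self, R: np.ndarray) -> np.ndarray:
        """Probability of each response value, shape like the input (n, K)."""
        R = np.atleast_2d(np.asarray(R, dtype=np.float64))
        if R.shape[-1] != self.n_dims:
            raise ValueError(f"dimension mismatch: {R.shape[-1]} != {self.n_dims}")
        idx = self._bin_index(R)
        c = self.counts[np.arange(self.n_dims)[None, :], idx]
        p = (c + self.eps) / (self.n_total + self.eps * self.bins)
        # degenerate dimensions carry no information: p = 1 exactly
        return np.where(self.degenerate, 1.0, p)


def _ggd_kurtosis(beta: float) -> float:
    # kurtosis of the generalized Gaussian: G(5/b) G(1/b) / G(3/b)^2
    return float(np.exp(gammaln(5.0 / beta) + gammaln(1.0 / beta) - 2.0 * gammaln(3.0 / beta)))


class GGDModel:
    """Generalized Gaussian fit per dimension by moment matching.

    density f(x) = beta / (2 alpha G(1/beta)) exp(-(|x - mu| / alpha)^beta);
    the shape beta is solved from the sample kurtosis (beta = 2 recovers the
    Gaussian, beta = 1 the Laplacian) and the scale alpha from the variance.
    Probabilities are density * histogram-bin width so they are comparable
    with :class:`HistogramModel` values; zero-variance dimensions fall back
    to the degenerate-histogram rule (p = 1).
    """

    def __init__(self, responses: np.ndarray, bins: int = 1000):
        R = responses.reshape(-1, responses.shape[-1]).astype(np.float64)
        self.n_dims = R.shape[1]
        self.mu = R.mean(axis=0)
        var = R.var(axis=0)
        self.degenerate = var <= 0
        lo, hi = R.min(axis=0), R.max(axis=0)
        self.width = np.where(self.degenerate, 1.0, (hi - lo) / bins)

        kurt = np.full(self.n_dims, 3.0)
        ok = ~self.degenerate
        centered = R - self.mu
        m2 = var
        m4 = (centered ** 4).mean(axis=0)
        kurt[ok] = m4[ok] / m2[ok] ** 2

        self.beta = np.empty(self.n_dims)
        self.alpha = np.empty(self.n_dims)
        for k in range(self.n_dims):
            if self.degenerate[k]:
                self.beta[k], self.alpha[k] = 2.0, 1.0
                continue
            self.beta[k] = self._solve_beta(kurt[k])
            b = self.beta[k]
            # var = alpha^2 G(3/b) / G(1/b)
            self.alpha[k] = np.sqrt(
                var[k] * np.exp(gammaln(1.0 / b) - gammaln(3.0 / b))
            )

    @staticmethod
    def _solve_beta(kurt: float, lo: float = 0.1, hi: float = 20.0) -> float:
        kurt = float(np.clip(kurt, _ggd_kurtosis(hi) + 1e-9, _ggd_kurtosis(lo) - 1e-9))
        return brentq(lambda b: _ggd_kurtosis(b) - kurt, lo, hi)

    def prob(self, R: np.ndarray) -> np.ndarray:
        R = np.atleast_2d(np.asarray(R, dtype=np.float64))
        if R.shape[-1] != self.n_dims:
            raise ValueError(f"dimension mismatch: {R.shape[-1]} != {self.n_dims}")
        z = np.abs(R - self.mu) / self.alpha
        log_norm = (
            np.log(self.beta) - np.log(2.0 * self.alpha) - gammaln(1.0 / self.beta)
        )
        dens = np.exp(log_norm - z ** self.beta)
        p = np.clip(dens * self.width, 1e-300, 1.0)
        return np.where(self.degenerate, 1.0, p)


def fit_histogram_model(
    response_map: np.ndarray, bins: int = 1000, eps: float = 1.0
) -> HistogramModel:
    """Histogram probability model over a (H, W, K) or (n, K) response array."""
    return HistogramModel(response_map, bins=bins, eps=eps)


def fit_ggd_model(response_map: np.ndarray, bins: int = 1000) -> GGDModel:
    """Moment-matched generalized-Gaussian model per response dimension."""
    return GGDModel(response_map, bins=bins)


# ---------------------------------------------------------------------------
# saliency maps
# ---------------------------------------------------------------------------

def self_information_map(
    response_map: np.ndarray, model: HistogramModel | GGDModel
) -> np.ndarray:
    """S(x, y) = sum_k -log p_k(r_k(x, y)); non-negative, finite everywhere."""
    h, w, K = response_map.shape
    p = model.prob(response_map.reshape(h * w, K))
    return (-np.log(p)).sum(axis=1).reshape(h, w)


def map_entropy(saliency_map: np.ndarray, m: int = 256) -> float:
    """Shannon entropy (nats) of the m-level quantized saliency histogram.

    The map is min-max normalized before quantization, so the entropy is
    invariant to monotone affine rescaling; a constant map has entropy 0.
    """
    sm = np.asarray(saliency_map, dtype=np.float64)
    lo, hi = sm.min(), sm.max()
    if hi - lo < 1e-12:
        return 0.0
    # rounding to m-1 maps m equally spaced values onto the m levels exactly
    levels = np.rint((sm - lo) / (hi - lo) * (m - 1)).astype(np.int64)
    counts = np.bincount(levels.ravel(), minlength=m)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# selection and fusion
# ---------------------------------------------------------------------------

@dataclass
class CombinationWeights:
    channels: list[str]          # gray + one winner per color space
    entropies: np.ndarray        # entropy of each combined sub-map
    weights: np.ndarray          # normalized, sum to 1


def _reciprocal_weights(entropies: np.ndarray) -> np.ndarray:
    entropies = np.asarray(entropies, dtype=np.float64)
    zero = entropies <= 0
    if zero.any():
        # a zero-entropy (constant) map would get infinite weight; put all
        # weight uniformly on the zero-entropy maps
        w = zero.astype(np.float64)
    else:
        w = 1.0 / entropies
    return w / w.sum()


def select_and_combine(
    sub_maps: dict[str, np.ndarray], m: int = 256
) -> tuple[np.ndarray, CombinationWeights]:
    """Entropy-based selection and reciprocal-entropy fusion.

    ``sub_maps`` maps channel name -> saliency sub-map and must contain the
    gray channel plus the three channels of each color space.  Within each
    space the sub-map with minimal entropy wins (ties go to the first
    channel in the frozen order); the four winners and the gray map are
    min-max normalized and summed with weights O_j = (1/E_j) / sum_i (1/E_i).
    The fused map is min-max normalized to [0, 1].
    """
    shapes = {v.shape for v in sub_maps.values()}
    if len(shapes) != 1:
        raise ValueError(f"sub-maps have mismatched shapes: {shapes}")
    entropy = {name: map_entropy(sm, m=m) for name, sm in sub_maps.items()}

    selected = ["gray"]
    for space, group in SPACE_GROUPS.items():
        # min() is stable: a tie goes to the first channel in the frozen order
        winner = min(group, key=lambda ch: entropy[ch])
        selected.append(winner)

    ents = np.array([entropy[ch] for ch in selected])
    weights = _reciprocal_weights(ents)
    fused = np.zeros(next(iter(shapes)))
    for w, ch in zip(weights, selected):
        fused += w * normalize01(sub_maps[ch])
    info = CombinationWeights(channels=selected, entropies=ents, weights=weights)
    return normalize01(fused), info


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class SaliencyResult:
    """Final map plus the per-channel bookkeeping of the fusion stage."""

    saliency: np.ndarray
    sub_maps: dict[str, np.ndarray]
    entropies: dict[str, float]
    combination: CombinationWeights


def compute_saliency(
    img: np.ndarray,
    rf: ReceptiveFieldSet,
    bins: int = 1000,
    eps: float = 1.0,
    prob_model: str = "hist",
    stride: int = 1,
    m: int = 256,
    smooth_sigma: float = 0.0,
) -> SaliencyResult:
    """Full pipeline: channels -> responses -> self-information -> fusion.

    When ``stride > 1`` the responses are computed on a subsampled pixel
    grid and each sub-map is bilinearly upsampled to the image size before
    fusion (the probability model always sees the raw integer counts).
    Deterministic given (img, rf, parameters).
    """
    channels = split_channels(img)
    h, w = img.shape[:2]
    sub_maps: dict[str, np.ndarray] = {}
    for name in CHANNEL_ORDER:
        rm = compute_response_map(channels[name], rf, stride=stride)
        if prob_model == "hist":
            model = fit_histogram_model(rm, bins=bins, eps=eps)
        elif prob_model == "ggd":
            model = fit_ggd_model(rm, bins=bins)
        else:
            raise ValueError(f"unknown prob_model {prob_model!r}")
        sm = self_information_map(rm, model)
        if stride > 1:
            sm = zoom(sm, (h / sm.shape[0], w / sm.shape[1]), order=1)
            sm = sm[:h, :w]
        sub_maps[name] = sm
    fused, info = select_and_combine(sub_maps, m=m)
    if smooth_sigma > 0:
        fused = normalize01(gaussian_filter(fused, smooth_sigma))
    entropies = {name: map_entropy(sm, m=m) for name, sm in sub_maps.items()}
    return SaliencyResult(fused, sub_maps, entropies, info)
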