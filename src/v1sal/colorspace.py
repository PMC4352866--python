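"""Color-space decomposition of RGB images.

An input RGB image (floats in [0, 1]) is expanded into thirteen
single-channel images: the gray-scale (NTSC luminance) image plus the
three channels of each of RGB, CIELAB, HSI and YIQ.  Saliency is later
computed independently per channel, so every channel is min-max rescaled
to [0, 1] before it reaches the encoder — one receptive-field set trained
on gray-scale patches then serves all channels.

Conventions
-----------
* RGB values are used linearly (no gamma decoding) by default; pass
  ``linearize=True`` to apply the sRGB electro-optical transfer function
  before the XYZ matrix.
* The RGB->XYZ matrix uses sRGB primaries with its rows rescaled so that
  RGB white maps exactly onto the D65 whitepoint (95.04, 100.00, 108.89).
* YIQ uses the NTSC matrix whose luminance row is (0.299, 0.587, 0.114);
  the gray-scale image is that same luminance, so gray == Y exactly.
* Hue is undefined for achromatic pixels (S = 0); it is set to 0 there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColorConstants",
    "CHANNEL_ORDER",
    "rgb_to_gray",
    "rgb_to_lab",
    "rgb_to_hsi",
    "rgb_to_yiq",
    "split_channels",
    "validate_rgb",
    "normalize01",
]

# Frozen channel order; part of the on-disk contract for cached artifacts.
CHANNEL_ORDER: tuple[str, ...] = (
    "gray",
    "R", "G", "B",
    "L", "a", "b",
    "H", "S", "I",
    "Y", "Iq", "Q",
)

# Channels grouped by color space, used by the entropy-based selection.
SPACE_GROUPS: dict[str, tuple[str, str, str]] = {
    "RGB": ("R", "G", "B"),
    "CIELAB": ("L", "a", "b"),
    "HSI": ("H", "S", "I"),
    "YIQ": ("Y", "Iq", "Q"),
}

_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

_YIQ = np.array(
    [
        [0.299, 0.587, 0.114],
        [0.595716, -0.274453, -0.321263],
        [0.211456, -0.522591, 0.311135],
    ]
)


def _xyz_matrix(whitepoint: tuple[float, float, float]) -> np.ndarray:
    """sRGB-primaries matrix with rows rescaled so white -> whitepoint."""
    m = _SRGB_TO_XYZ.copy()
    row_sums = m.sum(axis=1)
    return m * (np.asarray(whitepoint) / row_sums)[:, None]


@dataclass(frozen=True)
class ColorConstants:
    """Numerical constants of the color conversions.

    ``whitepoint`` is the D65 reference white in the 0-100 XYZ scale;
    ``lab_f_threshold`` is the (6/29)^3 breakpoint of the CIELAB
    cube-root function below which the linear segment applies.
    """

    whitepoint: tuple[float, float, float] = (95.04, 100.00, 108.89)
    lab_f_threshold: float = (6.0 / 29.0) ** 3
    linearize: bool = False
    rgb_to_xyz_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]
    yiq_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.rgb_to_xyz_matrix is None:
            object.__setattr__(self, "rgb_to_xyz_matrix", _xyz_matrix(self.whitepoint))
        if self.yiq_matrix is None:
            object.__setattr__(self, "yiq_matrix", _YIQ.copy())


DEFAULT_CONSTANTS = ColorConstants()


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check an (H, W, 3) float RGB image in [0, 1]; returns float64 view."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("RGB image contains non-finite values")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("RGB values must lie in [0, 1]")
    return np.clip(img, 0.0, 1.0)


def _srgb_decode(v: np.ndarray) -> np.ndarray:
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """NTSC luminance: 0.299 R + 0.587 G + 0.114 B (identical to YIQ's Y)."""
    img = validate_rgb(img)
    return img @ _YIQ[0]


def rgb_to_lab(
    img: np.ndarray, constants: ColorConstants = DEFAULT_CONSTANTS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RGB -> XYZ (linear matrix) -> CIELAB with D65 whitepoint.

    Returns (L, a, b); L in [0, 100], a and b signed chroma axes.
    """
    img = validate_rgb(img)
    rgb = _srgb_decode(img) if constants.linearize else img
    xyz = rgb @ constants.rgb_to_xyz_matrix.T
    ratios = xyz / np.asarray(constants.whitepoint)

    delta3 = constants.lab_f_threshold
    delta = delta3 ** (1.0 / 3.0)
    f = np.where(
        ratios > delta3,
        np.cbrt(ratios),
        ratios / (3.0 * delta * delta) + 4.0 / 29.0,
    )
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return L, a, b


def rgb_to_hsi(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RGB -> HSI; H rescaled to [0, 1], with H = 0 wherever S = 0."""
    img = validate_rgb(img)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]

    intensity = (r + g + b) / 3.0
    mn = np.minimum(np.minimum(r, g), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(intensity > 0, 1.0 - mn / np.maximum(intensity, 1e-300), 0.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    cosang = np.where(den > 0, num / np.maximum(den, 1e-300), 1.0)
    theta = np.arccos(np.clip(cosang, -1.0, 1.0))  # radians in [0, pi]
    hue = np.where(b > g, 2.0 * np.pi - theta, theta) / (2.0 * np.pi)
    hue = np.where(sat <= 0, 0.0, hue)
    return hue, sat, intensity


def rgb_to_yiq(
    img: np.ndarray, constants: ColorConstants = DEFAULT_CONSTANTS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NTSC YIQ: Y is luminance, I/Q the in-phase and quadrature chroma."""
    img = validate_rgb(img)
    yiq = img @ constants.yiq_matrix.T
    return yiq[..., 0], yiq[..., 1], yiq[..., 2]


def yiq_to_rgb(
    y: np.ndarray, i: np.ndarray, q: np.ndarray,
    constants: ColorConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    inv = np.linalg.inv(constants.yiq_matrix)
    return np.stack([y, i, q], axis=-1) @ inv.T


def normalize01(arr: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Min-max rescale to [0, 1]; a (near-)constant array maps to zeros."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi - lo < eps:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def split_channels(
    img: np.ndarray, constants: ColorConstants = DEFAULT_CONSTANTS
) -> dict[str, np.ndarray]:
    """All 13 single-channel images, each min-max normalized to [0, 1].

    Keys follow :data:`CHANNEL_ORDER`: gray, R, G, B, L, a, b, H, S, I,
    Y, Iq, Q ("Iq" is the YIQ in-phase channel, distinct from HSI's "I").
    """
    img = validate_rgb(img)
    L, a, b = rgb_to_lab(img, constants)
    H, S, I = rgb_to_hsi(img)
    Y, Iq, Q = rgb_to_yiq(img, constants)
    raw = {
        "gray": rgb_to_gray(img),
        "R": img[..., 0], "G": img[..., 1], "B": img[..., 2],
        "L": L, "a": a, "b": b,
        "H": H, "S": S, "I": I,
        "Y": Y, "Iq": Iq, "Q": Q,
    }
    return {name: normalize01(raw[name]) for name in CHANNEL_ORDER}
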