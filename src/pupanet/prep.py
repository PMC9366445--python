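"""Standardized preparation of specimen images for the contrast network.

The fixed processing chain is: chromatic-adaptation grayscale conversion
(colour sources only) -> percentile exposure normalization -> crop to the
specimen and recentre on a square pure-white frame -> area-average
step-down to the network input resolution (28x28 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .synthetic import SpecimenImage

__all__ = [
    "von_kries_grayscale",
    "normalize_exposure",
    "crop_and_frame",
    "step_down",
    "prepare_image",
    "prepare_set",
    "PrepParams",
]


class EmptySpecimenError(ValueError):
    """Raised when an image contains no non-background pixels."""


# CIE XYZ white points (Y = 1) of the supported adopted whites.
_WHITE_POINTS = {
    "D65": (0.95047, 1.00000, 1.08883),
    "D50": (0.96422, 1.00000, 0.82521),
    "A": (1.09850, 1.00000, 0.35585),
    "E": (1.00000, 1.00000, 1.00000),
}

# sRGB (linear) -> XYZ, D65 reference white
_M_RGB2XYZ = np.array([
    [0.4124564, 0.3575761, 0.1804375],
    [0.2126729, 0.7151522, 0.0721750],
    [0.0193339, 0.1191920, 0.9503041],
])

# Bradford cone-response matrix (XYZ -> LMS)
_M_BRADFORD = np.array([
    [0.8951, 0.2664, -0.1614],
    [-0.7502, 1.7135, 0.0367],
    [0.0389, -0.0685, 1.0296],
])


def _srgb_linearize(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _srgb_encode(c: np.ndarray) -> np.ndarray:
    c = np.clip(c, 0.0, 1.0)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1 / 2.4) - 0.055)


def von_kries_grayscale(rgb_image: np.ndarray, white_point: str = "D65") -> np.ndarray:
    """Convert an RGB image to grayscale via Von Kries chromatic adaptation.

    The image is linearized, mapped to Bradford cone responses, the cone
    responses are rescaled from the source white (sRGB's D65) to the adopted
    white point, and the adapted luminance channel is gamma-encoded back to
    [0, 1].  For achromatic pixels under the default D65 white the transform
    is an identity up to the linearization round trip.
    """
    rgb_image = np.asarray(rgb_image, dtype=float)
    if rgb_image.ndim != 3 or rgb_image.shape[2] != 3:
        raise ValueError(
            f"expected an HxWx3 RGB image, got shape {rgb_image.shape}"
        )
    if white_point not in _WHITE_POINTS:
        raise ValueError(
            f"unknown white point {white_point!r}; choose from {sorted(_WHITE_POINTS)}"
        )
    if rgb_image.max() > 1.5:
        rgb_image = rgb_image / 255.0

    lin = _srgb_linearize(np.clip(rgb_image, 0.0, 1.0))
    xyz = lin @ _M_RGB2XYZ.T

    lms = xyz @ _M_BRADFORD.T
    src_white = np.array(_WHITE_POINTS["D65"]) @ _M_BRADFORD.T
    dst_white = np.array(_WHITE_POINTS[white_point]) @ _M_BRADFORD.T
    lms_adapted = lms * (dst_white / src_white)

    xyz_adapted = lms_adapted @ np.linalg.inv(_M_BRADFORD).T
    y = xyz_adapted[..., 1]
    return _srgb_encode(y / _WHITE_POINTS[white_point][1])


def normalize_exposure(img: np.ndarray, low_pct: float = 1.0,
                       high_pct: float = 99.0) -> np.ndarray:
    """Linear exposure stretch mapping the ``low_pct`` percentile to 0 and
    the ``high_pct`` percentile to 1, clipped to [0, 1].

    Constant images are returned unchanged with a warning (no division by
    zero).  This is the automated surrogate for manual brightness/contrast
    editing of the source photomicrographs.
    """
    if not low_pct < high_pct:
        raise ValueError(f"low_pct ({low_pct}) must be < high_pct ({high_pct})")
    img = np.asarray(img, dtype=float)
    lo, hi = np.percentile(img, [low_pct, high_pct])
    if hi - lo < 1e-12:
        warnings.warn("constant image: exposure normalization skipped")
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def crop_and_frame(img: np.ndarray, background_threshold: float = 0.98) -> np.ndarray:
    """Crop to the tight bounding box of non-background pixels and centre the
    specimen on a square pure-white frame whose side is the larger box
    dimension."""
    img = np.asarray(img, dtype=float)
    mask = img < background_threshold
    if not mask.any():
        raise EmptySpecimenError("image contains no non-background pixels")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    box = img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    h, w = box.shape
    side = max(h, w)
    r0, c0 = (side - h) // 2, (side - w) // 2
    if (img.shape[0] == img.shape[1] == side
            and abs(rows[0] - r0) <= 1 and abs(cols[0] - c0) <= 1):
        # content already spans a square frame and is centred to within the
        # 1-px rasterization limit: recentring would only jitter the raster
        return img.copy()
    frame = np.ones((side, side), dtype=float)
    frame[r0:r0 + h, c0:c0 + w] = box
    return frame


def _area_weights(n_in: int, n_out: int) -> np.ndarray:
    """Weight matrix of exact area-average resampling on one axis.

    Row j holds the fractional overlap of output cell j (width n_in/n_out in
    input pixels) with each input pixel, normalized to sum to 1.
    """
    w = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for j in range(n_out):
        lo, hi = j * scale, (j + 1) * scale
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        for i in range(i0, min(i1, n_in)):
            w[j, i] = min(hi, i + 1) - max(lo, i)
    return w / scale


def step_down(img: np.ndarray, target: int = 28, method: str = "area") -> np.ndarray:
    """Resample a prepared image down to ``target`` x ``target`` pixels.

    ``method="area"`` (default) uses exact area averaging, which preserves
    the image mean; ``"bilinear"`` is available as an alternative kernel.
    Upscaling is refused: sources are assumed to be at least target-sized.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if min(img.shape) < target:
        raise ValueError(
            f"source {img.shape} smaller than target {target}x{target}: upscaling unsupported"
        )
    if method == "area":
        wr = _area_weights(img.shape[0], target)
        wc = _area_weights(img.shape[1], target)
        out = wr @ img @ wc.T
    elif method == "bilinear":
        out = _sk_resize(img, (target, target), order=1, anti_aliasing=True)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class PrepParams:
    target_size: int = 28
    low_pct: float = 1.0
    high_pct: float = 99.0
    background_threshold: float = 0.98
    resample: str = "area"
    white_point: str = "D65"

    def as_dict(self) -> dict:
        return {
            "target_size": self.target_size,
            "low_pct": self.low_pct,
            "high_pct": self.high_pct,
            "background_threshold": self.background_threshold,
            "resample": self.resample,
            "white_point": self.white_point,
        }


def prepare_image(pixels: np.ndarray, params: PrepParams = PrepParams()) -> np.ndarray:
    """Run the full order-fixed preparation chain on one raw image."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 3:
        img = von_kries_grayscale(pixels, params.white_point)
    else:
        img = pixels / 255.0 if pixels.max() > 1.5 else pixels
    img = normalize_exposure(img, params.low_pct, params.high_pct)
    img = crop_and_frame(img, params.background_threshold)
    return step_down(img, params.target_size, params.resample)


def prepare_set(images: list[SpecimenImage],
                params: PrepParams = PrepParams()) -> list[SpecimenImage]:
    """Prepare every image in a set, keeping manifest metadata."""
    return [
        SpecimenImage(im.specimen_id, im.group, im.substrate,
                      prepare_image(im.pixels, params))
        for im in images
    ]
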