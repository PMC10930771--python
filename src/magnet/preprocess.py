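"""Input conditioning: grey filtering, aspect-preserving resize/pad, and
dihedral augmentation.

All functions operate on H x W x 3 arrays on the 0-255 scale (uint8 or
float).  The grey filter blanks any pixel whose three channel values lie
within ``tau`` of each other — this removes both the white slide background
and grey scanning artifacts — and is applied identically at train and
inference time.  Colour normalisation and colour jitter are deliberately
not provided.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .errors import FormatError

__all__ = [
    "AUGMENT_CODES",
    "augment",
    "grey_filter",
    "grey_mask",
    "inverse_augment_code",
    "resize_pad",
]

GREY_TAU_DEFAULT = 15

AUGMENT_CODES = ("none", "hflip", "vflip", "rot90", "rot180", "rot270")

_INVERSE = {
    "none": "none",
    "hflip": "hflip",
    "vflip": "vflip",
    "rot90": "rot270",
    "rot180": "rot180",
    "rot270": "rot90",
}


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"expected an H x W x 3 image, got shape {image.shape}")
    return image


def grey_mask(image: np.ndarray, tau: float = GREY_TAU_DEFAULT) -> np.ndarray:
    """Boolean mask of pixels kept by the grey filter (channel spread >= tau)."""
    image = _check_rgb(image).astype(np.int16, copy=False)
    spread = image.max(axis=2) - image.min(axis=2)
    return spread >= tau


def grey_filter(image: np.ndarray, tau: float = GREY_TAU_DEFAULT) -> np.ndarray:
    """Set near-grey pixels (max pairwise channel difference < ``tau``) to black.

    For three channels the maximal pairwise difference equals max - min, so
    the predicate is evaluated as ``max(channel) - min(channel) < tau`` with
    the strict inequality kept as specified.
    """
    image = _check_rgb(image)
    out = image.copy()
    out[~grey_mask(image, tau)] = 0
    return out


def _resize_bilinear(image: np.ndarray, width: int, height: int) -> np.ndarray:
    """Bilinear resize that preserves the input dtype (uint8 or float)."""
    if image.dtype == np.uint8:
        return np.asarray(
            Image.fromarray(image).resize((width, height), Image.BILINEAR)
        )
    channels = [
        np.asarray(
            Image.fromarray(image[..., c].astype(np.float32), mode="F").resize(
                (width, height), Image.BILINEAR
            )
        )
        for c in range(image.shape[2])
    ]
    return np.stack(channels, axis=2).astype(image.dtype)


def resize_pad(image: np.ndarray, side: int) -> np.ndarray:
    """Resize so the longer side equals ``side`` (bilinear, aspect preserved),
    then pad the shorter side symmetrically with black to a square.

    Odd padding deficits place the extra row/column at the bottom/right.
    """
    image = _check_rgb(image)
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise FormatError("cannot resize an empty image")
    if side < 2:
        raise FormatError("target side must be >= 2")
    if h == w == side:
        return image.copy()
    if h >= w:
        new_h = side
        new_w = max(1, round(w * side / h))
    else:
        new_w = side
        new_h = max(1, round(h * side / w))
    resized = _resize_bilinear(image, new_w, new_h)
    out = np.zeros((side, side, 3), dtype=image.dtype)
    top = (side - new_h) // 2
    left = (side - new_w) // 2
    out[top : top + new_h, left : left + new_w] = resized
    return out


def augment(image: np.ndarray, code: str) -> np.ndarray:
    """Apply one of the six dihedral augmentation codes (exact pixel permutation)."""
    image = _check_rgb(image)
    if code == "none":
        return image.copy()
    if code == "hflip":
        return np.ascontiguousarray(image[:, ::-1])
    if code == "vflip":
        return np.ascontiguousarray(image[::-1])
    if code == "rot90":
        return np.ascontiguousarray(np.rot90(image, 1))
    if code == "rot180":
        return np.ascontiguousarray(np.rot90(image, 2))
    if code == "rot270":
        return np.ascontiguousarray(np.rot90(image, 3))
    raise FormatError(f"unknown augmentation code {code!r}")


def inverse_augment_code(code: str) -> str:
    try:
        return _INVERSE[code]
    except KeyError:
        raise FormatError(f"unknown augmentation code {code!r}") from None
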