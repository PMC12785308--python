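"""Shared low-level helpers: rounding, seed derivation, luma conversion."""

from __future__ import annotations

import hashlib
import math

import numpy as np

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def round_px(x: float) -> int:
    """Nearest nonnegative integer, exact ties rounding down (1.5 -> 1).

    Pixel-count arithmetic in the transform pipeline uses one fixed
    convention so that 0.75 rounds to 1, 5.91 to 6 and 1.5 to 1,
    independent of the banker's rounding of the builtin :func:`round`.
    """
    return max(int(math.ceil(x - 0.5)), 0)


def subseed(master: int, *parts) -> int:
    """Derive a stable 31-bit sub-seed from a master seed and identifiers.

    Uses SHA-256 of the string form, so the mapping is stable across Python
    processes and versions (unlike ``hash``).  Adding new identifiers never
    shifts the seed of an existing one.
    """
    payload = ":".join([str(int(master))] + [str(p) for p in parts])
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def luma(image: np.ndarray, *, rounded: bool = True) -> np.ndarray:
    """BT.601 luma channel of an RGB array.

    With ``rounded`` (default), returns round(0.299 R + 0.587 G + 0.114 B)
    as float; otherwise the unrounded weighted sum.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return np.rint(arr) if rounded else arr
    y = arr[..., 0] * LUMA_WEIGHTS[0] + arr[..., 1] * LUMA_WEIGHTS[1] + arr[..., 2] * LUMA_WEIGHTS[2]
    return np.rint(y) if rounded else y


def as_rgb_u8(image: np.ndarray) -> np.ndarray:
    """Validate and return an H x W x 3 uint8 array."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB array, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return arr
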