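"""Shared low-level helpers: integer shifts, disc rasterization, mask borders."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def shift_int(image: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate a 2D image by whole pixels, zero-filling exposed borders."""
    out = np.zeros_like(image)
    h, w = image.shape[:2]
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    ys_dst = slice(max(0, dy), min(h, h + dy))
    xs_dst = slice(max(0, dx), min(w, w + dx))
    out[ys_dst, xs_dst] = image[ys_src, xs_src]
    return out


def rasterize_disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disc: pixels whose center lies within `radius` of `center` (pixel units)."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def mask_border(mask: np.ndarray) -> np.ndarray:
    """Border of a 2D mask: mask pixels 4-adjacent to background."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return mask & ~ndimage.binary_erosion(mask, structure=_CROSS, border_value=1)


def distance_to_border_um(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Per-pixel Euclidean distance (μm) to the nearest border pixel of `mask`.

    Returns +inf everywhere when the mask is empty.
    """
    border = mask_border(mask)
    if not border.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~border) * pixel_size_um
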