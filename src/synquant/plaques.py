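"""Plaque segmentation and morphometry: burden, area, halo thickness, dystrophies.

Dense (ThioS-positive) plaques are segmented as 8-connected components of a
thresholded 2D image; plaque burden is the percentage of the cortex mask
covered by dense cores.  The halo is the annulus of diffuse (total-Aβ) signal
around a core: its thickness is the mean, over core-border pixels, of the
distance to the nearest non-diffuse pixel.  Dystrophic neurites are counted
per plaque when their equivalent circular diameter exceeds 2.5 μm and their
centroid lies within the dense core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from ._util import mask_border

__all__ = [
    "PlaqueObject",
    "segment_plaques",
    "plaque_burden",
    "halo_thickness",
    "count_dystrophies",
    "plaque_table",
]

MIN_DYSTROPHY_DIAMETER_UM = 2.5


@dataclass
class PlaqueObject:
    """One segmented dense-core plaque, optionally with its diffuse halo mask."""

    id: int
    core_mask: np.ndarray  # full-scene 2D bool
    pixel_size_um: float
    diffuse_mask: np.ndarray | None = None
    border: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.core_mask = np.asarray(self.core_mask, dtype=bool)
        if self.diffuse_mask is not None:
            self.diffuse_mask = np.asarray(self.diffuse_mask, dtype=bool)
            if (self.core_mask & ~self.diffuse_mask).any():
                raise ValueError("core must be contained in the diffuse mask")
        self.border = mask_border(self.core_mask)

    @property
    def area_um2(self) -> float:
        return float(self.core_mask.sum()) * self.pixel_size_um**2


def _binarize(image: np.ndarray, threshold_spec) -> np.ndarray:
    if isinstance(threshold_spec, (int, float)):
        return np.asarray(image) > threshold_spec
    if threshold_spec == "otsu":
        img = np.asarray(image)
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=bool)
        return img > threshold_otsu(img)
    raise ValueError(f"unknown threshold spec {threshold_spec!r}")


def segment_plaques(
    image: np.ndarray,
    pixel_size_um: float,
    threshold_spec="otsu",
    min_area_um2: float = 0.0,
    diffuse_image: np.ndarray | None = None,
    diffuse_threshold_spec="otsu",
) -> list[PlaqueObject]:
    """Threshold → 8-connected components → PlaqueObjects (small ones discarded).

    When the matching diffuse-Aβ image is supplied, each plaque also carries
    the diffuse component that contains its core (or the core itself when the
    diffuse stain adds nothing, so core ⊆ diffuse always holds).
    """
    core = _binarize(image, threshold_spec)
    labels = measure.label(core, connectivity=2)
    diffuse_all = None
    if diffuse_image is not None:
        diffuse_all = _binarize(diffuse_image, diffuse_threshold_spec) | core
        diffuse_labels = measure.label(diffuse_all, connectivity=2)

    out: list[PlaqueObject] = []
    for lab in range(1, labels.max() + 1):
        core_mask = labels == lab
        if core_mask.sum() * pixel_size_um**2 < min_area_um2:
            continue
        diffuse_mask = None
        if diffuse_all is not None:
            seed = np.argwhere(core_mask)[0]
            diffuse_mask = diffuse_labels == diffuse_labels[seed[0], seed[1]]
        out.append(
            PlaqueObject(
                id=len(out),
                core_mask=core_mask,
                pixel_size_um=pixel_size_um,
                diffuse_mask=diffuse_mask,
            )
        )
    return out


def plaque_burden(plaques: list[PlaqueObject], cortex_mask: np.ndarray) -> float:
    """Percentage of the cortex mask covered by the union of dense cores."""
    cortex = np.asarray(cortex_mask, dtype=bool)
    if not cortex.any():
        raise ValueError("cortex mask is empty")
    if not plaques:
        return 0.0
    union = np.zeros_like(cortex)
    for p in plaques:
        union |= p.core_mask
    return 100.0 * float((union & cortex).sum()) / float(cortex.sum())


def halo_thickness(plaque: PlaqueObject) -> float:
    """Mean radial extent (μm) of the diffuse annulus beyond the core border.

    Measured as the mean, over core-border pixels, of the Euclidean distance
    to the nearest non-diffuse pixel.  Zero when the diffuse mask adds no
    annulus.
    """
    if plaque.diffuse_mask is None:
        raise ValueError("plaque has no diffuse mask")
    if not plaque.border.any():
        return 0.0
    annulus = plaque.diffuse_mask & ~plaque.core_mask
    if not annulus.any():
        return 0.0
    dist_to_bg = ndimage.distance_transform_edt(plaque.diffuse_mask)
    return float(dist_to_bg[plaque.border].mean()) * plaque.pixel_size_um


def count_dystrophies(
    dystrophy_mask: np.ndarray,
    plaque: PlaqueObject,
    min_diameter_um: float = MIN_DYSTROPHY_DIAMETER_UM,
    *,
    diameter: str = "equivalent",
    membership: str = "centroid",
) -> int:
    """Count dystrophic-neurite blobs belonging to a plaque.

    A blob counts when its diameter exceeds ``min_diameter_um`` and it lies
    within the dense core.  Diameter is the equivalent circular diameter
    2·sqrt(area/π) by default ('feret' selects the max Feret diameter);
    membership is centroid-inside-core by default ('overlap' accepts any
    shared pixel).
    """
    mask = np.asarray(dystrophy_mask, dtype=bool)
    if mask.shape != plaque.core_mask.shape:
        raise ValueError("dystrophy mask must share the plaque's coordinates")
    px = plaque.pixel_size_um
    count = 0
    for region in measure.regionprops(measure.label(mask, connectivity=2)):
        if diameter == "equivalent":
            diam = region.equivalent_diameter_area * px
        elif diameter == "feret":
            diam = region.feret_diameter_max * px
        else:
            raise ValueError(f"unknown diameter definition {diameter!r}")
        if diam <= min_diameter_um:
            continue
        if membership == "centroid":
            cy, cx = (int(round(c)) for c in region.centroid)
            inside = plaque.core_mask[cy, cx]
        elif membership == "overlap":
            ys, xs = region.coords[:, 0], region.coords[:, 1]
            inside = bool(plaque.core_mask[ys, xs].any())
        else:
            raise ValueError(f"unknown membership rule {membership!r}")
        if inside:
            count += 1
    return count


def plaque_table(
    plaques: list[PlaqueObject],
    dystrophy_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-plaque CSV schema: id, area, halo thickness, dystrophy count."""
    rows = []
    for p in plaques:
        rows.append(
            {
                "id": p.id,
                "area_um2": p.area_um2,
                "halo_um": halo_thickness(p) if p.diffuse_mask is not None else np.nan,
                "n_dystrophies": (
                    count_dystrophies(dystrophy_mask, p) if dystrophy_mask is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows, columns=["id", "area_um2", "halo_um", "n_dystrophies"])
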