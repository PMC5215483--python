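"""ROI selection near/far from plaques, synapse densities, and Aβ colocalization.

Analysis columns of 10 × 10 μm are classified by the Euclidean distance from
the window's nearest pixel to the nearest plaque-border pixel: near when
< 20 μm, far when > 40 μm; the 20-40 μm annulus is a deliberate exclusion
zone.  Synapse density is centroid-in-column counting over the column volume;
colocalization is the fraction of synaptic puncta sharing at least one voxel
with the thresholded Aβ channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import distance_to_border_um
from .puncta import Punctum
from .stack import BinaryStack, SectionStack

__all__ = [
    "RoiSample",
    "select_rois",
    "punctum_density",
    "colocalization",
    "quantify_rois",
    "roi_table",
]

NEAR_UM = 20.0
FAR_UM = 40.0


@dataclass
class RoiSample:
    """A 10 × 10 μm analysis column through the whole aligned stack."""

    origin_um: tuple[float, float]  # (y, x) of the window's top-left corner
    size_um: tuple[float, float]
    n_sections_used: int
    section_thickness_um: float
    distance_class: str  # 'near' or 'far'
    distance_to_plaque_um: float
    densities: dict[str, float] = field(default_factory=dict)
    coloc_fractions: dict[str, float | None] = field(default_factory=dict)

    @property
    def volume_um3(self) -> float:
        return self.size_um[0] * self.size_um[1] * self.n_sections_used * self.section_thickness_um


def select_rois(
    plaque_mask: np.ndarray,
    stack: SectionStack,
    n_near: int,
    n_far: int,
    seed: int,
    *,
    roi_size_um: float = 10.0,
    margin_px: int | None = None,
) -> list[RoiSample]:
    """Sample near (< 20 μm) and far (> 40 μm) ROI columns around a plaque.

    Candidate windows tile the plane on a non-overlapping grid; each window's
    distance is the minimum over its pixels of the Euclidean distance to the
    nearest plaque-border pixel (distance transform).  Windows overlapping
    the dense core, falling in the 20-40 μm gap zone, or touching the
    alignment margin are never returned.  With an empty plaque mask every
    window is far with distance +inf.  If fewer eligible windows exist than
    requested, the shortfall is warned about and fewer ROIs are returned.
    """
    px = stack.pixel_size_um
    mask = np.asarray(plaque_mask, dtype=bool)
    if mask.shape != stack.plane_shape:
        raise ValueError("plaque mask must match the stack's plane shape")
    size_px = int(round(roi_size_um / px))
    if size_px < 1:
        raise ValueError("ROI smaller than one pixel")
    if margin_px is None:
        offs = stack.alignment_offsets
        margin_px = int(np.abs(offs).max()) if offs is not None else 0

    dist = distance_to_border_um(mask, px)
    h, w = mask.shape
    origins = [
        (y0, x0)
        for y0 in range(margin_px, h - margin_px - size_px + 1, size_px)
        for x0 in range(margin_px, w - margin_px - size_px + 1, size_px)
    ]

    near: list[RoiSample] = []
    far: list[RoiSample] = []
    for y0, x0 in origins:
        win_mask = mask[y0 : y0 + size_px, x0 : x0 + size_px]
        if win_mask.any():
            continue  # overlaps the dense core
        d = float(dist[y0 : y0 + size_px, x0 : x0 + size_px].min())
        if d < NEAR_UM:
            cls = "near"
        elif d > FAR_UM:
            cls = "far"
        else:
            continue  # 20-40 μm exclusion zone
        roi = RoiSample(
            origin_um=(y0 * px, x0 * px),
            size_um=(size_px * px, size_px * px),
            n_sections_used=stack.n_sections,
            section_thickness_um=stack.section_thickness_um,
            distance_class=cls,
            distance_to_plaque_um=d,
        )
        (near if cls == "near" else far).append(roi)

    rng = np.random.default_rng(seed)
    out: list[RoiSample] = []
    for pool, want, cls in ((near, n_near, "near"), (far, n_far, "far")):
        if len(pool) < want:
            warnings.warn(
                f"only {len(pool)} eligible {cls} windows for {want} requested", stacklevel=2
            )
        take = min(want, len(pool))
        if take:
            idx = rng.choice(len(pool), size=take, replace=False)
            out.extend(pool[i] for i in np.sort(idx))
    return out


def _centroids_in_roi(puncta: list[Punctum], roi: RoiSample) -> list[Punctum]:
    y0, x0 = roi.origin_um
    sy, sx = roi.size_um
    return [
        p
        for p in puncta
        if y0 <= p.centroid_um[1] < y0 + sy and x0 <= p.centroid_um[2] < x0 + sx
    ]


def punctum_density(puncta: list[Punctum], roi: RoiSample) -> dict[str, float]:
    """Puncta per μm³ in the ROI column, per channel, by centroid membership."""
    if roi.volume_um3 <= 0:
        raise ValueError("ROI has zero volume")
    counts: dict[str, int] = {}
    for p in _centroids_in_roi(puncta, roi):
        counts[p.channel] = counts.get(p.channel, 0) + 1
    return {ch: n / roi.volume_um3 for ch, n in counts.items()}


def colocalization(
    synaptic_puncta: list[Punctum],
    abeta_mask: BinaryStack,
    rule: str = "overlap",
    min_overlap_voxels: int = 1,
) -> float | None:
    """Fraction of synaptic puncta containing Aβ; None when there are no puncta.

    rule 'overlap'  — at least ``min_overlap_voxels`` of the punctum's voxels
                      are Aβ-positive (default 1)
    rule 'centroid' — the voxel nearest the punctum centroid is Aβ-positive
    """
    if not synaptic_puncta:
        return None
    mask = abeta_mask.mask
    hits = 0
    for p in synaptic_puncta:
        if rule == "overlap":
            v = p.voxels
            if int(mask[v[:, 0], v[:, 1], v[:, 2]].sum()) >= min_overlap_voxels:
                hits += 1
        elif rule == "centroid":
            z = int(round(p.centroid_um[0] / abeta_mask.section_thickness_um))
            y = int(round(p.centroid_um[1] / abeta_mask.pixel_size_um))
            x = int(round(p.centroid_um[2] / abeta_mask.pixel_size_um))
            z = min(max(z, 0), mask.shape[0] - 1)
            y = min(max(y, 0), mask.shape[1] - 1)
            x = min(max(x, 0), mask.shape[2] - 1)
            if mask[z, y, x]:
                hits += 1
        else:
            raise ValueError(f"unknown colocalization rule {rule!r}")
    return hits / len(synaptic_puncta)


def quantify_rois(
    rois: list[RoiSample],
    puncta_by_channel: dict[str, list[Punctum]],
    abeta_mask: BinaryStack | None = None,
    rule: str = "overlap",
) -> list[RoiSample]:
    """Fill densities (and colocalization fractions, if an Aβ mask is given) in place."""
    for roi in rois:
        roi.densities = {}
        roi.coloc_fractions = {}
        for ch, plist in puncta_by_channel.items():
            inside = _centroids_in_roi(plist, roi)
            roi.densities[ch] = len(inside) / roi.volume_um3
            if abeta_mask is not None:
                roi.coloc_fractions[ch] = colocalization(inside, abeta_mask, rule=rule)
    return rois


def roi_table(rois: list[RoiSample]) -> pd.DataFrame:
    """One row per ROI: geometry, class, distance, densities, colocalization."""
    rows = []
    for i, roi in enumerate(rois):
        row: dict = {
            "roi_id": i,
            "origin_y_um": roi.origin_um[0],
            "origin_x_um": roi.origin_um[1],
            "size_um": roi.size_um[0],
            "n_sections_used": roi.n_sections_used,
            "volume_um3": roi.volume_um3,
            "distance_class": roi.distance_class,
            "distance_to_plaque_um": roi.distance_to_plaque_um,
        }
        for ch, d in roi.densities.items():
            row[f"density_{ch}"] = d
        for ch, f in roi.coloc_fractions.items():
            row[f"coloc_{ch}"] = np.nan if f is None else f
        rows.append(row)
    return pd.DataFrame(rows)
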