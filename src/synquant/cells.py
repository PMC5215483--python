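"""Volumetric cell counting near and far from plaques.

Inputs are point sets (μm coordinates) — the countable contract of the
stereological procedure — not raw Nissl/GFAP images.  Neurons are counted in
30 × 30 × 50 μm boxes placed near (< 30 μm) and far (≥ 100 μm, same cortical
layer) from a plaque border; astrocytes are counted in a 30 μm-radius ring
from the plaque edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._util import mask_border

__all__ = [
    "CellField",
    "count_in_box",
    "place_near_far_boxes",
    "count_astrocytes_ring",
    "load_cell_field",
]

DEFAULT_BOX_UM = (50.0, 30.0, 30.0)  # (z, y, x)
NEAR_BOX_UM = 30.0
FAR_BOX_UM = 100.0


@dataclass
class CellField:
    """Point field of detected cells with its bounding geometry (μm)."""

    coordinates: np.ndarray  # (n, 3) of (z, y, x) μm
    cell_type: str
    volume_um: tuple[float, float, float]  # (z, y, x) extents

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        ext = np.asarray(self.volume_um, dtype=float)
        if len(self.coordinates) and (
            (self.coordinates < 0).any() or (self.coordinates > ext).any()
        ):
            raise ValueError("all points must lie inside the field geometry")

    def __len__(self) -> int:
        return len(self.coordinates)


def count_in_box(
    field: CellField,
    box_origin: tuple[float, float, float],
    box_size: tuple[float, float, float] = DEFAULT_BOX_UM,
) -> tuple[int, float]:
    """Count points in the half-open box [origin, origin + size); return (count, density).

    Half-open membership makes counts additive over adjacent boxes.
    """
    origin = np.asarray(box_origin, dtype=float)
    size = np.asarray(box_size, dtype=float)
    ext = np.asarray(field.volume_um, dtype=float)
    if (origin < 0).any() or (origin + size > ext + 1e-9).any():
        raise ValueError("box extends outside the imaged volume")
    pts = field.coordinates
    inside = np.all((pts >= origin) & (pts < origin + size), axis=1)
    count = int(np.count_nonzero(inside))
    return count, count / float(size.prod())


def place_near_far_boxes(
    plaque_mask: np.ndarray,
    pixel_size_um: float,
    field_geometry: tuple[float, float, float],
    seed: int,
    *,
    box_size: tuple[float, float, float] = DEFAULT_BOX_UM,
    near_um: float = NEAR_BOX_UM,
    far_um: float = FAR_BOX_UM,
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Seeded placement of one near and one far counting box (origins, μm).

    The near box must contain at least one pixel within ``near_um`` of the
    plaque border without overlapping the dense core; the far box must lie
    entirely at ``far_um`` or more from every border, in the same row band
    ("cortical layer" proxy) as the near box.  Raises with the violated
    constraint when no placement exists.
    """
    mask = np.asarray(plaque_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no plaque in the field: near box undefined")
    border = mask_border(mask)
    dist = ndimage.distance_transform_edt(~border) * pixel_size_um

    vz, vy, vx = field_geometry
    bz, by, bx = box_size
    if bz > vz:
        raise ValueError("box deeper than the imaged volume")
    by_px = max(1, int(round(by / pixel_size_um)))
    bx_px = max(1, int(round(bx / pixel_size_um)))
    h, w = mask.shape
    max_y0 = min(h - by_px, int((vy - by) / pixel_size_um))
    max_x0 = min(w - bx_px, int((vx - bx) / pixel_size_um))
    if max_y0 < 0 or max_x0 < 0:
        raise ValueError("box does not fit in the field")

    # sliding-window extrema of the distance map and core occupancy
    foot = np.ones((by_px, bx_px))
    min_d = ndimage.minimum_filter(dist, footprint=foot, mode="constant", cval=np.inf)
    has_core = ndimage.maximum_filter(mask.astype(np.uint8), footprint=foot, mode="constant", cval=0)
    # window statistic at the window's top-left origin
    oy, ox = (by_px - 1) // 2, (bx_px - 1) // 2
    min_d = min_d[oy : oy + max_y0 + 1, ox : ox + max_x0 + 1]
    has_core = has_core[oy : oy + max_y0 + 1, ox : ox + max_x0 + 1]

    near_ok = (min_d <= near_um) & (has_core == 0)
    far_ok = min_d >= far_um
    if not near_ok.any():
        raise ValueError(f"no near-box placement within {near_um} μm of the border")

    rng = np.random.default_rng(seed)
    near_candidates = np.argwhere(near_ok)
    ny, nx = near_candidates[rng.integers(len(near_candidates))]

    far_rows = far_ok[ny]
    if not far_rows.any():
        raise ValueError(
            f"no far-box placement >= {far_um} μm from every plaque border in the same layer band"
        )
    fx = int(np.flatnonzero(far_rows)[rng.integers(int(far_rows.sum()))])

    z0 = float(rng.uniform(0.0, vz - bz)) if vz > bz else 0.0
    near_origin = (z0, float(ny) * pixel_size_um, float(nx) * pixel_size_um)
    far_origin = (z0, float(ny) * pixel_size_um, fx * pixel_size_um)
    return near_origin, far_origin


def count_astrocytes_ring(
    field: CellField,
    core_mask: np.ndarray,
    pixel_size_um: float,
    radius_um: float = 30.0,
) -> int:
    """Count astrocytes within ``radius_um`` of the plaque edge, outside the core.

    Distance is measured in-plane from each point to the nearest core-border
    pixel; points whose (y, x) position falls on the dense core itself are
    excluded.
    """
    mask = np.asarray(core_mask, dtype=bool)
    border = mask_border(mask)
    if not border.any():
        return 0
    pts = field.coordinates
    if len(pts) == 0:
        return 0
    border_yx = np.argwhere(border) * pixel_size_um
    d = np.min(
        np.hypot(
            pts[:, 1][:, None] - border_yx[:, 0][None, :],
            pts[:, 2][:, None] - border_yx[:, 1][None, :],
        ),
        axis=1,
    )
    iy = np.clip((pts[:, 1] / pixel_size_um).astype(int), 0, mask.shape[0] - 1)
    ix = np.clip((pts[:, 2] / pixel_size_um).astype(int), 0, mask.shape[1] - 1)
    outside_core = ~mask[iy, ix]
    return int(np.count_nonzero((d <= radius_um) & outside_core))


def load_cell_field(path, cell_type: str, volume_um: tuple[float, float, float]) -> CellField:
    """Read a point set CSV with columns x_um, y_um, z_um (and optional type)."""
    df = pd.read_csv(path)
    if "type" in df.columns:
        df = df[df["type"] == cell_type]
    return CellField(
        coordinates=df[["z_um", "y_um", "x_um"]].to_numpy(float),
        cell_type=cell_type,
        volume_um=volume_um,
    )
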