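"""Synthetic data with known ground truth for every stage of the pipeline.

The generator emulates the study's two imaging modalities:

* Array-tomography stacks: ribbons of 70 nm sections carrying punctate
  pre-/post-synaptic channels (Gaussian blobs spanning 2-3 consecutive
  sections), single-section staining artifacts, an oligomeric-Aβ channel
  overlapping a planted fraction of synapses, an optional dense-plaque disc,
  per-section rigid stage jitter, and Gaussian background noise.  Synapse
  density is depressed by a planted loss fraction within 20 μm of the plaque
  border, recovering linearly to the far level by 40 μm.
* Histology scenes: dense plaque cores with diffuse-Aβ halos, tortuous
  neurite polylines with analytic curvature, and neuron/astrocyte point
  fields with near-plaque depletion.

Every planted object is recorded exactly once in a machine-readable
GroundTruth; planted densities are defined as planted counts over the
generated (margin-inset) volume.  One root seed drives independent spawned
sub-streams (placement, flags, jitter, noise), so identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import rasterize_disc
from .cells import CellField
from .stack import SectionStack
from ._util import shift_int

__all__ = [
    "AtStackParams",
    "GroundTruth",
    "generate_at_stack",
    "generate_plaque_section",
    "generate_neurites",
    "generate_cell_field",
    "plaque_scenario_params",
    "artifact_scenario_params",
    "coloc_scenario_params",
]

NEAR_UM = 20.0  # synapse-loss zone extends this far from the plaque border
FAR_UM = 40.0  # density/colocalization back at the far level beyond this


# ---------------------------------------------------------------------------
# parameters and ground truth
# ---------------------------------------------------------------------------


@dataclass
class AtStackParams:
    """Parameters of a synthetic array-tomography stack.

    Defaults describe a plaque-free cortical neuropil volume at the pixel
    scale of a 63× objective (0.1 μm/px) with 70 nm sections.  Densities are
    puncta/μm³ per synaptic channel; fractions are unitless in [0, 1].
    """

    n_sections: int = 20
    plane_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    section_thickness_um: float = 0.07
    synaptic_channels: tuple[str, ...] = ("synapsin", "psd95")
    synapse_density_far: float | dict[str, float] = 0.6
    near_loss_fraction: float = 0.4
    coloc_fraction_near: float = 0.30
    coloc_fraction_far: float = 0.10
    single_slice_noise_rate: float = 0.3
    punctum_radius_um: float = 0.25
    section_jitter_px: int = 3
    noise_sd: float = 0.15
    amplitude: float = 1.0
    plaque_center_um: tuple[float, float] | None = None
    plaque_radius_um: float = 6.0
    min_separation_um: float | None = None
    exact_counts: bool = False
    margin_px: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 2:
            raise ValueError("n_sections must be >= 2")
        if self.pixel_size_um <= 0 or self.section_thickness_um <= 0:
            raise ValueError("voxel spacings must be positive")
        for name in ("near_loss_fraction", "coloc_fraction_near", "coloc_fraction_far"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.punctum_radius_um < self.pixel_size_um:
            raise ValueError("punctum radius below one pixel cannot be rendered")

    def density_of(self, channel: str) -> float:
        if isinstance(self.synapse_density_far, dict):
            return float(self.synapse_density_far[channel])
        return float(self.synapse_density_far)

    @property
    def blob_sigma_px(self) -> float:
        # radius is interpreted as the ~2-sigma extent of the blob
        return (self.punctum_radius_um / 2.0) / self.pixel_size_um

    @property
    def default_margin_px(self) -> int:
        footprint = int(math.ceil(3 * self.blob_sigma_px))
        return self.section_jitter_px + footprint + 1

    @property
    def planted_volume_um3(self) -> float:
        """Volume of the margin-inset planting region; densities refer to it."""
        margin = self.default_margin_px if self.margin_px is None else self.margin_px
        h, w = self.plane_shape
        area = (h - 2 * margin) * (w - 2 * margin) * self.pixel_size_um**2
        return area * self.n_sections * self.section_thickness_um


@dataclass
class GroundTruth:
    """Machine-readable record of everything a generator planted.

    Only the fields relevant to the producing generator are populated.
    """

    params: dict = field(default_factory=dict)
    puncta: pd.DataFrame | None = None
    applied_shifts_px: np.ndarray | None = None
    plaque_center_um: tuple[float, float] | None = None
    plaque_radius_um: float | None = None
    region_volumes_um3: dict[str, float] | None = None
    true_densities: dict[tuple[str, str], float] | None = None
    true_coloc_fractions: dict[tuple[str, str], float] | None = None
    plaques: pd.DataFrame | None = None
    burden_percent: float | None = None
    halo_thickness_um: float | None = None
    neurites: pd.DataFrame | None = None
    cells: pd.DataFrame | None = None
    expected_counts: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# array-tomography stack
# ---------------------------------------------------------------------------


def _border_distance_um(y_um, x_um, params: AtStackParams):
    """Signed distance (μm) from points to the plaque border; +inf without a plaque.

    Positive outside the dense core, negative inside.
    """
    if params.plaque_center_um is None:
        return np.full(np.shape(y_um), np.inf)
    cy, cx = params.plaque_center_um
    r = np.hypot(np.asarray(y_um) - cy, np.asarray(x_um) - cx)
    return r - params.plaque_radius_um


def _loss_multiplier(d_um: np.ndarray, loss: float) -> np.ndarray:
    """Planted density multiplier as a function of distance beyond the border."""
    d = np.asarray(d_um, dtype=float)
    mult = np.ones_like(d)
    mult[d <= 0] = 0.0  # no synapses inside the dense core
    near = (d > 0) & (d <= NEAR_UM)
    mult[near] = 1.0 - loss
    ramp = (d > NEAR_UM) & (d < FAR_UM)
    mult[ramp] = (1.0 - loss) + loss * (d[ramp] - NEAR_UM) / (FAR_UM - NEAR_UM)
    return mult


def _coloc_fraction(d_um: np.ndarray, near_f: float, far_f: float) -> np.ndarray:
    d = np.asarray(d_um, dtype=float)
    frac = np.full_like(d, far_f)
    frac[d <= NEAR_UM] = near_f
    ramp = (d > NEAR_UM) & (d < FAR_UM)
    frac[ramp] = near_f + (far_f - near_f) * (d[ramp] - NEAR_UM) / (FAR_UM - NEAR_UM)
    return frac


def _region_label(d_um: np.ndarray) -> np.ndarray:
    d = np.asarray(d_um, dtype=float)
    lab = np.where(d > FAR_UM, "far", "mid")
    lab = np.where(d <= NEAR_UM, "near", lab)
    lab = np.where(d <= 0, "core", lab)
    return lab


def _place_centers(
    rng: np.random.Generator,
    n_target: int,
    lo: np.ndarray,
    hi: np.ndarray,
    min_sep_px: float | None,
    exact: bool,
    existing: np.ndarray | None = None,
) -> np.ndarray:
    """Uniform (y, x) pixel centers in [lo, hi), optionally with a hard-core spacing.

    The spacing is enforced against ``existing`` centers too (e.g. artifacts
    vs already-placed puncta in the same channel).  In exact mode, candidates
    are drawn until `n_target` admissible centers are kept (bounded attempts);
    otherwise one pass of sequential thinning is applied to the drawn
    candidates.
    """
    if n_target == 0:
        return np.empty((0, 2))
    if min_sep_px is None:
        return rng.uniform(lo, hi, size=(n_target, 2))
    kept: list[np.ndarray] = [] if existing is None else [np.asarray(e) for e in existing]
    n_existing = len(kept)
    sep2 = min_sep_px**2

    def admissible(c: np.ndarray) -> bool:
        return all(float(np.sum((c - k) ** 2)) >= sep2 for k in kept)

    if exact:
        attempts = 0
        while len(kept) - n_existing < n_target:
            if attempts > 200 * n_target:
                raise ValueError("could not place the requested puncta with the given separation")
            attempts += 1
            c = rng.uniform(lo, hi, size=2)
            if admissible(c):
                kept.append(c)
    else:
        # sequential (Matérn-style) thinning: rejected candidates are dropped
        for c in rng.uniform(lo, hi, size=(n_target, 2)):
            if admissible(c):
                kept.append(c)
    new = kept[n_existing:]
    return np.asarray(new) if new else np.empty((0, 2))


def _render_blob(plane: np.ndarray, cy: float, cx: float, sigma: float, amp: float) -> None:
    """Add an in-plane Gaussian blob to one section (in place)."""
    h, w = plane.shape
    r = int(math.ceil(4 * sigma))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - cy
    xx = np.arange(x0, x1)[None, :] - cx
    plane[y0:y1, x0:x1] += amp * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))


def generate_at_stack(params: AtStackParams) -> tuple[SectionStack, GroundTruth]:
    """Render a synthetic array-tomography stack and its ground truth.

    Channels are the synaptic channels plus ``abeta`` (oligomeric Aβ, planted
    at a fraction of synapses) and ``plaque`` (dense-core disc, blank when no
    plaque is configured).  Puncta are planted in a margin-inset region so
    that stage jitter and blob footprints never clip an object at the frame
    edge; planted densities refer to that inset volume.
    """
    rng = np.random.default_rng(params.seed)
    place_rng, flag_rng, jitter_rng, noise_rng = rng.spawn(4)

    h, w = params.plane_shape
    px = params.pixel_size_um
    dz = params.section_thickness_um
    margin = params.default_margin_px if params.margin_px is None else params.margin_px
    if 2 * margin >= min(h, w):
        raise ValueError("plane too small for the planting margin")
    lo = np.array([margin, margin], dtype=float)
    hi = np.array([h - margin, w - margin], dtype=float)
    depth_um = params.n_sections * dz
    area_um2 = float((hi - lo).prod()) * px**2
    volume_um3 = area_um2 * depth_um
    sigma = params.blob_sigma_px
    min_sep_px = None if params.min_separation_um is None else params.min_separation_um / px

    channels = tuple(params.synaptic_channels) + ("abeta", "plaque")
    vox = np.zeros((params.n_sections, h, w, len(channels)), dtype=np.float32)
    abeta_idx = channels.index("abeta")
    plaque_idx = channels.index("plaque")

    # dense-core plaque disc, identical on every section
    if params.plaque_center_um is not None:
        cy, cx = (c / px for c in params.plaque_center_um)
        disc = rasterize_disc((h, w), (cy, cx), params.plaque_radius_um / px)
        vox[:, :, :, plaque_idx] += params.amplitude * disc

    rows: list[dict] = []
    next_id = 0
    for ci, ch in enumerate(params.synaptic_channels):
        base = params.density_of(ch)

        def _count(rate: float) -> int:
            mean = rate * volume_um3
            return int(round(mean)) if params.exact_counts else int(place_rng.poisson(mean))

        # multi-section synaptic puncta
        centers = _place_centers(place_rng, _count(base), lo, hi, min_sep_px, params.exact_counts)
        d_um = _border_distance_um(centers[:, 0] * px, centers[:, 1] * px, params)
        keep = flag_rng.random(len(centers)) < _loss_multiplier(d_um, params.near_loss_fraction)
        centers, d_um = centers[keep], d_um[keep]
        spans = flag_rng.integers(2, 4, size=len(centers))  # {2, 3}
        has_abeta = flag_rng.random(len(centers)) < _coloc_fraction(
            d_um, params.coloc_fraction_near, params.coloc_fraction_far
        )

        # single-section artifacts (uniform; they are noise, not biology)
        art_centers = _place_centers(
            place_rng,
            _count(params.single_slice_noise_rate),
            lo,
            hi,
            min_sep_px,
            params.exact_counts,
            existing=centers,
        )
        art_d = _border_distance_um(art_centers[:, 0] * px, art_centers[:, 1] * px, params)
        art_keep = art_d > 0  # artifacts still cannot sit on the dense core
        art_centers, art_d = art_centers[art_keep], art_d[art_keep]

        all_centers = np.concatenate([centers, art_centers]) if len(art_centers) else centers
        all_spans = np.concatenate([spans, np.ones(len(art_centers), dtype=int)])
        all_d = np.concatenate([d_um, art_d])
        all_flags = np.concatenate([has_abeta, np.zeros(len(art_centers), dtype=bool)])
        is_art = np.concatenate([np.zeros(len(centers), dtype=bool), np.ones(len(art_centers), dtype=bool)])
        starts = np.array(
            [flag_rng.integers(0, params.n_sections - s + 1) for s in all_spans], dtype=int
        )

        labels = _region_label(all_d)
        for k in range(len(all_centers)):
            cy_px, cx_px = all_centers[k]
            start, span = int(starts[k]), int(all_spans[k])
            for s in range(start, start + span):
                _render_blob(vox[s, :, :, ci], cy_px, cx_px, sigma, params.amplitude)
                if all_flags[k]:
                    _render_blob(vox[s, :, :, abeta_idx], cy_px, cx_px, sigma, params.amplitude)
            rows.append(
                {
                    "id": next_id,
                    "channel": ch,
                    "z_um": (start + (span - 1) / 2.0) * dz,
                    "y_um": cy_px * px,
                    "x_um": cx_px * px,
                    "section_start": start,
                    "section_span": span,
                    "is_single_slice": bool(is_art[k]),
                    "has_abeta": bool(all_flags[k]),
                    "border_distance_um": float(all_d[k]),
                    "region": str(labels[k]),
                }
            )
            next_id += 1

    truth_df = pd.DataFrame(
        rows,
        columns=[
            "id",
            "channel",
            "z_um",
            "y_um",
            "x_um",
            "section_start",
            "section_span",
            "is_single_slice",
            "has_abeta",
            "border_distance_um",
            "region",
        ],
    )

    # per-section rigid stage jitter (section 0 is the reference)
    shifts = np.zeros((params.n_sections, 2), dtype=int)
    if params.section_jitter_px > 0:
        shifts[1:] = jitter_rng.integers(
            -params.section_jitter_px, params.section_jitter_px + 1, size=(params.n_sections - 1, 2)
        )
    for s in range(params.n_sections):
        dy, dx = shifts[s]
        if dy or dx:
            for c in range(vox.shape[3]):
                vox[s, :, :, c] = shift_int(vox[s, :, :, c], dy, dx)

    if params.noise_sd > 0:
        vox += noise_rng.normal(0.0, params.noise_sd, size=vox.shape).astype(np.float32)
        np.clip(vox, 0.0, None, out=vox)

    # region volumes and realized (planted) densities on the inset volume
    yy = (np.arange(int(lo[0]), int(hi[0])) + 0.5) * px
    xx = (np.arange(int(lo[1]), int(hi[1])) + 0.5) * px
    d_grid = _border_distance_um(yy[:, None], xx[None, :], params)
    region_volumes = {
        name: float(np.count_nonzero(sel)) * px**2 * depth_um
        for name, sel in {
            "near": (d_grid > 0) & (d_grid <= NEAR_UM),
            "mid": (d_grid > NEAR_UM) & (d_grid < FAR_UM),
            "far": d_grid >= FAR_UM,
        }.items()
    }
    true_densities: dict[tuple[str, str], float] = {}
    true_coloc: dict[tuple[str, str], float] = {}
    multi = truth_df.loc[~truth_df["is_single_slice"].astype(bool)]
    for ch in params.synaptic_channels:
        for region in ("near", "far"):
            sel = multi[(multi.channel == ch) & (multi.region == region)]
            if region_volumes[region] > 0:
                true_densities[(ch, region)] = len(sel) / region_volumes[region]
            if len(sel):
                true_coloc[(ch, region)] = float(sel.has_abeta.mean())

    stack = SectionStack(
        voxels=vox,
        pixel_size_um=px,
        section_thickness_um=dz,
        channel_names=channels,
    )
    truth = GroundTruth(
        params={"kind": "at_stack", "seed": params.seed, "margin_px": margin},
        puncta=truth_df,
        applied_shifts_px=shifts,
        plaque_center_um=params.plaque_center_um,
        plaque_radius_um=params.plaque_radius_um if params.plaque_center_um else None,
        region_volumes_um3=region_volumes,
        true_densities=true_densities,
        true_coloc_fractions=true_coloc,
    )
    return stack, truth


def plaque_scenario_params(seed: int, **overrides) -> AtStackParams:
    """Canonical near/far plaque scenario: an 80×80 μm plane with a 6 μm-radius
    dense core near one corner, leaving both a <20 μm near zone and a >40 μm
    far zone for 10×10 μm ROI sampling."""
    defaults = dict(
        n_sections=10,
        plane_shape=(800, 800),
        plaque_center_um=(10.0, 10.0),
        plaque_radius_um=6.0,
        seed=seed,
    )
    defaults.update(overrides)
    return AtStackParams(**defaults)


def artifact_scenario_params(seed: int, n_multi: int = 40, n_single: int = 15) -> AtStackParams:
    """Scenario for validating single-slice artifact removal: an exact number
    of multi-section puncta and single-section artifacts, hard-core spaced so
    every planted object resolves as its own component.

    Stage jitter is disabled: registration of such ultra-sparse stacks has a
    residual of a pixel or two (few shared blobs per section pair), which is a
    property of alignment — validated separately on dense stacks — and would
    confound the filter-exactness property this scenario isolates.
    """
    base = AtStackParams(
        n_sections=10,
        plane_shape=(256, 256),
        synaptic_channels=("psd95",),
        exact_counts=True,
        min_separation_um=1.0,
        section_jitter_px=0,
        seed=seed,
    )
    v = base.planted_volume_um3
    return AtStackParams(
        n_sections=10,
        plane_shape=(256, 256),
        synaptic_channels=("psd95",),
        synapse_density_far=n_multi / v,
        single_slice_noise_rate=n_single / v,
        exact_counts=True,
        min_separation_um=1.0,
        section_jitter_px=0,
        seed=seed,
    )


def coloc_scenario_params(seed: int, n_synapses: int = 200, coloc_fraction: float = 0.30) -> AtStackParams:
    """Scenario for validating Aβ-at-synapse colocalization: a plaque-free
    stack with an exact number of synapses and a planted Aβ fraction."""
    kwargs = dict(
        n_sections=20,
        plane_shape=(200, 200),
        synaptic_channels=("psd95",),
        coloc_fraction_far=coloc_fraction,
        exact_counts=True,
        min_separation_um=0.8,
        seed=seed,
    )
    base = AtStackParams(**kwargs)
    return AtStackParams(synapse_density_far=n_synapses / base.planted_volume_um3, **kwargs)


# ---------------------------------------------------------------------------
# plaque histology sections
# ---------------------------------------------------------------------------


def generate_plaque_section(
    core_radius_um: float | tuple[float, float],
    halo_width_um: float,
    n_plaques: int,
    cortex_mask_shape: tuple[int, int],
    seed: int,
    *,
    pixel_size_um: float = 1.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.05,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a 2-channel histology scene: dense cores and cores-plus-halos.

    Channel 0 emulates the dense-plaque stain (ThioS): one disc per plaque.
    Channel 1 emulates the total-Aβ stain (AW7): the same discs widened by an
    annular halo of the stated width.  Plaques are placed uniformly without
    overlap (halos included) by bounded rejection sampling.  Truth records
    per-plaque rasterized core area and the scene's plaque burden (% of the
    cortex mask covered by cores).
    """
    if halo_width_um < 0:
        raise ValueError("halo width must be >= 0")
    lo_r, hi_r = (core_radius_um, core_radius_um) if np.isscalar(core_radius_um) else core_radius_um
    if lo_r <= 0:
        raise ValueError("core radius must be positive")
    rng = np.random.default_rng(seed)
    h, w = cortex_mask_shape
    px = pixel_size_um

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    while len(centers) < n_plaques:
        if attempts > 200 * max(n_plaques, 1):
            raise ValueError(f"could not place {n_plaques} non-overlapping plaques")
        attempts += 1
        r_um = float(rng.uniform(lo_r, hi_r))
        reach_px = (r_um + halo_width_um) / px + 1
        if 2 * reach_px >= min(h, w):
            raise ValueError("plaque (with halo) does not fit in the cortex mask")
        c = rng.uniform([reach_px, reach_px], [h - reach_px, w - reach_px])
        if all(
            np.hypot(c[0] - cy, c[1] - cx) * px > r_um + halo_width_um + rr + halo_width_um + 2 * px
            for (cy, cx), rr in zip(centers, radii)
        ):
            centers.append((float(c[0]), float(c[1])))
            radii.append(r_um)

    core = np.zeros((h, w), dtype=bool)
    diffuse = np.zeros((h, w), dtype=bool)
    rows = []
    for i, ((cy, cx), r_um) in enumerate(zip(centers, radii)):
        disc = rasterize_disc((h, w), (cy, cx), r_um / px)
        halo = rasterize_disc((h, w), (cy, cx), (r_um + halo_width_um) / px)
        core |= disc
        diffuse |= halo
        rows.append(
            {
                "id": i,
                "center_y_px": cy,
                "center_x_px": cx,
                "core_radius_um": r_um,
                "core_area_px": int(disc.sum()),
                "core_area_um2": float(disc.sum()) * px**2,
                "halo_width_um": halo_width_um,
            }
        )

    image = np.stack(
        [amplitude * core.astype(np.float32), amplitude * diffuse.astype(np.float32)], axis=-1
    )
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=image.shape).astype(np.float32)
        np.clip(image, 0.0, None, out=image)

    plaques_df = pd.DataFrame(
        rows,
        columns=[
            "id", "center_y_px", "center_x_px", "core_radius_um",
            "core_area_px", "core_area_um2", "halo_width_um",
        ],
    )
    truth = GroundTruth(
        params={"kind": "plaque_section", "seed": seed, "pixel_size_um": px},
        plaques=plaques_df,
        burden_percent=100.0 * float(core.sum()) / core.size,
        halo_thickness_um=halo_width_um if n_plaques > 0 else None,
    )
    return image, truth


# ---------------------------------------------------------------------------
# neurite polylines
# ---------------------------------------------------------------------------


def _polyline_ratio(points: np.ndarray) -> tuple[float, float, float]:
    seg = np.diff(points, axis=0)
    length = float(np.sqrt((seg**2).sum(axis=1)).sum())
    chord = float(np.hypot(*(points[-1] - points[0])))
    return length, chord, length / chord


def generate_neurites(
    n: int,
    length_um: float,
    tortuosity_spec: dict,
    seed: int,
    *,
    field_size_um: float = 200.0,
    points_per_trace: int = 200,
) -> tuple[list[np.ndarray], GroundTruth]:
    """Emit traced neurite polylines ((y, x) μm) with analytic curvature truth.

    ``tortuosity_spec`` selects the family:
      {"kind": "straight"}                         — curvature ratio exactly 1
      {"kind": "arc", "theta_rad": θ}              — ratio (θ/2)/sin(θ/2)
      {"kind": "random_walk", "turn_sd_rad": s}    — ratio from the realized path

    Traces shorter than the 20 μm traceability floor are rejected at the
    parameter level, mirroring the measurement rule.
    """
    if length_um <= 20.0:
        raise ValueError("traces must exceed the 20 μm traceability floor")
    kind = tortuosity_spec.get("kind", "straight")
    rng = np.random.default_rng(seed)

    traces: list[np.ndarray] = []
    rows = []
    for i in range(n):
        start = rng.uniform(0.0, field_size_um, size=2)
        phi = rng.uniform(0.0, 2 * np.pi)
        if kind == "straight":
            t = np.linspace(0.0, length_um, points_per_trace)
            pts = start + np.outer(t, [np.sin(phi), np.cos(phi)])
            true_ratio = 1.0
        elif kind == "arc":
            theta = float(tortuosity_spec["theta_rad"])
            if not 0 < theta < 2 * np.pi:
                raise ValueError("arc angle must be in (0, 2π)")
            radius = length_um / theta
            a = phi + np.linspace(0.0, theta, points_per_trace)
            pts = start + radius * np.stack([np.sin(a) - np.sin(phi), np.cos(a) - np.cos(phi)], axis=1)
            true_ratio = (theta / 2.0) / math.sin(theta / 2.0)
        elif kind == "random_walk":
            turn_sd = float(tortuosity_spec.get("turn_sd_rad", 0.3))
            n_steps = points_per_trace - 1
            step = length_um / n_steps
            headings = phi + np.cumsum(rng.normal(0.0, turn_sd, size=n_steps))
            steps = step * np.stack([np.sin(headings), np.cos(headings)], axis=1)
            pts = np.vstack([start, start + np.cumsum(steps, axis=0)])
            true_ratio = _polyline_ratio(pts)[2]
        else:
            raise ValueError(f"unknown tortuosity kind {kind!r}")
        length, chord, _ = _polyline_ratio(pts)
        traces.append(pts)
        rows.append(
            {
                "id": i,
                "kind": kind,
                "length_um": length,
                "end_to_end_um": chord,
                "curvature_ratio": true_ratio,
            }
        )

    truth = GroundTruth(
        params={"kind": "neurites", "seed": seed, "spec": dict(tortuosity_spec)},
        neurites=pd.DataFrame(rows, columns=["id", "kind", "length_um", "end_to_end_um", "curvature_ratio"]),
    )
    return traces, truth


# ---------------------------------------------------------------------------
# cell point fields
# ---------------------------------------------------------------------------


def generate_cell_field(
    base_density: float,
    near_depletion: float,
    plaque_geometry: tuple[tuple[float, float], float] | None,
    volume: tuple[float, float, float],
    seed: int,
    *,
    cell_type: str = "neuron",
    near_radius_um: float = 30.0,
) -> tuple[CellField, GroundTruth]:
    """Homogeneous Poisson cell field with near-plaque depletion.

    ``plaque_geometry`` is ``((cy, cx) μm, radius μm)`` for an in-plane dense
    core, or None.  Intensity is multiplied by ``1 - near_depletion`` for
    points whose in-plane distance to the core border is at most
    ``near_radius_um`` (either side of the border).  Truth records the
    expected near/far counts.
    """
    if base_density < 0:
        raise ValueError("density must be >= 0")
    if not 0.0 <= near_depletion <= 1.0:
        raise ValueError("depletion must be in [0, 1]")
    rng = np.random.default_rng(seed)
    vz, vy, vx = volume
    total = vz * vy * vx
    n = rng.poisson(base_density * total)
    pts = rng.uniform([0, 0, 0], [vz, vy, vx], size=(n, 3))

    if plaque_geometry is not None:
        (cy, cx), r = plaque_geometry
        d = np.abs(np.hypot(pts[:, 1] - cy, pts[:, 2] - cx) - r)
        near = d <= near_radius_um
    else:
        near = np.zeros(n, dtype=bool)
    keep = ~near | (rng.random(n) < 1.0 - near_depletion)
    pts = pts[keep]
    near = near[keep]

    # near-region volume by in-plane grid integration at 0.5 μm resolution
    if plaque_geometry is not None:
        step = 0.5
        yy = np.arange(step / 2, vy, step)
        xx = np.arange(step / 2, vx, step)
        (cy, cx), r = plaque_geometry
        dg = np.abs(np.hypot(yy[:, None] - cy, xx[None, :] - cx) - r)
        near_area = float(np.count_nonzero(dg <= near_radius_um)) * step**2
    else:
        near_area = 0.0
    v_near = near_area * vz
    v_far = total - v_near

    field_df = pd.DataFrame(
        {
            "z_um": pts[:, 0],
            "y_um": pts[:, 1],
            "x_um": pts[:, 2],
            "region": np.where(near, "near", "far"),
        }
    )
    field = CellField(coordinates=pts.copy(), cell_type=cell_type, volume_um=(vz, vy, vx))
    truth = GroundTruth(
        params={"kind": "cell_field", "seed": seed, "cell_type": cell_type},
        cells=field_df,
        plaque_center_um=None if plaque_geometry is None else plaque_geometry[0],
        plaque_radius_um=None if plaque_geometry is None else plaque_geometry[1],
        region_volumes_um3={"near": v_near, "far": v_far},
        expected_counts={
            "near": base_density * (1.0 - near_depletion) * v_near,
            "far": base_density * v_far,
        },
    )
    return field, truth
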