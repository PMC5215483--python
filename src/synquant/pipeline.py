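"""End-to-end wiring: synthetic stack → align → threshold → puncta → ROIs → stats.

These helpers exist so the whole chain can be run (and re-run
deterministically) with one call: per-stack analysis, per-animal near/far
summaries, and multi-animal simulated experiments feeding the two-way
genotype × plaque-distance ANOVA.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import puncta as puncta_mod
from . import synapses
from .stack import SectionStack, align_stack, despeckle, threshold_channel
from .stats import two_way_distance_genotype
from .synthetic import AtStackParams, generate_at_stack, plaque_scenario_params

__all__ = [
    "analyze_at_stack",
    "run_animal",
    "simulate_experiment",
    "simulate_two_way_summaries",
    "run_pipeline_to_csv",
]

DEFAULT_THRESHOLD = 0.5  # half the rendered blob amplitude


def analyze_at_stack(
    stack: SectionStack,
    *,
    synaptic_channels: tuple[str, ...] = ("synapsin", "psd95"),
    reference_channel: str = "synapsin",
    threshold: float = DEFAULT_THRESHOLD,
    min_voxels: int = 4,
    n_near: int = 4,
    n_far: int = 4,
    roi_seed: int = 0,
    align: bool = True,
    min_plaque_area_um2: float = 5.0,
) -> dict:
    """Run the full array-tomography analysis on one stack.

    Returns a dict with the aligned stack, per-channel filtered puncta, the
    Aβ binary mask, the selected ROIs and the flat ROI table.
    """
    if align:
        stack = align_stack(stack, reference_channel)

    puncta_by_channel: dict[str, list] = {}
    for ch in synaptic_channels:
        mask = despeckle(threshold_channel(stack, ch, method="fixed", level=threshold))
        detected = puncta_mod.detect_puncta(mask, min_voxels=min_voxels)
        puncta_by_channel[ch] = puncta_mod.remove_single_slice(detected)

    abeta_mask = despeckle(threshold_channel(stack, "abeta", method="fixed", level=threshold))

    plaque_mask2d = np.zeros(stack.plane_shape, dtype=bool)
    if "plaque" in stack.channel_names:
        plaque_bin = threshold_channel(stack, "plaque", method="fixed", level=threshold)
        projected = plaque_bin.mask.any(axis=0)
        # drop isolated noise crossings: a dense core is orders of magnitude larger
        min_px = int(round(min_plaque_area_um2 / stack.pixel_size_um**2))
        labels, n = ndimage.label(projected)
        if n:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            plaque_mask2d = np.isin(labels, np.flatnonzero(sizes >= min_px))

    rois = synapses.select_rois(plaque_mask2d, stack, n_near, n_far, roi_seed)
    synapses.quantify_rois(rois, puncta_by_channel, abeta_mask)
    return {
        "stack": stack,
        "puncta_by_channel": puncta_by_channel,
        "abeta_mask": abeta_mask,
        "plaque_mask": plaque_mask2d,
        "rois": rois,
        "roi_table": synapses.roi_table(rois),
    }


def run_animal(params: AtStackParams, *, n_near: int = 4, n_far: int = 4) -> pd.DataFrame:
    """Generate one animal's stack, analyze it, and summarize near/far densities.

    Returns one row per (channel, distance class): the mean ROI density and
    colocalization fraction.
    """
    stack, _ = generate_at_stack(params)
    result = analyze_at_stack(stack, n_near=n_near, n_far=n_far, roi_seed=params.seed)
    table = result["roi_table"]
    rows = []
    for ch in ("synapsin", "psd95"):
        for cls, grp in table.groupby("distance_class"):
            coloc_col = grp.get(f"coloc_{ch}")
            rows.append(
                {
                    "channel": ch,
                    "distance_class": cls,
                    "density": float(grp[f"density_{ch}"].mean()),
                    "coloc_fraction": float(coloc_col.mean()) if coloc_col is not None else np.nan,
                    "n_rois": int(len(grp)),
                }
            )
    return pd.DataFrame(rows)


def simulate_experiment(
    n_animals_a: int,
    n_animals_b: int,
    seed: int,
    *,
    channel: str = "psd95",
    genotype_names: tuple[str, str] = ("APP_PS1", "APP_PS1_rTg21221"),
    **param_overrides,
) -> pd.DataFrame:
    """Full-pipeline multi-animal experiment with identical planted biology.

    Every animal of both genotypes is generated from the same plaque scenario
    (40% planted near loss by default), so a genotype effect is absent by
    construction while a plaque-distance effect is present.  Returns tidy
    per-animal near/far density summaries ready for the two-way ANOVA.
    """
    root = np.random.default_rng(seed)
    rows = []
    for genotype, n_animals in zip(genotype_names, (n_animals_a, n_animals_b)):
        for a in range(n_animals):
            animal_seed = int(root.integers(2**31 - 1))
            params = plaque_scenario_params(animal_seed, **param_overrides)
            summary = run_animal(params)
            sel = summary[summary.channel == channel]
            for _, r in sel.iterrows():
                rows.append(
                    {
                        "animal_id": f"{genotype}_{a}",
                        "genotype": genotype,
                        "distance_class": r["distance_class"],
                        "value": r["density"],
                    }
                )
    return pd.DataFrame(rows)


def simulate_two_way_summaries(
    n_animals_a: int,
    n_animals_b: int,
    seed: int,
    *,
    far_density: float = 0.6,
    near_loss_fraction: float = 0.4,
    genotype_effect: float = 0.0,
    animal_cv: float = 0.15,
    measurement_cv: float = 0.08,
    genotype_names: tuple[str, str] = ("APP_PS1", "APP_PS1_rTg21221"),
) -> pd.DataFrame:
    """Summary-level simulation of a near/far × genotype experiment.

    Each animal has a baseline far density drawn with between-animal
    coefficient of variation ``animal_cv``; its near value is depressed by
    ``near_loss_fraction``; both summaries carry independent measurement
    noise ``measurement_cv`` (the ROI-sampling error of a per-animal mean).
    ``genotype_effect`` scales the second genotype's densities (0 = none).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gi, (genotype, n_animals) in enumerate(zip(genotype_names, (n_animals_a, n_animals_b))):
        geno_scale = 1.0 + (genotype_effect if gi == 1 else 0.0)
        for a in range(n_animals):
            base = far_density * geno_scale * (1.0 + rng.normal(0.0, animal_cv))
            for cls, level in (("near", base * (1.0 - near_loss_fraction)), ("far", base)):
                rows.append(
                    {
                        "animal_id": f"{genotype}_{a}",
                        "genotype": genotype,
                        "distance_class": cls,
                        "value": level * (1.0 + rng.normal(0.0, measurement_cv)),
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline_to_csv(out_dir: str | Path, seed: int, **param_overrides) -> list[Path]:
    """Run the single-stack pipeline and write its tables as CSV files.

    Used to demonstrate end-to-end determinism: the same seed must yield
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = plaque_scenario_params(seed, **param_overrides)
    stack, truth = generate_at_stack(params)
    result = analyze_at_stack(stack, roi_seed=seed)

    paths = []
    for name, df in (
        ("roi_table.csv", result["roi_table"]),
        ("truth_puncta.csv", truth.puncta),
        (
            "puncta_table.csv",
            pd.concat(
                [puncta_mod.puncta_table(v) for v in result["puncta_by_channel"].values()],
                ignore_index=True,
            ),
        ),
    ):
        path = out_dir / name
        df.to_csv(path, index=False)
        paths.append(path)
    offsets = result["stack"].alignment_offsets
    path = out_dir / "alignment_offsets.csv"
    pd.DataFrame(offsets, columns=["dy_px", "dx_px"]).to_csv(path, index=False)
    paths.append(path)
    return paths


def distance_effect_anova(summaries: pd.DataFrame):
    """Convenience: the two-way genotype × distance ANOVA on tidy summaries."""
    return two_way_distance_genotype(summaries)
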