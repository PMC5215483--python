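"""Generator self-tests: determinism, conservation, truth-table consistency."""

import numpy as np
import pandas as pd
import pytest

from synquant import (
    AtStackParams,
    artifact_scenario_params,
    coloc_scenario_params,
    generate_at_stack,
    generate_cell_field,
    generate_neurites,
    generate_plaque_section,
    plaque_scenario_params,
)
from synquant.synthetic import _coloc_fraction, _loss_multiplier

from oracles import polyline_curvature


def small_params(**overrides):
    defaults = dict(n_sections=6, plane_shape=(96, 96), seed=3)
    defaults.update(overrides)
    return AtStackParams(**defaults)


# ----------------------------------------------------------- at stacks ----


def test_same_seed_is_byte_identical():
    a_stack, a_truth = generate_at_stack(small_params())
    b_stack, b_truth = generate_at_stack(small_params())
    assert np.array_equal(a_stack.voxels, b_stack.voxels)
    pd.testing.assert_frame_equal(a_truth.puncta, b_truth.puncta)
    assert np.array_equal(a_truth.applied_shifts_px, b_truth.applied_shifts_px)


def test_different_seeds_differ():
    a_stack, _ = generate_at_stack(small_params(seed=3))
    b_stack, _ = generate_at_stack(small_params(seed=4))
    assert not np.array_equal(a_stack.voxels, b_stack.voxels)


def test_exact_counts_match_requested():
    params = artifact_scenario_params(0, n_multi=40, n_single=15)
    _, truth = generate_at_stack(params)
    multi = truth.puncta[~truth.puncta.is_single_slice]
    single = truth.puncta[truth.puncta.is_single_slice]
    assert len(multi) == 40
    assert len(single) == 15
    assert (multi.section_span >= 2).all()
    assert (single.section_span == 1).all()


def test_zero_density_yields_empty_truth():
    params = small_params(synapse_density_far=0.0, single_slice_noise_rate=0.0)
    _, truth = generate_at_stack(params)
    assert truth.puncta.empty


def test_puncta_planted_inside_margin():
    params = small_params()
    _, truth = generate_at_stack(params)
    margin_um = truth.params["margin_px"] * params.pixel_size_um
    h_um = params.plane_shape[0] * params.pixel_size_um
    assert (truth.puncta.y_um >= margin_um).all()
    assert (truth.puncta.y_um <= h_um - margin_um).all()
    assert (truth.puncta.x_um >= margin_um).all()
    assert (truth.puncta.x_um <= h_um - margin_um).all()


def test_applied_shifts_shape_and_bounds():
    params = small_params(section_jitter_px=4)
    _, truth = generate_at_stack(params)
    shifts = truth.applied_shifts_px
    assert shifts.shape == (params.n_sections, 2)
    assert (shifts[0] == 0).all()
    assert np.abs(shifts).max() <= 4


def test_no_puncta_inside_dense_core():
    _, truth = generate_at_stack(plaque_scenario_params(1, plane_shape=(400, 400)))
    assert (truth.puncta.border_distance_um > 0).all()
    # region labels consistent with recorded distances
    d = truth.puncta.border_distance_um
    assert (truth.puncta.region[d <= 20].eq("near")).all()
    assert (truth.puncta.region[d > 40].eq("far")).all()


def test_loss_and_coloc_profiles():
    d = np.array([-1.0, 5.0, 20.0, 30.0, 40.0, 55.0])
    mult = _loss_multiplier(d, 0.4)
    assert mult == pytest.approx([0.0, 0.6, 0.6, 0.8, 1.0, 1.0])
    frac = _coloc_fraction(d, 0.30, 0.10)
    assert frac == pytest.approx([0.30, 0.30, 0.30, 0.20, 0.10, 0.10])


def test_planted_coloc_fraction_near_target():
    _, truth = generate_at_stack(coloc_scenario_params(0, n_synapses=200, coloc_fraction=0.30))
    multi = truth.puncta[~truth.puncta.is_single_slice]
    assert len(multi) == 200
    planted = multi.has_abeta.mean()
    # 4 sigma binomial band around 0.30 for n = 200
    assert abs(planted - 0.30) < 4 * np.sqrt(0.3 * 0.7 / 200)
    assert truth.true_coloc_fractions[("psd95", "far")] == pytest.approx(planted)


def test_true_densities_consistent_with_truth_table():
    params = plaque_scenario_params(2, plane_shape=(500, 500))
    _, truth = generate_at_stack(params)
    multi = truth.puncta[~truth.puncta.is_single_slice]
    for ch in ("synapsin", "psd95"):
        for region in ("near", "far"):
            n = len(multi[(multi.channel == ch) & (multi.region == region)])
            expected = n / truth.region_volumes_um3[region]
            assert truth.true_densities[(ch, region)] == pytest.approx(expected)


def test_params_validation():
    with pytest.raises(ValueError):
        AtStackParams(n_sections=1)
    with pytest.raises(ValueError):
        AtStackParams(near_loss_fraction=1.5)
    with pytest.raises(ValueError):
        AtStackParams(punctum_radius_um=0.01)


# ---------------------------------------------------- plaque histology ----


def test_plaque_section_zero_plaques():
    image, truth = generate_plaque_section(10.0, 5.0, 0, (128, 128), 0, noise_sd=0.0)
    assert truth.plaques.empty
    assert truth.burden_percent == 0.0
    assert image.max() == 0.0


def test_plaque_section_burden_is_pixel_tally():
    _, truth = generate_plaque_section(8.0, 4.0, 3, (256, 256), 5, noise_sd=0.0)
    # plaques never overlap, so the union is the sum of per-plaque areas
    expected = 100.0 * truth.plaques.core_area_px.sum() / (256 * 256)
    assert truth.burden_percent == pytest.approx(expected)


def test_plaque_section_nonoverlap():
    _, truth = generate_plaque_section((5.0, 9.0), 4.0, 5, (300, 300), 7, noise_sd=0.0)
    t = truth.plaques
    for i in range(len(t)):
        for j in range(i + 1, len(t)):
            d = np.hypot(
                t.center_y_px[i] - t.center_y_px[j], t.center_x_px[i] - t.center_x_px[j]
            )
            assert d > t.core_radius_um[i] + t.core_radius_um[j] + 2 * 4.0


def test_plaque_too_large_raises():
    with pytest.raises(ValueError):
        generate_plaque_section(100.0, 10.0, 1, (64, 64), 0)


# -------------------------------------------------------------- neurites ----


def test_neurites_straight_ratio_one():
    _, truth = generate_neurites(5, 40.0, {"kind": "straight"}, 0)
    assert truth.neurites.curvature_ratio.to_numpy() == pytest.approx(1.0, abs=1e-9)


def test_neurites_semicircle_analytic():
    traces, truth = generate_neurites(3, 30.0, {"kind": "arc", "theta_rad": np.pi}, 1)
    assert truth.neurites.curvature_ratio.to_numpy() == pytest.approx(np.pi / 2, abs=1e-12)
    for pts in traces:
        assert polyline_curvature(pts) == pytest.approx(np.pi / 2, abs=1e-3)


def test_neurites_random_walk_truth_matches_realized():
    traces, truth = generate_neurites(10, 35.0, {"kind": "random_walk", "turn_sd_rad": 0.4}, 2)
    for pts, ratio in zip(traces, truth.neurites.curvature_ratio):
        assert polyline_curvature(pts) == pytest.approx(ratio, rel=1e-9)


def test_neurites_floor_enforced():
    with pytest.raises(ValueError):
        generate_neurites(1, 20.0, {"kind": "straight"}, 0)


# ----------------------------------------------------------- cell fields ----


def test_cell_field_points_inside_volume():
    field, _ = generate_cell_field(1e-3, 0.0, None, (50.0, 100.0, 100.0), 0)
    assert (field.coordinates >= 0).all()
    assert (field.coordinates <= np.array([50.0, 100.0, 100.0])).all()


def test_cell_field_full_depletion_clears_near_zone():
    field, _ = generate_cell_field(
        2e-3, 1.0, ((100.0, 100.0), 15.0), (50.0, 200.0, 200.0), 3
    )
    d = np.abs(np.hypot(field.coordinates[:, 1] - 100.0, field.coordinates[:, 2] - 100.0) - 15.0)
    assert (d > 30.0).all()


def test_cell_field_poisson_mean():
    counts = [
        len(generate_cell_field(1e-3, 0.0, None, (20.0, 50.0, 50.0), s)[0]) for s in range(100)
    ]
    mean = np.mean(counts)  # Poisson(50): sample mean sd ~0.7 over 100 draws
    assert abs(mean - 50.0) < 3.0


def test_cell_field_depletion_ratio_recovered():
    near_n = far_n = 0
    near_exp = far_exp = 0.0
    for s in range(20):
        field, truth = generate_cell_field(
            2e-3, 0.3, ((100.0, 100.0), 15.0), (50.0, 200.0, 200.0), s
        )
        near_n += (truth.cells.region == "near").sum()
        far_n += (truth.cells.region == "far").sum()
        near_exp += truth.expected_counts["near"]
        far_exp += truth.expected_counts["far"]
    assert near_n / near_exp == pytest.approx(1.0, abs=0.05)
    assert far_n / far_exp == pytest.approx(1.0, abs=0.05)
    near_density = near_n / near_exp * (1 - 0.3)
    far_density = far_n / far_exp
    assert near_density / far_density == pytest.approx(0.7, abs=0.05)
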