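"""Per-animal aggregation, the normality gate, and calibration of both designs."""

import numpy as np
import pandas as pd
import pytest

from synquant import aggregate_per_animal, compare_groups, two_way_distance_genotype
from synquant.pipeline import simulate_two_way_summaries


def obs(rows):
    return pd.DataFrame(rows, columns=["animal_id", "genotype", "value"])


def group_df(groups: dict[str, list[float]]):
    rows = []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append({"animal_id": f"{g}{i}", "genotype": g, "value": v})
    return pd.DataFrame(rows)


# ----------------------------------------------------------- aggregation ----


def test_aggregate_small_n_uses_flagged_mean():
    out = aggregate_per_animal(obs([("a1", "wt", 1.0), ("a1", "wt", 2.0)]), "m")
    assert len(out) == 1
    assert out[0].value == 1.5
    assert out[0].aggregation == "mean"
    assert out[0].flagged
    assert out[0].normality_p is None


def test_aggregate_normal_data_uses_mean():
    rng = np.random.default_rng(0)
    vals = rng.normal(10.0, 1.0, size=30)
    df = obs([("a1", "wt", v) for v in vals])
    out = aggregate_per_animal(df, "m")
    assert out[0].aggregation == "mean"
    assert out[0].value == pytest.approx(vals.mean())
    assert out[0].normality_p >= 0.05


def test_aggregate_skewed_data_uses_median():
    rng = np.random.default_rng(1)
    vals = np.exp(rng.normal(0.0, 1.5, size=60))
    df = obs([("a1", "wt", v) for v in vals])
    out = aggregate_per_animal(df, "m")
    assert out[0].aggregation == "median"
    assert out[0].value == pytest.approx(np.median(vals))


def test_aggregate_median_branch_rate_on_lognormal():
    hits = 0
    for seed in range(100):
        vals = np.exp(np.random.default_rng(seed).normal(0.0, 1.5, size=60))
        out = aggregate_per_animal(obs([("a1", "wt", v) for v in vals]), "m")
        hits += out[0].aggregation == "median"
    assert hits >= 90  # Shapiro-Wilk has high power against sigma=1.5 lognormal at n=60


def test_aggregate_constant_values_treated_as_normal():
    out = aggregate_per_animal(obs([("a1", "wt", 2.0)] * 5), "m")
    assert out[0].aggregation == "mean"
    assert out[0].normality_p == 1.0


def test_aggregate_missing_column_raises():
    with pytest.raises(ValueError):
        aggregate_per_animal(pd.DataFrame({"value": [1.0]}), "m")


# ------------------------------------------------------- group comparison ----


def test_two_normal_groups_use_t_test():
    rng = np.random.default_rng(2)
    res = compare_groups(
        group_df({"wt": rng.normal(0, 1, 10).tolist(), "tg": rng.normal(3, 1, 10).tolist()})
    )
    assert res.test_name == "t-test"
    assert res.df == 18
    assert res.p_value < 0.01
    assert any("parametric" in line for line in res.decision_trail)


def test_skewed_groups_use_mann_whitney():
    rng = np.random.default_rng(3)
    a = np.exp(rng.normal(0, 1.5, 25)).tolist()
    b = np.exp(rng.normal(1, 1.5, 25)).tolist()
    res = compare_groups(group_df({"wt": a, "tg": b}))
    assert res.test_name == "Mann-Whitney U"
    assert any("nonparametric" in line for line in res.decision_trail)


def test_three_groups_anova_with_tukey():
    rng = np.random.default_rng(4)
    res = compare_groups(
        group_df(
            {
                "a": rng.normal(0, 1, 8).tolist(),
                "b": rng.normal(0, 1, 8).tolist(),
                "c": rng.normal(4, 1, 8).tolist(),
            }
        )
    )
    assert res.test_name == "one-way ANOVA"
    assert res.df == (2, 21)
    assert res.p_value < 0.01
    assert res.posthoc is not None  # Tukey HSD table attached
    assert any("Tukey" in line for line in res.decision_trail)


def test_three_skewed_groups_use_kruskal():
    rng = np.random.default_rng(5)
    groups = {g: np.exp(rng.normal(0, 1.5, 20)).tolist() for g in ("a", "b", "c")}
    res = compare_groups(group_df(groups))
    assert res.test_name == "Kruskal-Wallis"


def test_identical_groups_give_t_zero_p_one():
    res = compare_groups(group_df({"wt": [2.0, 2.0, 2.0], "tg": [2.0, 2.0, 2.0]}))
    assert res.test_name == "t-test"
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_zero_variance_group_falls_back_to_nonparametric():
    rng = np.random.default_rng(0)
    res = compare_groups(
        group_df({"wt": [2.0] * 4, "tg": rng.normal(3, 1, 20).tolist()})
    )
    assert res.test_name == "Mann-Whitney U"
    assert any("zero-variance" in line for line in res.decision_trail)


def test_group_size_validation():
    with pytest.raises(ValueError):
        compare_groups(group_df({"wt": [1.0, 2.0]}))
    with pytest.raises(ValueError):
        compare_groups(group_df({"wt": [1.0, 2.0], "tg": [1.0]}))


def test_type_one_error_calibrated_under_null():
    rejections = 0
    n_sim = 500
    for seed in range(n_sim):
        rng = np.random.default_rng(seed)
        df = group_df({"wt": rng.normal(0, 1, 6).tolist(), "tg": rng.normal(0, 1, 6).tolist()})
        rejections += compare_groups(df).p_value < 0.05
    assert 0.02 <= rejections / n_sim <= 0.08


def test_power_against_two_sd_shift():
    rejections = 0
    n_sim = 300
    for seed in range(n_sim):
        rng = np.random.default_rng(10_000 + seed)
        df = group_df({"wt": rng.normal(0, 1, 20).tolist(), "tg": rng.normal(2, 1, 20).tolist()})
        rejections += compare_groups(df).p_value < 0.05
    assert rejections / n_sim >= 0.95


# --------------------------------------------------------- two-way design ----


def test_two_way_detects_planted_distance_effect():
    df = simulate_two_way_summaries(6, 5, seed=0)
    res = two_way_distance_genotype(df)
    assert res.test_name == "two-way ANOVA"
    assert res.p_value < 0.05  # the distance effect
    assert res.effects is not None
    assert {"C(genotype)", "C(distance)", "C(genotype):C(distance)"} <= set(res.effects.index)


def test_two_way_all_equal_degenerates_to_zero_f():
    rows = []
    for a in range(4):
        for cls in ("near", "far"):
            rows.append({"animal_id": f"a{a}", "genotype": "wt" if a < 2 else "tg", "distance_class": cls, "value": 1.0})
    res = two_way_distance_genotype(pd.DataFrame(rows))
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_two_way_drops_incomplete_animals_and_logs():
    df = simulate_two_way_summaries(4, 4, seed=1)
    df = df[~((df.animal_id == df.animal_id.iloc[0]) & (df.distance_class == "near"))]
    res = two_way_distance_genotype(df)
    assert any("dropped animals" in line for line in res.decision_trail)


def test_two_way_needs_two_genotypes():
    df = simulate_two_way_summaries(4, 4, seed=2)
    with pytest.raises(ValueError):
        two_way_distance_genotype(df[df.genotype == df.genotype.iloc[0]])


def test_two_way_genotype_null_calibrated_in_planted_world():
    # the planted world has no genotype effect and no animal-level random
    # effect (every animal is generated from the same biology), so the
    # genotype F-test should reject at ~alpha
    hits = 0
    n_sim = 300
    for seed in range(n_sim):
        df = simulate_two_way_summaries(6, 5, seed=20_000 + seed, animal_cv=0.0)
        res = two_way_distance_genotype(df)
        hits += res.effects.loc["C(genotype)", "PR(>F)"] < 0.05
    assert 0.01 <= hits / n_sim <= 0.10


def test_two_way_permuted_genotype_labels_give_uniform_p():
    df = simulate_two_way_summaries(6, 6, seed=77, animal_cv=0.0)
    animals = df.animal_id.unique()
    rng = np.random.default_rng(0)
    pvals = []
    for _ in range(500):
        labels = rng.permutation(["a"] * 6 + ["b"] * 6)
        relab = dict(zip(animals, labels))
        perm = df.assign(genotype=df.animal_id.map(relab))
        res = two_way_distance_genotype(perm)
        pvals.append(res.effects.loc["C(genotype)", "PR(>F)"])
    pvals = np.asarray(pvals)
    # approximately uniform: a fixed dataset permutes over only C(12,6)
    # assignments, so allow dataset-level wobble around exact uniformity
    assert abs(np.mean(pvals < 0.05) - 0.05) <= 0.05
    assert abs(pvals.mean() - 0.5) <= 0.1
    grid = np.linspace(0.0, 1.0, 21)
    ecdf = np.array([(pvals <= g).mean() for g in grid])
    assert np.abs(ecdf - grid).max() <= 0.15
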