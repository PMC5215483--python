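"""Per-animal statistics with a normality-gated test selection.

The experimental unit is the animal: raw observations (per-ROI densities,
per-plaque areas, per-trace ratios ...) are first aggregated to one value per
animal — the mean when Shapiro–Wilk does not reject normality of that
animal's observations at α = 0.05, the median otherwise.  Group comparisons
then apply a Shapiro–Wilk gate on residuals: parametric branch (Student's
t-test for two groups, one-way ANOVA with Tukey's post hoc for more) or
nonparametric branch (Mann–Whitney U for two, Kruskal–Wallis for more).  The
near/far × genotype question uses a two-way ANOVA with type-II sums of
squares.  Every branch decision is recorded in the result's decision trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ALPHA",
    "AnimalSummary",
    "TestResult",
    "aggregate_per_animal",
    "compare_groups",
    "two_way_distance_genotype",
]

ALPHA = 0.05
_MIN_N_SHAPIRO = 3


@dataclass(frozen=True)
class AnimalSummary:
    """One animal's aggregated value for one metric."""

    animal_id: str
    genotype: str
    metric: str
    value: float
    aggregation: str  # 'mean' or 'median'
    n_observations: int
    normality_p: float | None = None
    flagged: bool = False  # normality untestable (n < 3): mean used


@dataclass
class TestResult:
    """Outcome of one statistical comparison with its full decision trail."""

    test_name: str
    statistic: float
    df: tuple | float | None
    p_value: float
    group_summaries: dict = field(default_factory=dict)
    normality_p: float | None = None
    decision_trail: list[str] = field(default_factory=list)
    effects: pd.DataFrame | None = None  # per-effect table for factorial designs
    posthoc: object | None = None

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if not self.decision_trail:
            raise ValueError("decision trail must not be empty")


def aggregate_per_animal(
    observations: pd.DataFrame,
    metric: str,
    *,
    value_col: str = "value",
    animal_col: str = "animal_id",
    genotype_col: str = "genotype",
    alpha: float = ALPHA,
) -> list[AnimalSummary]:
    """Collapse raw observations to one value per animal.

    Mean when the animal's observations look normal (Shapiro–Wilk p ≥ α),
    median otherwise; with fewer than 3 observations normality is untestable,
    the mean is used and the summary is flagged.
    """
    for col in (value_col, animal_col, genotype_col):
        if col not in observations.columns:
            raise ValueError(f"observations lack required column {col!r}")
    out: list[AnimalSummary] = []
    for (animal, genotype), grp in observations.groupby([animal_col, genotype_col], sort=True):
        vals = grp[value_col].to_numpy(float)
        if len(vals) < _MIN_N_SHAPIRO:
            out.append(
                AnimalSummary(str(animal), str(genotype), metric, float(np.mean(vals)), "mean", len(vals), None, True)
            )
            continue
        if np.ptp(vals) == 0:
            p_norm = 1.0  # constant data: nothing to reject
        else:
            p_norm = float(sps.shapiro(vals).pvalue)
        agg = "mean" if p_norm >= alpha else "median"
        value = float(np.mean(vals)) if agg == "mean" else float(np.median(vals))
        out.append(AnimalSummary(str(animal), str(genotype), metric, value, agg, len(vals), p_norm))
    return out


def _group_summaries(groups: dict[str, np.ndarray]) -> dict:
    return {
        name: {"n": len(v), "mean": float(np.mean(v)), "median": float(np.median(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
        for name, v in groups.items()
    }


def compare_groups(
    summaries: pd.DataFrame,
    *,
    value_col: str = "value",
    group_col: str = "genotype",
    alpha: float = ALPHA,
    normality_on: str = "residuals",
) -> TestResult:
    """Compare per-animal summaries across groups with a Shapiro–Wilk gate.

    Normality is assessed on residuals from group means by default
    (``normality_on='pooled'`` tests the raw pooled values instead).  A group
    with zero variance forces the nonparametric branch (the t statistic is
    undefined there), which is logged.
    """
    groups = {
        str(name): grp[value_col].to_numpy(float)
        for name, grp in summaries.groupby(group_col, sort=True)
    }
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least two animals per group")
    trail: list[str] = []
    values = list(groups.values())

    if normality_on == "residuals":
        resid = np.concatenate([v - v.mean() for v in values])
        trail.append("normality assessed on residuals from group means")
    else:
        resid = np.concatenate(values)
        trail.append("normality assessed on pooled values")
    if np.ptp(resid) == 0:
        p_norm = 1.0
        trail.append("residuals constant; Shapiro-Wilk skipped, treated as normal")
    else:
        p_norm = float(sps.shapiro(resid).pvalue)
        trail.append(f"Shapiro-Wilk p = {p_norm:.4g} vs alpha = {alpha}")

    parametric = p_norm >= alpha
    all_identical = np.ptp(np.concatenate(values)) == 0
    zero_var = [name for name, v in groups.items() if np.ptp(v) == 0]
    if parametric and zero_var and not all_identical and len(groups) == 2:
        # the t statistic is undefined (infinite) with a constant group and
        # differing means; all-identical data instead keeps t = 0, p = 1
        parametric = False
        trail.append(f"zero-variance group(s) {zero_var}: falling back to nonparametric branch")

    posthoc = None
    if parametric:
        if len(groups) == 2:
            a, b = values
            if np.ptp(np.concatenate(values)) == 0:
                stat, p = 0.0, 1.0
                trail.append("all values identical; t = 0, p = 1")
            else:
                res = sps.ttest_ind(a, b, equal_var=True)
                stat, p = float(res.statistic), float(res.pvalue)
            name, df = "t-test", len(a) + len(b) - 2
            trail.append("parametric branch: Student's t-test (2 groups)")
        else:
            res = sps.f_oneway(*values)
            stat, p = float(res.statistic), float(res.pvalue)
            k, n = len(groups), sum(len(v) for v in values)
            name, df = "one-way ANOVA", (k - 1, n - k)
            trail.append("parametric branch: one-way ANOVA (>2 groups)")
            flat = np.concatenate(values)
            labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
            posthoc = pairwise_tukeyhsd(flat, labels, alpha=alpha)
            trail.append("Tukey HSD post hoc computed")
    else:
        if len(groups) == 2:
            res = sps.mannwhitneyu(*values, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
            name, df = "Mann-Whitney U", None
            trail.append("nonparametric branch: Mann-Whitney U (2 groups)")
        else:
            res = sps.kruskal(*values)
            stat, p = float(res.statistic), float(res.pvalue)
            name, df = "Kruskal-Wallis", len(groups) - 1
            trail.append("nonparametric branch: Kruskal-Wallis (>2 groups)")

    return TestResult(
        test_name=name,
        statistic=stat,
        df=df,
        p_value=p,
        group_summaries=_group_summaries(groups),
        normality_p=p_norm,
        decision_trail=trail,
        posthoc=posthoc,
    )


def two_way_distance_genotype(
    summaries: pd.DataFrame,
    *,
    value_col: str = "value",
    animal_col: str = "animal_id",
    genotype_col: str = "genotype",
    distance_col: str = "distance_class",
) -> TestResult:
    """Two-way ANOVA (genotype × plaque distance + interaction, type-II SS).

    Each animal must contribute one near and one far summary; animals missing
    a cell are dropped and logged.  Reports F, df and p per effect.
    """
    df = summaries.copy()
    trail: list[str] = []
    counts = df.groupby(animal_col)[distance_col].nunique()
    incomplete = counts[counts < 2].index.tolist()
    if incomplete:
        df = df[~df[animal_col].isin(incomplete)]
        trail.append(f"dropped animals missing a near or far cell: {incomplete}")
    if df[genotype_col].nunique() < 2:
        raise ValueError("need two genotypes")
    trail.append("two-way ANOVA, factors genotype and plaque distance with interaction, type-II SS")

    data = df.rename(
        columns={value_col: "value", genotype_col: "genotype", distance_col: "distance"}
    )
    if np.ptp(data["value"].to_numpy(float)) == 0:
        # degenerate all-equal input: every effect F = 0
        effects = pd.DataFrame(
            {"F": [0.0, 0.0, 0.0], "PR(>F)": [1.0, 1.0, 1.0]},
            index=["C(genotype)", "C(distance)", "C(genotype):C(distance)"],
        )
        trail.append("all values equal; all F set to 0")
        return TestResult(
            test_name="two-way ANOVA",
            statistic=0.0,
            df=None,
            p_value=1.0,
            decision_trail=trail,
            effects=effects,
        )

    model = smf.ols("value ~ C(genotype) * C(distance)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    dist_row = table.loc["C(distance)"]
    return TestResult(
        test_name="two-way ANOVA",
        statistic=float(dist_row["F"]),
        df=(float(dist_row["df"]), float(table.loc["Residual", "df"])),
        p_value=float(dist_row["PR(>F)"]),
        group_summaries={
            f"{g}/{d}": {"n": int(len(grp)), "mean": float(grp["value"].mean())}
            for (g, d), grp in data.groupby(["genotype", "distance"])
        },
        decision_trail=trail,
        effects=table,
    )
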