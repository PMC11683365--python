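"""Group-comparison statistics: factorial ANOVA, distributional checks,
rank tests, Spearman correlation and the DXA femur-side selection rule.

These reproduce the descriptive layer of a cohort analysis: parameter-wise
N-way ANOVA with diabetes / sex / fracture factors (type-II sums of squares
for unbalanced designs), Lilliefors normality screening with nonparametric
confirmation, and rank correlations.  Raw p-values are reported without
multiple-testing correction (exploratory convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.diagnostic import lilliefors

from .errors import InputError


@dataclass
class AnovaResult:
    factors: list[str]
    f_values: dict[str, float]
    p_values: dict[str, float]
    interactions: list[str]


@dataclass
class DXARecord:
    """Per-side DXA densitometry of one subject (g/cm^2 and T-scores)."""

    left_total_abmd: float | None = None
    left_total_tscore: float | None = None
    left_neck_abmd: float | None = None
    left_neck_tscore: float | None = None
    right_total_abmd: float | None = None
    right_total_tscore: float | None = None
    right_neck_abmd: float | None = None
    right_neck_tscore: float | None = None
    spine_abmd: float | None = None
    spine_tscore: float | None = None
    side_used: str | None = None


@dataclass
class GroupComparison:
    normal: bool
    ranksum_p: float
    direction: int  # sign of median(group1) - median(group2)


def nway_anova(
    values,
    factors: dict[str, Sequence] | pd.DataFrame,
    interactions: Sequence[tuple[str, str]] = (),
) -> AnovaResult:
    """N-way ANOVA with type-II sums of squares.

    ``factors`` maps factor names to categorical level arrays; optional
    two-way ``interactions`` are added by name.  Rank-deficient designs are
    rejected with the aliased terms named.
    """
    y = np.asarray(values, dtype=float)
    fdf = pd.DataFrame(dict(factors)) if not isinstance(factors, pd.DataFrame) \
        else factors.copy()
    if len(fdf) != len(y):
        raise InputError("factor arrays must match the number of values")
    for name in fdf.columns:
        if fdf[name].nunique() < 2:
            raise InputError(f"factor {name!r} has fewer than 2 levels")
    df = fdf.copy()
    df["__y"] = y
    terms = [f"C(Q('{name}'))" for name in fdf.columns]
    inter_names = []
    for a, b in interactions:
        terms.append(f"C(Q('{a}')):C(Q('{b}'))")
        inter_names.append(f"{a}:{b}")
    formula = "__y ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()
    if model.df_resid <= 0:
        raise InputError("design has no residual degrees of freedom")
    rank = np.linalg.matrix_rank(model.model.exog)
    if rank < model.model.exog.shape[1]:
        raise InputError(
            "rank-deficient design: some factor combinations are aliased "
            f"(design rank {rank} < {model.model.exog.shape[1]} columns) "
            f"among terms {list(fdf.columns) + inter_names}"
        )
    table = sm.stats.anova_lm(model, typ=2)
    f_values, p_values = {}, {}
    for name in list(fdf.columns) + inter_names:
        if ":" in name:
            a, b = name.split(":")
            key = f"C(Q('{a}')):C(Q('{b}'))"
        else:
            key = f"C(Q('{name}'))"
        f_values[name] = float(table.loc[key, "F"])
        p_values[name] = float(table.loc[key, "PR(>F)"])
    return AnovaResult(factors=list(fdf.columns), f_values=f_values,
                       p_values=p_values, interactions=inter_names)


def anova_from_summaries(ns, means, sds) -> tuple[float, float]:
    """One-way ANOVA F and p from per-group (n, mean, SD) summaries.

    Algebraically identical to the raw-data one-way F; this is the identity
    that lets published per-cell summary tables be checked without the raw
    observations.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    n_tot = ns.sum()
    grand = np.sum(ns * means) / n_tot
    ss_between = np.sum(ns * (means - grand) ** 2)
    ss_within = np.sum((ns - 1) * sds**2)
    df_b = len(ns) - 1
    df_w = n_tot - len(ns)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def group_comparison_suite(values, groups) -> GroupComparison:
    """Two-group comparison: Lilliefors normality flag, rank-sum p, direction.

    Normality is accepted when neither group rejects the Lilliefors test at
    alpha = 0.05; the rank-sum p-value is two-sided (exact for small,
    untied samples); direction is the sign of the median difference.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    if len(levels) != 2:
        raise InputError("exactly two groups required")
    a, b = y[g == levels[0]], y[g == levels[1]]
    if len(a) < 4 or len(b) < 4:
        raise InputError("need n >= 4 per group")
    if np.all(y == y[0]):
        raise InputError("all values tied; rank-sum test is degenerate")
    normal = True
    for grp in (a, b):
        if np.std(grp) == 0:
            normal = False
            continue
        _, p_lf = lilliefors(grp, dist="norm")
        if p_lf < 0.05:
            normal = False
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    direction = int(np.sign(np.median(a) - np.median(b)))
    return GroupComparison(normal=normal, ranksum_p=float(res.pvalue),
                           direction=direction)


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie-corrected ranks.

    Returns ``(rho, p)`` with p from the large-sample approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise InputError("need n >= 5")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("constant input has no rank correlation")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def select_femur_side(record: DXARecord) -> DXARecord:
    """Apply the DXA side-selection rule.

    When both femora were measured, the side with the lower *total-area*
    aBMD is retained (its T-score follows); with one side, that side is
    used.  Equal sides resolve to the left (documented deterministic
    ordering) with ``side_used = "tie"``.
    """
    left = record.left_total_abmd is not None
    right = record.right_total_abmd is not None
    if not left and not right:
        raise InputError("no femur side measured")
    out = DXARecord(**{k: getattr(record, k) for k in record.__dataclass_fields__})
    if left and right:
        if record.left_total_abmd < record.right_total_abmd:
            side = "left"
        elif record.right_total_abmd < record.left_total_abmd:
            side = "right"
        else:
            side = "tie"
        keep = "left" if side in ("left", "tie") else "right"
        out.side_used = side
    else:
        keep = "left" if left else "right"
        out.side_used = keep
    for region in ("total", "neck"):
        for q in ("abmd", "tscore"):
            val = getattr(record, f"{keep}_{region}_{q}")
            setattr(out, f"left_{region}_{q}", val if keep == "left" else None)
            setattr(out, f"right_{region}_{q}", val if keep == "right" else None)
    return out


def retained_femur_values(record: DXARecord) -> dict[str, float | None]:
    """Total/neck aBMD and T-score retained after side selection."""
    selected = select_femur_side(record)
    side = "left" if selected.left_total_abmd is not None else "right"
    return {
        "aBMD_Femur(Total)": getattr(selected, f"{side}_total_abmd"),
        "T-score_Femur(Total)": getattr(selected, f"{side}_total_tscore"),
        "aBMD_Femur(Neck)": getattr(selected, f"{side}_neck_abmd"),
        "T-score_Femur(Neck)": getattr(selected, f"{side}_neck_tscore"),
        "side_used": selected.side_used,
    }
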