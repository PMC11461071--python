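"""Replicate-level aggregation and the group-comparison conventions.

Measurements are aggregated in two unweighted stages — nuclei to field
mean, field means to biological-replicate mean — and the replicate means
are the statistical units.  Comparisons follow the standard conventions
for this kind of data: a two-sided t-test for two groups, one-way ANOVA
with a Newman–Keuls post-test for three or more, and two-way ANOVA with
Bonferroni-corrected cellwise comparisons for two crossed factors.
Significance labels: *p < 0.05, **p < 0.01, ***p < 0.001, n.s. otherwise
(strict inequalities).

Studentized-range quantities for the Newman–Keuls stepdown come from
numerical evaluation of the distribution (``scipy.stats
.studentized_range``), not hard-coded tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "aggregate_replicates",
    "compare_groups",
    "newman_keuls",
    "significance_stars",
    "ComparisonResult",
    "format_comparison",
]


def aggregate_replicates(
    table: pd.DataFrame,
    value: str = "value",
    replicate: str = "replicate",
    field: str = "field",
    by: tuple[str, ...] = ("group", "variable"),
) -> pd.DataFrame:
    """Two-stage unweighted mean: nuclei -> field mean -> replicate mean.

    Fields are weighted equally regardless of how many nuclei they
    contribute.  Columns named in ``by`` are kept if present.  Input that
    is already at replicate level (no ``field`` column, one row per
    replicate) passes through unchanged, so the operation is idempotent.
    """
    if table.empty:
        raise ValueError("empty measurement table")
    keys = [c for c in by if c in table.columns] + [replicate]
    if replicate not in table.columns:
        raise ValueError(f"measurement table needs a {replicate!r} column")
    if field in table.columns:
        stage1 = table.groupby(keys + [field], sort=False)[value].mean().reset_index()
    else:
        stage1 = table
    out = stage1.groupby(keys, sort=False)[value].mean().reset_index()
    return out


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star label (strict thresholds)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass
class ComparisonResult:
    test_name: str
    group_stats: pd.DataFrame  # columns: group, n, mean, sem
    statistic: float
    p_value: float
    stars: str
    pairwise: pd.DataFrame | None = None
    anova_table: pd.DataFrame | None = None


def _group_stats(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, vals in groups.items():
        n = len(vals)
        rows.append(
            {
                "group": name,
                "n": n,
                "mean": float(np.mean(vals)),
                "sem": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _split_groups(table, group, value, min_n=2) -> dict[str, np.ndarray]:
    groups = {
        str(name): np.asarray(sub[value], dtype=float)
        for name, sub in table.groupby(group, sort=True)
    }
    for name, vals in groups.items():
        if len(vals) < min_n:
            raise ValueError(
                f"group {name!r} has {len(vals)} replicate(s); at least {min_n} required"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"group {name!r} contains non-finite values")
    return groups


def newman_keuls(
    means,
    mse: float,
    df_error: int,
    n_per_group,
    alpha: float = 0.05,
    group_names=None,
) -> pd.DataFrame:
    """Newman–Keuls stepdown on ordered group means.

    Ranges are tested with studentized-range critical points at span
    p = k..2; once a span is non-significant, every comparison nested
    inside it is declared non-significant without testing (the stepdown
    blocking rule).  Unbalanced group sizes are handled with the
    harmonic-mean n (with a warning).

    Returns one row per group pair: ``group_i, group_j, mean_diff, span,
    q, p_value, significant`` (``p_value`` is NaN for blocked pairs,
    which are never significant).
    """
    means = np.asarray(means, dtype=float)
    k = len(means)
    if k < 3:
        raise ValueError("Newman-Keuls needs >= 3 groups; use a t-test for two")
    n_arr = np.atleast_1d(np.asarray(n_per_group, dtype=float))
    if n_arr.size == 1:
        n = float(n_arr[0])
    elif np.ptp(n_arr) == 0:
        n = float(n_arr[0])
    else:
        n = sps.hmean(n_arr)
        warnings.warn(
            f"unbalanced group sizes {n_arr.astype(int).tolist()}: using harmonic mean "
            f"n = {n:.3g}",
            stacklevel=2,
        )
    if group_names is None:
        group_names = [f"g{i + 1}" for i in range(k)]
    group_names = list(group_names)

    order = np.argsort(means)
    sorted_means = means[order]
    if mse < 0:
        raise ValueError("mse must be non-negative")
    se = np.sqrt(mse / n)

    nonsig_spans: list[tuple[int, int]] = []
    rows = []
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            blocked = any(a <= i and j <= b for a, b in nonsig_spans)
            diff = sorted_means[j] - sorted_means[i]
            if blocked:
                rows.append((i, j, span, diff, np.nan, np.nan, False))
                continue
            if se == 0:
                q = np.inf if diff > 0 else 0.0
                p = 0.0 if diff > 0 else 1.0
            else:
                q = diff / se
                p = float(sps.studentized_range.sf(q, span, df_error))
            significant = p < alpha
            if not significant:
                nonsig_spans.append((i, j))
            rows.append((i, j, span, diff, q, p, significant))

    out = pd.DataFrame(
        rows, columns=["_i", "_j", "span", "mean_diff", "q", "p_value", "significant"]
    )
    out["group_i"] = [group_names[order[i]] for i in out["_i"]]
    out["group_j"] = [group_names[order[j]] for j in out["_j"]]
    return out[
        ["group_i", "group_j", "mean_diff", "span", "q", "p_value", "significant"]
    ]


def _pooled_mse(groups: dict[str, np.ndarray]) -> tuple[float, int]:
    ss = sum(np.sum((v - v.mean()) ** 2) for v in groups.values())
    df = sum(len(v) - 1 for v in groups.values())
    return (ss / df if df > 0 else 0.0), df


def compare_groups(
    table: pd.DataFrame,
    design: str,
    value: str = "value",
    group: str = "group",
    factors: tuple[str, str] = ("factor_a", "factor_b"),
    alpha: float = 0.05,
    equal_var: bool = True,
) -> ComparisonResult:
    """Compare groups of replicate-level values under a given design.

    ``design`` is ``"two_group"`` (two-sided Student t-test by default,
    Welch with ``equal_var=False``), ``"one_way"`` (F-test followed by a
    Newman–Keuls post-test) or ``"two_way"`` (two-factor ANOVA with
    interaction and Bonferroni-corrected comparisons of the first factor
    within each level of the second).

    Degenerate zero-variance data are reported as p = 1 when the group
    means are equal (with a warning) rather than NaN.
    """
    if design == "two_group":
        groups = _split_groups(table, group, value)
        if len(groups) != 2:
            raise ValueError(f"two_group design needs exactly 2 groups, got {len(groups)}")
        (na, a), (nb, b) = groups.items()
        mse, _ = _pooled_mse(groups)
        if mse == 0:
            if np.mean(a) == np.mean(b):
                warnings.warn(
                    "zero variance and equal means: p = 1 by convention", stacklevel=2
                )
                stat, p = 0.0, 1.0
            else:
                warnings.warn(
                    "zero within-group variance with different means: p = 0", stacklevel=2
                )
                stat, p = np.inf, 0.0
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
            stat, p = float(stat), float(p)
        name = "Student t-test" if equal_var else "Welch t-test"
        return ComparisonResult(name, _group_stats(groups), stat, p, significance_stars(p))

    if design == "one_way":
        groups = _split_groups(table, group, value)
        k = len(groups)
        if k < 3:
            raise ValueError("one_way design needs >= 3 groups; use two_group for two")
        mse, df_err = _pooled_mse(groups)
        means = np.array([v.mean() for v in groups.values()])
        if mse == 0:
            if np.ptp(means) == 0:
                warnings.warn(
                    "zero variance and equal means: p = 1 by convention", stacklevel=2
                )
                stat, p = 0.0, 1.0
            else:
                stat, p = np.inf, 0.0
        else:
            stat, p = sps.f_oneway(*groups.values())
            stat, p = float(stat), float(p)
        pairwise = newman_keuls(
            means,
            mse,
            df_err,
            [len(v) for v in groups.values()],
            alpha=alpha,
            group_names=list(groups),
        )
        return ComparisonResult(
            "one-way ANOVA + Newman-Keuls",
            _group_stats(groups),
            stat,
            p,
            significance_stars(p),
            pairwise=pairwise,
        )

    if design == "two_way":
        return _two_way(table, value, factors, alpha)

    raise ValueError(f"unknown design {design!r}")


def _two_way(table: pd.DataFrame, value: str, factors: tuple[str, str], alpha: float):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = factors
    for f in factors:
        if f not in table.columns:
            raise ValueError(f"two_way design needs a {f!r} column")
    df = table.rename(columns={value: "_y", fa: "_a", fb: "_b"})
    for (la, lb), sub in df.groupby(["_a", "_b"]):
        if len(sub) < 2:
            raise ValueError(f"cell ({la!r}, {lb!r}) has fewer than 2 replicates")
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    mse = float(anova.loc["Residual", "sum_sq"] / anova.loc["Residual", "df"])
    df_resid = int(anova.loc["Residual", "df"])

    # Bonferroni post-test: factor-a comparisons within each level of factor b,
    # pooled residual MSE, corrected over the total number of comparisons.
    a_levels = sorted(df["_a"].unique())
    b_levels = sorted(df["_b"].unique())
    comparisons = []
    for lb in b_levels:
        sub = df[df["_b"] == lb]
        for i in range(len(a_levels)):
            for j in range(i + 1, len(a_levels)):
                x = sub.loc[sub["_a"] == a_levels[i], "_y"].to_numpy()
                y = sub.loc[sub["_a"] == a_levels[j], "_y"].to_numpy()
                diff = float(np.mean(x) - np.mean(y))
                if mse == 0:
                    t = np.inf if diff != 0 else 0.0
                    p_raw = 0.0 if diff != 0 else 1.0
                else:
                    sed = np.sqrt(mse * (1 / len(x) + 1 / len(y)))
                    t = diff / sed
                    p_raw = 2 * float(sps.t.sf(abs(t), df_resid))
                comparisons.append(
                    {
                        "level_b": lb,
                        "group_i": a_levels[i],
                        "group_j": a_levels[j],
                        "mean_diff": diff,
                        "t": float(t),
                        "p_raw": p_raw,
                    }
                )
    pairwise = pd.DataFrame(comparisons)
    m = len(pairwise)
    pairwise["p_bonferroni"] = np.minimum(pairwise["p_raw"] * m, 1.0)
    pairwise["significant"] = pairwise["p_bonferroni"] < alpha
    pairwise["stars"] = pairwise["p_bonferroni"].map(significance_stars)

    inter = anova.index[anova.index.str.contains(":")][0]
    p_int = float(anova.loc[inter, "PR(>F)"])
    groups = {
        f"{la}/{lb}": g["_y"].to_numpy() for (la, lb), g in df.groupby(["_a", "_b"])
    }
    return ComparisonResult(
        "two-way ANOVA + Bonferroni",
        _group_stats(groups),
        float(anova.loc[inter, "F"]),
        p_int,
        significance_stars(p_int),
        pairwise=pairwise,
        anova_table=anova,
    )


def format_comparison(result: ComparisonResult) -> str:
    """Plain-text summary of a comparison (means ± SEM, p, stars)."""
    lines = [f"{result.test_name}"]
    for rec in result.group_stats.itertuples():
        lines.append(f"  {rec.group}: {rec.mean:.4g} ± {rec.sem:.3g} (n={rec.n})")
    lines.append(
        f"  statistic = {result.statistic:.4g}, p = {result.p_value:.4g} [{result.stars}]"
    )
    if result.pairwise is not None and not result.pairwise.empty:
        lines.append("  pairwise:")
        for rec in result.pairwise.itertuples():
            sig = "significant" if rec.significant else "n.s."
            lines.append(f"    {rec.group_i} vs {rec.group_j}: {sig}")
    return "\n".join(lines)
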