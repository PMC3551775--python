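"""Cohort-level group comparisons of disc indices.

The decision tree mirrors common biostatistics practice for small clinical
cohorts: an omnibus parametric test (one- or two-way ANOVA) when every group
passes Shapiro-Wilk normality and Levene variance homogeneity at alpha=0.05,
otherwise the rank-based counterpart — Kruskal-Wallis with Dunn's pairwise
post-hoc for one factor, and the Conover rank-transform ANOVA (factorial
ANOVA on global midranks) for the pathology x severity design.

Dunn's test is implemented directly: pairwise z-statistics on mean ranks with
the tie-corrected variance (N(N+1)/12 - sum(t^3-t)/(12(N-1))) (1/n_i + 1/n_j).
No multiple-testing correction is applied across the index x region grid by
default; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DesignError, InsufficientDataError

ALPHA_GATE = 0.05  # normality / homogeneity gate level

PATHOLOGY_GROUPS = ("scoliosis", "spondylolisthesis")
GROUPS = ("control",) + PATHOLOGY_GROUPS
SEVERITIES = ("low", "high")

PAIRWISE_COMPARISONS = (
    ("control", "scoliosis"),
    ("control", "spondylolisthesis"),
    ("scoliosis", "spondylolisthesis"),
)


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    posthoc: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    assumptions: dict[str, float] = field(default_factory=dict)
    effects: dict[str, tuple[float, float]] = field(default_factory=dict)  # name -> (F, p)


def _clean_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        out[name] = arr
    return out


def assumption_checks(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Minimum Shapiro-Wilk p over groups and Levene homogeneity p."""
    shapiro_ps = []
    for g in groups:
        if np.ptp(g) == 0:  # Shapiro is undefined on constant data
            shapiro_ps.append(0.0)
        else:
            shapiro_ps.append(float(stats.shapiro(g).pvalue))
    levene_p = float(stats.levene(*groups, center="median").pvalue)
    return min(shapiro_ps), levene_p


def choose_test(values_by_group: Mapping[str, Sequence[float]]) -> str:
    """Select the parametric or rank branch for a one-factor comparison."""
    groups = _clean_groups(values_by_group)
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    for name, g in groups.items():
        if len(g) < 3:
            raise InsufficientDataError(
                f"group {name!r} has {len(g)} observations; need >= 3"
            )
    shapiro_min, levene_p = assumption_checks(list(groups.values()))
    if shapiro_min > ALPHA_GATE and levene_p > ALPHA_GATE:
        return "one_way_anova"
    return "kruskal_wallis_dunn"


def dunn_posthoc(
    values_by_group: Mapping[str, Sequence[float]]
) -> list[tuple[tuple[str, str], float]]:
    """Dunn's pairwise mean-rank z-tests with midranks and tie correction."""
    groups = _clean_groups(values_by_group)
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    N = len(pooled)
    ranks = stats.rankdata(pooled)  # midrank convention
    idx = np.cumsum([0] + [len(groups[n]) for n in names])
    mean_ranks = {
        n: ranks[idx[i] : idx[i + 1]].mean() for i, n in enumerate(names)
    }
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    out = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        if se == 0:
            out.append(((a, b), 1.0))
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        out.append(((a, b), float(2.0 * stats.norm.sf(abs(z)))))
    return out


def one_way_compare(
    values_by_group: Mapping[str, Sequence[float]],
    *,
    test_name: str | None = None,
    alpha: float = 0.05,
) -> StatResult:
    """Omnibus one-factor comparison with post-hoc on rejection (>= 3 groups).

    The branch is chosen by :func:`choose_test` unless forced via
    ``test_name``; the rank branch uses Kruskal-Wallis + Dunn, the parametric
    branch one-way ANOVA + Tukey HSD.
    """
    groups = _clean_groups(values_by_group)
    test = test_name or choose_test(groups)
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        if test == "one_way_anova":
            # identical constant groups: no variance anywhere, F defined as 0
            return StatResult(test, 0.0, 1.0, assumptions={})
        return StatResult(test, 0.0, 1.0)
    shapiro_min, levene_p = assumption_checks(arrays)
    assumptions = {"normality_p": shapiro_min, "equal_variance_p": levene_p}
    if test == "one_way_anova":
        res = stats.f_oneway(*arrays)
        stat, p = float(res.statistic), float(res.pvalue)
        posthoc = []
        if len(arrays) >= 3 and p < alpha:
            names = list(groups)
            tk = stats.tukey_hsd(*arrays)
            posthoc = [
                ((names[i], names[j]), float(tk.pvalue[i, j]))
                for i, j in itertools.combinations(range(len(names)), 2)
            ]
        return StatResult(test, stat, p, posthoc, assumptions)
    res = stats.kruskal(*arrays)
    stat, p = float(res.statistic), float(res.pvalue)
    posthoc = dunn_posthoc(groups) if (len(arrays) >= 3 and p < alpha) else []
    return StatResult("kruskal_wallis_dunn", stat, p, posthoc, assumptions)


def _two_way_anova(df: pd.DataFrame) -> dict[str, tuple[float, float]]:
    model = smf.ols("value ~ C(pathology) * C(severity)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {}
    for row, key in [
        ("C(pathology)", "pathology"),
        ("C(severity)", "severity"),
        ("C(pathology):C(severity)", "interaction"),
    ]:
        out[key] = (float(table.loc[row, "F"]), float(table.loc[row, "PR(>F)"]))
    return out


def two_way_compare(
    df: pd.DataFrame,
    *,
    test_name: str | None = None,
) -> StatResult:
    """Pathology x severity factorial comparison (control excluded).

    ``df`` needs columns ``value``, ``pathology``, ``severity``.  The rank
    branch replaces values by their global midranks and fits the same linear
    model (rank-transform two-way ANOVA).
    """
    df = df.dropna(subset=["value"]).copy()
    cells = df.groupby(["pathology", "severity"], observed=True)["value"]
    sizes = cells.size()
    if len(sizes) < 4 or df["pathology"].nunique() < 2 or df["severity"].nunique() < 2:
        raise DesignError("two-way design requires both factors at two levels (no empty cells)")
    if (sizes < 3).any():
        raise InsufficientDataError("every pathology x severity cell needs >= 3 observations")
    cell_arrays = [g.to_numpy() for _, g in cells]
    if np.ptp(df["value"].to_numpy()) == 0:
        return StatResult(
            test_name or "two_way_anova", 0.0, 1.0,
            effects={k: (0.0, 1.0) for k in ("pathology", "severity", "interaction")},
        )
    shapiro_min, levene_p = assumption_checks(cell_arrays)
    assumptions = {"normality_p": shapiro_min, "equal_variance_p": levene_p}
    if test_name is None:
        test_name = (
            "two_way_anova"
            if (shapiro_min > ALPHA_GATE and levene_p > ALPHA_GATE)
            else "rank_two_way_anova"
        )
    if test_name == "rank_two_way_anova":
        df["value"] = stats.rankdata(df["value"].to_numpy())
    effects = _two_way_anova(df)
    f, p = effects["pathology"]
    return StatResult(test_name, f, p, assumptions=assumptions, effects=effects)


def _stars(p: float, alpha: float = 0.05, alpha2: float = 0.01) -> str:
    if not np.isfinite(p):
        return ""
    if p < alpha2:
        return "**"
    if p < alpha:
        return "*"
    return ""


def significance_report(
    cohort: pd.DataFrame,
    *,
    alpha: float = 0.05,
    alpha2: float = 0.01,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Significance grid over comparisons x normalization x region x index.

    ``cohort`` is the long table with columns subject_id, group, severity,
    region, normalization, index, value.  Rows of the grid are the three
    pairwise pathology comparisons plus the low/high severity contrast; cells
    hold '*' (p < alpha) or '**' (p < alpha2).  Pairwise stars come from the
    post-hoc only when the omnibus test rejects.  With ``bh_correct`` the
    omnibus p-values are Benjamini-Hochberg adjusted across the grid.
    """
    required = {"subject_id", "group", "severity", "region", "normalization", "index", "value"}
    if cohort.empty:
        return pd.DataFrame()
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")

    records: list[dict] = []
    keys = cohort.groupby(["normalization", "region", "index"], observed=True)
    for (normalization, region, index), sub in keys:
        sub = sub.dropna(subset=["value"])
        by_group = {
            g: sub.loc[sub["group"] == g, "value"].to_numpy()
            for g in GROUPS
            if (sub["group"] == g).sum() >= 3
        }
        pair_p: dict[tuple[str, str], float] = {}
        omnibus_p = np.nan
        if len(by_group) >= 2:
            try:
                res = one_way_compare(by_group)
                omnibus_p = res.p_value
                if len(by_group) == 2 and res.p_value < alpha:
                    pair = tuple(sorted(by_group))
                    pair_p[pair] = res.p_value
                for pair, p in res.posthoc:
                    pair_p[tuple(sorted(pair))] = p
            except InsufficientDataError:
                pass
        sev_p = np.nan
        path = sub[sub["group"].isin(PATHOLOGY_GROUPS) & sub["severity"].isin(SEVERITIES)]
        if not path.empty:
            try:
                two = two_way_compare(
                    path.rename(columns={"group": "pathology"})[
                        ["value", "pathology", "severity"]
                    ]
                )
                sev_p = two.effects["severity"][1]
            except (DesignError, InsufficientDataError):
                pass
        for a, b in PAIRWISE_COMPARISONS:
            records.append(
                dict(
                    comparison=f"{a}/{b}",
                    normalization=normalization,
                    region=region,
                    index=index,
                    p=pair_p.get(tuple(sorted((a, b))), np.nan)
                    if np.isfinite(omnibus_p) and omnibus_p < alpha
                    else np.nan,
                )
            )
        records.append(
            dict(
                comparison="severity low/high",
                normalization=normalization,
                region=region,
                index=index,
                p=sev_p,
            )
        )
    grid = pd.DataFrame.from_records(records)
    if grid.empty:
        return grid
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        mask = grid["p"].notna()
        if mask.any():
            grid.loc[mask, "p"] = multipletests(grid.loc[mask, "p"], method="fdr_bh")[1]
    grid["stars"] = grid["p"].map(lambda p: _stars(p, alpha, alpha2))
    return grid.pivot_table(
        index=["comparison", "normalization", "region"],
        columns="index",
        values="stars",
        aggfunc="first",
    ).fillna("")
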