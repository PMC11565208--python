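"""Experiment-level statistics for the phenotyping pipeline.

Implements the statistical toolkit the greenhouse analyses rely on:
subsample averaging to the replicate plant, one-way and two-way
factorial ANOVA, a univariate split-plot-in-time repeated-measures
ANOVA for the dry-down trajectories, Tukey's HSD with letter displays,
least-squares means ± SE, and planned contrasts on group means.

Conventions
-----------
* The replicate plant (or pot) is the experimental unit: multiple
  subsamples within a plant are averaged first
  (:func:`average_subsamples`).
* Unbalanced two-way designs use sum-to-zero (effect) coding and
  partial (Type-III) sums of squares, which reduce to the classical
  sequential decomposition when the design is balanced.
* Tukey adjusted p-values come from the studentized-range distribution
  (numerically integrated CDF via ``scipy.stats.studentized_range``).
* Dry-down post-hoc comparisons are run independently per day with no
  across-day multiplicity correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


def average_subsamples(df: pd.DataFrame, keys: Sequence[str], response: str | Sequence[str]) -> pd.DataFrame:
    """Average within-plant subsamples to one row per replicate unit.

    ``keys`` identify the replicate plant and any design cell it sits in
    (e.g. plant_id × leaf_position × surface); the response column(s)
    are replaced by their plain mean over subsamples regardless of
    subsample count.
    """
    responses = [response] if isinstance(response, str) else list(response)
    return df.groupby(list(keys), as_index=False)[responses].mean()


def _check_residual_df(df_resid: int) -> None:
    if df_resid < 1:
        raise ValueError(f"residual df must be >= 1, got {df_resid}")


def one_way_anova(df: pd.DataFrame, response: str, factor: str) -> pd.DataFrame:
    """Classical one-way ANOVA decomposition.

    Returns a table indexed by term (factor, Residual) with columns
    ``df, sum_sq, mean_sq, F, p``.
    """
    y = df[response].to_numpy(dtype=float)
    groups = df.groupby(factor, observed=False)[response]
    sizes = groups.size()
    if (sizes == 0).any():
        empty = sizes[sizes == 0].index.tolist()
        raise ValueError(f"factor level(s) with 0 observations: {empty}")
    if len(sizes) < 2:
        raise ValueError("one_way_anova needs >= 2 factor levels")
    grand = y.mean()
    means = groups.mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    sst = float(((y - grand) ** 2).sum())
    ssw = sst - ssb
    df_b = len(sizes) - 1
    df_w = len(y) - len(sizes)
    _check_residual_df(df_w)
    msb, msw = ssb / df_b, ssw / df_w
    if ssw == 0.0 and ssb == 0.0:
        f_stat, p = 0.0, 1.0
    elif ssw == 0.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = msb / msw
        p = float(stats.f.sf(f_stat, df_b, df_w))
    return pd.DataFrame(
        {
            "df": [df_b, df_w],
            "sum_sq": [ssb, ssw],
            "mean_sq": [msb, msw],
            "F": [f_stat, np.nan],
            "p": [p, np.nan],
        },
        index=[factor, "Residual"],
    )


def two_way_anova(
    df: pd.DataFrame, response: str, factor_a: str, factor_b: str, interaction: bool = True
) -> pd.DataFrame:
    """Two-way factorial ANOVA with sum-to-zero coding.

    Partial (Type-III) sums of squares, which coincide with the
    classical sequential decomposition on balanced data.  Requesting the
    interaction with an empty design cell is an error.
    """
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    if interaction:
        cells = df.groupby([factor_a, factor_b], observed=False).size()
        full = df[factor_a].nunique() * df[factor_b].nunique()
        if len(cells) < full or (cells == 0).any():
            raise ValueError("empty design cell(s): interaction not estimable")
    terms = f'C(Q("{factor_a}"), Sum)'
    terms += f' * C(Q("{factor_b}"), Sum)' if interaction else f' + C(Q("{factor_b}"), Sum)'
    model = smf.ols(f'Q("{response}") ~ {terms}', data=df).fit()
    _check_residual_df(int(model.df_resid))
    tab = anova_lm(model, typ=3).drop(index="Intercept")
    tab = tab.rename(columns={"PR(>F)": "p"})
    pretty = {}
    for ix in tab.index:
        name = ix.replace(f'C(Q("{factor_a}"), Sum)', factor_a).replace(f'C(Q("{factor_b}"), Sum)', factor_b)
        pretty[ix] = name
    tab = tab.rename(index=pretty)
    tab["mean_sq"] = tab["sum_sq"] / tab["df"]
    return tab[["df", "sum_sq", "mean_sq", "F", "p"]]


def repeated_measures_anova(
    df: pd.DataFrame, response: str, between: str, within: str, subject: str
) -> pd.DataFrame:
    """Univariate split-plot-in-time ANOVA for repeated measurements.

    Each subject (plant/pot), nested in a ``between`` group (genotype),
    is measured at every level of ``within`` (day).  The between-group
    effect is tested against the subject-within-group mean square; the
    time effect and the group × time interaction are tested against the
    within-subject residual.  An incomplete subject × time grid is an
    error (no missing-data imputation).
    """
    d = df[[response, between, within, subject]].copy()
    days = sorted(d[within].unique())
    n_days = len(days)
    counts = d.groupby([subject, within], observed=False).size()
    per_subject = d.groupby(subject, observed=False)[within].nunique()
    if (counts != 1).any() or (per_subject != n_days).any():
        raise ValueError("incomplete subject x time grid: every subject needs exactly one observation per time point")
    if d.groupby(subject, observed=False)[between].nunique().max() > 1:
        raise ValueError(f"subject assigned to multiple {between!r} levels")

    y = d[response].to_numpy(dtype=float)
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())

    subj_means = d.groupby(subject, observed=False)[response].mean()
    subj_group = d.groupby(subject, observed=False)[between].first()
    grp_sizes = subj_group.value_counts()  # subjects per group
    grp_means = d.groupby(between, observed=False)[response].mean()
    day_means = d.groupby(within, observed=False)[response].mean()
    cell_means = d.groupby([between, within], observed=False)[response].mean()

    ss_between_subj = float(n_days * ((subj_means - grand) ** 2).sum())
    ss_group = float(n_days * (grp_sizes * (grp_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group

    n_subj_total = len(subj_means)
    ss_day = float(n_subj_total * ((day_means - grand) ** 2).sum())
    ss_gd = 0.0
    for (g, t), cm in cell_means.items():
        ss_gd += grp_sizes[g] * (cm - grp_means[g] - day_means[t] + grand) ** 2
    ss_gd = float(ss_gd)
    ss_resid = sst - ss_between_subj - ss_day - ss_gd

    n_groups = d[between].nunique()
    df_g = n_groups - 1
    df_subj = n_subj_total - n_groups
    df_day = n_days - 1
    df_gd = df_g * df_day
    df_resid = df_subj * df_day
    _check_residual_df(df_resid)
    _check_residual_df(df_subj)

    ms_g = ss_group / df_g
    ms_subj = ss_subj_within / df_subj
    ms_day = ss_day / df_day
    ms_gd = ss_gd / df_gd
    ms_resid = max(ss_resid, 0.0) / df_resid

    def _f(ms_num: float, ms_den: float, dfn: int, dfd: int) -> tuple[float, float]:
        if ms_den == 0.0:
            return (0.0, 1.0) if ms_num == 0.0 else (np.inf, 0.0)
        f_stat = ms_num / ms_den
        return f_stat, float(stats.f.sf(f_stat, dfn, dfd))

    f_g, p_g = _f(ms_g, ms_subj, df_g, df_subj)
    f_day, p_day = _f(ms_day, ms_resid, df_day, df_resid)
    f_gd, p_gd = _f(ms_gd, ms_resid, df_gd, df_resid)

    return pd.DataFrame(
        {
            "df": [df_g, df_subj, df_day, df_gd, df_resid],
            "sum_sq": [ss_group, ss_subj_within, ss_day, ss_gd, max(ss_resid, 0.0)],
            "mean_sq": [ms_g, ms_subj, ms_day, ms_gd, ms_resid],
            "F": [f_g, np.nan, f_day, f_gd, np.nan],
            "p": [p_g, np.nan, p_day, p_gd, np.nan],
        },
        index=[between, f"subject({between})", within, f"{between}:{within}", "Residual"],
    )


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise Tukey HSD comparisons plus a letter display."""

    pairwise: pd.DataFrame  # group1, group2, diff, q, p_adj, significant
    letters: dict  # level -> letter string; shared letter <=> not significantly different
    msw: float
    df_resid: int
    alpha: float


def tukey_hsd(df: pd.DataFrame, response: str, factor: str, alpha: float = 0.05) -> TukeyResult:
    """Tukey's honestly-significant-difference test after a one-way ANOVA.

    For groups i, j the studentized-range statistic is

        q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))

    (the Tukey–Kramer form for unequal n), with adjusted p from the
    studentized-range distribution with k groups and the residual df.
    The letter display groups means that are not significantly
    different under a shared letter.
    """
    groups = df.groupby(factor, observed=False)[response]
    means = groups.mean()
    sizes = groups.size()
    k = len(means)
    if k < 2:
        raise ValueError("tukey_hsd needs >= 2 groups")
    aov = one_way_anova(df, response, factor)
    msw = float(aov.loc["Residual", "mean_sq"])
    df_resid = int(aov.loc["Residual", "df"])

    order = means.sort_values(ascending=False).index.tolist()
    rows = []
    sig = {}
    for g1, g2 in itertools.combinations(order, 2):
        diff = float(means[g1] - means[g2])
        se = np.sqrt(msw / 2.0 * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else np.inf
        else:
            q = abs(diff) / se
        p_adj = float(stats.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
        p_adj = min(max(p_adj, 0.0), 1.0)
        is_sig = p_adj < alpha
        rows.append({"group1": g1, "group2": g2, "diff": diff, "q": q, "p_adj": p_adj, "significant": is_sig})
        sig[(g1, g2)] = sig[(g2, g1)] = is_sig
    pairwise = pd.DataFrame(rows)
    letters = _letter_display(order, sig)
    return TukeyResult(pairwise=pairwise, letters=letters, msw=msw, df_resid=df_resid, alpha=alpha)


def _letter_display(order: Sequence[str], sig: Mapping[tuple, bool]) -> dict:
    """Greedy letter grouping over the pairwise significance matrix.

    Groups are scanned in descending-mean order; each maximal run of
    mutually non-significant groups gets one letter, and runs contained
    in an earlier run are skipped.
    """
    runs: list[tuple[int, int]] = []
    n = len(order)
    for i in range(n):
        j = i
        while j + 1 < n and all(not sig[(order[a], order[j + 1])] for a in range(i, j + 1)):
            j += 1
        if runs and runs[-1][0] <= i and runs[-1][1] >= j:
            continue  # contained in an earlier run
        runs.append((i, j))
    letters: dict = {g: "" for g in order}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (lo, hi) in enumerate(runs):
        for g in order[lo:hi + 1]:
            letters[g] += alphabet[idx % len(alphabet)]
    return letters


def lsmeans_se(df: pd.DataFrame, response: str, factors: Sequence[str], term: Sequence[str] | str | None = None) -> pd.DataFrame:
    """Least-squares (marginal) means ± SE for a model term.

    The model is the full factorial of ``factors``.  For each level
    combination of ``term`` (default: all factors), the lsmean is the
    unweighted mean of the design-cell means it spans — equal to the
    raw marginal mean only when the design is balanced.  SE propagates
    the residual mean square through the cell sample sizes:

        SE = sqrt(MSE / m^2 * sum_cells 1/n_cell)

    for a term spanning m cells.  An empty cell makes the term
    inestimable and raises.
    """
    factors = list(factors)
    if term is None:
        term = factors
    term = [term] if isinstance(term, str) else list(term)
    if not set(term) <= set(factors):
        raise ValueError(f"term {term} not a subset of model factors {factors}")

    cells = df.groupby(factors, observed=False)[response].agg(["mean", "size", "var"])
    n_full = int(np.prod([df[f].nunique() for f in factors]))
    if len(cells) < n_full or (cells["size"] == 0).any() or cells["mean"].isna().any():
        raise ValueError("inestimable: empty design cell(s)")
    # Residual (within-cell) mean square of the full factorial model.
    ss_resid = float((cells["var"].fillna(0.0) * (cells["size"] - 1)).sum())
    df_resid = int(cells["size"].sum() - len(cells))
    mse = ss_resid / df_resid if df_resid > 0 else np.nan

    cells = cells.reset_index()
    out_rows = []
    for combo, sub in cells.groupby(term, observed=False):
        combo = combo if isinstance(combo, tuple) else (combo,)
        m = len(sub)
        lsmean = float(sub["mean"].mean())
        se = float(np.sqrt(mse / m**2 * (1.0 / sub["size"]).sum())) if np.isfinite(mse) else np.nan
        row = dict(zip(term, combo))
        row.update({"lsmean": lsmean, "se": se, "n_cells": m})
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def planned_contrast(
    df: pd.DataFrame, response: str, factor: str, weights: Mapping[str, float]
) -> dict:
    """A priori contrast on group lsmeans with the pooled residual MSE.

    ``weights`` map factor levels to contrast coefficients and must sum
    to zero.  Returns estimate, SE, t, p (two-sided), and residual df.
    With weights (1, -1) on two groups this reproduces the pooled
    two-sample t-test.
    """
    total = sum(weights.values())
    if abs(total) > 1e-12:
        raise ValueError(f"contrast weights must sum to zero, got {total}")
    groups = df.groupby(factor, observed=False)[response]
    means = groups.mean()
    sizes = groups.size()
    missing = set(weights) - set(means.index)
    if missing:
        raise ValueError(f"weights reference unknown levels: {sorted(missing)}")
    aov = one_way_anova(df, response, factor)
    msw = float(aov.loc["Residual", "mean_sq"])
    df_resid = int(aov.loc["Residual", "df"])
    estimate = float(sum(w * means[lvl] for lvl, w in weights.items()))
    se = float(np.sqrt(msw * sum(w**2 / sizes[lvl] for lvl, w in weights.items())))
    if se == 0.0:
        t = 0.0 if estimate == 0.0 else np.inf * np.sign(estimate)
        p = 1.0 if estimate == 0.0 else 0.0
    else:
        t = estimate / se
        p = float(2.0 * stats.t.sf(abs(t), df_resid))
    return {"estimate": estimate, "se": se, "t": t, "p": p, "df": df_resid}


def per_day_posthoc(
    df: pd.DataFrame, response: str, factor: str, day_col: str = "day", alpha: float = 0.05
) -> pd.DataFrame:
    """Independent one-way ANOVA + Tukey HSD per day of a dry-down.

    Flags on which days and between which groups significant
    differences occurred; no across-day multiplicity correction is
    applied.  Returns one row per day × group pair.
    """
    rows = []
    for day, sub in df.groupby(day_col, sort=True):
        tk = tukey_hsd(sub, response, factor, alpha=alpha)
        for r in tk.pairwise.itertuples():
            rows.append({
                day_col: day, "group1": r.group1, "group2": r.group2,
                "diff": r.diff, "p_adj": r.p_adj, "significant": r.significant,
            })
    return pd.DataFrame(rows)
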