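"""Group-comparison statistics for longitudinal diet-intervention cohorts.

Mann-Whitney tests (exact small-sample permutation distribution, normal
approximation with tie correction otherwise), the repeated-measures
two-way mixed ANOVA with Greenhouse-Geisser correction and Sidak-adjusted
per-timepoint contrasts, change-from-baseline transforms, and the a-priori
two-sample-t sample-size calculation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DesignError,
    InfeasibilityError,
    MissingDataError,
    ValidationError,
)

#: Combined sample size up to which the exact permutation distribution of U
#: is enumerated.
EXACT_MAX_N = 16

#: Figure-legend significance thresholds.
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    adjustment: str = "none"
    n_a: int = 0
    n_b: int = 0
    direction: str = ""   # 'a>b', 'a<b' or 'a=b'


def stars(p: float) -> str:
    """Significance annotation at the conventional figure thresholds."""
    for thresh, mark in STAR_THRESHOLDS:
        if p < thresh:
            return mark
    return ""


def sidak(p_raw: float, m: int) -> float:
    """Sidak-adjusted p value for a family of m comparisons."""
    if not 0 <= p_raw <= 1:
        raise ValidationError("p must be in [0, 1]")
    if m < 1:
        raise ValidationError("family size m must be >= 1")
    return 1.0 - (1.0 - p_raw) ** m


@lru_cache(maxsize=64)
def _combo_index(n: int, k: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def _u_statistic(ranks_a_sum: float, n_a: int) -> float:
    return ranks_a_sum - n_a * (n_a + 1) / 2.0


def mann_whitney(group_a, group_b) -> ComparisonResult:
    """Two-sided Mann-Whitney U test between two independent samples.

    For combined n <= 16 the p value comes from the full permutation
    distribution of U over all assignments of the pooled (tie-averaged)
    ranks, so it is exact with or without ties; larger samples use the
    normal approximation with tie-corrected variance and continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = _u_statistic(ranks[:n_a].sum(), n_a)
    mean_u = n_a * n_b / 2.0

    if n <= EXACT_MAX_N:
        combos = _combo_index(n, n_a)
        rank_sums = ranks[combos].sum(axis=1)
        u_dist = rank_sums - n_a * (n_a + 1) / 2.0
        eps = 1e-9
        p_lo = np.mean(u_dist <= u_a + eps)
        p_hi = np.mean(u_dist >= u_a - eps)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        method = "mann-whitney-exact"
    else:
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (n * (n - 1))
        var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var_u == 0:
            p = 1.0
        else:
            z = (u_a - mean_u - 0.5 * np.sign(u_a - mean_u)) / math.sqrt(var_u)
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "mann-whitney-normal"
    if u_a > mean_u:
        direction = "a>b"
    elif u_a < mean_u:
        direction = "a<b"
    else:
        direction = "a=b"
    return ComparisonResult(method, float(u_a), float(p), None, "none",
                            n_a, n_b, direction)


def wilcoxon_signed_rank(before, after) -> ComparisonResult:
    """Paired two-sided Wilcoxon signed-rank test (thin contract)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.size < 3:
        raise ValidationError("need >= 3 matched pairs")
    diff = after - before
    if np.all(diff == 0):
        return ComparisonResult("wilcoxon", 0.0, 1.0, None, "none",
                                before.size, after.size, "a=b")
    res = sps.wilcoxon(before, after)
    direction = "a<b" if diff.mean() > 0 else "a>b"
    return ComparisonResult("wilcoxon", float(res.statistic),
                            float(res.pvalue), None, "none",
                            before.size, after.size, direction)


# --------------------------------------------------------------------------
# repeated-measures mixed two-way ANOVA
# --------------------------------------------------------------------------


def _complete_cases(data: pd.DataFrame, dv: str, within: str, subject: str,
                    between: str) -> pd.DataFrame:
    per_subj = data.groupby(subject)[between].nunique()
    if (per_subj > 1).any():
        bad = per_subj[per_subj > 1].index.tolist()
        raise DesignError(f"subject(s) {bad} appear under multiple "
                          f"{between} levels")
    levels = set(data[within].unique())
    keep = []
    for subj, sub in data.groupby(subject):
        have = set(sub.loc[sub[dv].notna(), within])
        if have == levels:
            keep.append(subj)
    return data[data[subject].isin(keep)].copy()


def _splitplot_components(cc: pd.DataFrame, dv: str, within: str,
                          subject: str, between: str) -> dict[str, tuple]:
    """Classical split-plot sums of squares on complete-case data.

    Used as the fallback when the library fit degenerates (zero residual
    variance); returns {effect: (ss, df, ss_error, df_error)}.
    """
    piv = cc.pivot_table(index=[between, subject], columns=within, values=dv)
    groups = piv.index.get_level_values(0).to_numpy()
    y = piv.to_numpy()
    n_subj, t = y.shape
    g_levels = sorted(set(groups))
    g = len(g_levels)
    grand = y.mean()
    ss_bsubj = t * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_diet = t * sum((groups == lvl).sum()
                      * (y[groups == lvl].mean() - grand) ** 2
                      for lvl in g_levels)
    ss_serr = max(ss_bsubj - ss_diet, 0.0)
    ss_age = n_subj * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_cells = sum((groups == lvl).sum()
                   * ((y[groups == lvl].mean(axis=0) - grand) ** 2).sum()
                   for lvl in g_levels)
    ss_int = max(ss_cells - ss_diet - ss_age, 0.0)
    ss_werr = max(((y - grand) ** 2).sum() - ss_bsubj - ss_age - ss_int, 0.0)
    return {
        between: (ss_diet, g - 1.0, ss_serr, float(n_subj - g)),
        within: (ss_age, t - 1.0, ss_werr, float((t - 1) * (n_subj - g))),
        "interaction": (ss_int, (g - 1.0) * (t - 1.0), ss_werr,
                        float((t - 1) * (n_subj - g))),
    }


def _f_row(label: str, ss: float, df1: float, ss_err: float, df2: float,
           eps: float | None) -> dict:
    tol = 1e-12
    if ss_err <= tol * max(ss, 1.0):
        if ss <= tol:
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
    else:
        F = (ss / df1) / (ss_err / df2)
        e = 1.0 if eps is None else eps
        p = float(sps.f.sf(F, e * df1, e * df2))
    out_df1 = df1 if eps is None else eps * df1
    out_df2 = df2 if eps is None else eps * df2
    return {"effect": label, "F": F, "df1": out_df1, "df2": out_df2,
            "p": p, "eps": np.nan if eps is None else eps}


def rm_mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str,
    posthoc: bool = True,
    m: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Two-way mixed ANOVA (between x within) with GG correction.

    Subjects with missing cells are dropped (complete-case split-plot fit);
    the Greenhouse-Geisser epsilon estimated from the within-subject
    covariance corrects the degrees of freedom of the within and
    interaction terms, which yields the fractional dfs conventional in
    repeated-measures reporting. Per-timepoint between-group contrasts are
    Sidak-adjusted with family size ``m`` (default: number of timepoints).

    Returns ``(anova_table, posthoc_table)``.
    """
    for col in (dv, within, subject, between):
        if col not in data.columns:
            raise ValidationError(f"missing column {col!r}")
    cc = _complete_cases(data, dv, within, subject, between)
    n_levels = cc[within].nunique()
    if n_levels < 2:
        raise ValidationError("need >= 2 within-subject timepoints")
    group_sizes = cc.groupby(between)[subject].nunique()
    if len(group_sizes) < 2 or (group_sizes < 2).any():
        raise ValidationError("need >= 2 subjects per between-group level")

    if np.ptp(cc[dv].to_numpy()) == 0:
        table = pd.DataFrame({
            "effect": [between, within, "interaction"],
            "F": [0.0, 0.0, 0.0],
            "df1": [len(group_sizes) - 1.0, n_levels - 1.0,
                    (len(group_sizes) - 1.0) * (n_levels - 1.0)],
            "df2": [float(group_sizes.sum() - len(group_sizes))] * 3,
            "p": [1.0, 1.0, 1.0],
            "eps": [np.nan, 1.0, 1.0],
        })
    else:
        import pingouin as pg

        try:
            with np.errstate(divide="ignore", invalid="ignore"):
                aov = pg.mixed_anova(data=cc, dv=dv, within=within,
                                     subject=subject, between=between,
                                     correction=True)
            aov = aov.set_index("Source")
            eps = float(aov.loc[within].get("eps", 1.0))
            if not np.isfinite(eps):
                eps = 1.0
            rows = []
            for source, label, correct in (
                    (between, between, False), (within, within, True),
                    ("Interaction", "interaction", True)):
                r = aov.loc[source]
                F = float(r["F"])
                df1, df2 = float(r["DF1"]), float(r["DF2"])
                ss = float(r["SS"])
                e = eps if correct else np.nan
                if correct:
                    df1, df2 = eps * df1, eps * df2
                if not np.isfinite(F):
                    if abs(ss) < 1e-12:
                        F, p = 0.0, 1.0   # 0/0: no effect, no residual
                    else:
                        F, p = np.inf, 0.0  # structure with zero residual
                else:
                    p = float(sps.f.sf(F, df1, df2))
                rows.append({"effect": label, "F": F, "df1": df1,
                             "df2": df2, "p": p, "eps": e})
        except Exception:
            # degenerate data (zero residual strata) breaks the library
            # fit; fall back to the classical sums of squares
            comp = _splitplot_components(cc, dv, within, subject, between)
            rows = [_f_row(between, *comp[between], eps=None),
                    _f_row(within, *comp[within], eps=1.0),
                    _f_row("interaction", *comp["interaction"], eps=1.0)]
        table = pd.DataFrame(rows)

    post = None
    if posthoc:
        levels = sorted(cc[within].unique())
        fam = m if m is not None else len(levels)
        grp_levels = sorted(cc[between].unique())
        if len(grp_levels) != 2:
            raise ValidationError("post hoc contrasts expect 2 groups")
        rows = []
        for lvl in levels:
            sub = cc[cc[within] == lvl]
            x = sub.loc[sub[between] == grp_levels[0], dv].to_numpy()
            y = sub.loc[sub[between] == grp_levels[1], dv].to_numpy()
            if np.ptp(np.concatenate([x, y])) == 0:
                t, p = 0.0, 1.0
            else:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    t, p = sps.ttest_ind(x, y, equal_var=True)
                t, p = float(t), float(p)
                if not np.isfinite(p):
                    p = 0.0 if abs(x.mean() - y.mean()) > 0 else 1.0
            p_adj = sidak(p, fam)
            rows.append({within: lvl,
                         "mean_diff": float(x.mean() - y.mean()),
                         "t": t, "p_raw": p, "p_sidak": p_adj,
                         "stars": stars(p_adj)})
        post = pd.DataFrame(rows)
    return table, post


def change_from_baseline(data: pd.DataFrame, dv: str, subject: str,
                         within: str) -> pd.DataFrame:
    """Per-subject change from the earliest timepoint; baseline rows dropped."""
    for col in (dv, subject, within):
        if col not in data.columns:
            raise ValidationError(f"missing column {col!r}")
    baseline_lvl = data[within].min()
    out = []
    for subj, sub in data.groupby(subject, sort=False):
        sub = sub.sort_values(within)
        base = sub.loc[sub[within] == baseline_lvl, dv]
        if base.empty or base.isna().all():
            raise MissingDataError(f"subject {subj!r} lacks the baseline "
                                   f"timepoint {baseline_lvl!r}")
        delta = sub[sub[within] != baseline_lvl].copy()
        delta[dv] = delta[dv] - float(base.iloc[0])
        out.append(delta)
    return pd.concat(out, ignore_index=True)


# --------------------------------------------------------------------------
# a-priori sample size
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample-t power specification (percent-of-reference scale)."""

    mean_ref: float = 100.0
    mean_test: float = 70.0
    sd: float = 20.0
    alpha: float = 0.05
    power: float = 0.80
    attrition_inflation: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValidationError("power must be in (0, 1)")
        if self.sd <= 0:
            raise ValidationError("sd must be > 0")
        if self.attrition_inflation < 0:
            raise ValidationError("attrition_inflation must be >= 0")


def sample_size_ttest(spec: PowerSpec = PowerSpec()) -> tuple[int, int]:
    """Per-group n for a two-sided two-sample comparison, plus the
    attrition-inflated n.

    Uses the normal-approximation formula
    n = ceil(2 sd^2 (z_{1-alpha/2} + z_{power})^2 / delta^2).
    """
    delta = abs(spec.mean_ref - spec.mean_test)
    if delta == 0:
        raise InfeasibilityError("zero effect size: no finite sample size")
    z = sps.norm.ppf(1.0 - spec.alpha / 2.0) + sps.norm.ppf(spec.power)
    n = math.ceil(2.0 * spec.sd**2 * z**2 / delta**2)
    n_inflated = math.ceil(n * (1.0 + spec.attrition_inflation))
    return n, n_inflated
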