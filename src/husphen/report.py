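"""Study-report tables: per-group mean +/- SD summaries, ordinal score
frequency tables and significance-starred group comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DependencyError, ValidationError
from .histo import score_frequencies
from .stats import mann_whitney, stars


@dataclass
class StudyReport:
    mean_sd: pd.DataFrame | None = None
    comparisons: pd.DataFrame | None = None
    frequencies: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_markdown(self) -> str:
        parts = []
        if self.mean_sd is not None:
            parts.append("## Group summaries (mean ± SD)\n\n"
                         + self.mean_sd.to_markdown(index=False))
        if self.comparisons is not None:
            parts.append("## Group comparisons\n\n"
                         + self.comparisons.to_markdown(index=False))
        for name, table in self.frequencies.items():
            parts.append(f"## Score frequencies: {name}\n\n"
                         + table.to_markdown(index=False))
        return "\n\n".join(parts) + "\n"


def mean_sd_table(
    data: pd.DataFrame,
    value_vars: Sequence[str],
    group_cols: Sequence[str] = ("sex", "diet", "age_weeks"),
) -> pd.DataFrame:
    """Long-format per-group mean, SD and n for each value variable."""
    if data.empty:
        raise ValidationError("empty input table")
    missing = [c for c in list(value_vars) + list(group_cols)
               if c not in data.columns]
    if missing:
        raise ValidationError(f"missing column(s): {missing}")
    rows = []
    for key, sub in data.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for var in value_vars:
            vals = sub[var].dropna()
            rows.append(dict(zip(group_cols, key)) | {
                "variable": var,
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "n": int(len(vals)),
            })
    return pd.DataFrame(rows)


def _comparison_table(data: pd.DataFrame, value_vars, between: str,
                      within: str, strata: list[str]) -> pd.DataFrame:
    rows = []
    grp_levels = sorted(data[between].unique())
    if len(grp_levels) != 2:
        raise ValidationError("comparisons expect exactly 2 diet groups")
    strat_iter = (data.groupby(strata, sort=True) if strata
                  else [((), data)])
    for key, stratum in strat_iter:
        key = key if isinstance(key, tuple) else (key,)
        for lvl in sorted(stratum[within].unique()):
            sub = stratum[stratum[within] == lvl]
            for var in value_vars:
                a = sub.loc[sub[between] == grp_levels[0], var].dropna()
                b = sub.loc[sub[between] == grp_levels[1], var].dropna()
                if len(a) < 2 or len(b) < 2:
                    continue
                res = mann_whitney(a, b)
                rows.append(dict(zip(strata, key)) | {
                    within: lvl, "variable": var, "u": res.statistic,
                    "p": res.p_raw, "stars": stars(res.p_raw),
                })
    return pd.DataFrame(rows)


def build_report(
    cohort: pd.DataFrame | None = None,
    value_vars: Sequence[str] | None = None,
    scores: Mapping[str, tuple[pd.DataFrame, str]] | None = None,
    between: str = "diet",
    within: str = "age_weeks",
    strata: Sequence[str] = ("sex",),
) -> StudyReport:
    """Assemble the study tables from the available stage outputs.

    ``cohort`` (with ``value_vars``) feeds the mean +/- SD summaries and the
    per-timepoint Mann-Whitney comparisons with significance stars;
    ``scores`` maps a table name to ``(per-mouse score table, score column)``
    and feeds the frequency tables. A call with no stage output raises
    :class:`~husphen.errors.DependencyError`.
    """
    if cohort is None and not scores:
        raise DependencyError("no stage outputs supplied to build_report")
    report = StudyReport()
    if cohort is not None:
        if cohort.empty:
            raise DependencyError("cohort table is empty")
        if not value_vars:
            raise DependencyError("value_vars required with a cohort table")
        strata = [c for c in strata if c in cohort.columns]
        report.mean_sd = mean_sd_table(cohort, value_vars,
                                       [*strata, between, within])
        report.comparisons = _comparison_table(cohort, value_vars, between,
                                               within, strata)
    for name, (table, score_col) in (scores or {}).items():
        if table.empty:
            raise DependencyError(f"score table {name!r} is empty")
        group_cols = [c for c in (*strata, between) if c in table.columns]
        report.frequencies[name] = score_frequencies(table, score_col,
                                                     group_cols or [between])
    return report
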