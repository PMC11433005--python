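"""Histopathology scoring: NAFLD activity score, renal glomerular grading,
frequency tables and cross-modality correlation.

The NAFLD activity score (NAS) is the unweighted sum of an ordinal
steatosis term, hepatocyte hypertrophy and lobular inflammation (each 0-3),
ranging 0-9. Macro- and micro-vesicular steatosis are graded separately;
their combination into the single steatosis term uses the maximum of the
two by default (preserving the 0-9 range under mixed-pattern steatosis),
with a sum-capped-at-3 variant behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedValueError, ValidationError

NAS_MAX = 9
SUBSCORE_LEVELS = (0, 1, 2, 3)
FIBROSIS_LEVELS = ("absent", "mild", "moderate", "severe")

#: Renal glomerular grading cut points (fraction of glomeruli altered).
RENAL_CUTS = (0.30, 0.70)
RENAL_TARGET_GLOMERULI = 20


@dataclass(frozen=True)
class NAFLDScore:
    """Per-mouse liver histology grades."""

    macro: int
    micro: int
    hypertrophy: int
    inflammation: int
    fibrosis: str = "absent"
    saf: int = 0

    def __post_init__(self) -> None:
        for name in ("macro", "micro", "hypertrophy", "inflammation"):
            if getattr(self, name) not in SUBSCORE_LEVELS:
                raise ValidationError(f"{name} must be an integer in 0-3")
        if self.fibrosis not in FIBROSIS_LEVELS:
            raise ValidationError(f"fibrosis must be one of {FIBROSIS_LEVELS}")
        if self.saf not in (0, 1, 2):
            raise ValidationError("saf must be in 0-2")

    @property
    def nas(self) -> int:
        return nas(self.macro, self.micro, self.hypertrophy, self.inflammation)


@dataclass(frozen=True)
class RenalScore:
    """Per-mouse glomerular alteration counts and derived grade."""

    n_altered: int
    n_glomeruli_examined: int = RENAL_TARGET_GLOMERULI

    def __post_init__(self) -> None:
        if not 0 <= self.n_altered <= self.n_glomeruli_examined:
            raise ValidationError(
                "need 0 <= n_altered <= n_glomeruli_examined")

    @property
    def score(self) -> int:
        return renal_grade(self.n_altered, self.n_glomeruli_examined)


def nas(macro: int, micro: int, hypertrophy: int, inflammation: int,
        steatosis_rule: str = "max") -> int:
    """NAFLD activity score (0-9).

    ``steatosis_rule="max"`` takes max(macro, micro) as the steatosis term;
    ``"capped_sum"`` takes min(macro + micro, 3).
    """
    for name, v in (("macro", macro), ("micro", micro),
                    ("hypertrophy", hypertrophy),
                    ("inflammation", inflammation)):
        if v not in SUBSCORE_LEVELS:
            raise ValidationError(f"{name}={v!r} outside 0-3")
    if steatosis_rule == "max":
        steatosis = max(macro, micro)
    elif steatosis_rule == "capped_sum":
        steatosis = min(macro + micro, 3)
    else:
        raise ValidationError("steatosis_rule must be 'max' or 'capped_sum'")
    return steatosis + hypertrophy + inflammation


def renal_grade(n_altered: int, n_examined: int) -> int:
    """Ordinal 0-2 grade from the fraction of altered glomeruli.

    fraction < 30% -> 0; 30% <= fraction < 70% -> 1; fraction >= 70% -> 2.
    The boundary fractions are assigned to the higher grade (closed lower
    bounds), since the strict inequalities of the verbal rule leave them
    unassigned.
    """
    if n_examined <= 0:
        raise UndefinedValueError("no glomeruli examined")
    if not 0 <= n_altered <= n_examined:
        raise ValidationError("need 0 <= n_altered <= n_examined")
    f = n_altered / n_examined
    if f < RENAL_CUTS[0]:
        return 0
    if f < RENAL_CUTS[1]:
        return 1
    return 2


def score_frequencies(
    scores: pd.DataFrame,
    score_col: str,
    group_cols: list[str] | tuple[str, ...] = ("sex", "diet"),
    levels: list[int] | None = None,
) -> pd.DataFrame:
    """Per-group counts and percentages of each ordinal score level.

    Percentages are over the group n, truncated to 2 decimals to match the
    sevenths-style printing of small-group frequencies (6/7 -> 85.71,
    1/7 -> 14.28).
    """
    if score_col not in scores.columns:
        raise ValidationError(f"missing score column {score_col!r}")
    vals = scores[score_col]
    if not np.issubdtype(vals.dtype, np.number):
        raise ValidationError(f"{score_col!r} must be numeric ordinal")
    if levels is None:
        levels = sorted(vals.dropna().unique().astype(int))
    rows = []
    for key, sub in scores.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(sub)
        for level in levels:
            count = int((sub[score_col] == level).sum())
            pct = (np.floor(100.0 * count / n * 100.0 + 1e-9) / 100.0
                   if n else np.nan)
            rows.append(dict(zip(group_cols, key))
                        | {"score": level, "count": count, "n": n,
                           "percent": pct})
    return pd.DataFrame(rows)


def cross_modality_correlation(x, y) -> tuple[float, float]:
    """One-tailed Pearson correlation between two per-mouse series.

    Returns (r, p) where p tests positive association using the t
    distribution with n - 2 degrees of freedom. Requires at least three
    complete pairs and non-degenerate variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("missing pairs are not allowed")
    if len(x) < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedValueError("zero variance; correlation undefined")
    res = sps.pearsonr(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)
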