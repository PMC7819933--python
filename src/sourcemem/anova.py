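"""Repeated-measures and mixed ANOVAs for 2 x 2 (x group) judgment designs.

Because every factor has exactly two levels, each effect carries one degree
of freedom and is computed exactly from a per-participant contrast score:
the F statistic equals the squared t statistic of the corresponding
(paired or two-sample) contrast, with partial eta squared
``F / (F + df2)``.  Mixed-design within effects use the unweighted mean of
the group contrast means with the pooled within-group variance (the Type-III
solution for this design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "AnovaResult",
    "f_sf",
    "rm_anova_2x2",
    "mixed_anova_2x2x2",
    "cell_matrix_from_long",
    "paired_simple_effect",
    "BONFERRONI_SIMPLE_EFFECT_ALPHA",
]

#: Bonferroni-corrected level for the two follow-up simple effects.
BONFERRONI_SIMPLE_EFFECT_ALPHA = 0.025


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p_value: float
    partial_eta_sq: float

    def as_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": round(self.F, 6) if np.isfinite(self.F) else self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": round(self.p_value, 6) if np.isfinite(self.p_value) else self.p_value,
            "eta_p2": round(self.partial_eta_sq, 6)
            if np.isfinite(self.partial_eta_sq)
            else self.partial_eta_sq,
        }


def f_sf(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the central F distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError(f"invalid degrees of freedom ({df1}, {df2})")
    if F < 0:
        raise ValueError(f"F must be nonnegative, got {F}")
    return float(scipy.stats.f.sf(F, df1, df2))


def _result(effect: str, F: float, df2: int) -> AnovaResult:
    if not np.isfinite(F):
        return AnovaResult(effect, np.nan, 1, df2, np.nan, np.nan)
    return AnovaResult(effect, F, 1, df2, f_sf(F, 1, df2), F / (F + df2))


def cell_matrix_from_long(
    frame: pd.DataFrame,
    participant: str,
    factor_a: str,
    factor_b: str,
    value: str,
    group: str | None = None,
) -> tuple[np.ndarray, np.ndarray | None, pd.Index, int]:
    """Pivot a long cell-means frame into an (n, 2, 2) array.

    Participants with any missing cell are listwise-excluded; the number
    excluded is returned.  Factor levels are taken in sorted order.
    """
    cols = [participant, factor_a, factor_b, value] + ([group] if group else [])
    frame = frame[cols].copy()
    wide = frame.pivot_table(
        index=[participant] + ([group] if group else []),
        columns=[factor_a, factor_b],
        values=value,
        aggfunc="mean",
    )
    a_levels = sorted(frame[factor_a].unique())
    b_levels = sorted(frame[factor_b].unique())
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("both within factors must have exactly 2 levels")
    wide = wide.reindex(columns=pd.MultiIndex.from_product([a_levels, b_levels]))
    complete = wide.dropna()
    n_excluded = len(wide) - len(complete)
    x = complete.to_numpy().reshape(-1, 2, 2)
    if group:
        groups = complete.index.get_level_values(group).to_numpy()
        participants = complete.index.get_level_values(participant)
    else:
        groups = None
        participants = complete.index
    return x, groups, participants, n_excluded


def _contrasts(x: np.ndarray) -> dict[str, np.ndarray]:
    """Per-participant contrast scores of the three within effects."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 4:
        x = x.reshape(len(x), 4)
    a = (x[:, 0] + x[:, 1] - x[:, 2] - x[:, 3]) / 2.0
    b = (x[:, 0] - x[:, 1] + x[:, 2] - x[:, 3]) / 2.0
    ab = (x[:, 0] - x[:, 1] - x[:, 2] + x[:, 3]) / 2.0
    return {"A": a, "B": b, "AxB": ab}


def _paired_F(scores: np.ndarray) -> tuple[float, int]:
    n = len(scores)
    if n < 2:
        raise ValueError("need at least 2 participants")
    var = scores.var(ddof=1)
    if var == 0.0:
        mean = scores.mean()
        return (np.inf if mean != 0 else 0.0), n - 1
    return float(n * scores.mean() ** 2 / var), n - 1


def rm_anova_2x2(
    x: np.ndarray | Sequence[Sequence[float]],
    factor_a: str = "A",
    factor_b: str = "B",
) -> list[AnovaResult]:
    """Repeated-measures 2x2 ANOVA from an (n, 2, 2) cell-means array.

    Returns both main effects and the interaction.  Each F equals the squared
    paired t of the corresponding contrast with df2 = n - 1.  A zero contrast
    variance yields an undefined (NaN) F unless the contrast mean is also
    zero, in which case F = 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        x = x.reshape(len(x), 4)
    if x.shape[1] != 4:
        raise ValueError("expected an (n, 2, 2) or (n, 4) cell-means array")
    names = {"A": factor_a, "B": factor_b, "AxB": f"{factor_a} x {factor_b}"}
    results = []
    for key, scores in _contrasts(x).items():
        try:
            F, df2 = _paired_F(scores)
        except ValueError:
            raise
        if np.isinf(F):
            results.append(AnovaResult(names[key], np.nan, 1, len(scores) - 1, np.nan, np.nan))
        else:
            results.append(_result(names[key], F, df2))
    return results


def _pooled(scores: np.ndarray, groups: np.ndarray, levels: Sequence) -> tuple[np.ndarray, float, int]:
    means = np.array([scores[groups == lv].mean() for lv in levels])
    ss = sum(((scores[groups == lv] - scores[groups == lv].mean()) ** 2).sum() for lv in levels)
    df2 = len(scores) - 2
    return means, ss / df2 if df2 > 0 else np.nan, df2


def mixed_anova_2x2x2(
    x: np.ndarray,
    groups: np.ndarray,
    factor_a: str = "A",
    factor_b: str = "B",
    group_name: str = "group",
) -> list[AnovaResult]:
    """Mixed 2 (between) x 2 x 2 (within) ANOVA from cell means and group labels.

    Within effects and their interactions with group are two-sample tests on
    the per-participant contrast scores (pooled variance, df2 = n1 + n2 - 2);
    the between effect is a two-sample test on the participant means.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        x = x.reshape(len(x), 4)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("exactly 2 groups are required")
    n1, n2 = (np.sum(groups == lv) for lv in levels)
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 participants")
    names = {"A": factor_a, "B": factor_b, "AxB": f"{factor_a} x {factor_b}"}
    results: list[AnovaResult] = []

    # between-subjects main effect on participant means
    pmeans = x.mean(axis=1)
    means, pooled_var, df2 = _pooled(pmeans, groups, levels)
    se2 = pooled_var * (1.0 / n1 + 1.0 / n2)
    F = np.nan if se2 == 0 else float((means[0] - means[1]) ** 2 / se2)
    results.append(_result(group_name, F, df2) if np.isfinite(F) else AnovaResult(group_name, np.nan, 1, df2, np.nan, np.nan))

    for key, scores in _contrasts(x).items():
        means, pooled_var, df2 = _pooled(scores, groups, levels)
        se2 = pooled_var * (1.0 / n1 + 1.0 / n2)
        if se2 == 0:
            results.append(AnovaResult(names[key], np.nan, 1, df2, np.nan, np.nan))
            results.append(AnovaResult(f"{names[key]} x {group_name}", np.nan, 1, df2, np.nan, np.nan))
            continue
        # within main effect: unweighted grand mean of group contrast means
        F_within = float(((means[0] + means[1]) / 2.0) ** 2 / (se2 / 4.0))
        results.append(_result(names[key], F_within, df2))
        # within x group interaction: difference of group contrast means
        F_inter = float((means[0] - means[1]) ** 2 / se2)
        results.append(_result(f"{names[key]} x {group_name}", F_inter, df2))
    return results


def paired_simple_effect(
    x1: np.ndarray,
    x2: np.ndarray,
    effect: str = "simple effect",
    alpha: float = BONFERRONI_SIMPLE_EFFECT_ALPHA,
) -> tuple[AnovaResult, bool]:
    """Paired comparison of two within-subject cell means at a corrected alpha.

    Follow-up of a significant interaction; with two follow-ups the
    Bonferroni-corrected level is 0.025.
    """
    diff = np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)
    F, df2 = _paired_F(diff)
    if np.isinf(F):
        result = AnovaResult(effect, np.nan, 1, df2, np.nan, np.nan)
        return result, False
    result = _result(effect, F, df2)
    return result, bool(result.p_value < alpha)


def anova_table(results: Sequence[AnovaResult]) -> pd.DataFrame:
    """Effect table with columns effect,F,df1,df2,p,eta_p2."""
    return pd.DataFrame([r.as_dict() for r in results])
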