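"""Statistics cascade for UPLC global methylation (%5mdC) measurements.

For each grouping — one generation across dose rates, or one dose rate
across generations — the cascade reports Shapiro-Wilk normality per group,
Bartlett homoscedasticity, a one-way ANOVA across the groups, and, when the
ANOVA is significant at alpha, a Tukey HSD table of pairwise differences.
Shapiro/Bartlett results are reported but do not gate the ANOVA; percentages
are analysed untransformed by default (set ``logit=True`` to transform).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .types import DOSES, GENERATIONS

logger = logging.getLogger(__name__)


def shapiro_wilk(values) -> float:
    """Shapiro-Wilk normality p-value; NaN (signalled) for constant input."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(values) == 0:
        logger.warning("Shapiro-Wilk undefined for constant input")
        return float("nan")
    return float(st.shapiro(values).pvalue)


def bartlett(groups) -> float:
    """Bartlett equal-variance p-value across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Bartlett needs at least 2 groups")
    if all(np.ptp(g) == 0 for g in groups):
        logger.warning("Bartlett undefined when every group is constant")
        return float("nan")
    return float(st.bartlett(*groups).pvalue)


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA (F, p) across >= 2 groups of >= 2 values.

    Zero within-group *and* between-group variance is undefined and returned
    as (NaN, NaN) with a warning, not silently as p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        logger.warning("ANOVA undefined: zero variance within and between groups")
        return float("nan"), float("nan")
    res = st.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def tukey_hsd(groups, labels=None) -> pd.DataFrame:
    """All pairwise mean differences with studentized-range adjusted p.

    Returns a frame (group_a, group_b, mean_difference, p_adj) where
    mean_difference = mean(b) - mean(a).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [str(i) for i in range(len(groups))]
    flat = np.concatenate(groups)
    rows = []
    if np.ptp(flat) == 0:
        # degenerate: no variance anywhere; all adjusted p = 1
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                rows.append((labels[i], labels[j], 0.0, 1.0))
        return pd.DataFrame(rows, columns=["group_a", "group_b",
                                           "mean_difference", "p_adj"])
    res = st.tukey_hsd(*groups)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            diff = float(np.mean(groups[j]) - np.mean(groups[i]))
            rows.append((labels[i], labels[j], diff, float(res.pvalue[i, j])))
    return pd.DataFrame(rows, columns=["group_a", "group_b",
                                       "mean_difference", "p_adj"])


@dataclass
class StatsCascadeResult:
    """One grouping's cascade: normality, homoscedasticity, ANOVA, Tukey."""

    grouping: str                 # e.g. "generation:S1" or "dose:g30"
    group_labels: list[str]
    shapiro_p: dict[str, float]
    bartlett_p: float
    anova_F: float
    anova_p: float
    tukey: pd.DataFrame | None = None  # present iff anova_p < alpha


def run_global_cascade(
    uplc: pd.DataFrame, alpha: float = 0.05, logit: bool = False,
) -> list[StatsCascadeResult]:
    """Run the cascade within each generation (across doses) and within each
    dose (across generations), in deterministic order.

    Groupings with fewer than two member conditions (or conditions lacking
    replicates) are skipped with a logged warning.
    """
    df = uplc.copy()
    values = df["percent_5mdC"].to_numpy(float)
    if logit:
        eps = 1e-6
        p = np.clip(values / 100.0, eps, 1 - eps)
        df["_y"] = np.log(p / (1 - p))
    else:
        df["_y"] = values

    results: list[StatsCascadeResult] = []

    def run_one(grouping: str, members: list[tuple[str, np.ndarray]]) -> None:
        usable = [(label, y) for label, y in members if y.size >= 2]
        skipped = [label for label, y in members if y.size < 2]
        for label in skipped:
            logger.warning("%s: condition %s lacks replicates; skipped",
                           grouping, label)
        if len(usable) < 2:
            logger.warning("grouping %s skipped: fewer than 2 conditions",
                           grouping)
            return
        labels = [label for label, _ in usable]
        ys = [y for _, y in usable]
        shapiro_p = {}
        for label, y in usable:
            try:
                shapiro_p[label] = shapiro_wilk(y)
            except ValueError:
                shapiro_p[label] = float("nan")
        F, p = anova_oneway(ys)
        res = StatsCascadeResult(
            grouping=grouping, group_labels=labels, shapiro_p=shapiro_p,
            bartlett_p=bartlett(ys), anova_F=F, anova_p=p)
        if np.isfinite(p) and p < alpha:
            res.tukey = tukey_hsd(ys, labels)
        results.append(res)

    for gen in GENERATIONS:
        sub = df[df["generation"] == gen]
        if sub.empty:
            continue
        members = [(d, sub.loc[sub["dose"] == d, "_y"].to_numpy())
                   for d in DOSES if (sub["dose"] == d).any()]
        run_one(f"generation:{gen}", members)
    for dose in DOSES:
        sub = df[df["dose"] == dose]
        if sub.empty:
            continue
        members = [(g, sub.loc[sub["generation"] == g, "_y"].to_numpy())
                   for g in GENERATIONS if (sub["generation"] == g).any()]
        run_one(f"dose:{dose}", members)
    return results


def cascade_report(results: list[StatsCascadeResult]) -> pd.DataFrame:
    """Flatten cascade results to one row per grouping (TSV-friendly)."""
    rows = []
    for r in results:
        rows.append({
            "grouping": r.grouping,
            "groups": ",".join(r.group_labels),
            "bartlett_p": r.bartlett_p,
            "anova_F": r.anova_F,
            "anova_p": r.anova_p,
            "min_shapiro_p": min(r.shapiro_p.values()) if r.shapiro_p else
            float("nan"),
            "n_tukey_pairs": 0 if r.tukey is None else len(r.tukey),
        })
    return pd.DataFrame(rows)
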