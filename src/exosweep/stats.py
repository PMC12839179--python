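"""Condition comparison statistics (Shapiro-Wilk, one-way ANOVA, Tukey HSD).

Compares per-contact energy expenditure (J/kg) across walking conditions
-- unassisted baseline (BL), exoskeleton worn without actuation (EXO-NA)
and the two best exoskeleton settings (EXO-S1, EXO-S2) -- over a cohort
of paired foot contacts, reporting means +/- SD, the classical one-way
between/within variance decomposition and studentized-range post-hoc
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ConditionTable", "normality_check", "anova_oneway", "tukey_hsd",
    "condition_report",
]

CONDITION_LABELS = ("BL", "EXO-NA", "EXO-S1", "EXO-S2")


@dataclass
class ConditionTable:
    """Per-contact values per condition (paired contacts, equal n)."""

    labels: tuple[str, ...]
    values: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        self.values = tuple(np.asarray(v, float) for v in self.values)
        if len(self.labels) != len(self.values):
            raise ValueError("labels and value lists must match")
        n = {v.size for v in self.values}
        if len(n) != 1:
            raise ValueError("conditions must have equal n (paired contacts)")
        if any(not np.all(np.isfinite(v)) for v in self.values):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return self.values[0].size

    def means_sds(self) -> dict:
        return {lab: {"mean": float(v.mean()),
                      "sd": float(v.std(ddof=1))}
                for lab, v in zip(self.labels, self.values)}


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (delegated to scipy)."""
    x = np.asarray(values, float)
    if not 3 <= x.size <= 50:
        raise ValueError("Shapiro-Wilk check supports 3 <= n <= 50")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance")
    res = _sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(table: ConditionTable) -> tuple[float, int, int, float]:
    """One-way ANOVA: (F, df_between, df_within, p).

    Classical decomposition: SS_between = sum n_g (mean_g - grand)^2,
    SS_within = sum of squared within-group deviations, F = MS_b / MS_w.
    """
    groups = table.values
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 conditions with >= 2 values each")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_between = len(groups) - 1
    df_within = all_values.size - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        raise ValueError("zero within-group variance")
    F = ms_between / ms_within
    p = float(_sps.f.sf(F, df_between, df_within))
    return float(F), df_between, df_within, p


def tukey_hsd(table: ConditionTable, alpha: float = 0.05) -> list[dict]:
    """All-pairs Tukey HSD using MS_within from the one-way ANOVA.

    For each pair: mean difference, studentized-range statistic
    q = |diff| / sqrt(MS_w / n), its p-value, and significance at
    ``alpha``. Balanced groups (paired contacts) are assumed.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    groups = table.values
    k = len(groups)
    n = table.n
    _, _, df_within, _ = anova_oneway(table)
    ms_within = sum(float(np.sum((g - g.mean()) ** 2))
                    for g in groups) / df_within
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(groups[i].mean() - groups[j].mean())
            se = np.sqrt(ms_within / n)
            q = abs(diff) / se if se > 0 else np.inf
            p = float(_sps.studentized_range.sf(q, k, df_within))
            out.append({
                "pair": (table.labels[i], table.labels[j]),
                "difference": diff,
                "q": float(q),
                "p": p,
                "significant": bool(p < alpha),
            })
    return out


def condition_report(table: ConditionTable, alpha: float = 0.05) -> dict:
    """Full report: per-condition mean +/- SD, normality, ANOVA, Tukey."""
    report = {"n_per_condition": table.n,
              "conditions": table.means_sds()}
    if 3 <= table.n <= 50:
        report["shapiro_wilk"] = {
            lab: dict(zip(("W", "p"), normality_check(v)))
            for lab, v in zip(table.labels, table.values)
        }
    else:       # normality check undefined at this sample size
        report["shapiro_wilk"] = None
    F, dfb, dfw, p = anova_oneway(table)
    report["anova"] = {"F": F, "df_between": dfb, "df_within": dfw, "p": p}
    report["tukey"] = [
        {**cmp, "pair": list(cmp["pair"])} for cmp in tukey_hsd(table, alpha)
    ]
    report["alpha"] = alpha
    return report
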