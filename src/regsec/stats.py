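"""Group-comparison decision procedure and reporting.

Gates every comparison through Shapiro-Wilk normality (per group) and
Levene homogeneity of variances (median-centered). When both pass,
parametric tests are used (Student t for two groups, one-way ANOVA with
Tukey HSD post hoc for more); otherwise Mann-Whitney U, or Kruskal-Wallis
with pairwise Mann-Whitney and Holm step-down adjustment. Every gate
p-value is logged in the decision record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError

__all__ = [
    "DecisionRecord",
    "choose_test",
    "holm_adjust",
    "run_comparison",
]

ALPHA_GATE = 0.05


@dataclass
class DecisionRecord:
    """Log of the test-selection gates and the chosen procedure."""

    parametric: bool
    test_name: str
    posthoc: str | None
    shapiro_p: dict[str, float] = field(default_factory=dict)
    levene_p: float = float("nan")
    alpha: float = ALPHA_GATE


def _groups(table: pd.DataFrame, value_col: str, group_col: str
            ) -> dict[str, np.ndarray]:
    if value_col not in table.columns or group_col not in table.columns:
        raise AnalysisError(f"table lacks columns {value_col!r}/{group_col!r}")
    if table[value_col].isna().any():
        raise AnalysisError("missing values in the analyzed column")
    out = {str(g): np.asarray(sub[value_col], dtype=np.float64)
           for g, sub in table.groupby(group_col, sort=True)}
    if len(out) < 2:
        raise AnalysisError("need at least two groups")
    for name, vals in out.items():
        if len(vals) < 3:
            raise AnalysisError(f"group {name!r} has n < 3")
    return out


def choose_test(table: pd.DataFrame, value_col: str = "value",
                group_col: str = "group", alpha: float = ALPHA_GATE
                ) -> DecisionRecord:
    """Pick parametric vs non-parametric tests from the gate p-values."""
    groups = _groups(table, value_col, group_col)
    shapiro_p = {name: float(sps.shapiro(vals).pvalue)
                 for name, vals in groups.items()}
    levene_p = float(sps.levene(*groups.values(), center="median").pvalue)
    parametric = all(p > alpha for p in shapiro_p.values()) and levene_p > alpha
    k = len(groups)
    if parametric:
        test = "t-test" if k == 2 else "one-way ANOVA"
        posthoc = None if k == 2 else "Tukey HSD"
    else:
        test = "Mann-Whitney U" if k == 2 else "Kruskal-Wallis"
        posthoc = None if k == 2 else "Mann-Whitney U + Holm"
    return DecisionRecord(parametric=parametric, test_name=test, posthoc=posthoc,
                          shapiro_p=shapiro_p, levene_p=levene_p, alpha=alpha)


def holm_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Holm step-down adjustment, input order preserved.

    The sorted p-values are multiplied by ``m, m-1, ..., 1``, a running
    maximum enforces monotonicity, and results are capped at 1.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if ((p < 0) | (p > 1)).any():
        raise AnalysisError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def run_comparison(table: pd.DataFrame, value_col: str = "value",
                   group_col: str = "group", alpha: float = ALPHA_GATE
                   ) -> tuple[pd.DataFrame, DecisionRecord]:
    """Run the selected omnibus test and post hoc comparisons.

    Returns a tidy report (one row per comparison: comparison label,
    statistic, raw p, adjusted p, test name) and the decision record.
    """
    decision = choose_test(table, value_col, group_col, alpha)
    groups = _groups(table, value_col, group_col)
    names = list(groups)
    rows: list[dict] = []

    if len(groups) == 2:
        a, b = groups[names[0]], groups[names[1]]
        if decision.parametric:
            res = sps.ttest_ind(a, b, equal_var=True)
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"comparison": f"{names[0]} vs {names[1]}",
                     "statistic": float(res.statistic),
                     "p_raw": float(res.pvalue), "p_adjusted": float(res.pvalue),
                     "test": decision.test_name})
    elif decision.parametric:
        f = sps.f_oneway(*groups.values())
        rows.append({"comparison": "omnibus", "statistic": float(f.statistic),
                     "p_raw": float(f.pvalue), "p_adjusted": float(f.pvalue),
                     "test": "one-way ANOVA"})
        tk = sps.tukey_hsd(*groups.values())
        for i, j in combinations(range(len(names)), 2):
            rows.append({"comparison": f"{names[i]} vs {names[j]}",
                         "statistic": float(tk.statistic[i, j]),
                         "p_raw": float(tk.pvalue[i, j]),
                         "p_adjusted": float(tk.pvalue[i, j]),
                         "test": "Tukey HSD"})
    else:
        kw = sps.kruskal(*groups.values())
        rows.append({"comparison": "omnibus", "statistic": float(kw.statistic),
                     "p_raw": float(kw.pvalue), "p_adjusted": float(kw.pvalue),
                     "test": "Kruskal-Wallis"})
        pair_rows = []
        for g1, g2 in combinations(names, 2):
            res = sps.mannwhitneyu(groups[g1], groups[g2], alternative="two-sided")
            pair_rows.append({"comparison": f"{g1} vs {g2}",
                              "statistic": float(res.statistic),
                              "p_raw": float(res.pvalue),
                              "test": "Mann-Whitney U + Holm"})
        adj = holm_adjust([r["p_raw"] for r in pair_rows])
        for r, p_adj in zip(pair_rows, adj):
            r["p_adjusted"] = float(p_adj)
        rows.extend(pair_rows)

    report = pd.DataFrame(rows, columns=["comparison", "statistic", "p_raw",
                                         "p_adjusted", "test"])
    return report, decision
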