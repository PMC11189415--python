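"""Nonparametric group-difference tests on anxiety scores and judgment variables.

Two families of post hoc tests:

* anxiety scores across the levels of each contextual variable - Wilcoxon
  rank-sum for two-level variables, Kruskal-Wallis (tie-corrected) for more
  than two levels;
* judgment-variable median shifts between the 'higher' and 'lower' anxiety
  groups at each STAI-S threshold - one-sided Wilcoxon rank-sum tests in
  both directions, Bonferroni-corrected across the six tests per variable
  (two directions x three thresholds, alpha = 0.05 / 6 ~ 0.0083).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

BONFERRONI_ALPHA = 0.05 / 6  # six tests per judgment variable

#: Contextual variables tested for score differences (edu_years excluded;
#: age enters as its 3-level bin).
CONTEXTUAL_TEST_VARS: tuple[str, ...] = (
    "loneliness", "age3", "sex", "income", "marital", "employment",
    "edu", "race_ethnicity", "covid_test", "covid_diagnosis",
)

#: Small-sample cutoff below which the exact rank-sum distribution is used.
EXACT_TEST_MAX_N = 50


@dataclass
class GroupTestResult:
    variable: str
    test: str  # kruskal_wallis / wilcoxon_rank_sum / wilcoxon_one_sided
    alternative: str  # 'two-sided', 'H>L' or 'H<L'
    p_value: float
    threshold: float | None = None
    bonferroni_significant: bool | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {"variable": self.variable, "test": self.test,
                "alternative": self.alternative, "p_value": self.p_value,
                "threshold": self.threshold,
                "bonferroni_significant": self.bonferroni_significant,
                "note": self.note}


def _rank_sum_method(n1: int, n2: int) -> str:
    return "exact" if min(n1, n2) < EXACT_TEST_MAX_N else "asymptotic"


def contextual_differences(cohort: pd.DataFrame, score_col: str = "stai_s",
                           variables: Sequence[str] = CONTEXTUAL_TEST_VARS
                           ) -> list[GroupTestResult]:
    """Test the anxiety score across the levels of each contextual variable."""
    results = []
    score = cohort[score_col]
    for var in variables:
        if var not in cohort.columns:
            results.append(GroupTestResult(var, "skipped", "two-sided",
                                           float("nan"), note="column absent"))
            continue
        groups = [score[cohort[var] == lvl].to_numpy()
                  for lvl in sorted(cohort[var].dropna().unique())]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            results.append(GroupTestResult(var, "skipped", "two-sided",
                                           float("nan"), note="single level"))
            continue
        if len(groups) == 2:
            stat = stats.mannwhitneyu(groups[0], groups[1],
                                      alternative="two-sided",
                                      method="asymptotic")
            results.append(GroupTestResult(var, "wilcoxon_rank_sum",
                                           "two-sided", float(stat.pvalue)))
        else:
            stat = stats.kruskal(*groups)
            results.append(GroupTestResult(var, "kruskal_wallis",
                                           "two-sided", float(stat.pvalue)))
    return results


def judgment_differences(cohort: pd.DataFrame,
                         judgment_vars: Sequence[str] | None = None,
                         thresholds: Sequence[float] = (35, 45, 55),
                         score_col: str = "stai_s") -> list[GroupTestResult]:
    """One-sided rank-sum tests of each judgment variable between anxiety groups.

    For every variable and threshold both alternatives are tested: 'H>L'
    (median higher in the 'higher'-anxiety group) and 'H<L'. The Bonferroni
    flag marks p below 0.05/6, correcting over the six tests per variable.
    """
    from .rpt_features import JUDGMENT_VARIABLES

    judgment = list(judgment_vars) if judgment_vars is not None else list(JUDGMENT_VARIABLES)
    score = cohort[score_col]
    results = []
    for var in judgment:
        vals = cohort[var]
        for thr in thresholds:
            hi = vals[score >= thr].dropna().to_numpy()
            lo = vals[score < thr].dropna().to_numpy()
            if len(hi) == 0 or len(lo) == 0:
                results.append(GroupTestResult(
                    var, "wilcoxon_one_sided", "H>L", float("nan"),
                    threshold=thr, note="empty group; skipped"))
                continue
            method = _rank_sum_method(len(hi), len(lo))
            for alt_label, alt in (("H>L", "greater"), ("H<L", "less")):
                p = float(stats.mannwhitneyu(hi, lo, alternative=alt,
                                             method=method).pvalue)
                results.append(GroupTestResult(
                    var, "wilcoxon_one_sided", alt_label, p, threshold=thr,
                    bonferroni_significant=bool(p < BONFERRONI_ALPHA)))
    return results


def results_frame(results: Sequence[GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def group_summaries(cohort: pd.DataFrame,
                    judgment_vars: Sequence[str] | None = None,
                    thresholds: Sequence[float] = (35, 45, 55),
                    score_col: str = "stai_s") -> pd.DataFrame:
    """Median and quartiles of each judgment variable per anxiety group."""
    from .rpt_features import JUDGMENT_VARIABLES

    judgment = list(judgment_vars) if judgment_vars is not None else list(JUDGMENT_VARIABLES)
    rows = []
    for thr in thresholds:
        grp = np.where(cohort[score_col] >= thr, "higher", "lower")
        for var in judgment:
            for g in ("higher", "lower"):
                v = cohort.loc[grp == g, var].dropna()
                if len(v) == 0:
                    continue
                rows.append({"threshold": thr, "variable": var, "group": g,
                             "n": len(v), "q1": float(v.quantile(0.25)),
                             "median": float(v.median()),
                             "q3": float(v.quantile(0.75))})
    return pd.DataFrame(rows)
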