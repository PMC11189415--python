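"""Mediation (Baron & Kenny / Sobel) and moderation (interaction) models.

Mediation asks whether a mediator Me carries the effect of an independent
variable X on the outcome Y. Three ordinary least-squares fits give the
path coefficients:

    Y  = g1 + c*X            (total effect)
    Me = g2 + a*X            (X -> mediator)
    Y  = g3 + c'*X + b*Me    (direct effect c' and mediator effect b)

The Sobel z statistic tests the indirect effect a*b (identical to c - c'
for nested OLS fits):

    z = a*b / sqrt(b^2 * s_a^2 + a^2 * s_b^2)

with a two-tailed normal p-value. The mediated percentage is
T_eff = 100 * (1 - c'/c); mediation is declared when p_a, p_b, p_c < 0.05,
p_Sobel < 0.05 and T_eff > 50.

Moderation fits the interaction model Y = b0 + b1*X + b2*Mo + b3*(X*Mo) + e
and tests H0: b3 = 0 with a partial F-test against the restricted model
without the interaction; the verdict requires p_b3 <= 0.05 and an overall
model F-test with p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

ALPHA = 0.05


class DegenerateModelError(ValueError):
    """Raised for collinear or constant regressors."""


def _ols(y: np.ndarray, X: np.ndarray):
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    res = model.fit()
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise DegenerateModelError("collinear regressors")
    return res


def _as_float(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D numeric vector")
    return arr


@dataclass
class MediationResult:
    x_name: str
    me_name: str
    y_name: str
    c: float
    p_c: float
    a: float
    s_a: float
    p_a: float
    b: float
    s_b: float
    p_b: float
    c_prime: float
    p_c_prime: float
    intercepts: tuple[float, float, float]
    residual_variances: tuple[float, float, float]
    sobel_z: float
    p_sobel: float
    t_eff: float  # percent of the total effect that is mediated
    significant: bool
    reason: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "x_name", "me_name", "y_name", "c", "p_c", "a", "p_a", "b", "p_b",
            "c_prime", "sobel_z", "p_sobel", "t_eff", "significant", "reason")}


def mediate(x, me, y, *, x_name: str = "X", me_name: str = "Me",
            y_name: str = "Y") -> MediationResult:
    """Run the four-step mediation analysis of X -> Me -> Y.

    Requires equal-length vectors of at least 10 observations with
    non-constant X and Me. A zero total effect c leaves T_eff undefined
    (reported as NaN, verdict False with a reason).
    """
    x, me, y = _as_float(x), _as_float(me), _as_float(y)
    if not (len(x) == len(me) == len(y)):
        raise ValueError("x, me, y must have equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(x) == 0 or np.ptp(me) == 0:
        raise DegenerateModelError("constant X or Me")

    r1 = _ols(y, x[:, None])                 # total effect
    r2 = _ols(me, x[:, None])                # X -> Me
    r3 = _ols(y, np.column_stack([x, me]))   # direct + mediator

    c, p_c = r1.params[1], r1.pvalues[1]
    a, s_a, p_a = r2.params[1], r2.bse[1], r2.pvalues[1]
    c_prime, p_c_prime = r3.params[1], r3.pvalues[1]
    b, s_b, p_b = r3.params[2], r3.bse[2], r3.pvalues[2]

    denom = np.sqrt(b ** 2 * s_a ** 2 + a ** 2 * s_b ** 2)
    sobel_z = (a * b) / denom if denom > 0 else 0.0
    p_sobel = 2.0 * stats.norm.sf(abs(sobel_z)) if denom > 0 else 1.0

    reason = ""
    if c == 0:
        t_eff = float("nan")
        reason = "total effect c is zero; T_eff undefined"
    else:
        t_eff = 100.0 * (1.0 - c_prime / c)

    significant = (p_a < ALPHA and p_b < ALPHA and p_c < ALPHA
                   and p_sobel < ALPHA and np.isfinite(t_eff) and t_eff > 50.0)

    return MediationResult(
        x_name=x_name, me_name=me_name, y_name=y_name,
        c=float(c), p_c=float(p_c), a=float(a), s_a=float(s_a), p_a=float(p_a),
        b=float(b), s_b=float(s_b), p_b=float(p_b),
        c_prime=float(c_prime), p_c_prime=float(p_c_prime),
        intercepts=(float(r1.params[0]), float(r2.params[0]), float(r3.params[0])),
        residual_variances=(float(r1.mse_resid), float(r2.mse_resid), float(r3.mse_resid)),
        sobel_z=float(sobel_z), p_sobel=float(p_sobel), t_eff=float(t_eff),
        significant=bool(significant), reason=reason)


@dataclass
class DirectedMediation:
    original: MediationResult
    swapped: MediationResult

    @property
    def directed(self) -> bool:
        """True when only the stated X -> Me -> Y orientation mediates."""
        return self.original.significant and not self.swapped.significant


def mediation_direction_check(x, me, y, **names) -> DirectedMediation:
    """Run mediation both ways (X/Me swapped) to test directionality."""
    x_name = names.get("x_name", "X")
    me_name = names.get("me_name", "Me")
    y_name = names.get("y_name", "Y")
    orig = mediate(x, me, y, x_name=x_name, me_name=me_name, y_name=y_name)
    swap = mediate(me, x, y, x_name=me_name, me_name=x_name, y_name=y_name)
    return DirectedMediation(original=orig, swapped=swap)


@dataclass
class ModerationResult:
    x_name: str
    mo_name: str
    y_name: str
    beta: tuple[float, float, float, float]       # b0, b1, b2, b3
    p_beta: tuple[float, float, float, float]
    restricted_beta: tuple[float, float, float]   # b0, b1, b2 without interaction
    partial_f: float
    p_b3: float
    overall_f: float
    p_overall: float
    significant: bool

    def to_dict(self) -> dict:
        return {"x_name": self.x_name, "mo_name": self.mo_name,
                "y_name": self.y_name, "beta3": self.beta[3],
                "partial_f": self.partial_f, "p_b3": self.p_b3,
                "overall_f": self.overall_f, "p_overall": self.p_overall,
                "significant": self.significant}


def moderate(x, mo, y, *, x_name: str = "X", mo_name: str = "Mo",
             y_name: str = "Y") -> ModerationResult:
    """Interaction model with partial-F test of the X*Mo term."""
    x, mo, y = _as_float(x), _as_float(mo), _as_float(y)
    if not (len(x) == len(mo) == len(y)):
        raise ValueError("x, mo, y must have equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(x) == 0 or np.ptp(mo) == 0:
        raise DegenerateModelError("constant X or Mo")

    inter = x * mo
    full_X = np.column_stack([x, mo, inter])
    if np.linalg.matrix_rank(sm.add_constant(full_X)) < 4:
        raise DegenerateModelError("interaction term collinear with X or Mo")
    full = _ols(y, full_X)
    restricted = _ols(y, np.column_stack([x, mo]))

    n = len(y)
    df_full = n - 4
    num = (restricted.ssr - full.ssr) / 1.0
    den = full.ssr / df_full
    partial_f = num / den if den > 0 else float("inf")
    p_b3 = float(stats.f.sf(partial_f, 1, df_full))
    overall_f = float(full.fvalue)
    p_overall = float(full.f_pvalue)

    significant = p_b3 <= ALPHA and p_overall <= ALPHA
    return ModerationResult(
        x_name=x_name, mo_name=mo_name, y_name=y_name,
        beta=tuple(float(v) for v in full.params),
        p_beta=tuple(float(v) for v in full.pvalues),
        restricted_beta=tuple(float(v) for v in restricted.params),
        partial_f=float(partial_f), p_b3=p_b3,
        overall_f=overall_f, p_overall=p_overall,
        significant=bool(significant))


def screen_all_pairs(cohort: pd.DataFrame,
                     contextuals: Sequence[str] = ("age", "loneliness", "income", "employment"),
                     judgment_vars: Sequence[str] | None = None,
                     y_col: str = "stai_s") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mediation and moderation screens for all contextual x judgment pairs.

    Judgment variables act as X, each contextual variable as Me (with the
    swapped direction also run) or Mo, and the anxiety score as Y. Ordinal
    contextual variables enter as their numeric codes. Returns one row per
    pair: a mediation table (with direction flag) and a moderation table.
    """
    from .rpt_features import JUDGMENT_VARIABLES

    judgment = list(judgment_vars) if judgment_vars is not None else list(JUDGMENT_VARIABLES)
    y = cohort[y_col].to_numpy(dtype=float)

    med_rows, mod_rows = [], []
    for ctx, jv in product(contextuals, judgment):
        xv = cohort[jv].to_numpy(dtype=float)
        cv = cohort[ctx].to_numpy(dtype=float)
        pair = mediation_direction_check(xv, cv, y, x_name=jv, me_name=ctx,
                                         y_name=y_col)
        row = pair.original.to_dict()
        row["swapped_significant"] = pair.swapped.significant
        row["directed"] = pair.directed
        med_rows.append(row)
        mod_rows.append(moderate(xv, cv, y, x_name=jv, mo_name=ctx,
                                 y_name=y_col).to_dict())
    return pd.DataFrame(med_rows), pd.DataFrame(mod_rows)
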