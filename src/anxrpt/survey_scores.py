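"""STAI-S scoring, contextual-variable encoding, and participant exclusion filters.

The state scale of the State-Trait Anxiety Inventory (STAI-S) has 20 items
answered on a 4-point Likert scale (1 = "Not at all" ... 4 = "Very much so").
Ten items are worded in the anxiety-absent direction and are reverse-keyed
(r -> 5 - r) before summing, so the total ranges from 20 to 80.

Survey-quality filters mirror common vendor practice: straight-lining within
any question section, implausibly many clinician diagnoses, an education
level inconsistent with reported years of education, and too-fast completion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Items of form Y-1 keyed in the anxiety-absent direction (1-based item numbers).
#: Kept as module-level config so the key can be corrected without code change.
REVERSE_KEYED_ITEMS: frozenset[int] = frozenset({1, 2, 5, 8, 10, 11, 15, 16, 19, 20})

STAI_ITEM_COLUMNS: tuple[str, ...] = tuple(f"stai{i}" for i in range(1, 21))

#: Minimum years of education considered consistent with each education level.
EDU_MIN_YEARS: dict[str, int] = {
    "less_than_high_school": 0,
    "high_school": 10,
    "some_college": 12,
    "college_degree": 14,
    "graduate_degree": 16,
}

#: Declared level order for ordinal contextual variables (code 0, 1, 2, ...).
ORDINAL_LEVEL_ORDERS: dict[str, tuple[str, ...]] = {
    "edu": (
        "less_than_high_school",
        "high_school",
        "some_college",
        "college_degree",
        "graduate_degree",
    ),
}

#: Unordered categorical variables and their admissible labels.
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "marital": ("single", "married", "divorced", "separated", "widowed", "living_with_partner"),
    "employment": ("unemployed", "student", "employed_part", "employed_full", "multiple_jobs", "retired"),
    "race_ethnicity": ("white", "black", "hispanic", "asian", "mixed", "other"),
    "covid_test": ("no", "yes"),
    "covid_diagnosis": ("no", "yes"),
}

MIN_COMPLETION_SECONDS = 800.0
MAX_DIAGNOSES = 10  # ten or more clinician-diagnosed illnesses -> exclude

#: Age bin edges for the 3-level age factor: [18, 40) / [40, cut+1) / [cut+1, inf).
AGE_BIN_UPPER_YOUNG = 39
AGE_BIN_UPPER_MIDDLE = 55  # configurable middle cut


class SurveyValidationError(ValueError):
    """Raised for malformed survey records (out-of-range items, unknown labels)."""


def score_stai_s(item_responses: Sequence[int]) -> int:
    """Score one participant's 20 STAI-S item responses into the 20-80 sum.

    Reverse-keyed items are mapped r -> 5 - r before summing. Missing or
    out-of-range items reject the record; no imputation is attempted.
    """
    items = list(item_responses)
    if len(items) != 20:
        raise SurveyValidationError(f"expected 20 STAI-S items, got {len(items)}")
    total = 0
    for i, r in enumerate(items, start=1):
        if r is None or (isinstance(r, float) and np.isnan(r)):
            raise SurveyValidationError(f"item {i} is missing")
        r = int(r)
        if not 1 <= r <= 4:
            raise SurveyValidationError(f"item {i} response {r} outside 1..4")
        total += (5 - r) if i in REVERSE_KEYED_ITEMS else r
    return total


def score_stai_table(items: pd.DataFrame) -> pd.Series:
    """Vectorized STAI-S scoring for a wide item table (columns stai1..stai20)."""
    missing = [c for c in STAI_ITEM_COLUMNS if c not in items.columns]
    if missing:
        raise SurveyValidationError(f"missing STAI item columns: {missing}")
    vals = items[list(STAI_ITEM_COLUMNS)].to_numpy()
    if np.isnan(vals.astype(float)).any():
        raise SurveyValidationError("missing STAI item responses")
    vals = vals.astype(int)
    if vals.min() < 1 or vals.max() > 4:
        raise SurveyValidationError("STAI item responses outside 1..4")
    rev = np.array([i in REVERSE_KEYED_ITEMS for i in range(1, 21)])
    scored = np.where(rev, 5 - vals, vals)
    return pd.Series(scored.sum(axis=1), index=items.index, name="stai_s")


@dataclass
class FilterReport:
    """Outcome of applying exclusion rules to a participant table."""

    triggered: dict[object, list[str]]  # participant id -> rules violated
    rule_counts: dict[str, int]
    retained_ids: list[object]

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    @property
    def n_excluded(self) -> int:
        return len(self.triggered)

    def to_dict(self) -> dict:
        return {
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "rule_counts": dict(self.rule_counts),
            "excluded": {str(k): v for k, v in self.triggered.items()},
        }


def apply_vendor_filters(
    survey: pd.DataFrame,
    *,
    sections: Mapping[str, Sequence[str]] | None = None,
    min_completion_seconds: float = MIN_COMPLETION_SECONDS,
    max_diagnoses: int = MAX_DIAGNOSES,
    edu_min_years: Mapping[str, int] | None = None,
) -> FilterReport:
    """Flag participants violating any of the four survey-quality rules.

    Parameters
    ----------
    survey
        One row per participant (indexed by participant id) with at least
        ``completion_seconds``, ``diagnosis_count``, ``edu``, ``edu_years``
        and the item columns named in ``sections``.
    sections
        Named question blocks checked for straight-lining (zero variance of
        responses within a block). Defaults to the STAI-S block.

    Filters are order-independent: each rule is evaluated on the raw input.
    """
    if sections is None:
        sections = {"stai": [c for c in STAI_ITEM_COLUMNS if c in survey.columns]}
    edu_min_years = dict(edu_min_years or EDU_MIN_YEARS)

    triggered: dict[object, list[str]] = {}

    def flag(pid: object, rule: str) -> None:
        triggered.setdefault(pid, []).append(rule)

    for pid, row in survey.iterrows():
        ct = row.get("completion_seconds")
        if ct is None or (isinstance(ct, float) and np.isnan(ct)):
            flag(pid, "missing_completion_time")
        elif float(ct) < min_completion_seconds:
            flag(pid, "fast_completion")
        dc = row.get("diagnosis_count")
        if dc is not None and not pd.isna(dc) and int(dc) >= max_diagnoses:
            flag(pid, "many_diagnoses")
        edu = row.get("edu")
        ey = row.get("edu_years")
        if edu in edu_min_years and ey is not None and not pd.isna(ey):
            if int(ey) < edu_min_years[edu]:
                flag(pid, "edu_mismatch")
        for name, cols in sections.items():
            if not cols:
                continue
            vals = row[list(cols)].to_numpy(dtype=float)
            if len(vals) > 1 and np.nanstd(vals) == 0.0:
                flag(pid, f"straight_line_{name}")

    retained = [pid for pid in survey.index if pid not in triggered]
    counts: dict[str, int] = {}
    for rules in triggered.values():
        for r in rules:
            counts[r] = counts.get(r, 0) + 1
    return FilterReport(triggered=triggered, rule_counts=counts, retained_ids=retained)


def bin_age(age: float, *, upper_young: int = AGE_BIN_UPPER_YOUNG,
            upper_middle: int = AGE_BIN_UPPER_MIDDLE) -> int:
    """Map age in years to the 3-level age factor (0 young / 1 middle / 2 older)."""
    if age <= upper_young:
        return 0
    if age <= upper_middle:
        return 1
    return 2


def encode_contextuals(
    raw: pd.DataFrame,
    *,
    loneliness_levels: int = 5,
    income_levels: int = 7,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Encode the 11 contextual variables to numeric codes.

    Ordinal variables use their declared level order; unordered categories get
    stable integer codes from the declared label lists. Age is passed through
    in years and additionally binned to the 3-level factor ``age3``. The
    encoding map is returned for audit.

    Raises
    ------
    SurveyValidationError
        If a category label is not in the declared level set.
    """
    required = ["loneliness", "age", "sex", "income", "marital", "employment",
                "edu", "edu_years", "race_ethnicity", "covid_test", "covid_diagnosis"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SurveyValidationError(f"missing contextual columns: {missing}")

    out = pd.DataFrame(index=raw.index)
    encoding: dict[str, dict] = {}

    for var in ("loneliness", "income"):
        n_levels = loneliness_levels if var == "loneliness" else income_levels
        vals = raw[var].astype(int)
        bad = vals[(vals < 1) | (vals > n_levels)]
        if len(bad):
            raise SurveyValidationError(f"{var} values outside 1..{n_levels}: {sorted(set(bad))}")
        out[var] = vals
        encoding[var] = {i: i for i in range(1, n_levels + 1)}

    out["age"] = raw["age"].astype(float)
    out["age3"] = raw["age"].astype(float).map(bin_age).astype(int)
    encoding["age3"] = {"young(18-39)": 0, "middle(40-55)": 1, "older(56+)": 2}

    out["edu_years"] = raw["edu_years"].astype(int)

    for var, levels in ORDINAL_LEVEL_ORDERS.items():
        codes = {lab: i for i, lab in enumerate(levels)}
        out[var] = _map_labels(raw[var], codes, var)
        encoding[var] = codes

    for var, levels in CATEGORY_LEVELS.items():
        codes = {lab: i for i, lab in enumerate(levels)}
        out[var] = _map_labels(raw[var], codes, var)
        encoding[var] = codes

    return out, encoding


def _map_labels(col: pd.Series, codes: Mapping[str, int], var: str) -> pd.Series:
    unknown = set(col.dropna()) - set(codes)
    if unknown:
        raise SurveyValidationError(f"unknown {var} label(s): {sorted(unknown)}")
    return col.map(codes).astype("Int64").astype(int)
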