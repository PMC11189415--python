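"""Synthetic survey cohorts with the statistical structure the analysis assumes.

A single latent anxiety trait z ~ N(0, 1) per participant drives:

* the 20 STAI-S items, through a cumulative-logit ordinal model with
  item-specific thresholds (reverse-keyed items load negatively on z so that
  their *scored* contribution still rises with z);
* contextual gradients - loneliness rises with z, age and household income
  fall with z (the directions seen in anxiety cohorts);
* the picture ratings, so that high-z participants show a steeper negative
  value limb (higher loss aversion), a flatter negative-limb curvature at
  their mean negative entropy (lower loss resilience), and a narrower
  angular spread of the per-category (H+, H-) points (lower tradeoff range).

All effect strengths scale with ``anxiety_effect``; at 0 every variable is
independent of z. All randomness comes from one generator seeded by
``CohortSpec.seed``; two calls with the same spec are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .survey_scores import (
    CATEGORY_LEVELS,
    EDU_MIN_YEARS,
    ORDINAL_LEVEL_ORDERS,
    REVERSE_KEYED_ITEMS,
    STAI_ITEM_COLUMNS,
)

_VALID_DIRECTIONS = {"+", "-", "none"}

DEFAULT_CONTEXTUAL_GRADIENTS: dict[str, str] = {
    "loneliness": "+",
    "age": "-",
    "income": "-",
}

#: Directions of the judgment-variable median shifts planted in the
#: high-anxiety stratum (recoverable by the post hoc tests at n >= 2000).
DEFAULT_RATING_SHIFT_PROFILE: dict[str, str] = {
    "LA": "+",
    "LR": "-",
    "TradeoffRange": "-",
}


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of one synthetic cohort."""

    n_participants: int
    seed: int
    anxiety_effect: float = 1.0
    contextual_gradients: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXTUAL_GRADIENTS))
    rating_shift_profile: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_RATING_SHIFT_PROFILE))
    missing_rate: float = 0.0
    loneliness_levels: int = 5
    income_levels: int = 7

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.anxiety_effect < 0:
            raise ValueError("anxiety_effect must be >= 0")
        for m in (self.contextual_gradients, self.rating_shift_profile):
            bad = set(m.values()) - _VALID_DIRECTIONS
            if bad:
                raise ValueError(f"invalid direction labels: {sorted(bad)}")


@dataclass
class SyntheticCohort:
    """All generated tables, sharing one participant index, plus ground truth."""

    spec: CohortSpec
    ratings: pd.DataFrame          # long: participant_id, picture_id, category, rating
    stai_items: pd.DataFrame       # wide: stai1..stai20
    contextual: pd.DataFrame       # 11 contextual variables
    completion_seconds: pd.Series
    diagnosis_count: pd.Series
    latent_trait: pd.Series        # ground-truth z
    invalid_reason: pd.Series      # ground-truth tag; None for clean rows

    @property
    def participant_ids(self) -> pd.Index:
        return self.stai_items.index

    def survey_frame(self) -> pd.DataFrame:
        """One row per participant with everything the vendor filters need."""
        out = pd.concat([self.stai_items, self.contextual], axis=1)
        out["completion_seconds"] = self.completion_seconds
        out["diagnosis_count"] = self.diagnosis_count
        return out


def _gradient_sign(gradients: Mapping[str, str], var: str) -> float:
    d = gradients.get(var, "none")
    return {"+": 1.0, "-": -1.0, "none": 0.0}[d]


def _ordinal_from_latent(u: np.ndarray, n_levels: int, rng: np.random.Generator,
                         spread: float = 1.0) -> np.ndarray:
    """Cumulative-logit draw: thresholds equally spaced, logistic noise."""
    cuts = np.linspace(-spread, spread, n_levels - 1)
    noise = rng.logistic(size=u.shape)
    lat = u + noise
    return 1 + (lat[:, None] > cuts[None, :]).sum(axis=1)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort per ``spec``; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    eff = spec.anxiety_effect
    ids = pd.Index([f"p{i:05d}" for i in range(n)], name="participant_id")

    z = rng.standard_normal(n)

    # --- STAI-S items: cumulative logit, slope ~ eff per item -------------
    item_offsets = rng.normal(0.0, 0.4, size=20)
    items = np.empty((n, 20), dtype=int)
    for j in range(20):
        s = -1.0 if (j + 1) in REVERSE_KEYED_ITEMS else 1.0
        # the -1.45*s shift anchors the scored sum so that 35/45/55 fall
        # near the 50th/75th/90th percentiles of the cohort
        u = 1.1 * eff * s * z + item_offsets[j] - 1.45 * s
        items[:, j] = _ordinal_from_latent(u, 4, rng, spread=1.6)
    stai = pd.DataFrame(items, index=ids, columns=list(STAI_ITEM_COLUMNS))

    # --- contextual variables --------------------------------------------
    g = spec.contextual_gradients
    ctx = pd.DataFrame(index=ids)
    ctx["loneliness"] = _ordinal_from_latent(
        0.9 * eff * _gradient_sign(g, "loneliness") * z,
        spec.loneliness_levels, rng, spread=1.2)
    age = 46.0 + 13.0 * rng.standard_normal(n) + 6.0 * eff * _gradient_sign(g, "age") * z
    ctx["age"] = np.clip(np.round(age), 18, 80).astype(int)
    ctx["income"] = _ordinal_from_latent(
        0.6 * eff * _gradient_sign(g, "income") * z,
        spec.income_levels, rng, spread=1.4)
    ctx["sex"] = rng.choice(CATEGORY_LEVELS["sex"], size=n, p=[0.385, 0.615])
    ctx["marital"] = rng.choice(
        CATEGORY_LEVELS["marital"], size=n,
        p=[0.20, 0.514, 0.10, 0.03, 0.056, 0.10])
    ctx["employment"] = rng.choice(
        CATEGORY_LEVELS["employment"], size=n,
        p=[0.10, 0.05, 0.12, 0.358, 0.052, 0.32])
    edu_levels = ORDINAL_LEVEL_ORDERS["edu"]
    edu_idx = rng.choice(len(edu_levels), size=n, p=[0.08, 0.25, 0.296, 0.23, 0.144])
    ctx["edu"] = np.array(edu_levels)[edu_idx]
    base_years = np.array([EDU_MIN_YEARS[lv] for lv in ctx["edu"]])
    ctx["edu_years"] = base_years + rng.integers(0, 3, size=n)
    ctx["race_ethnicity"] = rng.choice(
        CATEGORY_LEVELS["race_ethnicity"], size=n,
        p=[0.857, 0.04, 0.04, 0.03, 0.02, 0.013])
    ctx["covid_test"] = rng.choice(CATEGORY_LEVELS["covid_test"], size=n, p=[0.75, 0.25])
    ctx["covid_diagnosis"] = rng.choice(
        CATEGORY_LEVELS["covid_diagnosis"], size=n, p=[0.82, 0.18])

    completion = pd.Series(
        np.round(900.0 + rng.lognormal(6.6, 0.5, size=n), 1),
        index=ids, name="completion_seconds")
    diagnoses = pd.Series(
        np.minimum(rng.poisson(1.5, size=n), 9),
        index=ids, name="diagnosis_count")

    ratings = _generate_ratings(z, ids, spec, rng)

    if spec.missing_rate > 0:
        mask = rng.random(ctx.shape) < spec.missing_rate
        ctx = ctx.mask(pd.DataFrame(mask, index=ctx.index, columns=ctx.columns))

    return SyntheticCohort(
        spec=spec, ratings=ratings, stai_items=stai, contextual=ctx,
        completion_seconds=completion, diagnosis_count=diagnoses,
        latent_trait=pd.Series(z, index=ids, name="latent_trait"),
        invalid_reason=pd.Series([None] * n, index=ids, name="invalid_reason"),
    )


#: Magnitude-distribution anchors over |rating| in {1, 2, 3}. The per-category
#: mixing weight t interpolates from the concentrated low anchor (low mean,
#: low entropy, moderate variance) to the broad high anchor (higher mean,
#: higher entropy, lower variance), so across categories the (H, K) points
#: trace a rising value limb while (K, sigma) falls off with |K| - the
#: concave limit-curve shape the feature extraction assumes.
_P_LO = np.array([0.70, 0.00, 0.30])
_P_HI = np.array([0.10, 0.45, 0.45])
#: A weaker high anchor; mixing toward it flattens a limb's K range while
#: keeping entropy high, so the limb's slope falls and its curvature at the
#: mean entropy falls with it.
_P_HI_WEAK = np.array([0.25, 0.40, 0.35])

_CATEGORY_OFFSETS = np.array([-1.0, -0.6, -0.2, 0.2, 0.6, 1.0])


def _quota_counts(p: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of n draws to magnitudes 1..3.

    Keeps each signed set close to its target distribution, so participant-
    level curve parameters (not sampling noise) dominate the fitted features.
    """
    exact = p * n
    base = np.floor(exact).astype(int)
    rem = n - int(base.sum())
    if rem > 0:
        frac = exact - base + rng.uniform(0, 1e-9, size=3)
        base[np.argsort(-frac)[:rem]] += 1
    return base


def _generate_ratings(z: np.ndarray, ids: pd.Index, spec: CohortSpec,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Per-category signed rating sets whose RPT features move with z.

    The planted shifts (directions from ``spec.rating_shift_profile``):

    * LA up   - the positive limb flattens with z (its high anchor mixes
      toward the weak anchor), raising |a-|/a+; flattening around the limb
      centroid also raises the unit-entropy intercept, so Ante rises and RA
      falls with z - the directions seen in high-anxiety strata.
    * LR down - the negative limb's high anchor also weakens with z, but
      much more slowly than the positive limb's, lowering the negative
      curvature |a-| / mean(H-)^2 without cancelling the LA shift.
    * Tradeoff range down - the cross-category spread of mixing weights
      shrinks with z, compressing the angular spread of (H+, H-) points.
    """
    eff = spec.anxiety_effect
    prof = spec.rating_shift_profile
    la_dir = _gradient_sign(prof, "LA")
    lr_dir = -_gradient_sign(prof, "LR")        # LR down <=> mean H- up
    trade_dir = -_gradient_sign(prof, "TradeoffRange")  # range down <=> spread down

    n = z.size
    t_base = rng.uniform(0.32, 0.52, size=n)
    spread = np.clip(0.30 * np.exp(-0.20 * eff * trade_dir * z), 0.15, 0.42)
    pos_weak = np.clip(0.25 + 0.70 * eff * la_dir * z, 0.0, 0.95)
    neg_weak = np.clip(0.25 + 0.10 * eff * lr_dir * z, 0.0, 0.95)

    records: list[tuple] = []
    for i, pid in enumerate(ids):
        p_hi_pos = (1.0 - pos_weak[i]) * _P_HI + pos_weak[i] * _P_HI_WEAK
        p_hi_neg = (1.0 - neg_weak[i]) * _P_HI + neg_weak[i] * _P_HI_WEAK
        for c in range(1, 7):
            off = _CATEGORY_OFFSETS[c - 1]
            jit_p, jit_n = rng.normal(0.0, 0.04, size=2)
            t_pos = float(np.clip(t_base[i] + spread[i] * off + jit_p, 0.05, 1.0))
            t_neg = float(np.clip(t_base[i] - spread[i] * off + jit_n, 0.05, 1.0))
            p_pos = (1.0 - t_pos) * _P_LO + t_pos * p_hi_pos
            p_neg = (1.0 - t_neg) * _P_LO + t_neg * p_hi_neg
            n_pos = int(rng.integers(3, 6))  # 3..5 liked pictures per category
            counts_pos = _quota_counts(p_pos, n_pos, rng)
            counts_neg = _quota_counts(p_neg, 8 - n_pos, rng)
            vals = np.concatenate([
                np.repeat([1, 2, 3], counts_pos),
                -np.repeat([1, 2, 3], counts_neg),
            ])
            for j, v in enumerate(vals):
                records.append((pid, f"c{c}_pic{j + 1}", c, int(v)))
    return pd.DataFrame(records,
                        columns=["participant_id", "picture_id", "category", "rating"])


_INVALID_MODES = ("straight_line_ratings", "fast_completion", "many_diagnoses",
                  "edu_mismatch", "straight_line_stai")


def inject_invalid_responders(cohort: SyntheticCohort, fraction: float) -> SyntheticCohort:
    """Rewrite a fraction of participants to violate one exclusion rule each.

    The chosen participants cycle through the five violation modes (straight-
    line ratings, <800 s completion, >=10 diagnoses, education mismatch,
    straight-line STAI section) and are tagged in ``invalid_reason``.
    Deterministic given the cohort's seed; ``fraction = 0`` is a no-op copy.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    n = len(cohort.participant_ids)
    k = int(round(fraction * n))

    ratings = cohort.ratings.copy()
    stai = cohort.stai_items.copy()
    ctx = cohort.contextual.copy()
    completion = cohort.completion_seconds.copy()
    diagnoses = cohort.diagnosis_count.copy()
    invalid = cohort.invalid_reason.copy()

    if k > 0:
        rng = np.random.default_rng(cohort.spec.seed + 911)
        chosen = rng.choice(n, size=k, replace=False)
        for rank, idx in enumerate(chosen):
            pid = cohort.participant_ids[idx]
            mode = _INVALID_MODES[rank % len(_INVALID_MODES)]
            invalid.loc[pid] = mode
            if mode == "straight_line_ratings":
                ratings.loc[ratings["participant_id"] == pid, "rating"] = 3
            elif mode == "fast_completion":
                completion.loc[pid] = float(rng.uniform(120, 799))
            elif mode == "many_diagnoses":
                diagnoses.loc[pid] = int(rng.integers(10, 18))
            elif mode == "edu_mismatch":
                ctx.loc[pid, "edu"] = "graduate_degree"
                ctx.loc[pid, "edu_years"] = 6
            elif mode == "straight_line_stai":
                stai.loc[pid, :] = 2

    return SyntheticCohort(
        spec=cohort.spec, ratings=ratings, stai_items=stai, contextual=ctx,
        completion_seconds=completion, diagnosis_count=diagnoses,
        latent_trait=cohort.latent_trait.copy(), invalid_reason=invalid,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write ratings/stai/contextual CSVs plus a JSON ground-truth sidecar."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    cohort.ratings.to_csv(out / "ratings.csv", index=False)
    paths["ratings"] = str(out / "ratings.csv")
    cohort.stai_items.to_csv(out / "stai_items.csv")
    paths["stai_items"] = str(out / "stai_items.csv")
    survey = cohort.survey_frame()
    survey.to_csv(out / "contextual.csv")
    paths["contextual"] = str(out / "contextual.csv")
    truth = {
        "seed": cohort.spec.seed,
        "n_participants": cohort.spec.n_participants,
        "anxiety_effect": cohort.spec.anxiety_effect,
        "latent_trait": {str(k): float(v) for k, v in cohort.latent_trait.items()},
        "invalid_reason": {str(k): v for k, v in cohort.invalid_reason.items()
                           if v is not None},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    paths["ground_truth"] = str(out / "ground_truth.json")
    return paths
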