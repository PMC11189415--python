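"""End-to-end pipeline orchestration, configuration and tabular I/O.

The pipeline runs: vendor filters -> STAI-S scoring -> RPT feature
extraction -> rating-based exclusions -> cohort assembly (26 predictors +
anxiety score, complete cases) -> RF/bRF classification at each threshold ->
optional permutation null -> Gini importance -> mediation/moderation screens
-> post hoc group tests. Every stage logs row counts; a manifest JSON
records the configuration, seeds, per-stage counts and output checksums so
deterministic stages reproduce bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classifier, medmod, posthoc_stats, rpt_features, survey_scores
from .synthetic_data import CohortSpec, SyntheticCohort, generate_cohort

log = logging.getLogger("anxrpt.pipeline")

#: Column-name variants accepted when loading an external participant table.
COLUMN_NAME_MAP: dict[str, str] = {
    "id": "participant_id", "subject": "participant_id", "pid": "participant_id",
    "stai": "stai_s", "stai_score": "stai_s", "anxiety_score": "stai_s",
    "loss_aversion": "LA", "risk_aversion": "RA", "loss_resilience": "LR",
    "ante": "Ante", "insurance": "Insurance",
    "peak_pr": "PeakPR", "peak_nr": "PeakNR",
    "reward_tp": "RewardTP", "aversion_tp": "AversionTP",
    "total_rr": "TotalRR", "total_ar": "TotalAR",
    "ra_tradeoff": "RATradeoff", "tradeoff_range": "TradeoffRange",
    "ra_consistency": "RAConsistency", "consistency_range": "ConsistencyRange",
    "race": "race_ethnicity", "ethnicity": "race_ethnicity",
    "test": "covid_test", "diagnosis": "covid_diagnosis",
}

CONTEXTUAL_PREDICTORS: tuple[str, ...] = (
    "loneliness", "age", "sex", "income", "marital", "employment",
    "edu", "edu_years", "race_ethnicity", "covid_test", "covid_diagnosis",
)


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the study design choices."""

    out_dir: str = "anxrpt_out"
    synthetic: CohortSpec | None = None
    ratings_path: str | None = None
    survey_path: str | None = None
    thresholds: tuple[float, ...] = (35.0, 45.0, 55.0)
    modes: tuple[str, ...] = ("rf", "brf")
    n_trees: int = 1000
    vars_per_split: int = 5
    train_frac: float = 0.7
    seed: int = 0
    n_permutations: int = 0  # full null is expensive; off by default
    mad_multiplier: float = 5.0
    sample_variance: bool = False
    medmod_contextuals: tuple[str, ...] = ("age", "loneliness", "income", "employment")
    run_medmod: bool = True
    run_posthoc: bool = True


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_participant_table(path, name_map: Mapping[str, str] | None = None
                           ) -> pd.DataFrame:
    """Load a participant-level analysis table from CSV or XLSX.

    Column names are normalized through ``name_map`` (case-insensitive;
    defaults to :data:`COLUMN_NAME_MAP`); unmapped extra columns are kept
    and reported via a warning log. Requires a participant id column, the
    15 judgment variables and the anxiety score.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"participant table not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    full_map = dict(COLUMN_NAME_MAP)
    if name_map:
        full_map.update({k.lower(): v for k, v in name_map.items()})
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in full_map:
            renames[col] = full_map[key]
    df = df.rename(columns=renames)
    required = ["participant_id", "stai_s", *rpt_features.JUDGMENT_VARIABLES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"participant table missing required column(s): {missing}")
    known = set(required) | set(CONTEXTUAL_PREDICTORS) | {"age3"}
    extras = [c for c in df.columns if c not in known]
    if extras:
        log.warning("unmapped extra columns kept as-is: %s", extras)
    return df.set_index("participant_id")


def assemble_cohort(profiles: pd.DataFrame, encoded_ctx: pd.DataFrame,
                    scores: pd.Series, retained_ids: Sequence) -> pd.DataFrame:
    """Join judgment variables, encoded contextuals and scores; complete cases only."""
    ids = [pid for pid in retained_ids
           if pid in profiles.index and pid in encoded_ctx.index and pid in scores.index]
    cohort = pd.concat([
        profiles.loc[ids, list(rpt_features.JUDGMENT_VARIABLES)],
        encoded_ctx.loc[ids, [c for c in CONTEXTUAL_PREDICTORS if c in encoded_ctx.columns]],
        encoded_ctx.loc[ids, ["age3"]] if "age3" in encoded_ctx.columns else None,
        scores.loc[ids].rename("stai_s"),
    ], axis=1)
    n_before = len(cohort)
    cohort = cohort.dropna()
    if n_before != len(cohort):
        log.info("dropped %d incomplete cases during cohort assembly",
                 n_before - len(cohort))
    return cohort


def predictor_columns() -> list[str]:
    """The 26 predictors: 15 judgment + 11 contextual variables."""
    return [*rpt_features.JUDGMENT_VARIABLES, *CONTEXTUAL_PREDICTORS]


def run_pipeline(config: RunConfig, cohort_input: SyntheticCohort | None = None
                 ) -> dict:
    """Execute the full analysis chain; returns the manifest dictionary.

    Inputs come from ``cohort_input``, the synthetic spec in the config, or
    the ratings/survey CSV paths. Outputs are versioned CSV/JSON files in
    ``config.out_dir`` plus ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": {}, "outputs": {}}

    # --- input acquisition ------------------------------------------------
    if cohort_input is not None:
        cohort_data = cohort_input
    elif config.synthetic is not None:
        cohort_data = generate_cohort(config.synthetic)
    elif config.ratings_path and config.survey_path:
        cohort_data = _load_tables(config.ratings_path, config.survey_path)
    else:
        raise ValueError("no input: provide a synthetic spec or ratings/survey paths")
    n_input = len(cohort_data.participant_ids)
    manifest["stages"]["input"] = {"n_participants": n_input}
    log.info("input: %d participants", n_input)

    # --- vendor filters -----------------------------------------------------
    survey = cohort_data.survey_frame()
    vendor = survey_scores.apply_vendor_filters(survey)
    manifest["stages"]["vendor_filters"] = vendor.to_dict()
    log.info("vendor filters retained %d / %d", vendor.n_retained, n_input)

    # --- STAI scoring -------------------------------------------------------
    kept = survey.loc[vendor.retained_ids]
    scores = survey_scores.score_stai_table(kept[list(survey_scores.STAI_ITEM_COLUMNS)])
    manifest["stages"]["stai_scoring"] = {"n_scored": int(len(scores))}

    # --- RPT features -------------------------------------------------------
    ratings = cohort_data.ratings
    ratings = ratings[ratings["participant_id"].isin(vendor.retained_ids)]
    profiles = rpt_features.compute_profiles(ratings,
                                             sample_variance=config.sample_variance)
    rating_report = rpt_features.apply_rating_exclusions(
        ratings, profiles, mad_multiplier=config.mad_multiplier)
    manifest["stages"]["rating_exclusions"] = rating_report.to_dict()
    log.info("rating exclusions retained %d / %d",
             rating_report.n_retained, len(profiles))

    # --- contextual encoding ------------------------------------------------
    ctx_raw = cohort_data.contextual.loc[vendor.retained_ids].dropna()
    encoded, encoding_map = survey_scores.encode_contextuals(
        ctx_raw, loneliness_levels=getattr(cohort_data.spec, "loneliness_levels", 5))
    (out / "encoding_map.json").write_text(json.dumps(
        {k: {str(a): int(b) if isinstance(b, (int, np.integer)) else b
             for a, b in v.items()} for k, v in encoding_map.items()}, indent=1))

    # --- cohort assembly ----------------------------------------------------
    cohort = assemble_cohort(profiles, encoded, scores, rating_report.retained_ids)
    cohort.to_csv(out / "cohort.csv")
    manifest["stages"]["cohort"] = {"n_retained": int(len(cohort))}
    manifest["outputs"]["cohort.csv"] = _sha256(out / "cohort.csv")
    log.info("analysis cohort: %d participants", len(cohort))
    profiles.to_csv(out / "profiles.csv")
    manifest["outputs"]["profiles.csv"] = _sha256(out / "profiles.csv")

    # --- classification -----------------------------------------------------
    feats = cohort[predictor_columns()]
    class_results = {}
    for thr in config.thresholds:
        for mode in config.modes:
            run = classifier.ClassifierRun(
                threshold=thr, mode=mode, seed=config.seed,
                train_frac=config.train_frac, n_trees=config.n_trees,
                vars_per_split=config.vars_per_split)
            try:
                model, report, _, _ = classifier.classify_cohort(
                    feats, cohort["stai_s"], run)
            except classifier.ClassBalanceError as exc:
                log.warning("threshold %s mode %s skipped: %s", thr, mode, exc)
                continue
            key = f"{int(thr)}_{mode}"
            class_results[key] = report.to_dict()
            (out / f"metrics_{key}.json").write_text(
                json.dumps(report.to_dict(), indent=1))
            imp = classifier.gini_importance(model, feats.columns)
            imp.to_frame().to_csv(out / f"importance_{key}.csv")
            class_results[key]["importance_groups"] = imp.group_sums
            if config.n_permutations > 0:
                null = classifier.permutation_null(
                    feats, cohort["stai_s"], run, n_iter=config.n_permutations)
                class_results[key]["permutation_null"] = null.to_dict()
    manifest["stages"]["classification"] = class_results

    # --- mediation / moderation --------------------------------------------
    if config.run_medmod:
        med, mod = medmod.screen_all_pairs(
            cohort, contextuals=list(config.medmod_contextuals))
        med.to_csv(out / "mediation.csv", index=False)
        mod.to_csv(out / "moderation.csv", index=False)
        manifest["stages"]["medmod"] = {
            "n_mediation_rows": int(len(med)),
            "n_moderation_rows": int(len(mod)),
            "n_mediation_significant": int(med["significant"].sum()),
            "n_moderation_significant": int(mod["significant"].sum())}

    # --- post hoc tests -----------------------------------------------------
    if config.run_posthoc:
        ctx_tests = posthoc_stats.contextual_differences(cohort)
        jd_tests = posthoc_stats.judgment_differences(
            cohort, thresholds=config.thresholds)
        posthoc_stats.results_frame(ctx_tests + jd_tests).to_csv(
            out / "posthoc.csv", index=False)
        posthoc_stats.group_summaries(cohort, thresholds=config.thresholds).to_csv(
            out / "posthoc_summaries.csv", index=False)
        manifest["stages"]["posthoc"] = {
            "n_contextual_tests": len(ctx_tests),
            "n_judgment_tests": len(jd_tests)}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if config.synthetic is not None:
        d["synthetic"] = {**asdict(config.synthetic)}
    return d


def _load_tables(ratings_path: str, survey_path: str) -> SyntheticCohort:
    """Read ratings + survey CSVs into the in-memory cohort container."""
    rp, sp = Path(ratings_path), Path(survey_path)
    for p in (rp, sp):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    ratings = pd.read_csv(rp)
    survey = pd.read_csv(sp, index_col=0)
    stai_cols = [c for c in survey.columns if c in survey_scores.STAI_ITEM_COLUMNS]
    ctx_cols = [c for c in CONTEXTUAL_PREDICTORS if c in survey.columns]
    spec = CohortSpec(n_participants=max(len(survey), 2), seed=0, anxiety_effect=0.0)
    return SyntheticCohort(
        spec=spec, ratings=ratings, stai_items=survey[stai_cols],
        contextual=survey[ctx_cols],
        completion_seconds=survey.get("completion_seconds",
                                      pd.Series(np.nan, index=survey.index)),
        diagnosis_count=survey.get("diagnosis_count",
                                   pd.Series(0, index=survey.index)),
        latent_trait=pd.Series(np.nan, index=survey.index),
        invalid_reason=pd.Series([None] * len(survey), index=survey.index))
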