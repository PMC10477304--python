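"""End-to-end orchestration: simulate -> preprocess -> test -> mediate ->
strains -> delta-eval, with a JSON run report.

Every stage's RNG is derived from the single config seed (offsets below
2^31), so two runs with the same config produce identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import delta, differential, mediation, preprocess, strains, synthetic
from .config import RunConfig

logger = logging.getLogger("microdyn")

_STAGE_SEED_OFFSETS = {
    "cohort": 1,
    "features": 2,
    "diet": 3,
    "pileups": 4,
    "delta": 5,
}


def _stage_seed(config: RunConfig, stage: str) -> int:
    return int((config.seed * 101 + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1))


def participant_changes(table, feature_ids) -> pd.DataFrame:
    """Post-minus-pre change per participant for the given features."""
    meta = table.sample_meta
    pre = meta.index[meta["timepoint"] == "pre"]
    post = meta.index[meta["timepoint"] == "post"]
    pre_v = table.values.loc[pre, list(feature_ids)]
    post_v = table.values.loc[post, list(feature_ids)]
    pre_v.index = meta.loc[pre, "participant_id"]
    post_v.index = meta.loc[post, "participant_id"]
    return post_v - pre_v.reindex(post_v.index)


def run_pipeline(config: RunConfig | None = None, out_dir=None) -> dict:
    """Run the whole synthetic study and return the run report.

    The report carries per-stage counts (features retained, components
    removed, rejections per arm, mediation trajectories, replacement calls,
    delta-evaluation correlations) and all derived seeds. If ``out_dir`` is
    given, the report and the main result tables are written there.
    """
    config = config or RunConfig()
    t0 = time.time()
    report: dict = {"config": config.to_dict(), "stages": {}}

    # --- simulate -------------------------------------------------------
    cohort = synthetic.generate_cohort(config.n_per_arm, _stage_seed(config, "cohort"))
    panel = synthetic.PanelSpec(**config.panel)
    effect = synthetic.EffectSpec(**config.effect)
    table, truth = synthetic.generate_paired_features(
        cohort, panel, effect, _stage_seed(config, "features")
    )
    logs, diet_truth = synthetic.generate_diet_logs(
        cohort, config.n_days, seed=_stage_seed(config, "diet")
    )
    pileup_spec = synthetic.PileupSpec(**config.pileups)
    pileups, pileup_truth = synthetic.generate_pileups(
        cohort, pileup_spec, _stage_seed(config, "pileups")
    )
    report["stages"]["simulate"] = {
        "n_participants": int(len(cohort)),
        "n_features": int(table.n_features),
        "n_planted_effects": len(truth.affected_features),
        "n_planted_replacements": len(pileup_truth.replaced),
        "seeds": {s: _stage_seed(config, s) for s in _STAGE_SEED_OFFSETS},
    }
    logger.info("simulated %d features, %d participants", table.n_features, len(cohort))

    # --- preprocess -----------------------------------------------------
    clean, audit = preprocess.run_preprocessing(
        table,
        min_samples=config.min_samples,
        clip_k=config.clip_k,
        central_fraction=config.central_fraction,
        pc_count=config.pc_count,
        pc_var=config.pc_var,
    )
    retained_days, exclusions = preprocess.filter_diet_days(logs)
    diet_summary = preprocess.summarize_diet_periods(retained_days)
    report["stages"]["preprocess"] = {
        "n_features_retained": int(clean.n_features),
        "n_components_removed": {
            a: len(log.get("removed_components", []))
            for a, log in audit["assays"].items()
        },
        "n_diet_days_excluded": int(len(exclusions)),
    }

    # --- differential ---------------------------------------------------
    diff_results = {}
    for arm in synthetic.ARMS:
        res = differential.run_differential(
            clean, arm, alpha=config.alpha, method=config.method,
            min_unique=config.min_unique,
        )
        diff_results[arm] = res
    baseline = differential.baseline_screen(
        clean, alpha=config.alpha, method=config.method
    )
    report["stages"]["differential"] = {
        arm: {
            "n_eligible": int(res["eligible"].sum()),
            "n_significant": int(res["significant"].sum()),
        }
        for arm, res in diff_results.items()
    }
    report["stages"]["differential"]["baseline_significant"] = int(
        baseline["significant"].sum()
    )

    # --- mediation ------------------------------------------------------
    covariates = pd.DataFrame(
        {
            "age": cohort["age"],
            "sex": (cohort["sex"] == "M").astype(float),
            "bmi": cohort["bmi"],
        }
    )
    nutrients = ["carbohydrates_g", "lipids_g", "protein_g"]
    pivot = diet_summary.pivot_table(
        index="participant_id", columns="period", values=nutrients
    )
    diet_changes = pd.DataFrame(
        {
            n: pivot[(n, "intervention")] - pivot[(n, "profiling")]
            for n in nutrients
            if (n, "intervention") in pivot.columns and (n, "profiling") in pivot.columns
        }
    )
    n_trajectories = 0
    significant_trajectories = 0
    gut_features = [
        f for f in clean.feature_meta.index[clean.feature_meta["assay"] == "gut_species"]
    ]
    sig_mediators = [
        f for f in gut_features if diff_results["PPT"].loc[f, "significant"]
    ][:3]
    metab = clean.feature_meta.index[clean.feature_meta["assay"] == "metabolites"]
    sig_outcomes = [
        f for f in metab if diff_results["PPT"].loc[f, "significant"]
    ][:3]
    if sig_mediators and sig_outcomes and not diet_changes.empty:
        med_results = mediation.screen_trajectories(
            diet_changes.iloc[:, :2],
            participant_changes(clean, sig_mediators),
            participant_changes(clean, sig_outcomes),
            covariates.reindex(diet_changes.index),
            n_boot=config.n_boot,
            seed=config.mediation_seed,
            alpha=config.alpha,
        )
        n_trajectories = len(med_results)
        significant_trajectories = sum(r.significant for r in med_results)
    report["stages"]["mediation"] = {
        "n_trajectories_tested": n_trajectories,
        "n_significant": significant_trajectories,
    }

    # --- strains --------------------------------------------------------
    pairing = synthetic.sample_pairing(cohort)
    records = strains.dissimilarity_sets(
        pileups, pairing,
        min_positions=config.min_positions, clip=config.clip,
        min_depth=config.min_depth, presence_fraction=config.presence_fraction,
    )
    thresholds = strains.species_thresholds(
        records, q=config.q, min_inter_pairs=config.min_inter_pairs
    )
    calls = strains.call_replacements(records, thresholds)
    report["stages"]["strains"] = {
        "n_species_with_threshold": len(thresholds),
        "n_calls": int(len(calls)),
        "n_replaced": int(calls["replaced"].sum()) if len(calls) else 0,
    }

    # --- delta evaluation ----------------------------------------------
    rng = np.random.default_rng(_stage_seed(config, "delta"))
    gut = clean.subset_features(
        clean.feature_meta.index[clean.feature_meta["assay"] == "gut_species"]
    )
    meta = gut.sample_meta
    comp = gut.values.fillna(0.0)
    pre_rows = meta.index[meta["timepoint"] == "pre"]
    post_rows = meta.index[meta["timepoint"] == "post"]
    pre_comp = comp.loc[pre_rows].set_axis(meta.loc[pre_rows, "participant_id"])
    post_comp = comp.loc[post_rows].set_axis(meta.loc[post_rows, "participant_id"])
    n_metab = min(30, max(6, gut.n_features // 2))
    metab_ids = [f"pred_metab_{i:03d}" for i in range(n_metab)]
    W = pd.DataFrame(
        rng.normal(0, 0.3, (gut.n_features, n_metab)),
        index=comp.columns, columns=metab_ids,
    )
    predictor = delta.LinearPredictor(W, pd.Series(0.0, index=metab_ids))
    predicted = delta.predict_change(predictor, pre_comp, post_comp)
    noise_scale = float(predicted.stack().std())
    if not np.isfinite(noise_scale) or noise_scale == 0:
        noise_scale = 1.0
    observed = predicted + rng.normal(0, noise_scale, predicted.shape)
    training_r2 = pd.Series(
        np.where(np.arange(n_metab) % 2 == 0, 0.3, 0.01), index=metab_ids
    )
    evals = delta.evaluate_change(
        observed, predicted, training_r2,
        r2_threshold=config.r2_threshold,
        arms=cohort["arm"],
    )
    report["stages"]["delta_eval"] = [
        {
            "stratum": e.stratum, "arm": e.arm,
            "pearson_r": e.pearson_r,
            "variance_explained_percent": e.variance_explained_percent,
            "n_metabolites": e.n_metabolites,
        }
        for e in evals
    ]

    report["runtime_seconds"] = round(time.time() - t0, 2)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        clean.to_tsv(out / "features_preprocessed.tsv")
        for arm, res in diff_results.items():
            res.to_csv(out / f"differential_{arm}.tsv", sep="\t")
        calls.to_csv(out / "replacement_calls.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    return report
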