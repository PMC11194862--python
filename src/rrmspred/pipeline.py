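"""End-to-end driver: registry tables in, fitted models and reports out."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import timelines
from .config import PipelineConfig
from .features import complete_cases, derive_feature_table
from .models import (
    FAMILY_BINOMIAL,
    FAMILY_NEGBIN,
    ModelSpec,
    coefficient_mads,
    fit_outcome_model,
    predict_observed,
)
from .outcomes import derive_outcomes
from .synthetic_registry import RegistryBundle, SimConfig, generate_raw_registry
from .validation import evaluate_predictions, kfold_oos_predictions

log = logging.getLogger("rrmspred")

OUTCOME_OF_FAMILY = {FAMILY_NEGBIN: "relapse", FAMILY_BINOMIAL: "cdp"}


def simulate_bundle(config: PipelineConfig) -> RegistryBundle:
    sim = config.simulate
    if sim is None:
        raise ValueError("config has no simulate block")
    sc = SimConfig(
        n_centres=sim.n_centres,
        n_patients=sim.n_patients,
        sigma_centre=sim.sigma_centre,
        cdp_plant_rate=sim.cdp_plant_rate,
        gap_rate=sim.gap_rate,
        overlap_rate=sim.overlap_rate,
        study_window=sim.study_window,
        visit_interval_days=sim.visit_interval_days,
        seed=config.seed,
    )
    return generate_raw_registry(sc)


def preprocess(bundle: RegistryBundle, config: PipelineConfig):
    """Raw tables -> (train pairs, test pairs, all cycles, flow log)."""
    flow = timelines.FlowLog()

    episodes, qlog = timelines.quality_filter(bundle.therapies, bundle.patients)
    flow.extend(qlog)

    episodes, clog = timelines.censor_at_last_edss(
        episodes, bundle.visits, config.extraction_date
    )
    flow.extend(clog)

    centre_by_patient = bundle.patients.set_index("patient_id")["centre_id"]
    all_cycles = []
    for _, grp in episodes.groupby("patient_id", sort=True):
        all_cycles.extend(timelines.build_timeline(grp))
    cycles = timelines.cycles_to_frame(all_cycles, centre_by_patient)

    pairs = timelines.make_switch_pairs(cycles)
    pairs, elog = timelines.eligibility_filter(pairs, bundle.patients, config.registry_start)
    flow.extend(elog)

    pairs = timelines.select_one_cycle_per_patient(pairs, config.seed)
    train, test = timelines.temporal_split(
        pairs, config.split_date, config.train_includes_boundary
    )
    flow.record("split_train", len(pairs), len(train))
    flow.record("split_test", len(pairs), len(test))

    # prevent leakage: training follow-up ends before the split date
    train, slog = timelines.censor_at_last_edss(
        train,
        bundle.visits,
        config.split_date,
        start_col="index_start",
        end_col="index_end",
        censored_col="index_censored",
    )
    for step in slog.steps:
        step["filter_name"] = "train_" + step["filter_name"]
    flow.extend(slog)

    return train, test, cycles, flow


def build_analysis_table(pairs, bundle, cycles, config: PipelineConfig):
    """Features + outcomes per switch pair, complete cases only."""
    feats = derive_feature_table(
        pairs,
        bundle.patients,
        bundle.visits,
        bundle.relapses,
        cycles,
        never_relapsed_distance_cat=config.never_relapsed_distance_cat,
    )
    outs = derive_outcomes(
        pairs, bundle.visits, bundle.relapses, sustain_mode=config.sustain_mode
    )
    feats = feats.join(pairs[["centre_id"]].reset_index(drop=True))
    table = feats.join(outs.drop(columns=["patient_id"]))
    table, n_removed = complete_cases(table)
    return table.reset_index(drop=True), n_removed


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute simulate? -> preprocess -> outcomes -> features -> fit -> validate.

    Writes cycles.csv, train/test pair and analysis tables, flowlog.json,
    fitted models and report.json under ``outdir``; returns the report dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        bundle = simulate_bundle(config)
        bundle.save(outdir / "registry")
    elif config.indir:
        bundle = RegistryBundle.load(config.indir)
    else:
        raise ValueError("config needs either an input directory or a simulate block")

    train, test, cycles, flow = preprocess(bundle, config)
    cycles.to_csv(outdir / "cycles.csv", index=False, date_format="%Y-%m-%d")
    train.to_csv(outdir / "pairs_train.csv", index=False, date_format="%Y-%m-%d")
    test.to_csv(outdir / "pairs_test.csv", index=False, date_format="%Y-%m-%d")

    train_tab, n_cc_train = build_analysis_table(train, bundle, cycles, config)
    test_tab, n_cc_test = build_analysis_table(test, bundle, cycles, config)
    flow.record("train_complete_case", len(train_tab) + n_cc_train, len(train_tab))
    flow.record("test_complete_case", len(test_tab) + n_cc_test, len(test_tab))
    train_tab.to_csv(outdir / "analysis_train.csv", index=False, date_format="%Y-%m-%d")
    test_tab.to_csv(outdir / "analysis_test.csv", index=False, date_format="%Y-%m-%d")
    with open(outdir / "flowlog.json", "w") as fh:
        json.dump(flow.to_records(), fh, indent=2)

    ispec = config.interaction_spec()
    report: dict = {"flowlog": flow.to_records(), "n_train": len(train_tab), "n_test": len(test_tab)}

    for family in (FAMILY_NEGBIN, FAMILY_BINOMIAL):
        outcome = OUTCOME_OF_FAMILY[family]
        y_col = "relapse_count" if family == FAMILY_NEGBIN else "cdp"
        y_train = train_tab[y_col].to_numpy()
        y_test = test_tab[y_col].to_numpy()
        spec = ModelSpec(
            family=family,
            prior_scale=config.model.prior_scale,
            intercept_prior_sd=config.model.intercept_prior_sd,
            sigma_prior_scale=config.model.sigma_prior_scale,
            n_chains=config.model.n_chains,
            n_draws=config.model.n_draws,
            seed=config.seed,
            rhat_max=config.model.rhat_max,
            ess_min=config.model.ess_min,
            max_divergences=config.model.max_divergences,
        )
        fit_kwargs = dict(
            interaction_spec=ispec,
            cdp_log_duration=config.cdp_log_duration,
            continuous_predictors=config.continuous_predictors(),
        )
        fit = fit_outcome_model(
            train_tab, y_train, train_tab["centre_id"].to_numpy(),
            spec, bayes=config.bayes, **fit_kwargs,
        )
        if hasattr(fit, "save"):
            fit.save(outdir / f"fit_{outcome}.npz")
        n_params = len(fit.names)

        log.info("cross-validating %s model (%d folds)", outcome, config.cv_folds)
        cv_pred = kfold_oos_predictions(
            train_tab, y_train, train_tab["centre_id"].to_numpy(),
            spec, ispec, k=config.cv_folds, seed=config.seed,
            bayes=config.bayes,
            cdp_log_duration=config.cdp_log_duration,
            continuous_predictors=config.continuous_predictors(),
        )
        cv_metrics = evaluate_predictions(
            cv_pred["mean"], y_train, outcome, "cv",
            n_params=n_params, n_boot=config.n_boot, seed=config.seed,
        )

        temporal_metrics = None
        if len(test_tab) >= 20 and len(np.unique(y_test)) > 1:
            test_pred = predict_observed(fit, test_tab)
            temporal_metrics = evaluate_predictions(
                test_pred["mean"], y_test, outcome, "temporal",
                n_params=n_params, n_boot=config.n_boot, seed=config.seed,
            )

        entry = {"cv": cv_metrics.to_dict()}
        if temporal_metrics is not None:
            entry["temporal"] = temporal_metrics.to_dict()
        if hasattr(fit, "draws"):
            entry["coefficient_mads"] = coefficient_mads(fit, scaled=config.mad_scaled)
        report[outcome] = entry

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
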