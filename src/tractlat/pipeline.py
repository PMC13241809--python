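"""End-to-end pipeline: simulate/ingest -> LI -> fit -> charts -> analytics.

Each stage is a plain function that reads its inputs from, and writes its
outputs into, the configured output directory, so the CLI subcommands and
:func:`run_pipeline` compose to exactly the same artifacts.  Every output
carries the config hash; a JSON-lines run log records each model selection
(spec, BIC, convergence).  Given the same config (including seed) the
pipeline is deterministic down to the output bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .dynamics import (
    Epoch,
    detect_reversals,
    epoch_slopes,
    snapshot_heatmaps,
    snapshot_summary,
)
from .handedness import cohen_d_profile, stratified_fits
from .io import (
    plot_chart,
    read_chart,
    read_observations,
    write_chart,
    write_table,
)
from .laterality import build_laterality_table
from .model import (
    CentileChart,
    FitOptions,
    NormativeModel,
    centile_curves,
    select_model,
)
from .simulate import example_truth, make_cohort_design, simulate_dataset, varied_truth

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "stage_simulate",
    "stage_li",
    "stage_fit",
    "stage_charts",
    "stage_reversals",
    "stage_slopes",
    "stage_snapshots",
    "stage_handedness",
]

log = logging.getLogger("tractlat.pipeline")


@dataclass
class PipelineResult:
    config: PipelineConfig
    paths: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    charts: dict = field(default_factory=dict)


def _out(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _epochs(config: PipelineConfig) -> tuple[Epoch, ...]:
    eps = [Epoch(name, lo, hi) for name, lo, hi in config.epochs]
    if eps:
        eps[-1] = Epoch(eps[-1].name, eps[-1].lo, eps[-1].hi, closed_upper=True)
    return tuple(eps)


def _fit_options(config: PipelineConfig) -> FitOptions:
    return FitOptions(age_offset=config.age_offset, seed=config.seed)


def _combo_key(tract: str, feature: str) -> str:
    return f"{tract}_{feature}"


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig) -> Path:
    """Simulation mode: draw the cohort design and bilateral measures for
    every configured tract-feature combination; write observations.csv."""
    out = _out(config)
    subjects = make_cohort_design(
        n_cohorts=config.n_cohorts,
        subjects_per_cohort=config.subjects_per_cohort,
        age_range=config.age_range,
        sex_ratio=config.sex_ratio,
        left_handed_rate=config.left_handed_rate,
        seed=config.seed,
    )
    cohort_ids = sorted(subjects["cohort_id"].unique())
    truths = {}
    truth_specs = {}
    for tract in config.tracts:
        for feature in config.features:
            if config.truth_preset == "varied":
                truth = varied_truth(tract, feature, cohort_ids, config.seed)
            else:
                truth = example_truth(config.truth_preset, cohort_ids, config.seed)
            truths[(tract, feature)] = truth
            truth_specs[_combo_key(tract, feature)] = truth.to_dict()
    table = simulate_dataset(subjects, truths, config.seed)
    path = write_table(table, out / "observations.csv", config.config_hash)
    (out / "truths.json").write_text(json.dumps(truth_specs, indent=1, sort_keys=True) + "\n")
    return path


def stage_li(config: PipelineConfig) -> Path:
    """Ingest observations (simulated or user-provided) and build the LI table."""
    out = _out(config)
    source = Path(config.input) if config.input else out / "observations.csv"
    df, report = read_observations(source)
    if report.kind == "bilateral":
        covariates = df.drop_duplicates("subject_id")[
            ["subject_id", "age_years", "sex", "cohort_id", "handedness"]
        ]
        table, excl = build_laterality_table(df, covariates)
        log.info("LI table: %d rows, %d excluded (non-positive hemisphere values)",
                 len(table), excl.n_excluded)
    else:
        table = df[["subject_id", "age_years", "sex", "cohort_id", "handedness",
                    "tract", "feature", "li"]].copy()
    keep = table["tract"].isin(config.tracts) & table["feature"].isin(config.features)
    return write_table(table.loc[keep], out / "li_table.csv", config.config_hash)


def _load_li(config: PipelineConfig) -> pd.DataFrame:
    df, _ = read_observations(_out(config) / "li_table.csv")
    return df


def stage_fit(config: PipelineConfig) -> dict[tuple[str, str], NormativeModel]:
    """Per tract-feature BIC model selection; persist models and the log."""
    out = _out(config)
    table = _load_li(config)
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    options = _fit_options(config)
    models: dict[tuple[str, str], NormativeModel] = {}
    reports = []
    log_records = []
    for (tract, feature), group in sorted(table.groupby(["tract", "feature"])):
        result = select_model(
            group.reset_index(drop=True),
            power_set=config.power_set,
            max_order=config.max_order,
            strategy=config.strategy,
            options=options,
        )
        model = result.model
        model.tract, model.feature = tract, feature
        models[(tract, feature)] = model
        rep = result.report.copy()
        rep.insert(0, "feature", feature)
        rep.insert(0, "tract", tract)
        reports.append(rep)
        payload = model.to_dict()
        payload["config"] = config.config_hash
        (models_dir / f"{_combo_key(tract, feature)}.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True) + "\n"
        )
        log_records.append(
            {"stage": "fit", "tract": tract, "feature": feature,
             "spec_mu": str(model.spec_mu), "spec_sigma": str(model.spec_sigma),
             "n": model.n, "k": model.k, "bic": model.bic,
             "converged": model.converged, "config": config.config_hash}
        )
        log.info("selected %s/%s: mu %s sigma %s BIC %.2f", tract, feature,
                 model.spec_mu, model.spec_sigma, model.bic)
    write_table(pd.concat(reports, ignore_index=True), out / "selection_report.csv",
                config.config_hash)
    with open(out / "run_log.jsonl", "w") as fh:
        for record in log_records:
            fh.write(json.dumps(record, sort_keys=True) + "\n")
    return models


def _load_models(config: PipelineConfig) -> dict[tuple[str, str], NormativeModel]:
    models_dir = _out(config) / "models"
    models = {}
    for path in sorted(models_dir.glob("*.json")):
        model = NormativeModel.from_dict(json.loads(path.read_text()))
        models[(model.tract, model.feature)] = model
    if not models:
        raise FileNotFoundError(f"no fitted models under {models_dir}; run the fit stage")
    return models


def stage_charts(config: PipelineConfig) -> dict[tuple[str, str, str], CentileChart]:
    """Centile charts per tract-feature and context (npy + CSV + sidecar)."""
    out = _out(config)
    models = _load_models(config)
    charts_dir = out / "charts"
    contexts = tuple(dict.fromkeys((*config.contexts, "average")))
    charts = {}
    for (tract, feature), model in models.items():
        for context in contexts:
            chart = centile_curves(
                model,
                levels=config.levels,
                context=context,
                grid_size=config.grid_size,
                tract=tract,
                feature=feature,
            )
            base = charts_dir / f"{_combo_key(tract, feature)}_{context}"
            write_chart(chart, base, config.config_hash)
            if config.plots:
                plot_chart(chart, base.with_suffix(".png"))
            charts[(tract, feature, context)] = chart
    return charts


def _load_average_charts(config: PipelineConfig) -> dict[tuple[str, str], CentileChart]:
    charts_dir = _out(config) / "charts"
    charts = {}
    for path in sorted(charts_dir.glob("*_average.json")):
        chart = read_chart(path.with_suffix(""))
        charts[(chart.tract, chart.feature)] = chart
    if not charts:
        raise FileNotFoundError(f"no charts under {charts_dir}; run the charts stage")
    return charts


def stage_reversals(config: PipelineConfig) -> Path:
    """Zero-crossing (reversal) table from the sex-averaged median curves."""
    rows = []
    for (tract, feature), chart in _load_average_charts(config).items():
        for event in detect_reversals(chart, config.min_excursion):
            rows.append(
                {"tract": tract, "feature": feature, "direction": event.direction,
                 "age_years": event.age_years}
            )
    df = pd.DataFrame(rows, columns=["tract", "feature", "direction", "age_years"])
    return write_table(df, _out(config) / "reversals.csv", config.config_hash)


def stage_slopes(config: PipelineConfig) -> Path:
    """Epoch-slope matrix (epochs x tract-feature) of |median LI| change."""
    epochs = _epochs(config)
    cols = {}
    for (tract, feature), chart in _load_average_charts(config).items():
        slopes = epoch_slopes(chart, epochs)
        cols[_combo_key(tract, feature)] = {s.epoch: s.slope for s in slopes}
    matrix = pd.DataFrame(cols)
    matrix.index.name = "epoch"
    matrix = matrix.loc[[e.name for e in epochs]]
    return write_table(matrix.reset_index(), _out(config) / "epoch_slopes.csv",
                       config.config_hash)


def stage_snapshots(config: PipelineConfig) -> Path:
    """Median-LI and rightward-prevalence heatmap tables at snapshot ages."""
    out = _out(config)
    models = _load_models(config)
    summary = snapshot_summary(models, config.snapshot_ages, context="average")
    write_table(summary, out / "snapshots.csv", config.config_hash)
    median, prevalence = snapshot_heatmaps(summary)
    write_table(median.reset_index(), out / "snapshots_median.csv", config.config_hash)
    return write_table(prevalence.reset_index(), out / "snapshots_prevalence.csv",
                       config.config_hash)


def stage_handedness(config: PipelineConfig) -> Path:
    """Handedness-stratified fits and Cohen's d contrast tables."""
    out = _out(config)
    table = _load_li(config)
    options = _fit_options(config)
    contrast_rows = []
    profile_rows = []
    lo, hi = config.age_range
    ages = np.arange(max(1.0, np.ceil(lo)), min(80.0, np.floor(hi)) + 1)
    for (tract, feature), group in sorted(table.groupby(["tract", "feature"])):
        fits = stratified_fits(
            group.reset_index(drop=True),
            min_stratum_n=config.min_stratum_n,
            options=options,
            power_set=config.power_set,
            max_order=config.max_order,
            strategy=config.strategy,
        )
        if set(fits.results) < {"right", "left"}:
            contrast_rows.append(
                {"tract": tract, "feature": feature, "mean_d": np.nan,
                 "abs_mean_d": np.nan, "note": "; ".join(
                     f"{k}: {v}" for k, v in fits.skipped.items()) or "stratum missing"}
            )
            continue
        contrast = cohen_d_profile(
            fits.results["right"].model, fits.results["left"].model,
            ages=ages, tract=tract, feature=feature,
        )
        contrast_rows.append(
            {"tract": tract, "feature": feature, "mean_d": contrast.mean_d,
             "abs_mean_d": contrast.abs_mean_d, "note": ""}
        )
        for a, d in zip(contrast.ages, contrast.d):
            profile_rows.append(
                {"tract": tract, "feature": feature, "age_years": a, "cohen_d": d}
            )
    write_table(pd.DataFrame(profile_rows,
                             columns=["tract", "feature", "age_years", "cohen_d"]),
                out / "handedness_profile.csv", config.config_hash)
    return write_table(pd.DataFrame(contrast_rows),
                       out / "handedness_contrasts.csv", config.config_hash)


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write a manifest; deterministic given
    the config (seed included)."""
    out = _out(config)
    result = PipelineResult(config=config)
    if config.input is None:
        result.paths["observations"] = stage_simulate(config)
    result.paths["li_table"] = stage_li(config)
    result.models = stage_fit(config)
    result.charts = stage_charts(config)
    result.paths["reversals"] = stage_reversals(config)
    result.paths["epoch_slopes"] = stage_slopes(config)
    result.paths["snapshots"] = stage_snapshots(config)
    if config.handedness:
        result.paths["handedness"] = stage_handedness(config)
    manifest = {
        "schema": "tractlat-v1",
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
            and p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    result.paths["manifest"] = out / "manifest.json"
    return result
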