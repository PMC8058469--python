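"""End-to-end orchestration: normalize -> QC -> scans -> train -> evaluate.

Driven by a nested key/value config (YAML on disk); every stage logs its
before/after counts into a RunLog that is written alongside the outputs.
All randomness flows through two named seeds (generator, cv).
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import classifier, dataio, normalization, qc, stats, synthetic, variants

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "inputs": {"intensity": None, "runs": None, "subjects": None},
    "generator": None,          # GeneratorConfig fields; used when inputs unset
    "exclusions": None,         # path to newline-separated channel names
    "rsd": {"mode": "pools_raw", "threshold": 0.20},
    "scan": {"alpha": 0.05, "bh": True, "log_transform": False},
    "classifier": {"variant": "ratios", "k": 10, "max_iterations": 60},
    "seeds": {"generator": 1, "cv": 1},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(config.get(key), dict):
            config[key].update(val)
        else:
            config[key] = val
    _validate_config(config)
    return config

def _validate_config(config: dict) -> None:
    thr = config["rsd"]["threshold"]
    if not 0 < thr <= 1:
        raise dataio.DataError("rsd threshold must be in (0, 1]")
    alpha = config["scan"]["alpha"]
    if not 0 < alpha <= 1:
        raise dataio.DataError("alpha must be in (0, 1]")
    if config["classifier"]["variant"] not in variants.VARIANTS:
        raise dataio.DataError(
            f"unknown classifier variant {config['classifier']['variant']!r}")


class RunLog:
    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, stage: str, **fields) -> None:
        rec = {"stage": stage,
               "time": datetime.now(timezone.utc).isoformat(), **fields}
        self.records.append(rec)
        logger.info("stage %s: %s", stage, fields)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.records, fh, indent=2)
            fh.write("\n")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: dict, outdir) -> Path:
    """Execute the full chain and write all artifacts into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runlog = RunLog()
    runlog.add("config", config=config)

    raw, runs, design = _load_inputs(config, outdir, runlog)
    raw = _apply_exclusions(config, raw, runlog)

    normalized, report = _normalize(raw, runs, runlog)
    dataio.write_intensity(normalized, outdir / "intensity_normalized.tsv")
    report.pool_map.to_csv(outdir / "normalization_report.tsv", sep="\t",
                           index=False)

    rsd_table, filtered = _qc(config, raw, normalized, runs, design, runlog)
    qc.write_rsd(rsd_table, outdir / "rsd.tsv")
    dataio.write_intensity(filtered, outdir / "intensity_filtered.tsv")

    alpha = config["scan"]["alpha"]
    log_transform = config["scan"]["log_transform"]
    met_results, ratio_results = _scans(filtered, design, alpha, log_transform,
                                        runlog)
    dataio.write_results(met_results, outdir / "results_metabolites.tsv")
    dataio.write_results(ratio_results, outdir / "results_ratios.tsv")

    model, cv, evaluation = _classify(config, normalized, filtered, design,
                                      runlog)
    classifier.write_model(model, outdir / "model.tsv")
    _write_cv(cv, outdir / "cv.json")
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(evaluation.to_dict(), fh, indent=2)
        fh.write("\n")
    pd.DataFrame(evaluation.roc_points, columns=["fpr", "tpr"]).to_csv(
        outdir / "roc.tsv", sep="\t", index=False)

    runlog.write(outdir / "runlog.json")
    make_report(outdir)
    return outdir


@_stage("inputs")
def _load_inputs(config, outdir, runlog):
    gen = config.get("generator")
    inputs = config.get("inputs") or {}
    if inputs.get("intensity"):
        raw = dataio.read_intensity(inputs["intensity"], stage="raw")
        runs, design = dataio.read_metadata(inputs["runs"], inputs["subjects"])
    elif gen is not None:
        fields = dict(gen)
        planted = fields.pop("planted_effects", None)
        if planted is not None:
            fields["planted_effects"] = tuple(
                synthetic.PlantedEffect(p["metabolite_name"],
                                        p["log_fold_change"])
                for p in planted)
        fields.setdefault("seed", config["seeds"]["generator"])
        if "age_ranges" in fields:
            fields["age_ranges"] = {k: tuple(v)
                                    for k, v in fields["age_ranges"].items()}
        dataset = synthetic.generate(synthetic.GeneratorConfig(**fields))
        synthetic.write_dataset(dataset, outdir / "simulated")
        raw, runs, design = dataset.intensity, dataset.runs, dataset.design
    else:
        raise dataio.DataError("config provides neither inputs nor generator")
    n_pools = int((runs["sample_type"] == "pool").sum())
    runlog.add("inputs", runs_total=len(runs),
               study_runs=len(runs) - n_pools, pool_runs=n_pools,
               subjects=len(design.subjects),
               channels=raw.n_metabolites)
    return raw, runs, design


@_stage("exclusions")
def _apply_exclusions(config, raw, runlog):
    path = config.get("exclusions")
    if not path:
        return raw
    names = [line.strip() for line in open(path) if line.strip()]
    before = raw.n_metabolites
    raw = dataio.apply_exclusion_list(raw, names)
    runlog.add("exclusions", channels_in=before, channels_out=raw.n_metabolites)
    return raw


@_stage("normalize")
def _normalize(raw, runs, runlog):
    normalized, report = normalization.pool_normalize(raw, runs)
    runlog.add("normalize", runs_in=raw.n_runs,
               runs_out=normalized.n_runs,
               warnings=report.warnings)
    return normalized, report


@_stage("qc")
def _qc(config, raw, normalized, runs, design, runlog):
    mode = config["rsd"]["mode"]
    threshold = config["rsd"]["threshold"]
    rsd_table = qc.compute_rsd(mode, raw=raw, normalized=normalized,
                               runs=runs, design=design, threshold=threshold)
    filtered = qc.filter_matrix(normalized, rsd_table, threshold)
    runlog.add("qc", mode=mode, threshold=threshold,
               channels_in=normalized.n_metabolites,
               channels_out=filtered.n_metabolites)
    return rsd_table, filtered


@_stage("scan")
def _scans(filtered, design, alpha, log_transform, runlog):
    met_features = stats.average_replicates(filtered, design)
    met_results = stats.run_scan(met_features, design, "metabolite",
                                 alpha=alpha, log_transform=log_transform)
    ratio_features = stats.build_ratio_features(filtered, design)
    ratio_results = stats.run_scan(ratio_features, design, "ratio",
                                   alpha=alpha, log_transform=log_transform)
    runlog.add("scan",
               metabolite_features=len(met_results),
               metabolite_significant_raw=int(
                   met_results["significant_raw"].sum()),
               metabolite_significant_adj=int(
                   met_results["significant_adj"].sum()),
               ratio_features=len(ratio_results),
               ratio_significant_raw=int(
                   ratio_results["significant_raw"].sum()),
               ratio_significant_adj=int(
                   ratio_results["significant_adj"].sum()),
               alpha=alpha)
    return met_results, ratio_results


@_stage("classify")
def _classify(config, normalized, filtered, design, runlog):
    cc = config["classifier"]
    seed = config["seeds"]["cv"]
    data = variants.build_variant(cc["variant"], normalized, filtered, design)
    cv = variants.cross_validate_variant(
        data, k=cc["k"], max_iterations=cc["max_iterations"], seed=seed)
    model = classifier.fit_logitboost(data.features, data.labels,
                                      cv.selected_iterations)
    if data.groups is not None:
        subgroups = data.groups.map(design.age_groups())
    else:
        subgroups = design.age_groups().reindex(data.features.index)
    evaluation = classifier.evaluate(model, data.features, data.labels,
                                     subgroups=subgroups)
    runlog.add("classify", variant=cc["variant"], k=cc["k"],
               max_iterations=cc["max_iterations"], cv_seed=seed,
               features=data.features.shape[1],
               selected_iterations=cv.selected_iterations,
               cv_accuracy=cv.cv_accuracy,
               whole_set_accuracy=evaluation.accuracy,
               auc=evaluation.auc)
    return model, cv, evaluation


def _write_cv(cv: classifier.CrossValidationResult, path) -> None:
    payload = {
        "k": cv.k,
        "seed": cv.seed,
        "selected_iterations": cv.selected_iterations,
        "cv_accuracy": cv.cv_accuracy,
        "fold_accuracies": cv.fold_accuracies,
        "accuracy_curve": list(map(float, cv.accuracy_curve)),
        "folds": {str(k): int(v) for k, v in cv.folds.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def make_report(outdir) -> Path:
    """Assemble a markdown summary from the persisted pipeline outputs."""
    outdir = Path(outdir)
    needed = ["results_metabolites.tsv", "results_ratios.tsv",
              "evaluation.json", "cv.json", "model.tsv", "runlog.json"]
    missing = [n for n in needed if not (outdir / n).exists()]
    if missing:
        raise dataio.DataError(f"missing pipeline outputs: {missing}")
    met = dataio.read_results(outdir / "results_metabolites.tsv")
    ratios = dataio.read_results(outdir / "results_ratios.tsv")
    with open(outdir / "evaluation.json") as fh:
        ev = json.load(fh)
    with open(outdir / "cv.json") as fh:
        cv = json.load(fh)
    model = classifier.read_model(outdir / "model.tsv")

    lines = ["# Pipeline report", ""]
    for label, table in (("metabolites", met), ("ratios", ratios)):
        lines.append(f"## Top {label} by adjusted p")
        lines.append("")
        lines.append("| feature | t | p | p_adj |")
        lines.append("|---|---|---|---|")
        for row in table.sort_values("p_adj").head(10).itertuples():
            lines.append(f"| {row.feature_id} | {row.t:.3f} "
                         f"| {row.p:.3g} | {row.p_adj:.3g} |")
        lines.append("")
    lines.append("## Classifier")
    lines.append("")
    lines.append(f"- selected iterations: {cv['selected_iterations']}")
    lines.append(f"- cross-validation accuracy: {cv['cv_accuracy']:.3f}")
    lines.append(f"- whole-set accuracy: {ev['accuracy']:.3f}")
    lines.append(f"- sensitivity: {ev['sensitivity']:.3f}")
    lines.append(f"- specificity: {ev['specificity']:.3f}")
    lines.append(f"- AUC: {ev['auc']:.6f}")
    for name, sub in sorted(ev.get("subgroups", {}).items()):
        lines.append(f"- {name}: accuracy {sub['accuracy']:.3f}, "
                     f"AUC {sub['auc']:.3f}")
    lines.append("")
    lines.append("## Model features")
    lines.append("")
    for feat in model.features_used():
        lines.append(f"- {feat}")
    lines.append("")
    lines.append("## ROC points")
    lines.append("")
    lines.append("| FPR | TPR |")
    lines.append("|---|---|")
    for fpr, tpr in ev["roc_points"]:
        lines.append(f"| {fpr:.4f} | {tpr:.4f} |")
    lines.append("")
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
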