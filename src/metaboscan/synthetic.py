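"""Synthetic GC-MS-like dataset generator.

Emulates the acquisition structure the pipeline expects: a case/control
cohort measured in technical replicates, QC pool injections interleaved at a
fixed cadence, multiplicative run-order drift shared across channels, and a
configurable fraction of channels whose measurement coefficient of variation
falls below the 20% QC threshold.  Case/control effects are planted on named
channels as natural-log fold changes.

Model per study run and channel ``m``::

    intensity = baseline_m * subject_effect * group_effect
                * drift(run_index) * measurement_noise

where ``subject_effect`` is a mean-one lognormal per subject/channel,
``group_effect = exp(lfc)`` for cases on planted channels, and the
measurement noise is a mean-one lognormal with channel-specific CV.  Pool
runs are aliquots of a virtual grand mean: their expected intensity per
channel is the geometric mean of all study-sample expected intensities, with
drift and measurement noise applied like any other injection.

Everything is deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    DataError,
    IntensityMatrix,
    StudyDesign,
    age_group_for,
    build_design,
    write_intensity,
    write_runs,
    write_subjects,
)

DRIFT_MODELS = ("none", "linear", "smooth_random_walk")

#: Channels carrying the planted case/control effects in the default
#: configuration: one metabolite elevated in cases plus two channels whose
#: ratios to it are thereby shifted down.
DEFAULT_PLANTED = (
    ("pyruvic acid", 0.5),
    ("lactic acid", -0.1),
    ("RI1984", -0.1),
)


@dataclass(frozen=True)
class PlantedEffect:
    """A case-vs-control shift on one channel, as a natural-log fold change."""

    metabolite_name: str
    log_fold_change: float


@dataclass(frozen=True)
class GeneratorConfig:
    n_cases: int = 72
    n_controls: int = 72
    n_metabolites: int = 262
    n_replicates_per_subject: int = 2
    #: study runs between consecutive pool injections
    pool_cadence: int = 8
    drift_model: str = "none"
    #: multiplicative half-range of the drift (0.3 => sensitivity spans ±30%)
    drift_amplitude: float = 0.0
    #: natural-log interval channel baselines are drawn from
    baseline_log_mean_range: tuple[float, float] = (9.2, 13.8)
    #: interval the per-channel measurement CVs are drawn from
    channel_rsd_range: tuple[float, float] = (0.02, 0.60)
    #: fraction of channels with measurement CV below 0.20
    frac_low_rsd: float = 78 / 262
    #: between-subject biological coefficient of variation
    subject_cv: float = 0.4
    planted_effects: tuple[PlantedEffect, ...] = tuple(
        PlantedEffect(n, f) for n, f in DEFAULT_PLANTED)
    #: per-cohort inclusive age ranges in years
    age_ranges: dict = field(default_factory=lambda: {
        "case": (24, 65), "control": (19, 67)})
    #: explicit channel names; None auto-generates, embedding planted names
    metabolite_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_metabolites",
                     "n_replicates_per_subject", "pool_cadence"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be > 0")
        if self.drift_model not in DRIFT_MODELS:
            raise DataError(f"unknown drift_model {self.drift_model!r}")
        if self.drift_amplitude < 0:
            raise DataError("drift_amplitude must be >= 0")
        if not 0 <= self.frac_low_rsd <= 1:
            raise DataError("frac_low_rsd must be in [0, 1]")
        lo, hi = self.channel_rsd_range
        if not (0 < lo <= hi < 1):
            raise DataError("channel_rsd_range must lie within (0, 1)")


@dataclass
class SyntheticDataset:
    """A generated dataset: raw intensities, run table, design, and truth."""

    intensity: IntensityMatrix
    runs: pd.DataFrame
    design: StudyDesign
    truth: list[PlantedEffect]
    config: GeneratorConfig


def _channel_names(config: GeneratorConfig) -> list[str]:
    planted = [e.metabolite_name for e in config.planted_effects]
    if config.metabolite_names is not None:
        names = list(config.metabolite_names)
        if len(names) != config.n_metabolites:
            raise DataError("metabolite_names length != n_metabolites")
        return names
    if len(planted) > config.n_metabolites:
        raise DataError("more planted effects than channels")
    generic = [f"m{i + 1:03d}" for i in range(config.n_metabolites - len(planted))]
    return planted + generic


def _drift_curve(config: GeneratorConfig, n_runs: int,
                 rng: np.random.Generator) -> np.ndarray:
    if config.drift_model == "none" or config.drift_amplitude == 0:
        return np.ones(n_runs)
    a = config.drift_amplitude
    if config.drift_model == "linear":
        x = np.linspace(-1.0, 1.0, n_runs) if n_runs > 1 else np.zeros(1)
        return 1.0 + a * x
    # smooth_random_walk: cumulative gaussian steps rescaled to half-range a
    steps = rng.normal(size=n_runs)
    walk = np.cumsum(steps)
    walk -= walk.mean()
    span = np.abs(walk).max()
    if span > 0:
        walk *= a / span
    return np.exp(walk)


def _lognormal_sigma(cv: np.ndarray | float) -> np.ndarray | float:
    return np.sqrt(np.log1p(np.square(cv)))


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a synthetic dataset under ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    names = _channel_names(config)
    name_to_col = {n: j for j, n in enumerate(names)}
    for effect in config.planted_effects:
        if effect.metabolite_name not in name_to_col:
            raise DataError(
                f"planted metabolite {effect.metabolite_name!r} "
                "is not among the generated channels")

    m = config.n_metabolites
    n_cases, n_controls = config.n_cases, config.n_controls
    n_subjects = n_cases + n_controls
    reps = config.n_replicates_per_subject

    # channel baselines (log space) and measurement CVs
    lo, hi = config.baseline_log_mean_range
    log_baseline = rng.uniform(lo, hi, size=m)
    cv = _draw_channel_cvs(config, rng, names, name_to_col)

    # subjects: ids, groups, ages
    subject_ids = ([f"case{i + 1:03d}" for i in range(n_cases)]
                   + [f"ctrl{i + 1:03d}" for i in range(n_controls)])
    groups = np.array(["case"] * n_cases + ["control"] * n_controls)
    ages = np.empty(n_subjects, dtype=int)
    for grp in ("case", "control"):
        a_lo, a_hi = config.age_ranges[grp]
        sel = groups == grp
        ages[sel] = rng.integers(a_lo, a_hi + 1, size=sel.sum())

    # log expected intensity per subject x channel (drift/noise excluded)
    sigma_subj = _lognormal_sigma(config.subject_cv)
    subj_effect = rng.normal(-0.5 * sigma_subj**2, sigma_subj,
                             size=(n_subjects, m))
    log_expected = log_baseline[None, :] + subj_effect
    for effect in config.planted_effects:
        j = name_to_col[effect.metabolite_name]
        log_expected[groups == "case", j] += effect.log_fold_change
    log_pool = log_expected.mean(axis=0)  # geometric mean over study samples

    # acquisition order: seeded permutation of (subject, replicate) pairs,
    # with one pool injection after every `pool_cadence` study measurements
    pairs = [(s, r + 1) for s in range(n_subjects) for r in range(reps)]
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    n_study = len(pairs)
    n_pools = n_study // config.pool_cadence
    n_runs = n_study + n_pools

    drift = _drift_curve(config, n_runs, rng)
    sigma_meas = _lognormal_sigma(cv)

    run_rows = []
    values = np.empty((n_runs, m))
    study_i, pool_i = 0, 0
    for idx in range(1, n_runs + 1):
        is_pool = (study_i > 0 and study_i % config.pool_cadence == 0
                   and pool_i < study_i // config.pool_cadence)
        noise = rng.normal(-0.5 * sigma_meas**2, sigma_meas)
        if is_pool:
            pool_i += 1
            run_id = f"p{pool_i:03d}"
            log_val = log_pool
            run_rows.append((run_id, idx, "pool", "", ""))
        else:
            s, r = pairs[study_i]
            study_i += 1
            run_id = f"s{study_i:03d}"
            log_val = log_expected[s]
            run_rows.append((run_id, idx, "study", subject_ids[s], str(r)))
        values[idx - 1] = np.exp(log_val + noise) * drift[idx - 1]

    runs = pd.DataFrame(
        run_rows,
        columns=["run_id", "run_index", "sample_type", "subject_id",
                 "replicate_id"])
    intensity = IntensityMatrix(
        pd.DataFrame(values, index=pd.Index(runs["run_id"], name="run_id"),
                     columns=names),
        stage="raw")
    subjects = pd.DataFrame({
        "subject_id": subject_ids,
        "group": groups,
        "age": ages,
        "age_group": [age_group_for(a) for a in ages],
    })
    design = build_design(runs, subjects)
    return SyntheticDataset(intensity=intensity, runs=runs, design=design,
                            truth=list(config.planted_effects), config=config)


def _draw_channel_cvs(config, rng, names, name_to_col) -> np.ndarray:
    """Per-channel measurement CVs with the configured low-RSD fraction.

    Planted channels are always assigned low (sub-threshold) CVs so that they
    survive the downstream RSD filter.
    """
    m = config.n_metabolites
    lo, hi = config.channel_rsd_range
    low_cut = min(0.20, hi)
    n_low = int(round(config.frac_low_rsd * m))
    planted_cols = [name_to_col[e.metabolite_name]
                    for e in config.planted_effects]
    n_low = max(n_low, len(planted_cols))
    others = np.array([j for j in range(m) if j not in set(planted_cols)])
    rng.shuffle(others)
    low_cols = planted_cols + list(others[:n_low - len(planted_cols)])
    cv = np.empty(m)
    is_low = np.zeros(m, dtype=bool)
    is_low[low_cols] = True
    cv[is_low] = rng.uniform(lo, min(low_cut, hi), size=is_low.sum())
    if (~is_low).any():
        cv[~is_low] = rng.uniform(min(low_cut, hi), hi, size=(~is_low).sum())
    return cv


def assign_age_groups(design: StudyDesign) -> StudyDesign:
    """Label every subject with its age stratum (inclusive bounds)."""
    subjects = design.subjects.copy()
    subjects["age_group"] = subjects["age"].map(age_group_for)
    return StudyDesign(subjects=subjects, run_map=design.run_map)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the pipeline input files plus the planted-effect truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensity": outdir / "intensity.tsv",
        "runs": outdir / "metadata_runs.tsv",
        "subjects": outdir / "metadata_subjects.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_intensity(dataset.intensity, paths["intensity"])
    write_runs(dataset.runs, paths["runs"])
    write_subjects(dataset.design, paths["subjects"])
    truth = pd.DataFrame(
        [(e.metabolite_name, e.log_fold_change) for e in dataset.truth],
        columns=["metabolite", "log_fold_change"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def null_config(**overrides) -> GeneratorConfig:
    """Default configuration with no planted effects and no drift."""
    base = GeneratorConfig(planted_effects=(), drift_model="none",
                           drift_amplitude=0.0)
    return replace(base, **overrides) if overrides else base
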