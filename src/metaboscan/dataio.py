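"""Tabular data model and file IO for the analysis pipeline.

The interchange format is wide: one row per instrument run, one column per
metabolite channel.  Three tab-separated files describe a dataset:

``intensity.tsv``
    ``run_id<TAB>m1<TAB>m2...`` — non-negative intensities, no missing values.
``metadata_runs.tsv``
    ``run_id, run_index, sample_type, subject_id, replicate_id`` — one row per
    run; pool runs leave ``subject_id``/``replicate_id`` empty.
``metadata_subjects.tsv``
    ``subject_id, group, age, age_group``.

Results tables are written as
``feature_id, kind, mean_case, mean_control, t, df, p, p_adj``.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Inclusive age bounds for the three age strata.
AGE_GROUPS = {"G1": (19, 34), "G2": (35, 50), "G3": (51, 67)}

GROUPS = ("case", "control")
SAMPLE_TYPES = ("pool", "study")

RESULT_COLUMNS = [
    "feature_id", "kind", "mean_case", "mean_control", "t", "df", "p", "p_adj",
]

# float format that survives a write->read round trip bit-exactly
FLOAT_FMT = "%.17g"


class DataError(ValueError):
    """A dataset violates a structural invariant."""


def age_group_for(age: float) -> str:
    """Return the age stratum (G1/G2/G3) for an age in years."""
    for name, (lo, hi) in AGE_GROUPS.items():
        if lo <= age <= hi:
            return name
    raise DataError(f"age {age} outside supported range 19-67")


@dataclass
class IntensityMatrix:
    """Runs x metabolites intensity table.

    ``data`` is indexed by ``run_id`` with one column per metabolite channel;
    ``stage`` records whether values are raw detector intensities or unitless
    ratios-to-pool after normalization.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def run_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_runs(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if self.stage not in ("raw", "normalized"):
            raise DataError(f"unknown stage {self.stage!r}")
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise DataError(f"duplicate run_id {dup!r}")
        cols = self.data.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise DataError(f"duplicate metabolite name {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("non-numeric intensity values")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise DataError(
                f"missing value at run {idx[r]!r}, metabolite {cols[c]!r}")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise DataError(
                f"negative intensity at run {idx[r]!r}, metabolite {cols[c]!r}")

    def subset_runs(self, run_ids) -> "IntensityMatrix":
        return IntensityMatrix(self.data.loc[list(run_ids)], stage=self.stage)

    def subset_metabolites(self, names) -> "IntensityMatrix":
        return IntensityMatrix(self.data[list(names)], stage=self.stage)


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_intensity(path, dialect: str | None = None,
                   stage: str = "raw") -> IntensityMatrix:
    """Read a wide intensity table (first column ``run_id``).

    ``dialect`` forces the delimiter ("\\t" or ","); by default it is detected
    from the header line.  Ragged rows, duplicate run ids, negative values and
    missing cells are rejected with located error messages.
    """
    path = Path(path)
    sep = dialect or _detect_delimiter(path)
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        rows = list(reader)
    if not rows:
        raise DataError(f"{path}: empty file")
    header = rows[0]
    ncol = len(header)
    run_ids, values = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != ncol:
            raise DataError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, expected {ncol})")
        run_ids.append(row[0])
        try:
            values.append([float(v) for v in row[1:]])
        except ValueError as exc:
            raise DataError(f"{path}: bad value at line {lineno}: {exc}") from exc
    frame = pd.DataFrame(values, index=pd.Index(run_ids, name=header[0]),
                         columns=header[1:])
    try:
        return IntensityMatrix(frame, stage=stage)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_intensity(matrix: IntensityMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="run_id",
                       float_format=FLOAT_FMT)


def validate_runs(runs: pd.DataFrame) -> pd.DataFrame:
    """Validate a run metadata table and normalize its dtypes."""
    required = ["run_id", "run_index", "sample_type", "subject_id",
                "replicate_id"]
    missing = [c for c in required if c not in runs.columns]
    if missing:
        raise DataError(f"run metadata missing columns {missing}")
    runs = runs.copy()
    runs["run_id"] = runs["run_id"].astype(str)
    runs["run_index"] = runs["run_index"].astype(int)
    runs["subject_id"] = runs["subject_id"].fillna("").astype(str)
    runs["replicate_id"] = runs["replicate_id"].fillna("").astype(str)
    # pandas round-trips empty replicate ids through float; normalize "1.0"->"1"
    runs["replicate_id"] = runs["replicate_id"].str.replace(
        r"\.0$", "", regex=True)
    if runs["run_id"].duplicated().any():
        dup = runs.loc[runs["run_id"].duplicated(), "run_id"].iloc[0]
        raise DataError(f"duplicate run_id {dup!r}")
    n = len(runs)
    if sorted(runs["run_index"]) != list(range(1, n + 1)):
        raise DataError("run_index values are not a permutation of 1..N")
    bad_type = ~runs["sample_type"].isin(SAMPLE_TYPES)
    if bad_type.any():
        raise DataError(
            f"unknown sample_type {runs.loc[bad_type, 'sample_type'].iloc[0]!r}")
    pools = runs[runs["sample_type"] == "pool"]
    if ((pools["subject_id"] != "") | (pools["replicate_id"] != "")).any():
        bad = pools[(pools["subject_id"] != "")
                    | (pools["replicate_id"] != "")].iloc[0]
        raise DataError(f"pool run {bad['run_id']!r} has a subject/replicate")
    study = runs[runs["sample_type"] == "study"]
    if ((study["subject_id"] == "") | (study["replicate_id"] == "")).any():
        bad = study[(study["subject_id"] == "")
                    | (study["replicate_id"] == "")].iloc[0]
        raise DataError(f"study run {bad['run_id']!r} lacks subject/replicate")
    return runs.sort_values("run_index").reset_index(drop=True)


@dataclass
class StudyDesign:
    """Subject-level labels and the subject -> study-run mapping."""

    subjects: pd.DataFrame  # subject_id, group, age, age_group
    run_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.subjects) == 0:
            raise DataError("no subjects")
        subj = self.subjects.copy()
        subj["subject_id"] = subj["subject_id"].astype(str)
        if subj["subject_id"].duplicated().any():
            dup = subj.loc[subj["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise DataError(f"duplicate subject_id {dup!r}")
        bad = ~subj["group"].isin(GROUPS)
        if bad.any():
            raise DataError(
                f"unknown group {subj.loc[bad, 'group'].iloc[0]!r}")
        if "age_group" not in subj.columns or subj["age_group"].isna().any() \
                or (subj.get("age_group", pd.Series(dtype=str)) == "").any():
            subj["age_group"] = subj["age"].map(age_group_for)
        self.subjects = subj.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject_id"])

    def labels(self) -> pd.Series:
        return self.subjects.set_index("subject_id")["group"]

    def age_groups(self) -> pd.Series:
        return self.subjects.set_index("subject_id")["age_group"]

    def group_sizes(self) -> dict[str, int]:
        return self.subjects["group"].value_counts().to_dict()


def build_design(runs: pd.DataFrame, subjects: pd.DataFrame) -> StudyDesign:
    """Cross-validate run and subject tables and assemble a StudyDesign."""
    runs = validate_runs(runs)
    design = StudyDesign(subjects=subjects)
    known = set(design.subject_ids)
    study = runs[runs["sample_type"] == "study"]
    unknown = set(study["subject_id"]) - known
    if unknown:
        raise DataError(
            f"study run references unknown subject {sorted(unknown)[0]!r}")
    run_map: dict[str, list[str]] = {s: [] for s in design.subject_ids}
    for _, row in study.sort_values("run_index").iterrows():
        run_map[row["subject_id"]].append(row["run_id"])
    for sid, rids in run_map.items():
        if len(rids) == 0:
            raise DataError(f"subject {sid!r} has no mapped study runs")
        if len(rids) == 1:
            logger.info("subject %s has a single replicate", sid)
    design.run_map = run_map
    return design


def read_metadata(run_path, subject_path) -> tuple[pd.DataFrame, StudyDesign]:
    """Read run and subject metadata tables, cross-validating them."""
    runs = pd.read_csv(run_path, sep=None, engine="python",
                       keep_default_na=False, na_values=[])
    subjects = pd.read_csv(subject_path, sep=None, engine="python",
                           keep_default_na=False, na_values=[])
    if len(subjects) == 0:
        raise DataError("no subjects")
    subjects["age"] = subjects["age"].astype(float)
    design = build_design(runs, subjects)
    return validate_runs(runs), design


def write_runs(runs: pd.DataFrame, path) -> None:
    validate_runs(runs).to_csv(path, sep="\t", index=False)


def write_subjects(design: StudyDesign, path) -> None:
    design.subjects.to_csv(path, sep="\t", index=False)


def apply_exclusion_list(matrix: IntensityMatrix,
                         names: list[str]) -> IntensityMatrix:
    """Drop named channels (e.g. siloxane artefacts) from the matrix.

    Unknown names produce a warning, not an error; excluding every channel is
    an error.
    """
    present = [n for n in names if n in matrix.data.columns]
    unknown = [n for n in names if n not in matrix.data.columns]
    if unknown:
        warnings.warn(f"exclusion list names unknown channels: {unknown}")
        logger.warning("exclusion list names unknown channels: %s", unknown)
    if len(present) == matrix.n_metabolites:
        raise DataError("exclusion list would remove every channel")
    if not present:
        return matrix
    keep = [c for c in matrix.metabolite_names if c not in set(present)]
    return matrix.subset_metabolites(keep)


def write_results(results: pd.DataFrame, path) -> None:
    results[RESULT_COLUMNS].to_csv(path, sep="\t", index=False,
                                   float_format=FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
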