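"""Per-channel relative standard deviation (RSD) QC filtering.

Channels whose RSD is at or above the threshold (default 20%) are excluded.
The population the RSD is computed over is selectable; the default,
``pools_raw``, measures repeatability on the raw QC-pool injections, which is
independent of the case/control contrast and not deflated by the pool-based
normalization itself.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dataio import DataError, IntensityMatrix, StudyDesign
from .normalization import normalize_pools, replicate_cv

logger = logging.getLogger(__name__)

RSD_MODES = ("pools_raw", "pools_normalized", "study_normalized",
             "replicate_cv")

DEFAULT_THRESHOLD = 0.20


class QcError(DataError):
    pass


def rsd_of_values(values: pd.DataFrame) -> pd.Series:
    """Sample RSD (sd/mean, ddof=1) per column; zero mean maps to +inf."""
    if len(values) < 2:
        raise QcError("need >= 2 values per metabolite to compute RSD")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = sd / mean
    zero_mean = mean == 0
    if zero_mean.any():
        for name in values.columns[zero_mean]:
            logger.warning("metabolite %r has zero mean; RSD set to +inf",
                           name)
        rsd[zero_mean] = np.inf
    return rsd


def compute_rsd(mode: str = "pools_raw", *,
                raw: IntensityMatrix | None = None,
                normalized: IntensityMatrix | None = None,
                runs: pd.DataFrame | None = None,
                design: StudyDesign | None = None,
                threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Compute the per-metabolite RSD table for the selected population.

    Returns a DataFrame indexed by metabolite with columns ``rsd``, ``mode``
    and ``retained`` (strict: rsd == threshold is excluded).
    """
    if mode not in RSD_MODES:
        raise QcError(f"unknown RSD mode {mode!r}; choose from {RSD_MODES}")
    if mode == "pools_raw":
        if raw is None or runs is None:
            raise QcError("pools_raw mode needs the raw matrix and run table")
        run_tab = runs.set_index("run_id")
        pool_ids = [r for r in raw.run_ids
                    if run_tab.loc[r, "sample_type"] == "pool"]
        if len(pool_ids) < 2:
            raise QcError("need >= 2 pool runs for pools_raw RSD")
        rsd = rsd_of_values(raw.data.loc[pool_ids])
    elif mode == "pools_normalized":
        if raw is None or runs is None:
            raise QcError("pools_normalized mode needs the raw matrix and "
                          "run table")
        rsd = rsd_of_values(normalize_pools(raw, runs).data)
    elif mode == "study_normalized":
        if normalized is None:
            raise QcError("study_normalized mode needs the normalized matrix")
        rsd = rsd_of_values(normalized.data)
    else:  # replicate_cv
        if normalized is None or design is None:
            raise QcError("replicate_cv mode needs the normalized matrix "
                          "and design")
        rsd = replicate_cv(normalized, design)
    table = pd.DataFrame({"rsd": rsd})
    table.index.name = "metabolite"
    table["mode"] = mode
    table["retained"] = table["rsd"] < threshold
    return table


def filter_matrix(matrix: IntensityMatrix, rsd_table: pd.DataFrame,
                  threshold: float = DEFAULT_THRESHOLD) -> IntensityMatrix:
    """Drop channels with RSD >= threshold, preserving survivor order."""
    missing = [c for c in matrix.metabolite_names if c not in rsd_table.index]
    if missing:
        raise QcError(f"rsd table does not cover channel {missing[0]!r}")
    keep = [c for c in matrix.metabolite_names
            if rsd_table.loc[c, "rsd"] < threshold]
    if not keep:
        raise QcError("RSD filter removed every channel")
    return matrix.subset_metabolites(keep)


def write_rsd(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_rsd(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="metabolite")
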