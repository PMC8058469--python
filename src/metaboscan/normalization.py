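"""QC-pool based drift correction and replicate-level QC.

Each study-run intensity is divided by the median intensity of the three
chronologically nearest pool injections of the same channel; chronology is
acquisition-order index distance, with ties broken toward the earlier pool.
Pool rows are dropped from the normalized output since downstream statistics
use study samples only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import DataError, IntensityMatrix, StudyDesign

logger = logging.getLogger(__name__)


class NormalizationError(DataError):
    pass


@dataclass
class NormalizationReport:
    """Traceability of which pools normalized which run."""

    #: columns: run_id, pool_run_ids (comma-joined), n_pools
    pool_map: pd.DataFrame
    n_runs_normalized: int = 0
    warnings: list[str] = field(default_factory=list)


def nearest_pools(run_index: int, pool_indices, k: int = 3) -> list[int]:
    """Indices of the ``k`` pools closest to ``run_index`` in acquisition order.

    Ties in |pool - run| are broken toward the earlier pool.  Returns
    ``min(k, available)`` indices sorted ascending.
    """
    pools = sorted(pool_indices)
    if not pools:
        raise NormalizationError("no pool samples present")
    ranked = sorted(pools, key=lambda p: (abs(p - run_index), p))
    return sorted(ranked[:min(k, len(ranked))])


def pool_normalize(matrix: IntensityMatrix, runs: pd.DataFrame,
                   k: int = 3) -> tuple[IntensityMatrix, NormalizationReport]:
    """Divide study intensities by the median of the k nearest pools.

    Returns the normalized matrix (study runs only, acquisition order
    preserved) and a report mapping each study run to the pool runs used.
    """
    if matrix.stage != "raw":
        raise NormalizationError("pool_normalize expects a raw-stage matrix")
    runs = runs.set_index("run_id", drop=False)
    missing = [r for r in matrix.run_ids if r not in runs.index]
    if missing:
        raise NormalizationError(f"run {missing[0]!r} absent from metadata")

    idx_of = runs["run_index"]
    pool_ids = runs.loc[runs["sample_type"] == "pool", "run_id"]
    pool_indices = sorted(idx_of[p] for p in pool_ids if p in matrix.data.index)
    if not pool_indices:
        raise NormalizationError("no pool samples present")
    index_to_run = {int(idx_of[r]): r for r in matrix.run_ids}

    warnings_list: list[str] = []
    if len(pool_indices) < k:
        msg = (f"only {len(pool_indices)} pool runs available; using all "
               f"of them for every study run")
        warnings_list.append(msg)
        logger.warning(msg)

    study_ids = [r for r in matrix.run_ids
                 if runs.loc[r, "sample_type"] == "study"]

    median_cache: dict[tuple[int, ...], np.ndarray] = {}
    rows = []
    map_rows = []
    for rid in study_ids:
        sel = tuple(nearest_pools(int(idx_of[rid]), pool_indices, k))
        med = median_cache.get(sel)
        if med is None:
            pool_runs = [index_to_run[i] for i in sel]
            med = matrix.data.loc[pool_runs].median(axis=0).to_numpy()
            zero = np.flatnonzero(med == 0)
            if zero.size:
                name = matrix.metabolite_names[zero[0]]
                raise NormalizationError(
                    f"pool median is zero for metabolite {name!r} "
                    f"(pools {pool_runs})")
            median_cache[sel] = med
        rows.append(matrix.data.loc[rid].to_numpy() / med)
        map_rows.append((rid, ",".join(index_to_run[i] for i in sel), len(sel)))

    normalized = IntensityMatrix(
        pd.DataFrame(rows, index=pd.Index(study_ids, name="run_id"),
                     columns=matrix.metabolite_names),
        stage="normalized")
    report = NormalizationReport(
        pool_map=pd.DataFrame(map_rows,
                              columns=["run_id", "pool_run_ids", "n_pools"]),
        n_runs_normalized=len(study_ids),
        warnings=warnings_list)
    return normalized, report


def normalize_pools(matrix: IntensityMatrix, runs: pd.DataFrame,
                    k: int = 3) -> IntensityMatrix:
    """Leave-one-out normalization of the pool runs themselves.

    Each pool is divided by the median of its k nearest *other* pools; used
    only by the ``pools_normalized`` RSD mode.
    """
    if matrix.stage != "raw":
        raise NormalizationError("normalize_pools expects a raw-stage matrix")
    runs = runs.set_index("run_id", drop=False)
    idx_of = runs["run_index"]
    pool_ids = [r for r in matrix.run_ids
                if runs.loc[r, "sample_type"] == "pool"]
    if len(pool_ids) < 2:
        raise NormalizationError("need at least 2 pool runs")
    index_to_run = {int(idx_of[r]): r for r in pool_ids}
    all_indices = sorted(index_to_run)
    rows = []
    for rid in pool_ids:
        own = int(idx_of[rid])
        others = [i for i in all_indices if i != own]
        sel = nearest_pools(own, others, k)
        pool_runs = [index_to_run[i] for i in sel]
        med = matrix.data.loc[pool_runs].median(axis=0).to_numpy()
        if (med == 0).any():
            name = matrix.metabolite_names[int(np.flatnonzero(med == 0)[0])]
            raise NormalizationError(
                f"pool median is zero for metabolite {name!r}")
        rows.append(matrix.data.loc[rid].to_numpy() / med)
    return IntensityMatrix(
        pd.DataFrame(rows, index=pd.Index(pool_ids, name="run_id"),
                     columns=matrix.metabolite_names),
        stage="normalized")


def drift_correlation(matrix: IntensityMatrix,
                      runs: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of run order vs per-run mean log intensity.

    A diagnostic for shared multiplicative drift: the cross-channel mean of
    the log intensities tracks instrument sensitivity while per-channel noise
    averages out.  Returns (rho, p).
    """
    from scipy.stats import spearmanr

    runs = runs.set_index("run_id")
    order = runs.loc[matrix.run_ids, "run_index"].to_numpy()
    values = matrix.data.to_numpy()
    if (values <= 0).any():
        raise NormalizationError("drift diagnostic needs positive intensities")
    sensitivity = np.log(values).mean(axis=1)
    rho, p = spearmanr(order, sensitivity)
    return float(rho), float(p)


def replicate_cv(matrix: IntensityMatrix,
                 design: StudyDesign) -> pd.Series:
    """Median over subjects of the per-subject replicate CV, per metabolite.

    Subjects with a single replicate are skipped.  Requires at least one
    subject with >= 2 replicates.
    """
    per_subject = []
    for sid, run_ids in design.run_map.items():
        present = [r for r in run_ids if r in matrix.data.index]
        if len(present) < 2:
            continue
        vals = matrix.data.loc[present]
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = sd / mean
        per_subject.append(cv)
    if not per_subject:
        raise NormalizationError(
            "no subject has >= 2 replicates; cannot compute replicate CV")
    return pd.DataFrame(per_subject).median(axis=0).rename("replicate_cv")
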