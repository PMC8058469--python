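"""Replicate averaging, ratio features, Welch tests and BH adjustment.

The metabolite scan operates on replicate-averaged subject values; the ratio
scan builds one oriented feature per unordered channel pair (numerator =
lexicographically smaller name), computing the ratio within each replicate
run before averaging per subject.  Each scan is tested with a two-tailed
Welch t-test and Benjamini-Hochberg adjusted over its own feature family.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataio import RESULT_COLUMNS, DataError, IntensityMatrix, StudyDesign


class StatsError(DataError):
    pass


def average_replicates(matrix: IntensityMatrix,
                       design: StudyDesign) -> pd.DataFrame:
    """Arithmetic mean across each subject's replicate runs, per metabolite.

    Returns a subjects x metabolites DataFrame indexed by subject_id.
    """
    rows = {}
    for sid, run_ids in design.run_map.items():
        present = [r for r in run_ids if r in matrix.data.index]
        if not present:
            raise StatsError(f"subject {sid!r} has no runs in the matrix")
        rows[sid] = matrix.data.loc[present].mean(axis=0)
    table = pd.DataFrame(rows).T
    table.index.name = "subject_id"
    return table.loc[design.subject_ids]


def ratio_feature_ids(metabolites) -> list[str]:
    """Oriented 'num:den' ids for all unordered pairs (lexicographic order)."""
    ordered = sorted(metabolites)
    return [f"{a}:{b}" for a, b in combinations(ordered, 2)]


def build_ratio_features(matrix: IntensityMatrix,
                         design: StudyDesign) -> pd.DataFrame:
    """Per-subject replicate-averaged ratios for all unordered channel pairs.

    The ratio is computed within each replicate run, then averaged across a
    subject's replicates; a zero denominator in any run is an error.  For n
    channels the result has n(n-1)/2 columns.
    """
    names = sorted(matrix.metabolite_names)
    if len(names) < 2:
        raise StatsError("need >= 2 metabolites to build ratio features")
    values = matrix.data[names].to_numpy()
    zero = np.argwhere(values == 0)
    if zero.size:
        r, c = zero[0]
        raise StatsError(
            f"zero intensity in run {matrix.run_ids[r]!r} for metabolite "
            f"{names[c]!r}; ratio features undefined")
    iu, ju = np.triu_indices(len(names), k=1)
    ratios = values[:, iu] / values[:, ju]
    cols = [f"{names[i]}:{names[j]}" for i, j in zip(iu, ju)]
    per_run = pd.DataFrame(ratios, index=matrix.data.index, columns=cols)
    rows = {}
    for sid, run_ids in design.run_map.items():
        present = [r for r in run_ids if r in per_run.index]
        if not present:
            raise StatsError(f"subject {sid!r} has no runs in the matrix")
        rows[sid] = per_run.loc[present].mean(axis=0)
    table = pd.DataFrame(rows).T
    table.index.name = "subject_id"
    return table.loc[design.subject_ids]


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Two-tailed Welch t-test: returns (t, Welch-Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each group needs >= 2 values for Welch's t-test")
    t, df, p = _welch_arrays(x[:, None], y[:, None])
    return float(t[0]), float(df[0]), float(p[0])


def _welch_arrays(x: np.ndarray, y: np.ndarray):
    """Vectorized Welch test over columns of two (n, m) arrays."""
    nx, ny = x.shape[0], y.shape[0]
    mx, my = x.mean(axis=0), y.mean(axis=0)
    vx, vy = x.var(axis=0, ddof=1), y.var(axis=0, ddof=1)
    ax, ay = vx / nx, vy / ny
    denom = np.sqrt(ax + ay)
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        df = (ax + ay) ** 2 / (ax**2 / (nx - 1) + ay**2 / (ny - 1))
    # both groups constant: define t=0, p=1 when means agree, else +/-inf
    degenerate = denom == 0
    if np.any(degenerate):
        t = np.where(degenerate & (diff == 0), 0.0, t)
        t = np.where(degenerate & (diff != 0), np.sign(diff) * np.inf, t)
        df = np.where(degenerate, nx + ny - 2, df)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise StatsError("bh_adjust expects a 1-d array")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        bad = p[(p < 0) | (p > 1) | np.isnan(p)][0]
        raise StatsError(f"p-value {bad} outside [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def run_scan(features: pd.DataFrame, design: StudyDesign, kind: str,
             alpha: float = 0.05, log_transform: bool = False) -> pd.DataFrame:
    """Welch + BH scan of a subject-level feature table.

    One row per feature with the Welch statistic, raw and adjusted p-values
    and significance flags; BH is applied within this scan only.
    """
    if not 0 < alpha <= 1:
        raise StatsError("alpha must be in (0, 1]")
    labels = design.labels().reindex(features.index)
    if labels.isna().any():
        missing = features.index[labels.isna()][0]
        raise StatsError(f"subject {missing!r} has no group label")
    case = features.loc[labels == "case"]
    control = features.loc[labels == "control"]
    if len(case) < 2 or len(control) < 2:
        raise StatsError("each group needs >= 2 subjects")
    x = case.to_numpy(dtype=float)
    y = control.to_numpy(dtype=float)
    if log_transform:
        if (x <= 0).any() or (y <= 0).any():
            raise StatsError("log transform requires strictly positive values")
        x, y = np.log(x), np.log(y)
    t, df, p = _welch_arrays(x, y)
    p_adj = bh_adjust(p)
    results = pd.DataFrame({
        "feature_id": features.columns,
        "kind": kind,
        "mean_case": case.mean(axis=0).to_numpy(),
        "mean_control": control.mean(axis=0).to_numpy(),
        "t": t,
        "df": df,
        "p": p,
        "p_adj": p_adj,
        "n_case": len(case),
        "n_control": len(control),
        "significant_raw": p < alpha,
        "significant_adj": p_adj < alpha,
    })
    return results.sort_values("p_adj", kind="mergesort").reset_index(drop=True)


def results_for_output(results: pd.DataFrame) -> pd.DataFrame:
    return results[RESULT_COLUMNS]
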