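"""Assembly of the five training-data variants for the classifier.

raw                      run-level metabolite values (both replicates as rows,
                         subject label attached to each run; folds keep a
                         subject's replicates together)
averaged                 replicate-averaged metabolite values, all channels
averaged_rsd             replicate-averaged values, RSD-filtered channels only
ratios                   all pairwise ratio features of the filtered channels
ratios_plus_metabolites  ratios plus the RSD-filtered averaged metabolites
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classifier import CrossValidationResult, select_iterations
from .dataio import DataError, IntensityMatrix, StudyDesign
from .stats import average_replicates, build_ratio_features

VARIANTS = ("raw", "averaged", "averaged_rsd", "ratios",
            "ratios_plus_metabolites")


@dataclass
class VariantData:
    """A feature table plus the labels/groups needed to cross-validate it."""

    variant: str
    features: pd.DataFrame
    labels: pd.Series
    groups: pd.Series | None  # run -> subject map for run-level rows


def build_variant(variant: str, normalized: IntensityMatrix,
                  filtered: IntensityMatrix,
                  design: StudyDesign) -> VariantData:
    if variant not in VARIANTS:
        raise DataError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    subject_labels = design.labels()
    if variant == "raw":
        run_to_subject = {rid: sid for sid, rids in design.run_map.items()
                          for rid in rids}
        features = normalized.data.loc[list(run_to_subject)]
        groups = pd.Series({rid: run_to_subject[rid] for rid in features.index},
                           name="subject_id")
        labels = groups.map(subject_labels).rename("group")
        return VariantData(variant, features, labels, groups)
    if variant == "averaged":
        features = average_replicates(normalized, design)
    elif variant == "averaged_rsd":
        features = average_replicates(filtered, design)
    elif variant == "ratios":
        features = build_ratio_features(filtered, design)
    else:  # ratios_plus_metabolites
        ratios = build_ratio_features(filtered, design)
        mets = average_replicates(filtered, design)
        features = pd.concat([ratios, mets], axis=1)
    labels = subject_labels.reindex(features.index)
    return VariantData(variant, features, labels, None)


def cross_validate_variant(data: VariantData, k: int = 10,
                           max_iterations: int = 100,
                           seed: int = 0) -> CrossValidationResult:
    return select_iterations(data.features, data.labels, k=k,
                             max_iterations=max_iterations, seed=seed,
                             groups=data.groups)
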