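"""FPKM-threshold expression classification.

Genes are classified as *expressed* (mean FPKM >= 1 at some time point),
*stage-specific* (mean FPKM >= 5 at one stage and <= 1 at all others;
at most one stage can qualify since 5 > 1), and *ovule/seed-exclusive*
against an external tissue panel (mean FPKM < 1 in every external
tissue while >= 5 in ovules or in some 2-8 DAP seed stage). Boundary
comparisons are inclusive (>= for minima, <= for maxima), and means are
unweighted averages over biological replicates within a time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ClassificationRules:
    expressed_min: float = 1.0
    stage_min: float = 5.0
    other_stage_max: float = 1.0
    external_max: float = 1.0
    exclusive_min: float = 5.0

    def __post_init__(self) -> None:
        if not self.stage_min > self.other_stage_max:
            raise ValueError("stage_min must exceed other_stage_max")
        if not self.exclusive_min > self.external_max:
            raise ValueError("exclusive_min must exceed external_max")


def mean_fpkm_by_timepoint(fpkm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Genes x time-points matrix of replicate-mean FPKM."""
    design = design.loc[fpkm.columns]
    return fpkm.T.groupby(design["dap"].to_numpy()).mean().T


def classify_expressed(
    fpkm_by_timepoint: pd.DataFrame, rules: ClassificationRules | None = None
) -> pd.Series:
    rules = rules or ClassificationRules()
    return (fpkm_by_timepoint >= rules.expressed_min).any(axis=1).rename("expressed")


def classify_stage_specific(
    fpkm_by_timepoint: pd.DataFrame, rules: ClassificationRules | None = None
) -> pd.Series:
    """Stage label (time-point value) for stage-specific genes, else NaN."""
    rules = rules or ClassificationRules()
    means = fpkm_by_timepoint.to_numpy(dtype=float)
    stages = fpkm_by_timepoint.columns.to_numpy()
    label = np.full(len(fpkm_by_timepoint), np.nan, dtype=object)
    for j in range(means.shape[1]):
        others = np.delete(means, j, axis=1)
        ok = (means[:, j] >= rules.stage_min) & (others <= rules.other_stage_max).all(axis=1)
        label[ok] = stages[j]
    return pd.Series(label, index=fpkm_by_timepoint.index, name="stage_specific")


def classify_exclusive(
    fpkm_by_timepoint: pd.DataFrame,
    external_fpkm: pd.DataFrame,
    rules: ClassificationRules | None = None,
    ovule_stage: float = 0,
) -> pd.DataFrame:
    """Ovule/seed-exclusive classification against an external panel.

    `external_fpkm` holds mean FPKM per external tissue (columns) for
    each gene; a gene qualifies only when every external tissue is below
    `external_max`. Ovule exclusivity (mean FPKM >= 5 at the ovule
    stage) takes precedence in the single label, but both flags are
    retained.
    """
    rules = rules or ClassificationRules()
    ext = external_fpkm.reindex(fpkm_by_timepoint.index)
    if ext.shape[1] < 1:
        raise ValueError("external panel must cover at least one tissue")
    external_ok = (ext < rules.external_max).all(axis=1) & ext.notna().all(axis=1)
    ovule = fpkm_by_timepoint[ovule_stage] >= rules.exclusive_min
    seed_stages = [c for c in fpkm_by_timepoint.columns if c != ovule_stage]
    seed = (fpkm_by_timepoint[seed_stages] >= rules.exclusive_min).any(axis=1)
    ovule_excl = external_ok & ovule
    seed_excl = external_ok & seed
    label = np.where(ovule_excl, "ovule_exclusive",
                     np.where(seed_excl, "seed_exclusive", "none"))
    return pd.DataFrame(
        {"ovule_exclusive": ovule_excl, "seed_exclusive": seed_excl, "label": label},
        index=fpkm_by_timepoint.index,
    )
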