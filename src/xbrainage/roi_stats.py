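"""ROI-level statistics: atlas parcellation, per-region ANCOVA, and
Benjamini-Hochberg FDR correction.

Stage 1 of the map comparison: each map (morphometric channel or
sensitivity map) is reduced to per-region means via the atlas, and every
region is tested with an ANCOVA using the clinical condition as the
group and age as a covariate.  P-values are FDR-corrected *across
regions, separately per factor and per map type/modality* — the family
is one (map_type x modality x factor) combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._glm import ancova
from .io import as_array

__all__ = [
    "ROIMatrix",
    "parcellate",
    "build_roi_matrix",
    "roi_ancova",
    "fdr_correct",
    "percent_significant",
]


@dataclass
class ROIMatrix:
    """Subjects x regions matrix of ROI means for one map type."""

    values: pd.DataFrame          # index participant_id, columns region labels
    map_type: str = "morphometric"   # or "sensitivity"
    modality: str = "chan-0"

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("ROI matrix has missing cells")
        if self.map_type not in ("morphometric", "sensitivity"):
            raise ValueError(f"unknown map_type {self.map_type!r}")


def parcellate(volume, atlas, labels=None) -> pd.Series:
    """Mean map value per atlas region (background label 0 excluded).

    ``labels`` optionally fixes the region list; any listed region with
    no voxels raises (silent empty regions would corrupt downstream
    significance-set denominators).
    """
    vol = np.asarray(as_array(volume), dtype=float)
    lab = as_array(atlas)
    if vol.shape != lab.shape:
        raise ValueError(f"volume grid {vol.shape} != atlas grid {lab.shape}")
    lab = lab.astype(np.int64).ravel()
    counts = np.bincount(lab)
    sums = np.bincount(lab, weights=vol.ravel())
    if labels is None:
        labels = np.nonzero(counts)[0]
        labels = labels[labels > 0]
    else:
        labels = np.asarray(labels, dtype=np.int64)
        empty = [int(l) for l in labels if l >= len(counts) or counts[l] == 0]
        if empty:
            raise ValueError(f"empty atlas regions: {empty}")
    means = sums[labels] / counts[labels]
    return pd.Series(means, index=pd.Index(labels, name="region"))


def build_roi_matrix(volumes: dict[str, np.ndarray], atlas,
                     labels=None, map_type: str = "morphometric",
                     modality: str = "chan-0") -> ROIMatrix:
    """Parcellate one 3-D map per subject into a subjects x regions matrix."""
    rows = {sid: parcellate(vol, atlas, labels=labels)
            for sid, vol in volumes.items()}
    values = pd.DataFrame(rows).T
    values.index.name = "participant_id"
    return ROIMatrix(values=values, map_type=map_type, modality=modality)


def fdr_correct(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (q, significant) with q >= p elementwise and significance
    defined as q < alpha.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def roi_ancova(matrix: ROIMatrix, cohort: pd.DataFrame,
               covariates=("age",), alpha: float = 0.05) -> pd.DataFrame:
    """Per-region ANCOVA with FDR across regions, one family per factor.

    Returns one row per (region, factor):
    ``region, factor, SS, df, F, p, np2, q, significant``.
    """
    ids = matrix.values.index.to_numpy()
    cohort = cohort.set_index("participant_id") if "participant_id" in cohort.columns else cohort
    missing = [sid for sid in ids if sid not in cohort.index]
    if missing:
        raise ValueError(f"cohort rows missing for subjects: {missing}")
    demo = cohort.loc[ids]

    cov = {name: demo[name].to_numpy() for name in covariates}
    res = ancova(matrix.values.to_numpy(), demo["group"].to_numpy(), cov)
    regions = matrix.values.columns.to_numpy()
    res.insert(0, "region", regions[res.pop("column").to_numpy()])

    res["q"] = np.nan
    res["significant"] = False
    for factor in res["factor"].unique():
        mask = res["factor"] == factor
        q, sig = fdr_correct(res.loc[mask, "p"].to_numpy(), alpha=alpha)
        res.loc[mask, "q"] = q
        res.loc[mask, "significant"] = sig
    res["map_type"] = matrix.map_type
    res["modality"] = matrix.modality
    return res


def percent_significant(significant) -> float:
    """Percentage of significant regions, to two decimals."""
    significant = np.asarray(significant, dtype=bool)
    if significant.size == 0:
        raise ValueError("empty significance vector")
    return round(100.0 * significant.mean(), 2)
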