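"""Voxelwise association of DVR with DTI metric volumes across subjects.

Each masked voxel carries one metric value per subject (FA, MD or RD
from pre-aligned volumes); the across-subject Pearson correlation with
the per-subject DVR yields r and p maps, a significance mask
(uncorrected or Benjamini-Hochberg FDR), per-atlas-region counts and
percentages of significant voxels, and per-subject metric means
restricted to the significant mask for group comparison.

No registration or skeletonisation happens here: volumes must arrive
aligned, and the choice of voxelwise correction is recorded in the
output provenance because conventions differ.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def voxel_corr_map(dvr, volumes, mask=None):
    """Per-voxel Pearson r and two-sided p of metric vs DVR across subjects.

    ``volumes`` has shape (n_subjects, ...); voxels with zero variance
    across subjects are excluded (NaN in both maps).  Returns
    ``(r_map, p_map)`` with the spatial shape of one volume.
    """
    dvr = np.asarray(dvr, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    n = dvr.size
    if volumes.shape[0] != n:
        raise ValueError(
            f"{volumes.shape[0]} volumes for {n} DVR values")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if dvr.std() == 0:
        raise ValueError("zero variance in DVR across subjects")
    shape = volumes.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    V = volumes[:, mask]                      # (n, n_vox)
    Vc = V - V.mean(axis=0)
    dc = dvr - dvr.mean()
    sv = np.sqrt((Vc**2).sum(axis=0))
    sd = np.sqrt((dc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Vc * dc[:, None]).sum(axis=0) / (sv * sd)
    r[sv == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    r_map = np.full(shape, np.nan)
    p_map = np.full(shape, np.nan)
    r_map[mask] = r
    p_map[mask] = p
    return r_map, p_map


def significant_mask(p_map, alpha: float = 0.05,
                     method: str = "uncorrected"):
    """Threshold a p map into a binary significance mask.

    ``method`` is "uncorrected" (p < alpha per voxel) or "bh_fdr"
    (Benjamini-Hochberg across all finite voxels).  Returns
    ``(mask, provenance)``; keep the provenance with any downstream
    result, since the correction choice changes what 'significant'
    means.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p_map = np.asarray(p_map, dtype=float)
    finite = np.isfinite(p_map)
    if not finite.any():
        raise ValueError("empty p map: no finite p-values")
    mask = np.zeros(p_map.shape, dtype=bool)
    if method == "uncorrected":
        mask[finite] = p_map[finite] < alpha
    elif method == "bh_fdr":
        rej, *_ = multipletests(p_map[finite], alpha=alpha, method="fdr_bh")
        mask[finite] = rej
    else:
        raise ValueError(f"unknown method {method!r}; use 'uncorrected' "
                         "or 'bh_fdr'")
    provenance = {"alpha": alpha, "method": method,
                  "n_tested": int(finite.sum()),
                  "n_significant": int(mask.sum())}
    return mask, provenance


def region_table(mask, labels, region_names, highlight_pct: float = 30.0
                 ) -> pd.DataFrame:
    """Per-region significant-voxel counts and percentages, plus totals.

    ``region_names`` maps integer label -> name.  Regions whose
    percentage exceeds ``highlight_pct`` are flagged (the convention for
    calling out heavily affected regions).  A final "Whole mask" row
    counts over all labelled voxels.  A label present in the volume but
    absent from ``region_names`` is an error.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.asarray(labels)
    if mask.shape != labels.shape:
        raise ValueError("mask and label volume shapes differ")
    present = set(np.unique(labels[labels > 0]).tolist())
    missing = present - set(region_names)
    if missing:
        raise ValueError(f"labels missing from region-name table: "
                         f"{sorted(missing)}")
    rows = []
    for code in sorted(region_names):
        region = labels == code
        size = int(region.sum())
        count = int((mask & region).sum())
        pct = 100.0 * count / size if size else 0.0
        rows.append({"region": region_names[code], "label": code,
                     "size": size, "significant": count, "pct": pct,
                     "highlight": pct > highlight_pct})
    total_size = int((labels > 0).sum())
    total_count = int((mask & (labels > 0)).sum())
    rows.append({"region": "Whole mask", "label": 0, "size": total_size,
                 "significant": total_count,
                 "pct": 100.0 * total_count / total_size if total_size else 0.0,
                 "highlight": False})
    return pd.DataFrame(rows).set_index("region")


def subject_mean_over_mask(volumes, mask) -> np.ndarray:
    """Mean metric per subject over the masked voxels.

    Feeds the group comparison restricted to significant voxels.
    """
    volumes = np.asarray(volumes, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volumes.shape[1:]:
        raise ValueError("mask shape does not match volume shape")
    if not mask.any():
        raise ValueError("empty mask")
    return volumes[:, mask].mean(axis=1)
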