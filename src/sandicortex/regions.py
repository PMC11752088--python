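"""Lesional, perilesional and normal-appearing cortical regions.

The perilesional layers are two concentric 2-mm-thick distance bands grown
from every cortical lesion by a Euclidean distance transform over voxel
centers: the inner layer covers distances (0, 2] mm from the lesion set and
the outer layer (2, 4] mm, both restricted to cortical gray matter;
normal-appearing cortex is the remaining cortex.  Regional summaries are
partial-volume-weighted means, as appropriate for maps estimated on a grid
coarser than the cortical ribbon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

__all__ = ["RegionMasks", "build_shells", "pv_weighted_mean", "regional_table",
           "REGION_ORDER"]

REGION_ORDER = ("lesion", "inner_layer", "outer_layer", "na_cortex", "cortex")


@dataclass
class RegionMasks:
    """Region masks on the analysis grid plus the weighting maps.

    ``lesion``, ``inner``, ``outer`` and ``na`` partition the cortex
    (``cortex`` = union); ``gm_pv`` is the cortical partial-volume map used
    as the aggregation weight.
    """

    lesion: np.ndarray
    inner: np.ndarray
    outer: np.ndarray
    na: np.ndarray
    cortex: np.ndarray
    gm_pv: np.ndarray
    voxel_mm: float
    lesion_pv: np.ndarray | None = None

    def region(self, name: str) -> np.ndarray:
        return {"lesion": self.lesion, "inner_layer": self.inner,
                "outer_layer": self.outer, "na_cortex": self.na,
                "cortex": self.cortex}[name]


def build_shells(lesion_mask: np.ndarray, gm_pv: np.ndarray,
                 voxel_mm: float, inner_mm: float = 2.0,
                 outer_mm: float = 4.0,
                 lesion_pv: np.ndarray | None = None) -> RegionMasks:
    """Construct the lesion/inner/outer/normal-appearing partition.

    Distances are Euclidean in mm between voxel centers.  Layer membership
    uses half-open bands (0, inner_mm] and (inner_mm, outer_mm]; shells of
    different lesions merge by union, so a voxel belongs to the band of its
    nearest lesion boundary.  An empty lesion mask yields empty layers and
    ``na == cortex`` (the healthy-control case).
    """
    lesion = np.asarray(lesion_mask, dtype=bool)
    gm_pv = np.asarray(gm_pv, dtype=float)
    if lesion.shape != gm_pv.shape:
        raise ValueError("lesion mask and GM partial-volume map differ in shape")
    if voxel_mm <= 0:
        raise ValueError("voxel size must be positive")
    cortex = gm_pv > 0
    if lesion.any():
        d = distance_transform_edt(~lesion, sampling=voxel_mm)
        inner = (d > 0) & (d <= inner_mm) & cortex
        outer = (d > inner_mm) & (d <= outer_mm) & cortex
    else:
        inner = np.zeros_like(lesion)
        outer = np.zeros_like(lesion)
    na = cortex & ~lesion & ~inner & ~outer
    return RegionMasks(lesion=lesion & cortex, inner=inner, outer=outer, na=na,
                       cortex=cortex, gm_pv=gm_pv, voxel_mm=float(voxel_mm),
                       lesion_pv=lesion_pv)


def pv_weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    """Partial-volume-weighted mean: sum(w * x) / sum(w)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights differ in length")
    if np.any(weights < 0):
        raise ValueError("negative weights")
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("all-zero weights")
    return float(np.sum(weights * values) / wsum)


TABLE_COLUMNS = ["subject_id", "group", "age", "sex", "region", "measure",
                 "mean", "n_vox", "sum_w", "valid", "ncv"]


def regional_table(maps, masks: RegionMasks, subject_meta: dict,
                   min_voxels: int = 3,
                   icv_ml: float | None = None,
                   measures=("f_is", "f_in", "f_ec", "r_s")) -> pd.DataFrame:
    """Partial-volume-weighted regional means of each measure.

    ``maps`` is a :class:`~sandicortex.dictfit.SANDIMaps` (or any mapping of
    measure name to 3D array plus ``valid``/``soma_defined`` masks).  Rows
    below ``min_voxels`` contributing voxels are flagged invalid.  For the
    lesion region the aggregation weight is the lesion partial volume when
    available (the tissue under analysis); other regions weight by the
    cortical GM partial volume.  ``ncv`` is the normalized cortical volume:
    total cortical partial volume times voxel volume over the intracranial
    volume.
    """
    valid_mask = getattr(maps, "valid", None)
    soma_mask = getattr(maps, "soma_defined", None)
    voxel_ml = masks.voxel_mm ** 3 / 1000.0
    cortex_ml = float(masks.gm_pv.sum()) * voxel_ml
    ncv = cortex_ml / icv_ml if icv_ml else np.nan
    rows = []
    for region in REGION_ORDER:
        rmask = masks.region(region)
        if region == "lesion" and masks.lesion_pv is not None:
            weights_map = masks.lesion_pv
        else:
            weights_map = masks.gm_pv
        for measure in measures:
            vol = maps[measure]
            if vol.shape != rmask.shape:
                raise ValueError("map and mask grids differ")
            sel = rmask & np.isfinite(vol)
            if valid_mask is not None:
                sel = sel & valid_mask
            if measure == "r_s" and soma_mask is not None:
                sel = sel & soma_mask
            n_vox = int(sel.sum())
            w = weights_map[sel]
            ok = n_vox >= min_voxels and w.sum() > 0
            mean = pv_weighted_mean(vol[sel], w) if ok else np.nan
            rows.append({"subject_id": subject_meta.get("subject_id"),
                         "group": subject_meta.get("group"),
                         "age": subject_meta.get("age"),
                         "sex": subject_meta.get("sex"),
                         "region": region, "measure": measure,
                         "mean": mean, "n_vox": n_vox,
                         "sum_w": float(w.sum()), "valid": bool(ok),
                         "ncv": ncv})
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
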