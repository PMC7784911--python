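"""White-matter-lesion volumetry and ROI handling.

Lesion probability maps are binarised at a fixed threshold (default 0.3,
boundary-inclusive), lesion volume is voxel count times voxel volume and is
cube-root transformed for group statistics (raw volumes are strongly
positively skewed). Lesion voxels are removed from every other ROI before
regional parameter extraction, and regional means are taken over valid
(fitted) voxels only — missing voxels are excluded and reported, never
imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patlak import PKMaps

__all__ = [
    "LesionMap",
    "ROISet",
    "lesion_binarize",
    "wml_volume",
    "clean_rois",
    "regional_means",
]

logger = logging.getLogger(__name__)


@dataclass
class LesionMap:
    """Lesion probability field in [0, 1] (a pre-binarised mask is also valid)."""

    probability: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.probability = np.asarray(self.probability, dtype=float)
        p = self.probability
        if np.nanmin(p) < 0.0 or np.nanmax(p) > 1.0:
            raise ValueError("lesion probabilities must lie in [0, 1]")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive on all axes")


@dataclass
class ROISet:
    """Named boolean regions on a common grid."""

    masks: dict[str, np.ndarray]
    cleaned: bool = False
    removal_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"ROI masks are on different grids: {shapes}")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return next(iter(self.masks.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self) -> list[str]:
        return list(self.masks)


def lesion_binarize(lesion: LesionMap, threshold: float = 0.3) -> np.ndarray:
    """Binarise a lesion probability map: voxel included iff p >= threshold.

    The comparison is boundary-inclusive (a voxel exactly at the threshold is
    lesion).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return lesion.probability >= threshold


def wml_volume(mask: np.ndarray, voxel_size: tuple[float, float, float]) -> dict[str, float]:
    """Lesion volume (mm^3) and its cube root (mm) from a binary mask."""
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel_size must be positive on all axes")
    volume = float(np.count_nonzero(mask)) * float(np.prod(voxel_size))
    return {"volume": volume, "cube_root": volume ** (1.0 / 3.0)}


def clean_rois(rois: ROISet, wml_mask: np.ndarray) -> ROISet:
    """Remove lesion voxels from every non-WML ROI.

    The WML ROI itself is left untouched. Removal counts per ROI are recorded
    on the returned set; an ROI emptied entirely is retained (empty) with a
    logged warning.
    """
    wml_mask = np.asarray(wml_mask, dtype=bool)
    if wml_mask.shape != rois.grid_shape:
        raise ValueError(
            f"grid mismatch: ROIs {rois.grid_shape} vs WML mask {wml_mask.shape}"
        )
    cleaned: dict[str, np.ndarray] = {}
    removed: dict[str, int] = {}
    for name, mask in rois.masks.items():
        if name == "WML":
            cleaned[name] = mask.copy()
            removed[name] = 0
            continue
        new = mask & ~wml_mask
        removed[name] = int(mask.sum() - new.sum())
        if mask.any() and not new.any():
            logger.warning("ROI %r emptied entirely by lesion exclusion", name)
        cleaned[name] = new
    return ROISet(masks=cleaned, cleaned=True, removal_counts=removed)


def regional_means(maps: PKMaps, rois: ROISet) -> pd.DataFrame:
    """Per-region mean Ktrans and vp over valid (fitted) voxels.

    Returns a long-format table (region, metric, value, n_voxels). Regions
    with zero valid voxels get NaN and a logged warning.
    """
    if rois.grid_shape != maps.ktrans.shape:
        raise ValueError(
            f"grid mismatch: PK maps {maps.ktrans.shape} vs ROIs {rois.grid_shape}"
        )
    rows = []
    for name, mask in rois.masks.items():
        for metric, vol in (("ktrans", maps.ktrans), ("vp", maps.vp)):
            vals = vol[mask]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                logger.warning("region %r has no valid voxels for %s", name, metric)
                rows.append((name, metric, np.nan, 0))
            else:
                rows.append((name, metric, float(vals.mean()), int(vals.size)))
    return pd.DataFrame(rows, columns=["region", "metric", "value", "n_voxels"])
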