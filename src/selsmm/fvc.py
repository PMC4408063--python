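"""Fractional vegetation cover products.

FVC of a pixel is the summed abundance of all vegetation-class endmembers.
Maps are classified into six categories — five equal-width cover bins
(0.0-0.2, 0.2-0.4, 0.4-0.6, 0.6-0.8, 0.8-1.0, left-closed/right-open with
the top bin closed) plus "non-vegetation" for pixels whose vegetation
abundance is (numerically) zero or whose selected endmember set excludes
vegetation entirely — and summarized as area-proportion tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SpectralLibrary
from .lsmm import AbundanceMap

__all__ = ["CATEGORIES", "FvcMap", "fvc_from_abundance", "classify_fvc",
           "area_proportions"]

#: Category codes in order: five cover bins, non-vegetation, nodata.
CATEGORIES = ("c02", "c24", "c46", "c68", "c81", "non_vegetation", "nodata")
_BIN_EDGES = (0.2, 0.4, 0.6, 0.8)
_CODE_NONVEG = 5
_CODE_NODATA = 6
_UNCLASSIFIED = -1
_ZERO_EPS = 1e-6


@dataclass
class FvcMap:
    """Per-pixel fractional vegetation cover and its category.

    ``fvc`` is NaN on nodata pixels.  ``category`` holds indices into
    CATEGORIES, or -1 where classification has not been applied yet.
    """

    fvc: np.ndarray
    category: np.ndarray
    mask: np.ndarray
    geotransform: tuple | None = None

    def __post_init__(self) -> None:
        if self.fvc.shape != self.mask.shape or self.category.shape != self.fvc.shape:
            raise ValueError("fvc, category and mask shapes must agree")

    def category_labels(self) -> np.ndarray:
        """Category as strings ('unclassified' where -1)."""
        lut = np.array(list(CATEGORIES) + ["unclassified"])
        return lut[self.category]


def fvc_from_abundance(abund: AbundanceMap, library: SpectralLibrary,
                       nv_threshold: float = 0.0) -> FvcMap:
    """Sum vegetation-class abundances into an FVC map.

    Pixels where no vegetation endmember was selected, or where the summed
    vegetation abundance does not exceed ``nv_threshold`` (within numerical
    tolerance), are pre-flagged non-vegetation.  Categories other than
    non-vegetation/nodata are left unassigned until classify_fvc.
    """
    veg_idx = library.class_indices("vegetation")
    if veg_idx.size == 0:
        raise ValueError("library has no vegetation-class endmember")
    if abund.n_endmembers != library.n_endmembers:
        raise ValueError("abundance map and library endmember counts differ")

    fvc = np.nansum(abund.fractions[:, :, veg_idx], axis=2)
    fvc = np.where(abund.mask, np.nan, fvc)
    veg_selected = abund.selected_mask[:, :, veg_idx].any(axis=2)

    category = np.full(fvc.shape, _UNCLASSIFIED, dtype=np.int8)
    category[abund.mask] = _CODE_NODATA
    nonveg = (~abund.mask) & (~veg_selected | (fvc <= nv_threshold + _ZERO_EPS))
    category[nonveg] = _CODE_NONVEG
    return FvcMap(fvc=fvc, category=category, mask=abund.mask.copy(),
                  geotransform=abund.geotransform)


def classify_fvc(fvc_map: FvcMap) -> FvcMap:
    """Assign the six-category classification on top of the FVC values.

    Bins are [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1.0]; an
    existing non-vegetation flag overrides binning.  Idempotent.
    """
    fvc = fvc_map.fvc
    valid = ~fvc_map.mask
    vals = fvc[valid]
    if np.any(vals < -_ZERO_EPS) or np.any(vals > 1.0 + _ZERO_EPS):
        raise ValueError("FVC values outside [0, 1]")
    binned = np.digitize(np.clip(fvc, 0.0, 1.0), _BIN_EDGES).astype(np.int8)
    category = fvc_map.category.copy()
    assign = valid & (category != _CODE_NONVEG)
    category[assign] = binned[assign]
    return FvcMap(fvc=fvc.copy(), category=category, mask=fvc_map.mask.copy(),
                  geotransform=fvc_map.geotransform)


def area_proportions(fvc_map: FvcMap) -> pd.DataFrame:
    """Pixel counts and area percents per category over unmasked pixels.

    Returns a DataFrame (category, pixels, percent); percents sum to 100.
    """
    valid = ~fvc_map.mask
    total = int(valid.sum())
    if total == 0:
        raise ValueError("all pixels are masked")
    cats = fvc_map.category[valid]
    if np.any(cats == _UNCLASSIFIED):
        raise ValueError("map not classified yet; run classify_fvc first")
    rows = []
    for code, name in enumerate(CATEGORIES[:-1]):   # nodata excluded
        count = int((cats == code).sum())
        rows.append({"category": name, "pixels": count,
                     "percent": 100.0 * count / total})
    return pd.DataFrame(rows)
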