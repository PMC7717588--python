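"""Expand nuclear label masks into cell ROIs and apply the ROI size filter.

Cells are defined as nuclei dilated by a fixed physical distance (2 µm by
default), with contested pixels assigned to the nearest nucleus.  Outlier
ROIs are flagged (never deleted) when their area falls outside
mean ± k·SD of the cell-area distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import read_label_mask, write_label_mask


@dataclass
class NucleusSet:
    """Nuclear label raster (0 = background) with physical pixel size."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        if not np.issubdtype(np.asarray(self.labels).dtype, np.integer):
            raise ValueError("nucleus mask must be integer-typed")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("nucleus labels must be non-negative")

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def areas_um2(self) -> pd.Series:
        """Per-nucleus area in µm² (pixel count × pixel area)."""
        counts = np.bincount(self.labels.ravel())
        ids = self.ids
        return pd.Series(
            counts[ids] * self.pixel_size_um**2, index=ids, name="nucleus_area_um2"
        )


@dataclass
class CellMask:
    """Expanded-cell label raster plus per-cell bookkeeping.

    ``kept`` is None until :func:`filter_by_size` runs; afterwards it is a
    boolean Series indexed by cell id.  Every cell footprint is a superset
    of its nucleus and lies within ``expansion_distance_um`` of it.
    """

    labels: np.ndarray
    pixel_size_um: float
    expansion_distance_um: float
    nucleus_areas_um2: pd.Series = field(default=None)
    kept: pd.Series = field(default=None)

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def areas_um2(self) -> pd.Series:
        counts = np.bincount(self.labels.ravel())
        ids = self.ids
        return pd.Series(
            counts[ids] * self.pixel_size_um**2, index=ids, name="cell_area_um2"
        )

    def table(self) -> pd.DataFrame:
        """Per-cell CSV-ready table: id, nucleus area, cell area, kept flag."""
        df = pd.DataFrame({"cell_area_um2": self.areas_um2()})
        if self.nucleus_areas_um2 is not None:
            df.insert(0, "nucleus_area_um2", self.nucleus_areas_um2)
        df["kept"] = True if self.kept is None else self.kept
        df.index.name = "cell_id"
        return df

    def write(self, mask_path: str, table_path: str | None = None) -> None:
        write_label_mask(self.labels, mask_path)
        if table_path:
            self.table().to_csv(table_path)


def load_nuclei(mask_file: str, pixel_size_um: float) -> NucleusSet:
    """Read a nuclear label mask TIFF.  An empty mask is valid but warned about."""
    labels = read_label_mask(mask_file)
    nuclei = NucleusSet(labels, pixel_size_um)
    if len(nuclei.ids) == 0:
        warnings.warn(f"nucleus mask {mask_file} contains no labels", stacklevel=2)
    return nuclei


def expand_nuclei(nuclei: NucleusSet, distance_um: float = 2.0) -> CellMask:
    """Expand each nucleus by ``distance_um`` into the nearest-nucleus partition.

    Every background pixel within ``distance_um`` (Euclidean, to the nucleus
    region, not its centroid) of at least one nucleus is assigned to the
    nearest one; exact distance ties go to the lower label id.  Nucleus
    pixels keep their label, so the result partitions nucleus ∪ halo.
    """
    if distance_um < 0:
        raise ValueError("distance_um must be >= 0")
    labels = nuclei.labels
    r_px = distance_um / nuclei.pixel_size_um
    out = labels.astype(np.int32).copy()
    if distance_um == 0 or len(nuclei.ids) == 0:
        return CellMask(
            out, nuclei.pixel_size_um, distance_um, nucleus_areas_um2=nuclei.areas_um2()
        )

    pad = int(np.ceil(r_px)) + 1
    best = np.full(labels.shape, np.inf, dtype=np.float64)
    best[labels > 0] = 0.0
    objects = ndi.find_objects(labels)
    # per-label EDT on an inflated bounding box; ascending label order plus a
    # strict < comparison makes equidistant ties resolve to the lower id
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        ys = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, labels.shape[0]))
        xs = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, labels.shape[1]))
        crop = labels[ys, xs]
        d = ndi.distance_transform_edt(crop != lab)
        claim = (crop == 0) & (d <= r_px) & (d < best[ys, xs])
        out_crop = out[ys, xs]
        out_crop[claim] = lab
        best_crop = best[ys, xs]
        best_crop[claim] = d[claim]
    return CellMask(
        out, nuclei.pixel_size_um, distance_um, nucleus_areas_um2=nuclei.areas_um2()
    )


def filter_by_size(cells: CellMask, k_sd: float = 2.0) -> CellMask:
    """Flag cells whose area lies outside mean ± k_sd·SD (population SD).

    Flags only — labels are untouched, so provenance survives.  With zero
    spread every cell sits at the mean and none is rejected.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    areas = cells.areas_um2()
    if len(areas) == 0:
        raise ValueError("size filter needs at least one cell")
    mean, sd = areas.mean(), areas.std(ddof=0)
    kept = (areas >= mean - k_sd * sd) & (areas <= mean + k_sd * sd)
    return CellMask(
        cells.labels,
        cells.pixel_size_um,
        cells.expansion_distance_um,
        nucleus_areas_um2=cells.nucleus_areas_um2,
        kept=kept.rename("kept"),
    )


def apply_exclusion_list(cells: CellMask, exclude_ids) -> CellMask:
    """Flag manually curated cell ids as rejected (visual-inspection removals)."""
    kept = (
        cells.kept.copy()
        if cells.kept is not None
        else pd.Series(True, index=cells.ids)
    )
    kept[kept.index.isin(list(exclude_ids))] = False
    return CellMask(
        cells.labels,
        cells.pixel_size_um,
        cells.expansion_distance_um,
        nucleus_areas_um2=cells.nucleus_areas_um2,
        kept=kept,
    )
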