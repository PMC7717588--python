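"""RCA-dot detection, per-cell intensity measurement, and the counts matrix.

Each rolling-circle product images as a diffraction-limited, roughly
Gaussian dot (apparent half-maximum footprint around 0.55 µm²).  Dots are
detected per (cycle, channel) image with a multi-scale Laplacian of
Gaussian, sized by their half-maximum support, gated by area to reject
larger/dimmer autofluorescent clutter, and assigned to the cell ROI under
their centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import blob_log

from .io import ImageStack
from .panel import GenePanel
from .segmentation import CellMask

DOT_COLUMNS = [
    "gene", "cycle", "channel", "y_px", "x_px", "y_um", "x_um",
    "area_um2", "peak_intensity", "integrated_intensity", "cell_id",
]

#: default dot-area gates in µm², bracketing the measured 0.55–0.57 µm²
#: apparent dot footprints.
DEFAULT_MIN_AREA_UM2 = 0.1
DEFAULT_MAX_AREA_UM2 = 2.0


def empty_dot_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        DOT_COLUMNS,
        [str, int, int, float, float, float, float, float, float, float, int],
    )})


def detect_dots(
    image: np.ndarray,
    pixel_size_um: float,
    peak_threshold: float,
    sigma_range_um: tuple[float, float] = (0.2, 0.6),
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    max_area_um2: float = DEFAULT_MAX_AREA_UM2,
    background: float | None = None,
    gene: str = "",
    cycle: int = 0,
    channel: int = 1,
) -> pd.DataFrame:
    """Detect dots in one channel image.

    ``peak_threshold`` is the minimum peak height above background (image
    median unless given).  Candidate blobs come from a scale-normalized
    LoG over ``sigma_range_um``; each keeps the connected half-maximum
    support around its centre, whose pixel count gives the dot area.
    Dots outside [min_area_um2, max_area_um2] are rejected (clutter gate).
    Centroids are intensity-weighted over the support, reported in px and µm.
    """
    if peak_threshold <= 0:
        raise ValueError("peak_threshold must be positive")
    if min_area_um2 <= 0 or max_area_um2 <= min_area_um2:
        raise ValueError("need 0 < min_area_um2 < max_area_um2")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("detect_dots expects a single-channel 2D image")
    if background is None:
        background = float(np.median(image))
    signal = np.clip(image - background, 0, None)
    if signal.max() <= peak_threshold:
        return empty_dot_table()

    smin, smax = (s / pixel_size_um for s in sigma_range_um)
    blobs = blob_log(
        signal, min_sigma=smin, max_sigma=smax, num_sigma=5,
        threshold=peak_threshold / 8.0, overlap=0.5,
    )
    px_area = pixel_size_um**2

    # keep candidates whose raw peak clears the threshold, then collapse
    # multi-scale duplicates of the same dot (brightest wins)
    cand = []
    for by, bx, bs in blobs:
        iy, ix = int(round(by)), int(round(bx))
        peak = signal[iy, ix]
        if peak > peak_threshold:
            cand.append((iy, ix, bs, peak))
    cand = _dedup_candidates(cand, radius_px=max(1.5, smin * 2))
    centers = np.array([(c[0], c[1]) for c in cand]) if cand else np.empty((0, 2))

    rows = []
    for iy, ix, bs, peak in cand:
        # half-maximum support connected to the peak, on a local crop;
        # when several detected peaks share one support (dots crowded
        # inside a cell) the support area is split among them, so the
        # area gate rejects single-peak clutter blobs but not clumps
        r = int(np.ceil(4 * bs)) + 2
        y0, y1 = max(iy - r, 0), min(iy + r + 1, image.shape[0])
        x0, x1 = max(ix - r, 0), min(ix + r + 1, image.shape[1])
        crop = signal[y0:y1, x0:x1]
        support, _ = ndi.label(crop >= 0.5 * peak)
        lab = support[iy - y0, ix - x0]
        if lab == 0:
            continue
        mask = support == lab
        inside = (
            (centers[:, 0] >= y0) & (centers[:, 0] < y1)
            & (centers[:, 1] >= x0) & (centers[:, 1] < x1)
        )
        pts = centers[inside].astype(int)
        n_peaks = max(int(mask[pts[:, 0] - y0, pts[:, 1] - x0].sum()), 1)
        area = mask.sum() * px_area / n_peaks
        if not (min_area_um2 <= area <= max_area_um2):
            continue
        ww = crop * mask
        tot = ww.sum() / n_peaks
        yy, xx = np.mgrid[y0:y1, x0:x1]
        if n_peaks == 1:
            cy = float((ww * yy).sum() / (tot * n_peaks))
            cx = float((ww * xx).sum() / (tot * n_peaks))
        else:  # shared support: weighted centroid would mix neighbours
            cy, cx = float(iy), float(ix)
        rows.append(
            (gene, cycle, channel, cy, cx, cy * pixel_size_um, cx * pixel_size_um,
             float(area), float(peak), float(tot), 0)
        )
    if not rows:
        return empty_dot_table()
    return pd.DataFrame(rows, columns=DOT_COLUMNS).reset_index(drop=True)


def _dedup_candidates(cand: list[tuple], radius_px: float) -> list[tuple]:
    order = sorted(range(len(cand)), key=lambda i: -cand[i][3])
    keep: list[int] = []
    for i in order:
        iy, ix = cand[i][0], cand[i][1]
        if any((iy - cand[j][0]) ** 2 + (ix - cand[j][1]) ** 2 < radius_px**2
               for j in keep):
            continue
        keep.append(i)
    return [cand[i] for i in sorted(keep)]


def detect_all(
    stack: ImageStack,
    panel: GenePanel,
    peak_threshold: float | dict[str, float],
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`detect_dots` for every gene in the panel on an aligned stack.

    ``peak_threshold`` may be one number for all genes or a per-gene dict;
    the same thresholds should be used across conditions being compared.
    """
    tables = []
    for gene, (cy, ch) in panel.assignments.items():
        thr = peak_threshold[gene] if isinstance(peak_threshold, dict) else peak_threshold
        tables.append(
            detect_dots(
                stack.channel(cy, ch), stack.pixel_size_um, thr,
                gene=gene, cycle=cy, channel=ch, **kwargs,
            )
        )
    return pd.concat(tables, ignore_index=True)


@dataclass
class CountsMatrix:
    """Cells × genes integer dot counts plus per-cell auxiliary measures."""

    counts: pd.DataFrame  # index cell_id, columns genes
    unassigned: pd.Series  # per-gene dots whose centroid fell on background
    intensity: pd.DataFrame = field(default=None)  # per-cell RID per channel
    kept: pd.Series = field(default=None)  # size-filter flag from segmentation

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    def total_detected(self) -> pd.Series:
        return self.counts.sum(axis=0) + self.unassigned

    def write(self, path: str) -> None:
        out = self.counts.copy()
        if self.kept is not None:
            out["kept"] = self.kept
        out.to_csv(path)


def measure_roi_intensity(image: np.ndarray, cells: CellMask) -> pd.Series:
    """Raw integrated density per cell: plain pixel sum over the footprint,
    no background subtraction."""
    image = np.asarray(image)
    if image.shape != cells.labels.shape:
        raise ValueError(
            f"image shape {image.shape} != mask shape {cells.labels.shape}"
        )
    ids = cells.ids
    sums = ndi.sum_labels(image.astype(np.float64), cells.labels, index=ids)
    return pd.Series(sums, index=pd.Index(ids, name="cell_id"), name="rid")


def assign_dots_to_cells(
    dots: pd.DataFrame, cells: CellMask, genes: list[str] | None = None
) -> tuple[pd.DataFrame, CountsMatrix]:
    """Assign each dot to the cell label under its centroid pixel and tally.

    Dots over background stay unassigned (cell_id 0) and are reported per
    gene so that assigned + unassigned always equals detected.
    """
    dots = dots.copy()
    h, w = cells.labels.shape
    if len(dots):
        iy = np.clip(np.round(dots.y_px.to_numpy()).astype(int), 0, h - 1)
        ix = np.clip(np.round(dots.x_px.to_numpy()).astype(int), 0, w - 1)
        dots["cell_id"] = cells.labels[iy, ix]
    genes = genes if genes is not None else sorted(dots.gene.unique())
    ids = pd.Index(cells.ids, name="cell_id")
    counts = pd.DataFrame(0, index=ids, columns=genes, dtype=np.int64)
    unassigned = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=np.int64)
    if len(dots):
        tab = (
            dots.groupby(["cell_id", "gene"], sort=False).size().unstack(fill_value=0)
        )
        for g in tab.columns:
            if g not in counts.columns:
                raise ValueError(f"dot table contains gene {g!r} absent from panel")
        assigned = tab.reindex(index=ids, columns=genes, fill_value=0)
        counts += assigned.astype(np.int64)
        if 0 in tab.index:
            unassigned += tab.loc[0].reindex(genes, fill_value=0).astype(np.int64)
    kept = cells.kept if cells.kept is not None else None
    return dots, CountsMatrix(counts, unassigned, kept=kept)


def _zero_reference_ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    out = pd.Series(0.0, index=num.index)
    nz = den != 0
    out[nz] = num[nz] / den[nz]
    return out


def per_cell_ratio(
    counts: CountsMatrix, gene: str, reference_gene: str
) -> pd.Series:
    """Per-cell dots(gene)/dots(reference); cells with zero reference dots
    are assigned ratio 0 rather than NaN/inf."""
    for g in (gene, reference_gene):
        if g not in counts.counts.columns:
            raise KeyError(f"gene {g!r} not in counts matrix")
    return _zero_reference_ratio(
        counts.counts[gene].astype(float), counts.counts[reference_gene].astype(float)
    ).rename(f"{gene}/{reference_gene}")


def intensity_ratio(rid_gene: pd.Series, rid_reference: pd.Series) -> pd.Series:
    """Per-cell fluorescence ratio of raw integrated densities, with the
    same zero-reference convention as the dot-count ratio."""
    rid_gene, rid_reference = rid_gene.align(rid_reference, join="inner")
    return _zero_reference_ratio(rid_gene.astype(float), rid_reference.astype(float))
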