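"""Cycle-to-cycle rigid alignment on the nuclear channel.

Each hybridization cycle is re-imaged after stripping, so the field drifts
by a small translation.  The nuclear stain is present in every cycle and is
used to estimate that translation by normalized cross-correlation; the
estimate is then applied to all channels of the cycle.  Rotation and scale
are assumed negligible (slides on an automated stage), which is a
documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import match_template

from .io import ImageStack

#: cycles whose peak correlation falls below this are flagged for QC review
#: but still processed (fail-soft).
CONFIDENCE_FLAG_THRESHOLD = 0.3


@dataclass
class CycleOffsets:
    """Per-cycle translation (dy, dx) in px and alignment confidence in [0, 1]."""

    table: pd.DataFrame  # columns: cycle, dy, dx, confidence, flagged

    def offset(self, cycle: int) -> tuple[float, float]:
        row = self.table.loc[self.table.cycle == cycle].iloc[0]
        return (row.dy, row.dx)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def estimate_shift(
    reference: np.ndarray,
    moving: np.ndarray,
    max_shift_px: int,
    subpixel: bool = False,
) -> tuple[tuple[float, float], float]:
    """Estimate the translation of ``moving`` relative to ``reference``.

    Returns ``((dy, dx), confidence)`` where the offset maximizes the
    normalized cross-correlation over the ±``max_shift_px`` grid, i.e.
    ``moving[y, x] ≈ reference[y - dy, x - dx]``.  Confidence is the NCC
    peak value clipped to [0, 1]; an all-constant image yields offset
    (0, 0) with confidence 0 rather than an exception.

    With ``subpixel=True`` the integer peak is refined by a separable
    parabolic fit to the correlation surface.
    """
    reference = np.asarray(reference, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if reference.shape != moving.shape:
        raise ValueError(
            f"image shapes differ: {reference.shape} vs {moving.shape}"
        )
    if max_shift_px < 0:
        raise ValueError("max_shift_px must be >= 0")
    m = int(max_shift_px)
    if min(reference.shape) <= 2 * m:
        raise ValueError("max_shift_px too large for the image extent")
    if reference.std() == 0 or moving.std() == 0:
        return (0.0, 0.0), 0.0

    if m == 0:
        r = np.corrcoef(reference.ravel(), moving.ravel())[0, 1]
        return (0.0, 0.0), float(np.clip(r, 0.0, 1.0))

    # true NCC of the centre crop of `moving` against `reference` at every
    # candidate alignment (Lewis' fast normalized cross-correlation)
    template = moving[m:-m, m:-m]
    ncc = match_template(reference, template)  # (2m+1, 2m+1)
    i, j = np.unravel_index(np.argmax(ncc), ncc.shape)
    conf = float(np.clip(ncc[i, j], 0.0, 1.0))
    dy, dx = float(m - i), float(m - j)

    if subpixel:
        dy -= _parabolic_offset(ncc, i, j, axis=0)
        dx -= _parabolic_offset(ncc, i, j, axis=1)
    return (dy, dx), conf


def _parabolic_offset(ncc: np.ndarray, i: int, j: int, axis: int) -> float:
    """Sub-bin refinement of a correlation peak along one axis."""
    idx = i if axis == 0 else j
    if idx == 0 or idx == ncc.shape[axis] - 1:
        return 0.0
    take = (lambda k: ncc[k, j]) if axis == 0 else (lambda k: ncc[i, k])
    c0, c1, c2 = take(idx - 1), take(idx), take(idx + 1)
    denom = c0 - 2 * c1 + c2
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5))


def apply_shift(image: np.ndarray, offset: tuple[float, float]) -> np.ndarray:
    """Translate an image by ``offset`` = (dy, dx); vacated pixels become 0.

    Output pixel (y, x) equals input pixel (y - dy, x - dx).  Integer
    offsets are exact copies on the overlap region; fractional offsets use
    bilinear interpolation.
    """
    image = np.asarray(image)
    dy, dx = offset
    if abs(dy) > image.shape[0] or abs(dx) > image.shape[1]:
        raise ValueError("offset exceeds image extent")
    if float(dy).is_integer() and float(dx).is_integer():
        dy, dx = int(dy), int(dx)
        out = np.zeros_like(image)
        h, w = image.shape[-2:]
        ys_src = slice(max(0, -dy), min(h, h - dy))
        xs_src = slice(max(0, -dx), min(w, w - dx))
        ys_dst = slice(max(0, dy), min(h, h + dy))
        xs_dst = slice(max(0, dx), min(w, w + dx))
        out[..., ys_dst, xs_dst] = image[..., ys_src, xs_src]
        return out
    return ndi.shift(image.astype(np.float64), (dy, dx), order=1, cval=0.0)


def register_stack(
    stack: ImageStack,
    reference_cycle: int = 0,
    max_shift_px: int = 20,
    subpixel: bool = False,
) -> tuple[ImageStack, CycleOffsets]:
    """Align every cycle to ``reference_cycle`` using its nuclear channel.

    The shift estimated on the nuclear channel is inverted and applied to
    all channels of the cycle.  Low-confidence cycles are flagged in the
    returned offset table but still aligned.
    """
    for i, arr in enumerate(stack.cycles):
        if stack.nuclear_channel >= arr.shape[0]:
            raise ValueError(f"cycle {i} lacks nuclear channel {stack.nuclear_channel}")
    ref = stack.nuclear_image(reference_cycle)
    rows = []
    aligned = []
    for i, arr in enumerate(stack.cycles):
        if i == reference_cycle:
            off, conf = (0.0, 0.0), 1.0
        else:
            off, conf = estimate_shift(
                ref, stack.nuclear_image(i), max_shift_px, subpixel=subpixel
            )
        rows.append(
            {
                "cycle": i,
                "dy": off[0],
                "dx": off[1],
                "confidence": conf,
                "flagged": conf < CONFIDENCE_FLAG_THRESHOLD,
            }
        )
        if off == (0.0, 0.0):
            aligned.append(arr.copy())
        else:
            aligned.append(
                np.stack([apply_shift(ch, (-off[0], -off[1])) for ch in arr])
            )
    offsets = CycleOffsets(pd.DataFrame(rows))
    return (
        ImageStack(aligned, stack.pixel_size_um, stack.nuclear_channel),
        offsets,
    )
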