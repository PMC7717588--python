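"""Image-stack container and plain-file I/O (TIFF, CSV, YAML sidecars)."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml


@dataclass
class ImageStack:
    """Multi-cycle, multi-channel 2D image stack.

    Each element of ``cycles`` is a ``(n_channels, H, W)`` array for one
    hybridization cycle.  By convention channel 0 is the nuclear (DAPI)
    channel; signal channels start at 1.  ``pixel_size_um`` is the
    lateral pixel size in micrometres.
    """

    cycles: list[np.ndarray] = field(default_factory=list)
    pixel_size_um: float = 0.325
    nuclear_channel: int = 0

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cycles[0].shape[-2:]

    def nuclear_image(self, cycle: int) -> np.ndarray:
        return self.cycles[cycle][self.nuclear_channel]

    def channel(self, cycle: int, channel: int) -> np.ndarray:
        return self.cycles[cycle][channel]

    def copy(self) -> "ImageStack":
        return ImageStack(
            [c.copy() for c in self.cycles], self.pixel_size_um, self.nuclear_channel
        )


def write_stack(stack: ImageStack, out_dir: str, prefix: str = "cycle") -> list[str]:
    """Write one multi-page TIFF per cycle (pages = channels) plus a YAML sidecar.

    Pixel values are rounded and stored as uint16; the sidecar records the
    pixel size and channel convention.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, arr in enumerate(stack.cycles):
        path = os.path.join(out_dir, f"{prefix}{i:02d}.tif")
        data = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack")
        paths.append(path)
    sidecar = {
        "pixel_size_um": float(stack.pixel_size_um),
        "nuclear_channel": int(stack.nuclear_channel),
        "n_cycles": stack.n_cycles,
        "files": [os.path.basename(p) for p in paths],
    }
    with open(os.path.join(out_dir, f"{prefix}_meta.yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return paths


def read_stack(
    paths: list[str], pixel_size_um: float, nuclear_channel: int = 0
) -> ImageStack:
    """Read per-cycle multi-page TIFFs into an :class:`ImageStack`."""
    cycles = []
    for p in paths:
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        cycles.append(arr.astype(np.float32))
    return ImageStack(cycles, pixel_size_um, nuclear_channel)


def write_label_mask(labels: np.ndarray, path: str) -> None:
    if labels.max() > 65535:
        raise ValueError("more than 65535 labels do not fit a 16-bit mask")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_label_mask(path: str) -> np.ndarray:
    arr = tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label mask {path} is not integer-typed ({arr.dtype})")
    return arr.astype(np.int32)
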