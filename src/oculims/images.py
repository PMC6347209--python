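"""Ion images: TIC normalization, narrow-window extraction, display thresholding.

The extraction model follows narrow-window centroid imaging: an ion image is
the per-pixel *sum* of centroid intensities whose m/z lies inside a mass
window (default full width 0.0009 Da), optionally divided by that pixel's
total ion current (TIC).  Pixels with zero TIC yield a normalized value of 0
and are flagged rather than raising — off-tissue matrix pixels are expected.

The "full-intensity threshold" display operation reproduces the contrast
control of MSI viewers: values are clipped at the threshold and rescaled to
[0, 1], so lowering the threshold brightens weak (e.g. posterior) signal
without altering the underlying data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Set, Tuple

import numpy as np

from .imzml import Coord, MSIDataset
from .masses import MassWindow

__all__ = [
    "TICMap",
    "IonImage",
    "compute_tic",
    "extract_ion_image",
    "apply_intensity_threshold",
    "image_to_array",
    "write_image_tsv",
    "write_image_png",
]

logger = logging.getLogger(__name__)

TICMap = Dict[Coord, float]


@dataclass
class IonImage:
    """Per-pixel scalar map of (optionally TIC-normalized) intensity for one
    mass window."""

    window: MassWindow
    values: Dict[Coord, float]
    normalized: bool = False
    pitch_um: float = 100.0
    zero_tic_pixels: Set[Coord] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.values)

    def max(self) -> float:
        return max(self.values.values()) if self.values else 0.0


def compute_tic(
    dataset: MSIDataset, mz_range: Optional[Tuple[float, float]] = None
) -> TICMap:
    """Total ion current per pixel: sum of intensities with m/z inside
    ``mz_range`` (default: the dataset's full acquisition range)."""
    lo, hi = mz_range if mz_range is not None else dataset.mz_range
    tic: TICMap = {}
    for coord, spec in dataset.spectra.items():
        if len(spec) == 0:
            tic[coord] = 0.0
            continue
        mz = spec.mz
        if float(mz[0]) >= lo and float(mz[-1]) <= hi:
            tic[coord] = float(spec.intensity.sum(dtype=np.float64))
        else:
            i = int(np.searchsorted(mz, lo, side="left"))
            j = int(np.searchsorted(mz, hi, side="right"))
            tic[coord] = float(spec.intensity[i:j].sum(dtype=np.float64))
    return tic


def extract_ion_image(
    dataset: MSIDataset,
    window: MassWindow,
    tic: Optional[TICMap] = None,
) -> IonImage:
    """Extract a narrow-window ion image; normalize per pixel if ``tic`` given.

    A peak belongs to the window iff ``|mz - center| <= full_width/2``.
    Pixels with TIC 0 get a normalized value of 0 and are recorded in
    ``zero_tic_pixels``.
    """
    lo_r, hi_r = dataset.mz_range
    if not (lo_r <= window.center_mz <= hi_r):
        raise ValueError(
            f"window center {window.center_mz} outside dataset mass range "
            f"[{lo_r}, {hi_r}]"
        )
    lo, hi = window.bounds
    values: Dict[Coord, float] = {}
    zero_tic: Set[Coord] = set()
    for coord, spec in dataset.spectra.items():
        mz = spec.mz
        i = int(np.searchsorted(mz, lo, side="left"))
        j = int(np.searchsorted(mz, hi, side="right"))
        v = float(spec.intensity[i:j].sum(dtype=np.float64)) if j > i else 0.0
        if tic is not None:
            t = tic.get(coord, 0.0)
            if t > 0:
                v = v / t
            else:
                v = 0.0
                zero_tic.add(coord)
        values[coord] = v
    if zero_tic:
        logger.warning(
            "%d pixel(s) with zero TIC set to 0 in normalized ion image", len(zero_tic)
        )
    return IonImage(
        window=window,
        values=values,
        normalized=tic is not None,
        pitch_um=dataset.pitch_um,
        zero_tic_pixels=zero_tic,
    )


def apply_intensity_threshold(
    image: IonImage, full_intensity_at: float, relative: bool = False
) -> IonImage:
    """Clip at the full-intensity threshold and rescale to [0, 1] for display.

    ``full_intensity_at`` is an absolute value, or a fraction of the image
    maximum when ``relative=True``.  Values at or above the threshold display
    as 1; the mapping is monotone below it, so lowering the threshold never
    decreases any displayed value.
    """
    if full_intensity_at <= 0:
        raise ValueError("full-intensity threshold must be positive")
    threshold = full_intensity_at * image.max() if relative else full_intensity_at
    if threshold <= 0:
        raise ValueError("resolved threshold is not positive (empty image?)")
    scaled = {
        coord: min(v, threshold) / threshold for coord, v in image.values.items()
    }
    return IonImage(
        window=image.window,
        values=scaled,
        normalized=image.normalized,
        pitch_um=image.pitch_um,
        zero_tic_pixels=set(image.zero_tic_pixels),
    )


def image_to_array(image: IonImage, fill: float = np.nan) -> np.ndarray:
    """Render the pixel map as a (ny, nx) array; absent pixels get ``fill``."""
    if not image.values:
        return np.zeros((0, 0))
    nx = max(c[0] for c in image.values)
    ny = max(c[1] for c in image.values)
    arr = np.full((ny, nx), fill, dtype=np.float64)
    for (x, y), v in image.values.items():
        arr[y - 1, x - 1] = v
    return arr


def write_image_tsv(image: IonImage, path: str) -> None:
    """Export as a three-column TSV: x, y (1-based pixel indices), value."""
    with open(path, "w") as fh:
        fh.write("x\ty\tvalue\n")
        for (x, y) in sorted(image.values, key=lambda c: (c[1], c[0])):
            fh.write(f"{x}\t{y}\t{image.values[(x, y)]:.8g}\n")


def write_image_png(image: IonImage, path: str) -> None:
    """Export as 16-bit grayscale PNG, scaled so the image maximum maps to 65535."""
    import imageio.v3 as iio

    arr = image_to_array(image, fill=0.0)
    top = float(arr.max())
    scale = 65535.0 / top if top > 0 else 0.0
    iio.imwrite(path, (arr * scale).astype(np.uint16))
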