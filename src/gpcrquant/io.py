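"""File formats, configuration and domain containers.

Images are single-plane grayscale TIFF (16-bit unsigned on disk; signed
floating point in memory once a background estimate has been subtracted).
Label masks are integer-valued PNG or TIFF images in which 0 is background
and every positive value k labels the pixels of cell k. All tabular input
and output is UTF-8 CSV with a header row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

logger = logging.getLogger("gpcrquant")


class FormatError(ValueError):
    """Raised when an input file is not in the expected format."""


@dataclass
class FluorImage:
    """A single-channel fluorescence image.

    ``pixels`` holds intensity counts in arbitrary units; unsigned 16-bit
    when freshly read from disk, signed float after background subtraction
    (negative values are retained, not clipped).
    """

    pixels: np.ndarray
    channel: str = ""
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(
                f"expected a 2-D single-plane image, got shape {self.pixels.shape}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabelMask:
    """Integer cell-label image: 0 = background, k > 0 = cell k.

    Labels need not be consecutive; every positive label owns at least
    one pixel.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError(f"label mask must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(
                f"label mask must have an integer pixel type, got {self.labels.dtype}"
            )
        if self.labels.min() < 0:
            raise FormatError("label mask contains negative labels")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    def check_shape(self, image: FluorImage) -> None:
        if self.labels.shape != image.pixels.shape:
            raise FormatError(
                f"mask shape {self.labels.shape} does not match image shape "
                f"{image.pixels.shape}"
            )


@dataclass(frozen=True)
class RunConfig:
    """Fixed numeric settings of the quantification pipeline.

    Defaults reproduce the published analysis: 1-px diamond erosion to
    separate touching cells, removal of connected components below 5000 px,
    a 7-px peripheral ring, sigma-50 Gaussian pseudo-flat-field subtraction,
    radius-50 rolling-ball subtraction for confocal channels, alpha 0.05
    for Tukey comparisons and B = 1000 bootstrap resamples.
    """

    erosion_radius_separate: int = 1
    erosion_radius_ring: int = 7
    min_component_px: int = 5000
    flatfield_sigma: float = 50.0
    rollingball_radius: float = 50.0
    tukey_alpha: float = 0.05
    bootstrap_B: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.erosion_radius_separate < 1 or self.erosion_radius_ring < 1:
            raise ValueError("erosion radii must be >= 1 px")
        if self.flatfield_sigma <= 0 or self.rollingball_radius <= 0:
            raise ValueError("flat-field sigma and rolling-ball radius must be > 0")
        if not 0 < self.tukey_alpha < 1:
            raise ValueError("tukey_alpha must lie in (0, 1)")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load settings from a YAML or JSON mapping; unknown keys error."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise FormatError(f"config {path} must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


def _read_plane(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        raise FormatError(f"{path}: multi-channel (RGB/RGBA) input, expected grayscale")
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single 2-D plane, got shape {arr.shape}")
    return arr


def read_image(path: str | Path, channel: str = "") -> FluorImage:
    """Read a single-plane grayscale TIFF or PNG, preserving values bit-exactly."""
    arr = _read_plane(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: expected integer pixel type, got {arr.dtype}")
    return FluorImage(pixels=arr, channel=channel)


def write_image(img: FluorImage, path: str | Path) -> None:
    """Write a FluorImage as 16-bit TIFF (integer data) or float TIFF."""
    path = Path(path)
    px = img.pixels
    if np.issubdtype(px.dtype, np.integer):
        if px.min() < 0 or px.max() > 65535:
            raise FormatError("integer image out of the 16-bit range [0, 65535]")
        tifffile.imwrite(path, px.astype(np.uint16))
    else:
        tifffile.imwrite(path, px.astype(np.float32))


def read_label_mask(path: str | Path) -> LabelMask:
    """Read an integer label mask from PNG or TIFF; floats are rejected."""
    arr = _read_plane(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: label mask has floating-point type {arr.dtype}")
    mask = LabelMask(labels=arr.astype(np.int32))
    if mask.n_cells == 0:
        logger.warning("%s: label mask contains no cells", path)
    else:
        logger.info("%s: %d labeled cells", path, mask.n_cells)
    return mask


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    path = Path(path)
    labels = mask.labels
    if labels.max() > 65535:
        raise FormatError("more than 65535 labels cannot be stored as 16-bit")
    out = labels.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
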