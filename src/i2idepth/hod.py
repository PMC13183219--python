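"""Histogram-of-Depth (HoD) descriptor for depth frames.

The descriptor of one frame is built in four steps:

1. resize the raw depth image to ``target_size`` x ``target_size`` (bilinear)
   and min-max normalise to [0, 1];
2. compute image gradients gx, gy (central differences in the interior,
   one-sided at borders), hence per-pixel magnitude and four-quadrant
   direction in degrees;
3. split the image into a grid of ``cell_size`` x ``cell_size`` cells and, per
   cell, accumulate gradient magnitudes into ``n_bins`` direction bins
   spanning [-180, 180] degrees — no bin interpolation, no block
   normalisation;
4. append four intensity statistics of the normalised image: mean, standard
   deviation (N-1 denominator), minimum, maximum.

Under the defaults (224 px target, 16 px cells, 9 bins) the combined vector
has (224/16)^2 * 9 + 4 = 1768 entries.

Coordinate convention (fixed, because bin assignment depends on it): x is the
column index increasing rightward, y the row index increasing downward;
direction = atan2(gy, gx), so an intensity ramp that increases downward has
direction +90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .depth_io import ActionSample, DepthFrame

__all__ = [
    "HoDConfig",
    "GradientField",
    "preprocess",
    "gradients",
    "cell_histograms",
    "intensity_stats",
    "extract_hod",
    "extract_sequence",
]


@dataclass(frozen=True)
class HoDConfig:
    target_size: int = 224
    cell_size: int = 16
    n_bins: int = 9
    angle_min: float = -180.0
    angle_max: float = 180.0
    #: "minmax" (per-image min-max, guarantees the [0,1] range) or "bitdepth"
    #: (divide by 2^bit_depth - 1).
    normalization: str = "minmax"
    #: "central" finite differences or "sobel".
    gradient_op: str = "central"
    #: standard-deviation denominator: N-1 ("sample") or N ("population").
    std_denominator: str = "sample"

    def __post_init__(self) -> None:
        if self.target_size % self.cell_size != 0:
            raise ValueError(
                f"target_size {self.target_size} not divisible by cell_size {self.cell_size}"
            )
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not self.angle_min < self.angle_max:
            raise ValueError("need angle_min < angle_max")

    @property
    def n_cells(self) -> int:
        return (self.target_size // self.cell_size) ** 2

    @property
    def n_features(self) -> int:
        """Combined descriptor length: cell histograms + 4 intensity stats."""
        return self.n_cells * self.n_bins + 4


@dataclass(frozen=True)
class GradientField:
    gx: np.ndarray
    gy: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.gx, self.gy)

    @property
    def direction(self) -> np.ndarray:
        """Four-quadrant angle of (gx, gy) in degrees, in [-180, 180]."""
        return np.degrees(np.arctan2(self.gy, self.gx))


def _resize_bilinear(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resample to (size, size), no anti-aliasing, corner-aligned."""
    h, w = img.shape
    rows = np.linspace(0.0, h - 1.0, size)
    cols = np.linspace(0.0, w - 1.0, size)
    coords = np.stack(np.meshgrid(rows, cols, indexing="ij"))
    return ndimage.map_coordinates(img.astype(float), coords, order=1, mode="nearest")


def preprocess(frame: DepthFrame, config: HoDConfig = HoDConfig()) -> np.ndarray:
    """Resize to the target square and normalise values into [0, 1].

    A constant input maps to a constant output (all zeros under min-max
    normalisation, which is the only degenerate case).
    """
    img = _resize_bilinear(np.asarray(frame.pixels, dtype=float), config.target_size)
    if config.normalization == "minmax":
        lo, hi = img.min(), img.max()
        # the relative tolerance absorbs resampling round-off on constant input
        if hi - lo > 1e-9 * max(abs(hi), 1.0):
            img = (img - lo) / (hi - lo)
        else:
            img = np.zeros_like(img)
    elif config.normalization == "bitdepth":
        img = img / (2**frame.bit_depth - 1)
    else:
        raise ValueError(f"unknown normalization {config.normalization!r}")
    return img


def gradients(img: np.ndarray, config: HoDConfig = HoDConfig()) -> GradientField:
    """Per-pixel image gradients of a 2-D image.

    ``central``: central differences in the interior, one-sided forward/
    backward differences at the borders (this is ``numpy.gradient``).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError(f"need a 2-D image of at least 2x2, got shape {img.shape}")
    if config.gradient_op == "central":
        gy, gx = np.gradient(img)
    elif config.gradient_op == "sobel":
        gx = ndimage.sobel(img, axis=1) / 8.0
        gy = ndimage.sobel(img, axis=0) / 8.0
    else:
        raise ValueError(f"unknown gradient_op {config.gradient_op!r}")
    return GradientField(gx=gx, gy=gy)


def cell_histograms(field: GradientField, config: HoDConfig = HoDConfig()) -> np.ndarray:
    """Magnitude-accumulated orientation histograms on the cell grid.

    Returns an (n_cells, n_bins) matrix, cells in row-major grid order. Bin b
    covers [angle_min + b*width, angle_min + (b+1)*width) with the upper range
    limit (+180 deg) folded into the last bin. Zero-magnitude pixels have an
    undefined direction and contribute nothing (atan2(0, 0) = 0 contributes
    zero mass anyway).
    """
    mag = field.magnitude
    h, w = mag.shape
    cs = config.cell_size
    if h % cs or w % cs:
        raise ValueError(f"image shape {mag.shape} not divisible by cell_size {cs}")
    width = (config.angle_max - config.angle_min) / config.n_bins
    bins = np.floor((field.direction - config.angle_min) / width).astype(int)
    np.clip(bins, 0, config.n_bins - 1, out=bins)  # folds +180 into the last bin

    ny, nx = h // cs, w // cs
    rows, cols = np.indices(mag.shape)
    cell = (rows // cs) * nx + (cols // cs)
    flat = np.bincount(
        (cell * config.n_bins + bins).ravel(),
        weights=mag.ravel(),
        minlength=ny * nx * config.n_bins,
    )
    return flat.reshape(ny * nx, config.n_bins)


def intensity_stats(img: np.ndarray, config: HoDConfig = HoDConfig()) -> np.ndarray:
    """(mean, std, min, max) of the normalised image; std has N-1 denominator
    by default (a single-pixel image gets std 0)."""
    img = np.asarray(img, dtype=float)
    ddof = 1 if config.std_denominator == "sample" else 0
    std = img.std(ddof=ddof) if img.size > ddof else 0.0
    return np.array([img.mean(), std, img.min(), img.max()])


def extract_hod(frame: DepthFrame, config: HoDConfig = HoDConfig()) -> np.ndarray:
    """Full HoD descriptor of one frame: flattened cell histograms (cell-major,
    bin-minor) followed by the four intensity statistics."""
    img = preprocess(frame, config)
    hist = cell_histograms(gradients(img, config), config)
    return np.concatenate([hist.ravel(), intensity_stats(img, config)])


def extract_sequence(sample: ActionSample, config: HoDConfig = HoDConfig()) -> np.ndarray:
    """Per-frame HoD descriptors of a sample, stacked in frame order
    (n_frames, n_features)."""
    return np.stack([extract_hod(f, config) for f in sample.frames])
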