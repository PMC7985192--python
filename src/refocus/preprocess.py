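"""Stack normalization and cropping pipeline.

The reference image for normalization is an extended-depth-of-field (EDF)
projection of the stack; here the EDF is the per-pixel maximum-intensity
projection (monotone and parameter-free, which is all the downstream
thresholding needs).  Triangle thresholding on the EDF histogram separates
background from foreground; the background mean becomes the shift factor and
the 99th percentile of the foreground the scale factor, and every plane of
the volume is mapped through ``(pixels - shift) / scale``.  Stacks are then
cut into non-overlapping square tiles (256 x 256 by default at full scale),
discarding remainder margins.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .stack import ImagePlane, ImageStack, Z_SENTINEL

DEFAULT_N_BINS = 256  # matches the 8-bit display convention of the raw data
FOREGROUND_PERCENTILE = 99.0


@dataclasses.dataclass
class NormalizationFactors:
    """Affine normalization record: x_norm = (x - shift) / scale."""

    shift: float
    scale: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, pixels: np.ndarray) -> np.ndarray:
        return (pixels - self.shift) / self.scale

    def invert(self, pixels: np.ndarray) -> np.ndarray:
        return pixels * self.scale + self.shift


def compute_edf(stack: ImageStack) -> ImagePlane:
    """Per-pixel maximum-intensity projection across the stack.

    The returned plane carries a sentinel z (it is not a physical plane).
    """
    edf = np.max(stack.as_array(), axis=0)
    plane = ImagePlane.__new__(ImagePlane)  # allow sentinel z without checks
    plane.pixels = edf
    plane.z = Z_SENTINEL
    return plane


def triangle_threshold(image: ImagePlane | np.ndarray,
                       n_bins: int = DEFAULT_N_BINS) -> float:
    """Triangle-algorithm intensity threshold on an n_bins histogram.

    Builds the histogram, draws the line from its peak to the farthest
    non-empty tail bin, and returns the centre of the bin whose histogram
    point lies at maximal perpendicular distance below that line.
    """
    pixels = image.pixels if isinstance(image, ImagePlane) else np.asarray(image)
    vals = pixels.ravel()
    if np.ptp(vals) == 0:
        raise ValueError("constant image: histogram is degenerate")
    hist, edges = np.histogram(vals, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak = int(np.argmax(hist))
    nonzero = np.nonzero(hist)[0]
    # farthest non-empty bin from the peak, on the longer tail
    tail = nonzero[-1] if nonzero[-1] - peak >= peak - nonzero[0] else nonzero[0]
    if tail == peak:
        raise ValueError("degenerate histogram: single occupied bin")
    lo, hi = (peak, tail) if tail > peak else (tail, peak)
    idx = np.arange(lo, hi + 1)
    # perpendicular distance of (idx, hist[idx]) to the peak-tail chord
    x1, y1 = float(peak), float(hist[peak])
    x2, y2 = float(tail), float(hist[tail])
    num = np.abs((y2 - y1) * idx - (x2 - x1) * hist[idx] + x2 * y1 - y2 * x1)
    best = idx[int(np.argmax(num))]
    return float(centers[best])


def normalize_stack(stack: ImageStack, edf: ImagePlane | None = None,
                    n_bins: int = DEFAULT_N_BINS
                    ) -> tuple[ImageStack, NormalizationFactors]:
    """Normalize a volume by EDF-derived background shift and foreground scale.

    shift = mean of EDF pixels at or below the triangle threshold;
    scale = 99th percentile (linear interpolation) of EDF pixels above it.
    """
    if edf is None:
        edf = compute_edf(stack)
    thr = triangle_threshold(edf, n_bins=n_bins)
    fg = edf.pixels > thr
    if not np.any(fg):
        raise ValueError("empty foreground after triangle thresholding")
    if not np.any(~fg):
        raise ValueError("empty background after triangle thresholding")
    shift = float(np.mean(edf.pixels[~fg]))
    scale = float(np.percentile(edf.pixels[fg], FOREGROUND_PERCENTILE))
    scale = scale - shift
    if scale <= 0:
        raise ValueError("non-positive scale factor; image contrast too low")
    factors = NormalizationFactors(shift=shift, scale=scale)
    planes = [ImagePlane(factors.apply(p.pixels), p.z) for p in stack.planes]
    return ImageStack(planes, stack.z_grid.copy()), factors


def crop_tiles(stack: ImageStack, tile: int = 256) -> list[ImageStack]:
    """Cut the stack into non-overlapping tile x tile sub-stacks.

    All planes are cropped identically; remainder margins are discarded.
    """
    m, n = stack.planes[0].shape
    if tile > m or tile > n:
        raise ValueError(f"tile {tile} larger than image {(m, n)}")
    volume = stack.as_array()
    tiles = []
    for i in range(m // tile):
        for j in range(n // tile):
            sub = volume[:, i * tile:(i + 1) * tile, j * tile:(j + 1) * tile]
            tiles.append(ImageStack.from_array(sub, stack.z_grid))
    return tiles
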