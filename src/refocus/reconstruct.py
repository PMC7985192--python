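"""Volume inference from a few acquired planes.

Given M planes with known axial positions, the trained generator
synthesizes the image at any requested z (each request is an independent
sequence with freshly reset recurrent state) and assembles full stacks on a
requested z grid.  Also implements the adaptive acquisition rule: keep
adding input planes until successive reconstructed volumes differ by at most
epsilon in Frobenius norm (computed on normalized intensities).
"""

from __future__ import annotations

import numpy as np

from .dpm import DPM_SCALE_UM, assemble_sequence
from .network import RecurrentGenerator
from .stack import ImagePlane, ImageStack


def _pad_to_multiple(pixels: np.ndarray, factor: int) -> tuple[np.ndarray, tuple]:
    m, n = pixels.shape
    pm = (-m) % factor
    pn = (-n) % factor
    if pm == 0 and pn == 0:
        return pixels, (m, n)
    return np.pad(pixels, ((0, pm), (0, pn)), mode="reflect"), (m, n)


def infer_plane(model: RecurrentGenerator, planes: list[ImagePlane],
                z_out: float, ordering: str = "by_z",
                scale_constant: float = DPM_SCALE_UM) -> ImagePlane:
    """Synthesize the image at z_out from the given input planes.

    Images whose dimensions are not divisible by the network's down-sampling
    factor are reflect-padded to the next multiple and cropped back.
    """
    if not planes:
        raise ValueError("need at least one input plane")
    factor = model.config.down_factor
    padded = []
    orig = planes[0].shape
    for p in planes:
        if p.shape != orig:
            raise ValueError("input planes must share dimensions")
        px, _ = _pad_to_multiple(p.pixels, factor)
        padded.append(ImagePlane(px, p.z))
    seq = assemble_sequence(padded, target_z=z_out, order=ordering,
                            scale_constant=scale_constant)
    out = model.infer(seq)
    return ImagePlane(out.pixels[:orig[0], :orig[1]], float(z_out))


def infer_volume(model: RecurrentGenerator, planes: list[ImagePlane],
                 z_grid, ordering: str = "by_z",
                 scale_constant: float = DPM_SCALE_UM) -> ImageStack:
    """One independent infer_plane per grid point (grid strictly increasing)."""
    z_grid = np.asarray(z_grid, dtype=float)
    if z_grid.size == 0:
        raise ValueError("z_grid must be non-empty")
    if z_grid.size > 1 and not np.all(np.diff(z_grid) > 0):
        raise ValueError("z_grid must be strictly increasing")
    out_planes = [infer_plane(model, planes, float(z), ordering,
                              scale_constant) for z in z_grid]
    return ImageStack(out_planes, z_grid)


def frobenius_distance(a: ImageStack, b: ImageStack) -> float:
    """Elementwise L2 distance between two stacks on the same grid."""
    if a.shape != b.shape:
        raise ValueError("stacks must share shape")
    return float(np.linalg.norm(a.as_array() - b.as_array()))


def adaptive_M(model: RecurrentGenerator, plane_stream, z_grid,
               epsilon: float, ordering: str = "by_z",
               scale_constant: float = DPM_SCALE_UM
               ) -> tuple[int, ImageStack]:
    """Consume planes until the reconstruction stabilizes.

    After each added plane the full volume is reconstructed; returns the
    first M (>= 2) at which ||V_M - V_{M-1}||_F <= epsilon, together with
    that volume, or the stream length if the bound is never met.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    planes: list[ImagePlane] = []
    prev = None
    volume = None
    for plane in plane_stream:
        planes.append(plane)
        volume = infer_volume(model, planes, z_grid, ordering, scale_constant)
        if prev is not None and frobenius_distance(volume, prev) <= epsilon:
            return len(planes), volume
        prev = volume
    if volume is None:
        raise ValueError("plane stream yielded no planes")
    return len(planes), volume
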