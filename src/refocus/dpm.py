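"""Digital propagation matrices (DPMs) and M-plane input sequences.

A DPM is a constant-valued matrix paired with an input image; its value
encodes the signed axial distance from that image's plane to the desired
output plane, ``dz = z_target - z_input`` (propagating towards larger z is
positive), divided by a fixed scale constant so the DPM channel is O(1)
alongside normalized images.  An input sequence is an ordered list of
(image, DPM) pairs all referring to one target plane, materialized as an
M x m x n x 2 tensor with channel 0 the image and channel 1 the DPM.

The module also provides the transforms used to probe robustness of the
trained network: injecting Gaussian noise into the DPM values (one scalar
draw per plane, shifting the whole matrix uniformly), permuting the
sequence, and repeating a single plane M times.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .stack import ImagePlane

#: default DPM normalizer (um); keeps DPM channel values O(1)
DPM_SCALE_UM = 10.0


@dataclasses.dataclass
class DPM:
    """Constant matrix encoding a relative axial distance."""

    value: float                 # signed dz in um (z_target - z_input)
    dims: tuple[int, int]
    scale_constant: float = DPM_SCALE_UM

    def materialize(self) -> np.ndarray:
        return np.full(self.dims, self.value / self.scale_constant,
                       dtype=np.float32)


@dataclasses.dataclass
class InputSequence:
    """Ordered (image, DPM) pairs, all aimed at one target plane."""

    entries: list[tuple[ImagePlane, DPM]]
    target_z: float

    def __post_init__(self):
        if len(self.entries) < 1:
            raise ValueError("sequence must contain at least one plane")
        dims = self.entries[0][0].shape
        for plane, dpm in self.entries:
            if plane.shape != dims:
                raise ValueError("all planes must share the same dimensions")
            if dpm.dims != dims:
                raise ValueError("DPM dims must match image dims")

    def __len__(self):
        return len(self.entries)

    @property
    def M(self) -> int:
        return len(self.entries)

    def to_array(self, channel_first: bool = False) -> np.ndarray:
        """M x m x n x 2 tensor (or M x 2 x m x n if channel_first)."""
        frames = []
        for plane, dpm in self.entries:
            img = plane.pixels.astype(np.float32)
            frames.append(np.stack([img, dpm.materialize()], axis=-1))
        arr = np.stack(frames)            # (M, m, n, 2)
        if channel_first:
            arr = np.ascontiguousarray(np.transpose(arr, (0, 3, 1, 2)))
        return arr


def make_dpm(z_input: float, z_target: float, dims: tuple[int, int],
             scale_constant: float = DPM_SCALE_UM) -> DPM:
    if not (np.isfinite(z_input) and np.isfinite(z_target)):
        raise ValueError("z positions must be finite")
    return DPM(value=float(z_target) - float(z_input), dims=tuple(dims),
               scale_constant=scale_constant)


def assemble_sequence(planes: list[ImagePlane], target_z: float,
                      order: str = "by_z",
                      scale_constant: float = DPM_SCALE_UM) -> InputSequence:
    """Build an input sequence toward `target_z`.

    order: 'by_z' (ascending acquisition depth), 'by_abs_dz_desc'
    (descending |dz| to the target, ties broken by ascending z), or 'given'
    (keep caller order).
    """
    if len(planes) < 1:
        raise ValueError("need at least one plane")
    dims = planes[0].shape
    if any(p.shape != dims for p in planes):
        raise ValueError("all planes must share the same dimensions")
    if order == "by_z":
        planes = sorted(planes, key=lambda p: p.z)
    elif order == "by_abs_dz_desc":
        planes = sorted(planes, key=lambda p: (-abs(target_z - p.z), p.z))
    elif order != "given":
        raise ValueError(f"unknown order {order!r}")
    entries = [(p, make_dpm(p.z, target_z, dims, scale_constant))
               for p in planes]
    return InputSequence(entries, float(target_z))


def inject_dpm_noise(seq: InputSequence, sigma: float,
                     seed: int = 0) -> InputSequence:
    """Perturb each DPM value by one N(0, sigma^2) scalar draw (the whole
    constant matrix shifts uniformly); images are untouched."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return InputSequence(list(seq.entries), seq.target_z)
    rng = np.random.default_rng(seed)
    draws = rng.normal(0.0, sigma, size=len(seq))
    entries = []
    for (plane, dpm), d in zip(seq.entries, draws):
        entries.append((plane, DPM(dpm.value + float(d), dpm.dims,
                                   dpm.scale_constant)))
    return InputSequence(entries, seq.target_z)


def permute_sequence(seq: InputSequence, permutation) -> InputSequence:
    """Reorder the sequence; each image keeps its attached DPM."""
    perm = list(permutation)
    if sorted(perm) != list(range(len(seq))):
        raise ValueError(f"invalid permutation of length {len(seq)}: {perm}")
    return InputSequence([seq.entries[i] for i in perm], seq.target_z)


def repeat_plane(plane: ImagePlane, M: int, target_z: float,
                 scale_constant: float = DPM_SCALE_UM) -> InputSequence:
    """Sequence of M identical (image, DPM) pairs from a single plane."""
    if M < 1:
        raise ValueError("M must be at least 1")
    dpm = make_dpm(plane.z, target_z, plane.shape, scale_constant)
    return InputSequence([(plane, dpm)] * M, float(target_z))


# -- serialization -------------------------------------------------------------

def save_sequence(seq: InputSequence, tif_path, json_path=None) -> None:
    """Images to multi-page TIFF; z positions / target / DPM values to JSON."""
    tif_path = Path(tif_path)
    if json_path is None:
        json_path = tif_path.with_suffix(".json")
    tifffile.imwrite(tif_path, np.stack(
        [p.pixels.astype(np.float32) for p, _ in seq.entries]),
        photometric="minisblack")
    meta = {
        "target_z": seq.target_z,
        "z_positions": [p.z for p, _ in seq.entries],
        "dpm_values": [d.value for _, d in seq.entries],
        "scale_constant": seq.entries[0][1].scale_constant,
    }
    Path(json_path).write_text(json.dumps(meta, indent=2))


def load_sequence(tif_path, json_path=None) -> InputSequence:
    tif_path = Path(tif_path)
    if json_path is None:
        json_path = tif_path.with_suffix(".json")
    frames = tifffile.imread(tif_path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(Path(json_path).read_text())
    entries = []
    for img, z, dz in zip(frames, meta["z_positions"], meta["dpm_values"]):
        plane = ImagePlane(img, float(z))
        entries.append((plane, DPM(float(dz), plane.shape,
                                   meta["scale_constant"])))
    return InputSequence(entries, float(meta["target_z"]))
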