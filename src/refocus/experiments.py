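"""Desk-scale synthetic study: a complete train/evaluate experiment that
runs in minutes on one CPU.

The real instrument regime (6 um input spacing against a 0.4 um DOF,
1024x1024 frames, days of GPU training) is far outside what a small CPU run
can learn, so this study compresses the axial blur scale while keeping the
experiment's structure: sparse inputs at an exact spacing delta_z, a dense
ground-truth grid, EDF-referenced normalization, sequence assembly with
DPMs, and nearest-input-plane baselines.  Concretely: bead phantoms in a
6.4 x 6.4 x 9 um volume sampled at 0.1 um/pixel (64 x 64 frames), a defocus
model with sigma0 = 0.15 um and z_R = 1 um, M = 3 inputs at delta_z = 3 um,
ground truth every 0.25 um, and a K = 3 / 8-channel generator trained
without the GAN term.

Everything is deterministic given the experiment seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .metrics import psnr
from .phantom import OpticsModel, generate_bead_phantom, render_stack
from .preprocess import normalize_stack
from .reconstruct import infer_plane
from .stack import ImagePlane, ImageStack
from .train import TrainConfig, TrainResult, fit

#: desk-scale optics: blur length compressed so the refocusing map is
#: learnable from a few hundred small-crop steps
DESK_OPTICS = OpticsModel(sigma0=0.15, z_R=1.0, background=10.0,
                          read_noise_sd=2.0, photon_scale=1.0,
                          pixel_size=0.1)
DESK_EXTENT = (6.4, 6.4, 9.0)
DESK_Z_STEP = 0.25
DESK_DELTA_Z = 3.0
DESK_N_BEADS = 60
DESK_INPUT_Z = (1.5, 4.5, 7.5)
#: sequence ordering for the desk study: most-distant plane first, so the
#: residual path into the decoder carries the input nearest the target
DESK_ORDERING = "by_abs_dz_desc"


def desk_z_grid() -> np.ndarray:
    n = int(round(DESK_EXTENT[2] / DESK_Z_STEP)) + 1
    return DESK_Z_STEP * np.arange(n)


def make_ground_truth_stack(seed: int, noise: bool = True) -> ImageStack:
    """One normalized dense ground-truth stack from a random bead phantom."""
    phantom = generate_bead_phantom(DESK_N_BEADS, DESK_EXTENT,
                                    intensity_range=(1000.0, 4000.0),
                                    seed=seed,
                                    pixel_size=DESK_OPTICS.pixel_size)
    stack = render_stack(phantom, desk_z_grid(), DESK_OPTICS,
                         noise=noise, seed=seed + 1)
    normed, _ = normalize_stack(stack)
    return normed


def desk_train_config(seed: int, steps: int = 500,
                      batch: int = 8) -> TrainConfig:
    return TrainConfig(M=3, delta_z=DESK_DELTA_Z, crop=64,
                       learning_rate=1e-3, steps=steps, batch=batch,
                       ordering=DESK_ORDERING, seed=seed, gan_enabled=False,
                       validation_fraction=0.25, val_interval=50,
                       n_val_examples=4, n_scales=3, base_channels=8)


def train_desk_model(seed: int = 0, steps: int = 500, n_stacks: int = 12,
                     out_dir=None) -> TrainResult:
    """Train the desk-scale generator on synthetic bead stacks."""
    stacks = [make_ground_truth_stack(seed=1000 + seed * 100 + i)
              for i in range(n_stacks)]
    cfg = desk_train_config(seed=seed, steps=steps)
    return fit(stacks, cfg, out_dir=out_dir)


def input_planes(stack: ImageStack,
                 input_z=DESK_INPUT_Z) -> list[ImagePlane]:
    return [stack.nearest_plane(z) for z in input_z]


def midgap_z(input_z=DESK_INPUT_Z, half_width: float = 0.5) -> np.ndarray:
    """Ground-truth z values within half_width of the two gap centres."""
    grid = desk_z_grid()
    centres = [(input_z[i] + input_z[i + 1]) / 2.0
               for i in range(len(input_z) - 1)]
    sel = np.zeros(len(grid), dtype=bool)
    for c in centres:
        sel |= np.abs(grid - c) <= half_width + 1e-9
    return grid[sel]


@dataclasses.dataclass
class MidgapEvaluation:
    model_psnr: np.ndarray       # per evaluated plane (dB)
    baseline_psnr: np.ndarray    # nearest input plane as prediction
    z_values: np.ndarray
    median_model: float
    median_baseline: float


def evaluate_midgap(model, test_seeds=(9001, 9002),
                    half_width: float = 0.5) -> MidgapEvaluation:
    """PSNR of the model vs the nearest-input-plane baseline on held-out
    mid-gap planes of fresh test stacks."""
    model_vals, base_vals, zs = [], [], []
    for s in test_seeds:
        stack = make_ground_truth_stack(seed=s)
        planes = input_planes(stack)
        for z in midgap_z(half_width=half_width):
            gt = stack.nearest_plane(z)
            pred = infer_plane(model, planes, float(z),
                               ordering=DESK_ORDERING)
            nearest = min(planes, key=lambda p: abs(p.z - z))
            model_vals.append(psnr(pred, gt))
            base_vals.append(psnr(nearest.pixels, gt))
            zs.append(float(z))
    model_vals = np.asarray(model_vals)
    base_vals = np.asarray(base_vals)
    return MidgapEvaluation(model_vals, base_vals, np.asarray(zs),
                            float(np.median(model_vals)),
                            float(np.median(base_vals)))


def overfit_single_example(steps: int = 200, seed: int = 0,
                           crop: int = 32) -> np.ndarray:
    """Train on one fixed example; returns the per-step total loss curve.

    With a working optimizer the smoothed curve decreases monotonically.
    """
    from .nn import Adam
    from .network import GeneratorConfig, RecurrentGenerator
    from .train import make_batch, sample_training_example, train_step

    stack = make_ground_truth_stack(seed=7000 + seed)
    cfg = desk_train_config(seed=seed)
    cfg = dataclasses.replace(cfg, crop=crop, msssim_levels=1)
    rng = np.random.default_rng(seed)
    example = sample_training_example(stack, cfg, rng)
    batch = make_batch([example])
    gen = RecurrentGenerator(GeneratorConfig(n_scales=3, base_channels=8),
                             seed=seed)
    opt = Adam(gen.parameters(), lr=cfg.learning_rate)
    weights = cfg.loss_weights()
    losses = []
    for _ in range(steps):
        rec = train_step(gen, None, batch, weights, opt, None,
                         gan_enabled=False)
        losses.append(rec["total"])
    return np.asarray(losses)
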