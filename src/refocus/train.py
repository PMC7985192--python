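"""Sampling scheme and adversarial training loop.

Each training example is drawn from a normalized ground-truth z-stack: M
planes at an exact axial spacing delta_z (a random admissible start), one
target plane uniform over the full stack range (including beyond the
outermost inputs), and one shared random lateral crop.  The example becomes
an (image, DPM) input sequence aimed at the target plane.

The generator minimizes alpha*BerHu + beta*(1 - MS-SSIM) (+ the LSGAN term
when enabled) and alternates 1:1 with the discriminator under Adam.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dpm import DPM_SCALE_UM, InputSequence, assemble_sequence
from .losses import LossWeights, discriminator_loss, generator_loss, msssim, berhu
from .network import (Discriminator, DiscriminatorConfig, GeneratorConfig,
                      RecurrentGenerator, save_checkpoint)
from .nn import Adam
from .nn.autodiff import Tensor
from .stack import ImagePlane, ImageStack


@dataclasses.dataclass
class TrainConfig:
    M: int = 3
    delta_z: float = 6.0                 # axial input spacing (um)
    crop: int = 256
    learning_rate: float = 1e-5
    steps: int = 1000
    batch: int = 4
    ordering: str = "by_z"               # by_z | by_abs_dz_desc | random
    seed: int = 0
    gan_enabled: bool = True
    validation_fraction: float = 0.15
    val_interval: int = 50
    n_val_examples: int = 8
    n_scales: int = 5
    base_channels: int = 20
    scale_constant: float = DPM_SCALE_UM
    msssim_levels: int | None = None     # None: largest feasible for crop
    augment: bool = False                # flips/rotations, off by default
    cosine_decay: bool = True            # anneal lr to 10% over the run
    restore_best: bool = True            # return best-validation weights

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be at least 1")
        if self.delta_z <= 0:
            raise ValueError("delta_z must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def loss_weights(self) -> LossWeights:
        levels = self.msssim_levels
        if levels is None:
            window = LossWeights().msssim_window
            levels = max(1, min(5, int(np.log2(self.crop / window)) + 1))
        return LossWeights(msssim_levels=levels,
                           gamma=0.5 if self.gan_enabled else 0.0)


def _grid_step(stack: ImageStack) -> float:
    steps = np.diff(stack.z_grid)
    if len(steps) == 0:
        raise ValueError("stack has a single plane; cannot sample sequences")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("stack z grid is not uniform")
    return float(steps[0])


def sample_training_example(stack: ImageStack, cfg: TrainConfig,
                            rng: np.random.Generator
                            ) -> tuple[InputSequence, ImagePlane]:
    """Draw one (input sequence, ground-truth target plane) pair."""
    step = _grid_step(stack)
    stride_f = cfg.delta_z / step
    stride = int(round(stride_f))
    if abs(stride_f - stride) > 1e-6 or stride < 1:
        raise ValueError(f"delta_z={cfg.delta_z} um is not a multiple of the "
                         f"stack z step {step} um")
    n = len(stack)
    span = (cfg.M - 1) * stride
    if span >= n:
        raise ValueError("stack z range too small for M planes at delta_z")
    start = int(rng.integers(0, n - span))
    input_idx = [start + i * stride for i in range(cfg.M)]
    target_idx = int(rng.integers(0, n))

    m, w = stack.planes[0].shape
    if cfg.crop > m or cfg.crop > w:
        raise ValueError(f"crop {cfg.crop} larger than plane {(m, w)}")
    top = int(rng.integers(0, m - cfg.crop + 1))
    left = int(rng.integers(0, w - cfg.crop + 1))

    def cropped(i: int) -> ImagePlane:
        p = stack.planes[i]
        return ImagePlane(p.pixels[top:top + cfg.crop, left:left + cfg.crop],
                          p.z)

    planes = [cropped(i) for i in input_idx]
    target = cropped(target_idx)
    if cfg.ordering == "random":
        order = "given"
        planes = [planes[i] for i in rng.permutation(cfg.M)]
    else:
        order = cfg.ordering
    seq = assemble_sequence(planes, target_z=float(stack.z_grid[target_idx]),
                            order=order, scale_constant=cfg.scale_constant)
    return seq, target


def make_batch(examples: list[tuple[InputSequence, ImagePlane]]
               ) -> tuple[np.ndarray, np.ndarray]:
    seqs = np.stack([s.to_array(channel_first=True) for s, _ in examples])
    targets = np.stack([t.pixels[None].astype(np.float32)
                        for _, t in examples])
    return seqs, targets


def train_step(generator: RecurrentGenerator,
               discriminator: Discriminator | None,
               batch: tuple[np.ndarray, np.ndarray],
               weights: LossWeights,
               opt_g: Adam, opt_d: Adam | None,
               gan_enabled: bool = True) -> dict:
    """One generator update (and one discriminator update when the GAN term
    is enabled); returns every loss component."""
    seqs, targets = batch
    if seqs.shape[0] == 0:
        raise ValueError("empty batch")
    y = Tensor(targets)
    y_hat = generator.forward(seqs)
    d_score = None
    if gan_enabled and discriminator is not None:
        d_score = discriminator.forward(y_hat)
    total, terms = generator_loss(y_hat, y, d_score=d_score, weights=weights)
    record = {k: float(v.item() if isinstance(v, Tensor) else v)
              for k, v in terms.items()}
    if not np.isfinite(record["total"]):
        raise RuntimeError(f"non-finite generator loss: {record}")
    opt_g.zero_grad()
    if discriminator is not None:
        discriminator.zero_grad()
    total.backward()
    opt_g.step()

    if gan_enabled and discriminator is not None and opt_d is not None:
        d_fake = discriminator.forward(y_hat.detach())
        d_real = discriminator.forward(y)
        d_loss = discriminator_loss(d_fake, d_real)
        record["d_loss"] = float(d_loss.item())
        record["d_fake"] = float(d_fake.data.mean())
        record["d_real"] = float(d_real.data.mean())
        if not np.isfinite(record["d_loss"]):
            raise RuntimeError(f"non-finite discriminator loss: {record}")
        opt_d.zero_grad()
        opt_g.zero_grad()
        d_loss.backward()
        opt_d.step()
        opt_g.zero_grad()
    return record


def validation_loss(generator: RecurrentGenerator,
                    examples: list[tuple[InputSequence, ImagePlane]],
                    weights: LossWeights) -> float:
    """Non-adversarial fidelity loss (alpha*BerHu + beta*(1-MSSSIM)) in
    evaluation mode."""
    was_training = generator.training
    generator.eval()
    try:
        seqs, targets = make_batch(examples)
        y_hat = generator.forward(seqs)
        b = berhu(y_hat, Tensor(targets), c=weights.berhu_c, reduction="mean")
        s = msssim(y_hat, Tensor(targets), weights)
        val = weights.alpha * b.item() + weights.beta * (1.0 - s.item())
    finally:
        if was_training:
            generator.train()
    return float(val)


@dataclasses.dataclass
class TrainResult:
    generator: RecurrentGenerator
    discriminator: Discriminator | None
    log: pd.DataFrame
    best_val: float
    checkpoint_path: Path | None = None
    best_checkpoint_path: Path | None = None


def fit(stacks: list[ImageStack], cfg: TrainConfig,
        val_stacks: list[ImageStack] | None = None,
        out_dir=None) -> TrainResult:
    """Run the training loop over normalized ground-truth stacks.

    When `val_stacks` is not given, a validation_fraction share of `stacks`
    (at least one, if there are at least two) is held out.  Validation
    stacks never contribute gradient updates; the best-validation and final
    generator checkpoints are written to `out_dir` when given.
    """
    if not stacks:
        raise ValueError("no training stacks provided")
    if val_stacks is None:
        n_val = int(round(len(stacks) * cfg.validation_fraction))
        if n_val == 0 and len(stacks) >= 2:
            n_val = 1
        val_stacks = stacks[len(stacks) - n_val:] if n_val else []
        stacks = stacks[:len(stacks) - n_val] if n_val else stacks
    rng = np.random.default_rng(cfg.seed)
    weights = cfg.loss_weights()
    gen_cfg = GeneratorConfig(n_scales=cfg.n_scales,
                              base_channels=cfg.base_channels)
    generator = RecurrentGenerator(gen_cfg, seed=int(rng.integers(2 ** 31)))
    discriminator = None
    opt_d = None
    if cfg.gan_enabled:
        disc_cfg = DiscriminatorConfig(base_channels=max(2, cfg.base_channels // 2))
        discriminator = Discriminator(disc_cfg,
                                      seed=int(rng.integers(2 ** 31)))
        opt_d = Adam(discriminator.parameters(), lr=cfg.learning_rate)
    opt_g = Adam(generator.parameters(), lr=cfg.learning_rate)

    val_examples = []
    if val_stacks:
        val_rng = np.random.default_rng(cfg.seed + 1)
        for i in range(cfg.n_val_examples):
            stack = val_stacks[i % len(val_stacks)]
            val_examples.append(sample_training_example(stack, cfg, val_rng))

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    best_val = np.inf
    best_path = None
    best_state = None
    records = []
    generator.train()
    for step in range(cfg.steps):
        if cfg.cosine_decay and cfg.steps > 1:
            frac = 0.5 * (1 + np.cos(np.pi * step / (cfg.steps - 1)))
            opt_g.lr = cfg.learning_rate * (0.1 + 0.9 * frac)
            if opt_d is not None:
                opt_d.lr = opt_g.lr
        examples = [sample_training_example(stacks[int(rng.integers(len(stacks)))],
                                            cfg, rng)
                    for _ in range(cfg.batch)]
        record = train_step(generator, discriminator, make_batch(examples),
                            weights, opt_g, opt_d,
                            gan_enabled=cfg.gan_enabled)
        record["step"] = step
        if val_examples and (step % cfg.val_interval == cfg.val_interval - 1
                             or step == cfg.steps - 1):
            record["val_loss"] = validation_loss(generator, val_examples,
                                                 weights)
            if record["val_loss"] < best_val:
                best_val = record["val_loss"]
                best_state = {k: v.copy() for k, v
                              in generator.state_arrays().items()}
                if out_dir is not None:
                    best_path = out_dir / "best.npz"
                    save_checkpoint(best_path, generator,
                                    metadata={"step": step,
                                              "val_loss": best_val,
                                              "train_config":
                                              dataclasses.asdict(cfg)})
        records.append(record)
    log = pd.DataFrame(records)
    final_path = None
    if out_dir is not None:
        final_path = out_dir / "final.npz"
        save_checkpoint(final_path, generator,
                        metadata={"step": cfg.steps,
                                  "train_config": dataclasses.asdict(cfg)})
        log.to_csv(out_dir / "training_log.csv", index=False)
        (out_dir / "train_config.json").write_text(
            json.dumps(dataclasses.asdict(cfg), indent=2))
    if cfg.restore_best and best_state is not None:
        generator.load_state_arrays(best_state)
    return TrainResult(generator=generator, discriminator=discriminator,
                       log=log, best_val=best_val,
                       checkpoint_path=final_path,
                       best_checkpoint_path=best_path)
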