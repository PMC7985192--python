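"""Convolutional-recurrent generator and the adversarial discriminator.

The generator is a U-shaped encoder-decoder whose skip connections pass
through convolutional GRU blocks, so an arbitrary-length sequence of
(image, DPM) input pairs is integrated into a single set of multi-scale
features before decoding.  Weights are shared across sequence steps, so the
parameter count is independent of the sequence length M.

Encoder block k (k = 1..K):

    x_k = ReLU(BN(Conv_{k,2}(ReLU(BN(Conv_{k,1}(P(x_{k-1})))))))

with P the 2x2 max-pool (omitted at k = 1, the stem), all convolutions
3x3 / stride 1 / same padding, and channel widths base*2^{k-2} and
base*2^{k-1} for k >= 2 (base at the stem; base = 20 at full scale).

Recurrent block at scale k, applied once per sequence step:

    h_k <- GRU_k(x_k, h_k);   s_k = x_k + Conv1x1_k(h_k)

with hidden width equal to x_k's channel width and zero initial state.

Decoder block (k = K-1..1):

    y_k = ReLU(BN(Conv_{k,5}(ReLU(BN(Conv_{k,4}(I(y_{k+1}) (+) s_k))))))

with I the 2x2 nearest up-sampling and (+) channel concatenation, started
from y_K = s_K; a linear 1x1 convolution maps the top scale to one output
channel (no final ReLU: normalized targets may be slightly negative).

The discriminator stacks `n_blocks` conv blocks (two 3x3 convs of width
base*2^k each, then 2x2 max-pool), global average pooling, a 20-unit ReLU
dense layer and a sigmoid output unit.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import nn
from .dpm import InputSequence
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .stack import ImagePlane


@dataclasses.dataclass
class GeneratorConfig:
    n_scales: int = 5            # K
    base_channels: int = 20
    kernel: int = 3
    gru_kernel: int = 3
    input_channels: int = 2
    output_channels: int = 1

    def __post_init__(self):
        if self.n_scales < 2:
            raise ValueError("need at least 2 scales")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")

    def scale_channels(self, k: int) -> int:
        """Output channel width of encoder block k (1-based)."""
        return self.base_channels * 2 ** (k - 1)

    @property
    def down_factor(self) -> int:
        return 2 ** (self.n_scales - 1)


@dataclasses.dataclass
class DiscriminatorConfig:
    n_blocks: int = 5
    base_channels: int = 20
    hidden_units: int = 20

    def block_channels(self, k: int) -> int:
        return self.base_channels * 2 ** k


@dataclasses.dataclass
class GRUState:
    """Per-scale recurrent hidden maps carried across one input sequence."""

    hidden: list[Tensor]
    step: int = 0
    sequence_id: int | None = None


class EncoderBlock(nn.Module):
    def __init__(self, in_ch, mid_ch, out_ch, kernel, pool, rng):
        super().__init__()
        self.pool = pool
        self.conv1 = nn.Conv2d(in_ch, mid_ch, kernel, rng)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, out_ch, kernel, rng)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        if self.pool:
            h, w = x.shape[2], x.shape[3]
            if h % 2 or w % 2:
                raise ValueError(f"spatial dims {(h, w)} not divisible by 2 "
                                 "at this encoder depth")
            x = ad.maxpool2(x)
        x = ad.relu(self.bn1(self.conv1(x)))
        return ad.relu(self.bn2(self.conv2(x)))

    __call__ = forward


class RecurrentBlock(nn.Module):
    """GRU aggregation with a 1x1-projected residual around the current input."""

    def __init__(self, channels, gru_kernel, rng):
        super().__init__()
        self.cell = nn.ConvGRUCell(channels, rng, kernel=gru_kernel)
        self.proj = nn.Conv2d(channels, channels, 1, rng)

    def step(self, x_k: Tensor, h_prev: Tensor) -> tuple[Tensor, Tensor]:
        h = self.cell.step(x_k, h_prev)
        s_k = x_k + self.proj(h)
        return s_k, h

    __call__ = step


class DecoderBlock(nn.Module):
    def __init__(self, in_ch, mid_ch, out_ch, kernel, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, mid_ch, kernel, rng)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, out_ch, kernel, rng)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, y_prev: Tensor, s_k: Tensor) -> Tensor:
        up = ad.upsample2(y_prev)
        if up.shape[2:] != s_k.shape[2:]:
            raise ValueError(f"decoder shape mismatch: {up.shape} vs {s_k.shape}")
        x = ad.concat([up, s_k], axis=1)
        x = ad.relu(self.bn1(self.conv1(x)))
        return ad.relu(self.bn2(self.conv2(x)))

    __call__ = forward


class RecurrentGenerator(nn.Module):
    """Sequence-to-image generator; accepts any M >= 1 with one weight set."""

    def __init__(self, config: GeneratorConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        base, K = config.base_channels, config.n_scales
        enc = []
        for k in range(1, K + 1):
            if k == 1:
                enc.append(EncoderBlock(config.input_channels, base, base,
                                        config.kernel, pool=False, rng=rng))
            else:
                enc.append(EncoderBlock(config.scale_channels(k - 1),
                                        base * 2 ** (k - 2),
                                        base * 2 ** (k - 1),
                                        config.kernel, pool=True, rng=rng))
        self.encoder = enc
        self.recurrent = [RecurrentBlock(config.scale_channels(k),
                                         config.gru_kernel, rng)
                          for k in range(1, K + 1)]
        dec = []
        for k in range(K - 1, 0, -1):
            in_ch = config.scale_channels(k + 1) + config.scale_channels(k)
            out_ch = config.scale_channels(k)
            dec.append(DecoderBlock(in_ch, out_ch, out_ch, config.kernel, rng))
        self.decoder = dec  # ordered k = K-1 .. 1
        self.head = nn.Conv2d(base, config.output_channels, 1, rng)
        self._sequence_counter = 0

    # -- recurrent state management ------------------------------------------
    def init_state(self, batch: int, height: int, width: int) -> GRUState:
        K = self.config.n_scales
        hidden = []
        for k in range(1, K + 1):
            f = 2 ** (k - 1)
            hidden.append(self.recurrent[k - 1].cell.init_state(
                batch, height // f, width // f))
        self._sequence_counter += 1
        return GRUState(hidden=hidden, step=0,
                        sequence_id=self._sequence_counter)

    def encode(self, x: Tensor) -> list[Tensor]:
        feats = []
        for block in self.encoder:
            x = block(x)
            feats.append(x)
        return feats

    def step(self, x: Tensor, state: GRUState) -> list[Tensor]:
        """One sequence step: encode, update every scale's GRU state, and
        return the residual-aggregated features {s_k}."""
        if state.sequence_id != self._sequence_counter:
            raise RuntimeError("stale GRU state: call init_state() at the "
                               "start of every sequence")
        feats = self.encode(x)
        s = []
        for k, x_k in enumerate(feats):
            s_k, h = self.recurrent[k].step(x_k, state.hidden[k])
            state.hidden[k] = h
            s.append(s_k)
        state.step += 1
        return s

    def decode(self, s: list[Tensor]) -> Tensor:
        y = s[-1]
        for block, s_k in zip(self.decoder, reversed(s[:-1])):
            y = block(y, s_k)
        return self.head(y)

    def forward(self, seq: np.ndarray | Tensor) -> Tensor:
        """seq: (M, 2, H, W) or batched (N, M, 2, H, W) -> (N, 1, H, W)."""
        data = seq.data if isinstance(seq, Tensor) else np.asarray(seq)
        data = np.asarray(data, dtype=np.float32)
        if data.ndim == 4:
            data = data[None]
        if data.ndim != 5:
            raise ValueError("expected (N, M, 2, H, W) input")
        n, m, c, h, w = data.shape
        if m < 1:
            raise ValueError("empty input sequence")
        if c != self.config.input_channels:
            raise ValueError(f"expected {self.config.input_channels} channels")
        f = self.config.down_factor
        if h % f or w % f:
            raise ValueError(f"spatial dims {(h, w)} must be divisible by {f}")
        state = self.init_state(n, h, w)
        s = None
        for t in range(m):
            s = self.step(Tensor(data[:, t]), state)
        return self.decode(s)

    __call__ = forward

    def infer(self, seq: InputSequence) -> ImagePlane:
        """Run one sequence in evaluation mode, returning the output plane."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(seq.to_array(channel_first=True))
        finally:
            if was_training:
                self.train()
        return ImagePlane(out.data[0, 0].astype(np.float64), seq.target_z)


class Discriminator(nn.Module):
    def __init__(self, config: DiscriminatorConfig = None, seed: int = 0,
                 in_channels: int = 1, kernel: int = 3):
        super().__init__()
        self.config = config or DiscriminatorConfig()
        rng = np.random.default_rng(seed)
        blocks = []
        in_ch = in_channels
        for k in range(1, self.config.n_blocks + 1):
            ch = self.config.block_channels(k)
            blocks.append(EncoderBlock(in_ch, ch, ch, kernel,
                                       pool=(k > 1), rng=rng))
            in_ch = ch
        self.blocks = blocks
        self.fc1 = nn.Linear(in_ch, self.config.hidden_units, rng)
        self.fc2 = nn.Linear(self.config.hidden_units, 1, rng)

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        min_side = 2 ** self.config.n_blocks
        if x.shape[2] < min_side or x.shape[3] < min_side:
            raise ValueError(f"input must be at least {min_side} per side")
        for block in self.blocks:
            x = block(x)
        x = ad.global_avg_pool(x)
        x = ad.relu(self.fc1(x))
        return ad.sigmoid(self.fc2(x))

    __call__ = forward


def count_parameters(model: nn.Module) -> int:
    """Total trainable parameter count (independent of sequence length M)."""
    return int(sum(p.data.size for p in model.parameters()))


# -- checkpointing -------------------------------------------------------------

def save_checkpoint(path, generator: RecurrentGenerator,
                    metadata: dict | None = None) -> None:
    """Single-file weights + JSON config (embedded), bit-exact round trip."""
    cfg = dataclasses.asdict(generator.config)
    payload = {"__config__": np.frombuffer(
        json.dumps({"generator": cfg, "metadata": metadata or {}})
        .encode(), dtype=np.uint8)}
    for k, v in generator.state_arrays().items():
        payload["w." + k] = v
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[RecurrentGenerator, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"].tobytes()).decode())
        cfg = GeneratorConfig(**meta["generator"])
        gen = RecurrentGenerator(cfg, seed=0)
        state = {k[2:]: data[k] for k in data.files if k.startswith("w.")}
    gen.load_state_arrays(state)
    return gen, meta.get("metadata", {})
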