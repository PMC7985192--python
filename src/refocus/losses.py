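"""Composite training objective: BerHu + (1 - MS-SSIM) + least-squares GAN.

The generator loss is

    L_V = alpha * BerHu(y_hat, y) + beta * (1 - MSSSIM(y_hat, y))
          + gamma * (D(y_hat) - 1)^2

with alpha, beta, gamma = 3, 1, 0.5.  BerHu (reverse Huber) is linear in the
per-pixel residual below a threshold c = 0.1 and quadratic above it,

    |e|            for |e| <= c,
    (e^2 + c^2)/(2c) for |e| > c,

continuous at |e| = c.  MS-SSIM multiplies a luminance term at the coarsest
scale with contrast and structure terms over dyadically down-sampled scales,
using 11x11 Gaussian (sigma 1.5) local statistics and the canonical
five-level exponents; the similarity is converted to a loss as 1 - MSSSIM.
The discriminator minimizes the least-squares objective

    L_D = 0.5 * D(y_hat)^2 + 0.5 * (D(y) - 1)^2.

All functions accept plain numpy arrays or autodiff tensors; gradients flow
when tensors are supplied.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor

#: canonical 5-level MS-SSIM exponents (applied to contrast*structure per
#: level; the last also exponentiates the coarsest-level luminance term)
MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclasses.dataclass
class LossWeights:
    alpha: float = 3.0           # BerHu weight
    beta: float = 1.0            # (1 - MS-SSIM) weight
    gamma: float = 0.5           # adversarial weight
    berhu_c: float = 0.1
    msssim_levels: int = 5
    msssim_sigma: float = 1.5
    msssim_window: int = 11
    dynamic_range: float = 1.0   # L of the normalized intensity scale
    k1: float = 0.01
    k2: float = 0.03

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.berhu_c <= 0:
            raise ValueError("berhu_c must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0

    def level_weights(self) -> np.ndarray:
        w = np.asarray(MSSSIM_WEIGHTS[: self.msssim_levels], dtype=np.float64)
        return w / w.sum()


def _to_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    dtype = arr.dtype if arr.dtype in (np.float32, np.float64) else None
    return Tensor(arr, dtype=dtype or np.float32)


def berhu(x, y, c: float = 0.1, reduction: str = "sum"):
    """Reverse-Huber penalty between images x and y.

    reduction='sum' evaluates the per-pixel sum exactly as written above;
    'mean' divides by the pixel count (used inside the composite loss so the
    weights stay scale-balanced across crop sizes).
    """
    if c <= 0:
        raise ValueError("BerHu threshold c must be positive")
    if reduction not in ("sum", "mean"):
        raise ValueError("reduction must be 'sum' or 'mean'")
    x, y = _to_tensor(x), _to_tensor(y)
    if x.shape != y.shape:
        raise ValueError("images must share dimensions")
    e = x - y
    small = np.abs(e.data) <= c
    abs_e = ad.abs_(e)
    quad = (e * e + c * c) * (1.0 / (2.0 * c))
    total = (abs_e * Tensor(small.astype(e.data.dtype))
             + quad * Tensor((~small).astype(e.data.dtype))).sum()
    if reduction == "mean":
        total = total * (1.0 / e.data.size)
    return total


def _gaussian_kernel(window: int, sigma: float) -> np.ndarray:
    r = np.arange(window) - (window - 1) / 2.0
    g = np.exp(-0.5 * (r / sigma) ** 2)
    g /= g.sum()
    return np.outer(g, g).astype(np.float32)


def _ssim_terms(x: Tensor, y: Tensor, kernel: Tensor, margin: int,
                c1: float, c2: float, c3: float):
    """Windowed luminance / contrast / structure maps on the valid region."""
    def filt(t):
        out = ad.conv2d(t, kernel)
        return out[:, :, margin:-margin, margin:-margin]
    mu_x, mu_y = filt(x), filt(y)
    var_x = filt(x * x) - mu_x * mu_x
    var_y = filt(y * y) - mu_y * mu_y
    cov = filt(x * y) - mu_x * mu_y
    sd_x = ad.sqrt(ad.relu(var_x), eps=1e-12)
    sd_y = ad.sqrt(ad.relu(var_y), eps=1e-12)
    lum = (2.0 * mu_x * mu_y + c1) / (mu_x * mu_x + mu_y * mu_y + c1)
    con = (2.0 * sd_x * sd_y + c2) / (var_x + var_y + c2)
    struct = (cov + c3) / (sd_x * sd_y + c3)
    return lum, con, struct


def msssim(x, y, weights: LossWeights | None = None):
    """Multi-scale SSIM in (0, 1]; 1 iff the images are identical.

    Contrast and structure terms are averaged at every dyadic scale, the
    luminance term at the coarsest scale only; per-level exponents are the
    (renormalized) canonical weights.  Down-sampling is 2x2 mean pooling and
    local statistics use a Gaussian window on the valid (unpadded) region.
    """
    w = weights or LossWeights()
    x, y = _to_tensor(x), _to_tensor(y)
    if x.shape != y.shape:
        raise ValueError("images must share dimensions")
    if x.ndim == 2:
        x = x.reshape(1, 1, *x.shape)
        y = y.reshape(1, 1, *y.shape)
    levels = w.msssim_levels
    min_side = min(x.shape[2], x.shape[3])
    if min_side < 2 ** (levels - 1) * w.msssim_window:
        raise ValueError(
            f"image side {min_side} too small for {levels} scales with a "
            f"{w.msssim_window}-pixel window; reduce msssim_levels")
    kernel = Tensor(_gaussian_kernel(w.msssim_window, w.msssim_sigma)
                    .reshape(1, 1, w.msssim_window, w.msssim_window))
    margin = (w.msssim_window - 1) // 2
    exps = w.level_weights()
    result = None
    for j in range(levels):
        lum, con, struct = _ssim_terms(x, y, kernel, margin,
                                       w.c1, w.c2, w.c3)
        # clamp: contrast*structure can dip below 0 for anticorrelated
        # patches, and a fractional power of a negative mean is undefined;
        # the 1e-8 floor keeps the power's gradient finite at 0
        cs = (ad.relu((con * struct).mean()) + 1e-8) ** float(exps[j])
        result = cs if result is None else result * cs
        if j == levels - 1:
            result = result * (ad.relu(lum.mean()) + 1e-8) ** float(exps[j])
        else:
            x, y = ad.avgpool2(x), ad.avgpool2(y)
    return result


def generator_loss(y_hat, y, d_score=None, weights: LossWeights | None = None):
    """Composite generator objective; omit d_score to drop the GAN term."""
    w = weights or LossWeights()
    terms = {}
    terms["berhu"] = berhu(y_hat, y, c=w.berhu_c, reduction="mean")
    terms["msssim"] = msssim(y_hat, y, w)
    total = w.alpha * terms["berhu"] + w.beta * (1.0 - terms["msssim"])
    if d_score is not None and w.gamma > 0:
        d = _to_tensor(d_score)
        adv = ((d - 1.0) ** 2).mean()
        terms["adversarial"] = adv
        total = total + w.gamma * adv
    terms["total"] = total
    return total, terms


def discriminator_loss(d_fake, d_real):
    """Least-squares discriminator objective (0 iff scores are (0, 1))."""
    d_fake, d_real = _to_tensor(d_fake), _to_tensor(d_real)
    return (0.5 * (d_fake ** 2).mean()
            + 0.5 * ((d_real - 1.0) ** 2).mean())
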