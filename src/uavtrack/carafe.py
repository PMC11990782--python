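"""Content-aware reassembly of features (CARAFE): the numeric operator.

CARAFE upsamples an H x W x C feature map by an integer factor ``sigma``
using a distinct k_up x k_up reassembly kernel per *output* location.  Each
kernel is softmax-normalised (nonnegative, sums to 1) and the output value
is the dot product of the kernel with the k_up x k_up source neighbourhood
centred at the source pixel the output location maps back to (floor
division by sigma), applied identically to every channel.  Borders are
zero-padded.

Kernel prediction is a learned convolution in the original network; here
kernel logits arrive as data, which makes the reassembly arithmetic fully
testable without trained weights.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax

__all__ = ["normalize_kernels", "reassemble", "upsample"]


def normalize_kernels(raw: np.ndarray) -> np.ndarray:
    """Softmax over the kernel-tap axis at every output location.

    ``raw`` has shape (sigma*H, sigma*W, k_up**2); the result is
    nonnegative with each tap vector summing to 1.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("kernel logits must be finite")
    if raw.ndim != 3:
        raise ValueError(f"kernel field must be 3-D, got shape {raw.shape}")
    return softmax(raw, axis=-1)


def reassemble(
    feat: np.ndarray, kernels: np.ndarray, sigma: int = 2, k_up: int = 5
) -> np.ndarray:
    """Reassemble ``feat`` (H x W x C) into a (sigma*H x sigma*W x C) map.

    ``kernels`` must already be normalised and have shape
    (sigma*H, sigma*W, k_up**2).
    """
    feat = np.asarray(feat, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    if feat.ndim != 3:
        raise ValueError(f"feature map must be H x W x C, got shape {feat.shape}")
    H, W, C = feat.shape
    if sigma < 1 or k_up < 1 or k_up % 2 == 0:
        raise ValueError("sigma must be >= 1 and k_up a positive odd integer")
    expected = (sigma * H, sigma * W, k_up * k_up)
    if kernels.shape != expected:
        raise ValueError(
            f"kernel field shape {kernels.shape} does not match expected {expected}"
        )
    r = k_up // 2
    padded = np.zeros((H + 2 * r, W + 2 * r, C))
    padded[r : r + H, r : r + W] = feat

    out_i = np.arange(sigma * H)
    out_j = np.arange(sigma * W)
    src_i = out_i // sigma  # source row per output row
    src_j = out_j // sigma
    out = np.zeros((sigma * H, sigma * W, C))
    # Accumulate one tap offset at a time; each gather is a shifted view of
    # the padded map indexed by the per-output source centre.
    tap = 0
    for di in range(-r, r + 1):
        rows = padded[src_i + r + di]  # (sigma*H, W + 2r, C)
        for dj in range(-r, r + 1):
            vals = rows[:, src_j + r + dj]  # (sigma*H, sigma*W, C)
            out += kernels[:, :, tap, None] * vals
            tap += 1
    return out


def upsample(
    feat: np.ndarray, kernel_logits: np.ndarray, sigma: int = 2, k_up: int = 5
) -> np.ndarray:
    """Normalise raw kernel logits and reassemble in one call."""
    return reassemble(feat, normalize_kernels(kernel_logits), sigma, k_up)
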