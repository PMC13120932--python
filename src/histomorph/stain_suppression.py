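"""Morphology-dominant encoding with stain-bias suppression (SDA).

H&E staining varies across laboratories, scanners and reagent batches; a
classifier trained on one staining style can latch onto colour as a shortcut.
Instead of normalising colours at the input (which needs stain templates and
can distort tissue), this module factorises the backbone token features F
into

* a stain-related component  ``Fs = MLP_s(F)`` — a per-token feed-forward
  map, deliberately local so it can model colour/intensity drift but not
  spatial structure, and
* a morphology-dominant component ``Fm = F + DWConv(WAttn(F))`` — a residual
  branch whose window attention and depthwise convolution operate on the 2-D
  token grid, emphasising boundary continuity and local texture.

A token-level sigmoid gate computed from the raw features,
``alpha = sigmoid(F w_a + b_a)``, interpolates the two components:

    fused = alpha * Fm + (1 - alpha) * Fs

so each fused row is a componentwise convex combination of its morphology and
stain rows.  The decomposition is purely architectural — no auxiliary
disentanglement loss — and is trained end-to-end by the classification loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .backbone import TokenGrid
from .nn import (
    Tensor,
    Module,
    Linear,
    DepthwiseConv3x3,
    masked_softmax,
    Parameter,
)

__all__ = ["FusedFeatures", "StainSuppression"]

logger = logging.getLogger(__name__)


@dataclass
class FusedFeatures:
    """Result of the stain/morphology factorisation for one image."""

    stain: np.ndarray  # Fs, (N, C)
    morph: np.ndarray  # Fm, (N, C)
    alpha: np.ndarray  # gate, (N, 1), entries in (0, 1)
    fused: np.ndarray  # alpha*Fm + (1-alpha)*Fs, (N, C)


class StainSuppression(Module):
    """Gated stain/morphology factorisation on a token grid.

    Parameters
    ----------
    channels:
        Token channel dimension C.
    window:
        Side of the non-overlapping attention windows on the token grid.
        Grids not divisible by the window are zero-padded and the padded
        keys are masked out of the softmax; a grid smaller than one window
        degenerates to a single global window (logged).
    seed:
        Parameter initialisation seed.
    """

    def __init__(self, channels: int, window: int = 7, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.channels = channels
        self.window = int(window)
        # stain branch: token-wise MLP, one hidden layer of width C
        self.stain_fc1 = Linear(channels, channels, rng)
        self.stain_fc2 = Linear(channels, channels, rng)
        # morphology branch: window attention + depthwise conv, residual
        self.wq = Linear(channels, channels, rng, bias=False)
        self.wk = Linear(channels, channels, rng, bias=False)
        self.wv = Linear(channels, channels, rng, bias=False)
        self.dwconv = DepthwiseConv3x3(channels, zero_init=True)
        # token-level gate on the raw backbone features
        self.gate_weight = Parameter(np.zeros(channels))
        self.gate_bias = Parameter(np.zeros(1))

    # ---- branches ------------------------------------------------------
    def stain_branch(self, tokens: Tensor) -> Tensor:
        """Per-token feed-forward map; no cross-token mixing. (B,N,C)->(B,N,C)."""
        return self.stain_fc2(self.stain_fc1(tokens).relu())

    def window_attention(self, tokens: Tensor, grid_shape: tuple[int, int]) -> Tensor:
        """Single-head scaled dot-product attention in non-overlapping windows."""
        B, N, C = tokens.shape
        gh, gw = grid_shape
        w = self.window
        if gh < w or gw < w:
            logger.info(
                "token grid %dx%d smaller than window %d: using a single global window",
                gh, gw, w,
            )
        ph = (-gh) % w
        pw = (-gw) % w
        x = tokens.reshape(B, gh, gw, C).pad(((0, 0), (0, ph), (0, pw), (0, 0)))
        gh2, gw2 = gh + ph, gw + pw
        nh, nw = gh2 // w, gw2 // w
        valid = np.zeros((gh2, gw2), dtype=np.float64)
        valid[:gh, :gw] = 1.0
        key_mask = (
            valid.reshape(nh, w, nw, w).transpose(0, 2, 1, 3).reshape(nh * nw, 1, w * w)
        )
        x = x.reshape(B, nh, w, nw, w, C).transpose((0, 1, 3, 2, 4, 5))
        x = x.reshape(B * nh * nw, w * w, C)
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(C))
        attn = masked_softmax(scores, np.tile(key_mask, (B, 1, 1)), axis=-1)
        out = attn @ v
        out = out.reshape(B, nh, nw, w, w, C).transpose((0, 1, 3, 2, 4, 5))
        out = out.reshape(B, gh2, gw2, C)[:, :gh, :gw, :]
        return out.reshape(B, N, C)

    def morph_branch(self, tokens: Tensor, grid_shape: tuple[int, int]) -> Tensor:
        """Residual local-structure branch: F + DWConv(WAttn(F)). (B,N,C)->(B,N,C)."""
        B, N, C = tokens.shape
        gh, gw = grid_shape
        attn = self.window_attention(tokens, grid_shape).reshape(B, gh, gw, C)
        return tokens + self.dwconv(attn).reshape(B, N, C)

    def gate(self, tokens: Tensor) -> Tensor:
        """Token-level sigmoid gate from the RAW backbone features. (B,N,C)->(B,N,1)."""
        B, N, C = tokens.shape
        logits = tokens @ self.gate_weight.reshape(C, 1) + self.gate_bias
        return logits.sigmoid()

    @staticmethod
    def fuse(morph: Tensor, stain: Tensor, alpha: Tensor) -> Tensor:
        """Gated convex combination, alpha broadcast along channels."""
        return alpha * morph + (1.0 - alpha) * stain

    def forward(self, tokens: Tensor, grid_shape: tuple[int, int]) -> Tensor:
        """(B,N,C) raw tokens -> (B,N,C) fused morphology-dominant features."""
        fs = self.stain_branch(tokens)
        fm = self.morph_branch(tokens, grid_shape)
        alpha = self.gate(tokens)
        return self.fuse(fm, fs, alpha)

    # ---- single-image convenience ---------------------------------------
    def sda_forward(self, tokens: TokenGrid) -> FusedFeatures:
        """Factorise one image's token grid; returns all intermediate pieces."""
        x = Tensor(tokens.features[None])
        fs = self.stain_branch(x)
        fm = self.morph_branch(x, tokens.grid_shape)
        alpha = self.gate(x)
        fused = self.fuse(fm, fs, alpha)
        return FusedFeatures(
            stain=fs.numpy()[0],
            morph=fm.numpy()[0],
            alpha=alpha.numpy()[0],
            fused=fused.numpy()[0],
        )
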