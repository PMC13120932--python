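"""Token backbone: images to patch-token feature grids.

A backbone maps an RGB image to an ``N x C`` matrix of token features, where
the ``N`` tokens correspond one-to-one with the cells of a 2-D grid obtained
by downsampling the image by the backbone's total stride.  Downstream modules
(stain suppression, spatial aggregation head) consume only the token matrix
and the grid coordinates, so any feature extractor honouring this contract
can be plugged in: the default is a small trainable convolutional backbone
(stride 8) suited to desk-scale experiments; a hierarchical windowed
transformer (e.g. a pretrained Swin) can be attached through
:class:`CallableBackbone` by wrapping its final-stage feature map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from PIL import Image

from .nn import Tensor, Module, Linear, Conv2d, avg_pool2d

__all__ = [
    "TokenGrid",
    "ImageFormatError",
    "ImageSizeError",
    "MiniBackbone",
    "CallableBackbone",
    "extract_tokens",
    "grid_coords",
    "load_image",
    "resize_and_normalize",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)
DEFAULT_MEAN = (0.5, 0.5, 0.5)
DEFAULT_STD = (0.5, 0.5, 0.5)


class ImageFormatError(ValueError):
    """Input is not an RGB image in the expected layout."""


class ImageSizeError(ValueError):
    """Image dimensions are incompatible with the backbone stride."""


@dataclass
class TokenGrid:
    """Per-image token features aligned with a 2-D grid.

    ``coords`` enumerates the grid row-major in token-grid units, 0-based;
    all spatial structure downstream is derived from ``coords``, never from
    the row order of ``features``.
    """

    features: np.ndarray  # (N, C)
    grid_shape: tuple[int, int]  # (Gh, Gw)
    coords: np.ndarray = field(default=None)  # (N, 2) int, (row, col)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        gh, gw = self.grid_shape
        if self.features.ndim != 2 or self.features.shape[0] != gh * gw:
            raise ValueError(
                f"token count {self.features.shape[0]} != grid {gh}x{gw}"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("token features must be finite")
        if self.coords is None:
            self.coords = grid_coords(gh, gw)
        else:
            self.coords = np.asarray(self.coords, dtype=int)
            if self.coords.shape != (gh * gw, 2):
                raise ValueError("coords must be (N, 2)")
            if len({tuple(c) for c in self.coords}) != len(self.coords):
                raise ValueError("duplicate grid coordinates")

    @property
    def n_tokens(self) -> int:
        return self.features.shape[0]

    @property
    def channels(self) -> int:
        return self.features.shape[1]


def grid_coords(gh: int, gw: int) -> np.ndarray:
    """Row-major (row, col) integer coordinates of a gh x gw grid."""
    rr, cc = np.meshgrid(np.arange(gh), np.arange(gw), indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


@runtime_checkable
class TokenBackbone(Protocol):
    stride: int
    channels: int

    def forward(self, images: Tensor) -> Tensor:  # (B,H,W,3) -> (B,Gh,Gw,C)
        ...


class MiniBackbone(Module):
    """Small trainable convolutional backbone, total stride 8.

    Three stages: a 4x4 patch partition with linear embedding, a 3x3
    conv+ReLU stage followed by 2x2 average pooling, and a final 3x3
    conv+ReLU stage on the token grid.  Channels-last throughout.
    """

    def __init__(self, channels: tuple[int, int, int] = (16, 32, 32), seed: int = 0):
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        self.stride = 8
        self.channels = c3
        self.patch_embed = Linear(4 * 4 * 3, c1, rng)
        self.conv1 = Conv2d(c1, c2, rng)
        self.conv2 = Conv2d(c2, c3, rng)

    def forward(self, images: Tensor) -> Tensor:
        B, H, W, C = images.shape
        if C != 3:
            raise ImageFormatError(f"expected 3 channels, got {C}")
        if H < self.stride or W < self.stride:
            raise ImageSizeError(f"image {H}x{W} smaller than one backbone patch")
        if H % self.stride or W % self.stride:
            raise ImageSizeError(
                f"image {H}x{W} not divisible by backbone stride {self.stride}"
            )
        # 4x4 patch partition + linear embedding
        x = images.reshape(B, H // 4, 4, W // 4, 4, 3)
        x = x.transpose((0, 1, 3, 2, 4, 5)).reshape(B, H // 4, W // 4, 48)
        x = self.patch_embed(x)
        x = avg_pool2d(self.conv1(x).relu(), 2)
        x = self.conv2(x).relu()
        return x


class CallableBackbone:
    """Adapter wrapping an external feature extractor as a token backbone.

    ``fn`` maps a (B,H,W,3) array to a (B, H/stride, W/stride, channels)
    feature array — e.g. the final-stage feature grid of a pretrained
    hierarchical transformer.  The wrapped extractor is treated as fixed
    (no gradients flow into it).
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], stride: int, channels: int):
        self.fn = fn
        self.stride = stride
        self.channels = channels

    def forward(self, images: Tensor) -> Tensor:
        feats = np.asarray(self.fn(images.numpy()), dtype=np.float64)
        B, H, W, _ = images.shape
        expected = (B, H // self.stride, W // self.stride, self.channels)
        if feats.shape != expected:
            raise ValueError(f"backbone returned {feats.shape}, expected {expected}")
        return Tensor(feats)

    def parameters(self):
        return []


def extract_tokens(image: np.ndarray, backbone) -> TokenGrid:
    """Run `backbone` on one image and return its token grid.

    `image` is (H, W, 3) with finite values; grid shape is the image size
    divided by the backbone's total stride.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ImageFormatError(f"expected (H, W, 3) RGB array, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ImageFormatError("image contains non-finite values")
    feats = backbone.forward(Tensor(image[None])).numpy()[0]
    gh, gw, c = feats.shape
    return TokenGrid(features=feats.reshape(gh * gw, c), grid_shape=(gh, gw))


def load_image(path: str) -> np.ndarray:
    """Decode a PNG/JPEG file to an (H, W, 3) float array in [0, 1]."""
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            return np.asarray(im, dtype=np.float64) / 255.0
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc


def resize_and_normalize(
    raw_image: np.ndarray,
    side: int = 224,
    mean: tuple[float, float, float] = DEFAULT_MEAN,
    std: tuple[float, float, float] = DEFAULT_STD,
) -> np.ndarray:
    """Resize an RGB image in [0,1] to `side` x `side` and standardise channels."""
    raw_image = np.asarray(raw_image, dtype=np.float64)
    if raw_image.ndim != 3 or raw_image.shape[2] != 3:
        raise ImageFormatError(f"expected (H, W, 3) RGB array, got {raw_image.shape}")
    if raw_image.min() < 0 or raw_image.max() > 1:
        raise ImageFormatError("raw image values must lie in [0, 1]")
    if raw_image.shape[:2] != (side, side):
        im = Image.fromarray(np.uint8(np.round(raw_image * 255.0)))
        im = im.resize((side, side), Image.BILINEAR)
        raw_image = np.asarray(im, dtype=np.float64) / 255.0
    mean = np.asarray(mean, dtype=np.float64)
    std = np.asarray(std, dtype=np.float64)
    return (raw_image - mean) / std
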