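"""Full classifier: backbone -> stain suppression -> spatial aggregation head.

Two ablation switches mirror the component analysis the architecture is built
around: ``use_sda=False`` feeds raw backbone tokens straight to the head, and
``use_stc=False`` replaces the spatial head with plain mean pooling plus a
linear softmax classifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .backbone import MiniBackbone, grid_coords
from .nn import Tensor, Module, Linear, softmax
from .spatial_head import SpatialHead
from .stain_suppression import StainSuppression

__all__ = ["ModelConfig", "MeanPoolHead", "OsccClassifier"]


@dataclass
class ModelConfig:
    backbone_channels: tuple[int, int, int] = (16, 32, 32)
    head_dim: int = 128
    head_depth: int = 2
    head_radius: float = 1.5
    pe: str = "sinusoidal"
    renormalize: bool = False
    sda_window: int = 7
    use_sda: bool = True
    use_stc: bool = True
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["backbone_channels"] = tuple(d["backbone_channels"])
        return cls(**d)


class MeanPoolHead(Module):
    """Unstructured aggregation baseline: token mean -> linear -> softmax."""

    def __init__(self, in_channels: int, n_classes: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.classifier = Linear(in_channels, n_classes, rng)

    def forward(self, fused: Tensor, coords: np.ndarray) -> Tensor:
        return softmax(self.classifier(fused.mean(axis=-2)), axis=-1)


class OsccClassifier(Module):
    """End-to-end Normal-vs-OSCC image classifier on token features."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        self.backbone = MiniBackbone(channels=cfg.backbone_channels, seed=cfg.seed)
        c = self.backbone.channels
        if cfg.use_sda:
            self.sda = StainSuppression(c, window=cfg.sda_window, seed=cfg.seed + 1)
        else:
            self.sda = None
        if cfg.use_stc:
            self.head = SpatialHead(
                c, dim=cfg.head_dim, depth=cfg.head_depth, radius=cfg.head_radius,
                pe=cfg.pe, renormalize=cfg.renormalize, seed=cfg.seed + 2,
            )
        else:
            self.head = MeanPoolHead(c, seed=cfg.seed + 2)

    def forward(self, images: Tensor) -> Tensor:
        """(B, H, W, 3) images -> (B, 2) class probabilities (column 1 = OSCC)."""
        feats = self.backbone(images)  # (B, Gh, Gw, C)
        B, gh, gw, c = feats.shape
        tokens = feats.reshape(B, gh * gw, c)
        if self.sda is not None:
            tokens = self.sda(tokens, (gh, gw))
        return self.head(tokens, grid_coords(gh, gw))

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Forward pass over an (M, H, W, 3) array; returns (M, 2) probabilities."""
        images = np.asarray(images, dtype=np.float64)
        out = []
        for start in range(0, len(images), batch_size):
            probs = self.forward(Tensor(images[start : start + batch_size]))
            out.append(probs.numpy())
        return np.concatenate(out, axis=0)

    # ---- checkpoint (de)serialisation ------------------------------------
    def save(self, path: str, extra: dict | None = None) -> None:
        payload = {f"param/{k}": v for k, v in self.state_dict().items()}
        meta = {"config": asdict(self.config), "extra": extra or {}}
        payload["meta_json"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str) -> tuple["OsccClassifier", dict]:
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["meta_json"]).decode("utf-8"))
            state = {
                k[len("param/"):]: archive[k] for k in archive.files
                if k.startswith("param/")
            }
        cfg = meta["config"]
        cfg["backbone_channels"] = tuple(cfg["backbone_channels"])
        model = cls(ModelConfig(**cfg))
        model.load_state_dict(state)
        return model, meta.get("extra", {})
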