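"""Manifest-driven dataset loading.

A dataset on disk is a directory of PNG/JPEG files plus a manifest CSV with
at least ``path`` and ``label`` columns (labels either the strings
``Normal``/``OSCC`` or the integers 0/1) and optionally ``split``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import load_image, resize_and_normalize

__all__ = ["LABEL_NAMES", "read_manifest", "load_dataset"]

LABEL_NAMES = {0: "Normal", 1: "OSCC"}
_NAME_TO_LABEL = {"normal": 0, "oscc": 1, "0": 0, "1": 1}


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV; labels are normalised to integers (1 = OSCC)."""
    manifest = pd.read_csv(path)
    missing = {"path", "label"} - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {sorted(missing)}")
    labels = []
    for raw in manifest["label"]:
        key = str(raw).strip().lower()
        if key not in _NAME_TO_LABEL:
            raise ValueError(f"unrecognised label {raw!r}; expected Normal/OSCC or 0/1")
        labels.append(_NAME_TO_LABEL[key])
    manifest = manifest.copy()
    manifest["label"] = labels
    return manifest


def load_dataset(
    manifest: pd.DataFrame,
    root: str | Path,
    side: int | None = None,
    mean=(0.5, 0.5, 0.5),
    std=(0.5, 0.5, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Load, optionally resize, and standardise all images in a manifest.

    Returns (images (M, side, side, 3), labels (M,)).
    """
    root = Path(root)
    images = []
    for rel in manifest["path"]:
        img = load_image(str(root / rel))
        if side is not None:
            img = resize_and_normalize(img, side=side, mean=mean, std=std)
        else:
            img = (img - np.asarray(mean)) / np.asarray(std)
        images.append(img)
    return np.stack(images), manifest["label"].to_numpy(dtype=int)
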