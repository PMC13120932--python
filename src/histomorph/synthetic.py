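"""Synthetic histology-like image generator with controllable stain confounding.

The generator produces two classes of small RGB images whose *label is carried
by morphology alone*: class 1 ("OSCC-like") tiles contain many irregular
nuclei, class 0 ("normal-like") tiles contain few, rounder nuclei.  On top of
the morphology, each image is assigned a *stain domain* — a per-channel affine
transform applied in optical-density space (Beer-Lambert: OD = -log I), the
space in which real H&E staining variation is approximately multiplicative.

Because the label is a deterministic function of the rendered nuclei count and
the stain transform carries no morphological information, a colour-blind
classifier can always solve the task.  The ``confound`` parameter rho controls
how strongly domain and label correlate within a split (rho = 0: independent;
rho = 1: domain determines label), which makes stain-shortcut learning
directly measurable: train with a strong confound, test with none, and any
accuracy gap is colour reliance.

Determinism: a dataset is a pure function of (spec, seed); per-image RNG
streams are spawned from a single seed sequence, and images are quantised to
the 8-bit grid before being returned or written, so in-memory arrays and PNG
files agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "ClassMorphology",
    "MorphologySpec",
    "DomainStyle",
    "SyntheticDatasetSpec",
    "DEFAULT_DOMAINS",
    "HELDOUT_DOMAINS",
    "render_image",
    "apply_style",
    "generate_dataset",
    "shifted_test_set",
    "save_dataset",
]


@dataclass(frozen=True)
class ClassMorphology:
    """Nuclei statistics for one class."""

    nuclei_count_range: tuple[int, int]  # inclusive
    nucleus_radius: tuple[float, float]  # (mean, sd) in pixels
    boundary_irregularity: float  # >= 0, relative radius modulation


@dataclass(frozen=True)
class MorphologySpec:
    """Morphology parameters for both classes plus shared background texture.

    Defaults: the OSCC-like class has 2-3x the nuclear density of the
    normal-like class and markedly more irregular nuclear boundaries, the two
    morphological axes pathologists actually read; the count ranges are
    disjoint so the nuclei count alone determines the label.
    """

    normal: ClassMorphology = ClassMorphology((5, 10), (3.5, 0.5), 0.15)
    oscc: ClassMorphology = ClassMorphology((18, 28), (3.0, 0.6), 0.6)
    background_texture_scale: float = 4.0  # pixels

    def __post_init__(self):
        n, o = self.normal, self.oscc
        if n.nuclei_count_range == o.nuclei_count_range and \
           n.boundary_irregularity == o.boundary_irregularity and \
           n.nucleus_radius == o.nucleus_radius:
            raise ValueError("the two classes must differ on at least one axis")
        if n.nuclei_count_range[1] >= o.nuclei_count_range[0]:
            raise ValueError("nuclei count ranges must be disjoint (label = count threshold)")

    def for_label(self, label: int) -> ClassMorphology:
        return self.oscc if label == 1 else self.normal

    @property
    def count_threshold(self) -> float:
        """Label = 1 iff nuclei count >= this midpoint."""
        return 0.5 * (self.normal.nuclei_count_range[1] + self.oscc.nuclei_count_range[0])


@dataclass(frozen=True)
class DomainStyle:
    """Per-channel affine stain transform in optical-density space."""

    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    domain_id: int = 0

    def __post_init__(self):
        if any(g <= 0 for g in self.gain):
            raise ValueError("OD gains must be positive")

    @property
    def is_identity(self) -> bool:
        return self.gain == (1.0, 1.0, 1.0) and self.offset == (0.0, 0.0, 0.0)

    def inverse_apply(self, image: np.ndarray) -> np.ndarray:
        od = -np.log(np.clip(image, 1e-4, 1.0))
        od = (od - np.asarray(self.offset)) / np.asarray(self.gain)
        return np.exp(-np.clip(od, 0.0, None))


# Two moderately different staining protocols (hematoxylin-lean vs eosin-lean),
# the scale of drift seen between scanner/reagent batches.
DEFAULT_DOMAINS: tuple[DomainStyle, ...] = (
    DomainStyle(gain=(1.18, 0.88, 1.06), offset=(0.03, 0.0, 0.01), domain_id=0),
    DomainStyle(gain=(0.86, 1.12, 0.94), offset=(0.0, 0.04, 0.0), domain_id=1),
)

# Styles never used by DEFAULT_DOMAINS, for held-out-domain evaluation.
HELDOUT_DOMAINS: tuple[DomainStyle, ...] = (
    DomainStyle(gain=(1.05, 1.22, 0.90), offset=(0.02, 0.01, 0.04), domain_id=100),
    DomainStyle(gain=(0.92, 0.84, 1.20), offset=(0.05, 0.02, 0.0), domain_id=101),
)


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Full recipe for one dataset: counts, morphology, domains, confound, seed."""

    n_per_class: tuple[int, int] = (100, 100)
    image_side: int = 64
    domains: tuple[DomainStyle, ...] = DEFAULT_DOMAINS
    confound: float = 0.0  # rho in [-1, 1]: label-domain correlation
    seed: int = 0
    morphology: MorphologySpec = field(default_factory=MorphologySpec)
    split_ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)

    def __post_init__(self):
        if sum(self.n_per_class) < 2:
            raise ValueError("need at least two images")
        if not -1.0 <= self.confound <= 1.0:
            raise ValueError("confound rho must lie in [-1, 1]")
        if abs(self.confound) > 0 and len(self.domains) != 2:
            raise ValueError(
                "a nonzero label-domain confound requires exactly two domains; "
                "achievable range with more domains is rho = 0 only"
            )


def apply_style(image: np.ndarray, style: DomainStyle) -> np.ndarray:
    """Apply the stain transform in OD space; exact identity for the identity style."""
    if style.is_identity:
        return image.copy()
    od = -np.log(np.clip(image, 1e-4, 1.0))
    od = np.asarray(style.gain) * od + np.asarray(style.offset)
    return np.exp(-od)


def _quantize(image: np.ndarray) -> np.ndarray:
    """Snap to the 8-bit grid so in-memory and PNG round trips agree exactly."""
    return np.round(np.clip(image, 0.0, 1.0) * 255.0) / 255.0


def render_image(
    morph: MorphologySpec,
    style: DomainStyle,
    label: int,
    rng: np.random.Generator,
    side: int = 64,
) -> tuple[np.ndarray, int]:
    """Render one tile; returns (image in [0,1], nuclei count statistic).

    The returned count determines the label via ``morph.count_threshold``.
    """
    cls = morph.for_label(label)
    lo, hi = cls.nuclei_count_range
    count = int(rng.integers(lo, hi + 1))
    r_mean, r_sd = cls.nucleus_radius
    max_r = r_mean + 3 * r_sd
    if count * np.pi * max_r**2 > 0.9 * side * side:
        raise ValueError(
            f"cannot place {count} nuclei of radius ~{r_mean} on a {side}x{side} canvas"
        )

    # eosin-pink textured background
    base = np.array([0.91, 0.79, 0.86])
    tex = gaussian_filter(rng.normal(0.0, 1.0, (side, side)),
                          morph.background_texture_scale)
    tex = tex / (np.abs(tex).max() + 1e-9) * 0.04
    img = np.clip(base[None, None, :] + tex[:, :, None], 0.0, 1.0)

    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    nucleus_color = np.array([0.32, 0.22, 0.50])  # hematoxylin purple
    for _ in range(count):
        r0 = max(1.5, rng.normal(r_mean, r_sd))
        cy = rng.uniform(max_r, side - max_r)
        cx = rng.uniform(max_r, side - max_r)
        a2, a3 = rng.uniform(0.4, 1.0, size=2)
        p2, p3 = rng.uniform(0.0, 2 * np.pi, size=2)
        dy, dx = yy - cy, xx - cx
        dist = np.sqrt(dy**2 + dx**2)
        theta = np.arctan2(dy, dx)
        r_theta = r0 * (
            1.0 + cls.boundary_irregularity * 0.5 * (a2 * np.sin(2 * theta + p2)
                                                     + a3 * np.sin(3 * theta + p3))
        )
        alpha = np.clip((r_theta - dist + 0.8) / 1.6, 0.0, 1.0)  # soft edge
        shade = nucleus_color * rng.uniform(0.85, 1.1)
        img = img * (1 - alpha[:, :, None]) + shade[None, None, :] * alpha[:, :, None]

    img = _quantize(np.clip(img, 0.0, 1.0))
    img = _quantize(apply_style(img, style))
    return img, count


def _domain_counts(n: int, n_domains: int, matched: int, rho: float) -> list[int]:
    """Images of one class per domain, honouring the confound rho."""
    if rho == 0.0:
        base = [n // n_domains] * n_domains
        for i in range(n % n_domains):
            base[i] += 1
        return base
    p_matched = (1.0 + rho) / 2.0
    m = int(round(n * p_matched))
    counts = [0, 0]
    counts[matched] = m
    counts[1 - matched] = n - m
    return counts


def _sample_rows(spec: SyntheticDatasetSpec, split_tag: str | None,
                 seed: int, prefix: str) -> tuple[np.ndarray, pd.DataFrame]:
    ss = np.random.SeedSequence(seed)
    images, rows = [], []
    idx = 0
    for label, n in enumerate(spec.n_per_class):
        matched = label % len(spec.domains)
        per_domain = _domain_counts(n, len(spec.domains), matched, spec.confound)
        for d_idx, n_d in enumerate(per_domain):
            style = spec.domains[d_idx]
            for _ in range(n_d):
                rng = np.random.default_rng(ss.spawn(1)[0])
                img, stat = render_image(spec.morphology, style, label, rng,
                                         side=spec.image_side)
                assert (stat >= spec.morphology.count_threshold) == bool(label)
                images.append(img)
                rows.append({
                    "path": f"{prefix}{idx:05d}.png",
                    "label": label,
                    "domain": style.domain_id,
                    "stat": stat,
                    "split": split_tag,
                })
                idx += 1
    manifest = pd.DataFrame(rows)
    return np.stack(images), manifest


def _assign_splits(manifest: pd.DataFrame, ratios: tuple[float, float, float],
                   seed: int) -> pd.DataFrame:
    """Stratified 7:1:2-style split within each (label, domain) cell.

    Per-cell rounding: round for train and val, remainder to test — so class
    proportions (and the label-domain confound) carry into every split.
    """
    rng = np.random.default_rng(seed)
    manifest = manifest.copy()
    for (_, _), cell in manifest.groupby(["label", "domain"]):
        idx = cell.index.to_numpy()
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(ratios[0] * n))
        n_val = int(round(ratios[1] * n))
        tags = ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)
        manifest.loc[idx, "split"] = tags
    return manifest


def generate_dataset(spec: SyntheticDatasetSpec,
                     out_dir: str | Path | None = None
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate a dataset with exact per-class counts and the requested confound.

    Returns the image stack (M, side, side, 3) and a manifest with columns
    ``path,label,domain,stat,split``.  If `out_dir` is given, PNGs and
    ``manifest.csv`` are also written there.
    """
    images, manifest = _sample_rows(spec, None, spec.seed, prefix="img_")
    manifest = _assign_splits(manifest, spec.split_ratios, spec.seed)
    if out_dir is not None:
        save_dataset(images, manifest, out_dir)
    return images, manifest


def shifted_test_set(
    spec: SyntheticDatasetSpec,
    mode: str = "decorrelate",
    n_per_class: tuple[int, int] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw a fresh test set whose stain-label association differs from training.

    Modes: ``decorrelate`` (rho = 0 over the training domains), ``invert``
    (rho = -rho_train) and ``holdout`` (rho = 0 over domain styles never seen
    in training).  Morphology parameters are unchanged.
    """
    if mode == "decorrelate":
        new = replace(spec, confound=0.0)
    elif mode == "invert":
        new = replace(spec, confound=-spec.confound)
    elif mode == "holdout":
        new = replace(spec, confound=0.0, domains=HELDOUT_DOMAINS)
    else:
        raise ValueError(f"unknown shift mode {mode!r}")
    if n_per_class is not None:
        new = replace(new, n_per_class=tuple(n_per_class))
    images, manifest = _sample_rows(new, "test", spec.seed + 777_001, prefix="test_")
    if out_dir is not None:
        save_dataset(images, manifest, out_dir)
    return images, manifest


def save_dataset(images: np.ndarray, manifest: pd.DataFrame,
                 out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for img, path in zip(images, manifest["path"]):
        arr = np.uint8(np.round(img * 255.0))
        Image.fromarray(arr).save(out_dir / path)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
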