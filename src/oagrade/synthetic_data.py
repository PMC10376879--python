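"""Synthetic 4-class feature tables and toy stained images.

Emulates the fused deep-feature representation used for osteoarthritis
grading: 20 features (4 descriptors from each of 5 pseudo-backbones), four
ordered severity classes, and a controllable amount of class separation.

Class means sit on a one-dimensional "severity axis" embedded in the
informative dimensions, so feature importance and weight-recovery behaviour
can be tested against a known ground truth.  Noise features are pure
zero-mean Gaussians.  No claim of histological realism is made for the toy
images; they exist to exercise the image-manifest / extractor plumbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .core_io import FeatureTable, Grade, SpecimenRecord, StainType

__all__ = ["SyntheticSpec", "generate_features", "generate_toy_images",
           "irregularity_amplitude", "DEFAULT_BACKBONES"]

DEFAULT_BACKBONES = ("darknet19", "mobilenet", "nasnet", "resnet101", "shufflenet")


def _default_backbone_assignment(n_features: int) -> list[str]:
    """Tag features round-block: 4 consecutive features per pseudo-backbone."""
    per_block = 4
    names = []
    for j in range(n_features):
        backbone = DEFAULT_BACKBONES[(j // per_block) % len(DEFAULT_BACKBONES)]
        names.append(backbone)
    return names


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the Gaussian 4-class feature generator.

    ``separation`` is the Euclidean distance between adjacent class means,
    measured in the informative subspace, in units of ``noise_sd``.
    Informative feature
    indices are spread evenly across the feature vector (hence across
    pseudo-backbones) so that selection is non-trivial.
    """

    n_per_class: int = 40
    n_informative: int = 4
    n_noise: int = 16
    separation: float = 4.0
    noise_sd: float = 1.0
    backbone_assignment: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.n_informative < 1 or self.n_noise < 0:
            raise ValueError("need n_informative >= 1 and n_noise >= 0")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if (self.backbone_assignment is not None
                and len(self.backbone_assignment) != self.n_features):
            raise ValueError("backbone_assignment length must equal total feature count")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_noise

    @property
    def informative_indices(self) -> np.ndarray:
        """Evenly spaced column indices carrying the severity signal."""
        return np.unique(np.linspace(0, self.n_features - 1, self.n_informative).round()
                         .astype(int))

    def backbones(self) -> list[str]:
        if self.backbone_assignment is not None:
            return list(self.backbone_assignment)
        return _default_backbone_assignment(self.n_features)


def class_means(spec: SyntheticSpec) -> np.ndarray:
    """Per-class mean vectors (4 x n_features) implied by the spec.

    Grade g lies at ``g * separation * noise_sd`` along the unit severity
    axis spread uniformly over the informative dimensions, so adjacent class
    means are exactly ``separation`` noise-SDs apart in the informative
    subspace; noise dimensions stay at zero for every class.
    """
    means = np.zeros((len(Grade), spec.n_features))
    info = spec.informative_indices
    axis = np.zeros(spec.n_features)
    axis[info] = 1.0 / math.sqrt(len(info))
    for g in Grade:
        means[g.value] = g.value * spec.separation * spec.noise_sd * axis
    return means


def generate_features(spec: SyntheticSpec, stain: StainType = StainType.HE) -> FeatureTable:
    """Draw a balanced 4-class Gaussian feature table; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    means = class_means(spec)
    rows, labels, ids = [], [], []
    for g in Grade:
        block = rng.normal(loc=means[g.value], scale=spec.noise_sd,
                           size=(spec.n_per_class, spec.n_features))
        rows.append(block)
        labels.extend([g.value] * spec.n_per_class)
        ids.extend(f"{stain.value}_{g.label}_{i:03d}" for i in range(spec.n_per_class))

    backbones = spec.backbones()
    counts: dict[str, int] = {}
    names = []
    for b in backbones:
        counts[b] = counts.get(b, 0) + 1
        names.append(f"{b}_f{counts[b]}")

    return FeatureTable(
        values=np.vstack(rows),
        feature_names=names,
        feature_backbone=backbones,
        labels=np.asarray(labels),
        stain=stain,
        ids=ids,
    )


# ---------------------------------------------------------------------------
# Toy stained images
# ---------------------------------------------------------------------------

_STAIN_BASE = {
    StainType.HE: (200, 150, 180),    # pinkish eosin-like background
    StainType.SAFO: (220, 120, 90),   # orange safranin-like background
}


def irregularity_amplitude(grade: Grade, size: int) -> float:
    """Surface-irregularity amplitude (pixels), strictly increasing with grade."""
    return (grade.value + 1) * size / 16.0


def generate_toy_images(
    spec: SyntheticSpec,
    out_dir: str | Path,
    size: int = 64,
    stain: StainType = StainType.HE,
) -> list[SpecimenRecord]:
    """Render deterministic toy cartilage images under ``out_dir``.

    Each image shows a tissue block whose top "articular surface" is a sine
    profile with grade-indexed amplitude and whose interior holds dark cell
    dots with grade-indexed density; layout is the ``<stain>/<grade>/<id>``
    manifest dialect.
    """
    if size < 64:
        raise ValueError("size must be >= 64 pixels")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    base = np.array(_STAIN_BASE[stain], dtype=float)
    records: list[SpecimenRecord] = []
    yy = np.arange(size)[:, None]
    xx = np.arange(size)[None, :]
    for g in Grade:
        grade_dir = out_dir / stain.value / g.label
        grade_dir.mkdir(parents=True, exist_ok=True)
        amp = irregularity_amplitude(g, size)
        n_dots = 5 * (g.value + 1)
        for i in range(spec.n_per_class):
            phase = rng.uniform(0, 2 * np.pi)
            freq = rng.uniform(2, 5)
            surface = size / 4 + amp * np.sin(freq * 2 * np.pi * xx / size + phase)
            img = np.full((size, size, 3), 245.0)
            tissue = yy >= surface
            img[tissue] = base + rng.normal(0, 6, size=(size, size, 3))[tissue]
            for _ in range(n_dots):
                cy = rng.integers(size // 3, size - 4)
                cx = rng.integers(4, size - 4)
                r = rng.integers(1, 3)
                mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
                img[mask] = (60, 40, 90)
            img = np.clip(img, 0, 255).astype(np.uint8)
            rec_id = f"{stain.value}_{g.label}_{i:03d}"
            path = grade_dir / f"{rec_id}.png"
            Image.fromarray(img).save(path)
            records.append(SpecimenRecord(id=rec_id, stain=stain, grade=g,
                                          image_path=str(path)))
    return records
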