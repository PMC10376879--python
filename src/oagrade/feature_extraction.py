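"""Backbone feature-extractor contract and block fusion.

Each registered backbone maps one image to a 4-value class-descriptor block
(one value per severity level, mirroring a 4-way final fully connected
layer); the blocks from several backbones are concatenated column-wise into
a fused feature table.

Only the deterministic ``mock`` extractor ships with the package: it resizes
the image, downsamples to an 8x8 grey patch, and applies a fixed Gaussian
random projection seeded from the backbone name.  Real pretrained networks
(DarkNet-19, MobileNet, NasNet, ResNet-101, ShuffleNet) are plug-ins: any
callable taking an (H, W, 3) float array and returning a length-4 vector can
be registered under one of those names.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from PIL import Image

from .core_io import FeatureTable, Grade, SpecimenRecord, StainType

__all__ = [
    "ExtractorSpec",
    "BackboneFeatureBlock",
    "register_backbone",
    "registered_backbones",
    "extract_block",
    "fuse_blocks",
    "mock_projection",
    "KNOWN_BACKBONES",
]

N_GRADE_OUTPUTS = len(Grade)  # each backbone emits one descriptor per severity level

KNOWN_BACKBONES = ("darknet19", "mobilenet", "nasnet", "resnet101", "shufflenet", "mock")

_PATCH = 8  # mock extractor downsampling resolution (8x8 grey)

ExtractorFn = Callable[[np.ndarray], np.ndarray]

_REGISTRY: dict[str, ExtractorFn] = {}


@dataclass(frozen=True)
class ExtractorSpec:
    """Which backbone to run and at what input geometry."""

    backbone_name: str
    input_size: tuple[int, int, int] = (224, 224, 3)
    n_outputs: int = N_GRADE_OUTPUTS

    def __post_init__(self) -> None:
        if self.n_outputs != N_GRADE_OUTPUTS:
            raise ValueError(f"extractors emit one value per grade ({N_GRADE_OUTPUTS})")
        if len(self.input_size) != 3 or self.input_size[2] != 3:
            raise ValueError("input_size must be (height, width, 3)")


@dataclass
class BackboneFeatureBlock:
    """4-column descriptor block from a single backbone."""

    backbone_name: str
    values: np.ndarray          # (n_samples, 4)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_GRADE_OUTPUTS:
            raise ValueError("a backbone block has exactly 4 columns")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("one row per sample id required")


def register_backbone(name: str, fn: ExtractorFn) -> None:
    """Register (or replace) an extractor callable under ``name``."""
    _REGISTRY[name] = fn


def registered_backbones() -> list[str]:
    return sorted(_REGISTRY)


def mock_projection(backbone_name: str) -> np.ndarray:
    """Fixed (4 x 64) Gaussian projection matrix derived from the name alone."""
    seed = zlib.crc32(backbone_name.encode()) % (2 ** 31)
    rng = np.random.default_rng(seed)
    return rng.standard_normal((N_GRADE_OUTPUTS, _PATCH * _PATCH))


def _mock_extractor(pixels: np.ndarray, backbone_name: str = "mock") -> np.ndarray:
    """Project the 8x8 grey-mean downsampling of ``pixels`` to 4 descriptors."""
    grey = pixels.mean(axis=2)
    h, w = grey.shape
    patch = grey[: h - h % _PATCH, : w - w % _PATCH]
    patch = patch.reshape(_PATCH, patch.shape[0] // _PATCH,
                          _PATCH, patch.shape[1] // _PATCH).mean(axis=(1, 3))
    return mock_projection(backbone_name) @ (patch.ravel() / 255.0)


register_backbone("mock", _mock_extractor)


def _load_resized(record: SpecimenRecord, spec: ExtractorSpec) -> np.ndarray:
    if record.image_path is None:
        raise FileNotFoundError(f"specimen {record.id!r} carries no image path")
    try:
        with Image.open(record.image_path) as img:
            img = img.convert("RGB")
            h, w, _ = spec.input_size
            img = img.resize((w, h), resample=Image.BILINEAR)
            return np.asarray(img, dtype=float)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image for specimen {record.id!r}: "
                      f"{record.image_path} ({exc})") from exc


def extract_block(records: Sequence[SpecimenRecord], spec: ExtractorSpec) -> BackboneFeatureBlock:
    """Run one backbone over a manifest, preserving sample order."""
    if spec.backbone_name not in _REGISTRY:
        raise KeyError(
            f"backbone {spec.backbone_name!r} is not registered; registered: "
            f"{registered_backbones()} (use register_backbone() to plug in a "
            f"pretrained network)")
    fn = _REGISTRY[spec.backbone_name]
    values = np.empty((len(records), N_GRADE_OUTPUTS))
    for i, rec in enumerate(records):
        pixels = _load_resized(rec, spec)
        if fn is _mock_extractor:
            vec = _mock_extractor(pixels, spec.backbone_name)
        else:
            vec = np.asarray(fn(pixels), dtype=float)
        if vec.shape != (N_GRADE_OUTPUTS,):
            raise ValueError(f"backbone {spec.backbone_name!r} returned shape "
                             f"{vec.shape}, expected ({N_GRADE_OUTPUTS},)")
        values[i] = vec
    return BackboneFeatureBlock(
        backbone_name=spec.backbone_name,
        values=values,
        sample_ids=[r.id for r in records],
    )


def fuse_blocks(
    blocks: Sequence[BackboneFeatureBlock],
    labels: Iterable[Grade] | np.ndarray,
    stain: StainType,
    ids: Sequence[str] | None = None,
) -> FeatureTable:
    """Concatenate backbone blocks column-wise into a fused FeatureTable.

    All blocks must cover the same samples in the same order; five blocks of
    four descriptors give the standard 20-feature fused representation.
    """
    if not blocks:
        raise ValueError("need at least one block to fuse")
    ref_ids = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref_ids:
            raise ValueError(
                f"blocks cover different samples: {b.backbone_name!r} does not "
                f"match {blocks[0].backbone_name!r}")
    label_codes = np.asarray([g.value if isinstance(g, Grade) else int(g)
                              for g in labels])
    names, backbones = [], []
    for b in blocks:
        for j in range(N_GRADE_OUTPUTS):
            names.append(f"{b.backbone_name}_f{j + 1}")
            backbones.append(b.backbone_name)
    return FeatureTable(
        values=np.hstack([b.values for b in blocks]),
        feature_names=names,
        feature_backbone=backbones,
        labels=label_codes,
        stain=stain,
        ids=list(ids) if ids is not None else list(ref_ids),
    )
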