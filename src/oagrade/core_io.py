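"""Domain types and I/O for osteoarthritis histopathology feature tables.

The central container is :class:`FeatureTable`: one row per specimen image,
one column per deep-feature descriptor, each column tagged with the backbone
network that produced it, plus an ordinal OA grade per row and a single stain
tag (H&E or Safranin-O) per table.

Grades follow the OARSI total-score convention: a specimen's averaged OARSI
score (0-24) is banded into four ordered severity levels.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "Grade",
    "StainType",
    "SpecimenRecord",
    "FeatureTable",
    "SplitSpec",
    "grade_from_oarsi",
    "read_feature_table",
    "write_feature_table",
    "read_image_manifest",
    "stratified_split",
    "FeatureTableError",
]

OARSI_MAX = 24.0

#: Lower edges of the four severity bands on the OARSI total-score axis.
#: Bands are half-open with the lower band winning at shared edges:
#: early [0, 3.4), mild [3.4, 8.6), moderate [8.6, 15.4), severe [15.4, 24].
_BAND_EDGES = (3.4, 8.6, 15.4)


class FeatureTableError(ValueError):
    """Raised for malformed feature-table files or inconsistent tables."""


class Grade(enum.IntEnum):
    """Ordinal OA severity grade; the integer value encodes the order."""

    EARLY = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Grade":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise FeatureTableError(f"unknown grade label {label!r}; "
                                    f"expected one of {[g.label for g in cls]}") from None


class StainType(enum.Enum):
    """Histological stain of a specimen image."""

    HE = "HE"       # hematoxylin & eosin: nuclei / extracellular proteins
    SAFO = "SafO"   # safranin O + fast green: glycosaminoglycans

    @classmethod
    def from_label(cls, label: str) -> "StainType":
        for stain in cls:
            if label.strip().lower() == stain.value.lower():
                return stain
        raise FeatureTableError(f"unknown stain {label!r}; expected 'HE' or 'SafO'")


def grade_from_oarsi(score: float) -> Grade:
    """Band an averaged OARSI total score (0-24) into a severity grade.

    The published band edges overlap (early "< 3.4" vs mild "2.4-8.6"); this
    implementation resolves edges deterministically with half-open bands in
    which the lower band wins, so the mapping is a total, monotone
    non-decreasing step function on [0, 24].
    """
    score = float(score)
    if not (0.0 <= score <= OARSI_MAX):
        raise ValueError(f"OARSI score must lie in [0, {OARSI_MAX}], got {score}")
    for grade, edge in zip(Grade, _BAND_EDGES):
        if score < edge:
            return grade
    return Grade.SEVERE


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen image with its stain, grade and optional provenance."""

    id: str
    stain: StainType
    grade: Grade
    oarsi_score: float | None = None
    image_path: str | None = None

    def __post_init__(self) -> None:
        if self.oarsi_score is not None:
            banded = grade_from_oarsi(self.oarsi_score)
            if banded is not self.grade:
                raise ValueError(
                    f"specimen {self.id!r}: grade {self.grade.label} inconsistent with "
                    f"OARSI score {self.oarsi_score} (bands to {banded.label})")


@dataclass
class FeatureTable:
    """Specimen-by-feature matrix with grade labels and backbone provenance.

    ``feature_backbone[j]`` names the backbone network that produced column
    ``j``.  A fully fused table has 20 columns: 4 class descriptors from each
    of 5 backbones.
    """

    values: np.ndarray
    feature_names: list[str]
    feature_backbone: list[str]
    labels: np.ndarray          # Grade codes, one per row
    stain: StainType
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise FeatureTableError("values must be a 2-D matrix")
        n, p = self.values.shape
        if not self.ids:
            self.ids = [f"s{i}" for i in range(n)]
        if len(self.labels) != n or len(self.ids) != n:
            raise FeatureTableError("labels/ids length must equal the number of rows")
        if len(self.feature_names) != p or len(self.feature_backbone) != p:
            raise FeatureTableError("feature_names/feature_backbone must match column count")
        if len(set(self.feature_names)) != p:
            dupes = {f for f in self.feature_names if self.feature_names.count(f) > 1}
            raise FeatureTableError(f"duplicated feature name(s): {sorted(dupes)}")
        if np.isnan(self.values).any():
            r, c = np.argwhere(np.isnan(self.values))[0]
            raise FeatureTableError(
                f"missing value at row {r} ({self.ids[r]!r}), column {self.feature_names[c]!r}")
        if not np.isin(self.labels, [g.value for g in Grade]).all():
            raise FeatureTableError("labels must be Grade codes 0-3")

    # -- convenience ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def grades(self) -> list[Grade]:
        return [Grade(code) for code in self.labels]

    def backbone_of(self) -> dict[int, str]:
        return dict(enumerate(self.feature_backbone))

    def select_features(self, indices: Sequence[int]) -> "FeatureTable":
        """Column subset (by position), preserving provenance and labels."""
        idx = list(indices)
        return FeatureTable(
            values=self.values[:, idx],
            feature_names=[self.feature_names[j] for j in idx],
            feature_backbone=[self.feature_backbone[j] for j in idx],
            labels=self.labels.copy(),
            stain=self.stain,
            ids=list(self.ids),
        )

    def select_rows(self, indices: Sequence[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            feature_backbone=list(self.feature_backbone),
            labels=self.labels[idx],
            stain=self.stain,
            ids=[self.ids[i] for i in idx],
        )

    def with_values(self, values: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            values=values,
            feature_names=list(self.feature_names),
            feature_backbone=list(self.feature_backbone),
            labels=self.labels.copy(),
            stain=self.stain,
            ids=list(self.ids),
        )

    def equals(self, other: "FeatureTable", rtol: float = 1e-10, atol: float = 1e-12) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.values, other.values, rtol=rtol, atol=atol)
            and self.feature_names == other.feature_names
            and self.feature_backbone == other.feature_backbone
            and np.array_equal(self.labels, other.labels)
            and self.stain is other.stain
            and self.ids == other.ids
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition parameters (the study itself does not fix these)."""

    test_fraction: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# CSV dialect: columns id,label,stain,<backbone>_f<j>,...
# ---------------------------------------------------------------------------

_FEATURE_NAME_RE = re.compile(r"^(?P<backbone>[A-Za-z0-9]+)_f(?P<j>\d+)$")

_META_COLUMNS = ("id", "label", "stain")


def _backbone_from_name(name: str) -> str:
    m = _FEATURE_NAME_RE.match(name)
    return m.group("backbone") if m else "unknown"


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table in the package CSV dialect (17 significant digits)."""
    frame = pd.DataFrame(table.values, columns=table.feature_names)
    frame.insert(0, "stain", table.stain.value)
    frame.insert(0, "label", [g.label for g in table.grades()])
    frame.insert(0, "id", table.ids)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> FeatureTable:
    """Read a delimited feature table.

    ``schema`` optionally remaps the metadata column names, e.g.
    ``{"id": "specimen", "label": "grade", "stain": "dye"}``.  Feature
    columns are every remaining column; backbone provenance is parsed from
    names of the form ``<backbone>_f<j>``.
    """
    path = Path(path)
    colmap = {key: key for key in _META_COLUMNS}
    if schema:
        colmap.update(schema)

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise FeatureTableError(f"{path.name}: duplicated column {name!r}")
        seen.add(name)

    frame = pd.read_csv(path)
    for key in _META_COLUMNS:
        if colmap[key] not in frame.columns:
            raise FeatureTableError(f"{path.name}: missing required column {colmap[key]!r}")

    feature_cols = [c for c in frame.columns if c not in set(colmap.values())]
    if not feature_cols:
        raise FeatureTableError(f"{path.name}: no feature columns found")

    values = frame[feature_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise FeatureTableError(
            f"{path.name}: missing value at row {r} column {feature_cols[c]!r}")

    labels = []
    for r, raw in enumerate(frame[colmap["label"]]):
        try:
            labels.append(Grade.from_label(str(raw)).value)
        except FeatureTableError as exc:
            raise FeatureTableError(f"{path.name}: row {r}: {exc}") from None

    stains = {StainType.from_label(str(s)) for s in frame[colmap["stain"]]}
    if len(stains) != 1:
        raise FeatureTableError(
            f"{path.name}: a feature table must carry exactly one stain, found "
            f"{sorted(s.value for s in stains)}")

    return FeatureTable(
        values=values,
        feature_names=feature_cols,
        feature_backbone=[_backbone_from_name(c) for c in feature_cols],
        labels=np.asarray(labels),
        stain=stains.pop(),
        ids=[str(i) for i in frame[colmap["id"]]],
    )


_IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def read_image_manifest(root: str | Path) -> list[SpecimenRecord]:
    """Scan a ``<stain>/<grade>/<id>.<ext>`` directory layout into records."""
    root = Path(root)
    records: list[SpecimenRecord] = []
    for stain_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        stain = StainType.from_label(stain_dir.name)
        for grade_dir in sorted(p for p in stain_dir.iterdir() if p.is_dir()):
            grade = Grade.from_label(grade_dir.name)
            for img in sorted(grade_dir.iterdir()):
                if img.suffix.lower() in _IMAGE_EXTENSIONS:
                    records.append(SpecimenRecord(
                        id=img.stem, stain=stain, grade=grade, image_path=str(img)))
    return records


def stratified_split(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Partition a table into disjoint, exhaustive train/test subsets.

    Stratification keeps per-class test counts within one sample of
    ``round(test_fraction * class_size)``; identical seeds give identical
    partitions.
    """
    counts = np.bincount(table.labels, minlength=len(Grade))
    present = counts[counts > 0]
    if (present < 2).any():
        bad = [Grade(g).label for g in np.flatnonzero((counts > 0) & (counts < 2))]
        raise ValueError(f"every class needs >= 2 samples to split; too few in {bad}")
    indices = np.arange(table.n_samples)
    train_idx, test_idx = train_test_split(
        indices,
        test_size=spec.test_fraction,
        random_state=spec.seed,
        shuffle=True,
        stratify=table.labels if spec.stratified else None,
    )
    return table.select_rows(np.sort(train_idx)), table.select_rows(np.sort(test_idx))
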