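import numpy as np
import pytest

from oagrade.core_io import FeatureTable, StainType
from oagrade.synthetic_data import SyntheticSpec, generate_features


@pytest.fixture
def small_table() -> FeatureTable:
    """Balanced 4-class, 10-feature table with a clear severity signal."""
    return generate_features(
        SyntheticSpec(n_per_class=10, n_informative=4, n_noise=6,
                      separation=6.0, seed=42))


@pytest.fixture
def random_table() -> FeatureTable:
    """Structureless 20-feature table (separation 0)."""
    return generate_features(
        SyntheticSpec(n_per_class=10, separation=0.0, seed=7))


def make_table(values: np.ndarray, labels=None,
               stain: StainType = StainType.HE) -> FeatureTable:
    """Wrap a raw matrix into a FeatureTable with generic metadata."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if labels is None:
        labels = np.zeros(n, dtype=int)
    return FeatureTable(
        values=values,
        feature_names=[f"b_f{j + 1}" for j in range(p)],
        feature_backbone=["b"] * p,
        labels=np.asarray(labels, dtype=int),
        stain=stain,
    )
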