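"""PCA-based selection of a ranked subset of original features.

The procedure standardizes each feature to zero mean / unit sample variance,
eigendecomposes the sample covariance (= correlation) matrix, retains the
leading components reaching 95% cumulative explained variance, and scores
every *original* feature by the variance-weighted magnitude of its loadings
on the retained *structured* components:

    importance_j = sum_m (lambda_m / sum(lambda)) * |L_{jm}|

where m runs over retained components whose eigenvalue exceeds the
Marchenko-Pastur upper edge (1 + sqrt(p/n))^2 of a pure-noise correlation
spectrum.  Summing |loadings| over *all* retained components would be
dominated by features that spread mass across the many sampling-noise
components (their eigenvalues scatter in roughly [ (1-sqrt(p/n))^2,
(1+sqrt(p/n))^2 ] even for fully independent features), drowning the signal
concentrated in the leading components; the edge threshold keeps exactly
the components that carry more variance than sampling noise can explain.
If no retained component clears the edge the sum falls back to components
with eigenvalue > 1, then to all retained components.

The top-k features (k = 10 by default) form the selected subset that is
passed downstream; classification therefore operates on original features,
not on component scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np

from .core_io import FeatureTable

__all__ = ["PCAModel", "SelectionResult", "standardize", "fit_pca",
           "rank_features", "select_features", "selection_report"]


@dataclass
class PCAModel:
    """Standardization constants plus the covariance eigensystem."""

    means: np.ndarray
    sds: np.ndarray
    eigenvalues: np.ndarray       # non-increasing, length p
    loadings: np.ndarray          # (p, p), orthonormal columns
    n_retained: int
    variance_target: float
    n_samples: int = 0            # fitting sample count (0 = unknown)

    @property
    def noise_edge(self) -> float:
        """Marchenko-Pastur upper eigenvalue edge for a pure-noise spectrum."""
        p = self.loadings.shape[0]
        if self.n_samples <= 0:
            return 1.0
        return (1.0 + (p / self.n_samples) ** 0.5) ** 2

    @property
    def explained_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def cumulative_fraction(self) -> np.ndarray:
        return np.cumsum(self.explained_fraction)


@dataclass
class SelectionResult:
    """Top-k original features ranked by retained-component importance."""

    selected_indices: list[int]          # sorted by descending importance
    importance_scores: np.ndarray        # one per original feature
    composition: dict[str, int]          # backbone name -> count among selected
    feature_names: list[str]


def standardize(table: FeatureTable) -> tuple[FeatureTable, np.ndarray, np.ndarray]:
    """Zero-mean / unit-sample-variance scale each feature column.

    Raises on zero-variance features by default: dividing by zero is
    undefined, and a constant descriptor signals an extraction bug upstream.
    """
    means = table.values.mean(axis=0)
    sds = table.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [table.feature_names[j] for j in zero]
        raise ValueError(f"zero-variance feature(s): {names}; drop them before PCA")
    return table.with_values((table.values - means) / sds), means, sds


def apply_standardization(table: FeatureTable, means: np.ndarray,
                          sds: np.ndarray) -> FeatureTable:
    """Apply previously fitted standardization constants (e.g. to a test split)."""
    return table.with_values((table.values - means) / sds)


def fit_pca(standardized: FeatureTable, variance_target: float = 0.95,
            means: np.ndarray | None = None,
            sds: np.ndarray | None = None) -> PCAModel:
    """Eigendecompose the sample covariance of a standardized table.

    ``n_retained`` is the smallest m whose cumulative explained-variance
    fraction reaches ``variance_target``.  Loading-column signs are fixed so
    the largest-magnitude entry of each is positive (pure convention:
    eigenvectors are defined up to sign).
    """
    n, p = standardized.values.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must lie in (0, 1]")
    cov = np.cov(standardized.values, rowvar=False, ddof=1).reshape(p, p)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    loadings = eigenvectors[:, order]
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    cumulative = np.cumsum(eigenvalues) / eigenvalues.sum()
    n_retained = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
    return PCAModel(
        means=means if means is not None else np.zeros(p),
        sds=sds if sds is not None else np.ones(p),
        eigenvalues=eigenvalues,
        loadings=loadings,
        n_retained=n_retained,
        variance_target=variance_target,
        n_samples=n,
    )


def rank_features(model: PCAModel, backbone_map: dict[int, str] | list[str],
                  k: int = 10) -> SelectionResult:
    """Score original features by variance-weighted |loadings| on the
    structured retained components (eigenvalues above the noise edge; see
    module docstring).

    Ties break toward the lower column index so the ranking is deterministic.
    """
    p = model.loadings.shape[0]
    if k > p:
        raise ValueError(f"cannot select k={k} from {p} features")
    retained = np.arange(model.n_retained)
    structured = retained[model.eigenvalues[retained] > model.noise_edge]
    if structured.size == 0:
        structured = retained[model.eigenvalues[retained] > 1.0]
    if structured.size == 0:
        structured = retained
    fractions = model.explained_fraction[structured]
    importance = np.abs(model.loadings[:, structured]) @ fractions
    # stable sort on (-importance, index): lower index wins ties
    order = np.lexsort((np.arange(p), -importance))
    selected = [int(j) for j in order[:k]]
    backbones = ([backbone_map[j] for j in range(p)]
                 if isinstance(backbone_map, dict) else list(backbone_map))
    composition: dict[str, int] = {}
    for j in selected:
        composition[backbones[j]] = composition.get(backbones[j], 0) + 1
    return SelectionResult(
        selected_indices=selected,
        importance_scores=importance,
        composition=composition,
        feature_names=[f"feature_{j}" for j in selected],
    )


def select_features(table: FeatureTable, variance_target: float = 0.95,
                    k: int = 10) -> tuple[FeatureTable, PCAModel, SelectionResult]:
    """Standardize, fit PCA, and return the top-k original-feature subset."""
    standardized, means, sds = standardize(table)
    model = fit_pca(standardized, variance_target, means=means, sds=sds)
    result = rank_features(model, table.feature_backbone, k=k)
    result.feature_names = [table.feature_names[j] for j in result.selected_indices]
    return table.select_features(result.selected_indices), model, result


def selection_report(model: PCAModel, result: SelectionResult) -> str:
    """Human-readable report: variance spectrum and per-backbone composition."""
    out = StringIO()
    out.write("PCA feature selection\n")
    out.write(f"components retained: {model.n_retained} "
              f"(target {model.variance_target:.0%}, reached "
              f"{model.cumulative_fraction[model.n_retained - 1]:.4f})\n")
    out.write("eigenvalue fractions: "
              + ", ".join(f"{f:.4f}" for f in model.explained_fraction) + "\n")
    out.write(f"selected {len(result.selected_indices)} features "
              "(descending importance):\n")
    for rank, j in enumerate(result.selected_indices, start=1):
        out.write(f"  {rank:2d}. {result.feature_names[rank - 1]} "
                  f"(column {j}, importance {result.importance_scores[j]:.6f})\n")
    out.write("composition by backbone:\n")
    for backbone in sorted(result.composition):
        n = result.composition[backbone]
        out.write(f"  {n} feature{'s' if n != 1 else ''} from {backbone}\n")
    return out.getvalue()
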