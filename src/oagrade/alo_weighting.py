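"""Ant lion optimization of joint feature weights + k-NN neighbour count.

The decision vector holds one multiplicative weight per feature (in [0, 1],
applied as new_feature = weight * old_feature) plus one continuous
coordinate that decodes to an odd k for the k-nearest-neighbour fitness
classifier.  The loss minimized is 1 - stratified cross-validated k-NN
accuracy on the weighted features, evaluated on the training split only.

The optimizer is the canonical ant lion algorithm: ants perform cumulative
+/-1 random walks that are min-max normalized into bounds centred on a
roulette-selected antlion and on the elite ("king") antlion, the bounds
shrink over iterations by the ratio I = 1 + 10^w * t/T, each ant position is
the mean of its two walks, antlions are replaced by fitter ants, and the
best-ever candidate (the elite) is always retained — so the elite loss trace
is non-increasing by construction.

Because the fitness sits in the optimizer's inner loop, the k-NN
cross-validation is computed on cached per-feature squared-difference
matrices: with weights w the squared weighted Euclidean distance is
sum_j w_j^2 * (x_ij - x_kj)^2, a single tensor contraction per candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core_io import FeatureTable, Grade

__all__ = [
    "ALOConfig", "Candidate", "ALOTrace", "WeightedSolution",
    "apply_weights", "knn_cv_loss", "KnnCvFitness",
    "random_walk", "roulette_select", "alo_minimize", "alo_optimize",
    "weight_report", "trace_to_csv", "plot_convergence",
]

_EPS = 1e-12  # guards 1/loss in roulette weights

#: default boundary-shrink schedule: exponent w as a function of progress t/T
DEFAULT_SHRINK_SCHEDULE = ((0.10, 2.0), (0.50, 3.0), (0.75, 4.0),
                           (0.90, 5.0), (0.95, 6.0))


@dataclass(frozen=True)
class ALOConfig:
    """Optimizer knobs; defaults are desk-scale canonical choices."""

    n_ants: int = 20
    n_antlions: int = 20
    max_iterations: int = 100
    k_max: int = 15
    cv_folds: int = 5
    seed: int = 0
    shrink_schedule: tuple[tuple[float, float], ...] = DEFAULT_SHRINK_SCHEDULE

    def __post_init__(self) -> None:
        if self.n_ants < 2 or self.n_antlions < 2:
            raise ValueError("need at least 2 ants and 2 antlions")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class Candidate:
    """One evaluated decision vector."""

    weights: np.ndarray
    k: int
    loss: float


@dataclass
class ALOTrace:
    """Elite loss (and elite candidate) per iteration."""

    elite_loss_per_iteration: np.ndarray
    elite_history: list[Candidate]


@dataclass
class WeightedSolution:
    """Optimized per-feature weights plus the best neighbour count."""

    weights: np.ndarray
    k: int
    final_loss: float


# ---------------------------------------------------------------------------
# Fitness: weighted k-NN cross-validated accuracy
# ---------------------------------------------------------------------------

def apply_weights(table: FeatureTable, weights: Sequence[float]) -> FeatureTable:
    """Scale feature column j by weights[j] (labels/provenance unchanged)."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (table.n_features,):
        raise ValueError(f"expected {table.n_features} weights, got {w.shape}")
    if (w < 0).any() or (w > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    return table.with_values(table.values * w)


class KnnCvFitness:
    """Cached stratified-CV k-NN loss for candidate (weights, k) vectors.

    Folds are fixed once from (labels, seed); each evaluation contracts the
    cached per-feature squared-difference tensor with the squared weights and
    classifies every held-out sample by majority vote among its k nearest
    within-training-fold neighbours (vote ties break toward the lower grade).
    """

    def __init__(self, table: FeatureTable, folds: int = 5, seed: int = 0):
        y = table.labels
        counts = np.bincount(y, minlength=len(Grade))
        present = counts[counts > 0]
        if (present < folds).any():
            raise ValueError(f"every class needs >= {folds} samples for "
                             f"{folds}-fold CV; class counts {counts.tolist()}")
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        self.folds = [(np.asarray(tr), np.asarray(te))
                      for tr, te in splitter.split(np.zeros(len(y)), y)]
        self.min_train = min(len(tr) for tr, _ in self.folds)
        x = table.values
        # (p, n, n) squared per-feature differences
        self._sqdiff = (x[None, :, :].transpose(2, 1, 0) - x.T[:, None, :]) ** 2
        self.labels = y
        self.n_features = table.n_features

    def __call__(self, weights: np.ndarray, k: int) -> float:
        k = int(k)
        if k < 1 or k > self.min_train:
            raise ValueError(f"k={k} exceeds the smallest training fold "
                             f"({self.min_train}) or is < 1")
        w2 = np.asarray(weights, dtype=float) ** 2
        dist = np.tensordot(w2, self._sqdiff, axes=1)   # (n, n)
        correct = 0
        total = 0
        for train_idx, test_idx in self.folds:
            block = dist[np.ix_(test_idx, train_idx)]
            nearest = np.argpartition(block, k - 1, axis=1)[:, :k]
            votes = self.labels[train_idx][nearest]                # (n_test, k)
            counts = (votes[:, :, None] == np.arange(len(Grade))).sum(axis=1)
            pred = counts.argmax(axis=1)                           # ties -> lower grade
            correct += int((pred == self.labels[test_idx]).sum())
            total += len(test_idx)
        return 1.0 - correct / total


def knn_cv_loss(table: FeatureTable, weights: Sequence[float], k: int,
                folds: int = 5, seed: int = 0) -> float:
    """1 - mean stratified-CV accuracy of weighted Euclidean k-NN."""
    fitness = KnnCvFitness(table, folds=folds, seed=seed)
    return fitness(np.asarray(weights, dtype=float), k)


# ---------------------------------------------------------------------------
# Canonical ALO primitives
# ---------------------------------------------------------------------------

def random_walk(n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Cumulative +/-1 walk of length n_steps + 1 starting at 0."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    steps = rng.integers(0, 2, size=n_steps) * 2 - 1
    return np.concatenate([[0.0], np.cumsum(steps, dtype=float)])


def roulette_select(fitness_losses: Sequence[float], rng: np.random.Generator) -> int:
    """Draw an index with probability proportional to 1/(loss + eps)."""
    losses = np.asarray(fitness_losses, dtype=float)
    if losses.size == 0:
        raise ValueError("cannot select from an empty candidate set")
    weights = 1.0 / (losses + _EPS)
    return int(rng.choice(losses.size, p=weights / weights.sum()))


def _shrink_exponent(progress: float,
                     schedule: tuple[tuple[float, float], ...]) -> float | None:
    w = None
    for threshold, exponent in schedule:
        if progress > threshold:
            w = exponent
    return w


def _walk_around(centre: np.ndarray, lo_t: np.ndarray, hi_t: np.ndarray,
                 t: int, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Min-max-normalize per-dimension walks into bounds centred on ``centre``.

    Sign flips on each bound mirror the canonical formulation; min-max
    normalization handles inverted intervals transparently.
    """
    d = centre.size
    lo = centre + lo_t if rng.random() < 0.5 else centre - lo_t
    hi = centre + hi_t if rng.random() < 0.5 else centre - hi_t
    steps = rng.integers(0, 2, size=(d, n_steps)) * 2 - 1
    walks = np.concatenate([np.zeros((d, 1)), np.cumsum(steps, axis=1)], axis=1)
    wmin = walks.min(axis=1)
    span = walks.max(axis=1) - wmin
    span[span == 0] = 1.0
    scaled = (walks[:, t] - wmin) * (hi - lo) / span + lo
    return scaled


def alo_minimize(
    loss_fn: Callable[[np.ndarray], float],
    lower: np.ndarray,
    upper: np.ndarray,
    config: ALOConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize ``loss_fn`` over the box [lower, upper] with canonical ALO.

    Returns (elite position, elite loss, per-iteration elite-loss trace).
    Exposed separately from the feature-weighting wrapper so alternative
    objectives (benchmark functions, plugged-in fitnesses) can reuse it.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = lower.size
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = config.max_iterations

    antlions = rng.uniform(lower, upper, size=(config.n_antlions, d))
    antlion_loss = np.array([loss_fn(a) for a in antlions])
    order = np.argsort(antlion_loss, kind="stable")
    antlions, antlion_loss = antlions[order], antlion_loss[order]
    elite = antlions[0].copy()
    elite_loss = float(antlion_loss[0])

    trace = np.empty(T)
    for t in range(1, T + 1):
        progress = t / T
        w = _shrink_exponent(progress, config.shrink_schedule)
        ratio = 1.0 if w is None else 1.0 + (10.0 ** w) * progress
        lo_t, hi_t = lower / ratio, upper / ratio

        ants = np.empty((config.n_ants, d))
        for i in range(config.n_ants):
            j = roulette_select(antlion_loss, rng)
            walk_trap = _walk_around(antlions[j], lo_t, hi_t, t, T, rng)
            walk_elite = _walk_around(elite, lo_t, hi_t, t, T, rng)
            ants[i] = np.clip((walk_trap + walk_elite) / 2.0, lower, upper)
        ant_loss = np.array([loss_fn(a) for a in ants])

        merged = np.vstack([antlions, ants])
        merged_loss = np.concatenate([antlion_loss, ant_loss])
        keep = np.argsort(merged_loss, kind="stable")[: config.n_antlions]
        antlions, antlion_loss = merged[keep], merged_loss[keep]

        if antlion_loss[0] < elite_loss:
            elite, elite_loss = antlions[0].copy(), float(antlion_loss[0])
        antlions[0], antlion_loss[0] = elite, elite_loss
        trace[t - 1] = elite_loss

    return elite, elite_loss, trace


# ---------------------------------------------------------------------------
# Feature-weighting wrapper
# ---------------------------------------------------------------------------

def decode_k(coordinate: float, k_max: int) -> int:
    """Round a continuous [1, k_max] coordinate to the nearest odd integer."""
    k = int(2 * round((float(coordinate) - 1.0) / 2.0) + 1)
    hi_odd = k_max if k_max % 2 == 1 else k_max - 1
    return int(np.clip(k, 1, hi_odd))


def alo_optimize(table: FeatureTable, config: ALOConfig | None = None,
                 ) -> tuple[WeightedSolution, ALOTrace]:
    """Jointly optimize per-feature weights and odd k against the k-NN loss.

    The fitness is stratified CV on ``table`` only; call this on the training
    split and apply the returned weights unchanged to held-out data.
    """
    config = config or ALOConfig()
    fitness = KnnCvFitness(table, folds=config.cv_folds, seed=config.seed)
    k_hi = min(config.k_max, fitness.min_train)
    p = table.n_features
    lower = np.concatenate([np.zeros(p), [1.0]])
    upper = np.concatenate([np.ones(p), [float(k_hi)]])

    def loss_fn(vec: np.ndarray) -> float:
        return fitness(vec[:p], decode_k(vec[p], k_hi))

    rng = np.random.default_rng(config.seed)
    elite, elite_loss, loss_trace = alo_minimize(loss_fn, lower, upper, config, rng)

    solution = WeightedSolution(weights=elite[:p].copy(),
                                k=decode_k(elite[p], k_hi),
                                final_loss=float(elite_loss))
    history = [Candidate(weights=solution.weights, k=solution.k, loss=float(l))
               for l in loss_trace]
    return solution, ALOTrace(elite_loss_per_iteration=loss_trace,
                              elite_history=history)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def weight_report(solution: WeightedSolution, feature_names: Sequence[str]) -> str:
    """Weighted-sum expression over the selected features, plus k and loss."""
    terms = " + ".join(f"{w:.6f}*{name}"
                       for w, name in zip(solution.weights, feature_names))
    out = StringIO()
    out.write("ALO-optimized feature weighting\n")
    out.write(f"y = {terms}\n")
    out.write(f"k (nearest neighbours) = {solution.k}\n")
    out.write(f"final fitness loss (1 - CV accuracy) = {solution.final_loss:.6f}\n")
    return out.getvalue()


def trace_to_csv(trace: ALOTrace) -> str:
    lines = ["iteration,elite_loss"]
    lines += [f"{i + 1},{loss:.10f}"
              for i, loss in enumerate(trace.elite_loss_per_iteration)]
    return "\n".join(lines) + "\n"


def plot_convergence(trace: ALOTrace, path: str) -> None:
    """Elite loss vs iteration, in the style of a convergence diagnostic."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(np.arange(1, len(trace.elite_loss_per_iteration) + 1),
            trace.elite_loss_per_iteration, lw=1.5)
    ax.set_xlabel("iteration")
    ax.set_ylabel("elite loss (1 - CV accuracy)")
    ax.set_title("ALO convergence")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
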