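"""Relief and multiclass ReliefF instance-based feature weighting.

Relief scores each feature by how well it separates an instance from its
nearest neighbor of another class (near miss) relative to its nearest
neighbor of the same class (near hit): a good feature differs across the
class boundary and agrees within it.  ReliefF generalizes this to k
neighbors and multiple classes: for a sampled instance x of class y, the
weight of feature f is updated by

    w_f  +=  - mean_{h in kNN hits} diff(f, x, h)
             + sum_{c != y} P(c)/(1 - P(y)) * mean_{m in kNN misses of c} diff(f, x, m)

averaged over sampled instances, where diff is the range-normalized
absolute difference and P(c) the empirical class prior.  With full
deterministic sampling (every instance once) the weights are exact
functions of the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrix import LabeledMatrix

__all__ = ["FeatureWeights", "relieff_weights", "rank_features"]

logger = logging.getLogger(__name__)

DEFAULT_K = 10


@dataclass
class FeatureWeights:
    """Per-feature Relief weights; each lies in [-1, 1]."""

    weights: np.ndarray
    k_neighbors: int
    n_iterations: int
    seed: int
    feature_ids: list[str] = field(default_factory=list)

    def write_tsv(self, path) -> None:
        order = np.lexsort((np.arange(len(self.weights)), -self.weights))
        ranks = np.empty(len(self.weights), dtype=int)
        ranks[order] = np.arange(1, len(self.weights) + 1)
        ids = self.feature_ids or [f"f{i}" for i in range(len(self.weights))]
        with open(path, "w") as fh:
            fh.write("feature_id\tweight\trank\n")
            for fid, w, r in zip(ids, self.weights, ranks):
                fh.write(f"{fid}\t{w:.10g}\t{r}\n")


def _normalized(values: np.ndarray) -> np.ndarray:
    """Min-max scale each feature (row) to [0, 1]; constant rows become 0,
    so they contribute nothing to distances or diffs."""
    lo = values.min(axis=1, keepdims=True)
    span = values.max(axis=1, keepdims=True) - lo
    out = np.zeros_like(values, dtype=float)
    np.divide(values - lo, span, out=out, where=span > 0)
    return out


def relieff_weights(
    data: LabeledMatrix,
    k: int = DEFAULT_K,
    n_iterations: int | str = "all",
    seed: int = 0,
) -> FeatureWeights:
    """Compute ReliefF feature weights.

    Parameters
    ----------
    data
        Labeled matrix; at least two classes.
    k
        Neighbors per hit/miss set.  Capped (with a warning) at the
        smallest class size minus one so every instance has k hits.
    n_iterations
        ``"all"`` visits every instance once, deterministically (the
        default); an integer samples that many instances without
        replacement per pass using ``seed``.
    """
    if data.labels is None:
        raise ValueError("ReliefF requires class labels")
    labels = data.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ReliefF requires at least 2 classes (no misses exist)")
    min_class = classes[np.argmin(counts)]
    min_size = int(counts.min())
    if k >= min_size:
        if min_size - 1 < 1:
            raise ValueError(
                f"class {min_class!r} has {min_size} member(s); "
                f"k={k} nearest hits are not available"
            )
        logger.warning(
            "k=%d >= smallest class size %d (class %r); capping k at %d",
            k, min_size, min_class, min_size - 1,
        )
        k = min_size - 1
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")

    X = _normalized(data.values)  # features x samples, in [0,1]
    n = data.n_samples
    m = data.n_features
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    if n_iterations == "all":
        sample_idx = np.arange(n)
    else:
        n_iterations = int(n_iterations)
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1 or 'all'")
        rng = np.random.default_rng(seed)
        reps, rem = divmod(n_iterations, n)
        parts = [rng.permutation(n) for _ in range(reps)]
        if rem:
            parts.append(rng.permutation(n)[:rem])
        sample_idx = np.concatenate(parts) if parts else np.arange(0)

    # pairwise Manhattan distances on the normalized features
    dist = np.zeros((n, n))
    for f in range(m):
        dist += np.abs(X[f][:, None] - X[f][None, :])

    class_members = {c: np.flatnonzero(labels == c) for c in classes}

    weights = np.zeros(m)
    for i in sample_idx:
        y = labels[i]
        for c in classes:
            members = class_members[c][class_members[c] != i]
            # neighbor ties at equal distance resolved by ascending index
            order = members[np.lexsort((members, dist[i, members]))][:k]
            diffs = np.abs(X[:, order] - X[:, [i]]).mean(axis=1)
            if c == y:
                weights -= diffs
            else:
                weights += priors[c] / (1.0 - priors[y]) * diffs

    weights /= len(sample_idx)
    n_it = len(sample_idx)
    return FeatureWeights(
        weights=weights,
        k_neighbors=k,
        n_iterations=n_it,
        seed=seed,
        feature_ids=list(data.feature_ids),
    )


def rank_features(weights: FeatureWeights, n_select: int):
    """Indices of the ``n_select`` largest weights, descending; ties broken
    by ascending feature index.  Returns (indices, scores)."""
    w = np.asarray(weights.weights, dtype=float)
    if not 1 <= n_select <= len(w):
        raise ValueError(f"n_select must be in [1, {len(w)}], got {n_select}")
    order = np.lexsort((np.arange(len(w)), -w))[:n_select]
    return order, w[order]
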