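import numpy as np
import pytest

from nmfrelieff import LabeledMatrix, SyntheticSpec, simulate


@pytest.fixture
def planted_small():
    """50-feature, 40-sample matrix with 2 strongly informative features."""
    spec = SyntheticSpec(
        n_features=50, n_samples=40, n_informative=2, effect_size=10.0,
        count_model="negbinom", seed=1,
    )
    return simulate(spec)


@pytest.fixture
def tiny_labeled():
    """Deterministic 3-feature, 6-sample two-class matrix."""
    values = np.array(
        [
            [0.0, 0.1, 0.2, 0.8, 0.9, 1.0],
            [0.3, 0.9, 0.1, 0.7, 0.2, 0.5],
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
        ]
    )
    labels = np.array(["A", "A", "A", "B", "B", "B"])
    return LabeledMatrix(values, labels=labels)


def brute_relieff(X, labels, k):
    """Independent ReliefF oracle: explicit neighbor lists and diff sums.

    Full deterministic sampling, min-max normalized Manhattan distance,
    neighbor ties broken by ascending sample index.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    lo = X.min(axis=1)
    span = X.max(axis=1) - lo
    Xn = np.zeros_like(X)
    for f in range(m):
        if span[f] > 0:
            Xn[f] = (X[f] - lo[f]) / span[f]
    labels = list(labels)
    classes = sorted(set(labels))
    priors = {c: labels.count(c) / n for c in classes}
    w = np.zeros(m)
    for i in range(n):
        y = labels[i]
        for c in classes:
            cand = [j for j in range(n) if labels[j] == c and j != i]
            cand.sort(key=lambda j: (sum(abs(Xn[f][i] - Xn[f][j]) for f in range(m)), j))
            near = cand[:k]
            for f in range(m):
                d = sum(abs(Xn[f][i] - Xn[f][j]) for j in near) / len(near)
                if c == y:
                    w[f] -= d
                else:
                    w[f] += priors[c] / (1 - priors[y]) * d
    return w / n
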