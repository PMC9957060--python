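"""Feature selectors: NMF-ReliefF and the three comparison methods.

The headline method factorizes the nonnegative data matrix V ~ W H and
scores the r metagene encodings (rows of H) with ReliefF, so that the
class-relevance of each latent component is measured in sample space.
Two output modes are exposed:

* ``component`` — return the top-n metagene indices themselves;
* ``gene`` — map component relevance back onto the original features via

      score(f) = sum_j max(w_j, 0) * W[f, j] / ||W[:, j]||_1

  i.e. each component distributes its (positive) ReliefF weight over the
  features in proportion to their share of the component's basis column,
  and the top-n original features are returned.  This is what lets the
  method name concrete gene families.

Baselines: plain ReliefF on the raw features, PCA-ReliefF (ReliefF on
principal-component scores) and SVM-RFE (backward elimination by linear
SVM weight magnitude), optionally pre-filtered by an mRMR
(minimum-redundancy maximum-relevance) mutual-information ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import mutual_info_score
from sklearn.svm import SVC

from .matrix import LabeledMatrix
from .nmf import nmf_factorize
from .relieff import DEFAULT_K, relieff_weights, rank_features

__all__ = [
    "SelectionResult",
    "nmf_relieff_select",
    "relieff_select",
    "pca_relieff_select",
    "svm_rfe_select",
    "default_rank",
    "SELECTOR_NAMES",
]

SELECTOR_NAMES = ("nmf_relieff", "relieff", "pca_relieff", "svm_rfe")


@dataclass
class SelectionResult:
    """Ordered selected features with scores and full provenance."""

    method: str
    selected: np.ndarray  # ordered feature (or component) indices
    scores: np.ndarray  # score per selected entry, same order
    params: dict = field(default_factory=dict)
    feature_ids: list[str] = field(default_factory=list)
    component_weights: Optional[np.ndarray] = None  # ReliefF weights per latent component

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.selected) != len(set(self.selected.tolist())):
            raise ValueError("selected indices must be unique")

    def write_tsv(self, path) -> None:
        """Write ``rank\\tfeature_id\\tscore`` rows."""
        with open(path, "w") as fh:
            fh.write("rank\tfeature_id\tscore\n")
            for r, (idx, score) in enumerate(zip(self.selected, self.scores), start=1):
                fid = self.feature_ids[r - 1] if self.feature_ids else f"f{idx}"
                fh.write(f"{r}\t{fid}\t{score:.10g}\n")


def default_rank(data: LabeledMatrix) -> int:
    """Factorization rank used when none is given: min(50, min(m, n) - 1)."""
    return max(1, min(50, min(data.n_features, data.n_samples) - 1))


def _h_as_matrix(H: np.ndarray, data: LabeledMatrix, prefix: str) -> LabeledMatrix:
    return LabeledMatrix(
        H,
        [f"{prefix}{j}" for j in range(H.shape[0])],
        list(data.sample_ids),
        data.labels.copy(),
    )


def nmf_relieff_select(
    data: LabeledMatrix,
    rank: int | None = None,
    k: int = DEFAULT_K,
    n_select: int = 50,
    mode: str = "gene",
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SelectionResult:
    """Select features by ReliefF scoring of NMF metagene encodings.

    Requires nonnegative data (shift expression matrices first, e.g. via
    :meth:`LabeledMatrix.shifted_nonnegative`) and per-sample labels.
    """
    if mode not in ("component", "gene"):
        raise ValueError(f"mode must be 'component' or 'gene', got {mode!r}")
    if data.labels is None:
        raise ValueError("NMF-ReliefF requires class labels")
    if not data.is_nonnegative():
        raise ValueError(
            "data contains negative entries; NMF-ReliefF requires nonnegative "
            "input — shift to zero first or use the relieff/pca_relieff/svm_rfe baselines"
        )
    if rank is None:
        rank = default_rank(data)
    if mode == "component" and rank < n_select:
        raise ValueError(
            f"component mode selects among {rank} components; n_select={n_select} exceeds the rank"
        )

    factors = nmf_factorize(data, rank=rank, max_iter=max_iter, tol=tol, seed=seed)
    h_data = _h_as_matrix(factors.H, data, "component")
    fw = relieff_weights(h_data, k=k, n_iterations="all", seed=seed)
    w = fw.weights

    params = {
        "rank": rank,
        "k": fw.k_neighbors,
        "n_select": n_select,
        "mode": mode,
        "seed": seed,
        "nmf_iterations": factors.iterations_run,
        "nmf_final_error": factors.final_error,
    }

    if mode == "component":
        sel, scores = rank_features(fw, n_select)
        ids = [f"component{j}" for j in sel]
        return SelectionResult("nmf_relieff", sel, scores, params, ids, component_weights=w)

    # gene mode: distribute each component's positive relevance over the
    # basis column, normalized to unit column sum
    col_mass = factors.W.sum(axis=0)  # L1 norm; W >= 0
    safe = np.where(col_mass > 0, col_mass, 1.0)
    gene_scores = (factors.W / safe) @ np.maximum(w, 0.0)
    if not 1 <= n_select <= data.n_features:
        raise ValueError(f"n_select must be in [1, {data.n_features}], got {n_select}")
    order = np.lexsort((np.arange(len(gene_scores)), -gene_scores))[:n_select]
    ids = [data.feature_ids[i] for i in order]
    return SelectionResult(
        "nmf_relieff", order, gene_scores[order], params, ids, component_weights=w
    )


def relieff_select(
    data: LabeledMatrix,
    k: int = DEFAULT_K,
    n_select: int = 50,
    seed: int = 0,
) -> SelectionResult:
    """Plain ReliefF on the raw features."""
    fw = relieff_weights(data, k=k, n_iterations="all", seed=seed)
    sel, scores = rank_features(fw, n_select)
    ids = [data.feature_ids[i] for i in sel]
    params = {"k": fw.k_neighbors, "n_select": n_select, "seed": seed}
    return SelectionResult("relieff", sel, scores, params, ids)


def pca_relieff_select(
    data: LabeledMatrix,
    n_components: int | None = None,
    k: int = DEFAULT_K,
    n_select: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """ReliefF ranking of principal-component scores.

    Samples are projected onto the leading principal components of the
    centered data (ordered by explained variance; each component's
    largest-magnitude loading made positive for a deterministic sign),
    then the component score vectors are ReliefF-weighted and the top
    ``n_select`` components returned.
    """
    if data.labels is None:
        raise ValueError("PCA-ReliefF requires class labels")
    max_comp = min(data.n_features, data.n_samples)
    if n_components is None:
        n_components = min(max_comp - 1 if max_comp > 1 else 1, 50)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    if not 1 <= n_select <= n_components:
        raise ValueError(f"n_select must be in [1, {n_components}], got {n_select}")

    pca = PCA(n_components=n_components, svd_solver="full")
    scores_sn = pca.fit_transform(data.values.T)  # samples x components
    components = pca.components_  # components x features
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(components[np.arange(n_components), np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores_sn = scores_sn * flip

    comp_data = LabeledMatrix(
        scores_sn.T,
        [f"pc{j + 1}" for j in range(n_components)],
        list(data.sample_ids),
        data.labels.copy(),
    )
    fw = relieff_weights(comp_data, k=k, n_iterations="all", seed=seed)
    sel, sel_scores = rank_features(fw, n_select)
    ids = [f"pc{j + 1}" for j in sel]
    params = {
        "n_components": n_components,
        "k": fw.k_neighbors,
        "n_select": n_select,
        "seed": seed,
    }
    return SelectionResult("pca_relieff", sel, sel_scores, params, ids, component_weights=fw.weights)


# ---------------------------------------------------------------------------
# SVM-RFE with optional mRMR pre-filter


def _discretize_equal_frequency(x: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Equal-frequency binning by rank; constant vectors map to one bin."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(x))
    return (ranks * n_bins // len(x)).astype(int)


def _mrmr_scores(X: np.ndarray, labels: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Relevance minus mean redundancy, from discretized mutual information.

    X is features x samples.  Relevance is I(feature; label); redundancy
    is the mean I(feature_i; feature_j) over the other features.
    """
    m = X.shape[0]
    disc = np.stack([_discretize_equal_frequency(X[f]) for f in range(m)])
    relevance = np.array([mutual_info_score(disc[f], labels) for f in range(m)])
    if m == 1:
        return relevance
    mi = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            mi[i, j] = mi[j, i] = mutual_info_score(disc[i], disc[j])
    redundancy = mi.sum(axis=1) / (m - 1)
    return relevance - redundancy


def svm_rfe_select(
    data: LabeledMatrix,
    n_select: int = 50,
    step: int = 1,
    use_mrmr: bool = False,
    seed: int = 0,
    C: float = 1.0,
) -> SelectionResult:
    """Backward feature elimination guided by linear SVM weights.

    Repeatedly trains a linear maximum-margin classifier on the surviving
    features and removes the ``step`` features with the smallest squared
    weights until ``n_select`` remain.  With ``use_mrmr`` the features are
    first ranked by mutual-information relevance minus mean redundancy
    (3 equal-frequency bins) and the bottom half is discarded before RFE
    starts.  Binary classification only.
    """
    if data.labels is None:
        raise ValueError("SVM-RFE requires class labels")
    classes = data.classes()
    if len(classes) != 2:
        raise ValueError(f"SVM-RFE handles exactly 2 classes, got {len(classes)}")
    if step < 1:
        raise ValueError("step must be >= 1")
    m = data.n_features
    if not 1 <= n_select <= m:
        raise ValueError(f"n_select must be in [1, {m}], got {n_select}")

    y = (data.labels == classes[1]).astype(int)
    surviving = np.arange(m)

    if use_mrmr and m > 2 * n_select:
        mrmr = _mrmr_scores(data.values, y)
        keep = max(m // 2, n_select)
        order = np.lexsort((np.arange(m), -mrmr))
        surviving = np.sort(order[:keep])

    eliminated: list[np.ndarray] = []  # rounds, in elimination order
    while len(surviving) > n_select:
        clf = SVC(kernel="linear", C=C, random_state=seed)
        clf.fit(data.values[surviving].T, y)
        sq = np.ravel(clf.coef_) ** 2
        n_drop = min(step, len(surviving) - n_select)
        # smallest squared weight goes first; ties by ascending feature index
        drop_local = np.lexsort((surviving, sq))[:n_drop]
        eliminated.append(surviving[np.sort(drop_local)])
        surviving = np.delete(surviving, np.sort(drop_local))

    # rank surviving features by final SVM weight magnitude
    clf = SVC(kernel="linear", C=C, random_state=seed)
    clf.fit(data.values[surviving].T, y)
    sq = np.ravel(clf.coef_) ** 2
    order = np.lexsort((surviving, -sq))
    sel = surviving[order]
    scores = sq[order]
    ids = [data.feature_ids[i] for i in sel]
    params = {"n_select": n_select, "step": step, "use_mrmr": use_mrmr, "seed": seed, "C": C}
    res = SelectionResult("svm_rfe", sel, scores, params, ids)
    res.params["elimination_rounds"] = [e.tolist() for e in eliminated]
    return res
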