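"""Labeled feature matrices and their TSV layout.

The central container is :class:`LabeledMatrix`: a nonnegative real matrix
``V`` of shape (m features, n samples) plus feature identifiers, sample
identifiers and one class label per sample.  Every selector and the
cross-validation harness consume this object.  On disk the matrix is stored
transposed, one row per sample, because that is how gene-family count
tables are laid out: first column the sample (species) id, an optional
second column the class label, then one column per feature (family).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledMatrix"]

LABEL_COLUMN = "label"


@dataclass
class LabeledMatrix:
    """Features x samples data matrix with per-sample class labels.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_features, n_samples)``.  Columns are
        sample vectors.  NMF-based selectors additionally require every
        entry to be nonnegative; use :meth:`require_nonnegative` to check
        or :meth:`shifted_nonnegative` to enforce it.
    feature_ids, sample_ids
        Identifier per row / column.  Generated as ``f0, f1, ...`` and
        ``s0, s1, ...`` when omitted.
    labels
        One class label per sample (any hashable values; at least two
        distinct classes are required by the selectors and evaluators).
    """

    values: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (features x samples)")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("matrix must have at least one feature and one sample")
        if not self.feature_ids:
            self.feature_ids = [f"f{i}" for i in range(m)]
        if not self.sample_ids:
            self.sample_ids = [f"s{j}" for j in range(n)]
        if len(self.feature_ids) != m:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} columns")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError(f"labels has shape {self.labels.shape}, expected ({n},)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contains non-finite entries")

    # -- basic introspection -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def classes(self) -> np.ndarray:
        """Sorted distinct labels; raises if labels are absent."""
        if self.labels is None:
            raise ValueError("matrix carries no labels")
        return np.unique(self.labels)

    # -- nonnegativity -------------------------------------------------------

    def is_nonnegative(self) -> bool:
        return bool(np.all(self.values >= 0))

    def require_nonnegative(self) -> None:
        if not self.is_nonnegative():
            i, j = np.unravel_index(int(np.argmin(self.values)), self.values.shape)
            raise ValueError(
                f"matrix entry ({self.feature_ids[i]}, {self.sample_ids[j]}) = "
                f"{self.values[i, j]:g} is negative; NMF requires nonnegative input"
            )

    def shifted_nonnegative(self) -> "LabeledMatrix":
        """Return a copy with each feature shifted so its minimum is zero.

        A preprocessing convenience for expression matrices that contain
        negative intensities; count matrices pass through unchanged.
        """
        shift = np.minimum(self.values.min(axis=1, keepdims=True), 0.0)
        return LabeledMatrix(
            self.values - shift,
            list(self.feature_ids),
            list(self.sample_ids),
            None if self.labels is None else self.labels.copy(),
        )

    def subset_features(self, indices) -> "LabeledMatrix":
        idx = np.asarray(indices, dtype=int)
        return LabeledMatrix(
            self.values[idx, :],
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            None if self.labels is None else self.labels.copy(),
        )

    def subset_samples(self, indices) -> "LabeledMatrix":
        idx = np.asarray(indices, dtype=int)
        return LabeledMatrix(
            self.values[:, idx],
            list(self.feature_ids),
            [self.sample_ids[j] for j in idx],
            None if self.labels is None else self.labels[idx],
        )

    # -- TSV I/O -------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write samples-as-rows TSV: sample_id [label] feature columns."""
        df = pd.DataFrame(self.values.T, index=self.sample_ids, columns=self.feature_ids)
        df.index.name = "sample_id"
        if self.labels is not None:
            df.insert(0, LABEL_COLUMN, self.labels)
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "LabeledMatrix":
        """Read the layout written by :meth:`to_tsv`.

        A column named ``label`` (any position) is taken as the class
        label; all remaining non-index columns must be numeric features.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = None
        if LABEL_COLUMN in df.columns:
            labels = df[LABEL_COLUMN].to_numpy()
            df = df.drop(columns=[LABEL_COLUMN])
        try:
            values = df.to_numpy(dtype=float).T
        except ValueError as exc:
            raise ValueError(f"non-numeric feature column in {path}: {exc}") from exc
        return cls(values, [str(c) for c in df.columns], [str(i) for i in df.index], labels)
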