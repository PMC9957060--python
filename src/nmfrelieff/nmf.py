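"""Frobenius-norm nonnegative matrix factorization by multiplicative updates.

Factorizes a nonnegative data matrix V (m features x n samples) into
V ~ W H with W (m x r) and H (r x n) nonnegative, minimizing the squared
Frobenius reconstruction error

    min ||V - W H||_F^2   s.t.  W >= 0, H >= 0

with the classic Lee-Seung multiplicative rules

    W <- W * (V H^T) / (W H H^T)
    H <- H * (W^T V) / (W^T W H)

(* and / element-wise).  Each sweep updates W first, then H against the
new W, which makes the objective non-increasing.  Columns of W are
"metagenes"; rows of H are the corresponding per-sample encodings and are
what the NMF-ReliefF selector scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import LabeledMatrix

__all__ = ["NMFFactors", "nmf_factorize", "reconstruction_error"]

# guard against zero denominators in the multiplicative rules
_EPS = 1e-12

DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-6


@dataclass
class NMFFactors:
    """Result of one factorization run.

    ``objective_history[t]`` is the (non-squared) Frobenius error
    ``||V - W H||_F`` after ``t`` update sweeps; entry 0 is the error at
    the random initialization, and the sequence is non-increasing up to
    numerical noise.
    """

    W: np.ndarray
    H: np.ndarray
    rank: int
    objective_history: list[float] = field(default_factory=list)
    seed: int = 0
    iterations_run: int = 0

    @property
    def final_error(self) -> float:
        return self.objective_history[-1]

    def write(self, prefix) -> None:
        """Write W and H as TSV plus a JSON sidecar with run metadata."""
        prefix = Path(prefix)
        pd.DataFrame(self.W).to_csv(prefix.with_suffix(".W.tsv"), sep="\t", header=False, index=False)
        pd.DataFrame(self.H).to_csv(prefix.with_suffix(".H.tsv"), sep="\t", header=False, index=False)
        meta = {
            "rank": self.rank,
            "seed": self.seed,
            "iterations_run": self.iterations_run,
            "final_error": self.final_error,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def reconstruction_error(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Frobenius norm ||V - W H||_F (not squared)."""
    V = np.asarray(V, dtype=float)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if W.shape[1] != H.shape[0] or V.shape != (W.shape[0], H.shape[1]):
        raise ValueError(
            f"shape mismatch: V {V.shape}, W {W.shape}, H {H.shape}"
        )
    return float(np.linalg.norm(V - W @ H, "fro"))


def nmf_factorize(
    data: LabeledMatrix | np.ndarray,
    rank: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> NMFFactors:
    """Run multiplicative-update NMF from a seeded positive initialization.

    Parameters
    ----------
    data
        Nonnegative matrix (features x samples) or a :class:`LabeledMatrix`.
    rank
        Inner dimension r, ``1 <= r <= min(m, n)``.
    max_iter
        Upper bound on update sweeps.
    tol
        Stop when the relative decrease of the Frobenius error between
        sweeps falls below this; ``tol=0`` always runs ``max_iter`` sweeps.
    seed
        Seeds the Uniform(0.1, 1.1) initialization of W and H; strictly
        positive starting values avoid absorbing zeros.
    init
        Optional explicit starting factors ``(W0, H0)``; overrides the
        seeded initialization.  The multiplicative flow is
        scale-covariant: scaling V by c and both starting factors by
        sqrt(c) scales every iterate of the objective by exactly c.
    """
    if isinstance(data, LabeledMatrix):
        data.require_nonnegative()
        V = data.values
    else:
        V = np.asarray(data, dtype=float)
        if V.ndim != 2:
            raise ValueError("V must be 2-D")
        if np.any(V < 0):
            i, j = np.unravel_index(int(np.argmin(V)), V.shape)
            raise ValueError(f"V[{i},{j}] = {V[i, j]:g} is negative; NMF requires V >= 0")
    m, n = V.shape
    if not 1 <= rank <= min(m, n):
        raise ValueError(f"rank must be in [1, {min(m, n)}], got {rank}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol < 0:
        raise ValueError("tol must be >= 0")

    if init is not None:
        W = np.array(init[0], dtype=float)
        H = np.array(init[1], dtype=float)
        if W.shape != (m, rank) or H.shape != (rank, n):
            raise ValueError(
                f"init shapes {W.shape}, {H.shape} do not match ({m},{rank}), ({rank},{n})"
            )
        if np.any(W < 0) or np.any(H < 0):
            raise ValueError("init factors must be nonnegative")
    else:
        rng = np.random.default_rng(seed)
        W = rng.uniform(0.1, 1.1, size=(m, rank))
        H = rng.uniform(0.1, 1.1, size=(rank, n))

    history = [float(np.linalg.norm(V - W @ H, "fro"))]
    it = 0
    for it in range(1, max_iter + 1):
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        H *= (W.T @ V) / ((W.T @ W) @ H + _EPS)
        err = float(np.linalg.norm(V - W @ H, "fro"))
        history.append(err)
        prev = history[-2]
        if prev > 0 and (prev - err) / prev < tol:
            break

    return NMFFactors(W=W, H=H, rank=rank, objective_history=history, seed=seed, iterations_run=it)
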