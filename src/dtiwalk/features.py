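"""Low-dimensional node features and the bilinear scoring projection.

Diffusion states are compressed per node class: each node's stationary
distributions across all views are concatenated into one long row, a
smoothed elementwise log is applied (diffusion mass spans orders of
magnitude; the log makes small visiting probabilities informative rather
than negligible), columns are centered, and a truncated SVD keeps the top
``dim`` directions.  Features are the left singular vectors scaled by the
square root of the singular values, so feature inner products approximate
the log-state Gram matrix.

Drug features X (N_d x f_d) and protein features Y (N_p x f_p) are tied
together by a projection matrix Z minimizing

    || A - X Z Y^T ||_F^2 + ridge penalties on Z,

whose closed-form minimizer is Z = (X^T X + lam I)^{-1} X^T A Y
(Y^T Y + lam I)^{-1}.  Pair scores are S = X Z Y^T.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.utils.extmath import randomized_svd

from .diffusion import DiffusionState


def embed_multinetwork(
    states: Sequence[DiffusionState] | Sequence[np.ndarray],
    dim: int,
    *,
    smoothing: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Compress a list of diffusion states into N x dim node features.

    Parameters
    ----------
    states
        Diffusion states over one node class (all N x N with the same N);
        column i of each is the stationary distribution seeded at node i.
    dim
        Number of retained singular directions; at most N * len(states).
    smoothing
        Additive constant inside the log; defaults to 1/N.  Must be
        positive so the log is finite at zero mass.
    seed
        Seed for the randomized SVD, making the embedding deterministic.
    """
    mats = [s.Pi if isinstance(s, DiffusionState) else np.asarray(s) for s in states]
    if not mats:
        raise ValueError("at least one diffusion state is required")
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise ValueError("all diffusion states must share the node count")
    if not 1 <= dim <= n * len(mats):
        raise ValueError(f"dim must be in [1, {n * len(mats)}]")
    if smoothing is None:
        smoothing = 1.0 / n
    if smoothing <= 0:
        raise ValueError("smoothing must be positive")
    # node i's feature row = its diffusion states across views, concatenated
    stacked = np.hstack([m.T for m in mats])
    logged = np.log(stacked + smoothing)
    if not np.isfinite(logged).all():
        raise ValueError("non-finite values after log transform")
    centered = logged - logged.mean(axis=0, keepdims=True)
    U, S, _ = randomized_svd(centered, n_components=dim, random_state=seed)
    return U * np.sqrt(S)


def solve_projection(
    X: np.ndarray,
    Y: np.ndarray,
    A_train: np.ndarray,
    lam: float = 0.1,
) -> np.ndarray:
    """Two-sided ridge solve for the projection Z.

    ``A_train`` is the interaction matrix with held-out (test) entries set
    to 0 — at training time an unobserved pair is treated as a
    non-interaction.  With lam=0 the normal equations may be singular; a
    positive ridge is then required.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    A_train = np.asarray(A_train, dtype=float)
    if A_train.shape != (X.shape[0], Y.shape[0]):
        raise ValueError(
            f"interaction matrix shape {A_train.shape} does not match "
            f"features ({X.shape[0]}, {Y.shape[0]})"
        )
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    gram_x = X.T @ X + lam * np.eye(X.shape[1])
    gram_y = Y.T @ Y + lam * np.eye(Y.shape[1])
    rhs = X.T @ A_train @ Y
    try:
        Z = scipy.linalg.solve(gram_x, rhs, assume_a="pos")
        Z = scipy.linalg.solve(gram_y, Z.T, assume_a="pos").T
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "normal equations are singular; use a ridge penalty lam > 0"
        ) from exc
    return Z


def score_pairs(X: np.ndarray, Z: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Bilinear pair scores S = X Z Y^T (N_d x N_p)."""
    X, Z, Y = (np.asarray(m, dtype=float) for m in (X, Z, Y))
    if X.shape[1] != Z.shape[0] or Z.shape[1] != Y.shape[1]:
        raise ValueError(
            f"inconsistent shapes: X {X.shape}, Z {Z.shape}, Y {Y.shape}"
        )
    return X @ Z @ Y.T
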