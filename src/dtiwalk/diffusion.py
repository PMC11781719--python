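"""Restart-random-walk diffusion on similarity networks.

Four transition-matrix constructions are supported, all row-stochastic:

* ``RWR`` — classic degree-normalized walk: P_ij = 1/K(i) for neighbors.
* ``MHRW`` — Metropolis-Hastings acceptance: P_ij = (1/K(i)) min(1, K(i)/K(j)),
  with the rejected mass kept as a self-loop.  Off-diagonal entries are
  symmetric, so without restart the walk's stationary distribution is
  uniform on a connected non-bipartite graph.
* ``IMRWR`` — MHRW with the self-loop mass redistributed to neighbors in
  proportion to their degree, so the particle must move every step.
* ``ISLRWR`` — similarity-weighted walk whose row denominator is inflated
  by the number of isolated nodes in the network:
  P_ij = J(i,j) / (sum_j J(i,j) + n_iso).  The residual mass
  n_iso / (sum J + n_iso) is placed either uniformly on the isolated nodes
  ("teleport", the default) or on the diagonal ("selfloop"), so rows still
  sum to 1.  Isolated nodes thereby remain visible to the walk instead of
  being dead weight.

Degrees K(i) are unweighted neighbor counts over the support of the weight
matrix; edge weights enter only through the neighborhood structure and
through ISLRWR's J.  Isolated nodes (K(i)=0) would yield all-zero rows
under the first three rules; they receive a unit self-loop (the standard
dangling-node correction) so every P is properly stochastic.

Given a row-stochastic P and a continuation probability c (restart
probability 1-c), the diffusion state seeded at node i is the stationary
point of pi = c P^T pi + (1-c) e_i, computed either in closed form,
pi_i = (1-c)(I - c P^T)^{-1} e_i, or by power iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import scipy.linalg

VARIANTS = ("RWR", "MHRW", "IMRWR", "ISLRWR")
ISOLATED_POLICIES = ("teleport", "selfloop")

ROW_SUM_TOL = 1e-10


@dataclass
class NetworkGraph:
    """One node class's weighted similarity graph.

    ``W`` is symmetric and non-negative with zero diagonal; the neighbor
    set of node i is the support of row i.  ``isolated`` flags nodes with
    no neighbors; their count ``n_iso`` enters the ISLRWR denominator.
    """

    W: np.ndarray
    adjacency: np.ndarray = field(init=False)
    degrees: np.ndarray = field(init=False)
    isolated: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        W = np.array(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if (W < 0).any():
            raise ValueError("weight matrix must be non-negative")
        np.fill_diagonal(W, 0.0)
        if not np.allclose(W, W.T):
            raise ValueError("weight matrix must be symmetric")
        self.W = W
        self.adjacency = W > 0
        self.degrees = self.adjacency.sum(axis=1)
        self.isolated = self.degrees == 0

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def n_iso(self) -> int:
        return int(self.isolated.sum())

    @classmethod
    def from_similarity(cls, sim: np.ndarray) -> "NetworkGraph":
        """Build a graph from a similarity matrix (diagonal ignored)."""
        return cls(W=np.asarray(sim, dtype=float))


@dataclass
class TransitionMatrix:
    P: np.ndarray
    variant: str

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        row_err = np.abs(P.sum(axis=1) - 1.0).max()
        if row_err > 1e-8:
            raise ValueError(f"rows do not sum to 1 (max error {row_err:.3g})")
        if (P < -ROW_SUM_TOL).any() or (P > 1 + 1e-12).any():
            raise ValueError("transition entries outside [0, 1]")
        self.P = P


@dataclass
class DiffusionConfig:
    """Walk parameters: continuation probability c, solver tolerances,
    and where ISLRWR's residual mass goes."""

    c: float = 0.85
    tolerance: float = 1e-8
    max_iterations: int = 1000
    isolated_policy: str = "teleport"

    def __post_init__(self) -> None:
        if not 0.0 <= self.c < 1.0:
            raise ValueError("continuation probability c must be in [0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.isolated_policy not in ISOLATED_POLICIES:
            raise ValueError(f"isolated_policy must be one of {ISOLATED_POLICIES}")


@dataclass
class DiffusionState:
    """Stationary visiting distributions: column i is the diffusion state
    of seed node i.  Every column sums to 1."""

    Pi: np.ndarray
    variant: str
    c: float

    def __post_init__(self) -> None:
        Pi = np.asarray(self.Pi, dtype=float)
        if (Pi < -1e-12).any():
            raise ValueError("diffusion state has negative entries")
        col_err = np.abs(Pi.sum(axis=0) - 1.0).max()
        if col_err > 1e-8:
            raise ValueError(f"columns do not sum to 1 (max error {col_err:.3g})")
        self.Pi = Pi


# ---------------------------------------------------------------------------
# transition builders


def build_rwr_transition(g: NetworkGraph) -> TransitionMatrix:
    """Uniform walk over neighbors; isolated nodes get a unit self-loop."""
    P = np.zeros((g.n, g.n))
    active = ~g.isolated
    P[active] = g.adjacency[active] / g.degrees[active, None]
    P[g.isolated, g.isolated] = 1.0
    return TransitionMatrix(P=P, variant="RWR")


def build_mhrw_transition(g: NetworkGraph) -> TransitionMatrix:
    """Metropolis-Hastings walk: off-diagonal min(1/K(i), 1/K(j)) on edges,
    rejected mass on the diagonal."""
    P = np.zeros((g.n, g.n))
    K = g.degrees.astype(float)
    active = ~g.isolated
    with np.errstate(divide="ignore"):
        inv_k = np.where(K > 0, 1.0 / np.where(K > 0, K, 1.0), 0.0)
    # min(1/K(i), 1/K(j)) on the edge set
    pair_min = np.minimum(inv_k[:, None], inv_k[None, :])
    P = np.where(g.adjacency, pair_min, 0.0)
    diag = 1.0 - P.sum(axis=1)
    idx = np.arange(g.n)
    P[idx, idx] = np.where(active, diag, 1.0)
    return TransitionMatrix(P=P, variant="MHRW")


def build_imrwr_transition(g: NetworkGraph) -> TransitionMatrix:
    """MHRW with each node's self-loop mass pushed onto its neighbors in
    proportion to neighbor degree, so the particle moves every step."""
    mhrw = build_mhrw_transition(g).P
    P = mhrw.copy()
    idx = np.arange(g.n)
    self_mass = P[idx, idx].copy()
    P[idx, idx] = 0.0
    K = g.degrees.astype(float)
    # per-row sum of neighbor degrees, sum_{l in Gamma(i)} K(l)
    neighbor_degree_sum = g.adjacency @ K
    active = ~g.isolated
    rows = np.where(active & (self_mass > 0))[0]
    for i in rows:
        share = K * g.adjacency[i] / neighbor_degree_sum[i]
        P[i] += self_mass[i] * share
    P[g.isolated, g.isolated] = 1.0
    return TransitionMatrix(P=P, variant="IMRWR")


def build_islrwr_transition(
    g: NetworkGraph,
    J: np.ndarray | None = None,
    *,
    isolated_policy: str = "teleport",
) -> TransitionMatrix:
    """Similarity-weighted walk with the isolated-node-inflated denominator.

    For a non-isolated node i with neighbor weights J(i,j):
    P_ij = J(i,j) / (sum_{j in Gamma(i)} J(i,j) + n_iso).  The residual
    row mass n_iso / (sum J + n_iso) goes to the isolated nodes (uniform,
    policy "teleport") or to the diagonal (policy "selfloop").  Isolated
    nodes keep a unit self-loop.
    """
    if isolated_policy not in ISOLATED_POLICIES:
        raise ValueError(f"isolated_policy must be one of {ISOLATED_POLICIES}")
    if J is None:
        J = g.W
    J = np.asarray(J, dtype=float)
    if J.shape != g.W.shape:
        raise ValueError("J must match the graph's node count")
    n_iso = g.n_iso
    weights = np.where(g.adjacency, J, 0.0)
    np.fill_diagonal(weights, 0.0)
    row_weight = weights.sum(axis=1)
    P = np.zeros((g.n, g.n))
    idx = np.arange(g.n)
    for i in np.where(~g.isolated)[0]:
        denom = row_weight[i] + n_iso
        if denom == 0:
            warnings.warn(
                f"node {i}: zero similarity to all neighbors and no isolated "
                "nodes; falling back to a self-loop"
            )
            P[i, i] = 1.0
            continue
        P[i] = weights[i] / denom
        residual = n_iso / denom
        if n_iso > 0:
            if isolated_policy == "teleport":
                P[i, g.isolated] += 1.0 / denom
            else:
                P[i, i] += residual
    P[g.isolated, g.isolated] = 1.0
    return TransitionMatrix(P=P, variant="ISLRWR")


_BUILDERS = {
    "RWR": lambda g, J, policy: build_rwr_transition(g),
    "MHRW": lambda g, J, policy: build_mhrw_transition(g),
    "IMRWR": lambda g, J, policy: build_imrwr_transition(g),
    "ISLRWR": lambda g, J, policy: build_islrwr_transition(
        g, J, isolated_policy=policy
    ),
}


def build_transition(
    g: NetworkGraph,
    variant: str,
    *,
    J: np.ndarray | None = None,
    isolated_policy: str = "teleport",
) -> TransitionMatrix:
    """Dispatch to the requested transition construction."""
    if variant not in _BUILDERS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    return _BUILDERS[variant](g, J, isolated_policy)


# ---------------------------------------------------------------------------
# stationary solvers


def stationary_closed_form(
    P: TransitionMatrix, cfg: DiffusionConfig
) -> DiffusionState:
    """Solve pi_i = (1-c)(I - c P^T)^{-1} e_i for all seeds at once."""
    n = P.P.shape[0]
    system = np.eye(n) - cfg.c * P.P.T
    Pi = scipy.linalg.solve(system, (1.0 - cfg.c) * np.eye(n))
    Pi = np.clip(Pi, 0.0, None)
    Pi /= Pi.sum(axis=0, keepdims=True)
    return DiffusionState(Pi=Pi, variant=P.variant, c=cfg.c)


def stationary_power_iteration(
    P: TransitionMatrix, cfg: DiffusionConfig
) -> DiffusionState:
    """Iterate pi(t+1) = c P^T pi(t) + (1-c) I from pi(0) = I.

    The iteration map is a contraction with factor c, so the distance to
    the fixed point is bounded by c/(1-c) times the last update; the loop
    stops once that bound falls below the configured tolerance.
    """
    n = P.P.shape[0]
    PT = P.P.T
    restart = (1.0 - cfg.c) * np.eye(n)
    Pi = np.eye(n)
    gain = cfg.c / (1.0 - cfg.c) if cfg.c > 0 else 0.0
    for _ in range(cfg.max_iterations):
        new = cfg.c * (PT @ Pi) + restart
        delta = np.abs(new - Pi).max()
        Pi = new
        if delta * max(gain, 1.0) < cfg.tolerance:
            break
    else:
        raise RuntimeError(
            f"power iteration did not converge in {cfg.max_iterations} "
            f"iterations (residual {delta:.3g})"
        )
    return DiffusionState(Pi=Pi, variant=P.variant, c=cfg.c)


def diffuse_all(
    views: Dict[str, np.ndarray] | Sequence[np.ndarray],
    variant: str,
    cfg: DiffusionConfig,
    *,
    method: str = "closed_form",
) -> list[DiffusionState]:
    """Diffuse every similarity view with one variant and one c.

    Each view's own similarity matrix plays the role of both the graph
    (through its support) and, for ISLRWR, the edge weights J.
    """
    solver = {
        "closed_form": stationary_closed_form,
        "power": stationary_power_iteration,
    }[method]
    matrices = list(views.values()) if isinstance(views, dict) else list(views)
    states = []
    for sim in matrices:
        g = NetworkGraph.from_similarity(sim)
        P = build_transition(
            g, variant, J=sim, isolated_policy=cfg.isolated_policy
        )
        states.append(solver(P, cfg))
    return states
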