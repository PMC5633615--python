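"""Pinning-observability criteria for heterogeneous dynamical networks.

The network couples ``N`` nodes with possibly different linear drift
matrices ``A_i`` (common state dimension ``n``) through an output
nonlinearity ``f`` bounded, in the Lipschitz sense, by a symmetric
matrix ``Gamma``:

    dx_i/dt = A_i x_i + sum_j dt_ij f(x_j)

An observer copy of the network is feedback-coupled ("pinned") to the
original at a subset of nodes with gains ``d_i > 0``.  Synchronization
of observer and plant — hence recovery of all states from the pinned
ones — is certified by Lyapunov matrix-definiteness tests:

* a global test on the ``Nn x Nn`` matrix
  ``(A + A^T)/2 - D (x) I_n + (Dt (x) Gamma + Dt^T (x) Gamma)/2``
  (``(x)`` the Kronecker product), and
* a decoupled per-node test on an ``n x n`` matrix that involves only
  node ``i``'s own dynamics and its row/column of the coupling matrix.

A node whose zero-gain per-node test already holds needs no pinning;
the nodes that fail it are the ones that must be observed/controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "HeterogeneousNetwork",
    "PinningPlan",
    "global_sync_condition",
    "node_condition",
    "find_pinned_nodes",
    "minimal_gain",
    "schur_node_condition",
    "best_c_per_node",
]

#: negative-definiteness margin: satisfied means lambda_max < -DEFINITE_TOL
DEFINITE_TOL = 1e-9


@dataclass(frozen=True)
class HeterogeneousNetwork:
    """Heterogeneous linearly-drifting nodes with nonlinear coupling.

    Attributes
    ----------
    A_list : tuple of (n, n) ndarray
        Per-node drift matrices.
    Dtilde : (N, N) ndarray
        Coupling configuration matrix (need not be symmetric).
    Gamma : (n, n) ndarray
        Symmetric bound matrix for the coupling nonlinearity.
    f_name, f_gain : str, float
        Output nonlinearity descriptor; ``'tanh'`` with gain ``K``
        means ``f(x) = tanh(K x)``, whose Lipschitz bound is ``K I``.
    """

    A_list: tuple[np.ndarray, ...]
    Dtilde: np.ndarray
    Gamma: np.ndarray
    f_name: str = "tanh"
    f_gain: float = 1.0
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        A_list = tuple(np.atleast_2d(np.asarray(A, dtype=float)) for A in self.A_list)
        if not A_list:
            raise ValueError("need at least one node")
        n = A_list[0].shape[0]
        for A in A_list:
            if A.shape != (n, n):
                raise ValueError("all A_i must be square of identical dimension")
        Dt = np.atleast_2d(np.asarray(self.Dtilde, dtype=float))
        if Dt.shape != (len(A_list), len(A_list)):
            raise ValueError(
                f"coupling matrix must be {len(A_list)}x{len(A_list)}, "
                f"got {Dt.shape}"
            )
        Gamma = np.atleast_2d(np.asarray(self.Gamma, dtype=float))
        if Gamma.shape != (n, n):
            raise ValueError(f"Gamma must be {n}x{n}")
        if not np.allclose(Gamma, Gamma.T, rtol=0.0, atol=1e-12):
            raise ValueError("Gamma must be symmetric")
        labels = self.node_labels or tuple(f"node{i+1}" for i in range(len(A_list)))
        if len(labels) != len(A_list):
            raise ValueError("node_labels length mismatch")
        object.__setattr__(self, "A_list", A_list)
        object.__setattr__(self, "Dtilde", Dt)
        object.__setattr__(self, "Gamma", Gamma)
        object.__setattr__(self, "node_labels", tuple(labels))

    @property
    def N(self) -> int:
        return len(self.A_list)

    @property
    def n(self) -> int:
        return self.A_list[0].shape[0]

    def f(self) -> Callable[[np.ndarray], np.ndarray]:
        """The coupling output nonlinearity as a vectorised callable."""
        K = self.f_gain
        if self.f_name == "tanh":
            return lambda x: np.tanh(K * np.asarray(x, dtype=float))
        if self.f_name == "identity":
            return lambda x: K * np.asarray(x, dtype=float)
        raise ValueError(f"unknown nonlinearity {self.f_name!r}")


@dataclass(frozen=True)
class PinningPlan:
    """Feedback gains for the pinned (observed) nodes.

    ``gains[i] > 0`` means node ``i`` (0-based) is pinned with that
    gain; ``c`` is the positive constant of the decoupled test, uniform
    across nodes by default (pass a sequence for per-node values).
    """

    gains: tuple[float, ...]
    c: float | tuple[float, ...] = 1.0

    def __post_init__(self) -> None:
        g = tuple(float(x) for x in self.gains)
        if any(x < 0 for x in g):
            raise ValueError("gains must be nonnegative")
        c = self.c
        if np.isscalar(c):
            if c <= 0:
                raise ValueError("c must be positive")
            c = float(c)
        else:
            c = tuple(float(x) for x in c)
            if any(x <= 0 for x in c):
                raise ValueError("all c_i must be positive")
            if len(c) != len(g):
                raise ValueError("per-node c length mismatch")
        object.__setattr__(self, "gains", g)
        object.__setattr__(self, "c", c)

    def c_vector(self, N: int) -> np.ndarray:
        if np.isscalar(self.c):
            return np.full(N, float(self.c))
        return np.asarray(self.c, dtype=float)

    @property
    def pinned_set(self) -> tuple[int, ...]:
        """1-based indices of nodes with positive gain."""
        return tuple(i + 1 for i, g in enumerate(self.gains) if g > 0)

    @classmethod
    def unpinned(cls, N: int, c: float = 1.0) -> "PinningPlan":
        return cls(gains=(0.0,) * N, c=c)

    def with_gain(self, i: int, gain: float) -> "PinningPlan":
        """Copy of the plan with the gain of 1-based node ``i`` replaced."""
        g = list(self.gains)
        g[i - 1] = float(gain)
        return PinningPlan(gains=tuple(g), c=self.c)


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2.0


def global_sync_matrix(
    net: HeterogeneousNetwork, plan: PinningPlan
) -> np.ndarray:
    """The Nn x Nn Lyapunov test matrix of the global criterion."""
    if len(plan.gains) != net.N:
        raise ValueError(f"plan has {len(plan.gains)} gains for {net.N} nodes")
    n = net.n
    A = scipy.linalg.block_diag(*net.A_list)
    D = np.kron(np.diag(plan.gains), np.eye(n))
    Dt = net.Dtilde
    coupling = (np.kron(Dt, net.Gamma) + np.kron(Dt.T, net.Gamma)) / 2.0
    return _symmetrize(A) - D + coupling


def global_sync_condition(
    net: HeterogeneousNetwork, plan: PinningPlan, tol: float = DEFINITE_TOL
) -> tuple[bool, float]:
    """Global synchronization test for the pinned observer network.

    Returns ``(satisfied, margin)`` where ``margin`` is the largest
    eigenvalue of the symmetrised test matrix; the condition holds when
    the margin is below ``-tol`` (strict negative definiteness).
    """
    M = _symmetrize(global_sync_matrix(net, plan))
    margin = float(scipy.linalg.eigvalsh(M).max())
    return margin < -tol, margin


def node_condition_matrix(
    net: HeterogeneousNetwork, i: int, plan: PinningPlan
) -> np.ndarray:
    """The n x n decoupled test matrix for 1-based node ``i``.

    ``(A_i + A_i^T)/2 - d_i I + dt_ii Gamma
    + (1/(2 c_i)) sum_{j != i} |dt_ij| Gamma Gamma^T
    + (1/2) sum_{j != i} |dt_ji| / c_j * I``.
    """
    if not 1 <= i <= net.N:
        raise ValueError(f"node index {i} out of range 1..{net.N}")
    k = i - 1
    n = net.n
    c = plan.c_vector(net.N)
    Dt = net.Dtilde
    G = net.Gamma
    others = [j for j in range(net.N) if j != k]
    out_w = sum(abs(Dt[k, j]) for j in others)
    in_w = sum(abs(Dt[j, k]) / c[j] for j in others)
    return (
        _symmetrize(net.A_list[k])
        - plan.gains[k] * np.eye(n)
        + Dt[k, k] * G
        + out_w / (2.0 * c[k]) * (G @ G.T)
        + in_w / 2.0 * np.eye(n)
    )


def node_condition(
    net: HeterogeneousNetwork, i: int, plan: PinningPlan, tol: float = DEFINITE_TOL
) -> tuple[bool, float]:
    """Decoupled per-node synchronization test for 1-based node ``i``.

    A node at which the zero-gain test already holds does not need to
    be pinned; the test matrix involves only node ``i``'s drift and its
    row and column of the coupling matrix.
    """
    M = _symmetrize(node_condition_matrix(net, i, plan))
    margin = float(scipy.linalg.eigvalsh(M).max())
    return margin < -tol, margin


def find_pinned_nodes(
    net: HeterogeneousNetwork, c: "float | Sequence[float]" = 1.0
) -> tuple[int, ...]:
    """Nodes (1-based) whose zero-gain decoupled test fails.

    These are the nodes that must be pinned (observed/controlled) for
    the decoupled criterion to certify synchronization.
    """
    plan = PinningPlan(gains=(0.0,) * net.N, c=c if np.isscalar(c) else tuple(c))
    return tuple(
        i for i in range(1, net.N + 1) if not node_condition(net, i, plan)[0]
    )


def minimal_gain(
    net: HeterogeneousNetwork,
    i: int,
    c: "float | Sequence[float]" = 1.0,
    tol: float = 1e-6,
) -> float:
    """Smallest gain making the decoupled test pass at 1-based node ``i``.

    Because the gain enters as ``-d_i I``, the test margin decreases
    exactly linearly in ``d_i``; the bisection (upper bracket doubled
    from 1) therefore converges to the zero-gain margin.  Returns 0 for
    a node that already satisfies the zero-gain test.
    """
    plan = PinningPlan(gains=(0.0,) * net.N, c=c if np.isscalar(c) else tuple(c))
    ok, margin0 = node_condition(net, i, plan)
    if ok:
        return 0.0
    hi = 1.0
    while not node_condition(net, i, plan.with_gain(i, hi))[0]:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("no finite gain satisfies the node condition")
    lo = 0.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if node_condition(net, i, plan.with_gain(i, mid))[0]:
            hi = mid
        else:
            lo = mid
    return hi


def schur_node_condition(
    net: HeterogeneousNetwork, i: int, plan: PinningPlan, tol: float = DEFINITE_TOL
) -> tuple[bool, float]:
    """Schur-complement (LMI block) variant of the per-node test.

    Evaluates negative definiteness of the 2n x 2n block matrix

        [ (A_i+A_i^T)/2 - d_i I + dt_ii I + (c/2) sum_{j!=i} dt_ij I ,
          sum_{j!=i} |dt_ij| I ;
          sum_{j!=i} |dt_ij| I , -2c I ]

    This block form is provided as a cross-check only: its terms are
    not algebraically identical to the decoupled test (it bounds the
    coupling through the identity rather than Gamma), so the two tests
    can disagree on borderline instances.
    """
    if not 1 <= i <= net.N:
        raise ValueError(f"node index {i} out of range 1..{net.N}")
    k = i - 1
    n = net.n
    c = plan.c_vector(net.N)[k]
    Dt = net.Dtilde
    others = [j for j in range(net.N) if j != k]
    signed = sum(Dt[k, j] for j in others)
    absw = sum(abs(Dt[k, j]) for j in others)
    I = np.eye(n)
    Q = (
        _symmetrize(net.A_list[k])
        - plan.gains[k] * I
        + Dt[k, k] * I
        + c / 2.0 * signed * I
    )
    S = absw * I
    Xi = np.block([[Q, S], [S, -2.0 * c * I]])
    margin = float(scipy.linalg.eigvalsh(_symmetrize(Xi)).max())
    return margin < -tol, margin


def best_c_per_node(
    net: HeterogeneousNetwork,
    gains: "Sequence[float] | None" = None,
    grid: "np.ndarray | None" = None,
) -> list[dict]:
    """Log-grid search over the uniform constant ``c`` per node.

    For each node, scans ``c`` over a logarithmic grid (default 25
    points in [1e-2, 1e2]) and reports the ``c`` giving the most
    negative decoupled-test margin.
    """
    if grid is None:
        grid = np.logspace(-2, 2, 25)
    gains = tuple(gains) if gains is not None else (0.0,) * net.N
    out = []
    for i in range(1, net.N + 1):
        best = None
        for c in grid:
            _, margin = node_condition(net, i, PinningPlan(gains=gains, c=float(c)))
            if best is None or margin < best[1]:
                best = (float(c), margin)
        out.append({"node": i, "c": best[0], "margin": best[1]})
    return out
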