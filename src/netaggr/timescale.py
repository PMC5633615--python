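"""Slow/fast coordinate transform and two-time-scale model reduction.

For a clustered network with state ``x`` the slow variable is the
vector of per-area means, ``y = Ma^{-1} U^T x``, and the fast variable
collects orthonormal within-area differences, ``z = Q x``.  In these
coordinates the linear dynamics ``dx/dt = K x`` become a singularly
perturbed system: after rescaling by the internal degree ``cI`` and the
sparsity parameters ``d`` and ``delta``,

    dy/dts = A11 y + A12 z
    delta * dz/dts = d * A21 y + A22 z

with the slow time ``ts = delta * cI * t``.  When the fast block
``A22`` is Hurwitz and ``d, delta`` are small, the slow dynamics are
approximated by the reduced matrix ``A0 = A11 - d A12 A22^{-1} A21``
and, more coarsely, by the rigid aggregate model
``Ma dys/dt = Ka ys`` with ``Ka = U^T K_external U``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .network import (
    AreaPartition,
    ConnectivityNetwork,
    link_counts,
    node_parameter,
    area_parameter,
    split_connection_matrix,
)

__all__ = [
    "SlowFastTransform",
    "TwoTimeScaleSystem",
    "ReducedModels",
    "AggregabilityReport",
    "orthonormal_difference_matrix",
    "build_transform",
    "singular_perturbed_system",
    "slow_fast_subsystems",
    "aggregate_system",
    "check_aggregability",
    "sort_spectrum",
]

#: an eigenvalue with real part above -HURWITZ_TOL is not considered stable
HURWITZ_TOL = 1e-9
#: condition number above which the fast block counts as singular
COND_LIMIT = 1e12


def sort_spectrum(eigs: np.ndarray) -> np.ndarray:
    """Sort eigenvalues by real part descending, ties by imaginary part."""
    eigs = np.asarray(eigs)
    order = np.lexsort((-eigs.imag, -eigs.real))
    return eigs[order]


def orthonormal_difference_matrix(n: int) -> np.ndarray:
    """(n-1) x n difference matrix with orthonormal rows and null vector 1_n.

    The first column is constantly ``-1 + (n-1)*v``; the remaining
    block has ``1 - v`` on its diagonal and ``-v`` off it, with
    ``v = (n - sqrt(n)) / (n (n-1))``.  Rows are orthonormal and sum to
    zero, so the pseudoinverse is the transpose.
    """
    n = int(n)
    if n < 2:
        raise ValueError("difference matrix needs n >= 2")
    v = (n - np.sqrt(n)) / (n * (n - 1))
    Q = np.full((n - 1, n), -v)
    Q[:, 0] = -1.0 + (n - 1) * v
    Q[np.arange(n - 1), np.arange(1, n)] = 1.0 - v
    return Q


@dataclass(frozen=True)
class SlowFastTransform:
    """The invertible map ``x -> (y, z)`` and the inter-area difference map.

    Attributes
    ----------
    U : (N, r) ndarray
        Block indicator matrix; column ``alpha`` is the ones-vector of
        area ``alpha``.
    Ma : (r, r) ndarray
        Diagonal matrix of area sizes.
    G : (r, N) ndarray
        ``Ma^{-1} U^T``; maps states to area means.
    Q : (N-r, N) ndarray
        Block-diagonal orthonormal within-area difference matrix.
    R : (r-1, r) ndarray or None
        Orthonormal inter-area difference matrix (None when ``r == 1``,
        where the aggregate is a single node and inter-area dynamics
        are trivial).
    C : (r-1, r-1) ndarray or None
        ``R Ma^{-1} R^T``.
    """

    partition: AreaPartition
    U: np.ndarray
    Ma: np.ndarray
    G: np.ndarray
    Q: np.ndarray
    R: np.ndarray | None
    C: np.ndarray | None

    def to_slow_fast(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map full states to (area means y, within-area differences z).

        ``x`` may be a vector or a (time, N) array of states.
        """
        x = np.asarray(x, dtype=float)
        return x @ self.G.T, x @ self.Q.T

    def from_slow_fast(self, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Inverse map ``x = U y + Q^T z``."""
        return np.asarray(y) @ self.U.T + np.asarray(z) @ self.Q


def build_transform(partition: AreaPartition) -> SlowFastTransform:
    """Assemble the slow/fast transform for a partition.

    Singleton areas contribute an empty (0-row) block to ``Q``.  For a
    single-area partition ``R`` and ``C`` are ``None``.
    """
    N, r = partition.n_nodes, partition.r
    U = np.zeros((N, r))
    for alpha in range(1, r + 1):
        U[partition.nodes_in_area(alpha), alpha - 1] = 1.0
    Ma = np.diag([float(m) for m in partition.sizes])
    G = np.diag([1.0 / m for m in partition.sizes]) @ U.T
    blocks = [
        orthonormal_difference_matrix(m) if m >= 2 else np.zeros((0, m))
        for m in partition.sizes
    ]
    Q = scipy.linalg.block_diag(*blocks) if blocks else np.zeros((0, N))
    Q = Q.reshape(N - r, N)  # block_diag of empty blocks can lose shape
    if r >= 2:
        R = orthonormal_difference_matrix(r)
        C = R @ np.diag([1.0 / m for m in partition.sizes]) @ R.T
    else:
        R = None
        C = None
    return SlowFastTransform(partition=partition, U=U, Ma=Ma, G=G, Q=Q, R=R, C=C)


@dataclass(frozen=True)
class TwoTimeScaleSystem:
    """Block matrices of the linear singularly perturbed system.

    ``A11t .. A22t`` are the unscaled blocks of the (y, z) dynamics,

        A11t = G K_ext U      A12t = G K_ext Q^T
        A21t = Q K_ext U      A22t = Q (K_int + K_ext) Q^T

    and ``A11 .. A22`` the rescaled blocks ``A11 = A11t/(cI*delta)``,
    ``A12 = A12t/(cI*delta)``, ``A21 = A21t/(cI*d)``, ``A22 = A22t/cI``.
    """

    network: ConnectivityNetwork
    transform: SlowFastTransform
    A11t: np.ndarray
    A12t: np.ndarray
    A21t: np.ndarray
    A22t: np.ndarray
    cI: int
    d: float
    delta: float
    q_dialect: str = "orthonormal"
    A11: np.ndarray = field(init=False)
    A12: np.ndarray = field(init=False)
    A21: np.ndarray = field(init=False)
    A22: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        s = self.cI * self.delta
        object.__setattr__(self, "A11", self.A11t / s)
        object.__setattr__(self, "A12", self.A12t / s)
        object.__setattr__(self, "A21", self.A21t / (self.cI * self.d))
        object.__setattr__(self, "A22", self.A22t / self.cI)

    @property
    def t_fast_factor(self) -> float:
        """Fast time per unit real time: ``tf = cI * t``."""
        return float(self.cI)

    @property
    def t_slow_factor(self) -> float:
        """Slow time per unit real time: ``ts = delta * cI * t``."""
        return self.delta * self.cI

    def full_block_matrix(self) -> np.ndarray:
        """Unscaled (y, z) block matrix (real-time units)."""
        return np.block([[self.A11t, self.A12t], [self.A21t, self.A22t]])


def singular_perturbed_system(
    network: ConnectivityNetwork,
    cI: int | None = None,
    d: float | None = None,
    delta: float | None = None,
    q_dialect: str = "orthonormal",
) -> TwoTimeScaleSystem:
    """Build the two-time-scale block system for a clustered network.

    ``cI``, ``d`` and ``delta`` default to the combinatorial values
    computed from the network (max-ratio node parameter).  With the
    default orthonormal ``Q`` the transpose is its pseudoinverse; the
    ``'difference'`` dialect uses the plain -1/+1 difference matrix and
    substitutes the pseudoinverse ``Q^+`` for ``Q^T`` in the coupling
    blocks.
    """
    counts = link_counts(network)
    if cI is None:
        cI = counts["cI"]
    if d is None:
        d = node_parameter(network, mode="max_ratio")
    if delta is None:
        delta = area_parameter(network)
    if cI <= 0:
        raise ValueError("cI must be a positive integer")
    if d <= 0.0 or delta <= 0.0:
        raise ValueError(
            "d and delta must be positive (the rescaling divides by them); "
            "a network with no external links has no two-time-scale structure"
        )
    K_int, K_ext = split_connection_matrix(network)
    tr = build_transform(network.partition)
    if q_dialect == "orthonormal":
        Q, Qpi = tr.Q, tr.Q.T
    elif q_dialect == "difference":
        Q = _plain_difference_blocks(network.partition)
        Qpi = np.linalg.pinv(Q)
    else:
        raise ValueError(f"unknown q_dialect {q_dialect!r}")
    G, U = tr.G, tr.U
    return TwoTimeScaleSystem(
        network=network,
        transform=tr,
        A11t=G @ K_ext @ U,
        A12t=G @ K_ext @ Qpi,
        A21t=Q @ K_ext @ U,
        A22t=Q @ (K_int + K_ext) @ Qpi,
        cI=int(cI),
        d=float(d),
        delta=float(delta),
        q_dialect=q_dialect,
    )


def _plain_difference_blocks(partition: AreaPartition) -> np.ndarray:
    """Non-orthonormal (-1 first column | identity) difference matrix."""
    blocks = []
    for m in partition.sizes:
        B = np.zeros((max(m - 1, 0), m))
        B[:, 0] = -1.0
        B[np.arange(m - 1), np.arange(1, m)] = 1.0
        blocks.append(B)
    N, r = partition.n_nodes, partition.r
    return scipy.linalg.block_diag(*blocks).reshape(N - r, N)


@dataclass(frozen=True)
class ReducedModels:
    """Reduced slow/fast subsystems and the rigid aggregate model."""

    A0: np.ndarray | None
    A22: np.ndarray
    Ka: np.ndarray
    Ma: np.ndarray
    slow_eigs: np.ndarray | None
    fast_eigs: np.ndarray
    aggregate_eigs: np.ndarray
    aggregable: bool
    reason: str = ""


def slow_fast_subsystems(system: TwoTimeScaleSystem) -> ReducedModels:
    """Reduce a two-time-scale system to its slow and fast subsystems.

    The slow subsystem (in slow time units) is
    ``dys/dts = A0 ys`` with ``A0 = A11 - d A12 A22^{-1} A21``; the
    fast subsystem (fast time units) is ``dzf/dtf = A22 zf``.  A
    singular fast block makes the reduction invalid and is reported via
    ``aggregable=False`` instead of raising.
    """
    A22 = system.A22
    fast_eigs = sort_spectrum(np.linalg.eigvals(A22))
    Ma, Ka, aggregate_eigs = aggregate_system(system.network)
    if A22.size and np.linalg.cond(A22) > COND_LIMIT:
        return ReducedModels(
            A0=None,
            A22=A22,
            Ka=Ka,
            Ma=Ma,
            slow_eigs=None,
            fast_eigs=fast_eigs,
            aggregate_eigs=aggregate_eigs,
            aggregable=False,
            reason="fast subsystem singular",
        )
    A0 = system.A11 - system.d * system.A12 @ np.linalg.solve(A22, system.A21)
    return ReducedModels(
        A0=A0,
        A22=A22,
        Ka=Ka,
        Ma=Ma,
        slow_eigs=sort_spectrum(np.linalg.eigvals(A0)),
        fast_eigs=fast_eigs,
        aggregate_eigs=aggregate_eigs,
        aggregable=True,
    )


def fast_initial_condition(
    system: TwoTimeScaleSystem, x0: np.ndarray
) -> np.ndarray:
    """Corrected fast initial condition ``zf(0) = z(0) + d A22^{-1} A21 y(0)``."""
    y0, z0 = system.transform.to_slow_fast(np.asarray(x0, dtype=float))
    return z0 + system.d * np.linalg.solve(system.A22, system.A21 @ y0)


def aggregate_system(
    network: ConnectivityNetwork,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid aggregate model ``Ma dys/dt = Ka ys`` with ``Ka = U^T K_ext U``.

    Returns ``(Ma, Ka, spectrum of Ma^{-1} Ka)``.
    """
    _, K_ext = split_connection_matrix(network)
    tr = build_transform(network.partition)
    Ka = tr.U.T @ K_ext @ tr.U
    eigs = sort_spectrum(np.linalg.eigvals(np.linalg.inv(tr.Ma) @ Ka))
    return tr.Ma, Ka, eigs


@dataclass(frozen=True)
class AggregabilityReport:
    aggregable: bool
    reasons: tuple[str, ...]
    d: float | None
    delta: float | None


def check_aggregability(network: ConnectivityNetwork) -> AggregabilityReport:
    """Check whether the two-time-scale reduction is valid for a network.

    The reduction requires: zero row sums, every node internally
    linked, sparsity parameters ``d`` and ``delta`` below 1, and a
    nonsingular Hurwitz fast block.  Each failed check is listed; the
    check never raises.
    """
    reasons: list[str] = []
    if not network.row_sums_ok:
        reasons.append("zero-row-sum validation failed")
    counts = link_counts(network)
    internal = counts["internal_per_node"]
    assign = network.partition.assignment
    for i in np.nonzero(internal == 0)[0]:
        reasons.append(
            f"node with zero internal links in area {assign[int(i)]} "
            f"({network.node_labels[int(i)]})"
        )
    d = delta = None
    if not reasons:
        d = node_parameter(network, mode="max_ratio")
        delta = area_parameter(network)
        if d >= 1.0:
            reasons.append(f"node parameter d = {d:g} not < 1")
        if delta >= 1.0:
            reasons.append(f"area parameter delta = {delta:g} not < 1")
        if d > 0.0 and delta > 0.0:
            system = singular_perturbed_system(network)
            A22 = system.A22
            if A22.size:
                if np.linalg.cond(A22) > COND_LIMIT:
                    reasons.append("fast subsystem singular")
                elif np.linalg.eigvals(A22).real.max() >= -HURWITZ_TOL:
                    reasons.append("fast subsystem not Hurwitz")
        else:
            # No external links: nothing to aggregate across areas, but the
            # fast block is still required to be stable.
            K_int, _ = split_connection_matrix(network)
            tr = build_transform(network.partition)
            A22t = tr.Q @ K_int @ tr.Q.T
            if A22t.size and (
                np.linalg.cond(A22t) > COND_LIMIT
                or np.linalg.eigvals(A22t).real.max() >= -HURWITZ_TOL
            ):
                reasons.append("fast subsystem singular")
    return AggregabilityReport(
        aggregable=not reasons, reasons=tuple(reasons), d=d, delta=delta
    )
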