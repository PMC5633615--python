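"""Synthetic clustered networks and heterogeneous dynamics.

The generator emulates the topology class the reduction methods assume:
densely linked nodes inside each area, sparse links between areas, with
the internal minimum degree and the per-node / per-area external link
counts under explicit caps so the sparsity parameters ``d`` and
``delta`` are controlled by construction.  Connection matrices are
emitted as negative weighted Laplacians (symmetric, zero row sums), so
the conserved eigenvalue 0 and the stability structure of the worked
examples hold for every generated instance.

Two exact fixtures are provided: the printed 8-node, 2-area network
used to demonstrate the slow/fast reduction, and the printed 3-node
heterogeneous network used to demonstrate pinning observability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import AreaPartition, ConnectivityNetwork
from .pinning import HeterogeneousNetwork

__all__ = [
    "GeneratorConfig",
    "generate_clustered_network",
    "example1_network",
    "example3_network",
    "generate_heterogeneous_dynamics",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Target structure of a generated clustered network.

    ``internal_min_degree`` is the target minimum internal degree cI;
    ``external_per_node_max`` and ``external_per_area_max`` cap the
    per-node (cE) and per-area (gammaE) external link counts.
    ``external_total`` is the number of external links to place
    (default: ``r * external_per_area_max // 2``, i.e. as many as the
    area caps allow when links spread evenly).  Weights are 1 unless a
    ``weight_range`` interval is given.
    """

    sizes: tuple[int, ...]
    internal_min_degree: int = 2
    external_per_node_max: int = 1
    external_per_area_max: int = 2
    external_total: int | None = None
    weight_range: tuple[float, float] | None = None
    seed: int = 0
    r: int = field(init=False)

    def __post_init__(self) -> None:
        sizes = tuple(int(m) for m in self.sizes)
        if any(m < 2 for m in sizes):
            raise ValueError("every area needs at least 2 nodes")
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "r", len(sizes))
        if self.internal_min_degree < 1:
            raise ValueError("internal_min_degree must be >= 1")
        if self.internal_min_degree > min(sizes) - 1:
            raise ValueError(
                "internal_min_degree exceeds what the smallest area supports "
                f"(binding constraint: min area size {min(sizes)})"
            )
        total = self.external_total
        if total is None:
            total = self.r * self.external_per_area_max // 2
            object.__setattr__(self, "external_total", total)
        if total > 0 and self.r < 2:
            raise ValueError("external links require at least 2 areas")
        # each external link consumes one unit of two areas' budgets and one
        # unit of two nodes' budgets
        area_budget = self.r * self.external_per_area_max
        node_budget = sum(sizes) * self.external_per_node_max
        if 2 * total > area_budget:
            raise ValueError(
                f"external_total={total} unachievable "
                f"(binding constraint: external_per_area_max="
                f"{self.external_per_area_max} over {self.r} areas)"
            )
        if 2 * total > node_budget:
            raise ValueError(
                f"external_total={total} unachievable "
                f"(binding constraint: external_per_node_max="
                f"{self.external_per_node_max})"
            )


def _internal_edges(m: int, min_degree: int, rng: np.random.Generator) -> list:
    """Connected graph on m nodes with minimum degree >= min_degree.

    Random spanning tree plus extra random edges until the degree floor
    is met; connectivity guarantees a nonsingular internal Laplacian
    block, keeping generated instances reducible by construction.
    """
    tree = nx.random_labeled_tree(m, seed=int(rng.integers(2**31)))
    g = nx.Graph(tree.edges())
    g.add_nodes_from(range(m))
    while min(dict(g.degree()).values()) < min_degree:
        deficient = [v for v, k in g.degree() if k < min_degree]
        u = int(rng.choice(deficient))
        candidates = [v for v in range(m) if v != u and not g.has_edge(u, v)]
        g.add_edge(u, int(rng.choice(candidates)))
    return sorted(tuple(sorted(e)) for e in g.edges())


def generate_clustered_network(config: GeneratorConfig) -> ConnectivityNetwork:
    """Generate a clustered network meeting the config's caps.

    Deterministic under a fixed seed.  The emitted ``K`` is the
    negative (weighted) Laplacian of the generated graph.
    """
    rng = np.random.default_rng(config.seed)
    partition = AreaPartition.from_sizes(config.sizes)
    N = partition.n_nodes
    offsets = np.cumsum((0,) + config.sizes)
    edges: list[tuple[int, int]] = []
    for alpha, m in enumerate(config.sizes):
        base = int(offsets[alpha])
        edges.extend((base + i, base + j) for i, j in
                     _internal_edges(m, config.internal_min_degree, rng))
    # external links: draw random cross-area pairs under both caps
    node_ext = np.zeros(N, dtype=int)
    area_ext = np.zeros(config.r, dtype=int)
    assign = np.asarray(partition.assignment) - 1
    placed: set[tuple[int, int]] = set()
    attempts = 0
    while len(placed) < (config.external_total or 0):
        attempts += 1
        if attempts > 10000:
            raise ValueError(
                "could not place all external links (binding constraint: "
                "per-node or per-area external caps)"
            )
        i, j = sorted(int(v) for v in rng.choice(N, size=2, replace=False))
        ai, aj = assign[i], assign[j]
        if ai == aj or (i, j) in placed:
            continue
        if node_ext[i] >= config.external_per_node_max:
            continue
        if node_ext[j] >= config.external_per_node_max:
            continue
        if area_ext[ai] >= config.external_per_area_max:
            continue
        if area_ext[aj] >= config.external_per_area_max:
            continue
        placed.add((i, j))
        node_ext[[i, j]] += 1
        area_ext[[ai, aj]] += 1
    edges.extend(sorted(placed))
    adjacency = np.zeros((N, N))
    for i, j in edges:
        if config.weight_range is None:
            w = 1.0
        else:
            lo, hi = config.weight_range
            w = float(rng.uniform(lo, hi))
        adjacency[i, j] = adjacency[j, i] = w
    K = adjacency.copy()
    np.fill_diagonal(K, -adjacency.sum(axis=1))
    return ConnectivityNetwork(K=K, partition=partition)


def example1_network() -> ConnectivityNetwork:
    """The printed 8-node, 2-area demonstration network.

    Area 1 (nodes 1-4) has internal links {1-2, 1-3, 1-4, 2-3, 3-4};
    area 2 (nodes 5-8) is internally complete; the two external links
    are 3-5 and 4-8.  Exact integer matrices; byte-stable across calls.
    """
    K1I = np.array(
        [[-3, 1, 1, 1], [1, -2, 1, 0], [1, 1, -3, 1], [1, 0, 1, -2]], float
    )
    K2I = np.array(
        [[-3, 1, 1, 1], [1, -3, 1, 1], [1, 1, -3, 1], [1, 1, 1, -3]], float
    )
    K12E = np.zeros((4, 4))
    K12E[2, 0] = 1.0  # node 3 - node 5
    K12E[3, 3] = 1.0  # node 4 - node 8
    K11E = np.diag([0.0, 0.0, -1.0, -1.0])
    K22E = np.diag([-1.0, 0.0, 0.0, -1.0])
    K = np.block([[K1I + K11E, K12E], [K12E.T, K2I + K22E]])
    return ConnectivityNetwork(
        K=K, partition=AreaPartition.from_sizes((4, 4))
    )


def example3_network() -> HeterogeneousNetwork:
    """The printed 3-node heterogeneous pinning demonstration network.

    Scalar nodes with self-decay magnitudes a = (2, 1.6, 0.5)
    (drift A_i = -a_i), the printed symmetric coupling matrix, and a
    sigmoid output nonlinearity tanh(K x) with K = 1, whose Lipschitz
    bound gives Gamma = 1.
    """
    a = (2.0, 1.6, 0.5)
    Dtilde = np.array(
        [[0.7, -0.2, -0.1], [-0.2, 0.5, -0.3], [-0.1, -0.3, 0.8]]
    )
    return HeterogeneousNetwork(
        A_list=tuple(np.array([[-ai]]) for ai in a),
        Dtilde=Dtilde,
        Gamma=np.array([[1.0]]),
        f_name="tanh",
        f_gain=1.0,
    )


def generate_heterogeneous_dynamics(
    N: int,
    n: int,
    decay_range: tuple[float, float] = (1.0, 2.0),
    coupling_density: float = 0.2,
    seed: int = 0,
) -> HeterogeneousNetwork:
    """Random heterogeneous network: stable drifts, sparse symmetric coupling.

    Each drift is ``-diag(decays)`` plus a small random skew part (the
    skew part does not affect the symmetric-part stability); the
    coupling matrix is symmetric with the given off-diagonal density
    and entries uniform in [-0.5, 0.5].  Deterministic under the seed.
    """
    lo, hi = decay_range
    if lo <= 0 or hi < lo:
        raise ValueError("decay_range must be a positive interval")
    rng = np.random.default_rng(seed)
    A_list = []
    for _ in range(N):
        decays = rng.uniform(lo, hi, size=n)
        S = rng.normal(scale=0.1 * lo, size=(n, n))
        A_list.append(-np.diag(decays) + (S - S.T) / 2.0)
    Dt = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            if rng.random() < coupling_density:
                Dt[i, j] = Dt[j, i] = rng.uniform(-0.5, 0.5)
    return HeterogeneousNetwork(
        A_list=tuple(A_list),
        Dtilde=Dt,
        Gamma=np.eye(n),
        f_name="tanh",
        f_gain=1.0,
    )
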