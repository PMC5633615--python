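"""Clustered network representation and static sparsity parameters.

A clustered network is a weighted, undirected graph on ``N`` nodes whose
node set is partitioned into ``r`` areas (dense clusters).  The total
connection matrix ``K`` is Laplacian-like (symmetric, zero row sums) and
splits into an internal part ``K_internal`` (links within areas) and an
external part ``K_external`` (links between areas).  Two combinatorial
parameters summarise how sparse the inter-area coupling is relative to
the intra-area coupling:

* the node parameter ``d = c_E / c_I``, the ratio of the largest
  per-node external link count to the smallest per-node internal link
  count, and
* the area parameter ``delta = gamma_E / (m * c_I)``, where ``gamma_E``
  is the largest per-area external link count and ``m`` the smallest
  area size.

Both parameters are purely combinatorial: a weighted link counts as one
link.  Weights enter only the dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AreaPartition",
    "ConnectivityNetwork",
    "IncidenceDecomposition",
    "ValidationWarning",
    "build_incidence",
    "split_connection_matrix",
    "link_counts",
    "node_parameter",
    "area_parameter",
]

#: absolute tolerance for the zero-row-sum (conservation) validation
ROW_SUM_TOL = 1e-9


class ValidationWarning(UserWarning):
    """Raised (as a warning) when a network violates a soft invariant."""


@dataclass(frozen=True)
class AreaPartition:
    """Assignment of ``N`` nodes to ``r`` non-empty areas.

    Nodes must be ordered area-by-area: ``assignment`` is a
    non-decreasing sequence of area indices ``1..r`` so that the block
    structure of the slow/fast transform is realised directly.  File
    readers reorder nodes before constructing a partition.

    Attributes
    ----------
    assignment : tuple of int
        ``assignment[i]`` is the 1-based area index of node ``i``.
    sizes : tuple of int
        Area sizes ``m_alpha``; ``sum(sizes) == N``.
    r : int
        Number of areas.
    """

    assignment: tuple[int, ...]
    sizes: tuple[int, ...] = field(init=False)
    r: int = field(init=False)

    def __post_init__(self) -> None:
        a = tuple(int(x) for x in self.assignment)
        if len(a) == 0:
            raise ValueError("empty partition")
        if a[0] != 1:
            raise ValueError("area indices must start at 1")
        if any(b - c not in (0, 1) for b, c in zip(a[1:], a[:-1])):
            raise ValueError(
                "assignment must be block-contiguous: nodes ordered by area, "
                "area indices consecutive from 1"
            )
        object.__setattr__(self, "assignment", a)
        r = a[-1]
        sizes = tuple(a.count(alpha) for alpha in range(1, r + 1))
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "r", r)

    @property
    def n_nodes(self) -> int:
        return len(self.assignment)

    @property
    def min_size(self) -> int:
        """Smallest area size ``m``."""
        return min(self.sizes)

    def nodes_in_area(self, alpha: int) -> np.ndarray:
        """0-based node indices of area ``alpha`` (1-based)."""
        a = np.asarray(self.assignment)
        return np.nonzero(a == alpha)[0]

    @classmethod
    def from_sizes(cls, sizes: "list[int] | tuple[int, ...]") -> "AreaPartition":
        assignment: list[int] = []
        for alpha, m in enumerate(sizes, start=1):
            if m < 1:
                raise ValueError("every area must be non-empty")
            assignment.extend([alpha] * int(m))
        return cls(tuple(assignment))


@dataclass(frozen=True)
class ConnectivityNetwork:
    """Weighted N-node network with an area partition.

    ``K`` is the total connection matrix.  It must be symmetric
    (undirected connectivity; asymmetric input is an error) and should
    have zero row sums to machine precision.  Row-sum violations only
    warn — empirical weighted graphs may be non-conservative — but the
    aggregation pipeline then refuses to certify reducibility.
    """

    K: np.ndarray
    partition: AreaPartition
    node_labels: tuple[str, ...] = ()
    row_sums_ok: bool = field(init=False)

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be a square matrix")
        if K.shape[0] != self.partition.n_nodes:
            raise ValueError(
                f"K is {K.shape[0]}x{K.shape[0]} but the partition has "
                f"{self.partition.n_nodes} nodes"
            )
        if not np.allclose(K, K.T, rtol=0.0, atol=1e-12):
            raise ValueError("K must be symmetric (undirected connectivity)")
        labels = self.node_labels or tuple(f"n{i+1}" for i in range(K.shape[0]))
        if len(labels) != K.shape[0]:
            raise ValueError("node_labels length does not match K")
        rs_ok = bool(np.abs(K.sum(axis=1)).max() <= ROW_SUM_TOL)
        if not rs_ok:
            warnings.warn(
                "connection matrix has nonzero row sums "
                f"(max |row sum| = {np.abs(K.sum(axis=1)).max():.3g}); "
                "aggregation will not be certified",
                ValidationWarning,
                stacklevel=3,
            )
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "node_labels", tuple(labels))
        object.__setattr__(self, "row_sums_ok", rs_ok)

    @property
    def n_nodes(self) -> int:
        return self.K.shape[0]


@dataclass(frozen=True)
class IncidenceDecomposition:
    """Oriented incidence matrix reordered as ``[D_internal | D_external]``.

    Each column encodes one undirected link with a +1 at its positive
    end and a -1 at its negative end.  Columns ``0..M_internal-1`` are
    internal links, block-ordered by area (so ``D_internal`` is block
    diagonal over areas); the remaining columns are external links.
    For a link ``{i, j}`` with ``i < j``, node ``i`` is the positive end.
    """

    D: np.ndarray
    M_internal: int
    M_external: int
    link_list: tuple[tuple[int, int, int], ...]  # (pos end, neg end, area or 0)

    @property
    def M(self) -> int:
        return self.D.shape[1]

    @property
    def D_internal(self) -> np.ndarray:
        return self.D[:, : self.M_internal]

    @property
    def D_external(self) -> np.ndarray:
        return self.D[:, self.M_internal :]


def build_incidence(network: ConnectivityNetwork) -> IncidenceDecomposition:
    """Build the oriented, area-ordered incidence decomposition of a network.

    Every nonzero off-diagonal entry ``K[i, j]`` defines one undirected
    link; diagonal entries are never links.  Internal links come first,
    grouped by area index then lexicographically by ``(i, j)``; external
    links follow, lexicographically.  Link ``{i, j}`` with ``i < j`` has
    positive end ``i``.
    """
    K = network.K
    n = network.n_nodes
    assign = network.partition.assignment
    internal: list[tuple[int, int, int]] = []
    external: list[tuple[int, int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if K[i, j] != 0.0:
                if assign[i] == assign[j]:
                    internal.append((i, j, assign[i]))
                else:
                    external.append((i, j, 0))
    internal.sort(key=lambda t: (t[2], t[0], t[1]))
    links = internal + external
    D = np.zeros((n, len(links)), dtype=int)
    for k, (i, j, _) in enumerate(links):
        D[i, k] = 1
        D[j, k] = -1
    return IncidenceDecomposition(
        D=D,
        M_internal=len(internal),
        M_external=len(external),
        link_list=tuple(links),
    )


def split_connection_matrix(
    network: ConnectivityNetwork,
) -> tuple[np.ndarray, np.ndarray]:
    """Split ``K`` into internal and external Laplacian-like parts.

    Off-diagonal entries go to ``K_internal`` when both endpoints share
    an area and to ``K_external`` otherwise.  The diagonal is split so
    that each area block of ``K_internal`` has zero row sums; the
    remainder of the diagonal goes to ``K_external``.  For a
    zero-row-sum ``K`` this makes both parts Laplacian-like and the
    split is exact: ``K_internal + K_external == K`` entrywise.

    Raises
    ------
    ValueError
        If no diagonal split yields zero row sums for both parts (this
        happens exactly when ``K`` itself violates the zero-row-sum
        invariant beyond tolerance).
    """
    K = network.K
    n = network.n_nodes
    assign = np.asarray(network.partition.assignment)
    same_area = assign[:, None] == assign[None, :]
    off = K.copy()
    np.fill_diagonal(off, 0.0)
    K_int = np.where(same_area, off, 0.0)
    K_ext = off - K_int
    # internal diagonal: make each area block zero-row-sum
    np.fill_diagonal(K_int, -K_int.sum(axis=1))
    ext_diag = np.diag(K) - np.diag(K_int)
    K_ext[np.diag_indices(n)] = ext_diag
    if np.abs(K_ext.sum(axis=1)).max() > ROW_SUM_TOL:
        raise ValueError(
            "connection matrix is not an internal+external Laplacian sum "
            "(external part has nonzero row sums)"
        )
    return K_int, K_ext


def link_counts(network: ConnectivityNetwork) -> dict:
    """Count internal/external links per node and per area.

    Returns a dict with per-node internal and external link counts,
    per-area external link counts, and the combinatorial extremes
    ``cI`` (min internal per node), ``cE`` (max external per node) and
    ``gammaE`` (max external per area).
    """
    K = network.K
    n = network.n_nodes
    assign = np.asarray(network.partition.assignment)
    adj = (K != 0.0) & ~np.eye(n, dtype=bool)
    same_area = assign[:, None] == assign[None, :]
    internal_per_node = (adj & same_area).sum(axis=1)
    external_per_node = (adj & ~same_area).sum(axis=1)
    r = network.partition.r
    external_per_area = np.array(
        [external_per_node[assign == alpha].sum() for alpha in range(1, r + 1)]
    )
    return {
        "internal_per_node": internal_per_node,
        "external_per_node": external_per_node,
        "external_per_area": external_per_area,
        "cI": int(internal_per_node.min()) if n else 0,
        "cE": int(external_per_node.max()) if n else 0,
        "gammaE": int(external_per_area.max()) if r else 0,
    }


def _require_internal_links(counts: dict, network: ConnectivityNetwork) -> None:
    internal = counts["internal_per_node"]
    bad = np.nonzero(internal == 0)[0]
    if bad.size:
        label = network.node_labels[bad[0]]
        raise ValueError(
            f"node {label!r} (index {int(bad[0])}) has zero internal links; "
            "the internal link count cI is undefined"
        )


def node_parameter(network: ConnectivityNetwork, mode: str = "max_ratio") -> float:
    """Node parameter ``d``: external-to-internal link count ratio.

    ``mode='max_ratio'`` returns ``cE / cI`` with ``cE`` the maximum
    per-node external link count and ``cI`` the minimum per-node
    internal link count.  ``mode='average'`` returns the mean over
    nodes of each node's own external/internal count ratio (the
    ``d_ave`` variant used when summarising empirical graphs).
    """
    counts = link_counts(network)
    _require_internal_links(counts, network)
    if mode == "max_ratio":
        return counts["cE"] / counts["cI"]
    if mode == "average":
        ratios = counts["external_per_node"] / counts["internal_per_node"]
        return float(ratios.mean())
    raise ValueError(f"unknown mode {mode!r}; expected 'max_ratio' or 'average'")


def area_parameter(network: ConnectivityNetwork) -> float:
    """Area parameter ``delta = gammaE / (m * cI)``.

    ``gammaE`` is the largest external link count over areas, ``m`` the
    smallest area size and ``cI`` the smallest per-node internal link
    count.
    """
    counts = link_counts(network)
    _require_internal_links(counts, network)
    m = network.partition.min_size
    return counts["gammaE"] / (m * counts["cI"])
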