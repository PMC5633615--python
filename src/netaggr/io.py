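"""File formats: adjacency/edge-list TSV, partition TSV/JSON, dynamics JSON.

TSV is the canonical dialect (tab-separated, '.' decimal, UTF-8, '#'
comment lines); comma-separated files are accepted on read.  Nodes are
reordered area-by-area when a network is read, so the in-memory
representation always has the block structure the slow/fast transform
expects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import AreaPartition, ConnectivityNetwork
from .pinning import HeterogeneousNetwork

__all__ = [
    "read_network",
    "write_network",
    "read_partition",
    "read_dynamics",
    "write_report",
]


def _read_table(path: "str | Path") -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, comment="#", header=0, dtype=str)


def read_partition(path: "str | Path") -> dict[str, int]:
    """Read a node-label -> area-id mapping (2-column TSV/CSV or JSON).

    Returns the mapping with area ids renumbered 1..r in sorted order
    of the original ids; insertion order of nodes is preserved.
    """
    path = Path(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
        items = [(str(k), v) for k, v in raw.items()]
    else:
        df = _read_table(path)
        if df.shape[1] != 2:
            raise ValueError(
                f"partition file {path} must have 2 columns "
                f"(node_label, area_id); got {df.shape[1]}"
            )
        items = [(str(a), b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
    area_ids = sorted({v for _, v in items}, key=lambda v: (str(v)))
    renumber = {v: i + 1 for i, v in enumerate(area_ids)}
    return {label: renumber[v] for label, v in items}


def _adjacency_from_table(path: Path) -> tuple[np.ndarray, list[str]]:
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", header=0, index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError(
            f"adjacency file {path}: row labels do not match column labels"
        )
    try:
        K = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"adjacency file {path}: non-numeric cell ({exc})")
    return K, labels


def _adjacency_from_edge_list(path: Path) -> tuple[np.ndarray, list[str]]:
    df = _read_table(path)
    if df.shape[1] != 3:
        raise ValueError(
            f"edge list {path} must have 3 columns (node_i, node_j, weight)"
        )
    labels: list[str] = []
    for col in (0, 1):
        for v in df.iloc[:, col]:
            if str(v) not in labels:
                labels.append(str(v))
    idx = {v: i for i, v in enumerate(labels)}
    N = len(labels)
    adjacency = np.zeros((N, N))
    for _, (a, b, w) in df.iterrows():
        try:
            w = float(w)
        except ValueError:
            raise ValueError(f"edge list {path}: non-numeric weight {w!r}")
        adjacency[idx[str(a)], idx[str(b)]] = w
        adjacency[idx[str(b)], idx[str(a)]] = w
    K = adjacency.copy()
    np.fill_diagonal(K, -adjacency.sum(axis=1))
    return K, labels


def read_network(
    adjacency_path: "str | Path", partition_path: "str | Path"
) -> ConnectivityNetwork:
    """Read a clustered network from an adjacency (or edge-list) file.

    An adjacency file carries node labels in its first row and column
    and a dense numeric body; a 3-column file is interpreted as an
    undirected edge list whose connection matrix is the negative
    weighted Laplacian.  Nodes are reordered area-by-area.
    """
    adjacency_path = Path(adjacency_path)
    partition = read_partition(partition_path)
    first_data = next(
        line for line in adjacency_path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    )
    n_cols = len(first_data.replace(",", "\t").split("\t"))
    if n_cols == 3 and len(partition) != 2:
        K, labels = _adjacency_from_edge_list(adjacency_path)
    else:
        K, labels = _adjacency_from_table(adjacency_path)
    for label in labels:
        if label not in partition:
            raise ValueError(f"node label {label!r} missing from partition file")
    for label in partition:
        if label not in labels:
            raise ValueError(
                f"partition references unknown node label {label!r}"
            )
    order = sorted(range(len(labels)), key=lambda i: (partition[labels[i]], i))
    K = K[np.ix_(order, order)]
    ordered_labels = [labels[i] for i in order]
    assignment = tuple(partition[v] for v in ordered_labels)
    return ConnectivityNetwork(
        K=K,
        partition=AreaPartition(assignment),
        node_labels=tuple(ordered_labels),
    )


def write_network(
    network: ConnectivityNetwork,
    adjacency_path: "str | Path",
    partition_path: "str | Path",
) -> None:
    """Write a network as adjacency TSV + partition TSV (round-trip safe)."""
    labels = list(network.node_labels)
    df = pd.DataFrame(network.K, index=labels, columns=labels)
    df.to_csv(adjacency_path, sep="\t", float_format="%.17g")
    with open(partition_path, "w") as fh:
        fh.write("node\tarea\n")
        for label, area in zip(labels, network.partition.assignment):
            fh.write(f"{label}\t{area}\n")


def read_dynamics(path: "str | Path") -> tuple[HeterogeneousNetwork, float]:
    """Read a heterogeneous-dynamics JSON spec.

    Schema: ``{"n": int, "nodes": [{"label", "A": matrix-or-scalar}],
    "coupling": matrix-or-path, "gamma": matrix-or-"lipschitz:<K>",
    "f": {"name", "gain"}?, "c": positive float?}``.
    Returns the network and the constant ``c`` (default 1.0).
    """
    path = Path(path)
    spec = json.loads(path.read_text())
    n = int(spec["n"])
    A_list, labels = [], []
    for node in spec["nodes"]:
        A = np.atleast_2d(np.asarray(node["A"], dtype=float))
        if A.shape != (n, n):
            raise ValueError(
                f"node {node.get('label')!r}: A has shape {A.shape}, "
                f"expected ({n}, {n})"
            )
        A_list.append(A)
        labels.append(str(node.get("label", f"node{len(labels)+1}")))
    coupling = spec["coupling"]
    if isinstance(coupling, str):
        cdf = _read_table(path.parent / coupling)
        Dt = cdf.to_numpy(dtype=float)
    else:
        Dt = np.asarray(coupling, dtype=float)
    gamma = spec.get("gamma", "lipschitz:1")
    if isinstance(gamma, str):
        if not gamma.startswith("lipschitz:"):
            raise ValueError(f"unknown gamma spec {gamma!r}")
        Gamma = float(gamma.split(":", 1)[1]) * np.eye(n)
    else:
        Gamma = np.asarray(gamma, dtype=float)
    f_spec = spec.get("f", {})
    net = HeterogeneousNetwork(
        A_list=tuple(A_list),
        Dtilde=Dt,
        Gamma=Gamma,
        f_name=f_spec.get("name", "tanh"),
        f_gain=float(f_spec.get("gain", 1.0)),
        node_labels=tuple(labels),
    )
    return net, float(spec.get("c", 1.0))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        if np.iscomplexobj(obj):
            return [_jsonify(v) for v in obj.tolist()]
        return obj.tolist()
    if isinstance(obj, complex):
        return [obj.real, obj.imag]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_report(report: dict, path: "str | Path") -> None:
    """Write a JSON report; complex spectra become [re, im] pairs."""
    Path(path).write_text(json.dumps(_jsonify(report), indent=2) + "\n")
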