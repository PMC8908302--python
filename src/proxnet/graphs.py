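"""Per-factor weighted graphs, eigenvector centralities and activity series.

Each row of the coefficient matrix U is rendered as an undirected
weighted graph over the full participant set (isolated nodes kept).
Centrality is the principal eigenvector of the weighted adjacency
matrix, normalized to unit maximum so the best-connected participant
scores exactly 1 (and 0.00 after the natural-log transform).
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from proxnet.contacts import DyadIndex, EpochGrid
from proxnet.nmf import FactorModel

DEFAULT_LOG_FLOOR = 1e-6


def factor_to_graph(model: FactorModel, k: int, dyads: DyadIndex,
                    threshold: float = 0.0) -> nx.Graph:
    """Undirected weighted graph of factor ``k`` (0-based).

    Edge (a, b) carries weight ``u_kj`` for dyad column j and is present
    iff ``u_kj > threshold``.  The full participant set is retained as
    nodes; ``factor_index`` and ``weight_threshold`` are stored as graph
    attributes.
    """
    if not 0 <= k < model.K:
        raise IndexError(f"factor index {k} out of range [0, {model.K})")
    if model.U.shape[1] != dyads.n_dyads:
        raise ValueError("dyad index does not match U's column count")
    G = nx.Graph(factor_index=k, weight_threshold=threshold)
    G.add_nodes_from(dyads.participants)
    row = model.U[k]
    for j, (a, b) in enumerate(dyads.pairs):
        if row[j] > threshold:
            G.add_edge(a, b, weight=float(row[j]))
    return G


def eigenvector_centrality(graph: nx.Graph, tol: float = 1e-10,
                           max_iter: int = 10_000) -> dict[str, float]:
    """Principal-eigenvector scores of the weighted adjacency, max = 1.

    Uses shifted power iteration from the uniform vector (the shift,
    proportional to the largest edge weight, guarantees convergence on
    bipartite graphs and keeps the result invariant to uniform weight
    rescaling).  Nodes outside the component attaining the principal
    eigenvalue come out (near-)zero.  Raises on an edgeless graph.
    """
    nodes = list(graph.nodes)
    if graph.number_of_edges() == 0:
        raise ValueError("eigenvector centrality undefined on an edgeless graph")
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    shift = A.max()
    x = np.ones(len(nodes)) / np.sqrt(len(nodes))
    for _ in range(max_iter):
        x_new = A @ x + shift * x
        nrm = np.linalg.norm(x_new)
        if nrm == 0:
            raise ValueError("power iteration collapsed to zero vector")
        x_new /= nrm
        if np.linalg.norm(x_new - x) < tol:
            x = x_new
            break
        x = x_new
    x = np.clip(x, 0.0, None)
    x /= x.max()
    return dict(zip(nodes, x.tolist()))


def log_centrality(raw: dict[str, float], floor: float = DEFAULT_LOG_FLOOR) -> dict[str, float]:
    """Natural log of max(raw, floor); the maximal participant maps to 0.0."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return {p: float(np.log(max(v, floor))) for p, v in raw.items()}


def centrality_table(model: FactorModel, dyads: DyadIndex,
                     threshold: float = 0.0,
                     floor: float = DEFAULT_LOG_FLOOR) -> pd.DataFrame:
    """Participant-by-factor table of raw and log eigenvector centralities.

    Columns are ``factor<k>_raw`` and ``factor<k>_log`` for each factor,
    indexed by participant id.
    """
    data: dict[str, list[float]] = {}
    for k in range(model.K):
        G = factor_to_graph(model, k, dyads, threshold=threshold)
        raw = eigenvector_centrality(G)
        logv = log_centrality(raw, floor=floor)
        data[f"factor{k + 1}_raw"] = [raw[p] for p in dyads.participants]
        data[f"factor{k + 1}_log"] = [logv[p] for p in dyads.participants]
    return pd.DataFrame(data, index=list(dyads.participants)).rename_axis("participant_id")


def activity_series(model: FactorModel, k: int, grid: EpochGrid) -> pd.Series:
    """Column k of H as a time series indexed by epoch start timestamps."""
    if not 0 <= k < model.K:
        raise IndexError(f"factor index {k} out of range [0, {model.K})")
    if model.H.shape[0] != grid.n_epochs:
        raise ValueError("grid does not match H's row count")
    idx = pd.DatetimeIndex(grid.epoch_starts(), name="epoch_start")
    return pd.Series(model.H[:, k], index=idx, name=f"factor{k + 1}")


def top_epochs(series: pd.Series, m: int = 10) -> pd.Series:
    """The ``m`` highest-activity epochs, ties broken by earlier time."""
    order = np.lexsort((series.index.astype("int64"), -series.to_numpy()))
    return series.iloc[order[:m]]


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """GraphML export (plain-XML text) of a factor graph."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, path)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Weighted edge list as delimited text: participant_a, participant_b, weight."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_a", "participant_b", "weight"])
        for a, b, d in sorted(graph.edges(data=True)):
            w.writerow([a, b, repr(d["weight"])])
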