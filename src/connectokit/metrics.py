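"""Graph metrics for weighted connectomes.

The four measures used throughout the analysis:

* **degree** — number of edges incident to a node (always a binary
  count, whatever the weights);
* **global efficiency** (Eglob) — average inverse shortest-path length
  over all pairs of distinct nodes, with disconnected pairs
  contributing 0;
* **local efficiency** (Eloc) — for each node, the global efficiency
  of the subgraph induced by its neighbors (the node itself excluded);
  nodes with fewer than two neighbors score 0;
* **betweenness centrality** (BC) — Brandes accumulation of the
  fraction of shortest paths through a node, over unordered
  source-target pairs, unnormalized.

In ``weighted`` mode a connection of FA weight ``w`` has length
``1/w`` (strong connections are short), the conventional mapping for
FA-weighted connectomes; ``binary`` mode uses hop counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph

from .errors import CohortError, ConnectokitError
from .io import Cohort, ConnectivityMatrix

__all__ = [
    "node_degree", "mean_degree", "shortest_path_lengths",
    "global_efficiency", "local_efficiency", "betweenness_centrality",
    "count_possible_connections", "compute_metrics_table", "MetricsTable",
    "NODAL_METRICS",
]

NODAL_METRICS = ("degree", "eloc", "bc")
MODES = ("weighted", "binary")


def _weights(matrix) -> np.ndarray:
    if isinstance(matrix, ConnectivityMatrix):
        return matrix.weights
    return np.asarray(matrix, dtype=float)


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def node_degree(matrix) -> np.ndarray:
    """Count of strictly positive off-diagonal weights per node."""
    w = _weights(matrix)
    return np.count_nonzero(w > 0, axis=1)


def mean_degree(matrix) -> float:
    return float(node_degree(matrix).mean())


def shortest_path_lengths(matrix, mode: str = "weighted") -> np.ndarray:
    """All-pairs shortest path lengths; +inf for disconnected pairs.

    Weighted mode runs Dijkstra over edge lengths 1/w; binary mode
    returns hop counts.
    """
    _check_mode(mode)
    w = _weights(matrix)
    n = w.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    i, j = np.nonzero(np.triu(w, 1))
    if mode == "weighted":
        data = 1.0 / w[i, j]
    else:
        data = np.ones(len(i))
    g = sparse.csr_matrix((data, (i, j)), shape=(n, n))
    return csgraph.shortest_path(g, method="D", directed=False,
                                 unweighted=(mode == "binary"))


def global_efficiency(matrix, mode: str = "weighted") -> float:
    """Mean of 1/d(i, j) over all ordered pairs i != j (1/inf = 0)."""
    w = _weights(matrix)
    n = w.shape[0]
    if n < 2:
        raise ConnectokitError(f"global efficiency needs >= 2 nodes, got {n}")
    d = shortest_path_lengths(w, mode)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv[off].mean())


def local_efficiency(matrix, mode: str = "weighted") -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph."""
    _check_mode(mode)
    w = _weights(matrix)
    n = w.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(w[v] > 0)
        if len(nb) < 2:
            continue
        out[v] = global_efficiency(w[np.ix_(nb, nb)], mode)
    return out


def betweenness_centrality(matrix, mode: str = "weighted") -> np.ndarray:
    """Unnormalized Brandes betweenness over unordered pairs s != t != v."""
    _check_mode(mode)
    import networkx as nx

    w = _weights(matrix)
    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    i, j = np.nonzero(np.triu(w, 1))
    if mode == "weighted":
        g.add_weighted_edges_from(zip(i.tolist(), j.tolist(),
                                      (1.0 / w[i, j]).tolist()),
                                  weight="length")
        bc = nx.betweenness_centrality(g, normalized=False, weight="length")
    else:
        g.add_edges_from(zip(i.tolist(), j.tolist()))
        bc = nx.betweenness_centrality(g, normalized=False, weight=None)
    return np.array([bc[v] for v in range(n)])


def count_possible_connections(n_nodes: int) -> int:
    """Number of ordered node pairs, n(n-1); 26732 for the 164-node atlas."""
    if n_nodes < 2:
        raise ConnectokitError(f"need >= 2 nodes, got {n_nodes}")
    return int(n_nodes) * (int(n_nodes) - 1)


@dataclass
class MetricsTable:
    """Per-subject nodal metrics plus per-subject global scalars.

    ``nodal[metric]`` is a (subjects x nodes) DataFrame; ``scalars``
    holds one row per subject with ``eglob`` and ``mean_degree``;
    ``groups`` maps subject id to group label.
    """

    nodal: dict[str, pd.DataFrame]
    scalars: pd.DataFrame
    groups: pd.Series
    mode: str = "weighted"
    node_ids: list[str] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.scalars.index)

    def subjects_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def group_values(self, metric: str, group: str) -> pd.DataFrame:
        """(subjects-in-group x nodes) slice of one nodal metric."""
        return self.nodal[metric].loc[self.subjects_in(group)]

    def group_mean_profile(self, metric: str, group: str) -> np.ndarray:
        ids = self.subjects_in(group)
        if not ids:
            raise CohortError(f"no subjects in group {group!r}")
        return self.nodal[metric].loc[ids].mean(axis=0).to_numpy()

    def to_long_frame(self) -> pd.DataFrame:
        frames = []
        for metric, df in self.nodal.items():
            f = df.stack().rename("value").reset_index()
            f.columns = ["subject_id", "node", "value"]
            f["metric"] = metric
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def compute_metrics_table(cohort: Cohort, mode: str = "weighted",
                          metrics: tuple[str, ...] = NODAL_METRICS
                          ) -> MetricsTable:
    """All requested metrics for every subject of a cohort.

    ``metrics`` selects the nodal measures to compute (degree is
    always included); ``eglob`` and ``mean_degree`` scalars are always
    produced.  Per-subject failures are re-raised with the subject id.
    """
    _check_mode(mode)
    unknown = set(metrics) - set(NODAL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}; "
                         f"choose from {NODAL_METRICS}")
    metrics = tuple(dict.fromkeys(("degree",) + tuple(metrics)))
    nodal: dict[str, list] = {m: [] for m in metrics}
    scal_rows = []
    ids = []
    for s in cohort.subjects:
        try:
            deg = node_degree(s.matrix)
            for m in metrics:
                if m == "degree":
                    nodal[m].append(deg.astype(float))
                elif m == "eloc":
                    nodal[m].append(local_efficiency(s.matrix, mode))
                elif m == "bc":
                    nodal[m].append(betweenness_centrality(s.matrix, mode))
            scal_rows.append({"eglob": global_efficiency(s.matrix, mode),
                              "mean_degree": float(deg.mean())})
            ids.append(s.subject_id)
        except Exception as exc:
            raise CohortError(
                f"metric computation failed for subject "
                f"{s.subject_id!r}: {exc}") from exc
    nodal_frames = {m: pd.DataFrame(np.vstack(vals), index=ids)
                    for m, vals in nodal.items()}
    scalars = pd.DataFrame(scal_rows, index=ids)
    return MetricsTable(nodal_frames, scalars, cohort.groups, mode,
                        list(cohort.node_ids))
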