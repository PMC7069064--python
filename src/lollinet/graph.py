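"""Weighted undirected graphs: the container every generator emits and the
random walk consumes.

A :class:`WeightedGraph` is a symmetric nonnegative weight matrix with a zero
diagonal (self loops exist only after walk normalization) and unique string
node labels. Serialization is plain text: a square tab-separated matrix with
a label header row and label first column, or a three-column edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from .errors import ValidationError

__all__ = ["WeightedGraph", "is_connected"]

_SYMMETRY_TOL = 1e-8


def _default_labels(n: int) -> list[str]:
    return [f"n{i}" for i in range(n)]


@dataclass
class WeightedGraph:
    """Symmetric weighted graph with labeled nodes.

    Parameters
    ----------
    weights
        N x N array of nonnegative reals; symmetric with zero diagonal.
    labels
        N unique node labels. Defaults to ``n0 .. n{N-1}``.
    """

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"weight matrix must be square, got shape {w.shape}")
        if np.isnan(w).any():
            raise ValidationError("weight matrix contains NaN")
        if not np.allclose(w, w.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValidationError(
                f"weight matrix asymmetric beyond {_SYMMETRY_TOL:g}; "
                "inspect the input before symmetrizing"
            )
        w = (w + w.T) / 2.0  # remove round-off asymmetry
        np.fill_diagonal(w, 0.0)
        if (w < 0).any():
            raise ValidationError("negative weights are not allowed")
        self.weights = w
        if not self.labels:
            self.labels = _default_labels(w.shape[0])
        if len(self.labels) != w.shape[0]:
            raise ValidationError("label count does not match matrix size")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("node labels must be unique")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of positive-weight undirected edges."""
        return int(np.count_nonzero(np.triu(self.weights, 1) > 0))

    def degrees(self) -> np.ndarray:
        """Weighted degree d_i = sum_j |w_ij| (diagonal excluded)."""
        return np.abs(self.weights).sum(axis=1)

    def copy(self) -> "WeightedGraph":
        return WeightedGraph(self.weights.copy(), list(self.labels))

    # -- conversions -------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        """Positive-weight edges as a networkx Graph (nodes 0..N-1,
        'weight' edge attribute)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        ii, jj = np.nonzero(np.triu(self.weights, 1) > 0)
        g.add_weighted_edges_from(
            (int(i), int(j), float(self.weights[i, j])) for i, j in zip(ii, jj)
        )
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, labels: list[str] | None = None) -> "WeightedGraph":
        w = nx.to_numpy_array(g, weight="weight")
        return cls(w, labels or [str(v) for v in g.nodes])

    # -- text serialization ------------------------------------------------

    def to_tsv(self, path) -> None:
        """Square tab-separated matrix with label header row and column."""
        from .pipeline import write_matrix  # local import: avoid cycle

        write_matrix(path, self.weights, self.labels)

    @classmethod
    def from_tsv(cls, path) -> "WeightedGraph":
        from .pipeline import _read_square_table

        w, labels = _read_square_table(path)
        return cls(w, labels)

    def to_edgelist(self, path) -> None:
        """Three-column text edge list: label_a<TAB>label_b<TAB>weight."""
        ii, jj = np.nonzero(np.triu(self.weights, 1) > 0)
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for i, j in zip(ii, jj):
                fh.write(f"{self.labels[i]}\t{self.labels[j]}\t{self.weights[i, j]:.12g}\n")

    @classmethod
    def from_edgelist(cls, path) -> "WeightedGraph":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        labels = sorted(set(df["node_a"]) | set(df["node_b"]))
        idx = {lab: k for k, lab in enumerate(labels)}
        w = np.zeros((len(labels), len(labels)))
        for a, b, v in zip(df["node_a"], df["node_b"], df["weight"]):
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = float(v)
        return cls(w, labels)


def is_connected(weights: np.ndarray, floor: float = 1e-12) -> bool:
    """Whether the graph induced by weights > floor is a single component.

    Degrees below the floor count as isolated nodes (they would make the
    walk reducible numerically even if formally positive).
    """
    w = np.asarray(weights)
    adj = csr_array(w > floor)
    n_comp = connected_components(adj, directed=False, return_labels=False)
    return int(n_comp) == 1
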