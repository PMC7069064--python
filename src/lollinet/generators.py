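"""Synthetic graph families.

Generators for the graph families used in the simulation studies: complete,
lollipop (clique + path "stick"), Erdős–Rényi random graphs (both G(n,m) and
G(n,p)), Watts–Strogatz small-world rings, stochastic block models with
randomly sized communities, and the progressive chain-isolation sequence.

All randomness flows through a ``numpy.random.Generator`` seeded per call;
there is no global RNG state. Generators whose output must be connected
(hitting times are undefined otherwise) redraw with an incremented seed up to
a bounded retry count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .errors import GenerationError, InvalidSizeError
from .graph import WeightedGraph, is_connected

__all__ = [
    "make_complete",
    "make_lollipop",
    "make_random",
    "make_small_world",
    "make_sbm",
    "make_isolation_sequence",
    "IsolationSequence",
]

_MAX_RETRIES = 100


def make_complete(n: int) -> WeightedGraph:
    """Complete graph K_n with unit weights."""
    if n < 2:
        raise InvalidSizeError(f"complete graph needs n >= 2, got {n}")
    w = np.ones((n, n)) - np.eye(n)
    return WeightedGraph(w)


def make_lollipop(n_total: int, n_path: int) -> WeightedGraph:
    """Lollipop graph: a clique of ``n_total - n_path`` nodes with a simple
    path of ``n_path`` nodes attached at one clique node.

    Nodes ``0 .. n_clique-1`` form the clique; the path hangs off node
    ``n_clique - 1``. All weights are 1. A path one third of the total size
    maximizes hitting times among lollipop splits.
    """
    if not (1 <= n_path <= n_total - 2):
        raise InvalidSizeError(
            f"need 1 <= n_path <= n_total - 2, got n_path={n_path}, n_total={n_total}"
        )
    n_clique = n_total - n_path
    w = np.zeros((n_total, n_total))
    w[:n_clique, :n_clique] = 1.0
    for i in range(n_clique - 1, n_total - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(w)


def make_random(
    n: int,
    edges: int | None = None,
    prob: float | None = None,
    seed: int | None = None,
    require_connected: bool = False,
) -> WeightedGraph:
    """Erdős–Rényi random graph with unit weights.

    Exactly one of ``edges`` (G(n,m): that many distinct edges drawn
    uniformly) or ``prob`` (G(n,p): each pair independently) must be given.
    """
    if (edges is None) == (prob is None):
        raise ValueError("supply exactly one of edges= or prob=")
    max_edges = n * (n - 1) // 2
    if edges is not None and not (0 < edges <= max_edges):
        raise InvalidSizeError(f"edges must be in [1, {max_edges}], got {edges}")
    if prob is not None and not (0 < prob < 1):
        raise InvalidSizeError(f"prob must be in (0,1), got {prob}")

    for attempt in range(_MAX_RETRIES):
        s = None if seed is None else int(seed) + attempt
        rng = np.random.default_rng(s)
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        if edges is not None:
            pick = rng.choice(max_edges, size=edges, replace=False)
            w[iu[0][pick], iu[1][pick]] = 1.0
        else:
            w[iu] = rng.random(max_edges) < prob
        w = w + w.T
        if not require_connected or is_connected(w):
            return WeightedGraph(w)
    raise GenerationError(
        f"no connected draw in {_MAX_RETRIES} attempts (n={n}, edges={edges}, prob={prob})"
    )


def make_small_world(
    n: int,
    ring_k: int = 4,
    beta: float = 0.1,
    seed: int | None = None,
    require_connected: bool = True,
) -> WeightedGraph:
    """Watts–Strogatz ring-rewire small-world graph, unit weights.

    Defaults ``ring_k=4, beta=0.1`` sit in the conventional small-world
    regime (high clustering, short paths). Rewiring preserves the edge count
    n*ring_k/2. Disconnected draws are regenerated with an incremented seed.
    """
    if ring_k >= n:
        raise InvalidSizeError(f"ring_k must be < n, got ring_k={ring_k}, n={n}")
    for attempt in range(_MAX_RETRIES):
        s = None if seed is None else int(seed) + attempt
        g = nx.watts_strogatz_graph(n, ring_k, beta, seed=s)
        w = nx.to_numpy_array(g)
        if not require_connected or is_connected(w):
            return WeightedGraph(w)
    raise GenerationError(f"no connected small-world draw in {_MAX_RETRIES} attempts")


def make_sbm(
    n_total: int,
    p_in: float = 0.7,
    q_out: float = 0.1,
    seed: int | None = None,
    size_range: tuple[int, int] = (30, 170),
    require_connected: bool = False,
) -> tuple[WeightedGraph, np.ndarray]:
    """Stochastic block model with randomly sized communities.

    Community sizes are drawn sequentially (uniform integers in
    ``size_range``) until the running total reaches ``n_total``; the last
    community is truncated to fit. Unit-weight edges appear independently
    with probability ``p_in`` within and ``q_out`` between communities.

    Returns the graph and an integer community label per node.
    """
    if not (0 < q_out < p_in <= 1):
        raise InvalidSizeError(f"need 0 < q_out < p_in <= 1, got p_in={p_in}, q_out={q_out}")
    for attempt in range(_MAX_RETRIES):
        s = None if seed is None else int(seed) + attempt
        rng = np.random.default_rng(s)
        sizes: list[int] = []
        while sum(sizes) < n_total:
            sizes.append(int(rng.integers(size_range[0], size_range[1] + 1)))
        sizes[-1] -= sum(sizes) - n_total  # truncate the last community
        if sizes[-1] <= 0:
            sizes.pop()
        labels = np.repeat(np.arange(len(sizes)), sizes)
        n = len(labels)
        same = labels[:, None] == labels[None, :]
        p_mat = np.where(same, p_in, q_out)
        iu = np.triu_indices(n, 1)
        w = np.zeros((n, n))
        w[iu] = rng.random(len(iu[0])) < p_mat[iu]
        w = w + w.T
        if not require_connected or is_connected(w):
            return WeightedGraph(w), labels
    raise GenerationError(f"no connected SBM draw in {_MAX_RETRIES} attempts")


@dataclass
class IsolationSequence:
    """Ordered graph sequence from the chain-isolation experiment.

    ``graphs[0]`` is the baseline random graph; each later entry has edge
    weights reduced by ``delta`` — either every edge touching the selected
    chain except the chain's own consecutive path edges (``isolate_chain``),
    or every edge in the graph (``global_reduction``). ``d_ref`` is the
    baseline maximum degree, against which every iteration should be
    normalized so that lost edge weight reappears as self-loop mass.
    """

    mode: str
    graphs: list[WeightedGraph]
    chain_nodes: list[int] = field(default_factory=list)
    delta: float = 0.05
    d_ref: float = 0.0


def _sample_simple_path(w: np.ndarray, length: int, rng: np.random.Generator,
                        max_tries: int = 1000) -> list[int]:
    """Self-avoiding random walk until `length` nodes are collected."""
    n = w.shape[0]
    for _ in range(max_tries):
        path = [int(rng.integers(n))]
        while len(path) < length:
            nbrs = np.nonzero(w[path[-1]] > 0)[0]
            nbrs = nbrs[~np.isin(nbrs, path)]
            if len(nbrs) == 0:
                break
            path.append(int(rng.choice(nbrs)))
        if len(path) == length:
            return path
    raise GenerationError(f"no simple path of length {length} found in {max_tries} tries")


def make_isolation_sequence(
    n: int = 50,
    prob: float = 0.6,
    chain_len: int = 10,
    delta: float = 0.05,
    iters: int = 19,
    mode: str = "isolate_chain",
    seed: int | None = None,
    weight_floor: float = 1e-6,
) -> IsolationSequence:
    """Progressively isolate a chain inside a random graph (or, as a
    control, weaken the whole graph uniformly).

    Baseline: G(n, prob) with unit weights, regenerated until connected. In
    ``isolate_chain`` mode a ``chain_len``-node simple path is sampled by a
    self-avoiding random walk and every edge incident to a chain node —
    except the consecutive path edges themselves, which stay at weight 1 —
    loses ``delta`` per iteration, sculpting a lollipop stick. In
    ``global_reduction`` mode every edge loses ``delta`` per iteration.
    Weights are clamped at ``weight_floor`` (with a warning) if a decrement
    would cross zero, preserving connectivity.
    """
    if mode not in ("isolate_chain", "global_reduction"):
        raise ValueError(f"unknown mode {mode!r}")
    if chain_len >= n:
        raise InvalidSizeError("chain_len must be < n")

    base = make_random(n, prob=prob, seed=seed, require_connected=True)
    rng = np.random.default_rng(None if seed is None else int(seed) + 10_000)

    if mode == "isolate_chain":
        chain = _sample_simple_path(base.weights, chain_len, rng)
        decay_mask = np.zeros_like(base.weights, dtype=bool)
        decay_mask[chain, :] = True
        decay_mask[:, chain] = True
        for a, b in zip(chain[:-1], chain[1:]):  # path edges stay intact
            decay_mask[a, b] = decay_mask[b, a] = False
    else:
        chain = []
        decay_mask = np.ones_like(base.weights, dtype=bool)
    decay_mask &= base.weights > 0

    graphs = [base]
    w = base.weights.copy()
    clamped = False
    for _ in range(iters):
        w = w.copy()
        w[decay_mask] -= delta
        if (w[decay_mask] <= 0).any():
            clamped = True
            w[decay_mask & (w <= 0)] = weight_floor
        g = WeightedGraph(w.copy(), list(base.labels))
        if not is_connected(g.weights):
            raise GenerationError("isolation sequence disconnected the graph")
        graphs.append(g)
    if clamped:
        warnings.warn(
            f"edge weights clamped at {weight_floor:g} to preserve connectivity",
            stacklevel=2,
        )
    return IsolationSequence(
        mode=mode,
        graphs=graphs,
        chain_nodes=list(chain),
        delta=delta,
        d_ref=float(base.degrees().max()),
    )
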