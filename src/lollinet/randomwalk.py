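"""Self-loop-normalized random walks and hitting times.

The core method. A weighted graph with adjacency A = [|rho_ij|] and degrees
d_i = sum_j |rho_ij| is normalized by giving every node a self loop of weight
d_max − d_i, so all nodes share the common degree d_max while their relative
connectivity is preserved: a weakly connected node mostly sits on its self
loop instead of being forced to move. The walk's transition matrix is then
P' = A'/d_max, its normalized Laplacian is L = I − P' (symmetric, because the
degree matrix is a multiple of the identity), and the expected first-visit
step counts h_ij come from the spectral (Lovász–Simonovits) formula

    h_ij = sum_{k>1} (d'/lambda_k) (mu_kj^2/d'_j − mu_ki mu_kj/sqrt(d'_i d'_j)),

with lambda_k, mu_k the eigenpairs of L, d'_i the normalized degrees (all
equal d_max) and d' their sum. Two independent solvers — a first-step linear
system and Monte-Carlo walk simulation — serve as oracles for the spectral
route.

Self loops count as steps: they are transitions of the chain, and the
spectral formula's walk is exactly the chain with those self loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConnectivityError, DegenerateInputError, EstimationError, ValidationError
from .graph import WeightedGraph, is_connected

__all__ = [
    "NormalizedWalkModel",
    "HittingTimeMatrix",
    "build_graph",
    "normalize",
    "laplacian",
    "hitting_spectral",
    "hitting_linear",
    "hitting_montecarlo",
]

_DEGREE_FLOOR = 1e-12
_LAMBDA_TOL = 1e-10


@dataclass
class NormalizedWalkModel:
    """Self-loop-augmented walk model.

    ``a_prime`` has off-diagonal |w_ij| and diagonal d_ref − d_i;
    ``p_prime = a_prime / d_ref`` is row stochastic. ``d_max`` stores the
    reference degree d_ref (the graph's own maximum degree unless a larger
    external reference was supplied, e.g. a baseline graph's d_max in the
    isolation experiment).
    """

    a_prime: np.ndarray
    d_max: float
    degrees: np.ndarray
    p_prime: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.a_prime.shape[0]


@dataclass
class HittingTimeMatrix:
    """Expected first-visit step counts h_ij; zero diagonal, generally
    asymmetric (reaching an isolated chain takes far longer than leaving it).
    """

    h: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.h.shape[0]

    def offdiag(self) -> np.ndarray:
        """Row-major off-diagonal values (the 'hitting-time distribution')."""
        n = self.h.shape[0]
        mask = ~np.eye(n, dtype=bool)
        return self.h[mask]


def build_graph(pcm) -> WeightedGraph:
    """Walk weights from a partial-correlation matrix: w_ij = |rho_ij|,
    diagonal zeroed, labels preserved."""
    rho = np.asarray(pcm.rho, dtype=float)
    if not np.allclose(rho, rho.T, atol=1e-8, rtol=0.0):
        raise ValidationError("partial-correlation matrix asymmetric beyond 1e-8")
    w = np.abs(rho)
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(w, list(pcm.labels))


def normalize(graph: WeightedGraph, d_ref: float | None = None) -> NormalizedWalkModel:
    """Build the self-loop-normalized walk model.

    Parameters
    ----------
    graph
        Connected weighted graph (positive-weight edges), >= 2 nodes.
    d_ref
        Reference degree; defaults to the graph's maximum degree. Passing a
        larger value (e.g. a baseline graph's d_max) converts globally lost
        edge weight into self loops, slowing the walk — required for the
        chain-isolation control where uniform weight loss must register as
        reduced connectivity rather than a pure rescaling.
    """
    if graph.n_nodes < 2:
        raise DegenerateInputError("need at least 2 nodes")
    d = graph.degrees()
    if d.max() <= _DEGREE_FLOOR:
        raise DegenerateInputError("all-zero graph has no walk")
    if (d <= _DEGREE_FLOOR).any():
        raise ConnectivityError("graph has (numerically) isolated nodes")
    if not is_connected(graph.weights, floor=_DEGREE_FLOOR):
        raise ConnectivityError("graph is disconnected; hitting times undefined")
    dmax = float(d.max()) if d_ref is None else float(d_ref)
    if dmax < d.max() - 1e-12:
        raise ValidationError(f"d_ref={dmax} is below the graph's max degree {d.max()}")
    a_prime = np.abs(graph.weights).copy()
    np.fill_diagonal(a_prime, np.maximum(dmax - d, 0.0))
    return NormalizedWalkModel(
        a_prime=a_prime,
        d_max=dmax,
        degrees=d,
        p_prime=a_prime / dmax,
        labels=list(graph.labels),
    )


def laplacian(model: NormalizedWalkModel) -> np.ndarray:
    """Normalized graph Laplacian L = D'^{-1/2}(D' − A')D'^{-1/2} = I − P'.

    Because D' = d_max I the two forms coincide and L is symmetric, with
    eigenvalues in [0, 2] and a zero eigenvalue whose eigenvector is
    constant.
    """
    n = model.n_nodes
    L = np.eye(n) - model.a_prime / model.d_max
    return (L + L.T) / 2.0


def _spectrum(model: NormalizedWalkModel, tol: float = _LAMBDA_TOL):
    lam, U = np.linalg.eigh(laplacian(model))
    null = lam < tol
    if null.sum() != 1:
        raise ConnectivityError(
            f"{int(null.sum())} near-zero Laplacian eigenvalues; the walk is "
            "reducible (graph not connected)"
        )
    return lam[~null], U[:, ~null]


def hitting_spectral(model: NormalizedWalkModel, tol: float = _LAMBDA_TOL) -> HittingTimeMatrix:
    """Hitting-time matrix from the Laplacian spectrum.

    With uniform normalized degrees d'_i = d_max the spectral formula
    reduces to  h_ij = N sum_{k>1} (mu_kj^2 − mu_ki mu_kj)/lambda_k. The
    formula is basis-invariant within repeated eigenspaces, so any
    orthonormal eigenbasis (as returned by ``eigh``) is acceptable.
    """
    lam, U = _spectrum(model, tol)
    n = model.n_nodes
    w = 1.0 / lam
    s = (U * U * w).sum(axis=1)            # s_j = sum_k mu_kj^2 / lambda_k
    cross = (U * w) @ U.T                  # cross_ij = sum_k mu_ki mu_kj / lambda_k
    h = n * (s[None, :] - cross)
    np.fill_diagonal(h, 0.0)
    return HittingTimeMatrix(h=h, labels=list(model.labels))


def hitting_linear(model: NormalizedWalkModel) -> HittingTimeMatrix:
    """Hitting times by direct solution of the first-step equations
    h_ij = 1 + sum_k p'_ik h_kj (i != j, h_jj = 0); independent oracle for
    the spectral route."""
    p = model.p_prime
    n = model.n_nodes
    h = np.zeros((n, n))
    eye = np.eye(n - 1)
    for j in range(n):
        keep = np.arange(n) != j
        a = eye - p[np.ix_(keep, keep)]
        try:
            h[keep, j] = np.linalg.solve(a, np.ones(n - 1))
        except np.linalg.LinAlgError as exc:
            raise ConnectivityError(f"singular first-step system for target {j}") from exc
    return HittingTimeMatrix(h=h, labels=list(model.labels))


def hitting_montecarlo(
    model: NormalizedWalkModel,
    source: int,
    target: int,
    n_walks: int = 10_000,
    max_steps: int = 1_000_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of h[source, target]: mean first-visit step count
    over simulated trajectories of P' (self loops count as steps).

    Returns ``(estimate, standard_error)``. Walks still running after
    ``max_steps`` are censored; if more than 1% are censored the estimate is
    refused as inconclusive.
    """
    if source == target:
        raise ValueError("source must differ from target")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(model.p_prime, axis=1)
    cum[:, -1] = 1.0
    state = np.full(n_walks, source, dtype=np.intp)
    steps = np.zeros(n_walks, dtype=np.int64)
    active = np.ones(n_walks, dtype=bool)
    for _ in range(max_steps):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        u = rng.random(len(idx))
        nxt = (cum[state[idx]] < u[:, None]).sum(axis=1)
        state[idx] = nxt
        steps[idx] += 1
        active[idx] = nxt != target
    censored = int(active.sum())
    if censored:
        import warnings

        warnings.warn(f"{censored}/{n_walks} walks censored at {max_steps} steps",
                      stacklevel=2)
        if censored > 0.01 * n_walks:
            raise EstimationError(
                f"{censored}/{n_walks} walks censored; estimate inconclusive"
            )
    done = steps[~active].astype(float)
    return float(done.mean()), float(done.std(ddof=1) / np.sqrt(len(done)))
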