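"""Distribution and node-level statistics of hitting-time matrices.

Kelley skewness compares the tails of a distribution directly —
P90 + P10 − 2·P50 in raw form — which makes it sensitive to the extreme
hitting times an isolated chain produces while staying robust to interior
reshuffling. The raw form carries the units of the data (hitting-time
steps); the bounded coefficient form divides by P90 − P10. Group-level
effects reported on hitting times (differences around 10 steps of skewness)
are only expressible in the raw form, so raw is the default and the
coefficient sits behind a flag.

The chain index zeta_i scores how much a node's local connectivity looks
like a link of an isolated chain: the sum of its two strongest connection
weights minus all its remaining weights, defined only for nodes sitting on a
chain motif (two dominant neighbors that are themselves weakly connected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import EstimationError, ValidationError
from .graph import WeightedGraph
from .randomwalk import HittingTimeMatrix

__all__ = [
    "SkewnessReport",
    "ChainIndexVector",
    "offdiag_values",
    "kelley_skewness",
    "pearson_skewness",
    "normality_test",
    "skewness_report",
    "to_hitting_profile",
    "chain_index",
]


@dataclass
class SkewnessReport:
    """Skewness and normality summary of one hitting-time distribution."""

    kelley_raw: float
    kelley_coefficient: float | None
    pearson_moment: float
    dagostino: tuple[float, float, float] | None  # (z_skew, chi2, p)
    n_values: int

    def to_dict(self) -> dict:
        return {
            "kelley_raw": self.kelley_raw,
            "kelley_coefficient": self.kelley_coefficient,
            "pearson_moment": self.pearson_moment,
            "dagostino_z_skew": None if self.dagostino is None else self.dagostino[0],
            "dagostino_chi2": None if self.dagostino is None else self.dagostino[1],
            "dagostino_p": None if self.dagostino is None else self.dagostino[2],
            "n_values": self.n_values,
        }


@dataclass
class ChainIndexVector:
    """Per-node chain index; NaN where the node is not on a chain motif."""

    zeta: np.ndarray
    on_motif: np.ndarray
    strongest_pair: list[tuple[int, int] | None]
    labels: list[str] = field(default_factory=list)


def _effectively_constant(v: np.ndarray) -> bool:
    """True when the spread is pure floating-point noise relative to the
    magnitude of the values (e.g. hitting times of a complete graph)."""
    return np.ptp(v) <= 1e-12 * max(1.0, float(np.max(np.abs(v))))


def offdiag_values(H: HittingTimeMatrix) -> np.ndarray:
    """The N(N-1) off-diagonal hitting times in stable row-major order."""
    return H.offdiag()


def kelley_skewness(values, normalized: bool = False) -> float:
    """Percentile skewness P90 + P10 − 2·P50 (raw form, data units) or its
    bounded coefficient (divided by P90 − P10).

    Percentiles use linear interpolation between order statistics (numpy's
    default rule); the value depends on this convention, which is fixed
    here.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 values")
    p10, p50, p90 = np.percentile(v, [10, 50, 90], method="linear")
    raw = p90 + p10 - 2.0 * p50
    if not normalized:
        return float(raw)
    spread = p90 - p10
    if spread <= 1e-12 * max(1.0, abs(p90), abs(p10)):
        raise EstimationError("normalized Kelley skewness undefined: P90 == P10")
    return float(raw / spread)


def pearson_skewness(values) -> float:
    """Moment coefficient of skewness g1 = m3 / m2^{3/2} (biased moments)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValidationError("need at least 3 values")
    if _effectively_constant(v):
        raise EstimationError("skewness undefined for zero-variance data")
    m2 = np.mean((v - v.mean()) ** 2)
    m3 = np.mean((v - v.mean()) ** 3)
    return float(m3 / m2**1.5)


def normality_test(values) -> tuple[float, float, float]:
    """D'Agostino–Pearson omnibus normality test.

    Returns ``(z_skew, chi2, p)``: the skewness z statistic, the combined
    skewness+kurtosis chi-squared statistic (2 df), and its p value.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 20:
        raise ValidationError("normality test needs n >= 20")
    if _effectively_constant(v):
        raise EstimationError("normality test undefined for constant data")
    z_skew, _ = sps.skewtest(v)
    chi2, p = sps.normaltest(v)
    return float(z_skew), float(chi2), float(p)


def skewness_report(values) -> SkewnessReport:
    """Full skewness/normality summary of a value vector."""
    v = np.asarray(values, dtype=float)
    try:
        coeff = kelley_skewness(v, normalized=True)
    except EstimationError:
        coeff = None
    try:
        dago = normality_test(v)
    except (ValidationError, EstimationError):
        dago = None
    return SkewnessReport(
        kelley_raw=kelley_skewness(v),
        kelley_coefficient=coeff,
        pearson_moment=0.0 if _effectively_constant(v) else pearson_skewness(v),
        dagostino=dago,
        n_values=int(v.size),
    )


def to_hitting_profile(H: HittingTimeMatrix) -> np.ndarray:
    """Per-node to-hitting time: node j's mean hitting time from all other
    nodes. Large for nodes at the end of isolated chains."""
    n = H.n_nodes
    return (H.h.sum(axis=0)) / (n - 1)


def chain_index(graph: WeightedGraph, gamma: float = 0.5) -> ChainIndexVector:
    """Chain index zeta_i = w_i,i1 + w_i,i2 − sum of remaining incident
    weights, for nodes on a chain motif.

    A node is on a chain motif when its two strongest connections (ties
    broken toward the lower node index) strictly dominate every remaining
    incident weight and the two strong neighbors are only weakly connected
    to each other: w(i1, i2) < gamma * w2. An interior node of an isolated
    unit path scores the maximum zeta = 2; a hub with many equal connections
    is excluded or scores a large negative value.
    """
    if not 0 < gamma <= 1:
        raise ValidationError("gamma must be in (0, 1]")
    w = graph.weights
    n = graph.n_nodes
    zeta = np.full(n, np.nan)
    on = np.zeros(n, dtype=bool)
    pairs: list[tuple[int, int] | None] = [None] * n
    for i in range(n):
        nbrs = np.nonzero(w[i] > 0)[0]
        if len(nbrs) < 2:
            continue
        # sort by (-weight, index): strongest first, ties to lower index
        order = nbrs[np.lexsort((nbrs, -w[i, nbrs]))]
        i1, i2 = int(order[0]), int(order[1])
        w2 = w[i, i2]
        rest = order[2:]
        if len(rest) and w[i, rest].max() >= w2:  # strictness on w2
            continue
        if w[i1, i2] >= gamma * w2:
            continue
        on[i] = True
        pairs[i] = (i1, i2)
        zeta[i] = w[i, i1] + w2 - w[i, rest].sum()
    return ChainIndexVector(zeta=zeta, on_motif=on, strongest_pair=pairs,
                            labels=list(graph.labels))
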