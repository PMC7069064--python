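"""Synthetic multivariate time series and partial-correlation estimation.

The walk model consumes a connectivity matrix of partial correlations, which
in real use comes from regional BOLD time series. This module provides (a) a
Gaussian generator whose samples carry a prescribed conditional-independence
structure — the population partial correlation between two regions is
nonzero exactly where the structure graph has an edge — and (b) the
partial-correlation estimator itself, via the (optionally shrunk) inverse
sample covariance.

The generator draws temporally independent samples: only the spatial
conditional-dependence pattern matters to the walk statistics, so BOLD
autocorrelation and hemodynamics are deliberately left out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, ValidationError
from .graph import WeightedGraph

__all__ = [
    "TimeSeriesPanel",
    "PartialCorrelationMatrix",
    "generate_panel",
    "estimate_partial_correlation",
]


@dataclass
class TimeSeriesPanel:
    """T x N panel of regional signals for one subject."""

    data: np.ndarray
    labels: list[str]
    subject_id: str = "sub-0"
    condition: str | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] < 2:
            raise ValidationError("panel must be T x N with T >= 2")
        if np.isnan(d).any():
            raise ValidationError("panel contains missing values")
        if (d.std(axis=0) == 0).any():
            raise ValidationError("panel has constant columns")
        if len(self.labels) != d.shape[1]:
            raise ValidationError("label count does not match column count")
        self.data = d

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, columns=self.labels).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **meta) -> "TimeSeriesPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(float), list(df.columns), **meta)


@dataclass
class PartialCorrelationMatrix:
    """Symmetric matrix of partial correlations, unit diagonal."""

    rho: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        if not np.allclose(r, r.T, atol=1e-8, rtol=0.0):
            raise ValidationError("partial-correlation matrix must be symmetric")
        r = (r + r.T) / 2.0
        if (np.abs(r) > 1 + 1e-12).any():
            raise ValidationError("partial correlations must lie in [-1, 1]")
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        self.rho = r


def generate_panel(
    structure: WeightedGraph,
    T: int = 2000,
    coupling: float = 0.2,
    noise_sd: float = 1.0,
    seed: int | None = None,
    subject_id: str = "sub-0",
    condition: str | None = None,
    covariates: dict | None = None,
) -> TimeSeriesPanel:
    """Draw T iid samples from a zero-mean Gaussian whose precision matrix
    encodes ``structure``.

    The precision matrix is built diagonally dominant:
    Omega_ij = −coupling * w_ij (i != j), Omega_ii = 1 + coupling * d_i,
    so the population partial correlation
    rho_ij = coupling * w_ij / sqrt((1 + c d_i)(1 + c d_j)) is positive
    exactly on the structure's edges. ``noise_sd`` scales the marginal
    amplitude (irrelevant after standardization downstream).
    """
    w = structure.weights
    n = structure.n_nodes
    omega = -coupling * w
    np.fill_diagonal(omega, 1.0 + coupling * structure.degrees())
    eigmin = float(np.linalg.eigvalsh(omega).min())
    if eigmin <= 0:
        raise ValidationError(
            f"coupling={coupling} makes the precision matrix non-positive-definite "
            f"(min eigenvalue {eigmin:.3g}); reduce coupling"
        )
    cov = np.linalg.inv(omega) * noise_sd**2
    rng = np.random.default_rng(seed)
    data = rng.multivariate_normal(np.zeros(n), cov, size=T, method="cholesky")
    return TimeSeriesPanel(
        data=data,
        labels=list(structure.labels),
        subject_id=subject_id,
        condition=condition,
        covariates=covariates or {},
    )


def population_partial_correlation(structure: WeightedGraph, coupling: float) -> np.ndarray:
    """Closed-form partial correlation implied by :func:`generate_panel`."""
    d = structure.degrees()
    denom = np.sqrt(np.outer(1 + coupling * d, 1 + coupling * d))
    rho = coupling * structure.weights / denom
    np.fill_diagonal(rho, 1.0)
    return rho


def estimate_partial_correlation(
    panel: TimeSeriesPanel,
    shrinkage: float | str = "auto",
) -> PartialCorrelationMatrix:
    """Partial correlations rho_ij = −Omega_ij / sqrt(Omega_ii Omega_jj)
    from the inverse of the (optionally shrunk) sample covariance.

    ``shrinkage="auto"`` applies Ledoit–Wolf shrinkage (the default: with
    many regions and typical scan lengths the raw covariance is
    ill-conditioned); a float in [0, 1] mixes the sample covariance with a
    scaled identity; ``0`` inverts the raw covariance and requires T > N.
    Columns are standardized before estimation.
    """
    t, n = panel.data.shape
    if t <= 3:
        raise ValidationError("need more than 3 timepoints")
    x = panel.data - panel.data.mean(axis=0)
    x = x / x.std(axis=0, ddof=0)

    if shrinkage == "auto":
        from sklearn.covariance import LedoitWolf

        cov = LedoitWolf(assume_centered=True).fit(x).covariance_
    else:
        s = float(shrinkage)
        if not 0.0 <= s <= 1.0:
            raise ValidationError("shrinkage must be in [0, 1] or 'auto'")
        sample = x.T @ x / t
        cov = (1 - s) * sample + s * (np.trace(sample) / n) * np.eye(n)

    try:
        omega = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "covariance is singular; use shrinkage='auto' or a positive shrinkage"
        ) from exc
    cond = np.linalg.cond(cov)
    if cond > 1e12:
        raise EstimationError(
            f"covariance condition number {cond:.2g} too high; increase shrinkage"
        )
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return PartialCorrelationMatrix(rho=rho, labels=list(panel.labels))
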