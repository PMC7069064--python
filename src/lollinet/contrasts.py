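"""Group comparison harnesses: per-node contrasts with Bonferroni
correction, and skewness regression models.

Node contrasts operate on per-subject node profiles — to-hitting times
(mean hitting time into each node) or chain indices — and run a t test per
node, Bonferroni-adjusted over the number of nodes, ranking nodes by
absolute effect so the "top k changed regions" convention is directly
available.

Skewness models regress per-subject distribution skewness on a contrast
variable plus covariates. Unpaired designs use ordinary least squares with
dummy-coded group (explicit reference level) and gender (reference female)
and mean-centered age. Paired designs (task vs rest within subject) reduce
the subject random effect to within-subject differences regressed on
covariates — the paired-contrast equivalent of a random-intercept model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import DesignError, ValidationError
from .randomwalk import HittingTimeMatrix
from .stats import ChainIndexVector, to_hitting_profile

__all__ = ["NodeContrastTable", "compare_nodes", "fit_skewness_model"]


@dataclass
class NodeContrastTable:
    """Per-node contrast results, ranked by |effect|."""

    table: pd.DataFrame  # node, effect, t, p_raw, p_adjusted, significant
    contrast: str = ""
    n_a: int = 0
    n_b: int = 0
    correction: str = "bonferroni"
    alpha: float = 0.05

    def top(self, k: int = 10) -> pd.DataFrame:
        """The k nodes with the largest absolute effects."""
        if k > len(self.table):
            import warnings

            warnings.warn(f"k={k} exceeds node count {len(self.table)}; clipping",
                          stacklevel=2)
            k = len(self.table)
        return self.table.head(k)


def _as_profiles(group, labels_out: list) -> np.ndarray:
    rows = []
    for item in group:
        if isinstance(item, HittingTimeMatrix):
            rows.append(to_hitting_profile(item))
            labels = item.labels
        elif isinstance(item, ChainIndexVector):
            rows.append(item.zeta)
            labels = item.labels
        else:
            rows.append(np.asarray(item, dtype=float))
            labels = None
        if labels is not None:
            if labels_out and labels_out != list(labels):
                raise ValidationError("node labels differ across subjects")
            labels_out[:] = list(labels)
    return np.vstack(rows)


def compare_nodes(
    group_a,
    group_b,
    paired: bool = False,
    alpha: float = 0.05,
    contrast: str = "A-vs-B",
) -> NodeContrastTable:
    """Per-node t tests between two groups of node profiles.

    Accepts lists of :class:`HittingTimeMatrix` (converted to to-hitting
    profiles), :class:`ChainIndexVector` (zeta, NaN off-motif entries
    omitted pairwise), or raw per-node vectors. ``paired=True`` requires
    subject-aligned lists of equal length. p values are Bonferroni-adjusted
    over the number of nodes; effects are mean differences (A − B), and the
    table is sorted by descending |effect|.
    """
    labels: list = []
    a = _as_profiles(group_a, labels)
    b = _as_profiles(group_b, labels)
    if a.shape[1] != b.shape[1]:
        raise ValidationError("groups have different node counts")
    if paired and a.shape[0] != b.shape[0]:
        raise DesignError("paired comparison needs equal, subject-aligned group sizes")
    n_nodes = a.shape[1]
    if not labels:
        labels = [f"n{i}" for i in range(n_nodes)]

    eff = np.full(n_nodes, np.nan)
    tt = np.full(n_nodes, np.nan)
    pp = np.full(n_nodes, np.nan)
    for j in range(n_nodes):
        av, bv = a[:, j], b[:, j]
        if paired:
            ok = ~np.isnan(av) & ~np.isnan(bv)
            d = av[ok] - bv[ok]
            if len(d) < 2 or np.all(d == d[0]):
                eff[j] = d.mean() if len(d) else np.nan
                tt[j], pp[j] = (0.0, 1.0) if len(d) and np.allclose(d, 0) else (np.nan, np.nan)
                continue
            res = sps.ttest_rel(av[ok], bv[ok])
            eff[j] = d.mean()
        else:
            av, bv = av[~np.isnan(av)], bv[~np.isnan(bv)]
            if len(av) < 2 or len(bv) < 2:
                continue
            if np.ptp(av) == 0 and np.ptp(bv) == 0:
                eff[j] = av.mean() - bv.mean()
                tt[j], pp[j] = (0.0, 1.0) if av.mean() == bv.mean() else (np.inf, 0.0)
                continue
            res = sps.ttest_ind(av, bv)
            eff[j] = av.mean() - bv.mean()
        tt[j], pp[j] = float(res.statistic), float(res.pvalue)

    p_adj = np.minimum(pp * n_nodes, 1.0)
    df = pd.DataFrame(
        {
            "node": labels,
            "effect": eff,
            "t": tt,
            "p_raw": pp,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    ).sort_values("effect", key=np.abs, ascending=False, ignore_index=True)
    return NodeContrastTable(table=df, contrast=contrast, n_a=a.shape[0],
                             n_b=b.shape[0], alpha=alpha)


def fit_skewness_model(
    records: pd.DataFrame,
    contrast: str,
    paired_on: str | None = None,
    reference: str | None = None,
    covariates: tuple[str, ...] = ("gender", "age"),
) -> pd.DataFrame:
    """Regress per-subject skewness on a contrast variable plus covariates.

    ``records`` needs columns ``skewness``, the ``contrast`` column, and any
    of the covariates present. Unpaired: OLS of skewness on dummy-coded
    contrast (reference level = ``reference`` or the alphabetically first
    level), dummy-coded gender (reference female) and mean-centered age.
    Paired (``paired_on`` = subject column): within-subject differences
    (non-reference minus reference level) regressed on covariates; the
    intercept is the contrast effect.

    Returns a coefficient table (estimate, std error, t, p per term).
    """
    df = records.copy()
    if "skewness" not in df.columns or contrast not in df.columns:
        raise DesignError(f"records need 'skewness' and '{contrast}' columns")
    levels = sorted(df[contrast].astype(str).unique())
    if len(levels) < 2:
        raise DesignError(f"contrast '{contrast}' has a single level: {levels}")
    ref = str(reference) if reference is not None else levels[0]
    if ref not in levels:
        raise DesignError(f"reference level {ref!r} not among {levels}")

    def _covariate_design(frame: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        if "gender" in covariates and "gender" in frame.columns:
            g = frame["gender"].astype(str)
            for lev in sorted(g.unique()):
                if lev.lower() in ("female", "f"):
                    continue
                cols[f"gender[{lev}]"] = (g == lev).astype(float)
        if "age" in covariates and "age" in frame.columns:
            cols["age_centered"] = frame["age"].astype(float) - frame["age"].astype(float).mean()
        return pd.DataFrame(cols, index=frame.index)

    if paired_on is None:
        x = _covariate_design(df)
        for lev in levels:
            if lev == ref:
                continue
            x[f"{contrast}[{lev}]"] = (df[contrast].astype(str) == lev).astype(float)
        x = sm.add_constant(x)
        y = df["skewness"].astype(float)
        if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
            raise DesignError("rank-deficient design matrix")
        fit = sm.OLS(y, x).fit()
    else:
        if len(levels) != 2:
            raise DesignError("paired design requires exactly 2 contrast levels")
        other = [lv for lv in levels if lv != ref][0]
        wide = df.pivot_table(index=paired_on, columns=contrast, values="skewness",
                              aggfunc="first")
        if wide[[ref, other]].isna().any().any():
            raise DesignError("unbalanced pairing: some subjects lack a condition")
        diff = (wide[other] - wide[ref]).rename("skewness_diff")
        meta = df.drop_duplicates(paired_on).set_index(paired_on).loc[diff.index]
        x = _covariate_design(meta)
        x = sm.add_constant(x)
        x = x.rename(columns={"const": f"{contrast}[{other}]"})
        fit = sm.OLS(diff.astype(float), x).fit()

    return pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "std_error": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
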