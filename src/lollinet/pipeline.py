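"""File I/O, run configuration, and end-to-end pipelines.

A subject's input — a regional time-series panel or a ready connectivity
matrix — flows through partial-correlation estimation, |rho| walk weights,
self-loop normalization, spectral hitting times, and the distribution/node
statistics. A group run assembles per-subject outputs into node contrasts
and skewness models. Every stage failure is re-raised tagged with the stage
name; every run can write its config next to its outputs so reruns are
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contrasts as ct
from . import randomwalk as rw
from . import stats as st
from . import timeseries as ts
from .errors import PipelineError, ValidationError
from .graph import WeightedGraph

__all__ = [
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "run_subject_pipeline",
    "run_group_pipeline",
    "SubjectResult",
]


@dataclass
class RunConfig:
    """Pipeline switches; JSON-serializable, written next to outputs."""

    shrinkage: float | str = "auto"
    gamma: float = 0.5
    kelley_normalized: bool = False
    alpha: float = 0.05
    top_k: int = 10
    seed: int | None = None
    out_dir: str | None = None
    log_level: str = "INFO"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _read_square_table(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(c) for c in df.columns]
    row_labels = [str(r) for r in df.index]
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"{path}: table is {df.shape[0]}x{df.shape[1]}, not square")
    if labels != row_labels:
        raise ValidationError(f"{path}: row labels do not match column labels")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValidationError(f"{path}: NaN at row {row_labels[r]!r}, column {labels[c]!r}")
    return values, labels


def write_matrix(path, values: np.ndarray, labels: list[str]) -> None:
    """Square tab-separated matrix with a label header row and first column."""
    pd.DataFrame(np.asarray(values, float), index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def read_matrix(path, kind: str = "connectivity"):
    """Read a labeled square matrix as connectivity (partial correlations,
    symmetrized if asymmetry <= 1e-8) or as a hitting-time matrix."""
    values, labels = _read_square_table(path)
    if kind == "connectivity":
        if not np.allclose(values, values.T, atol=1e-8, rtol=0.0):
            worst = float(np.abs(values - values.T).max())
            raise ValidationError(
                f"{path}: connectivity asymmetric by {worst:.3g} (> 1e-8); inspect the file"
            )
        return ts.PartialCorrelationMatrix(rho=(values + values.T) / 2.0, labels=labels)
    if kind == "hitting":
        return rw.HittingTimeMatrix(h=values, labels=labels)
    raise ValueError(f"unknown kind {kind!r}")


@dataclass
class SubjectResult:
    """Everything the subject pipeline computes for one input."""

    hitting: rw.HittingTimeMatrix
    skewness: st.SkewnessReport
    chain: st.ChainIndexVector
    profile: np.ndarray
    labels: list[str]
    subject_id: str = "sub-0"
    condition: str | None = None
    covariates: dict = field(default_factory=dict)

    def write(self, outdir, config: RunConfig | None = None) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(out / "hitting.tsv", self.hitting.h, self.labels)
        pd.DataFrame({"node": self.labels, "to_hitting": self.profile,
                      "zeta": self.chain.zeta, "on_motif": self.chain.on_motif}).to_csv(
            out / "nodes.tsv", sep="\t", index=False)
        with open(out / "skewness.json", "w") as fh:
            json.dump(self.skewness.to_dict(), fh, indent=2)
        if config is not None:
            config.to_json(out / "config.json")


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc


def run_subject_pipeline(subject, config: RunConfig | None = None) -> SubjectResult:
    """Panel or connectivity matrix -> hitting times, skewness report,
    chain index, to-hitting profile.

    ``subject`` may be a :class:`TimeSeriesPanel` (partial correlations are
    estimated first), a :class:`PartialCorrelationMatrix`, or a
    :class:`WeightedGraph` already holding walk weights.
    """
    cfg = config or RunConfig()
    meta = {"subject_id": "sub-0", "condition": None, "covariates": {}}
    if isinstance(subject, ts.TimeSeriesPanel):
        meta = {"subject_id": subject.subject_id, "condition": subject.condition,
                "covariates": subject.covariates}
        pcm = _stage("partial_correlation", ts.estimate_partial_correlation,
                     subject, shrinkage=cfg.shrinkage)
        graph = _stage("build_graph", rw.build_graph, pcm)
    elif isinstance(subject, ts.PartialCorrelationMatrix):
        graph = _stage("build_graph", rw.build_graph, subject)
    elif isinstance(subject, WeightedGraph):
        graph = subject
    else:
        raise TypeError(f"unsupported subject input {type(subject)!r}")

    model = _stage("normalize", rw.normalize, graph)
    hitting = _stage("hitting_spectral", rw.hitting_spectral, model)
    values = hitting.offdiag()
    report = _stage("skewness", st.skewness_report, values)
    chain = _stage("chain_index", st.chain_index, graph, gamma=cfg.gamma)
    profile = _stage("to_hitting_profile", st.to_hitting_profile, hitting)
    return SubjectResult(hitting=hitting, skewness=report, chain=chain,
                         profile=profile, labels=list(graph.labels), **meta)


def run_group_pipeline(
    subjects: list[SubjectResult],
    contrast: str = "condition",
    paired: bool = False,
    config: RunConfig | None = None,
    reference: str | None = None,
) -> dict:
    """Assemble per-subject outputs into group statistics.

    Splits ``subjects`` by the value of ``contrast`` (a covariate key, or
    'condition'), then: per-node to-hitting contrast, per-node chain-index
    contrast (both Bonferroni over nodes, top-k by |effect|), and the
    skewness regression. Returns a dict with 'hitting_contrast',
    'chain_contrast', 'skewness_model', 'top_nodes'.
    """
    cfg = config or RunConfig()

    def _level(s: SubjectResult):
        if contrast == "condition":
            return s.condition
        return s.covariates.get(contrast)

    levels = sorted({str(_level(s)) for s in subjects})
    if len(levels) != 2:
        raise ValidationError(f"group pipeline needs exactly 2 levels of {contrast!r}, "
                              f"got {levels}")
    ref = str(reference) if reference is not None else levels[0]
    other = [lv for lv in levels if lv != ref][0]
    group_a = [s for s in subjects if str(_level(s)) == other]
    group_b = [s for s in subjects if str(_level(s)) == ref]
    if min(len(group_a), len(group_b)) < 2:
        raise ValidationError("need at least 2 subjects per group")
    if paired:
        group_a = sorted(group_a, key=lambda s: s.subject_id)
        group_b = sorted(group_b, key=lambda s: s.subject_id)
        if [s.subject_id for s in group_a] != [s.subject_id for s in group_b]:
            raise ValidationError("paired groups must contain the same subjects")

    hit_contrast = _stage(
        "compare_nodes", ct.compare_nodes,
        [s.hitting for s in group_a], [s.hitting for s in group_b],
        paired=paired, alpha=cfg.alpha, contrast=f"{other}-vs-{ref}")
    chain_contrast = _stage(
        "compare_chain", ct.compare_nodes,
        [s.chain for s in group_a], [s.chain for s in group_b],
        paired=paired, alpha=cfg.alpha, contrast=f"{other}-vs-{ref}:zeta")

    records = pd.DataFrame(
        {
            "subject": [s.subject_id for s in subjects],
            "skewness": [
                s.skewness.kelley_coefficient if cfg.kelley_normalized
                else s.skewness.kelley_raw
                for s in subjects
            ],
            contrast: [str(_level(s)) for s in subjects],
            **{
                k: [s.covariates.get(k) for s in subjects]
                for k in ("gender", "age")
                if any(k in s.covariates for s in subjects)
            },
        }
    )
    model = _stage("fit_skewness_model", ct.fit_skewness_model, records,
                   contrast=contrast, paired_on="subject" if paired else None,
                   reference=ref)
    return {
        "hitting_contrast": hit_contrast,
        "chain_contrast": chain_contrast,
        "skewness_model": model,
        "top_nodes": hit_contrast.top(cfg.top_k),
    }
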