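"""Subject-level functional connectomes: construction, vectorization, QC.

A connectome here is a symmetric node x node matrix of Fisher z-transformed
Pearson correlations between node timeseries, with a zero diagonal. All
downstream feature handling uses the canonical upper-triangle edge order
(0-based, i < j, row-major), fixed once here so that masks, exports and
oracles can never silently misalign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NodeTimeSeries",
    "ConnectivityMatrix",
    "MotionRecord",
    "MotionConfig",
    "n_edges",
    "edge_pairs",
    "build_connectome",
    "vectorize_edges",
    "devectorize_edges",
    "average_runs",
    "apply_motion_exclusion",
]

# |r| above this is treated as numerically perfect correlation (degenerate).
_DEGENERATE_R = 1.0 - 1e-12


@dataclass
class NodeTimeSeries:
    """Node-averaged BOLD timeseries for one subject/run (nodes x timepoints)."""

    subject_id: str
    run_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("timeseries must be a 2-D (nodes x timepoints) array")
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if not np.isfinite(self.values).all():
            raise ValueError(
                f"timeseries for {self.subject_id}/{self.run_id} contains missing values"
            )

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix with a zero diagonal."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("connectivity matrix must be finite everywhere")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.diag(v) == 0):
            raise ValueError("connectivity matrix diagonal must be exactly 0")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MotionRecord:
    """Mean framewise displacement (mm) of one subject/run."""

    subject_id: str
    run_id: str
    mean_fd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_fd) or self.mean_fd < 0:
            raise ValueError("mean_fd must be a nonnegative number")


@dataclass(frozen=True)
class MotionConfig:
    """Motion-exclusion rule.

    fd_threshold
        Mean-FD cutoff in millimetres; comparison is strict ('>' excludes).
    run_level
        When True, runs above threshold are dropped first and the subject is
        then judged on the mean of mean-FD across runs (multi-run datasets);
        when False the subject's overall mean decides directly.
    subject_mean_over
        'retained' (default) averages mean-FD over the surviving runs only;
        'all' averages over every run. Only meaningful when run_level is True.
    """

    fd_threshold: float = 0.15
    run_level: bool = False
    subject_mean_over: str = "retained"

    def __post_init__(self) -> None:
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be positive")
        if self.subject_mean_over not in ("retained", "all"):
            raise ValueError("subject_mean_over must be 'retained' or 'all'")


def n_edges(n_nodes: int) -> int:
    """Number of unique edges among ``n_nodes`` nodes: n*(n-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) node indices per canonical edge: 0-based upper triangle, row-major."""
    return np.triu_indices(n_nodes, k=1)


def build_connectome(ts: NodeTimeSeries) -> ConnectivityMatrix:
    """Fisher z-transformed Pearson correlation matrix of node timeseries.

    Raises on zero-variance nodes and on perfect off-diagonal correlations
    (|r| = 1 has no finite Fisher z); degenerate inputs should surface as
    errors rather than be clipped away.
    """
    x = ts.values
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance node(s): {bad.tolist()}")
    r = np.corrcoef(x)
    off = ~np.eye(ts.n_nodes, dtype=bool)
    if np.any(np.abs(r[off]) >= _DEGENERATE_R):
        i, j = np.nonzero((np.abs(r) >= _DEGENERATE_R) & off)
        raise ValueError(
            f"perfect correlation between nodes {i[0]} and {j[0]}: "
            "no finite Fisher z (degenerate input)"
        )
    with np.errstate(divide="ignore"):  # diagonal r=1 is zeroed below
        z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # enforce exact symmetry
    return ConnectivityMatrix(subject_id=ts.subject_id, values=z)


def vectorize_edges(cm: ConnectivityMatrix) -> np.ndarray:
    """Length-E vector of unique edges in canonical upper-triangle order."""
    i, j = edge_pairs(cm.n_nodes)
    return cm.values[i, j].copy()


def devectorize_edges(vec: np.ndarray, n_nodes: int, subject_id: str = "") -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_edges`; reconstructs the symmetric matrix."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n_edges(n_nodes),):
        raise ValueError(
            f"edge vector length {vec.size} inconsistent with {n_nodes} nodes"
        )
    m = np.zeros((n_nodes, n_nodes))
    i, j = edge_pairs(n_nodes)
    m[i, j] = vec
    m[j, i] = vec
    return ConnectivityMatrix(subject_id=subject_id, values=m)


def average_runs(cms: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of one subject's retained runs (on the Fisher-z scale)."""
    if len(cms) == 0:
        raise ValueError("no retained runs")
    n = cms[0].n_nodes
    sid = cms[0].subject_id
    for cm in cms[1:]:
        if cm.n_nodes != n:
            raise ValueError("mismatched n_nodes across runs")
        if cm.subject_id != sid:
            raise ValueError("average_runs expects runs of a single subject")
    mean = np.mean([cm.values for cm in cms], axis=0)
    return ConnectivityMatrix(subject_id=sid, values=mean)


def apply_motion_exclusion(
    records: Iterable[MotionRecord], cfg: MotionConfig
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Drop high-motion runs/subjects; returns retained runs and an exclusion log.

    Returns
    -------
    retained : dict
        subject_id -> list of retained run_ids (insertion order preserved).
    log : DataFrame
        One row per exclusion with columns subject_id, run_id (empty for
        subject-level), reason, value.
    """
    by_subject: dict[str, list[MotionRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)

    retained: dict[str, list[str]] = {}
    log_rows: list[dict] = []
    thr = cfg.fd_threshold
    for sid, recs in by_subject.items():
        fds = np.array([r.mean_fd for r in recs])
        if cfg.run_level:
            keep = fds <= thr
            for rec, k in zip(recs, keep):
                if not k:
                    log_rows.append(
                        dict(subject_id=sid, run_id=rec.run_id,
                             reason="run mean_fd above threshold", value=rec.mean_fd)
                    )
            if not keep.any():
                log_rows.append(
                    dict(subject_id=sid, run_id="",
                         reason="no runs below threshold", value=float(fds.min()))
                )
                continue
            pool = fds[keep] if cfg.subject_mean_over == "retained" else fds
            subj_mean = float(pool.mean())
            if subj_mean > thr:
                log_rows.append(
                    dict(subject_id=sid, run_id="",
                         reason=f"mean FD across {cfg.subject_mean_over} runs above threshold",
                         value=subj_mean)
                )
                continue
            retained[sid] = [r.run_id for r, k in zip(recs, keep) if k]
        else:
            subj_mean = float(fds.mean())
            if subj_mean > thr:
                log_rows.append(
                    dict(subject_id=sid, run_id="",
                         reason="overall mean_fd above threshold", value=subj_mean)
                )
                continue
            retained[sid] = [r.run_id for r in recs]

    log = pd.DataFrame(log_rows, columns=["subject_id", "run_id", "reason", "value"])
    return retained, log
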