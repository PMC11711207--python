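"""Readers, writers and the end-to-end pipeline orchestration.

All interchange is plain text (CSV/TSV/JSON/YAML). Subjects are always
joined by id — ordering inside files is never semantic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome import (
    ConnectivityMatrix,
    MotionConfig,
    MotionRecord,
    NodeTimeSeries,
    apply_motion_exclusion,
    average_runs,
    build_connectome,
    vectorize_edges,
)
from .core import (
    PermutationConfig,
    SelectionConfig,
    edge_presence,
    finalize_model,
    permutation_test,
    run_cv,
    select_models,
)
from .ffmq import ITEM_COLUMNS, SCORE_COLUMNS, score_ffmq

__all__ = [
    "RunConfig",
    "load_phenotypes",
    "load_edges",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Paths and parameters for one end-to-end pipeline run."""

    edges_manifest: str
    phenotype: str
    out_dir: str
    targets: tuple = ("total",)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    motion: MotionConfig = field(default_factory=MotionConfig)
    seed: int = 0
    alpha: float = 0.05

    def validate(self) -> None:
        missing = [
            p for p in (self.edges_manifest, self.phenotype) if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")

    def digest(self) -> str:
        payload = json.dumps(
            {
                "edges_manifest": str(self.edges_manifest),
                "phenotype": str(self.phenotype),
                "targets": list(self.targets),
                "selection": vars(self.selection) | {},
                "permutation": {
                    "n_perm": self.permutation.n_perm,
                    "rng_seed": self.permutation.rng_seed,
                    "add_one": self.permutation.add_one,
                },
                "motion": {
                    "fd_threshold": self.motion.fd_threshold,
                    "run_level": self.motion.run_level,
                    "subject_mean_over": self.motion.subject_mean_over,
                },
                "seed": self.seed,
                "alpha": self.alpha,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_phenotypes(path: str | Path) -> pd.DataFrame:
    """Load and validate the phenotype CSV; auto-score items when present.

    The table must have a unique ``subject_id`` column. When item columns
    (item_01..item_39) are present and subscale columns absent, the FFMQ
    scoring engine fills in AA..O and the totals. Validation problems are
    collected and reported together.
    """
    tab = pd.read_csv(path)
    problems = []
    if "subject_id" not in tab.columns:
        raise ValueError("phenotype file must have a subject_id column")
    dup = tab["subject_id"][tab["subject_id"].duplicated()].unique().tolist()
    if dup:
        problems.append(f"duplicate subject id(s): {dup}")
    has_items = all(c in tab.columns for c in ITEM_COLUMNS)
    has_scores = any(c in tab.columns for c in SCORE_COLUMNS)
    if has_items and not has_scores:
        scored = score_ffmq(tab.set_index("subject_id")[ITEM_COLUMNS])
        tab = tab.merge(scored, left_on="subject_id", right_index=True)
    for col in SCORE_COLUMNS + ["mean_fd"]:
        if col in tab.columns and not pd.api.types.is_numeric_dtype(tab[col]):
            problems.append(f"non-numeric values in column {col!r}")
    if problems:
        raise ValueError("; ".join(problems))
    return tab


def _read_matrix_csv(path: Path) -> np.ndarray:
    tab = pd.read_csv(path, index_col=0)
    m = tab.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix file is not square: {path}")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError(f"asymmetric connectivity matrix: {path}")
    return m


def _read_timeseries_csv(path: Path) -> np.ndarray:
    tab = pd.read_csv(path, sep=None, engine="python")
    if tab.isna().any().any():
        raise ValueError(f"missing values in timeseries file: {path}")
    return tab.to_numpy(dtype=float).T  # rows=timepoints on disk -> nodes x T


def load_edges(
    manifest_path: str | Path,
    phenotype: pd.DataFrame,
    motion: MotionConfig | None = None,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Assemble the subject x E edge matrix a manifest describes.

    The manifest CSV has columns subject_id, run_id, path, mean_fd; paths
    are relative to the manifest. Square-matrix files are validated and
    vectorized; timeseries files (rows = timepoints, columns = nodes) are
    routed through the Fisher-z connectome builder. Runs surviving motion
    exclusion are averaged per subject. Subjects are aligned to the
    phenotype table by id.

    Returns (edges, aligned phenotype subset, exclusion log).
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    root = manifest_path.parent

    pheno_ids = set(phenotype["subject_id"])
    man_ids = set(manifest["subject_id"])
    only_m = sorted(man_ids - pheno_ids)
    only_p = sorted(pheno_ids - man_ids)
    if only_m or only_p:
        raise ValueError(
            f"subject mismatch: only in manifest {only_m}, only in phenotypes {only_p}"
        )

    records = [
        MotionRecord(r.subject_id, str(r.run_id), float(r.mean_fd))
        for r in manifest.itertuples()
    ]
    retained, log = apply_motion_exclusion(records, motion or MotionConfig())

    vectors: dict[str, np.ndarray] = {}
    for sid, run_ids in retained.items():
        cms = []
        for rid in run_ids:
            row = manifest[
                (manifest["subject_id"] == sid) & (manifest["run_id"].astype(str) == rid)
            ].iloc[0]
            p = root / row["path"]
            if p.suffix in (".csv", ".tsv") and "timeseries" in p.name:
                ts = NodeTimeSeries(subject_id=sid, run_id=rid, values=_read_timeseries_csv(p))
                cms.append(build_connectome(ts))
            else:
                cms.append(ConnectivityMatrix(subject_id=sid, values=_read_matrix_csv(p)))
        vectors[sid] = vectorize_edges(average_runs(cms))

    kept = phenotype[phenotype["subject_id"].isin(vectors)].reset_index(drop=True)
    edges = np.vstack([vectors[sid] for sid in kept["subject_id"]])
    return edges, kept, log


def run_pipeline(cfg: RunConfig) -> dict:
    """Exclusion -> scoring -> training -> permutation -> selection, to disk.

    Writes per-target model directories, a pipeline report JSON embedding
    the config digest and seed, and the exclusion log. Returns the report.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load_phenotypes"
    try:
        pheno = load_phenotypes(cfg.phenotype)
        stage = "load_edges"
        edges, pheno, log = load_edges(cfg.edges_manifest, pheno, cfg.motion)
        log.to_csv(out / "exclusion_log.csv", index=False)

        report: dict = {
            "version": __version__,
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "n_subjects": int(len(pheno)),
            "n_excluded": int(log["subject_id"].nunique()) if len(log) else 0,
            "targets": {},
        }
        for target in cfg.targets:
            stage = f"train[{target}]"
            y = pheno[target].to_numpy(dtype=float)
            cv = run_cv(edges, y, cfg.selection)
            stage = f"permute[{target}]"
            null, p_perm = permutation_test(
                edges, y, cfg.selection, cfg.permutation, observed_r=cv.r["combined"]
            )
            stage = f"finalize[{target}]"
            model = finalize_model(edges, y, cfg.selection, target_name=target)
            model.save(out / f"model_{target}")
            presence = edge_presence(cv, model)
            report["targets"][target] = {
                "cv_r": cv.r,
                "permutation_p": p_perm,
                "n_positive_edges": model.positive_mask.size,
                "n_negative_edges": model.negative_mask.size,
                "edge_presence_percent": presence,
                "n_degenerate_folds": cv.n_degenerate_folds,
            }
        selected = select_models(
            {t: report["targets"][t]["permutation_p"] for t in cfg.targets},
            alpha=cfg.alpha,
        )
        report["selected_models"] = selected
    except Exception as exc:  # annotate with the failing stage, then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "pipeline_report.json").write_text(json.dumps(report, indent=2))
    return report
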