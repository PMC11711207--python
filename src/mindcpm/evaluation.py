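"""Applying trained CPMs to independent data: generalization, overlap, stability.

A frozen model (masks + coefficients) is applied to an external dataset
without re-screening: mask, sum to network strength, predict through the
stored linear model, then compare predicted and observed scores with
Pearson correlation, mean squared error and covariate-controlled partial
correlations. Further operations quantify cross-model relationships
(strength correlation, mask overlap against a random-mask null), split-half
stability of network strengths against a single-edge null, and the pooled
shuffle-then-split sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CPMModel,
    PermutationConfig,
    SelectionConfig,
    VARIANTS,
    _corr_pvalues,
    _pearson,
    _strength_columns,
    finalize_model,
    partial_correlation,
    run_cv,
    permutation_test,
)

__all__ = [
    "EvaluationReport",
    "OverlapReport",
    "StabilityReport",
    "apply_model",
    "cross_predict",
    "strength_correlation",
    "overlap_percent",
    "mask_overlap",
    "split_half_stability",
    "combined_shuffle_split",
]


@dataclass
class EvaluationReport:
    """Predicted-vs-observed comparison of one model on one dataset."""

    dataset: str
    model: str
    variant: str
    predicted: np.ndarray
    observed: np.ndarray
    r: float
    p: float
    mse: float
    n: int
    partial_r: dict = field(default_factory=dict)  # covariate-set label -> (r, p)

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "model": self.model,
            "variant": self.variant,
            "r": self.r,
            "p": self.p,
            "mse": self.mse,
            "n": self.n,
            "partial_r": {k: list(v) for k, v in self.partial_r.items()},
        }


@dataclass
class OverlapReport:
    """Shared-edge count of two masks against a random-mask null."""

    model_a: str
    model_b: str
    sign: str
    shared: int
    size_a: int
    size_b: int
    percent: float
    p: float
    null_mean: float


@dataclass
class StabilityReport:
    """Split-half stability of network strength vs single-edge null."""

    model: str
    r_split: float
    null_r: np.ndarray
    p: float


def apply_model(
    model: CPMModel,
    edges: np.ndarray,
    observed: np.ndarray,
    covariate_sets: dict | None = None,
    dataset: str = "test",
) -> dict:
    """Apply a frozen model to an external dataset; one report per variant.

    ``covariate_sets`` maps a label to a (n x q) covariate array; each set
    yields a partial correlation between predicted and observed scores.
    The edge space must match the model's exactly — no silent re-indexing.
    """
    X = np.asarray(edges, float)
    y = np.asarray(observed, float)
    E = model.positive_mask.member.size
    if X.shape[1] != E:
        raise ValueError(
            f"edge-space mismatch: model has {E} edges, data has {X.shape[1]}"
        )
    strengths = _strength_columns(X, model.positive_mask, model.negative_mask)
    n = X.shape[0]
    reports = {}
    for v in VARIANTS:
        beta = model.coefficients[v]["beta"]
        c = model.coefficients[v]["c"]
        pred = beta * strengths[v] + c
        r = _pearson(pred, y)
        p = float(_corr_pvalues(np.array(r), n - 2))
        mse = float(np.mean((pred - y) ** 2))
        partial = {}
        for label, Z in (covariate_sets or {}).items():
            partial[label] = partial_correlation(pred, y, Z)
        reports[v] = EvaluationReport(
            dataset=dataset,
            model=model.target_name,
            variant=v,
            predicted=pred,
            observed=y,
            r=r,
            p=p,
            mse=mse,
            n=n,
            partial_r=partial,
        )
    return reports


def cross_predict(
    model: CPMModel,
    edges: np.ndarray,
    other_target: np.ndarray,
    covariate_sets: dict | None = None,
    dataset: str = "test",
) -> dict:
    """Apply a model trained on one score to a DIFFERENT observed score."""
    return apply_model(model, edges, other_target, covariate_sets, dataset=dataset)


def strength_correlation(
    model_a: CPMModel, model_b: CPMModel, edges: np.ndarray
) -> tuple[float, float]:
    """Correlation between two models' combined strengths over pooled subjects."""
    X = np.asarray(edges, float)
    E = model_a.positive_mask.member.size
    if model_b.positive_mask.member.size != E or X.shape[1] != E:
        raise ValueError("edge-space mismatch between models and data")
    sa = _strength_columns(X, model_a.positive_mask, model_a.negative_mask)["combined"]
    sb = _strength_columns(X, model_b.positive_mask, model_b.negative_mask)["combined"]
    r = _pearson(sa, sb)
    p = float(_corr_pvalues(np.array(r), X.shape[0] - 2))
    return r, p


def overlap_percent(shared: int, size_a: int, size_b: int) -> float:
    """Shared edges as a percentage of the two mask sizes' sum."""
    return 100.0 * shared / (size_a + size_b)


def mask_overlap(
    model_a: CPMModel,
    model_b: CPMModel,
    sign: str,
    n_perm: int = 10000,
    seed: int = 0,
) -> OverlapReport:
    """Observed mask overlap against a shuffled-edges (random mask) null.

    The null draws two uniformly random masks of the observed sizes over the
    E-edge space; the shared count is then Hypergeometric(E, size_a, size_b),
    sampled directly. p = P(null shared >= observed).
    """
    mask_a = {"positive": model_a.positive_mask, "negative": model_a.negative_mask}[sign]
    mask_b = {"positive": model_b.positive_mask, "negative": model_b.negative_mask}[sign]
    E = mask_a.member.size
    if mask_b.member.size != E:
        raise ValueError("models do not share an edge space")
    size_a, size_b = mask_a.size, mask_b.size
    if size_a > E or size_b > E:
        raise ValueError("mask size exceeds the edge space")
    shared = int(np.sum(mask_a.member & mask_b.member))
    rng = np.random.default_rng(seed)
    null = rng.hypergeometric(size_a, E - size_a, size_b, size=n_perm)
    p = float(np.mean(null >= shared))
    return OverlapReport(
        model_a=model_a.target_name,
        model_b=model_b.target_name,
        sign=sign,
        shared=shared,
        size_a=size_a,
        size_b=size_b,
        percent=overlap_percent(shared, size_a, size_b),
        p=p,
        null_mean=float(null.mean()),
    )


def split_half_stability(
    model: CPMModel,
    edges_split_a: np.ndarray,
    edges_split_b: np.ndarray,
    n_random_edges: int = 1000,
    seed: int = 0,
    two_sided: bool = False,
) -> StabilityReport:
    """Stability of combined network strength across two scan halves.

    Correlates, across subjects, the combined strength computed from the
    first half of the data (e.g., runs 1-2) with that from the second half
    (runs 3-4), and compares it with the split correlations of
    ``n_random_edges`` uniformly sampled single edges.
    p = P(single-edge r >= strength r) one-sided by default.
    """
    Xa = np.asarray(edges_split_a, float)
    Xb = np.asarray(edges_split_b, float)
    if Xa.shape != Xb.shape:
        raise ValueError("splits must cover the same subjects and edge space")
    sa = _strength_columns(Xa, model.positive_mask, model.negative_mask)["combined"]
    sb = _strength_columns(Xb, model.positive_mask, model.negative_mask)["combined"]
    r_split = _pearson(sa, sb)
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, Xa.shape[1], size=n_random_edges)
    null = np.array([_pearson(Xa[:, e], Xb[:, e]) for e in picks])
    if two_sided:
        p = float(np.mean(np.abs(null) >= abs(r_split)))
    else:
        p = float(np.mean(null >= r_split))
    return StabilityReport(model=model.target_name, r_split=r_split, null_r=null, p=p)


def combined_shuffle_split(
    datasets: list,
    target: str = "score",
    train_frac: float = 0.8,
    seed: int = 0,
    site_mean_control: bool = False,
    cfg: SelectionConfig | None = None,
    pcfg: PermutationConfig | None = None,
    alpha: float = 0.05,
) -> dict:
    """Pool sites, shuffle, split 80-20, train a CPM and test on the held-out part.

    ``datasets`` is a list of (edges, scores, site_label) triples sharing one
    edge space. The pooled subjects are shuffled with ``seed``, the model is
    trained (cross-validated + permutation-tested + single-fold finalized) on
    the training fraction and applied frozen to the rest. When
    ``site_mean_control`` is set, evaluation adds a partial correlation using
    each subject's site-mean observed score as the covariate, absorbing
    between-site score offsets.

    Returns a dict with train r, permutation p, selection flag and the
    held-out evaluation reports.
    """
    cfg = cfg or SelectionConfig()
    pcfg = pcfg or PermutationConfig()
    X = np.vstack([np.asarray(d[0], float) for d in datasets])
    y = np.concatenate([np.asarray(d[1], float) for d in datasets])
    site = np.concatenate([np.repeat(d[2], len(d[1])) for d in datasets])
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_frac * n))
    if n_train < 10 or n - n_train < 10:
        raise ValueError("shuffled split leaves fewer than 10 subjects in a part")
    tr, te = order[:n_train], order[n_train:]

    cv = run_cv(X[tr], y[tr], cfg)
    null, p_perm = permutation_test(X[tr], y[tr], cfg, pcfg, observed_r=cv.r["combined"])
    model = finalize_model(X[tr], y[tr], cfg, target_name=target)

    covariate_sets = {}
    if site_mean_control:
        site_means = pd.Series(y[te]).groupby(pd.Series(site[te])).transform("mean")
        covariate_sets["site_mean"] = site_means.to_numpy().reshape(-1, 1)
    reports = apply_model(
        model, X[te], y[te], covariate_sets=covariate_sets, dataset="held_out_20"
    )
    return {
        "train_r": cv.r["combined"],
        "permutation_p": p_perm,
        "selected": p_perm < alpha,
        "model": model,
        "test_reports": reports,
        "n_train": len(tr),
        "n_test": len(te),
        "seed": seed,
    }
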