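"""Connectome-based predictive modeling: training, cross-validation, inference.

CPM screens every unique functional-connectivity edge for Pearson
correlation with a behavioral score, keeps edges passing a two-tailed
p-threshold (default 0.01) split by correlation sign into a positive and a
negative binary mask, sums each subject's edge values over the masks into
network-strength features, and fits the one-predictor linear model

    score = beta * network_strength + c

for the combined (positive sum minus negative sum), positive-only and
negative-only strength variants. Held-out prediction, by convention, uses
the combined variant; the sign-specific variants are always recorded
alongside. Group-level inference re-runs the ENTIRE cross-validation
(screening inside each fold) on permuted scores and reports the fraction of
null predicted-vs-observed correlations at or above the observed one.

Leave-one-out cross-validation has a vectorized fast path built on
leave-one-out downdates of the screening sufficient statistics, so the
nested permutation scheme is tractable; the explicit per-fold path (used
for k-fold) computes the same quantities and the two are tested for
equivalence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import stdtr

from .connectome import edge_pairs, n_edges

__all__ = [
    "SelectionConfig",
    "PermutationConfig",
    "EdgeMask",
    "CPMModel",
    "CVResult",
    "VARIANTS",
    "edge_screen",
    "network_strength",
    "fit_strength_model",
    "run_cv",
    "permutation_test",
    "partial_correlation",
    "finalize_model",
    "edge_presence",
    "select_models",
]

VARIANTS = ("combined", "pos_only", "neg_only")

_VAR_EPS = 1e-24  # variance below this marks a degenerate (constant) predictor


@dataclass(frozen=True)
class SelectionConfig:
    """Edge screening and cross-validation settings.

    edge_p_threshold: two-tailed p cutoff for edge selection (strict '<').
    cv_scheme: 'loocv' or 'kfold'; k folds are a seeded uniform shuffle.
    """

    edge_p_threshold: float = 0.01
    cv_scheme: str = "loocv"
    k: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.edge_p_threshold < 1:
            raise ValueError("edge_p_threshold must be in (0, 1)")
        if self.cv_scheme not in ("loocv", "kfold"):
            raise ValueError("cv_scheme must be 'loocv' or 'kfold'")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-null settings: number of relabelings and the RNG seed."""

    n_perm: int = 1000
    rng_seed: int = 0
    add_one: bool = False  # (count+1)/(n+1) variant; off by default

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class EdgeMask:
    """Binary edge set tagged with the sign of its score correlation."""

    sign: str
    member: np.ndarray

    def __post_init__(self) -> None:
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")
        self.member = np.asarray(self.member, dtype=bool)

    @property
    def size(self) -> int:
        return int(self.member.sum())


@dataclass
class CPMModel:
    """A trained CPM: masks plus linear coefficients per strength variant."""

    positive_mask: EdgeMask
    negative_mask: EdgeMask
    coefficients: dict  # variant -> {"beta": float, "c": float}
    target_name: str
    n_train: int
    edge_p_threshold: float
    n_nodes: int
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.positive_mask.member & self.negative_mask.member):
            raise ValueError("positive and negative masks must be disjoint")
        if set(self.coefficients) != set(VARIANTS):
            raise ValueError(f"coefficients must cover variants {VARIANTS}")

    @property
    def n_edges(self) -> int:
        return self.positive_mask.member.size

    def save(self, directory: str | Path) -> None:
        """Write model.json plus per-sign edge-list TSVs (canonical order)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "target_name": self.target_name,
            "n_train": self.n_train,
            "edge_p_threshold": self.edge_p_threshold,
            "n_nodes": self.n_nodes,
            "rng_seed": self.rng_seed,
            "coefficients": self.coefficients,
            "mask_sizes": {
                "positive": self.positive_mask.size,
                "negative": self.negative_mask.size,
            },
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))
        ii, jj = edge_pairs(self.n_nodes)
        for sign, mask in (("positive", self.positive_mask), ("negative", self.negative_mask)):
            idx = np.flatnonzero(mask.member)
            pd.DataFrame(
                {"node_i": ii[idx], "node_j": jj[idx], "sign": sign, "weight": 1}
            ).to_csv(d / f"edges_{sign}.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "CPMModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        n_nodes = meta["n_nodes"]
        E = n_edges(n_nodes)
        masks = {}
        for sign in ("positive", "negative"):
            member = np.zeros(E, dtype=bool)
            tab = pd.read_csv(d / f"edges_{sign}.tsv", sep="\t")
            if len(tab):
                i = tab["node_i"].to_numpy()
                j = tab["node_j"].to_numpy()
                # canonical index of edge (i, j), i < j
                member[(i * (2 * n_nodes - i - 1)) // 2 + (j - i - 1)] = True
            masks[sign] = EdgeMask(sign=sign, member=member)
        return cls(
            positive_mask=masks["positive"],
            negative_mask=masks["negative"],
            coefficients=meta["coefficients"],
            target_name=meta["target_name"],
            n_train=meta["n_train"],
            edge_p_threshold=meta["edge_p_threshold"],
            n_nodes=n_nodes,
            rng_seed=meta.get("rng_seed"),
        )


@dataclass
class CVResult:
    """Held-out predictions and per-fold masks from one cross-validation."""

    observed: np.ndarray
    predicted: dict                  # variant -> (n,) held-out predictions
    fold_positive: np.ndarray        # folds x E boolean
    fold_negative: np.ndarray
    fold_of_subject: np.ndarray      # fold index per subject
    r: dict                          # variant -> predicted-vs-observed Pearson r
    config: SelectionConfig = None
    n_degenerate_folds: int = 0


def _corr_pvalues(r: np.ndarray, df: int | np.ndarray) -> np.ndarray:
    """Two-tailed p of Pearson r via the exact t transform with df = n - 2."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
        t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, np.nan_to_num(t, posinf=np.inf, neginf=-np.inf))
    return 2.0 * stdtr(df, -np.abs(t))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def edge_screen(
    edges: np.ndarray, scores: np.ndarray, threshold: float = 0.01
) -> tuple[EdgeMask, EdgeMask, np.ndarray, np.ndarray]:
    """Correlate every edge with the scores and threshold into signed masks.

    Edge e enters the positive mask iff r_e > 0 and its two-tailed p < the
    threshold (strict); the negative mask iff r_e < 0 and p < threshold.
    Zero-variance edges are ineligible (r reported as 0, p as 1).

    Returns (positive mask, negative mask, per-edge r, per-edge p).
    """
    X = np.asarray(edges, float)
    y = np.asarray(scores, float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects to screen edges")
    yc = y - y.mean()
    vy = yc @ yc
    if vy == 0:
        raise ValueError("scores have zero variance")
    Xc = X - X.mean(axis=0)
    vx = np.einsum("ij,ij->j", Xc, Xc)
    eligible = vx > _VAR_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / np.sqrt(vx * vy)
    r = np.where(eligible, np.clip(r, -1.0, 1.0), 0.0)
    p = np.where(eligible, _corr_pvalues(r, n - 2), 1.0)
    pos = EdgeMask("positive", (r > 0) & (p < threshold) & eligible)
    neg = EdgeMask("negative", (r < 0) & (p < threshold) & eligible)
    return pos, neg, r, p


def network_strength(
    edges: np.ndarray, pos: EdgeMask, neg: EdgeMask
) -> pd.DataFrame:
    """Per-subject network strengths: positive sum, negative sum, combined.

    Combined strength is the positive-network sum minus the negative-network
    sum. Empty masks yield zero sums (a degenerate but legal model).
    """
    X = np.asarray(edges, float)
    if pos.member.size != X.shape[1] or neg.member.size != X.shape[1]:
        raise ValueError("mask length does not match the edge space")
    pos_sum = X @ pos.member.astype(float)
    neg_sum = X @ neg.member.astype(float)
    return pd.DataFrame(
        {"pos_sum": pos_sum, "neg_sum": neg_sum, "combined": pos_sum - neg_sum}
    )


def fit_strength_model(strength: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Ordinary least squares fit of score on a single strength feature."""
    s = np.asarray(strength, float)
    y = np.asarray(scores, float)
    sc = s - s.mean()
    var = sc @ sc
    if var <= _VAR_EPS:
        raise ValueError("degenerate predictor: strength is constant")
    beta = (sc @ (y - y.mean())) / var
    c = y.mean() - beta * s.mean()
    return float(beta), float(c)


def _strength_columns(X: np.ndarray, pos: EdgeMask, neg: EdgeMask) -> dict:
    s = network_strength(X, pos, neg)
    return {
        "combined": s["combined"].to_numpy(),
        "pos_only": s["pos_sum"].to_numpy(),
        "neg_only": s["neg_sum"].to_numpy(),
    }


def _loocv_vectorized(X: np.ndarray, y: np.ndarray, threshold: float):
    """All LOOCV folds at once via leave-one-out downdates of screening sums.

    Returns (predicted dict, fold_pos (n x E), fold_neg, n_degenerate).
    """
    n, E = X.shape
    nt = n - 1
    Sx = X.sum(axis=0)
    Sxx = (X * X).sum(axis=0)
    Sy = y.sum()
    Syy = y @ y
    Sxy = X.T @ y

    sx = Sx[None, :] - X                      # training sums per fold
    sxx = Sxx[None, :] - X * X
    sy = Sy - y
    syy = Syy - y * y
    sxy = Sxy[None, :] - X * y[:, None]

    cov = sxy - sx * (sy / nt)[:, None]
    varx = sxx - sx * sx / nt
    vary = syy - sy * sy / nt
    eligible = varx > _VAR_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(varx * vary[:, None])
    r = np.where(eligible, np.clip(r, -1.0, 1.0), 0.0)
    p = np.where(eligible, _corr_pvalues(r, nt - 2), 1.0)
    fold_pos = (r > 0) & (p < threshold) & eligible
    fold_neg = (r < 0) & (p < threshold) & eligible

    # strength of every subject under every fold's masks: (folds x subjects)
    SP = fold_pos.astype(float) @ X.T
    SN = fold_neg.astype(float) @ X.T
    strengths = {"combined": SP - SN, "pos_only": SP, "neg_only": SN}

    predicted = {}
    n_degenerate = 0
    train_mean = sy / nt
    for variant, S in strengths.items():
        diag = np.einsum("ii->i", S)
        row_s = S.sum(axis=1) - diag          # training strength sums
        row_sq = (S * S).sum(axis=1) - diag * diag
        row_sy = S @ y - diag * y
        cov_s = row_sy - row_s * sy / nt
        var_s = row_sq - row_s * row_s / nt
        ok = var_s > _VAR_EPS
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(ok, cov_s / np.where(ok, var_s, 1.0), 0.0)
        c = (sy - beta * row_s) / nt
        pred = np.where(ok, beta * diag + c, train_mean)
        predicted[variant] = pred
        if variant == "combined":
            n_degenerate = int((~ok).sum())
    return predicted, fold_pos, fold_neg, n_degenerate


def _kfold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded uniform shuffle into k near-equal folds; fold index per subject."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, k)):
        fold[chunk] = f
    return fold


def run_cv(edges: np.ndarray, scores: np.ndarray, cfg: SelectionConfig) -> CVResult:
    """Cross-validated CPM: screening and fitting repeated inside every fold.

    Each fold screens edges on its training subjects only, computes network
    strengths, fits all three strength-variant linear models on training, and
    predicts the held-out subject(s) from each variant. A fold whose
    predictor is constant (e.g., empty masks) falls back to the
    training-score mean and is counted in ``n_degenerate_folds``.
    """
    X = np.asarray(edges, float)
    y = np.asarray(scores, float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 subjects for cross-validation")

    if cfg.cv_scheme == "loocv":
        predicted, fold_pos, fold_neg, ndeg = _loocv_vectorized(
            X, y, cfg.edge_p_threshold
        )
        fold_of_subject = np.arange(n)
    else:
        fold_of_subject = _kfold_assignment(n, cfg.k, cfg.rng_seed)
        n_folds = fold_of_subject.max() + 1
        E = X.shape[1]
        predicted = {v: np.empty(n) for v in VARIANTS}
        fold_pos = np.zeros((n_folds, E), dtype=bool)
        fold_neg = np.zeros((n_folds, E), dtype=bool)
        ndeg = 0
        for f in range(n_folds):
            test = fold_of_subject == f
            train = ~test
            pos, neg, _, _ = edge_screen(X[train], y[train], cfg.edge_p_threshold)
            fold_pos[f] = pos.member
            fold_neg[f] = neg.member
            s_train = _strength_columns(X[train], pos, neg)
            s_test = _strength_columns(X[test], pos, neg)
            for v in VARIANTS:
                try:
                    beta, c = fit_strength_model(s_train[v], y[train])
                    predicted[v][test] = beta * s_test[v] + c
                except ValueError:
                    predicted[v][test] = y[train].mean()
                    if v == "combined":
                        ndeg += 1

    r = {v: _pearson(predicted[v], y) for v in VARIANTS}
    return CVResult(
        observed=y,
        predicted=predicted,
        fold_positive=fold_pos,
        fold_negative=fold_neg,
        fold_of_subject=fold_of_subject,
        r=r,
        config=cfg,
        n_degenerate_folds=ndeg,
    )


def permutation_pvalue(null: np.ndarray, observed: float, add_one: bool = False) -> float:
    """Fraction of null values at or above the observed statistic.

    The default is the plain count/n definition; ``add_one`` switches to the
    (count+1)/(n+1) variant.
    """
    null = np.asarray(null, float)
    count = int((null >= observed).sum())
    if add_one:
        return (count + 1) / (null.size + 1)
    return count / null.size


def permutation_test(
    edges: np.ndarray,
    scores: np.ndarray,
    cfg: SelectionConfig,
    pcfg: PermutationConfig,
    observed_r: float | None = None,
    variant: str = "combined",
) -> tuple[np.ndarray, float]:
    """Permutation null for the cross-validated prediction correlation.

    Each iteration randomly relabels the scores across subjects and re-runs
    the ENTIRE cross-validation (screening inside folds); the p-value is the
    fraction of null correlations at or above the observed one.
    """
    X = np.asarray(edges, float)
    y = np.asarray(scores, float)
    if observed_r is None:
        observed_r = run_cv(X, y, cfg).r[variant]
    rng = np.random.default_rng(pcfg.rng_seed)
    null = np.empty(pcfg.n_perm)
    for b in range(pcfg.n_perm):
        null[b] = run_cv(X, rng.permutation(y), cfg).r[variant]
    return null, permutation_pvalue(null, observed_r, add_one=pcfg.add_one)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariates by OLS.

    Residualizes both variables on the covariates (with intercept) and
    correlates the residuals; p uses the t transform with n - 2 - q df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    Z = np.atleast_2d(np.asarray(covariates, float))
    if Z.shape[0] != x.size:
        Z = Z.T
    n, q = Z.shape
    if n != x.size or n != y.size:
        raise ValueError("x, y and covariates must share the subject dimension")
    if n <= q + 2:
        raise ValueError("need n > q + 2 subjects")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    if (rx @ rx) <= _VAR_EPS or (ry @ ry) <= _VAR_EPS:
        raise ValueError("zero residual variance: partial correlation undefined")
    r = _pearson(rx, ry)
    p = float(_corr_pvalues(np.array(r), n - 2 - q))
    return r, p


def finalize_model(
    edges: np.ndarray,
    scores: np.ndarray,
    cfg: SelectionConfig,
    target_name: str = "score",
    n_nodes: int | None = None,
) -> CPMModel:
    """Single-fold model: screen and fit on ALL subjects, for external use."""
    X = np.asarray(edges, float)
    y = np.asarray(scores, float)
    pos, neg, _, _ = edge_screen(X, y, cfg.edge_p_threshold)
    if pos.size == 0 and neg.size == 0:
        raise ValueError("no edges survive threshold")
    strengths = _strength_columns(X, pos, neg)
    coefficients = {}
    for v in VARIANTS:
        try:
            beta, c = fit_strength_model(strengths[v], y)
        except ValueError:
            beta, c = 0.0, float(y.mean())
        coefficients[v] = {"beta": beta, "c": c}
    if n_nodes is None:
        # recover node count from E = n(n-1)/2
        E = X.shape[1]
        n_nodes = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
        if n_edges(n_nodes) != E:
            raise ValueError("edge count is not n*(n-1)/2 for any integer n; pass n_nodes")
    return CPMModel(
        positive_mask=pos,
        negative_mask=neg,
        coefficients=coefficients,
        target_name=target_name,
        n_train=X.shape[0],
        edge_p_threshold=cfg.edge_p_threshold,
        n_nodes=n_nodes,
        rng_seed=cfg.rng_seed,
    )


def edge_presence(cv: CVResult, final: CPMModel) -> dict:
    """Mean fraction of CV folds containing each final-model edge, per sign.

    Reported as a percentage; None when the final mask of a sign is empty.
    """
    out = {}
    for sign, fold_masks, final_mask in (
        ("positive", cv.fold_positive, final.positive_mask),
        ("negative", cv.fold_negative, final.negative_mask),
    ):
        idx = np.flatnonzero(final_mask.member)
        if idx.size == 0:
            out[sign] = None
            continue
        frac = fold_masks[:, idx].mean(axis=0)
        out[sign] = float(100.0 * frac.mean())
    return out


def select_models(p_values: dict, alpha: float = 0.05) -> list:
    """Labels whose permutation p is strictly below alpha (uncorrected)."""
    for label, p in p_values.items():
        if not 0 <= p <= 1:
            raise ValueError(f"p value for {label!r} outside [0, 1]")
    return [label for label, p in p_values.items() if p < alpha]
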