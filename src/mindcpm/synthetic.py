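"""Synthetic multi-site connectome cohorts with planted brain-behavior signal.

The generator emulates the statistical structure the CPM analysis assumes:
three sites with distinct trait-score means/SDs, a small set of planted
edges whose Fisher-z connectivity correlates positively or negatively with
a target score at a configurable effect size, optional motion-coupled
confound edges, correlated questionnaire facets, and multi-run acquisitions
with a configurable split-half edge reliability. Ground truth (which edges
carry signal) is carried alongside so mask-recovery sensitivity and
specificity are measurable; the analysis path never reads it.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import n_edges, edge_pairs
from .ffmq import FACETS

__all__ = [
    "SiteConfig",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_item_responses",
    "generate_timeseries_cohort",
    "write_fixture",
    "load_fixture",
]

#: split-half reliability of a 2-run average given stable variance fraction lam
#: is 2*lam/(1+lam); inverted below to hit a requested single-edge reliability.


@dataclass(frozen=True)
class SiteConfig:
    name: str
    n_subjects: int
    score_mean: float
    score_sd: float

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("site needs n >= 2")


def _default_sites() -> list:
    # three sites with the distinct trait means/SDs of a typical multi-site
    # mindfulness cohort (university community, student, and overseas samples)
    return [
        SiteConfig("siteA", 200, 134.8, 17.8),
        SiteConfig("siteB", 200, 126.8, 17.4),
        SiteConfig("siteC", 200, 107.2, 11.3),
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    effect_r is the target correlation between each planted edge and the
    target score within a site; edge_reliability is the split-half
    reliability of a single edge (average of two runs vs average of the
    other two) in multi-run mode; shared_run_noise in [0, 1] is the fraction
    of run-level noise common to all edges (1 makes aggregate strength no
    more stable than single edges).
    """

    n_nodes: int = 100
    sites: tuple = field(default_factory=lambda: tuple(_default_sites()))
    n_planted_positive: int = 30
    n_planted_negative: int = 30
    effect_r: float = 0.3
    target: str = "total"
    facet_corr: float = 0.4
    fd_mean: float = 0.12
    fd_sd: float = 0.05
    fd_score_corr: float = -0.3
    confound_strength: float = 0.0
    n_confound_edges: int = 30
    n_runs: int = 1
    edge_reliability: float = 0.4
    shared_run_noise: float = 0.0
    edge_baseline_mean: float = 0.25
    edge_baseline_sd: float = 0.15
    edge_noise_sd: float = 0.2
    site_edge_shift_sd: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.effect_r < 1:
            raise ValueError("effect_r must be in (-1, 1)")
        if self.n_planted_positive < 0 or self.n_planted_negative < 0:
            raise ValueError("planted edge counts must be >= 0")
        if self.target not in FACETS + ("total",):
            raise ValueError(f"target must be one of {FACETS + ('total',)}")
        if not 0 <= self.shared_run_noise <= 1:
            raise ValueError("shared_run_noise must be in [0, 1]")
        if not 0 < self.edge_reliability < 1:
            raise ValueError("edge_reliability must be in (0, 1)")


@dataclass
class SyntheticCohort:
    """Generated phenotypes, edges (run-averaged), per-run edges, ground truth."""

    phenotype: pd.DataFrame
    edges: np.ndarray
    run_edges: list | None
    truth: dict
    n_nodes: int
    config: GeneratorConfig

    @property
    def n_subjects(self) -> int:
        return len(self.phenotype)


def _facet_scores(rng, site: SiteConfig, rho: float) -> pd.DataFrame:
    """Five correlated facet scores summing to the configured total mean/SD."""
    k = len(FACETS)
    facet_sd = site.score_sd / np.sqrt(k * (1 + (k - 1) * rho))
    cov = np.full((k, k), rho * facet_sd**2)
    np.fill_diagonal(cov, facet_sd**2)
    mean = np.full(k, site.score_mean / k)
    vals = rng.multivariate_normal(mean, cov, size=site.n_subjects, method="cholesky")
    return pd.DataFrame(vals, columns=list(FACETS))


def _target_site_params(cfg: GeneratorConfig, site: SiteConfig) -> tuple[float, float]:
    """Configured mean/SD of the target score within a site."""
    if cfg.target == "total":
        return site.score_mean, site.score_sd
    k = len(FACETS)
    facet_sd = site.score_sd / np.sqrt(k * (1 + (k - 1) * cfg.facet_corr))
    return site.score_mean / k, facet_sd


def generate_cohort(cfg: GeneratorConfig | None = None) -> SyntheticCohort:
    """Sample a multi-site cohort of edge vectors with planted signal.

    Planted positive edges follow  baseline + site shift + sd*(r*z(score) +
    sqrt(1-r^2)*noise)  with z the within-site standardized target score;
    planted negative edges flip the sign of r; null edges are independent
    noise; confound edges couple to standardized framewise displacement.
    In multi-run mode the noise splits into a stable subject component and
    run noise sized so single edges reach the configured split-half
    reliability; ``edges`` holds the across-run average.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    E = n_edges(cfg.n_nodes)
    n_special = cfg.n_planted_positive + cfg.n_planted_negative + (
        cfg.n_confound_edges if cfg.confound_strength > 0 else 0
    )
    if n_special > E:
        raise ValueError(f"planted/confound edges ({n_special}) exceed edge space ({E})")
    special = rng.choice(E, size=n_special, replace=False)
    pos_idx = special[: cfg.n_planted_positive]
    neg_idx = special[cfg.n_planted_positive : cfg.n_planted_positive + cfg.n_planted_negative]
    conf_idx = special[cfg.n_planted_positive + cfg.n_planted_negative :]

    sign = np.zeros(E)
    sign[pos_idx] = 1.0
    sign[neg_idx] = -1.0
    conf = np.zeros(E)
    conf[conf_idx] = 1.0

    baseline = rng.normal(cfg.edge_baseline_mean, cfg.edge_baseline_sd, size=E)
    site_shift = {
        s.name: rng.normal(0.0, cfg.site_edge_shift_sd, size=E) for s in cfg.sites
    }

    # stable fraction of noise variance hitting the requested 2-vs-2-run
    # split-half reliability: rel = 2*lam/(1+lam)  =>  lam = rel/(2-rel)
    lam = cfg.edge_reliability / (2.0 - cfg.edge_reliability)

    pheno_rows = []
    subject_edges = []
    run_edges: list[list[np.ndarray]] = [[] for _ in range(cfg.n_runs)]
    r = cfg.effect_r
    c = cfg.confound_strength
    for site in cfg.sites:
        facets = _facet_scores(rng, site, cfg.facet_corr)
        total = facets.sum(axis=1)
        t_mean, t_sd = _target_site_params(cfg, site)
        target = total if cfg.target == "total" else facets[cfg.target]
        z_t = (target.to_numpy() - t_mean) / t_sd

        if c > 0:
            z_fd = cfg.fd_score_corr * z_t + np.sqrt(
                1 - cfg.fd_score_corr**2
            ) * rng.standard_normal(site.n_subjects)
        else:
            z_fd = rng.standard_normal(site.n_subjects)
        mean_fd = np.clip(cfg.fd_mean + cfg.fd_sd * z_fd, 0.005, None)

        # per-edge noise scale keeping unit total noise variance
        resid_sd = np.sqrt(
            np.clip(1.0 - (r * sign) ** 2 - (c * conf) ** 2, 1e-6, 1.0)
        )
        signal = (
            r * np.outer(z_t, sign) + c * np.outer(z_fd, conf)
        )  # subjects x E
        base = baseline + site_shift[site.name]

        if cfg.n_runs == 1:
            noise = rng.standard_normal((site.n_subjects, E)) * resid_sd
            vals = base + cfg.edge_noise_sd * (signal + noise)
            subject_edges.append(vals)
        else:
            # shared_run_noise mixes an all-edge common factor into BOTH the
            # stable and the run-level noise; at 1.0 every edge tracks one
            # common process, so no aggregate can be more stable than a
            # single edge (the uniform-reliability construction)
            # averaging n_runs shrinks noise variance to lam + (1-lam)/n_runs;
            # scale the signal down by the same factor so the run-averaged
            # edge still correlates with the score at effect_r
            shrink = np.sqrt(lam + (1.0 - lam) / cfg.n_runs)
            signal = signal * shrink
            g = cfg.shared_run_noise
            stable_shared = rng.standard_normal((site.n_subjects, 1))
            stable_indep = rng.standard_normal((site.n_subjects, E))
            stable = (np.sqrt(g) * stable_shared + np.sqrt(1 - g) * stable_indep) * (
                np.sqrt(lam) * resid_sd
            )
            per_run = []
            for _ in range(cfg.n_runs):
                shared = rng.standard_normal((site.n_subjects, 1))
                indep = rng.standard_normal((site.n_subjects, E))
                run_noise = (np.sqrt(g) * shared + np.sqrt(1 - g) * indep) * (
                    np.sqrt(1 - lam) * resid_sd
                )
                per_run.append(base + cfg.edge_noise_sd * (signal + stable + run_noise))
            subject_edges.append(np.mean(per_run, axis=0))
            for k in range(cfg.n_runs):
                run_edges[k].append(per_run[k])

        tab = facets.copy()
        tab.insert(0, "subject_id", [f"{site.name}_{i:04d}" for i in range(site.n_subjects)])
        tab.insert(1, "site", site.name)
        tab["total"] = total
        tab["total_without_observing"] = total - facets["O"]
        tab["mean_fd"] = mean_fd
        tab["asthma"] = rng.binomial(1, 0.15, size=site.n_subjects)
        is_second = len(cfg.sites) > 1 and site is cfg.sites[1]
        tab["clinical"] = rng.binomial(1, 0.25 if is_second else 0.0, size=site.n_subjects)
        tab["resolution"] = int(len(cfg.sites) > 1 and site is cfg.sites[-1])
        pheno_rows.append(tab)

    phenotype = pd.concat(pheno_rows, ignore_index=True)
    edges = np.vstack(subject_edges)
    runs = [np.vstack(r_) for r_ in run_edges] if cfg.n_runs > 1 else None

    truth = {
        "planted_positive": np.sort(pos_idx).tolist(),
        "planted_negative": np.sort(neg_idx).tolist(),
        "confound_edges": np.sort(conf_idx).tolist(),
        "effect_r": r,
        "target": cfg.target,
    }
    cohort = SyntheticCohort(
        phenotype=phenotype,
        edges=edges,
        run_edges=runs,
        truth=truth,
        n_nodes=cfg.n_nodes,
        config=cfg,
    )
    _check_realized_effect(cohort)
    return cohort


def _check_realized_effect(cohort: SyntheticCohort) -> None:
    """Generation-time self check: mean planted-edge correlation near target."""
    cfg = cohort.config
    planted = np.array(
        cohort.truth["planted_positive"] + cohort.truth["planted_negative"], dtype=int
    )
    if planted.size == 0:
        return
    signs = np.concatenate(
        [
            np.ones(len(cohort.truth["planted_positive"])),
            -np.ones(len(cohort.truth["planted_negative"])),
        ]
    )
    target = cohort.truth["target"]
    for site, grp in cohort.phenotype.groupby("site", sort=False):
        if len(grp) < 200:
            continue
        idx = grp.index.to_numpy()
        y = grp[target].to_numpy()
        X = cohort.edges[idx][:, planted]
        yc = y - y.mean()
        Xc = X - X.mean(axis=0)
        rr = (Xc.T @ yc) / np.sqrt((Xc**2).sum(axis=0) * (yc @ yc))
        mean_r = float(np.mean(rr * signs))
        if abs(mean_r - abs(cfg.effect_r)) > 0.1:
            raise RuntimeError(
                f"realized planted-edge correlation {mean_r:.3f} in site {site} "
                f"misses target {cfg.effect_r}"
            )


def generate_timeseries_cohort(
    cfg: GeneratorConfig | None = None, n_timepoints: int = 200
) -> tuple[SyntheticCohort, list]:
    """Cohort of node timeseries whose FC carries the planted edge structure.

    Planted edges are re-drawn as node-disjoint pairs; each pair of nodes
    shares a latent factor with loading chosen per subject so that the
    expected Fisher-z correlation tracks the target score with the
    configured effect size (estimation noise of ~1/(T-3) variance is
    accounted for). Null node pairs are uncorrelated. Returns the cohort
    (with ``edges`` holding each subject's empirical Fisher-z vector) and
    the per-subject list of (n_nodes x T) timeseries arrays.
    """
    cfg = cfg or GeneratorConfig()
    if n_timepoints < 50:
        raise ValueError("need at least 50 timepoints")
    n_pairs = cfg.n_planted_positive + cfg.n_planted_negative
    if 2 * n_pairs > cfg.n_nodes:
        raise ValueError("too many planted edges for node-disjoint pairs")
    rng = np.random.default_rng(cfg.rng_seed)
    nodes = rng.permutation(cfg.n_nodes)[: 2 * n_pairs].reshape(n_pairs, 2)
    nodes.sort(axis=1)
    ii, jj = edge_pairs(cfg.n_nodes)
    edge_of_pair = np.array(
        [
            (a * (2 * cfg.n_nodes - a - 1)) // 2 + (b - a - 1)
            for a, b in nodes
        ]
    )
    pair_sign = np.concatenate(
        [np.ones(cfg.n_planted_positive), -np.ones(cfg.n_planted_negative)]
    )

    # subject-level z for a planted pair: alpha*z_t + beta*eps; alpha set so
    # corr(empirical z, score) ~= effect_r after estimation noise 1/(T-3)
    beta = 0.15
    est_var = 1.0 / (n_timepoints - 3)
    rho = abs(cfg.effect_r)
    alpha = rho * np.sqrt((beta**2 + est_var) / (1 - rho**2)) if rho > 0 else 0.0

    pheno_rows = []
    ts_list: list[np.ndarray] = []
    z_cap = np.arctanh(0.95)
    for site in cfg.sites:
        facets = _facet_scores(rng, site, cfg.facet_corr)
        total = facets.sum(axis=1)
        t_mean, t_sd = _target_site_params(cfg, site)
        target = total if cfg.target == "total" else facets[cfg.target]
        z_t = (target.to_numpy() - t_mean) / t_sd
        mean_fd = np.clip(
            cfg.fd_mean + cfg.fd_sd * rng.standard_normal(site.n_subjects), 0.005, None
        )
        for s in range(site.n_subjects):
            z_pair = np.clip(
                pair_sign * (alpha * z_t[s]) + beta * rng.standard_normal(n_pairs),
                -z_cap,
                z_cap,
            )
            r_pair = np.tanh(z_pair)
            x = rng.standard_normal((cfg.n_nodes, n_timepoints))
            for (a, b), rp in zip(nodes, r_pair):
                g = rng.standard_normal(n_timepoints)
                w = np.sqrt(abs(rp))
                e = np.sqrt(1 - abs(rp))
                x[a] = w * g + e * rng.standard_normal(n_timepoints)
                x[b] = np.sign(rp) * w * g + e * rng.standard_normal(n_timepoints)
            ts_list.append(x)
        tab = facets.copy()
        tab.insert(0, "subject_id", [f"{site.name}_{i:04d}" for i in range(site.n_subjects)])
        tab.insert(1, "site", site.name)
        tab["total"] = total
        tab["total_without_observing"] = total - facets["O"]
        tab["mean_fd"] = mean_fd
        tab["asthma"] = rng.binomial(1, 0.15, size=site.n_subjects)
        tab["clinical"] = 0
        tab["resolution"] = 0
        pheno_rows.append(tab)

    phenotype = pd.concat(pheno_rows, ignore_index=True)
    # empirical Fisher-z edges through the same transform the pipeline uses
    from .connectome import NodeTimeSeries, build_connectome, vectorize_edges

    edges = np.vstack(
        [
            vectorize_edges(
                build_connectome(
                    NodeTimeSeries(subject_id=str(k), run_id="run1", values=ts)
                )
            )
            for k, ts in enumerate(ts_list)
        ]
    )
    truth = {
        "planted_positive": np.sort(
            edge_of_pair[: cfg.n_planted_positive]
        ).tolist(),
        "planted_negative": np.sort(
            edge_of_pair[cfg.n_planted_positive :]
        ).tolist(),
        "confound_edges": [],
        "effect_r": cfg.effect_r,
        "target": cfg.target,
    }
    cohort = SyntheticCohort(
        phenotype=phenotype,
        edges=edges,
        run_edges=None,
        truth=truth,
        n_nodes=cfg.n_nodes,
        config=cfg,
    )
    return cohort, ts_list


def generate_item_responses(
    scores: pd.DataFrame, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sample 39 ordinal item responses consistent with target facet scores.

    For each subject and facet the target sum is rounded and clipped to the
    achievable range, then spread over the facet's items as scored values in
    1..5 (the remainder distributed over randomly chosen items); reverse
    items are converted back to raw responses (6 - scored). Scoring the
    returned table reproduces the clipped, rounded facet sums exactly.
    """
    from .ffmq import FACETS as _FACETS, ITEM_COLUMNS, load_scoring_map

    rng = rng or np.random.default_rng(0)
    scoring = load_scoring_map()
    n = len(scores)
    raw = np.zeros((n, 39), dtype=int)
    for facet in _FACETS:
        items = scoring.items_of(facet)
        k = items.size
        target = np.clip(np.rint(scores[facet].to_numpy()), k, 5 * k).astype(int)
        for row, s in enumerate(target):
            base = s // k
            vals = np.full(k, base)
            extra = rng.permutation(k)[: s - base * k]
            vals[extra] += 1
            raw[row, items] = vals
    rev = np.array(scoring.reverse)
    raw = np.where(rev[None, :], 6 - raw, raw)
    return pd.DataFrame(raw, columns=ITEM_COLUMNS, index=scores.index)


def write_fixture(
    cohort: SyntheticCohort, directory: str | Path, overwrite: bool = False
) -> Path:
    """Write a cohort as plain-text fixture files.

    Layout: phenotype.csv, manifest.csv (subject_id, run_id, path, mean_fd),
    one square connectivity CSV per subject(-run), and a ground-truth
    sidecar truth.json that the analysis path never reads.
    """
    d = Path(directory)
    if d.exists() and any(d.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{d} exists and is not empty (pass overwrite=True)")
        shutil.rmtree(d)
    d.mkdir(parents=True, exist_ok=True)
    (d / "matrices").mkdir()

    cohort.phenotype.to_csv(d / "phenotype.csv", index=False, float_format="%.17g")
    node_ids = [f"n{k}" for k in range(cohort.n_nodes)]
    i, j = edge_pairs(cohort.n_nodes)

    def _write_matrix(vec: np.ndarray, path: Path) -> None:
        m = np.zeros((cohort.n_nodes, cohort.n_nodes))
        m[i, j] = vec
        m[j, i] = vec
        pd.DataFrame(m, index=node_ids, columns=node_ids).to_csv(
            path, float_format="%.17g"
        )

    rows = []
    subjects = cohort.phenotype["subject_id"].tolist()
    fds = cohort.phenotype["mean_fd"].tolist()
    if cohort.run_edges is None:
        for k, (sid, fd) in enumerate(zip(subjects, fds)):
            rel = f"matrices/{sid}.csv"
            _write_matrix(cohort.edges[k], d / rel)
            rows.append(dict(subject_id=sid, run_id="run1", path=rel, mean_fd=fd))
    else:
        for k, (sid, fd) in enumerate(zip(subjects, fds)):
            for r_, run in enumerate(cohort.run_edges, start=1):
                rel = f"matrices/{sid}_run{r_}.csv"
                _write_matrix(run[k], d / rel)
                rows.append(dict(subject_id=sid, run_id=f"run{r_}", path=rel, mean_fd=fd))
    pd.DataFrame(rows).to_csv(d / "manifest.csv", index=False, float_format="%.17g")

    truth = dict(cohort.truth)
    truth["n_nodes"] = cohort.n_nodes
    (d / "truth.json").write_text(json.dumps(truth, indent=2))
    return d


def load_fixture(directory: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back a fixture's phenotype table and manifest."""
    d = Path(directory)
    phenotype = pd.read_csv(d / "phenotype.csv")
    manifest = pd.read_csv(d / "manifest.csv")
    return phenotype, manifest
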