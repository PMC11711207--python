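"""Five Facet Mindfulness Questionnaire (FFMQ-39) scoring and group comparison.

The FFMQ has 39 five-point Likert items partitioned into five facets —
acting with awareness (AA), non-judging (NJ), non-reactivity (NR),
describing (D) and observing (O). Reverse-scored items (present in AA, NJ
and D) contribute (6 - response). Totals range from 39 to 195; a total
without the observing facet is also conventional. The item->facet map is an
editable packaged YAML so the scoring stays auditable and swappable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import scipy.stats as st
import yaml

FACETS = ("AA", "NJ", "NR", "D", "O")
N_ITEMS = 39
ITEM_COLUMNS = [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]
SCORE_COLUMNS = list(FACETS) + ["total", "total_without_observing"]

__all__ = [
    "FACETS",
    "N_ITEMS",
    "ITEM_COLUMNS",
    "SCORE_COLUMNS",
    "ScoringMap",
    "GroupSummary",
    "load_scoring_map",
    "score_ffmq",
    "welch_t",
    "cohens_d",
    "subscale_correlations",
]


@dataclass(frozen=True)
class ScoringMap:
    """Item -> facet assignment with reverse-scoring flags (1-based items)."""

    facet: tuple[str, ...]     # facet[i] for item i+1
    reverse: tuple[bool, ...]  # reverse[i] for item i+1

    def __post_init__(self) -> None:
        if len(self.facet) != N_ITEMS or len(self.reverse) != N_ITEMS:
            raise ValueError(f"scoring map must cover exactly {N_ITEMS} items")
        unknown = set(self.facet) - set(FACETS)
        if unknown:
            raise ValueError(f"unknown facet label(s): {sorted(unknown)}")
        missing = set(FACETS) - set(self.facet)
        if missing:
            raise ValueError(f"facet(s) with no items: {sorted(missing)}")
        # the published instrument reverse-scores within AA, NJ and D
        for f in ("AA", "NJ", "D"):
            if not any(r for fa, r in zip(self.facet, self.reverse) if fa == f):
                raise ValueError(f"facet {f} must contain at least one reverse-scored item")

    def items_of(self, facet: str) -> np.ndarray:
        """0-based item indices belonging to ``facet``."""
        return np.flatnonzero(np.array(self.facet) == facet)


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one sample's scores."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def load_scoring_map(path: str | None = None) -> ScoringMap:
    """Load a scoring map from YAML; defaults to the packaged FFMQ-39 map."""
    if path is None:
        text = (resources.files("mindcpm.data") / "ffmq39_scoring.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)["items"]
    if sorted(int(k) for k in raw) != list(range(1, N_ITEMS + 1)):
        raise ValueError(f"scoring map must assign items 1..{N_ITEMS} exactly once each")
    facet = tuple(raw[i]["facet"] for i in range(1, N_ITEMS + 1))
    reverse = tuple(bool(raw[i]["reverse"]) for i in range(1, N_ITEMS + 1))
    return ScoringMap(facet=facet, reverse=reverse)


def score_ffmq(items: pd.DataFrame, scoring: ScoringMap | None = None) -> pd.DataFrame:
    """Score item responses into facet sums and totals.

    Parameters
    ----------
    items
        One row per subject; columns item_01..item_39 with responses in 1..5.
        The index is preserved (use subject ids).
    scoring
        Item map; defaults to the packaged FFMQ-39 assignment.

    Returns
    -------
    DataFrame with columns AA, NJ, NR, D, O, total, total_without_observing.
    """
    scoring = scoring or load_scoring_map()
    missing = [c for c in ITEM_COLUMNS if c not in items.columns]
    if missing:
        raise ValueError(f"missing item column(s): {missing}")
    resp = items[ITEM_COLUMNS].to_numpy()
    bad_rows, bad_cols = np.nonzero(~np.isin(resp, [1, 2, 3, 4, 5]))
    if bad_rows.size:
        raise ValueError(
            f"response outside 1..5 at subject {items.index[bad_rows[0]]!r}, "
            f"item {bad_cols[0] + 1}"
        )
    rev = np.array(scoring.reverse)
    scored = np.where(rev, 6 - resp, resp)
    out = pd.DataFrame(index=items.index)
    for f in FACETS:
        out[f] = scored[:, scoring.items_of(f)].sum(axis=1)
    out["total"] = out[list(FACETS)].sum(axis=1)
    out["total_without_observing"] = out["total"] - out["O"]
    return out


def welch_t(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Unpaired heteroskedastic (Welch) t-test from group summaries.

    Returns (t, df, p) with Welch–Satterthwaite degrees of freedom and a
    two-tailed p-value.
    """
    res = st.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def cohens_d(a: GroupSummary, b: GroupSummary) -> float:
    """Pooled-SD Cohen's d for two independent groups."""
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD")
    return (a.mean - b.mean) / np.sqrt(pooled_var)


def subscale_correlations(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Pearson correlations between facets, and of each facet with the total.

    ``scores`` must have the five facet columns; a ``total`` column is used
    when present, else computed as the facet sum.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 subjects")
    facets = scores[list(FACETS)]
    sd = facets.std()
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance facet(s): {dead}")
    total = scores["total"] if "total" in scores.columns else facets.sum(axis=1)
    corr = facets.corr(method="pearson")
    with_total = facets.corrwith(total)
    with_total.name = "r_with_total"
    return corr, with_total
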