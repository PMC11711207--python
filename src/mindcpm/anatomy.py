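"""Anatomical summaries of learned edge masks: degree, network pairs, export.

Nodes are assigned to large-scale networks (e.g., a 10-network labelling
such as SMN, CO, AUD, DMN, VIS, FPN, SAL, SUB, VAN, DAN, plus
"unassigned") via a label table supplied as data; mask edges are then
summarized as node degrees and within/between-network counts. Surface or
connectogram rendering is out of scope; instead masks export to a plain
edge-list TSV that external viewers and re-imports consume.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import edge_pairs, n_edges
from .core import EdgeMask

__all__ = [
    "load_network_labels",
    "node_degree",
    "network_pair_counts",
    "export_edge_list",
    "import_edge_list",
]


def load_network_labels(path: str | Path, n_nodes: int) -> pd.Series:
    """Read a node_id,network CSV into a per-node label series.

    Nodes absent from the file are labelled "unassigned".
    """
    tab = pd.read_csv(path)
    labels = pd.Series("unassigned", index=pd.RangeIndex(n_nodes), name="network")
    ids = tab["node_id"].to_numpy()
    if (ids < 0).any() or (ids >= n_nodes).any():
        raise ValueError("node_id outside 0..n_nodes-1")
    labels.iloc[ids] = tab["network"].astype(str).to_numpy()
    return labels


def node_degree(mask: EdgeMask, n_nodes: int) -> pd.Series:
    """Mask edges incident to each node; degrees sum to twice the mask size."""
    if mask.member.size != n_edges(n_nodes):
        raise ValueError("mask length inconsistent with n_nodes")
    i, j = edge_pairs(n_nodes)
    deg = np.zeros(n_nodes, dtype=int)
    sel = mask.member
    np.add.at(deg, i[sel], 1)
    np.add.at(deg, j[sel], 1)
    return pd.Series(deg, name=f"degree_{mask.sign}")


def network_pair_counts(mask: EdgeMask, labels: pd.Series) -> pd.DataFrame:
    """Symmetric network x network matrix of mask-edge counts.

    Cell (A, B) counts mask edges with one endpoint labelled A and the other
    B; the diagonal holds within-network counts. "unassigned" appears as its
    own row/column when present. Upper triangle plus diagonal sums to the
    mask size.
    """
    n_nodes = len(labels)
    if mask.member.size != n_edges(n_nodes):
        raise ValueError("mask length inconsistent with the label table")
    i, j = edge_pairs(n_nodes)
    sel = mask.member
    la = labels.to_numpy()[i[sel]]
    lb = labels.to_numpy()[j[sel]]
    names = sorted(pd.unique(labels))
    idx = {name: k for k, name in enumerate(names)}
    counts = np.zeros((len(names), len(names)), dtype=int)
    for a, b in zip(la, lb):
        ka, kb = idx[a], idx[b]
        counts[ka, kb] += 1
        if ka != kb:
            counts[kb, ka] += 1
    return pd.DataFrame(counts, index=names, columns=names)


def export_edge_list(mask: EdgeMask, n_nodes: int, path: str | Path) -> pd.DataFrame:
    """Write the mask as a TSV edge list (node_i, node_j, sign, weight=1)."""
    i, j = edge_pairs(n_nodes)
    sel = np.flatnonzero(mask.member)
    tab = pd.DataFrame(
        {"node_i": i[sel], "node_j": j[sel], "sign": mask.sign, "weight": 1}
    )
    tab.to_csv(path, sep="\t", index=False)
    return tab


def import_edge_list(path: str | Path, n_nodes: int) -> EdgeMask:
    """Inverse of :func:`export_edge_list`; reconstructs the mask exactly."""
    tab = pd.read_csv(path, sep="\t")
    member = np.zeros(n_edges(n_nodes), dtype=bool)
    if len(tab):
        sign = tab["sign"].iloc[0]
        i = tab["node_i"].to_numpy()
        j = tab["node_j"].to_numpy()
        if (i >= j).any():
            raise ValueError("edge list must use canonical i < j ordering")
        member[(i * (2 * n_nodes - i - 1)) // 2 + (j - i - 1)] = True
    else:
        sign = "positive"
    return EdgeMask(sign=sign, member=member)
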