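"""Stress-expression analysis: TPM retention filtering, up/down regulation
calls between two conditions, per-group summaries, heatmap row ordering, and
a correlation-based co-expression layer.

Regulation is called on fold change between condition means with a small
pseudocount: fold = (stress + eps) / (control + eps).  The default cutoff of
1.5-fold is a conventional choice for calling direction without replicate
dispersion modeling; it is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .seqio import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_UP_THRESHOLD = 1.5


def retention_filter(
    m: ExpressionMatrix, conditions: tuple[str, str], min_tpm: float = 1.0
) -> ExpressionMatrix:
    """Keep genes expressed in both conditions (mean TPM >= 1, inclusive).

    The condition value of a gene is the mean over that condition's samples.
    """
    if m.unit != "tpm":
        raise ValueError("retention filter expects a TPM matrix")
    mean_a = m.condition_means(conditions[0])
    mean_b = m.condition_means(conditions[1])
    keep = (mean_a >= min_tpm) & (mean_b >= min_tpm)
    filtered = m.values.loc[keep]
    # column sums no longer reach 1e6 after dropping rows, hence the new unit tag
    return ExpressionMatrix(filtered, dict(m.condition_map), unit="tpm_filtered")


@dataclass(frozen=True)
class RegulationCall:
    gene_id: str
    control_tpm: float
    stress_tpm: float
    fold_change: float
    label: str  # up | down | unchanged


def call_regulation(
    m: ExpressionMatrix,
    control: str,
    stress: str,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[RegulationCall]:
    """Direction of regulation per gene between two conditions.

    up when fold >= up_threshold, down when fold <= 1/up_threshold, else
    unchanged; the partition is exhaustive and exclusive.
    """
    if up_threshold <= 1:
        raise ValueError("up_threshold must be > 1")
    ctrl = m.condition_means(control)
    strs = m.condition_means(stress)
    calls = []
    for gene in m.gene_ids:
        c, s = float(ctrl[gene]), float(strs[gene])
        fold = (s + pseudocount) / (c + pseudocount)
        if fold >= up_threshold:
            label = "up"
        elif fold <= 1.0 / up_threshold:
            label = "down"
        else:
            label = "unchanged"
        calls.append(RegulationCall(gene, c, s, fold, label))
    return calls


def call_single(
    control_tpm: float,
    stress_tpm: float,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> str:
    """Regulation label for one (control, stress) TPM pair."""
    fold = (stress_tpm + pseudocount) / (control_tpm + pseudocount)
    if fold >= up_threshold:
        return "up"
    if fold <= 1.0 / up_threshold:
        return "down"
    return "unchanged"


def group_regulation_summary(
    calls: list[RegulationCall], group_of: dict[str, str]
) -> pd.DataFrame:
    """Contingency of regulation label by phylogenetic group, rows ordered by
    group letter."""
    rows = [
        {"group": group_of.get(c.gene_id, "unassigned"), "label": c.label}
        for c in calls
    ]
    if not rows:
        return pd.DataFrame(columns=["group", "up", "down", "unchanged"])
    df = pd.DataFrame(rows)
    table = (
        df.pivot_table(index="group", columns="label", aggfunc="size", fill_value=0)
        .reindex(columns=["up", "down", "unchanged"], fill_value=0)
        .reset_index()
        .sort_values("group")
        .reset_index(drop=True)
    )
    table.columns.name = None
    return table


def heatmap_order(m: ExpressionMatrix) -> tuple[list[str], np.ndarray]:
    """Row ordering for a heatmap: Euclidean distance, average linkage.

    Rows are sorted by gene id before clustering, which pins tie resolution
    and makes the leaf order invariant to input row permutation.  Returns the
    ordered gene ids and the scipy linkage matrix.
    """
    if len(m.gene_ids) < 2:
        raise ValueError("heatmap ordering needs at least 2 genes")
    values = m.values.sort_index()
    ids = list(values.index)
    Z = hierarchy.linkage(pdist(values.to_numpy(), metric="euclidean"), method="average")
    order = hierarchy.leaves_list(Z)
    return [ids[i] for i in order], Z


def linkage_to_newick(Z: np.ndarray, ids: list[str]) -> str:
    """Render a scipy linkage matrix as a rooted Newick dendrogram with
    merge heights as branch lengths."""
    n = len(ids)
    heights = {i: 0.0 for i in range(n)}
    parts = {i: ids[i] for i in range(n)}
    for k, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        la, lb = h - heights[a], h - heights[b]
        node = n + k
        parts[node] = f"({parts[a]}:{la:.6g},{parts[b]}:{lb:.6g})"
        heights[node] = h
    return parts[n + len(Z) - 1] + ";"


@dataclass(frozen=True)
class CoexpressionEdge:
    gene_a: str
    gene_b: str
    r: float


def coexpression_edges(
    m: ExpressionMatrix, threshold: float = 0.9
) -> list[CoexpressionEdge]:
    """All gene pairs with |Pearson r| >= threshold across samples.

    Zero-variance genes cannot be correlated and are excluded (logged).
    """
    if len(m.sample_ids) < 3:
        raise ValueError("co-expression needs at least 3 samples")
    values = m.values.sort_index()
    stds = values.std(axis=1, ddof=0)
    flat = list(values.index[stds == 0])
    if flat:
        logger.info("excluding %d zero-variance gene(s): %s", len(flat), flat[:5])
        values = values.loc[stds > 0]
    ids = list(values.index)
    if len(ids) < 2:
        return []
    r = np.corrcoef(values.to_numpy())
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(r[i, j]) >= threshold:
                edges.append(CoexpressionEdge(ids[i], ids[j], float(r[i, j])))
    return edges


def write_calls_tsv(calls: list[RegulationCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcontrol_tpm\tstress_tpm\tfold_change\tlabel\n")
        for c in sorted(calls, key=lambda c: c.gene_id):
            fh.write(
                f"{c.gene_id}\t{c.control_tpm:.6g}\t{c.stress_tpm:.6g}\t"
                f"{c.fold_change:.6g}\t{c.label}\n"
            )


def write_edges_tsv(edges: list[CoexpressionEdge], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tr\n")
        for e in sorted(edges, key=lambda e: (e.gene_a, e.gene_b)):
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.r:.6g}\n")
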