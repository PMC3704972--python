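"""Relative expression from qPCR Ct tables (delta-delta Ct) and
hierarchical clustering of expression matrices.

The delta-delta Ct method assumes perfect PCR doubling: with reference
gene r, calibrator sample c and target t,
    dCt(s) = Ct(t, s) - Ct(r, s)
    ddCt   = dCt(sample) - dCt(calibrator)
    fold   = 2 ** (-ddCt)
Replicate Ct values are averaged (arithmetic mean) before the deltas.

Clustering is agglomerative with Euclidean distance and complete linkage
(inter-cluster distance = maximum pairwise), via scipy; merge heights are
checked to be non-decreasing, which complete linkage guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import InputError, InvariantError

CT_COLUMNS = ("gene", "condition", "replicate", "ct")


@dataclass
class CtTable:
    """Long-format Ct measurements with designated reference/calibrator."""

    data: pd.DataFrame  # columns: gene, condition, replicate, ct
    reference_gene: str
    calibrator: str

    def __post_init__(self):
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise InputError(f"Ct table missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise InputError("Ct values must be positive")
        if self.reference_gene not in set(self.data["gene"]):
            raise InputError(
                f"reference gene {self.reference_gene!r} not in Ct table"
            )

    def mean_ct(self, gene: str, condition: str) -> float:
        sel = self.data[
            (self.data["gene"] == gene) & (self.data["condition"] == condition)
        ]
        if sel.empty:
            raise InputError(f"no Ct for gene {gene!r} in condition {condition!r}")
        return float(sel["ct"].mean())


@dataclass
class Dendrogram:
    """Agglomerative merge list over labelled items.

    ``linkage`` is a scipy linkage matrix; row k merges clusters
    linkage[k, 0] and linkage[k, 1] at height linkage[k, 2].
    """

    labels: list[str]
    linkage: np.ndarray

    def __post_init__(self):
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise InvariantError("merge heights decrease: linkage not monotone")

    def merges(self) -> list[tuple[int, int, float]]:
        return [
            (int(a), int(b), float(h)) for a, b, h, _ in self.linkage
        ]


def ddct_fold_change(
    ct: CtTable, target_gene: str, sample: str
) -> float:
    """Relative expression of ``target_gene`` in ``sample`` vs the
    calibrator, normalised to the reference gene (2^-ddCt)."""
    if sample == ct.calibrator:
        return 1.0
    dct_sample = ct.mean_ct(target_gene, sample) - ct.mean_ct(
        ct.reference_gene, sample
    )
    dct_cal = ct.mean_ct(target_gene, ct.calibrator) - ct.mean_ct(
        ct.reference_gene, ct.calibrator
    )
    ddct = dct_sample - dct_cal
    return float(2.0 ** (-ddct))


def fold_change_table(ct: CtTable) -> pd.DataFrame:
    """Fold change for every (target gene, condition) pair in the table."""
    genes = sorted(g for g in ct.data["gene"].unique() if g != ct.reference_gene)
    conditions = list(pd.unique(ct.data["condition"]))
    out = pd.DataFrame(
        {
            cond: [ddct_fold_change(ct, g, cond) for g in genes]
            for cond in conditions
        },
        index=genes,
    )
    out.index.name = "gene"
    return out


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "genes") -> Dendrogram:
    """Complete-linkage Euclidean clustering of rows (genes) or columns."""
    if axis not in ("genes", "conditions"):
        raise InputError("axis must be 'genes' or 'conditions'")
    data = matrix if axis == "genes" else matrix.T
    if data.shape[0] < 2:
        raise InputError("need at least 2 items to cluster")
    if data.isna().any().any():
        raise InputError("expression matrix has missing cells")
    linkage = hierarchy.linkage(data.values, method="complete",
                                metric="euclidean")
    return Dendrogram(list(data.index), linkage)


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Cut into exactly k clusters at the lowest height achieving k.

    Returns item label -> cluster id (1..k).
    """
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise InputError(f"k={k} outside 1..{n}")
    assignments = hierarchy.fcluster(dendrogram.linkage, t=k,
                                     criterion="maxclust")
    return dict(zip(dendrogram.labels, (int(a) for a in assignments)))


def leaf_order(dendrogram: Dendrogram) -> list[str]:
    """Dendrogram leaf ordering, for heatmap-style exports."""
    idx = hierarchy.leaves_list(dendrogram.linkage)
    return [dendrogram.labels[i] for i in idx]


def tissue_fold_summary(
    matrix: pd.DataFrame, reference_condition: str
) -> pd.DataFrame:
    """Per-gene fold change of every condition relative to a reference
    condition; genes with a zero reference value get NaN folds."""
    if reference_condition not in matrix.columns:
        raise InputError(
            f"reference condition {reference_condition!r} not in matrix"
        )
    ref = matrix[reference_condition]
    with np.errstate(divide="ignore", invalid="ignore"):
        folds = matrix.div(ref.where(ref != 0), axis=0)
    return folds


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scaling for display; clustering runs on raw values."""
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0).replace(0, 1.0)
    return matrix.sub(mu, axis=0).div(sd, axis=0)
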