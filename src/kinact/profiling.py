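"""Unsupervised profiling of the activity matrix.

Agglomerative hierarchical clustering on Euclidean distances groups the
peptides (three activity strata: A intermediate, B high, C low) and the
samples (two phosphorylation groups: 1 low, 2 high), and a Welch t-test with
Benjamini-Hochberg FDR control identifies peptides differentially
phosphorylated between the two sample groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .quantify import ActivityMatrix

__all__ = [
    "ClusterAssignment",
    "cluster_matrix",
    "label_peptide_clusters",
    "label_sample_clusters",
    "welch_t_test",
    "bh_fdr",
    "differential_table",
]


@dataclass
class ClusterAssignment:
    """A flat cut of a hierarchical clustering on one axis of the matrix."""

    axis: Literal["peptides", "samples"]
    labels: dict
    k: int
    linkage_tree: np.ndarray
    leaf_order: list

    def __post_init__(self) -> None:
        if len(set(self.labels.values())) != self.k:
            raise ValueError(
                f"expected exactly {self.k} clusters, found {len(set(self.labels.values()))}"
            )

    def members(self, label) -> list:
        return [item for item, lab in self.labels.items() if lab == label]

    def relabel(self, mapping: Mapping) -> "ClusterAssignment":
        return ClusterAssignment(
            axis=self.axis,
            labels={item: mapping[lab] for item, lab in self.labels.items()},
            k=self.k,
            linkage_tree=self.linkage_tree,
            leaf_order=self.leaf_order,
        )


def cluster_matrix(
    matrix: ActivityMatrix,
    axis: Literal["peptides", "samples"],
    k: int,
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Hierarchical clustering (Euclidean distance) cut to exactly k groups."""
    if k < 2:
        raise ValueError("k must be >= 2")
    data = matrix.values if axis == "peptides" else matrix.values.T
    ids = list(data.index)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} items on axis {axis!r}")
    X = data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(f"missing cells on axis {axis!r}; impute or drop first")
    Z = hierarchy.linkage(X, method=linkage_method, metric="euclidean")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if len(set(flat)) != k:
        # maxclust can undershoot on exactly tied merges; cut by distance instead
        heights = sorted(Z[:, 2])
        cut = heights[-(k - 1)] - 1e-12 if k > 1 else np.inf
        flat = hierarchy.fcluster(Z, t=cut, criterion="distance")
    leaf_order = [ids[i] for i in hierarchy.leaves_list(Z)]
    return ClusterAssignment(
        axis=axis,
        labels=dict(zip(ids, (int(c) for c in flat))),
        k=k,
        linkage_tree=Z,
        leaf_order=leaf_order,
    )


def _mean_by_cluster(matrix: ActivityMatrix, assignment: ClusterAssignment) -> dict:
    data = matrix.values if assignment.axis == "peptides" else matrix.values.T
    out: dict = {}
    for lab in set(assignment.labels.values()):
        members = assignment.members(lab)
        out[lab] = float(data.loc[members].to_numpy().mean())
    return out


def label_peptide_clusters(
    matrix: ActivityMatrix, assignment: ClusterAssignment
) -> ClusterAssignment:
    """Name the k=3 peptide strata by mean activity: B high, A mid, C low."""
    if assignment.k != 3 or assignment.axis != "peptides":
        raise ValueError("peptide labelling expects k=3 on the peptides axis")
    means = _mean_by_cluster(matrix, assignment)
    ordered = sorted(means, key=means.get, reverse=True)  # high -> low
    return assignment.relabel(dict(zip(ordered, ["B", "A", "C"])))


def label_sample_clusters(
    matrix: ActivityMatrix, assignment: ClusterAssignment
) -> ClusterAssignment:
    """Name the k=2 sample groups by mean activity: 1 low, 2 high."""
    if assignment.k != 2 or assignment.axis != "samples":
        raise ValueError("sample labelling expects k=2 on the samples axis")
    means = _mean_by_cluster(matrix, assignment)
    low, high = sorted(means, key=means.get)
    return assignment.relabel({low: "1", high: "2"})


def welch_t_test(group1: Sequence[float], group2: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df; two-sided p.

    Degenerate inputs: both groups constant with equal means -> (0, df, 1);
    constant with unequal means -> p = 0.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0.0 and vb == 0.0:
        df = float(na + nb - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), df, 0.0
    se2 = va / na + vb / nb
    t = float((a.mean() - b.mean()) / math.sqrt(se2))
    df = float(se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    matrix: ActivityMatrix,
    groups: ClusterAssignment | Mapping,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-peptide Welch test between the two sample groups.

    Fold change is computed on the linear scale: mean(2^v) in the globally
    higher-activity group over mean(2^v) in the lower one.  Rows are sorted
    by p ascending; ``significant`` marks p < alpha; the overall FDR of that
    selection (max q among significant rows) is stored in
    ``result.attrs["selection_fdr"]``.
    """
    labels = groups.labels if isinstance(groups, ClusterAssignment) else dict(groups)
    by_group: dict = {}
    for sample, lab in labels.items():
        by_group.setdefault(lab, []).append(sample)
    if len(by_group) != 2:
        raise ValueError(f"expected exactly 2 sample groups, got {len(by_group)}")
    (lab_a, cols_a), (lab_b, cols_b) = sorted(by_group.items(), key=lambda kv: str(kv[0]))
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each sample group needs at least 2 samples")
    A = matrix.values[cols_a]
    B = matrix.values[cols_b]
    # globally higher-activity group provides the fold-change numerator
    if B.to_numpy().mean() >= A.to_numpy().mean():
        hi, lo = B, A
    else:
        hi, lo = A, B
    rows = []
    for pep in matrix.values.index:
        t, df, p = welch_t_test(A.loc[pep].to_numpy(), B.loc[pep].to_numpy())
        lin_hi = float((2.0 ** hi.loc[pep]).mean())
        lin_lo = float((2.0 ** lo.loc[pep]).mean())
        rows.append(
            {
                "peptide_id": pep,
                "t_statistic": t,
                "df": df,
                "p_value": p,
                "fold_change": lin_hi / lin_lo,
                "mean_signal": (lin_hi + lin_lo) / 2.0,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["p_value"] < alpha
    out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    sig_q = out.loc[out["significant"], "q_value"]
    out.attrs["selection_fdr"] = float(sig_q.max()) if len(sig_q) else float("nan")
    out.attrs["groups"] = (lab_a, lab_b)
    return out
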