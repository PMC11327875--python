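"""Expression matrices: replicate averaging, expressed filter, specificity, Z-scores.

The single currency is a genes x samples TPM (or count) matrix with a
sample-metadata sheet.  Replicates are collapsed by arithmetic mean into a
genes x conditions matrix; a gene counts as *expressed* in a condition when
its replicate-averaged TPM is at least 1.  Tissue-specific genes are
expressed (>=1 TPM) in stages of exactly one tissue and nowhere else;
stage-specific genes symmetrically.  For heatmap-style summaries each gene's
profile is standardized to Z-scores, clipped to [-3, 3], and genes/conditions
are ordered by complete-linkage hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

EXPRESSED_TPM = 1.0  # inclusive threshold

META_COLUMNS = ["sample_id", "tissue", "stage", "replicate", "genotype", "condition"]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix plus per-sample metadata.

    ``values`` is indexed by gene_id with sample_id columns; ``meta`` is
    indexed by sample_id.  ``unit`` is "TPM" or "counts".
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression matrix contains negative entries")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if self.unit not in ("TPM", "counts"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.meta.loc[list(sample_ids)], self.unit
        )


@dataclass
class ConditionExpression:
    """Replicate-averaged genes x conditions matrix.

    Columns are a MultiIndex over the grouping factors (e.g. tissue, stage).
    """

    values: pd.DataFrame
    factors: tuple[str, ...]
    n_replicates: dict[tuple, int] = field(default_factory=dict)


def load_expression(
    matrix_path: str | Path, meta_path: str | Path, unit: str = "TPM"
) -> ExpressionMatrix:
    """Read a TSV matrix (first column gene_id) and a metadata TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values=values, meta=meta, unit=unit)


def average_replicates(
    em: ExpressionMatrix, by: Sequence[str] = ("tissue", "stage")
) -> ConditionExpression:
    """Arithmetic mean of replicate columns per condition.

    A condition is one combination of the ``by`` metadata factors; every
    condition present in the metadata must have at least one sample column.
    """
    by = tuple(by)
    for col in by:
        if col not in em.meta.columns:
            raise ValueError(f"metadata lacks column {col!r}")
    groups = em.meta.groupby(list(by), sort=True, observed=True).groups
    cols = {}
    n_reps = {}
    for key, sample_ids in groups.items():
        key = key if isinstance(key, tuple) else (key,)
        sample_ids = list(sample_ids)
        if not sample_ids:
            raise ValueError(f"condition {key} has no samples")
        cols[key] = em.values[sample_ids].mean(axis=1)
        n_reps[key] = len(sample_ids)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=by)
    return ConditionExpression(values=out, factors=by, n_replicates=n_reps)


def expressed_mask(
    ce: ConditionExpression, threshold: float = EXPRESSED_TPM
) -> pd.DataFrame:
    """Boolean genes x conditions mask: averaged TPM >= threshold (inclusive)."""
    return ce.values >= threshold


def expressed_set(
    ce: ConditionExpression, threshold: float = EXPRESSED_TPM
) -> dict[tuple, set[str]]:
    """Per-condition sets of expressed genes."""
    mask = expressed_mask(ce, threshold)
    return {cond: set(mask.index[mask[cond]]) for cond in mask.columns}


def specificity(
    ce: ConditionExpression, axis: str = "tissue", threshold: float = EXPRESSED_TPM
) -> pd.Series:
    """Label each gene with the single level of ``axis`` it is expressed in.

    A gene is tissue-specific for tissue T when it is expressed (>=1 TPM,
    replicate-averaged) in at least one stage of T and in no condition of any
    other tissue — independent of which stages those are.  Genes expressed in
    zero or in more than one level get NA.
    """
    if axis not in ce.factors:
        raise ValueError(f"axis {axis!r} not among condition factors {ce.factors}")
    mask = expressed_mask(ce, threshold)
    by_level = mask.T.groupby(level=axis, observed=True).any().T  # genes x levels
    n_levels = by_level.sum(axis=1)
    labels = by_level.idxmax(axis=1).where(n_levels == 1)
    labels.name = f"{axis}_specific"
    return labels


@dataclass
class ClusteredMatrix:
    """Z-scored matrix with hierarchical-clustering orders and labels."""

    z: pd.DataFrame                      # clipped Z-scores, original order
    gene_order: list[str]                # dendrogram leaf order
    condition_order: list                # dendrogram leaf order of columns
    gene_clusters: pd.Series | None      # k-cut labels (1..k), or None
    zero_variance_genes: list[str]
    gene_linkage: np.ndarray
    condition_linkage: np.ndarray


def standardize_and_cluster(
    ce: ConditionExpression,
    clip: float = 3.0,
    k: int | None = None,
    metric: str = "euclidean",
    expressed_threshold: float = EXPRESSED_TPM,
) -> ClusteredMatrix:
    """Z-score gene profiles, clip to +/-clip, cluster genes and conditions.

    Genes expressed in no condition are removed first.  Z = (x - mean)/sd per
    gene across conditions; zero-variance genes get all-zero rows and are
    flagged.  Clustering is complete linkage on the clipped Z matrix
    (Euclidean by default); ``k`` requests a flat cut into k gene clusters.
    """
    vals = ce.values
    keep = (vals >= expressed_threshold).any(axis=1)
    vals = vals.loc[keep]
    if vals.empty:
        raise ValueError("no gene is expressed in any condition")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    zero_var = sd == 0
    sd_safe = sd.mask(zero_var, 1.0)
    z = vals.sub(mean, axis=0).div(sd_safe, axis=0)
    z.loc[zero_var] = 0.0
    z = z.clip(-clip, clip)

    if len(z) > 1:
        gene_link = hierarchy.linkage(pdist(z.values, metric=metric), method="complete")
        gene_order = [z.index[i] for i in hierarchy.leaves_list(gene_link)]
    else:
        gene_link = np.empty((0, 4))
        gene_order = list(z.index)
    if z.shape[1] > 1:
        cond_link = hierarchy.linkage(pdist(z.values.T, metric=metric), method="complete")
        cond_order = [z.columns[i] for i in hierarchy.leaves_list(cond_link)]
    else:
        cond_link = np.empty((0, 4))
        cond_order = list(z.columns)

    clusters = None
    if k is not None and len(z) > 1:
        labels = hierarchy.fcluster(gene_link, t=k, criterion="maxclust")
        clusters = pd.Series(labels, index=z.index, name="cluster")

    return ClusteredMatrix(
        z=z,
        gene_order=gene_order,
        condition_order=cond_order,
        gene_clusters=clusters,
        zero_variance_genes=list(z.index[zero_var]),
        gene_linkage=gene_link,
        condition_linkage=cond_link,
    )
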