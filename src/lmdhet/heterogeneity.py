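"""Spatial heterogeneity statistics over the protein matrix.

Covers variable-feature selection (raw MAD cutoff), hierarchical
clustering of samples/proteins on correlation distance, pairwise Spearman
correlations between sampling levels, per-patient dendrograms with a
Mann-Whitney comparison of intra-ET vs intra-ES relatedness, and the
secreted-protein between-level variance test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .stats import mad, mann_whitney_u, MWUResult

logger = logging.getLogger(__name__)

__all__ = [
    "mad_select",
    "Dendrogram",
    "hier_cluster",
    "pairwise_spearman",
    "patient_dendrogram",
    "secreted_variance_test",
    "eligible_patients",
]


def mad_select(matrix: pd.DataFrame, mad_min: float = 1.0) -> List[str]:
    """Proteins whose row MAD is strictly above ``mad_min``.

    Raw MAD (no consistency constant); result sorted by MAD descending,
    ties by protein id.
    """
    mads = pd.Series(mad(matrix.to_numpy(), axis=1), index=matrix.index)
    selected = mads[mads > mad_min]
    order = sorted(selected.index, key=lambda p: (-selected[p], p))
    return list(order)


@dataclass
class Dendrogram:
    """Average-linkage tree over correlation distances, newick-serializable."""

    linkage: np.ndarray
    labels: List[str]
    method: str = "average"
    metric: str = "1 - pearson"

    def cut(self, k: int) -> pd.Series:
        """Assign each leaf to one of ``k`` flat clusters."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.10g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def _corr_linkage(data: pd.DataFrame, corr_method: str,
                  what: str) -> Dendrogram:
    """Average-linkage tree over 1 - correlation among ``data`` columns."""
    data = data[sorted(data.columns)]  # deterministic leaf/tie order
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(data.columns, sd) if s == 0]
        raise ValueError(f"zero-variance {what} under selected features: {bad}")
    if corr_method == "pearson":
        corr = np.corrcoef(X, rowvar=False)
    elif corr_method == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        corr = np.corrcoef(ranks, rowvar=False)
    else:
        raise ValueError(f"unknown correlation method {corr_method!r}")
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=Z, labels=list(data.columns),
                      metric=f"1 - {corr_method}")


def hier_cluster(
    matrix: pd.DataFrame,
    proteins: Optional[Sequence[str]] = None,
    corr_method: str = "pearson",
    cluster_proteins: bool = True,
) -> Tuple[Dendrogram, Optional[Dendrogram]]:
    """Unsupervised hierarchical clustering of samples (and proteins).

    Distance is 1 - correlation (Pearson by default), average linkage.
    Returns ``(sample_tree, protein_tree)``; the protein tree is None when
    ``cluster_proteins`` is False.
    """
    if proteins is not None:
        if len(proteins) == 0:
            raise ValueError("selected protein list is empty")
        matrix = matrix.loc[list(proteins)]
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    sample_tree = _corr_linkage(matrix, corr_method, "samples")
    protein_tree = None
    if cluster_proteins and matrix.shape[0] >= 2:
        protein_tree = _corr_linkage(matrix.T, corr_method, "proteins")
    return sample_tree, protein_tree


@dataclass
class CorrelationResult:
    corr: pd.DataFrame            # symmetric Spearman matrix, unit diagonal
    summary: Dict[str, float]     # median/min/max over off-diagonal entries
    method: str = "spearman"

    def offdiag(self) -> np.ndarray:
        vals = self.corr.to_numpy()
        iu = np.triu_indices_from(vals, k=1)
        return vals[iu]


def pairwise_spearman(
    matrix: pd.DataFrame,
    annot: Optional[pd.DataFrame] = None,
    patient: Optional[str] = None,
    collection_type: Optional[str] = None,
) -> CorrelationResult:
    """Spearman correlations between sampling levels over ALL proteins.

    With ``annot`` plus ``patient``/``collection_type`` the matrix is
    restricted to that group's samples first. Off-diagonal summaries
    exclude each level's self-correlation of 1.
    """
    sub = matrix
    if annot is not None:
        sel = pd.Series(True, index=annot.index)
        if patient is not None:
            sel &= annot["patient"] == patient
        if collection_type is not None:
            sel &= annot["collection_type"] == collection_type
        samples = [s for s in annot.loc[sel, "sample_id"] if s in matrix.columns]
        sub = matrix[samples]
    if sub.shape[1] < 2:
        warnings.warn("correlation group has < 2 samples; empty summary",
                      stacklevel=2)
        corr = pd.DataFrame(np.ones((sub.shape[1],) * 2),
                            index=sub.columns, columns=sub.columns)
        return CorrelationResult(corr, {})
    rho = stats.spearmanr(sub.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    corr = pd.DataFrame(rho, index=sub.columns, columns=sub.columns)
    off = corr.to_numpy()[np.triu_indices(len(corr), k=1)]
    summary = {"median": float(np.median(off)),
               "min": float(np.min(off)),
               "max": float(np.max(off)),
               "n_pairs": int(off.size)}
    return CorrelationResult(corr, summary)


@dataclass
class PatientDendrogramResult:
    patient: str
    dendrogram: Dendrogram
    n_proteins: int
    intra_et: np.ndarray       # pairwise Spearman within ET levels
    intra_es: np.ndarray       # pairwise Spearman within ES levels
    test: MWUResult
    more_correlated: str       # "ET" or "ES" (higher median intra correlation)


def patient_dendrogram(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    patient: str,
    mad_min: float = 1.0,
    min_levels: int = 3,
) -> Optional[PatientDendrogramResult]:
    """Per-patient ET+ES dendrogram and intra-type relatedness comparison.

    Feature selection (MAD > ``mad_min``) is computed within the patient's
    own ET+ES samples. Requires >= ``min_levels`` levels in both ET and ES
    (otherwise returns None with a logged reason). The Mann-Whitney U test
    compares all C(n,2) intra-ET pairwise Spearman correlations against the
    intra-ES ones, two-sided.
    """
    sub_annot = annot[(annot["patient"] == patient)
                      & annot["collection_type"].isin(["ET", "ES"])]
    counts = sub_annot.groupby("collection_type")["sample_id"].count()
    if counts.get("ET", 0) < min_levels or counts.get("ES", 0) < min_levels:
        logger.info("patient %s skipped: needs >= %d levels in both ET and ES "
                    "(has ET=%d, ES=%d)", patient, min_levels,
                    counts.get("ET", 0), counts.get("ES", 0))
        return None
    samples = [s for s in sub_annot["sample_id"] if s in matrix.columns]
    sub = matrix[samples]
    selected = mad_select(sub, mad_min)
    if len(selected) < 2:
        logger.info("patient %s skipped: < 2 proteins pass MAD > %g",
                    patient, mad_min)
        return None
    sub = sub.loc[selected]
    tree, _ = hier_cluster(sub, corr_method="spearman", cluster_proteins=False)

    def intra(ctype: str) -> np.ndarray:
        ids = [s for s in sub_annot.loc[
            sub_annot["collection_type"] == ctype, "sample_id"] if s in sub.columns]
        res = pairwise_spearman(sub[ids])
        return res.offdiag()

    et_corr, es_corr = intra("ET"), intra("ES")
    test = mann_whitney_u(et_corr, es_corr)
    more = "ET" if np.median(et_corr) >= np.median(es_corr) else "ES"
    return PatientDendrogramResult(
        patient=patient, dendrogram=tree, n_proteins=len(selected),
        intra_et=et_corr, intra_es=es_corr, test=test, more_correlated=more)


def eligible_patients(annot: pd.DataFrame, min_levels: int = 4,
                      max_levels: int = 5) -> List[str]:
    """Patients with ``min_levels``-``max_levels`` levels in both ET and ES."""
    out = []
    for patient, grp in annot.groupby("patient"):
        c = grp.groupby("collection_type")["sample_id"].count()
        if (min_levels <= c.get("ET", 0) <= max_levels
                and min_levels <= c.get("ES", 0) <= max_levels):
            out.append(patient)
    return sorted(out)


@dataclass
class SecretedVarianceResult:
    patient: str
    collection_type: str
    n_secreted: int
    n_other: int
    median_mad_secreted: float
    median_mad_other: float
    test: MWUResult


def secreted_variance_test(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    secreted_flags: pd.Series,
    patient: str,
    collection_type: str = "ET",
) -> SecretedVarianceResult:
    """Do secreted/extracellular proteins vary more between levels?

    Per protein, between-level variability is the raw MAD of its abundance
    across the scope's sampling levels; the two classes are compared by a
    two-sided Mann-Whitney U test.
    """
    ids = annot.loc[(annot["patient"] == patient)
                    & (annot["collection_type"] == collection_type),
                    "sample_id"]
    samples = [s for s in ids if s in matrix.columns]
    if len(samples) < 2:
        raise ValueError(
            f"scope ({patient}, {collection_type}) has < 2 levels")
    sub = matrix[samples]
    mads = pd.Series(mad(sub.to_numpy(), axis=1), index=sub.index)
    flags = secreted_flags.reindex(sub.index).astype(bool)
    sec = mads[flags].to_numpy()
    other = mads[~flags].to_numpy()
    if sec.size < 2 or other.size < 2:
        raise ValueError(
            "need >= 2 proteins in both the secreted and non-secreted class")
    test = mann_whitney_u(sec, other)
    return SecretedVarianceResult(
        patient=patient, collection_type=collection_type,
        n_secreted=int(sec.size), n_other=int(other.size),
        median_mad_secreted=float(np.median(sec)),
        median_mad_other=float(np.median(other)),
        test=test)
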