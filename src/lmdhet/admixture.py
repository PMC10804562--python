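"""ssGSEA tumor/stroma/immune admixture scoring.

Single-sample gene set enrichment: per sample, features are ranked by
abundance and a rank-weighted running sum is accumulated along the ranked
list — in-set features contribute their rank value raised to ``alpha``
(normalized over the set), out-of-set features contribute a flat ECDF
step — and the score is the sum of the running differences over the whole
list. With alpha = 0.25 this is the conventional single-sample weighting.

Scores are reported raw by default; optional min-max normalization across
samples per signature is behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ssgsea_score",
    "ssgsea_sample_score",
    "ScoreTable",
    "truth_signatures",
    "purity_recovery",
]


def ssgsea_sample_score(values: pd.Series, members: Sequence[str],
                        alpha: float = 0.25) -> float:
    """ssGSEA running-sum score of one feature set in one sample.

    Features are ordered by decreasing abundance (ties broken by feature id
    for determinism); rank values are average ranks of the ascending order,
    so the most abundant feature carries rank ~N. At each position the
    running in-set weighted ECDF (weight = rank**alpha, normalized over the
    set) minus the out-of-set ECDF is accumulated; the score is the sum of
    those running differences.
    """
    ids = values.index.to_numpy()
    x = values.to_numpy(dtype=float)
    n = x.size
    member_mask = np.isin(ids, np.asarray(list(members)))
    m = int(member_mask.sum())
    if m == 0:
        raise ValueError("feature set has no overlap with the matrix")
    ranks = stats.rankdata(x, method="average")  # ascending: top feature ~ n
    order = np.lexsort((ids, -x))                # descending abundance
    in_set = member_mask[order]
    w = ranks[order] ** alpha
    w_in = np.where(in_set, w, 0.0)
    norm_in = w_in.sum()
    if m == n:
        raise ValueError("feature set covers the whole matrix; no background")
    ecdf_in = np.cumsum(w_in) / norm_in
    ecdf_out = np.cumsum(~in_set) / float(n - m)
    return float(np.sum(ecdf_in - ecdf_out))


@dataclass
class ScoreTable:
    scores: pd.DataFrame     # samples x signatures
    coverage: Dict[str, float]  # fraction of each set present in the matrix
    alpha: float = 0.25
    normalized: bool = False


def ssgsea_score(matrix: pd.DataFrame, signatures: Mapping[str, Sequence[str]],
                 alpha: float = 0.25, normalize: bool = False) -> ScoreTable:
    """Score every signature in every sample of a complete matrix."""
    if matrix.isna().any().any():
        raise ValueError("matrix must be complete (impute first)")
    features = set(matrix.index)
    coverage = {}
    used: Dict[str, list] = {}
    for name, members in signatures.items():
        if len(members) == 0:
            raise ValueError(f"signature {name!r} is empty")
        present = [f for f in members if f in features]
        if not present:
            raise ValueError(f"signature {name!r} has no features in the matrix")
        coverage[name] = len(present) / len(members)
        used[name] = present

    out = pd.DataFrame(index=matrix.columns, columns=list(signatures), dtype=float)
    for sample in matrix.columns:
        col = matrix[sample]
        for name, present in used.items():
            out.loc[sample, name] = ssgsea_sample_score(col, present, alpha)
    if normalize:
        rng = out.max(axis=0) - out.min(axis=0)
        rng = rng.replace(0.0, 1.0)
        out = (out - out.min(axis=0)) / rng
    out.index.name = "sample_id"
    return ScoreTable(scores=out, coverage=coverage, alpha=alpha,
                      normalized=normalize)


def truth_signatures(truth, n_top: int = 50) -> Dict[str, list]:
    """Tumor/Stroma signatures from planted truth (top ET-up / ES-up)."""
    lfc = truth.true_logfc
    up = lfc[lfc > 0].sort_values(ascending=False)
    down = lfc[lfc < 0].sort_values()
    if up.empty or down.empty:
        raise ValueError("ground truth has no planted effects in one direction")
    return {
        "Tumor": list(up.index[:n_top]),
        "Stroma": list(down.index[:n_top]),
    }


def purity_recovery(score_table: ScoreTable, truth, annot: pd.DataFrame,
                    signature: str = "Stroma") -> Tuple[float, float, pd.DataFrame]:
    """Spearman rho between a stroma score and true 1 - tumor fraction (BT).

    Returns (rho, p, scatter table) over the cohort's BT samples.
    """
    bt = annot[annot["collection_type"] == "BT"]
    rows = []
    for r in bt.itertuples():
        if r.sample_id not in score_table.scores.index:
            continue
        f = truth.bt_tumor_fraction.loc[r.patient, r.level]
        rows.append({
            "sample_id": r.sample_id,
            "score": float(score_table.scores.loc[r.sample_id, signature]),
            "true_stroma_fraction": float(1.0 - f),
        })
    tab = pd.DataFrame(rows)
    if len(tab) < 3:
        raise ValueError("need >= 3 BT samples with ground-truth fractions")
    res = stats.spearmanr(tab["score"], tab["true_stroma_fraction"])
    return float(res.statistic), float(res.pvalue), tab
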