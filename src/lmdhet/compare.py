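"""Cross-dataset and cross-platform comparison.

Concordant-alteration overlap between two datasets (Venn-style partition
with an explicit discordant-direction class), Spearman correlation of
shared logFCs, RPPA-style preprocessing (limit-of-detection floor, log2,
target-wise median centering), per-sample / per-feature cross-platform
correlations via an antibody/feature map, and association of alteration
abundances with external tumor-purity estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rppa_preprocess",
    "overlap_concordant",
    "OverlapResult",
    "logfc_correlation",
    "cross_platform_correlation",
    "purity_association",
]


def rppa_preprocess(raw: pd.DataFrame, lod_floor_log: float = -10.0) -> pd.DataFrame:
    """Floor sub-detection values at exp(lod_floor_log), log2, median center.

    Rows are antibody targets, columns samples. Zero/absent values become
    ``exp(lod_floor_log)`` before the log2 transform; each target row is
    then centered on its median. All-zero targets survive as constant rows
    (with a warning).
    """
    if (raw.fillna(0.0) < 0).any().any():
        raise ValueError("raw RPPA values must be non-negative")
    vals = raw.to_numpy(dtype=float).copy()
    floor = float(np.exp(lod_floor_log))
    below = ~(vals > 0) | np.isnan(vals)
    vals[below] = floor
    allzero = below.all(axis=1)
    if allzero.any():
        warnings.warn(
            f"all-zero targets retained as constant rows: "
            f"{list(raw.index[allzero])}", stacklevel=2)
    out = pd.DataFrame(np.log2(vals), index=raw.index, columns=raw.columns)
    return out.sub(out.median(axis=1), axis=0)


@dataclass
class OverlapResult:
    shared: pd.Index        # same protein, same direction
    discordant: pd.Index    # same protein, opposite direction
    unique_a: pd.Index
    unique_b: pd.Index

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "shared_same_direction": len(self.shared),
            "discordant_direction": len(self.discordant),
            "unique_a": len(self.unique_a),
            "unique_b": len(self.unique_b),
        }


def overlap_concordant(a: pd.DataFrame, b: pd.DataFrame) -> OverlapResult:
    """Partition the union of two alteration sets.

    Inputs are protein-indexed frames with a nonzero ``direction`` column.
    Shared requires the same protein AND the same sign; shared proteins
    with opposite signs form their own discordant class (the headline
    "commonly altered" count is |shared same-direction|).
    """
    for name, d in (("a", a), ("b", b)):
        if (np.sign(d["direction"]) == 0).any():
            raise ValueError(f"alteration set {name} has zero directions")
        if d.index.duplicated().any():
            raise ValueError(f"alteration set {name} has duplicate proteins")
    common = a.index.intersection(b.index)
    same = common[np.sign(a.loc[common, "direction"]).to_numpy()
                  == np.sign(b.loc[common, "direction"]).to_numpy()]
    disc = common.difference(same)
    return OverlapResult(
        shared=same.sort_values(),
        discordant=disc.sort_values(),
        unique_a=a.index.difference(b.index).sort_values(),
        unique_b=b.index.difference(a.index).sort_values(),
    )


def logfc_correlation(a: pd.DataFrame, b: pd.DataFrame,
                      proteins: Optional[pd.Index] = None,
                      column: str = "logfc_overall") -> Tuple[float, float]:
    """Spearman correlation of logFCs over shared proteins."""
    if proteins is None:
        proteins = a.index.intersection(b.index)
    if len(proteins) < 3:
        raise ValueError("need >= 3 shared proteins")
    res = stats.spearmanr(a.loc[proteins, column], b.loc[proteins, column])
    return float(res.statistic), float(res.pvalue)


def cross_platform_correlation(
    x: pd.DataFrame,
    y: pd.DataFrame,
    feature_map: pd.DataFrame,
    per: str = "sample",
) -> pd.DataFrame:
    """Spearman correlations between two feature x sample platforms.

    ``feature_map`` has columns ``target`` (feature id in ``y``, e.g. an
    antibody) and ``accession`` (feature id in ``x``); many-to-one maps
    expand to one row per (target, accession) pair.

    per="sample": for each (x sample, y sample) pair, Spearman over the
    mapped feature pairs — returns a long table (sample_x, sample_y, rho,
    p, n_features). per="feature": for each mapped pair, Spearman across
    shared samples — returns (target, accession, rho, p, n_samples).
    """
    fmap = feature_map[["target", "accession"]].drop_duplicates()
    fmap = fmap[fmap["target"].isin(y.index) & fmap["accession"].isin(x.index)]
    if len(fmap) == 0:
        raise ValueError("feature map has no usable (target, accession) pairs")

    if per == "sample":
        if len(fmap) < 3:
            raise ValueError("need >= 3 mapped features for per-sample mode")
        xv = x.loc[fmap["accession"]]
        yv = y.loc[fmap["target"]]
        rows = []
        for sx in x.columns:
            a = xv[sx].to_numpy(dtype=float)
            for sy in y.columns:
                b = yv[sy].to_numpy(dtype=float)
                res = stats.spearmanr(a, b)
                rows.append({"sample_x": sx, "sample_y": sy,
                             "rho": float(res.statistic),
                             "p": float(res.pvalue),
                             "n_features": len(fmap)})
        return pd.DataFrame(rows)
    elif per == "feature":
        shared = [s for s in x.columns if s in y.columns]
        if len(shared) < 3:
            raise ValueError("need >= 3 shared samples for per-feature mode")
        rows = []
        for r in fmap.itertuples():
            a = x.loc[r.accession, shared].to_numpy(dtype=float)
            b = y.loc[r.target, shared].to_numpy(dtype=float)
            res = stats.spearmanr(a, b)
            rows.append({"target": r.target, "accession": r.accession,
                         "rho": float(res.statistic), "p": float(res.pvalue),
                         "n_samples": len(shared)})
        return pd.DataFrame(rows)
    raise ValueError("per must be 'sample' or 'feature'")


def purity_association(
    matrix: pd.DataFrame,
    alterations: pd.DataFrame,
    purity: pd.Series,
) -> Tuple[pd.DataFrame, float, float]:
    """Correlate alteration abundances with per-sample tumor purity.

    Returns (per-protein Spearman table, aggregate rho, aggregate p).
    The aggregate correlates each sample's mean abundance over ET-up
    (direction +1) alteration proteins with its purity.
    """
    samples = [s for s in purity.index if s in matrix.columns]
    if len(samples) < 3:
        raise ValueError("need >= 3 samples with purity values")
    pvec = purity.loc[samples].to_numpy(dtype=float)
    if np.all(pvec == pvec[0]):
        raise ValueError("purity is constant across samples")
    prots = [p for p in alterations.index if p in matrix.index]
    rows = []
    for prot in prots:
        vals = matrix.loc[prot, samples].to_numpy(dtype=float)
        res = stats.spearmanr(vals, pvec)
        rows.append({"protein": prot,
                     "direction": int(alterations.loc[prot, "direction"]),
                     "rho": float(res.statistic), "p": float(res.pvalue)})
    per_protein = pd.DataFrame(rows).set_index("protein")
    up = [p for p in prots if alterations.loc[p, "direction"] > 0]
    if not up:
        raise ValueError("no tumor-up (direction +1) proteins in the set")
    sig = matrix.loc[up, samples].mean(axis=0).to_numpy()
    res = stats.spearmanr(sig, pvec)
    return per_protein, float(res.statistic), float(res.pvalue)
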