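"""PSM-level filtering, reporter-ratio roll-up, normalization and imputation.

Turns per-plex PSM tables into a merged proteins x samples log2
ratio-to-reference matrix:

1. ``filter_psms``    — q-value < 0.01, isolation interference < 50%,
                        reference-channel signal present, >= 1 other channel.
2. ``psm_ratios``     — per PSM, log2(channel / reference channel).
3. ``rollup_proteins``— per-plex median over a protein's PSM ratios,
                        requiring >= 2 PSMs per protein per plex.
4. ``normalize_medians`` — per-sample median centering.
5. ``merge_plexes``   — union over plexes, missing where unquantified.
6. ``impute_knn``     — drop proteins seen in < 50% of samples, k-NN impute
                        the rest (plain Euclidean over mutually observed
                        samples, unweighted mean of the k nearest proteins).

Missing values are NaN throughout; imputation provenance is returned as a
boolean mask alongside the matrix.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "filter_psms",
    "psm_ratios",
    "rollup_proteins",
    "normalize_medians",
    "merge_plexes",
    "impute_knn",
    "quantify_cohort",
    "ImputedMatrix",
]


def _intensity_columns(psms: pd.DataFrame) -> Dict[str, str]:
    """Map channel label -> intensity column name."""
    return {c[len("intensity_"):]: c for c in psms.columns
            if c.startswith("intensity_")}


def filter_psms(
    psms: pd.DataFrame,
    q_max: float = 0.01,
    interference_max_pct: float = 50.0,
    reference_channel: str = "126",
    return_counts: bool = False,
):
    """Apply the PSM retention rules; thresholds are strict inequalities.

    Retains rows with q_value < ``q_max``, isolation interference <
    ``interference_max_pct`` (so a value exactly at the threshold is
    excluded), a present positive reference-channel intensity, and at least
    one other channel with positive signal. Exclusion counts per rule are
    logged (each row is attributed to the first rule it fails, in the order
    above).
    """
    chan_cols = _intensity_columns(psms)
    if reference_channel not in chan_cols:
        raise ValueError(f"unknown reference channel label {reference_channel!r}")
    ref = psms[chan_cols[reference_channel]]
    others = [col for ch, col in chan_cols.items() if ch != reference_channel]

    ok_q = psms["q_value"] < q_max
    ok_int = psms["isolation_interference_pct"] < interference_max_pct
    ok_ref = ref.notna() & (ref > 0)
    if others:
        other_vals = psms[others]
        ok_signal = (other_vals.notna() & (other_vals > 0)).any(axis=1)
    else:
        ok_signal = pd.Series(False, index=psms.index)

    keep = ok_q & ok_int & ok_ref & ok_signal
    counts = {
        "input": int(len(psms)),
        "fail_q_value": int((~ok_q).sum()),
        "fail_interference": int((ok_q & ~ok_int).sum()),
        "fail_reference_signal": int((ok_q & ok_int & ~ok_ref).sum()),
        "fail_no_other_signal": int((ok_q & ok_int & ok_ref & ~ok_signal).sum()),
        "retained": int(keep.sum()),
    }
    logger.info("filter_psms: %s", counts)
    if counts["retained"] == 0:
        warnings.warn("filter_psms retained no PSMs", stacklevel=2)
    out = psms.loc[keep].copy()
    if return_counts:
        return out, counts
    return out


def psm_ratios(psms: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-PSM log2 ratios of each sample channel to the reference channel.

    ``design`` rows map (channel -> sample_id) with an ``is_reference``
    flag. The reference channel is dropped from the output; channels
    without signal become NaN. Returns a frame with ``protein_accession``
    plus one column per sample.
    """
    chan_cols = _intensity_columns(psms)
    ref_rows = design[design["is_reference"].astype(bool)]
    if len(ref_rows) != 1:
        raise ValueError("design must declare exactly one reference channel")
    ref_channel = str(ref_rows["channel"].iloc[0])
    if ref_channel not in chan_cols:
        raise ValueError(f"unknown reference channel label {ref_channel!r}")

    ref = psms[chan_cols[ref_channel]].to_numpy(dtype=float)
    if np.any(~(ref > 0)):
        raise ValueError(
            "PSMs with missing/zero reference intensity encountered; "
            "run filter_psms first")

    out = pd.DataFrame({"protein_accession": psms["protein_accession"].to_numpy()})
    for row in design[~design["is_reference"].astype(bool)].itertuples():
        ch = str(row.channel)
        if ch not in chan_cols:
            raise ValueError(f"unknown channel label {ch!r} in design")
        vals = psms[chan_cols[ch]].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log2(vals / ref)
        ratio[~(vals > 0)] = np.nan
        out[row.sample_id] = ratio
    return out


def rollup_proteins(ratios: pd.DataFrame, min_psms: int = 2) -> pd.DataFrame:
    """Per-plex protein matrix: median over PSM-level log2 ratios.

    Proteins contributing fewer than ``min_psms`` PSMs (after filtering,
    counted within this plex) are absent from the output. Cells where a
    protein has no PSM with signal in a sample are NaN.
    """
    grouped = ratios.groupby("protein_accession", sort=True)
    counts = grouped.size()
    keep = counts[counts >= min_psms].index
    mat = grouped.median(numeric_only=True)
    mat = mat.loc[keep]
    mat.index.name = "protein"
    return mat


def normalize_medians(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample column's observed-value median."""
    all_missing = matrix.isna().all(axis=0)
    if all_missing.any():
        bad = list(matrix.columns[all_missing])
        raise ValueError(f"samples with no observed values: {bad}")
    return matrix - matrix.median(axis=0, skipna=True)


def merge_plexes(matrices: Mapping[str, pd.DataFrame] | Iterable[pd.DataFrame],
                 annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Union of proteins over plexes; NaN where a plex lacks a protein."""
    if isinstance(matrices, Mapping):
        mats = [matrices[k] for k in sorted(matrices)]
    else:
        mats = list(matrices)
    seen: set = set()
    for m in mats:
        dup = seen & set(m.columns)
        if dup:
            raise ValueError(f"duplicate sample ids across plexes: {sorted(dup)}")
        seen |= set(m.columns)
    merged = pd.concat(mats, axis=1, join="outer")
    merged = merged.sort_index(axis=0)
    if annotation is not None:
        order = [s for s in annotation["sample_id"] if s in merged.columns]
        merged = merged[order]
    merged.index.name = "protein"
    return merged


class ImputedMatrix(NamedTuple):
    matrix: pd.DataFrame
    imputed_mask: pd.DataFrame  # True where a cell was filled by k-NN


def impute_knn(matrix: pd.DataFrame, k: int = 10,
               min_quant_frac: float = 0.5) -> ImputedMatrix:
    """k-nearest-neighbor imputation of a merged log2 matrix.

    Proteins observed in fewer than ``min_quant_frac`` of samples
    (inclusive: exactly 50% observed is kept at the default) are dropped.
    Each remaining missing cell is filled with the unweighted mean, in that
    sample, of the k nearest proteins by plain Euclidean distance computed
    over mutually observed samples; distance ties break by protein id
    order. Fully observed proteins are untouched.
    """
    obs_frac = matrix.notna().mean(axis=1)
    kept = matrix.loc[obs_frac >= min_quant_frac].copy()
    X = kept.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n = X.shape[0]
    id_rank = np.argsort(np.argsort(kept.index.to_numpy()))
    out = X.copy()
    mask = np.zeros_like(X, dtype=bool)

    targets = np.where(~obs.all(axis=1))[0]
    Xz = np.where(obs, X, 0.0)
    for t in targets:
        both = obs & obs[t]  # (n, n_samples) overlap masks
        diff = Xz - Xz[t]
        d2 = np.where(both, diff * diff, 0.0).sum(axis=1)
        overlap = both.sum(axis=1)
        dist = np.sqrt(d2)
        valid = overlap > 0
        valid[t] = False
        for s in np.where(~obs[t])[0]:
            cand = np.where(valid & obs[:, s])[0]
            if cand.size == 0:
                warnings.warn(
                    f"no imputation neighbors for {kept.index[t]} in "
                    f"{kept.columns[s]}; cell left missing", stacklevel=2)
                continue
            if cand.size < k:
                warnings.warn(
                    f"only {cand.size} neighbors (< k={k}) for "
                    f"{kept.index[t]}; using all", stacklevel=2)
            order = cand[np.lexsort((id_rank[cand], dist[cand]))]
            chosen = order[:min(k, order.size)]
            out[t, s] = X[chosen, s].mean()
            mask[t, s] = True

    return ImputedMatrix(
        matrix=pd.DataFrame(out, index=kept.index, columns=kept.columns),
        imputed_mask=pd.DataFrame(mask, index=kept.index, columns=kept.columns),
    )


def quantify_cohort(
    psm_tables: Mapping[str, pd.DataFrame],
    designs: Mapping[str, pd.DataFrame],
    annotation: pd.DataFrame | None = None,
    q_max: float = 0.01,
    interference_max_pct: float = 50.0,
    min_psms: int = 2,
    knn_k: int = 10,
    min_quant_frac: float = 0.5,
    impute: bool = True,
) -> ImputedMatrix:
    """Full quantitation chain over a multi-plex cohort."""
    per_plex = {}
    for plex in sorted(psm_tables):
        design = designs[plex]
        ref_channel = str(
            design.loc[design["is_reference"].astype(bool), "channel"].iloc[0])
        filtered = filter_psms(psm_tables[plex], q_max=q_max,
                               interference_max_pct=interference_max_pct,
                               reference_channel=ref_channel)
        ratios = psm_ratios(filtered, design)
        mat = rollup_proteins(ratios, min_psms=min_psms)
        per_plex[plex] = normalize_medians(mat)
    merged = merge_plexes(per_plex, annotation=annotation)
    if not impute:
        return ImputedMatrix(merged, merged.isna())
    return impute_knn(merged, k=knn_k, min_quant_frac=min_quant_frac)
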