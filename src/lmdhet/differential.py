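"""ET-vs-ES differential abundance with empirical-Bayes moderated t-statistics.

The model is the standard limma-style workflow written out explicitly:
per protein, an ordinary linear model of log2 abundance on the ET/ES group
indicator with patient as an additive blocking covariate; the residual
variances of all proteins are then squeezed toward a common prior fitted
by moment matching of log variances (scaled inverse-chi-square prior,
digamma/trigamma inversion), and the moderated t uses the posterior
variance with d0 + d_residual degrees of freedom. BH adjustment over all
proteins.

Exposed both as free functions mirroring the pipeline operations and as a
small Model/Results pair (`EtEsDifferential(...).fit()`), since the fitted
model is the statistical core of this stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, mann_whitney_u, squeeze_variances

__all__ = [
    "EtEsDifferential",
    "DifferentialResults",
    "moderated_ttest",
    "per_patient_logfc",
    "concordance_filter",
    "wilcoxon_marker",
]


def _design_matrix(annot: pd.DataFrame, block_patient: bool):
    """Intercept + (patient dummies) + ET indicator; returns (X, contrast idx)."""
    n = len(annot)
    cols = [np.ones(n)]
    if block_patient:
        patients = sorted(annot["patient"].unique())
        for p in patients[1:]:
            cols.append((annot["patient"] == p).to_numpy(dtype=float))
    cols.append((annot["collection_type"] == "ET").to_numpy(dtype=float))
    X = np.column_stack(cols)
    return X, X.shape[1] - 1


class EtEsDifferential:
    """Moderated-t model for ET vs ES differential protein abundance.

    Parameters
    ----------
    matrix : pd.DataFrame
        Complete (imputed) proteins x samples log2 abundance matrix.
    annot : pd.DataFrame
        Sample annotation with sample_id, patient, collection_type.
    block_patient : bool
        Include patient as an additive blocking covariate (default; matches
        the paired multi-plex design). ``False`` pools all samples.
    """

    def __init__(self, matrix: pd.DataFrame, annot: pd.DataFrame,
                 block_patient: bool = True):
        annot = annot[annot["collection_type"].isin(["ET", "ES"])]
        annot = annot[annot["sample_id"].isin(matrix.columns)]
        for grp in ("ET", "ES"):
            if (annot["collection_type"] == grp).sum() == 0:
                raise ValueError(f"no {grp} samples in the matrix")
        self.annot = annot.reset_index(drop=True)
        self.matrix = matrix[list(self.annot["sample_id"])]
        self.block_patient = block_patient

    def fit(self, alpha: float = 0.05, d0: Optional[float] = None,
            s0_2: Optional[float] = None) -> "DifferentialResults":
        X, cidx = _design_matrix(self.annot, self.block_patient)
        Y = self.matrix.to_numpy(dtype=float).T  # samples x proteins
        if np.any(~np.isfinite(Y)):
            raise ValueError("matrix must be complete (impute first)")
        n, p = X.shape
        rank = np.linalg.matrix_rank(X)
        df_resid = n - rank
        if df_resid <= 0:
            raise ValueError("saturated design: no residual degrees of freedom")
        XtX_inv = np.linalg.pinv(X.T @ X)
        beta = XtX_inv @ X.T @ Y
        resid = Y - X @ beta
        s2 = (resid ** 2).sum(axis=0) / df_resid
        if np.any(~np.isfinite(s2)):
            raise ValueError("non-finite residual variances")
        logfc = beta[cidx]
        se_factor = float(np.sqrt(XtX_inv[cidx, cidx]))

        sq = squeeze_variances(s2, df_resid, d0=d0, s0_2=s0_2)
        se = np.sqrt(sq.s2_post) * se_factor
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = logfc / se
        df_total = sq.d0 + df_resid
        if np.isinf(df_total):
            pvals = 2.0 * sps.norm.sf(np.abs(t_mod))
        else:
            pvals = 2.0 * sps.t.sf(np.abs(t_mod), df_total)
        adj = bh_adjust(pvals)

        table = pd.DataFrame({
            "logfc_overall": logfc,
            "s2": s2,
            "s2_post": sq.s2_post,
            "t_mod": t_mod,
            "p": pvals,
            "adj_p": adj,
            "direction": np.sign(logfc).astype(int),
        }, index=self.matrix.index)
        ppl = per_patient_logfc(self.matrix, self.annot)
        return DifferentialResults(
            table=table, per_patient=ppl, d0=sq.d0, s0_2=sq.s0_2,
            df_resid=float(df_resid), se_factor=se_factor, alpha=alpha)


@dataclass
class DifferentialResults:
    """Per-protein moderated-t results plus per-patient logFCs."""

    table: pd.DataFrame
    per_patient: pd.DataFrame  # patients x proteins logFC
    d0: float
    s0_2: float
    df_resid: float
    se_factor: float
    alpha: float = 0.05

    def concordant_alterations(self, alpha: Optional[float] = None) -> pd.DataFrame:
        return concordance_filter(self.table, self.per_patient,
                                  alpha=self.alpha if alpha is None else alpha)

    def summary(self, n_top: int = 10) -> str:
        t = self.table
        n_sig = int((t["adj_p"] < self.alpha).sum())
        conc = self.concordant_alterations()
        lines = [
            "ET vs ES moderated-t differential abundance",
            "=" * 47,
            f"proteins tested:            {len(t)}",
            f"residual df per protein:    {self.df_resid:g}",
            f"prior df (d0):              {self.d0:.4g}",
            f"prior variance (s0^2):      {self.s0_2:.4g}",
            f"adj. p < {self.alpha:g}:               {n_sig}",
            f"sign-concordant across all patients: {len(conc)}",
            "",
            f"top {n_top} proteins by adj. p:",
            t.sort_values(["adj_p", "p"]).head(n_top)[
                ["logfc_overall", "t_mod", "p", "adj_p"]].to_string(),
        ]
        return "\n".join(lines)


def moderated_ttest(matrix: pd.DataFrame, annot: pd.DataFrame,
                    block_patient: bool = True, alpha: float = 0.05,
                    d0: Optional[float] = None,
                    s0_2: Optional[float] = None) -> DifferentialResults:
    """Functional entry point: fit the ET-vs-ES moderated-t model."""
    return EtEsDifferential(matrix, annot, block_patient=block_patient).fit(
        alpha=alpha, d0=d0, s0_2=s0_2)


def per_patient_logfc(matrix: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Per (patient, protein) logFC: median over ET levels - median over ES.

    Patients lacking either group are excluded with a warning.
    """
    rows = {}
    for patient, grp in annot.groupby("patient"):
        et = [s for s in grp.loc[grp["collection_type"] == "ET", "sample_id"]
              if s in matrix.columns]
        es = [s for s in grp.loc[grp["collection_type"] == "ES", "sample_id"]
              if s in matrix.columns]
        if not et or not es:
            warnings.warn(f"patient {patient} lacks an ET or ES group; "
                          "excluded from per-patient logFCs", stacklevel=2)
            continue
        rows[patient] = matrix[et].median(axis=1) - matrix[es].median(axis=1)
    out = pd.DataFrame(rows).T
    out.index.name = "patient"
    return out


def concordance_filter(table: pd.DataFrame, per_patient: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Keep proteins significant AND sign-concordant in every patient.

    A protein passes when its BH-adjusted p is below ``alpha`` and its
    per-patient logFCs all share one strict (nonzero) sign. Returns the
    alteration set (protein, direction, logfc_overall, adj_p).
    """
    signs = np.sign(per_patient.to_numpy())
    all_pos = (signs > 0).all(axis=0)
    all_neg = (signs < 0).all(axis=0)
    concordant = pd.Series(all_pos | all_neg, index=per_patient.columns)
    keep = (table["adj_p"] < alpha) & concordant.reindex(
        table.index, fill_value=False)
    out = table.loc[keep, ["direction", "logfc_overall", "adj_p"]].copy()
    # direction from the unanimous per-patient sign (matches logfc_overall
    # except in pathological near-zero fits)
    pp_sign = pd.Series(np.where(all_pos, 1, -1), index=per_patient.columns)
    out["direction"] = pp_sign.reindex(out.index).astype(int)
    return out.sort_index()


def wilcoxon_marker(matrix: pd.DataFrame, annot: pd.DataFrame,
                    protein: str):
    """Two-sided rank-sum test of one protein, ET vs ES pooled across patients.

    Returns ``(MWUResult, direction)`` with direction +1 when ET median is
    higher. Constant pooled values give p = 1 with a warning.
    """
    sub = annot[annot["collection_type"].isin(["ET", "ES"])]
    et = [s for s in sub.loc[sub["collection_type"] == "ET", "sample_id"]
          if s in matrix.columns]
    es = [s for s in sub.loc[sub["collection_type"] == "ES", "sample_id"]
          if s in matrix.columns]
    if len(et) < 2 or len(es) < 2:
        raise ValueError("both groups need >= 2 samples")
    x = matrix.loc[protein, et].to_numpy(dtype=float)
    y = matrix.loc[protein, es].to_numpy(dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn(f"{protein}: constant values; p = 1", stacklevel=2)
        from .stats import MWUResult
        return MWUResult(len(x) * len(y) / 2.0, 1.0, "degenerate"), 0
    res = mann_whitney_u(x, y)
    direction = int(np.sign(np.median(x) - np.median(y)))
    return res, direction
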