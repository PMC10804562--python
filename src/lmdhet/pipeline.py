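"""End-to-end driver: simulate -> quantify -> heterogeneity -> differential
-> admixture -> compare, with a hashed output manifest.

Every stage writes TSV/JSON artifacts under its own subdirectory of the
output directory; the manifest records a sha256 per file plus the echoed
configuration and seed, so a repeated run with the same seed is
hash-identical. Stage errors abort the run with the failing stage named.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as lio
from .admixture import purity_recovery, ssgsea_score, truth_signatures
from .compare import logfc_correlation, overlap_concordant, purity_association
from .config import PipelineConfig
from .differential import moderated_ttest
from .heterogeneity import (eligible_patients, hier_cluster, mad_select,
                            pairwise_spearman, patient_dendrogram,
                            secreted_variance_test)
from .quantify import quantify_cohort
from .simulate import GroundTruth, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineRun", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineRun:
    outdir: Path
    manifest_path: Path
    files: List[Path] = field(default_factory=list)
    results: Dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineRun:
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: List[Path] = []
    results: Dict = {}

    sim_cfg = config.sim.replace(seed=config.seed)
    truth: Optional[GroundTruth] = None
    matrix = None
    annot = None

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            raise StageError(name, exc) from exc

    if config.run_simulate:
        def do_simulate():
            nonlocal truth, annot
            truth, psms, designs, annot = simulate_cohort(sim_cfg)
            files.extend(write_cohort(outdir / "simulate", truth, psms, designs))
            results["simulate"] = {
                "n_patients": sim_cfg.n_patients,
                "n_proteins": sim_cfg.n_proteins,
                "n_samples": int(len(annot)),
                "n_de_planted": int((truth.true_logfc != 0).sum()),
            }
        _stage("simulate", do_simulate)

    if config.run_quantify:
        def do_quantify():
            nonlocal matrix, annot
            simdir = outdir / "simulate"
            psms = {}
            designs = {}
            for p in sorted(simdir.glob("psm_*.tsv")):
                plex = p.stem[len("psm_"):]
                psms[plex] = lio.read_psm_table(p)
                designs[plex] = lio.read_plex_design(
                    simdir / f"design_{plex}.tsv")
            annot2 = lio.read_annotation(simdir / "annotation.tsv")
            imputed = quantify_cohort(
                psms, designs, annotation=annot2,
                q_max=config.q_max,
                interference_max_pct=config.interference_max_pct,
                min_psms=config.min_psms, knn_k=config.knn_k,
                min_quant_frac=config.min_quant_frac)
            matrix = imputed.matrix
            annot = annot2
            qdir = outdir / "quantify"
            files.append(lio.write_matrix(matrix, qdir / "matrix.tsv"))
            files.append(lio.write_matrix(
                imputed.imputed_mask.astype(int), qdir / "imputed_flags.tsv"))
            results["quantify"] = {
                "n_proteins": int(matrix.shape[0]),
                "n_samples": int(matrix.shape[1]),
                "n_imputed_cells": int(imputed.imputed_mask.to_numpy().sum()),
            }
        _stage("quantify", do_quantify)
    elif config.matrix_path:
        matrix = lio.read_matrix(config.matrix_path)
        if config.annot_path:
            annot = lio.read_annotation(config.annot_path)

    if config.run_heterogeneity:
        def do_het():
            hdir = outdir / "heterogeneity"
            hdir.mkdir(parents=True, exist_ok=True)
            selected = mad_select(matrix, config.mad_min)
            cluster_set = selected if len(selected) >= 2 else mad_select(
                matrix, config.cluster_mad_min)
            if len(cluster_set) < 2:  # tiny cohorts: fall back to all proteins
                cluster_set = list(matrix.index)
            sample_tree, protein_tree = hier_cluster(
                matrix, cluster_set, cluster_proteins=True)
            p = hdir / "samples.nwk"
            p.write_text(sample_tree.to_newick() + "\n")
            files.append(p)
            if protein_tree is not None:
                p = hdir / "proteins.nwk"
                p.write_text(protein_tree.to_newick() + "\n")
                files.append(p)

            rows = []
            for (patient, ctype), _ in annot.groupby(
                    ["patient", "collection_type"]):
                res = pairwise_spearman(matrix, annot, patient, ctype)
                if res.summary:
                    rows.append({"patient": patient, "collection_type": ctype,
                                 **res.summary})
            summary = pd.DataFrame(rows)
            files.append(lio.write_tsv(
                summary, hdir / "pairwise_spearman.tsv", index=False))

            drows = []
            for patient in sorted(annot["patient"].unique()):
                res = patient_dendrogram(matrix, annot, patient,
                                         mad_min=config.mad_min)
                if res is None:
                    res = patient_dendrogram(matrix, annot, patient,
                                             mad_min=config.cluster_mad_min)
                if res is None:
                    continue
                p = hdir / f"dendrogram_{patient}.nwk"
                p.write_text(res.dendrogram.to_newick() + "\n")
                files.append(p)
                drows.append({
                    "patient": patient, "n_proteins": res.n_proteins,
                    "U": res.test.statistic, "p": res.test.pvalue,
                    "more_correlated": res.more_correlated,
                })
            files.append(lio.write_tsv(pd.DataFrame(drows),
                                       hdir / "patient_dendrograms.tsv",
                                       index=False))

            bt = summary[summary["collection_type"] == "BT"] if len(summary) else summary
            results["heterogeneity"] = {
                "n_mad_selected": len(selected),
                "n_cluster_features": len(cluster_set),
                "bt_median_pairwise_spearman": (
                    float(bt["median"].median()) if len(bt) else float("nan")),
            }

            if truth is not None:
                srows = []
                for patient in eligible_patients(annot):
                    for ctype in ("ET", "ES"):
                        r = secreted_variance_test(
                            matrix, annot, truth.secreted_flag, patient, ctype)
                        srows.append({
                            "patient": patient, "collection_type": ctype,
                            "n_secreted": r.n_secreted, "n_other": r.n_other,
                            "median_mad_secreted": r.median_mad_secreted,
                            "median_mad_other": r.median_mad_other,
                            "U": r.test.statistic, "p": r.test.pvalue,
                        })
                if srows:
                    files.append(lio.write_tsv(
                        pd.DataFrame(srows), hdir / "secreted_variance.tsv",
                        index=False))
                    results["heterogeneity"]["secreted_min_p"] = float(
                        min(r["p"] for r in srows))
        _stage("heterogeneity", do_het)

    diff_res = None
    if config.run_differential:
        def do_diff():
            nonlocal diff_res
            ddir = outdir / "differential"
            diff_res = moderated_ttest(matrix, annot, alpha=config.alpha)
            files.append(lio.write_tsv(diff_res.table, ddir / "differential.tsv"))
            files.append(lio.write_tsv(diff_res.per_patient,
                                       ddir / "per_patient_logfc.tsv"))
            alts = diff_res.concordant_alterations()
            files.append(lio.write_tsv(alts, ddir / "alterations.tsv"))
            results["differential"] = {
                "d0": diff_res.d0, "s0_2": diff_res.s0_2,
                "n_significant": int(
                    (diff_res.table["adj_p"] < config.alpha).sum()),
                "n_concordant": int(len(alts)),
            }
            if truth is not None:
                planted = truth.true_logfc[truth.true_logfc != 0]
                planted = planted[planted.index.isin(matrix.index)]
                found = alts.index
                tp = len(found.intersection(planted.index))
                results["differential"]["sensitivity"] = (
                    tp / len(planted) if len(planted) else float("nan"))
                results["differential"]["fdp"] = (
                    (len(found) - tp) / len(found) if len(found) else 0.0)
        _stage("differential", do_diff)

    if config.run_admixture:
        def do_admix():
            adir = outdir / "admixture"
            if truth is None:
                raise ValueError("admixture stage needs simulated ground truth "
                                 "signatures (or a user GMT via the CLI)")
            sigs = truth_signatures(truth, n_top=config.signature_size)
            files.append(lio.write_gmt(sigs, adir / "signatures.gmt"))
            st = ssgsea_score(matrix, sigs, alpha=config.ssgsea_alpha)
            files.append(lio.write_tsv(st.scores, adir / "ssgsea_scores.tsv"))
            rho, pval, tab = purity_recovery(st, truth, annot, "Stroma")
            files.append(lio.write_tsv(tab, adir / "stroma_purity.tsv",
                                       index=False))
            results["admixture"] = {
                "stroma_purity_spearman": rho,
                "stroma_purity_p": pval,
            }
        _stage("admixture", do_admix)

    if config.run_compare:
        def do_compare():
            cdir = outdir / "compare"
            cdir.mkdir(parents=True, exist_ok=True)
            # companion cohort sharing planted truth with independent noise
            cfg_b = sim_cfg.replace(seed=sim_cfg.seed + 1000003,
                                    truth_seed=sim_cfg.seed)
            truth_b, psms_b, designs_b, annot_b = simulate_cohort(cfg_b)
            imput_b = quantify_cohort(
                psms_b, designs_b, annotation=annot_b,
                q_max=config.q_max,
                interference_max_pct=config.interference_max_pct,
                min_psms=config.min_psms, knn_k=config.knn_k,
                min_quant_frac=config.min_quant_frac)
            diff_b = moderated_ttest(imput_b.matrix, annot_b,
                                     alpha=config.alpha)
            alts_a = diff_res.concordant_alterations()
            alts_b = diff_b.concordant_alterations()
            ov = overlap_concordant(alts_a, alts_b)
            rho, pval = (float("nan"), float("nan"))
            if len(ov.shared) >= 3:
                rho, pval = logfc_correlation(alts_a, alts_b, ov.shared)
            with open(cdir / "overlap.json", "w") as fh:
                json.dump({**ov.counts, "logfc_spearman": rho,
                           "logfc_spearman_p": pval},
                          fh, indent=2, sort_keys=True)
                fh.write("\n")
            files.append(cdir / "overlap.json")

            bt = annot[annot["collection_type"] == "BT"]
            purity = pd.Series({
                r.sample_id: float(truth.bt_tumor_fraction.loc[r.patient, r.level])
                for r in bt.itertuples() if r.sample_id in matrix.columns})
            agg_rho, agg_p = float("nan"), float("nan")
            has_up = len(alts_a) > 0 and (alts_a["direction"] > 0).any()
            if has_up and len(purity) >= 3:
                per_prot, agg_rho, agg_p = purity_association(
                    matrix, alts_a, purity)
                files.append(lio.write_tsv(per_prot,
                                           cdir / "purity_association.tsv"))
            results["compare"] = {
                **ov.counts,
                "logfc_spearman": rho,
                "purity_aggregate_spearman": agg_rho,
                "purity_aggregate_p": agg_p,
            }
        _stage("compare", do_compare)

    def do_finish():
        with open(outdir / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
        files.append(outdir / "results.json")
        manifest = lio.write_manifest(outdir, files, config, config.seed)
        return manifest

    manifest_path = _stage("manifest", do_finish)
    return PipelineRun(outdir=outdir, manifest_path=manifest_path,
                       files=files, results=results)
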