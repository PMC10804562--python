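"""Synthetic multi-plex TMT cohort generator with planted ground truth.

The generator produces, per patient, latent log2 abundance profiles for
enriched tumor (ET), enriched stroma (ES) and bulk tissue (BT) across
spatial sampling levels, then emits PSM-level reporter-ion tables (one
patient-specific TMT multiplex per patient) with nuisance q-values and
isolation-interference columns, so every downstream stage — PSM filtering,
ratio computation, protein roll-up, normalization, merging, imputation,
heterogeneity statistics, differential abundance and admixture scoring —
can be tested against known truth without any external download.

Key generative choices
----------------------
* BT is a physical admixture: at level l the BT latent *linear* intensity is
  ``f * 2**ET(l) + (1-f) * 2**ES(l)`` with f the tumor fraction of that
  (patient, level). Reporter intensities are additive in ion counts, so
  mixing happens on the linear scale, never in log space.
* Per-level variation is a random walk across levels (spatial
  autocorrelation of contiguous tissue strata); an i.i.d. option exists.
* Secreted/extracellular-flagged proteins get their drift SD multiplied by
  ``secreted_var_inflation``.
* The pooled reference channel (label "126") is the mean linear intensity
  over the patient's actual ET/ES/BT samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .config import SimConfig, TMT_CHANNELS

__all__ = [
    "GroundTruth",
    "simulate_latent_profiles",
    "emit_psm_tables",
    "simulate_cohort",
    "write_cohort",
]

_COLLECTION_TYPES = ("ET", "ES", "BT")


@dataclass
class GroundTruth:
    """Planted truth of one simulated cohort.

    Attributes
    ----------
    true_logfc : pd.Series
        Per-protein log2(ET/ES); exactly 0 for non-DE proteins.
    de_direction : pd.Series
        Sign (+1/-1) for DE proteins, 0 otherwise.
    secreted_flag : pd.Series of bool
        Signal-peptide / extracellular class flag per protein.
    bt_tumor_fraction : pd.DataFrame
        patients x levels tumor fraction in [0, 1].
    profiles : pd.DataFrame
        Latent log2 abundance, proteins x MultiIndex(patient, collection_type,
        level). Includes all levels for every type (the sampling design
        decides which become samples).
    reference_log2 : pd.DataFrame
        proteins x patients log2 intensity of the pooled reference channel.
    annotation : pd.DataFrame
        One row per emitted sample: sample_id, patient, collection_type,
        level, tumor_cellularity_pct.
    """

    true_logfc: pd.Series
    de_direction: pd.Series
    secreted_flag: pd.Series
    bt_tumor_fraction: pd.DataFrame
    profiles: pd.DataFrame
    reference_log2: pd.DataFrame
    annotation: pd.DataFrame
    config: SimConfig

    @property
    def proteins(self) -> pd.Index:
        return self.true_logfc.index

    @property
    def patients(self) -> List[str]:
        return list(self.bt_tumor_fraction.index)

    def latent_ratio_matrix(self) -> pd.DataFrame:
        """Latent log2 ratio-to-reference for every emitted sample.

        This is what a noise-free quantitation should recover (up to the
        per-column median shift applied during normalization).
        """
        cols = {}
        for row in self.annotation.itertuples():
            latent = self.profiles[(row.patient, row.collection_type, row.level)]
            cols[row.sample_id] = latent - self.reference_log2[row.patient]
        return pd.DataFrame(cols)


def _protein_ids(n: int) -> pd.Index:
    width = max(4, len(str(n - 1)))
    return pd.Index([f"P{i:0{width}d}" for i in range(n)], name="protein")


def _patient_ids(n: int) -> List[str]:
    return [f"PT{i + 1:02d}" for i in range(n)]


def simulate_latent_profiles(cfg: SimConfig) -> GroundTruth:
    """Draw planted truth and latent per-level log2 profiles for a cohort."""
    cfg.validate()
    truth_seed = cfg.seed if cfg.truth_seed is None else cfg.truth_seed
    rng_truth = np.random.default_rng([int(truth_seed), 101])
    rng = np.random.default_rng([int(cfg.seed), 202])

    proteins = _protein_ids(cfg.n_proteins)
    patients = _patient_ids(cfg.n_patients)
    levels = np.arange(1, cfg.n_levels + 1)

    # planted ET-vs-ES differences
    n_de = int(round(cfg.frac_de * cfg.n_proteins))
    de_idx = rng_truth.choice(cfg.n_proteins, size=n_de, replace=False)
    sign = rng_truth.choice([-1.0, 1.0], size=n_de)
    if cfg.effect_size_model == "fixed":
        magnitude = np.full(n_de, cfg.effect_size_log2)
    else:
        magnitude = rng_truth.exponential(cfg.effect_size_log2, size=n_de)
    true_logfc = np.zeros(cfg.n_proteins)
    true_logfc[de_idx] = sign * magnitude
    secreted = rng_truth.random(cfg.n_proteins) < cfg.frac_secreted

    baseline = rng_truth.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                                size=cfg.n_proteins)
    drift_sd = np.where(secreted,
                        cfg.level_drift_sd * cfg.secreted_var_inflation,
                        cfg.level_drift_sd)

    bt_frac = pd.DataFrame(
        rng.uniform(cfg.bt_fraction_range[0], cfg.bt_fraction_range[1],
                    size=(cfg.n_patients, cfg.n_levels)),
        index=pd.Index(patients, name="patient"),
        columns=pd.Index(levels, name="level"),
    )

    # latent per-level profiles; ES baseline = b, ET baseline = b + logFC
    blocks: Dict[Tuple[str, str, int], np.ndarray] = {}
    for patient in patients:
        for ctype, base in (("ET", baseline + true_logfc), ("ES", baseline)):
            steps = rng.normal(0.0, 1.0, size=(cfg.n_levels, cfg.n_proteins))
            steps *= drift_sd[None, :]
            if cfg.level_model == "random_walk":
                walk = np.cumsum(steps, axis=0)
            else:
                walk = steps
            for li, level in enumerate(levels):
                blocks[(patient, ctype, int(level))] = base + walk[li]
        for level in levels:
            f = bt_frac.loc[patient, level]
            et_lin = np.exp2(blocks[(patient, "ET", int(level))])
            es_lin = np.exp2(blocks[(patient, "ES", int(level))])
            blocks[(patient, "BT", int(level))] = np.log2(
                f * et_lin + (1.0 - f) * es_lin)

    profiles = pd.DataFrame(
        blocks, index=proteins,
    )
    profiles.columns = pd.MultiIndex.from_tuples(
        profiles.columns, names=["patient", "collection_type", "level"])

    annotation = _sampling_design(cfg, patients, levels, bt_frac, rng)

    # pooled reference per patient: mean linear intensity over emitted samples
    ref = {}
    for patient in patients:
        sub = annotation[annotation["patient"] == patient]
        lin = np.zeros(cfg.n_proteins)
        for row in sub.itertuples():
            lin += np.exp2(
                profiles[(row.patient, row.collection_type, row.level)].to_numpy())
        ref[patient] = np.log2(lin / len(sub))
    reference_log2 = pd.DataFrame(ref, index=proteins)

    return GroundTruth(
        true_logfc=pd.Series(true_logfc, index=proteins, name="true_logfc"),
        de_direction=pd.Series(np.sign(true_logfc).astype(int), index=proteins,
                               name="de_direction"),
        secreted_flag=pd.Series(secreted, index=proteins, name="secreted_flag"),
        bt_tumor_fraction=bt_frac,
        profiles=profiles,
        reference_log2=reference_log2,
        annotation=annotation,
        config=cfg,
    )


def _sampling_design(cfg: SimConfig, patients, levels, bt_frac,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Pick which (patient, type, level) combinations become samples.

    BT is harvested at every level; ET and ES get a random subset of levels
    whose size is drawn from the configured ranges, mirroring real blocks
    where some strata yield too little tissue for every harvest type.
    """
    rows = []
    for patient in patients:
        n_et = int(rng.integers(cfg.et_levels_range[0], cfg.et_levels_range[1] + 1))
        n_es = int(rng.integers(cfg.es_levels_range[0], cfg.es_levels_range[1] + 1))
        et_levels = np.sort(rng.choice(levels, size=n_et, replace=False))
        es_levels = np.sort(rng.choice(levels, size=n_es, replace=False))
        cellularity = {
            "ET": lambda lv: 95.0 + rng.uniform(0.0, 4.0),
            "ES": lambda lv: rng.uniform(0.0, 5.0),
            "BT": lambda lv: 100.0 * bt_frac.loc[patient, lv],
        }
        for ctype, lvls in (("ET", et_levels), ("ES", es_levels), ("BT", levels)):
            for lv in lvls:
                rows.append({
                    "sample_id": f"{patient}_{ctype}_L{int(lv)}",
                    "patient": patient,
                    "collection_type": ctype,
                    "level": int(lv),
                    "tumor_cellularity_pct": round(cellularity[ctype](int(lv)), 2),
                })
    return pd.DataFrame(rows)


def emit_psm_tables(
    truth: GroundTruth, cfg: SimConfig | None = None,
) -> Tuple[Dict[str, pd.DataFrame], Dict[str, pd.DataFrame], pd.DataFrame]:
    """Emit one PSM table and plex design per patient, plus the annotation.

    Returns ``(psm_tables, plex_designs, annotation)`` where both dicts are
    keyed by plex id (= patient id). Each PSM row carries reporter
    intensities ``latent_linear * 2**N(0, noise_sd)`` per channel, a
    q-value and an isolation-interference percentage drawn from the
    configured nuisance mixtures (independent of abundance), and per-plex
    protein dropout with probability ``frac_missing_per_plex``.
    """
    cfg = truth.config if cfg is None else cfg
    proteins = truth.proteins
    n_prot = len(proteins)
    psm_tables: Dict[str, pd.DataFrame] = {}
    designs: Dict[str, pd.DataFrame] = {}

    for pi, patient in enumerate(truth.patients):
        rng = np.random.default_rng([int(cfg.seed), 303, pi])
        sub = truth.annotation[truth.annotation["patient"] == patient]
        sample_ids = list(sub["sample_id"])
        if len(sample_ids) + 1 > len(TMT_CHANNELS):
            raise ValueError(
                f"plex {patient}: {len(sample_ids) + 1} channels needed, "
                f"TMTpro supports at most {len(TMT_CHANNELS)}")
        channels = [TMT_CHANNELS[0]] + list(
            TMT_CHANNELS[1:1 + len(sample_ids)])
        designs[patient] = pd.DataFrame({
            "plex_id": patient,
            "channel": channels,
            "sample_id": [f"{patient}_POOL"] + sample_ids,
            "is_reference": [True] + [False] * len(sample_ids),
        })

        # latent log2 per protein x channel (reference first)
        latent = np.empty((n_prot, len(channels)))
        latent[:, 0] = truth.reference_log2[patient].to_numpy()
        for ci, row in enumerate(sub.itertuples(), start=1):
            latent[:, ci] = truth.profiles[
                (patient, row.collection_type, row.level)].to_numpy()

        if cfg.psm_count_model == "fixed":
            n_psms = np.full(n_prot, int(round(cfg.psms_per_protein)))
        else:
            n_psms = rng.poisson(cfg.psms_per_protein, size=n_prot)
        dropped = rng.random(n_prot) < cfg.frac_missing_per_plex
        n_psms = np.where(dropped, 0, n_psms)

        prot_rows = np.repeat(np.arange(n_prot), n_psms)
        total = len(prot_rows)
        noise = rng.normal(0.0, 1.0, size=(total, len(channels)))
        intensities = np.exp2(latent[prot_rows] + cfg.noise_sd * noise)

        q_fail = rng.random(total) < cfg.frac_q_fail
        q_val = np.where(q_fail,
                         rng.uniform(0.01, cfg.q_fail_max, size=total),
                         rng.uniform(0.0, 0.01, size=total))
        i_fail = rng.random(total) < cfg.frac_interference_fail
        interference = np.where(i_fail,
                                rng.uniform(50.0, 100.0, size=total),
                                rng.uniform(0.0, 50.0, size=total))

        psm_index = np.concatenate(
            [np.arange(k) for k in n_psms if k > 0]) if total else np.array([], int)
        table = pd.DataFrame({
            "plex_id": patient,
            "spectrum_id": [f"{patient}_S{i:06d}" for i in range(total)],
            "peptide": [f"PEP_{proteins[p]}_{j}"
                        for p, j in zip(prot_rows, psm_index)],
            "protein_accession": proteins.to_numpy()[prot_rows],
            "q_value": q_val,
            "isolation_interference_pct": interference,
        })
        for ci, ch in enumerate(channels):
            table[f"intensity_{ch}"] = intensities[:, ci]
        psm_tables[patient] = table

    return psm_tables, designs, truth.annotation.copy()


def simulate_cohort(cfg: SimConfig):
    """Convenience: latent profiles + PSM emission in one call."""
    truth = simulate_latent_profiles(cfg)
    psms, designs, annot = emit_psm_tables(truth, cfg)
    return truth, psms, designs, annot


def write_cohort(outdir: str | Path, truth: GroundTruth,
                 psms: Dict[str, pd.DataFrame],
                 designs: Dict[str, pd.DataFrame]) -> List[Path]:
    """Write PSM / design / annotation / ground-truth TSVs; return paths."""
    from . import io as lio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for plex in sorted(psms):
        p = outdir / f"psm_{plex}.tsv"
        lio.write_tsv(psms[plex], p, index=False)
        written.append(p)
        d = outdir / f"design_{plex}.tsv"
        lio.write_tsv(designs[plex], d, index=False)
        written.append(d)
    p = outdir / "annotation.tsv"
    lio.write_tsv(truth.annotation, p, index=False)
    written.append(p)

    gt = pd.DataFrame({
        "true_logfc": truth.true_logfc,
        "de_direction": truth.de_direction,
        "secreted_flag": truth.secreted_flag.astype(int),
    })
    p = outdir / "ground_truth_proteins.tsv"
    lio.write_tsv(gt, p, index=True)
    written.append(p)

    frac = truth.bt_tumor_fraction.reset_index().melt(
        id_vars="patient", var_name="level", value_name="bt_tumor_fraction")
    p = outdir / "ground_truth_bt_fraction.tsv"
    lio.write_tsv(frac, p, index=False)
    written.append(p)
    return written
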