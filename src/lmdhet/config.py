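"""Configuration objects for the simulator and the end-to-end pipeline.

The simulator emulates a multi-region laser-microdissection (LMD) study
design: each patient tumor block is cut into spatially distinct sampling
levels, and from each level enriched tumor epithelium (ET), enriched
tumor-involved stroma (ES) and whole "bulk" tissue (BT) are harvested and
quantified in a patient-specific isobaric TMT multiplex against a pooled
reference channel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

__all__ = ["SimConfig", "PipelineConfig", "TMT_CHANNELS"]

#: TMTpro 16-plex reporter channel labels, in mass order.
TMT_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic multi-plex cohort generator.

    Defaults mirror the study design the pipeline targets: 9 patients,
    5 spatial levels, ~2000 proteins per plex, 10% of proteins with a
    planted ET-vs-ES log2 fold change of mean magnitude 1.5, per-level
    spatial drift, inflated drift for secreted/extracellular proteins,
    and plex-wise protein dropout.
    """

    n_patients: int = 9
    n_levels: int = 5
    n_proteins: int = 2000
    #: mean PSM count per protein per plex (Poisson unless psm_count_model="fixed")
    psms_per_protein: float = 4.0
    psm_count_model: str = "poisson"  # "poisson" | "fixed"
    frac_de: float = 0.10
    #: mean |true log2 fold change| of DE proteins
    effect_size_log2: float = 1.5
    effect_size_model: str = "fixed"  # "fixed" | "exponential"
    #: SD of the per-level random walk on log2 abundance
    level_drift_sd: float = 0.15
    level_model: str = "random_walk"  # "random_walk" | "iid"
    #: per-PSM log2 measurement noise SD
    noise_sd: float = 0.3
    frac_secreted: float = 0.2
    #: multiplier on level_drift_sd for secreted/extracellular proteins
    secreted_var_inflation: float = 2.0
    #: probability a protein is entirely unobserved in a given plex
    frac_missing_per_plex: float = 0.1
    #: BT tumor fraction is drawn uniformly from this range per (patient, level)
    bt_fraction_range: Tuple[float, float] = (0.15, 0.99)
    #: inclusive range of sampled ET / ES level counts per patient (BT gets all)
    et_levels_range: Tuple[int, int] = (4, 5)
    es_levels_range: Tuple[int, int] = (2, 5)
    #: fraction of PSMs drawn with a failing q-value (>= q threshold)
    frac_q_fail: float = 0.05
    q_fail_max: float = 0.2
    #: fraction of PSMs drawn with failing isolation interference (>= 50%)
    frac_interference_fail: float = 0.05
    baseline_log2_mean: float = 16.0
    baseline_log2_sd: float = 1.5
    seed: int = 0
    #: if set, planted truth (DE set, logFCs, secreted flags) is drawn from this
    #: seed while measurement randomness follows `seed`; lets two cohorts share
    #: ground truth with independent noise.
    truth_seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_patients", "n_levels", "n_proteins"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name in (
            "frac_de", "frac_secreted", "frac_missing_per_plex",
            "frac_q_fail", "frac_interference_fail",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.effect_size_log2 <= 0:
            raise ValueError("effect_size_log2 must be > 0")
        if self.psms_per_protein < 0:
            raise ValueError("psms_per_protein must be >= 0")
        for name in ("level_drift_sd", "noise_sd", "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.secreted_var_inflation <= 0:
            raise ValueError("secreted_var_inflation must be > 0")
        lo, hi = self.bt_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("bt_fraction_range must satisfy 0 <= lo <= hi <= 1")
        for name in ("et_levels_range", "es_levels_range"):
            a, b = getattr(self, name)
            if not (1 <= a <= b <= self.n_levels):
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi <= n_levels")
        if self.psm_count_model not in ("poisson", "fixed"):
            raise ValueError("psm_count_model must be 'poisson' or 'fixed'")
        if self.effect_size_model not in ("fixed", "exponential"):
            raise ValueError("effect_size_model must be 'fixed' or 'exponential'")
        if self.level_model not in ("random_walk", "iid"):
            raise ValueError("level_model must be 'random_walk' or 'iid'")
        if not (0.0 < self.q_fail_max <= 1.0):
            raise ValueError("q_fail_max must lie in (0, 1]")

    def replace(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("bt_fraction_range", "et_levels_range", "es_levels_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """Stage toggles, per-stage parameters and paths for `lmdhet run`."""

    sim: SimConfig = field(default_factory=SimConfig)
    # stage toggles
    run_simulate: bool = True
    run_quantify: bool = True
    run_heterogeneity: bool = True
    run_differential: bool = True
    run_admixture: bool = True
    run_compare: bool = True
    # quantify parameters
    q_max: float = 0.01
    interference_max_pct: float = 50.0
    min_psms: int = 2
    knn_k: int = 10
    min_quant_frac: float = 0.5
    # heterogeneity parameters
    mad_min: float = 1.0
    cluster_mad_min: float = 0.5
    # differential parameters
    alpha: float = 0.05
    # admixture parameters
    ssgsea_alpha: float = 0.25
    signature_size: int = 50
    # paths (matrix_path used when quantify is disabled)
    matrix_path: Optional[str] = None
    annot_path: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.q_max <= 1.0):
            raise ValueError("q_max must lie in (0, 1]")
        if not (0.0 < self.interference_max_pct <= 100.0):
            raise ValueError("interference_max_pct must lie in (0, 100]")
        if self.min_psms < 1:
            raise ValueError("min_psms must be >= 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if not (0.0 < self.min_quant_frac <= 1.0):
            raise ValueError("min_quant_frac must lie in (0, 1]")
        if self.mad_min < 0 or self.cluster_mad_min < 0:
            raise ValueError("MAD cutoffs must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.ssgsea_alpha < 0:
            raise ValueError("ssgsea_alpha must be >= 0")
        if self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")
        if not self.run_quantify and self.run_heterogeneity and not self.matrix_path:
            raise ValueError(
                "heterogeneity stage enabled without the quantify stage: "
                "matrix_path is required"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
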