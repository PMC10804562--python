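# Methods

This note documents the models, statistical procedures and numerical
choices behind `lmdhet`, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Study design being modeled

Each patient contributes one specimen block cut into `n_levels` (default
5) spatially distinct sampling levels. Per level, up to three harvests
exist: enriched tumor epithelium (ET), enriched tumor-involved stroma
(ES) and whole bulk tissue (BT). All of a patient's harvests are labeled
in one isobaric TMTpro multiplex (≤ 16 channels) whose first channel
("126") carries a patient-specific pooled reference, so quantitation is
always a log2 ratio to that pool. ET is sampled at 4–5 levels and ES at
2–5 levels per patient by default, mirroring incomplete real designs
where some strata yield too little stroma; BT exists at every level.

## Synthetic-data generator

**Latent profiles.** Each protein gets a baseline log2 intensity
b ~ N(16, 1.5²) (arbitrary reporter-intensity scale). A fraction
`frac_de` = 0.10 of proteins receives a planted ET-vs-ES log2 fold change
whose magnitude is fixed at `effect_size_log2` = 1.5 with a random sign
(an exponential-magnitude option exists behind `effect_size_model`). ES
baselines are b, ET baselines b + logFC. Per patient and collection type
the level profiles follow a random walk across levels with step SD
`level_drift_sd` = 0.15, modeling spatial autocorrelation of contiguous
tissue strata; an i.i.d. per-level option is available. Proteins flagged
secreted/extracellular (`frac_secreted` = 0.2) drift with SD multiplied
by `secreted_var_inflation` = 2.0, so their expected between-level
variance ratio is the square of that multiplier.

**Bulk mixing.** BT at level ℓ is a *linear-scale* mixture
f·2^ET(ℓ) + (1−f)·2^ES(ℓ) with tumor fraction f drawn uniformly per
(patient, level) from `bt_fraction_range` = (0.15, 0.99), because
physical admixture of cell populations adds ion counts, not log ratios.
The distribution of f across levels is deliberately a config choice, not
a fixed fact; uniform over the observed purity range is the default.

**PSM emission.** Each protein receives Poisson(4) PSMs per plex (a
fixed-count mode supports exact round-trip checks). A PSM's reporter
intensity in a channel is the latent linear intensity times
2^N(0, `noise_sd` = 0.3). The reference channel holds the mean linear
intensity over the patient's actual samples (pooling equal peptide masses
approximates averaging). Nuisance columns are drawn independently of
abundance: 5% of PSMs get a failing q-value (≥ 0.01) and 5% failing
isolation interference (≥ 50%), so the filters are genuinely exercised.
Whole proteins drop out of a plex with probability
`frac_missing_per_plex` = 0.1. Identical seeds give byte-identical
outputs; a separate `truth_seed` lets two cohorts share planted truth
with independent measurement noise (used for cross-dataset comparisons).

**What is not emulated.** Spectrum-level physics (m/z, retention time,
co-isolation as a process), peptide sequence realism, shared peptides,
reagent-lot isotopic impurity (intensities are emitted as already
corrected), abundance-dependent missingness, and any immune component in
the BT mixture. Consequently, passing tests demonstrate the pipeline's
correctness and calibration under a clean two-population admixture with
log-normal noise — not robustness to interference artifacts, razor-peptide
ambiguity or three-way admixture in real data.

## Quantitation rules

Filter thresholds are strict: q < 0.01 and interference < 50 (a value
exactly at either threshold is excluded). A PSM must have a positive
reference-channel intensity and signal in ≥ 1 other channel. Roll-up is
the median of PSM log2 ratios, per protein × sample, requiring ≥ 2 PSMs
per protein counted within each plex after filtering. Columns are median
centered (exact zero medians afterwards). Merging is the union over
plexes with explicit missingness. Imputation drops proteins observed in
< 50% of samples (inclusive at exactly 50%; the denominator is samples,
with the per-patient alternative discussed below) and fills each missing
cell with the unweighted mean over the k = 10 nearest proteins by *plain*
Euclidean distance computed over mutually observed samples. Distance ties
break by protein id order for determinism; if fewer than k candidates
exist all are used with a warning. This contract is pinned by an
exhaustive brute-force oracle in the tests; it intentionally differs from
scikit-learn's `KNNImputer` (which rescales distances by the fraction of
missing coordinates).

Whether the ≥ 50% quantification rule should count samples or patients is
ambiguous in practice; per-sample counting is the stricter contract and
is the default.

## Heterogeneity statistics

MAD is always raw — median(|x − median|) with no 1.4826 consistency
factor — because the selection cutoffs (1.0, 0.5) are conventionally
applied to raw values. Clustering uses 1 − Pearson distance with average
linkage (the defaults of the clustering tools this emulates), leaf order
deterministic by sample label. Per-patient dendrograms select MAD > 1
proteins *within that patient's ET+ES samples* (protein counts then vary
per patient, as observed in practice), use 1 − Spearman distance, and
require ≥ 3 levels in both ET and ES. The intra-type relatedness test
feeds all C(n,2) within-type pairwise Spearman correlations of each type
into a two-sided Mann–Whitney U. The secreted-variance test compares raw
MADs across levels of secreted vs non-secreted proteins within one
(patient, collection-type) scope, restricted to patients with 4–5 levels
in both ET and ES; MAD was chosen over variance for robustness and is
configurable in spirit (the statistic is a small, isolated function).

Mann–Whitney U uses the exact null distribution when both groups have ≤ 8
observations and no ties, otherwise the normal approximation with tie
correction. Exactness is verified against full enumeration of group
assignments in the tests.

## Moderated t and concordance

The per-protein model is ordinary least squares of log2 abundance on an
ET indicator plus patient dummies (blocking reflects the paired
multi-plex design; un-blocked pooling is available). Empirical-Bayes
variance squeezing fits (d₀, s₀²) by matching the mean and variance of
log s²_g to the theoretical moments under a scaled inverse-chi-square
prior: the excess variance of log s² beyond trigamma(d_g/2) is inverted
through the trigamma function (Newton iteration) to give d₀, and s₀²
follows from the mean via digamma terms. Homogeneous variances push d₀ to
infinity (full shrinkage); d₀ = 0 reproduces the classical t exactly
(verified against statsmodels OLS to 1e-10). P-values use d₀ + d_g
degrees of freedom and BH adjustment.

Per-patient logFC is median-over-ET-levels minus median-over-ES-levels
(robust to one aberrant level). The concordance filter requires
adj. p < α **and** one strict nonzero per-patient sign everywhere; an
exact zero (possible only on synthetic data) counts as discordant. On the
default cohort this recovers planted effects with pooled sensitivity
≈ 0.98 at realized FDP ≈ 0.04 over 10 seeds; the residual false
discoveries are null proteins whose chance drift is both sign-consistent
across 9 patients (probability 2⁻⁸) and BH-significant.

## ssGSEA

Features are ranked per sample (average ranks for ties; walk order breaks
ties by feature id). In-set features contribute rank^α (α = 0.25,
configurable) normalized over the set; out-of-set features contribute a
flat 1/(N−m) ECDF step; the score is the sum of the running differences
over the whole list. Scores are reported raw by default — min–max
normalization across samples is behind a flag, since cross-sample
normalization changes no rankings but does change absolute values. For
synthetic cohorts, Tumor/Stroma signatures are the top 50 planted ET-up /
ES-up proteins; real analyses supply GMT files.

## Comparison operations

The concordant overlap partitions the union of two alteration sets into
shared-same-direction, shared-discordant, and the two unique sets; the
headline "commonly altered" count is shared-same-direction only, and the
discordant class is reported explicitly rather than silently dropped.
RPPA preprocessing floors sub-detection values at e⁻¹⁰ before log2 and
target-wise median centering; all-zero targets survive as constant rows
with a warning. Antibody→accession maps may be many-to-one
(phospho-epitopes map to their parent accession) and expand to one row
per pair.

## Pipeline and determinism

`lmdhet run` chains simulate → quantify → heterogeneity → differential →
admixture → compare, writing TSV/newick/JSON artifacts per stage and a
manifest of sha256 hashes plus the echoed configuration. The manifest
contains no timestamps, so a repeated run with one seed is byte-identical;
floats are serialized with shortest-repr formatting and parsed back with
correctly-rounded (`round_trip`) precision, making write→read→write
byte-stable. The compare stage simulates a companion cohort sharing the
planted truth (via `truth_seed`) with an independent noise seed.

## Problem sizes used in validation

The validation suite runs the full default cohort (9 patients, 2000
proteins) for the zero-noise round trip, clustering separation, admixture
recovery and (over 10 seeds) differential recovery; the moderated-t null
calibration uses 10,000 simulated null proteins; the secreted-variance
size/power calibration uses 200 null and 100 inflated single-patient
cohorts of 600 proteins built from latent profiles directly (the test
operates per patient-scope, so PSM emission adds nothing there); the
imputation oracle check uses 50 random matrices up to 30 × 16; and the
determinism check runs a 4-patient, 400-protein pipeline twice. These
sizes are the package's own validation choices, balancing statistical
resolution against quick iteration.

## Known limitations

- Quantitation starts at scored PSM tables; search, FDR estimation and
  isotope-impurity correction are upstream concerns.
- The MAD > 1 selection cutoff is calibrated to real-data log2 ranges; on
  the synthetic scale (planted |logFC| = 1.5, row MADs ≈ 0.75 for
  differential proteins) the secondary cutoff 0.5 is the useful default
  for clustering, and the pipeline falls back accordingly.
- Signature derivation (e.g. SVM-RFE) is out of scope: signatures are
  inputs (GMT) or ground-truth-derived on synthetic runs.
- The Mann–Whitney exact path requires tie-free data; correlations of
  discretized data fall back to the tie-corrected normal approximation.
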