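# lmdhet

Spatial intratumor-heterogeneity analysis for multi-region
laser-microdissection (LMD) proteomics.

## The problem

Bulk tumor tissue is a mixture of tumor epithelium, stroma and immune
infiltrate, and its measured proteome shifts with the mixing fractions
rather than with biology alone. One way to resolve this is to
laser-microdissect enriched tumor epithelium (ET), enriched tumor-involved
stroma (ES) and whole "bulk" tissue (BT) from several spatially distinct
sampling levels of each specimen block, quantify each harvest in a
patient-specific isobaric TMT multiplex against a pooled reference
channel, and then ask: how related are levels within a collection type,
which proteins separate tumor from stroma consistently in every patient,
and how much of what bulk tissue shows is just admixture?

`lmdhet` implements that analysis end to end for anyone working with
PSM-level TMT exports (and emulated RPPA/transcript matrices), plus a
synthetic-cohort generator with planted ground truth so every stage is
testable without access to patient data.

## What it computes

- **Quantitation** (`lmdhet.quantify`): PSM filtering (q-value < 0.01,
  isolation interference < 50%, reference-channel signal present), per-PSM
  log2 ratios to the pooled reference channel, protein roll-up as the
  median over ≥ 2 PSMs per plex, per-sample median centering, multi-plex
  merging, and k-NN imputation (k = 10) of proteins quantified in ≥ 50%
  of samples.
- **Heterogeneity** (`lmdhet.heterogeneity`): variable-protein selection
  by raw median absolute deviation (MAD, no consistency constant),
  average-linkage clustering on 1 − Pearson distance, pairwise Spearman
  correlations between sampling levels, per-patient ET/ES dendrograms with
  a Mann–Whitney U comparison of intra-type relatedness, and a
  Mann–Whitney test of whether secreted/extracellular proteins vary more
  between levels.
- **Differential abundance** (`lmdhet.differential`): an empirical-Bayes
  moderated t — per protein a linear model of log2 abundance on the ET/ES
  indicator with patient as a blocking covariate; residual variances s²_g
  are squeezed toward a prior (d₀, s₀²) fitted by moment matching of
  log s²_g via digamma/trigamma inversion, giving
  s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and
  t_g = β̂_g / (s̃_g·c) on d₀ + d_g degrees of freedom, BH-adjusted.
  A sign-concordance filter then keeps proteins with adj. p < 0.05 whose
  per-patient logFC (median over ET levels − median over ES levels) has
  one strict sign in **every** patient.
- **Admixture** (`lmdhet.admixture`): single-sample GSEA (rank-weighted
  running sum, exponent α = 0.25) of tumor/stroma/immune signatures per
  sample, and recovery of BT mixing fractions against ground truth.
- **Comparison** (`lmdhet.compare`): concordant-alteration overlap between
  two datasets (shared same-direction / discordant / unique partition),
  Spearman correlation of shared logFCs, RPPA-style preprocessing
  (e⁻¹⁰ detection floor, log2, target-wise median centering),
  cross-platform per-sample/per-feature correlations, and association of
  alteration abundances with tumor purity.
- **Simulation** (`lmdhet.simulate`): 9 patients × 5 levels × {ET, ES, BT}
  by default; BT is a *linear-scale* mixture f·2^ET + (1−f)·2^ES with
  per-(patient, level) tumor fraction f ∈ [0.15, 0.99]; per-level random
  walks model spatial drift (doubled SD for secreted proteins); PSM
  emission adds reporter noise, nuisance q-values/interference and
  plex-wise dropout.

## Worked example

```python
import lmdhet as L

cfg = L.SimConfig(seed=1)                      # default study conditions
truth, psms, designs, annot = L.simulate_cohort(cfg)
res = L.quantify_cohort(psms, designs, annotation=annot)
dr = L.moderated_ttest(res.matrix, annot)
print(dr.summary(n_top=5))
```

prints

```
ET vs ES moderated-t differential abundance
===============================================
proteins tested:            1951
residual df per protein:    63
prior df (d0):              11.05
prior variance (s0^2):      0.0712
adj. p < 0.05:               465
sign-concordant across all patients: 205

top 5 proteins by adj. p:
         logfc_overall      t_mod             p         adj_p
protein
P1492        -1.612270 -38.933352  4.609037e-51  8.992231e-48
P0904        -1.701016 -35.348123  4.109060e-48  4.008388e-45
P0358        -1.573456 -32.275394  2.303029e-45  1.497736e-42
P1751        -1.515547 -30.936543  4.285313e-44  2.090161e-41
P1779         1.575851  30.745178  6.566158e-44  2.253914e-41
```

1951 of 2000 simulated proteins survive quantitation (the rest fall below
the 50% observation rule after plex dropout); 205 proteins pass the
all-patient sign-concordance filter, against 200 planted differential
proteins at |log2FC| = 1.5. The strongest hits recover the planted effect
size with the planted sign. Continuing,

```python
st = L.ssgsea_score(res.matrix, L.truth_signatures(truth, n_top=50))
rho, p, tab = L.purity_recovery(st, truth, annot, "Stroma")
print(f"stroma-score vs true stroma fraction: "
      f"Spearman rho = {rho:.3f} over {len(tab)} BT samples")
```

prints

```
stroma-score vs true stroma fraction: Spearman rho = 0.951 over 45 BT samples
```

i.e. the ssGSEA stroma score tracks the simulated bulk-tissue stroma
fraction almost perfectly across the purity range.

The same flow is available from the shell:

```bash
lmdhet simulate --outdir sim --seed 1
lmdhet quantify --psms sim --annot sim/annotation.tsv -o matrix.tsv
lmdhet diff --matrix matrix.tsv --annot sim/annotation.tsv -o diff.tsv
lmdhet run --outdir full_run --seed 1      # everything + hashed manifest
```

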