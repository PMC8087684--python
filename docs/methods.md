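# Methods

## Setting and model

`ulmomics` analyzes two-cohort paired tumor omics: a log2 protein abundance
matrix (TMT reporter quantification), a transcript matrix (TPM, transformed
to log2(TPM + 1)), a sample design mapping each sample to one of two cohorts
(by convention cohort A is the case group, e.g. FH-mutant/HLRCC, and B the
control, e.g. non-syndromic), and a PSM-level table for modification-centric
analyses. The three scientific axes are (i) per-gene differential abundance
between cohorts, (ii) the coupling between a sample's transcriptome and
proteome, summarized as a per-sample Spearman correlation and contrasted
between cohorts, and (iii) succination (2SC): the +116.0109 Da fumarate
adduct on cysteine, quantified at PSM level and aggregated to a cohort
stratification statistic.

## Differential abundance

Per feature, complete-case group means give logFC = mean(A) − mean(B), a
pooled residual variance s² on d = n_A + n_B − 2 df (features with fewer
than two observed values in either group are dropped and logged). The
empirical-Bayes layer assumes s²_g | σ²_g ~ σ²_g χ²_d/d and a scaled
inverse-chi-square prior σ²_g ~ s₀² d₀/χ²_{d₀}. Hyperparameters are fitted
by method of moments on z = log s²: the mean and variance of
e = z − ψ(d/2) + log(d/2) identify d₀ through the trigamma inverse (Newton
iteration) and s₀² through the digamma correction. When the observed spread
of e does not exceed the chi-square sampling noise, d₀ = ∞ and every feature
shares the ensemble variance exp(mean e) — the moderated t then degenerates
to an ordinary t with a common variance and normal reference distribution.
The implementation reproduces an independent reference implementation of
the moderated t (Bioconductor limma) to 1e-8 on a frozen fixture; that
check lives in the test suite, not in the code path.

Multiple testing uses Benjamini–Hochberg (the default of the referenced
differential framework; the adjustment method is configurable nowhere
because no other method is claimed). The Mann–Whitney U test delegates to
scipy with an explicit branch rule: exact permutation p when the combined
sample is ≤ 12 without ties (the regime of small spot checks), otherwise
the normal approximation with tie and continuity corrections (the regime of
the 16 vs 12 cohort comparison). A fully tied input returns p = 1 rather
than a divide-by-zero.

## Cross-ome correlation

Per-sample correlation is Spearman with average ranks over the genes
co-observed in both layers for that sample (pairwise-complete). Transcript
matrices are per-sample z-scored first for fidelity with the source
protocol; this is a no-op for rank statistics and is covered by an
invariance test. Cohort medians are contrasted with the MWU test above.

The pair-level screen computes, per gene, the Spearman correlation between
its protein and transcript values across cohort-A samples and cohort-B
samples separately (minimum four usable samples per cohort; smaller pairs
are dropped and logged — below four, a rank correlation is noise). The
variability score is the MAD of the two values {ρ_A, ρ_B}, which for two
numbers is |ρ_A − ρ_B|/2; scores strictly above 0.5 mark a pair "variable",
and the A-/B-positive subsets require ρ > 0.6 in the respective cohort. An
`absdiff` metric flag exposes |ρ_A − ρ_B| as an alternative because the
two-value MAD reading, while literal, is not the only defensible one.

Co-altered pairs are genes with BH q below threshold (default 0.01) in both
layers; the summary statistic is the Spearman correlation between the two
logFC vectors plus the count of sign-concordant rows. External-signature
concordance counts shared genes replicating at raw p < 0.05 and at
q < 0.01 and correlates internal against external logFCs within each
subset, reporting the non-replicated remainder with its own correlation.

## Succination

Monoisotopic masses are summed from the NIST atomic mass table shipped with
pyteomics; isotope labels are written as a leading mass number (13C, 15N),
so the 2SC adduct is C4H4O4 → 116.0110 Da and the TMT-10 label
H20 C8 13C4 N 15N O2 → 229.1629 Da. PSM validation accepts a record iff at
least one modification sits on a cysteine whose annotated letter matches
the sequence and whose delta is within an absolute tolerance (default
0.01 Da — table validation, not search tolerance) of 116.0109; rejections
are categorized (wrong residue / wrong mass / malformed) rather than
raised. Rollup keys are (peptide sequence, set of 2SC-modified indices), so
positional isomers count as distinct peptides; per-sample abundances
aggregate by median over contributing PSMs. The completeness filter keeps
rows observed in every sample.

The headline stratification statistic is the median over complete-case
peptides of per-peptide cohort median differences (median(A) − median(B)).
The aggregation order is a documented choice — the source analysis does not
state whether its figure-level statistic was computed per PSM or per unique
peptide — and the per-peptide vector is returned so either summary can be
formed. The accompanying MWU contrasts per-sample mean 2SC abundance;
PCA treats samples as observations with features centered (unscaled).
Residue mapping is protein position = start offset + peptide index − 1
(both 1-based), giving labels like C283.

## Stratification

The MAD filter uses the raw median absolute deviation (no 1.4826 factor)
with a strict ">" threshold — 1.0 for transcript and 0.5 for protein
matrices by default. Clustering is average-linkage (UPGMA) on
1 − Pearson correlation, pairwise-complete, with an optional Spearman flag;
an optional feature-centering step (the usual heatmap convention, and the
default in the end-to-end pipeline) subtracts each feature's mean so that
both cohorts cohere around their own signatures rather than only the case
cohort deviating from zero. PCA is an SVD of the feature-centered data;
variance explained is the normalized squared singular-value spectrum, with
a unit-variance scaling flag for ClustVis-style runs.

## Synthetic cohorts

The generator plants *per-sample* cross-ome correlation — matching the
statistic under study — rather than gene-level correlation structure, which
is left exchangeable. For sample s in cohort c, the transcript profile is
iid standard normal over genes and the protein profile is
r_s z + √(1 − r_s²) ε, with r_s the Gaussian-copula conversion
r = 2 sin(πρ/6) of a per-sample Spearman target drawn
N(ρ_c, spread). Planting through the copula conversion matters: naive
Pearson planting systematically underestimates the intended Spearman.
Defaults are the study conditions: ρ = 0.35 (case) / 0.242 (control),
16 + 12 samples, 3 411 genes; the within-cohort spread (0.05) is a
generator parameter, since the source reports no spread — it controls how
strongly the cohort comparison separates and is deliberately not tuned.
Targets within 1e-6 of ±1 are rejected (the noise weight underflows);
exact ±1 is a deterministic copy handled separately.

Per-gene log2FC effects are added to case-cohort samples per layer. PSM
tables draw tryptic-like peptides with exactly one cysteine; exactly
`n_complete` peptides are fully observed and every remaining peptide is
forced to carry at least one missing cell (missing-completely-at-random
otherwise, default rate 0.3 — no informative missingness is simulated), so
the planted complete-case count is exact by construction and tested as an
invariant. Accessions cycle over `round(n_peptides · 253/367)` proteins to
mirror the study's peptide:protein ratio. Optional decoy records (wrong
residue or wrong mass) exercise the validator. All draws derive from one
seeded numpy generator; identical config + seed reproduces byte-identical
files.

What the generator does *not* emulate: reporter-ion ratio compression,
interference, batch/multiplex structure, gene–gene covariance, realistic
dynamic range, or informative missingness. Passing recovery tests therefore
demonstrates estimator correctness under the planted model, not robustness
to those real-data artifacts.

## Numerical choices and degenerate inputs

- Missing values are NaN end to end; TSV I/O uses empty/`NA` and `%.17g`
  formatting so finite values round-trip bit-exactly.
- Duplicate feature ids collapse by per-sample median (order-independent);
  symbol matching is case-folded uppercase with no alias resolution.
- Replicate QC flags pairs with Spearman < 0.3 (separating the reported
  low-quality ~0.2 pairs from typical ~0.6–0.83 technical replicates);
  replicate #1 is always the one retained, and retained columns are never
  modified.
- BH is the literal step-up with a reverse cumulative minimum; it matches a
  brute-force implementation of the definition to 1e-12 under a property
  test.
- Ties in Spearman use average ranks throughout; correlation p-values are
  not relied on except where reported alongside summaries.
- Degenerate cases raise typed errors: empty matrices, single-cohort
  designs, all-zero variance ensembles, PCA with missing values, cluster
  pairs with fewer than three co-observed values.

## Problem sizes in the shipped checks

The test suite and the benchmark script run the recovery analyses at the
study scale (3 411 genes, 16 + 12 samples, 367/60 peptides) over 20 seeds,
which completes in seconds; heavier Monte Carlo (null calibration of the
MWU at 2 000 replicates, null uniformity of moderated-t p-values at 10 × 500
features) is sized to keep the whole suite under a minute on one CPU while
still giving binomial error bars well inside the asserted bands.

## Known limitations

- Two-group designs only: no covariates, batch terms, or voom-style
  mean-variance weighting.
- Protein inference, isoform handling and identifier mapping are out of
  scope; the matrices are taken at face value, one symbol per row.
- The ARE gene list ships only as the 17-gene demo table; full published
  ARE / synthetic-lethality catalogs are user-supplied inputs (the packaged
  synthetic-lethality GMT is a labelled placeholder).
- Real-cohort headline counts (e.g. numbers of co-altered pairs or MAD-
  filtered features) depend on the actual data matrices and are not
  reproduced by the synthetic checks; only the estimators and their
  recovery behavior are.
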