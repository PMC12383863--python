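# Methods

## Overview

`epiclust` re-implements, as a tested pipeline, an analysis that links
adolescent internalizing/externalizing symptom profiles to perinatal risk
and candidate-gene CpG methylation. The chain is:

1. **Synthetic data** — a cohort generator (phenotypes, risks, per-CpG
   methylation percentages with known component labels) and a bisulfite
   read simulator with a per-molecule truth record.
2. **Methylation calling** — bisulfite-aware local alignment of read pairs
   to amplicon references, coherent-pair retention, per-CpG base-frequency
   tallies, the C/(C+T) methylation percentage, and coverage/conversion QC.
3. **Clustering** — constrained-covariance Gaussian mixtures (EII, VII,
   EEI) fitted by EM on the bivariate (Internalizing, Externalizing)
   T-scores, compared by BIC.
4. **Characterization** — cleaning, hot-deck imputation, and two-group
   tests (Welch/pooled t, Yates χ², Bonferroni) across demographics,
   risks, and all 54 CpG methylation variables.

## Cohort model

Subjects belong to one of two latent severity components. Component 0
("LOW", weight 0.51) has T-score means (51.0, 47.1) with SDs (6.91, 6.51);
component 1 ("HIGH", weight 0.49) has means (63.7, 58.9) with SDs (5.97,
7.10); dimensions are (Internalizing, Externalizing) and covariance is
diagonal. Binary risks are per-component Bernoulli: stressful life events
0.37/0.48, perinatal risk 0.46/0.66 (the cluster-level values are taken as
generating truth; whole-sample prevalences quoted elsewhere are not
consistent with them and are ignored). Demographics: age N(14.5, 2.02) /
N(14.4, 2.31), male fraction 76/102 and 77/98, SES N(50.8, 20.3) /
N(47.0, 18.3). Methylation percentages at 54 CpG sites across six
amplicons are per-component truncated normals (clip to [0, 100]) with the
published per-cluster means and SDs. T-scores are CBCL scales (population
mean 50, SD 10; ≥60 borderline, ≥64 clinical).

Truncation matters only for the near-zero BDNF and IGF2 CpG5 sites
(means < 2%), where clipping shifts the realized mean slightly upward and
makes the distribution non-normal; the two components are truncated
identically, so null contrasts remain null.

## Amplicon references and read simulation

Six regions are modelled with their genomic coordinates (hg19) and CpG
counts: BDNF intron 1 (chr11:27723077–27723244, 11 CpGs), FKBP5 intron 7
(chr6:35558405–35558550, 3), the IGF2 DMR (chr11:2169373–2169658, 5), and
three OXTR regions — exon 3 (chr3:8809340–8809530, 15), intron 1
(chr3:8810654–8810919, 13), and the promoter (chr3:8811488–8811837, 9
CpGs, 7 analyzed). Gene labels and coordinates are keyed by coordinates;
each reference carries an explicit `analyzed_cpgs` inclusion mask (the
promoter defaults to its first 7 CpGs, an arbitrary but fixed choice since
nothing pins down which two were excluded). True genomic sequences are not
bundled: sequences are synthetic with exactly the declared CpG layout
(stars-and-bars placement of CG blocks, then destruction of accidental
CGs), which is sufficient because every downstream step depends only on
the CpG and non-CpG-cytosine layout, not on the actual base identities.

Read simulation works per template molecule on the original top strand
only (amplicon bisulfite PCR is strand-specific; one strand keeps calling
unambiguous). Each CpG cytosine is drawn methylated with its site
probability; every unprotected cytosine (unmethylated CpG or any non-CpG
C) converts C→T with probability `conversion_eff`. Mate 1 reads the
converted strand 5'→3'; mate 2 reads its reverse complement, so the
default full-length insert makes the mates overlap the entire amplicon.
Uniform substitution errors at `error_rate` are applied last. Base
qualities are constant Phred 40 (Phred+33). There is no PCR-bias, chimera,
adapter, or indel error model — passing tests say nothing about those
artifacts in real libraries.

## Alignment and calling

Each mate is aligned to *every* reference by affine-gap local
Smith–Waterman (gap of length L costs open + (L−1)·extend; defaults
match +2, mismatch −3, open −5, extend −2 — chosen as ordinary
short-read local-alignment values since none are prescribed). The
substitution matrix is asymmetric: reference C vs read T scores as a
match (the bisulfite rule), reference T vs read C does not. A pair is
kept only when both mates' best references coincide ("coherent"); ties
break to the lowest reference index; either mate scoring below
0.6·read_len·match rejects the pair (threshold chosen to stop spurious
short local hits from producing false coherent pairs). The aligner engine
is Biopython's `PairwiseAligner`; tests verify its scores against an
independent plain-Python Gotoh DP on short instances.

Tallying counts each reference position once per pair (mate 1 wins where
overlapping mates disagree) so one molecule is never counted twice.
Methylation per CpG is 100·C/(C+T); A/G observations are excluded from
the denominator but kept in the report; C+T = 0 yields a missing (never
0) value. Conversion efficiency is 100·T/(C+T) pooled over all non-CpG
cytosines. QC excludes a sample×amplicon batch if any analyzed CpG is
below 100x coverage or conversion is not strictly greater than 99%.

## Mixture model

For data x_i ∈ R², the likelihood is Σ_k π_k N(x_i; μ_k, Σ_k) with the
covariance constrained by family: EII Σ_k = λI; VII Σ_k = λ_k I; EEI
Σ_k = diag(λ_1, λ_2) shared. Free-parameter counts at d=2, K=2 are 6, 7,
7. Model comparison uses BIC = 2·logL − m·ln n, larger better; ties break
toward smaller m, then smaller K. The printed best-model worked example
(−2887.49 = 2·(−1427.85) − 6·ln 200) is consistent with the
spherical-equal-volume (EII) parameter count; the diagonal EEI model is
what the recovery simulations fit, and both are first-class here.

EM: E-step responsibilities via log-sum-exp; M-step closed forms per
family; tol 1e−8 relative log-likelihood change, max 500 iterations,
variance floor 1e−6; 10 restarts seeded by k-means hard partitions
(model-based hierarchical initialization, the R reference's default, is
deliberately not reproduced — with restarts the two implementations reach
the same optima on this data scale, which a test verifies directly
against R's mclust). Components are always ordered by ascending
internalizing mean, so component 0 is LOW. Known limitation: with ~1.8 SD
separation on the internalizing axis, single-cohort weight estimates at
n=200 have SD ≈ 0.06, and fitting EEI to components whose true SDs differ
per component biases the recovered LOW weight downward by roughly 1–2
points; averaging 50 replicates leaves ≈ 49–50% against a generating 51%.

## Statistics

Cleaning removes subjects with strictly more than 50% of non-identifier
cells missing; remaining holes are filled by random hot-deck imputation
(uniform draw from the variable's observed values), preserving each
variable's empirical support. Two-sample t-tests default to Welch
(nothing pins the variant; recomputing printed rows from rounded
summaries matches Welch for some rows and pooled for others, so both are
exposed and reported). Cohen's d always uses the pooled SD. 2×2 χ² uses
Yates continuity correction by default, with Phi = √(χ²/N) always from
the uncorrected statistic — the combination that reproduces the printed
perinatal-risk contrast (χ²=7.51, Phi=0.20). Bonferroni correction is
applied within a configurable family, defaulting to the 54 methylation
comparisons; variables outside the family are judged at raw α. Signed
statistics are reported as HIGH − LOW with absolute values alongside.
Shapiro–Wilk is scipy's AS R94 implementation, checked against an R
reference value.

## Problem sizes and determinism

Every stochastic step takes an explicit seed, and a pipeline run writes a
manifest with per-stage seeds and SHA-256 digests of every output; reruns
are bit-identical. Read-level simulation plus all-references alignment
costs about 3 ms per pair, so read-level defaults (150 pairs per
subject×amplicon) suit single-sample or small-batch runs; cohort-scale
statistical studies use `read_level=False`, in which the generator's
methylation percentages feed the statistics directly. Test and
acceptance simulations use 50 replicate cohorts of n=200 for recovery
and calibration, 5000 pairs for the conversion-efficiency check, and
≤50 bp instances for the exhaustive alignment oracle.

## Limitations

- One bisulfite strand, uniform errors, constant qualities: the simulator
  validates the calling logic, not robustness to real-library artifacts.
- Synthetic reference sequences share the real regions' CpG layout but
  not their base composition; alignment difficulty on real amplicons
  (repeats, homopolymers) is untested.
- No SNP-aware calling, no UMI/duplicate handling, no genome-scale
  alignment, no covariate adjustment or mediation in the statistics.
- The two-cluster solution's stability on held-out data is not assessed.
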