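# Methods

## Scope and design

`mhcmap` has two halves: an analysis stack (QC, omnibus/conditional
association, stepwise mapping, interaction and onset tests, pipeline/CLI)
and a generative model of the data such an analysis consumes.  The
generator is first-class, tested code: its ground truth is what the
analysis-side tests recover.  Everything is deterministic given a single
seed; all randomness flows through one `numpy` Generator per run.

## Marker model

Four marker categories share one dosage container (samples × markers,
dosages in [0, 2], NaN = missing, one imputation info score per marker):
biallelic SNPs, amino-acid residue indicators, and classical HLA alleles
at two- and four-digit resolution.  Residue dosages are derived, never
independent data: the dosage of residue *x* at position *p* of a gene is
the sum of the dosages of that gene's alleles carrying *x* at *p*.  This
makes residue sums exactly conserve the allele total per sample (an exact
invariant, tested without tolerance) and makes the expansion idempotent
and order-independent.  Two-digit allele dosages are likewise sums of
their four-digit subtypes, so both resolutions stay mutually consistent.
A missing allele dosage blanks every residue of that gene for that sample
— the residue content of an unobserved haplotype is unknown, and partial
sums would understate dosage rather than flag it.

Testable units ("marker groups") are one SNP, one amino-acid position, or
one locus at one resolution; group ids are joinable strings (`B_97`,
`C_4digit`, the SNP id).

## Regression engine

Logistic fits use iteratively reweighted least squares with step-halving
whenever a Newton step would lower the likelihood; convergence is
|Δ log L| < 1e-8 with a 100-iteration cap.  Collinear design columns are
detected by pivoted QR and dropped with a warning (recorded in the fit);
any |β| > 15 flags quasi-separation and the corresponding confidence
interval is reported as unbounded rather than silently huge — no
penalised fallback is applied, matching plain maximum likelihood.
Missing data are handled by listwise deletion per test, with the null and
full models of an LRT restricted to the *same* complete rows so their
likelihoods are comparable; `n_used` is reported.  The engine is verified
against statsmodels, a generic optimizer maximum (1e-6), closed-form 2×2
odds ratios, and a label-permutation null.

All p-values are computed and serialized as log10(p) via `chi2.logsf` /
`norm.logsf`; the signals this field produces (p ≈ 1e-66) underflow a
double if exponentiated in intermediate steps.

## Omnibus, conditional and stepwise tests

For a multiallelic group the reference member is the most frequent in the
control population (frequency = mean dosage / 2 among controls — supplied
separately from the analysis samples so case-case contrasts still use
control-population references).  The full model adds all non-reference
member dosages to the covariates; the omnibus p is the LRT against the
covariate-only null with df = members − 1, reduced when members are
monomorphic in the analysis samples.  The omnibus p is invariant to the
reference choice (tested to 1e-8 in log10 p); only the per-member Wald
ORs re-parameterize.

Conditional tests add the conditioned groups' non-reference dosages to
both models; a group conditioned on itself reports p = 1 with a
`self_conditioned` flag.  Forward stepwise selection re-tests every
unselected group conditionally each round, selects the minimum-p group
while it beats the threshold, and breaks ties by control MAF descending
then group id — the trace is fully deterministic.  Ranking is by the
group omnibus p (not the best single member), which keeps multiallelic
and biallelic units comparable under one threshold.  The Bonferroni
denominator is the total marker-column count (SNPs + residues + alleles
at both resolutions), mirroring the reference accounting
6833 + 334 + 71 + 87 = 7325 → 0.05 / 7325 = 6.8e-6; `max_rounds`
defaults to 10 and the termination reason is recorded.

Interaction tests code the primary marker as dominant (carrier if imputed
dosage > 0.5 — the natural midpoint between 0 and 1 copies; imputation at
info ≥ 0.9 rarely leaves dosages near the boundary) and the SNP as
additive, with a Wald test on the product term.  Empty carrier cells are
an error, not a silent zero.  Reports flag p > α results as
nonsignificant rather than dropping them: a null interaction is a
finding.

Principal components come from an SVD of the column-standardized
(mean-imputed) SNP dosage matrix, k = 2 by default, with each
component's sign fixed by its largest-magnitude loading so outputs are
byte-reproducible.  PCs are recomputed on the analysis sample set of each
contrast.  Onset adjustment is a single linear onset-age covariate — the
simplest model consistent with "controlling for onset"; the sign-flip
experiments below confirm it suffices under the generator's selection
model.

Ages of onset are compared by OLS (dose association, two-sided t test on
log scale) and a Wilcoxon rank-sum test — exact null distribution when
both groups have n ≤ 25 without ties, otherwise the continuity-corrected
normal approximation.

## Marker QC

Retention requires info ≥ 0.9, folded MAF ≥ 0.1 (from mean dosage / 2,
missing excluded), call rate ≥ 0.99, and — only when hard genotype calls
are supplied — a 1-df χ² Hardy-Weinberg p ≥ 7.5e-8.  Dosage-only markers
are not HWE-testable and callers are expected to pass control-only counts
(the standard practice; case samples legitimately deviate from HWE at
associated loci).  In the pipeline the MAF rule applies to SNPs and
classical-allele markers but not to residue indicators: the omnibus tests
a whole position, and rare residues (asparagine at 4.7%, tryptophan at
3.8%) belong inside their group rather than on the scan's exclusion list.
The exclusion log names each removed marker and the first failed rule.

## The synthetic cohort

The generator encodes the minimal structure that produces the bias:

- **Haplotypes.**  A C-locus × B-locus cross (independent by
  construction, so the onset allele and position-97 residues share no
  LD): HLA-C\*06:02 at population frequency 0.15 versus C\*07:01, and
  seven B alleles carrying the six position-97 residues at the published
  control frequencies (R 0.4619, S 0.2785 split over B\*07:02/B\*08:01,
  T 0.1003, V 0.0751, N 0.0474 on B\*27:05, W 0.0384), plus ~50
  background SNPs whose alleles ride the haplotypes (strong LD, as in
  the real region; assignments are redrawn until the realized frequency
  clears the MAF filter, since 14 haplotypes leave few distinct
  frequencies).  Position 45 (E/M, with E on the B\*07/08/27 alleles)
  provides the partially correlated secondary position used in
  conditional-analysis demonstrations.
- **Disease.**  Two logistic stages: psoriasis (intercept −3.6,
  log-OR ln 4.5 per C\*06:02 copy → prevalence ≈ 5.6%, strong allele
  enrichment in cases), then PsA among psoriasis cases (intercept −0.8 →
  ≈ 37% of psoriasis, near the 1945/(1945+2808) case split of the design
  it mirrors) with the published case-case effects as generative truth:
  log-OR ln 2.46 for asparagine and ln 1.45 for serine at position 97,
  and **zero** for the onset allele — any case-case signal it shows is
  artefact by construction.
- **Onset.**  Truncated normal (at 0) with non-carrier mean 43 y,
  −12.5 y per C\*06:02 copy, SD 16.  These were calibrated once so that
  carriers' median onset precedes non-carriers' by ≈ 14 y among
  psoriasis cases.
- **Ascertainment.**  PsC inclusion weight logistic in onset,
  expit((location − t) / scale) with location 26 y and scale 6 y; PsA
  and control selection are onset-neutral.  Selection is exact-size
  weighted sampling without replacement (Gumbel-top-k).  The location
  sits well below the nominal type-I boundary of 40 y because a weight
  centred at 40 barely discriminates within the under-40 range: the
  observed PsC onset median of ≈ 19 y (vs ≈ 34 y for PsA) is only
  reachable if recruitment keeps favouring ever-younger onset, and the
  calibrated defaults reproduce both medians within ±3 y.  The true
  selection strength of real collections is unknown; it is an explicit
  parameter, and `onset_dependent=False` gives the no-bias control.
- **Imputation noise.**  Dosages are degraded to a target info score
  (default 0.97) by the convex mixture d′ = a·d + b·g + (1−a−b)·2p with
  an independent genotype draw g ~ Bin(2, p), choosing a, b so the
  variance is exactly target × 2pq.  The mixture stays in [0, 2] without
  clipping — clipping would crush the variance of rare markers and push
  their realized info far below target.  Realized info is recomputed
  from the output and stored per marker.

Default cohort sizes are 8900 controls / 2800 PsC / 2000 PsA drawn from
a 300,000-person population — the rounded sample sizes of the design this
emulates, with a population large enough that the PsC pool exceeds its
target ~4-fold (weighted sampling needs headroom to be selective).

What the generator does *not* emulate: realistic MHC-wide LD maps and
recombination, phasing, family structure, genotyping batch effects,
population stratification (the population is panmictic, so fitted PCs are
noise directions — harmless but uninformative), and any onset
measurement error.  Passing tests therefore demonstrate that the
statistics behave correctly under the stated mechanism, not that real
cohorts contain no other biases.

## Validation experiments and problem sizes

The test suite freezes these experiments (sizes chosen to give stable
verdicts at seconds-to-minutes scale):

- **Parameter recovery:** 50 cohorts of 10,000 psoriasis cases; the mean
  omnibus-estimated asparagine and serine ORs land within 5% of the
  generative 2.46 / 1.45 (arginine is the reference in every replicate).
- **Sign-flip:** 20 seeded cohorts at the full default sizes; in ≥ 90%
  of seeds the naive PsA-vs-PsC test of the onset allele is protective
  with p < 1e-4 while the onset-adjusted test gives p > 0.01.  Constant
  selection weights remove the artefact entirely.
- **Null calibration:** 2000 df-5 omnibus replicates at n = 300 hold
  5% size within [0.04, 0.06] and pass a KS test against χ²(5);
  500 interaction nulls at n = 5000 hold size within [0.03, 0.07].
- **Oracle equivalences:** LRT vs 10,000 label permutations (n = 400);
  IRLS vs generic-optimizer likelihood (1e-6); Wilcoxon vs full
  enumeration at 3 + 3; Hardy-Weinberg χ² vs hand computation; 2×2
  logistic OR vs the cross-product ratio.
- **Stepwise behaviour:** two planted independent signals recovered
  strongest-first in ≥ 95% of 20 seeds at n = 4000; an r² ≈ 0.8 proxy is
  never co-selected with its partner.

## Numerical choices and degenerate inputs

Deviances in (−1e-8, 0) from convergence noise are clamped to zero;
anything more negative raises (non-nested or unconverged models).
Monomorphic markers give Hardy-Weinberg p = 1 by convention and are
dropped from omnibus groups with a df reduction.  Zero-variance columns
are removed before PCA standardization; an all-constant matrix is an
error.  Stepwise ties (exactly equal log10 p) break by control MAF then
lexicographic group id.  Group sizes that exceed their population pool
raise an error naming the group — silent truncation would invalidate the
requested design.

## Open choices made here

- The reference marker accounting (7325) counts residue *indicators*,
  not positions; this matches 334 amino-acid entries alongside 6833 SNPs
  and 71 + 87 classical alleles, and it is the Bonferroni denominator
  default (a per-dataset denominator is used when the pipeline runs on
  its own marker set).
- Hardy-Weinberg filtering is controls-only (case deviation at true loci
  is signal, not artefact).
- Stepwise ranks by group omnibus p rather than best single-member p.
- PCs are recomputed on each analysis dataset rather than imported from
  source cohorts.

## Known limitations

The dominant-coding threshold (0.5) is a convention; dosages near 0.5
are coded hard.  The linear onset adjustment is correct under the
generator's selection model but could leave residual confounding under a
strongly non-logistic real-world selection function.  The omnibus Wald
CIs are not profile likelihoods and degrade under quasi-separation
(flagged, reported unbounded).  The simulator's LD structure (14
haplotypes) is far simpler than the real MHC; conditional-analysis
results on real data depend on LD detail the generator does not model.
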