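# mhcmap

Cross-phenotype fine-mapping of the MHC for psoriatic arthritis (PsA)
versus cutaneous-only psoriasis (PsC), with a synthetic-cohort simulator
that reproduces the ascertainment mechanism behind the "paradoxical"
HLA-C\*06:02 association.

## The problem

Comparing two subgroups of the same disease (here: psoriasis patients who
developed arthritis versus those who did not) is the natural design for
finding variants that drive progression — but it is exquisitely sensitive
to how the two case groups were recruited.  HLA-C\*06:02 is the strongest
psoriasis risk allele and strongly lowers the age of psoriasis onset.
Dermatology-based PsC collections over-represent early-onset (type I,
onset < 40 y) psoriasis, while rheumatology-based PsA collections are
recruited on arthritis and are onset-neutral.  The result is a large,
highly significant *protective* association of HLA-C\*06:02 with PsA in
the naive case-case comparison that is pure selection artefact: it
disappears once age of psoriasis onset enters the model, unmasking the
real progression signal at amino-acid position 97 of HLA-B, where
asparagine (carried by HLA-B\*27) and serine (HLA-B\*07/B\*08) residues
increase PsA risk.

`mhcmap` implements the full analysis as a tested, reusable pipeline and a
generator of synthetic cohorts with known ground truth, so the bias and
its correction can be studied without any real genotype data.

## The statistics

All tests are additive logistic (or linear, for onset) regressions on
imputed dosages in [0, 2], with the top principal components (default 2)
as covariates:

- **Omnibus test** — for a multiallelic marker group (the residues of one
  amino-acid position, or the alleles of one HLA locus), the most common
  member in the *control* population is the reference and is excluded;
  the remaining member dosages enter the model jointly, and the group
  p-value is a log-likelihood-ratio test against the covariate-only null
  on χ²(k − 1).  P-values are carried as log10(p) throughout (MHC signals
  reach p ~ 1e-66).
- **Conditional / forward stepwise mapping** — previously selected
  groups' dosage columns join both the null and full models; selection
  repeats until no group beats the Bonferroni threshold α / (number of
  markers).
- **Interaction tests** — dominant(HLA-B\*27) × additive(SNP) product
  term, Wald test.
- **Onset analyses** — linear regression of onset age on allele dose and
  a Wilcoxon rank-sum test of PsA versus PsC onset medians.
- **Marker QC** — imputation info ≥ 0.9, MAF ≥ 0.1, call rate ≥ 0.99,
  and a χ² Hardy-Weinberg test (p ≥ 7.5e-8) when hard calls exist.

The simulator draws C-locus/B-locus haplotypes with LD SNPs, assigns
psoriasis and then PsA-given-psoriasis from two logistic stages, gives
each psoriasis case a truncated-normal onset age shifted ~ −12.5 y per
HLA-C\*06:02 copy, selects the PsC group with an early-onset-favouring
logistic weight, and degrades dosages to a target imputation info score.
See `docs/methods.md` for every parameter and its justification.

## Worked example

```python
from mhcmap import CohortConfig
from mhcmap.pipeline import RunConfig, run_pipeline

config = RunConfig(
    seed=7,
    simulate=CohortConfig(seed=7, n_population=120_000,
                          n_control=2500, n_psc=1500, n_psa=1100),
)
bundle = run_pipeline(config)
```

Inspecting the bundle (as in `scan.tsv` / `summary.json` written by
`bundle.write(...)`) prints:

```
markers analysed:        76
Bonferroni threshold:    6.58e-04
C*06:02 naive log10 p:   -13.17
C*06:02 adjusted log10 p:-0.24
B pos-97 adjusted log10 p:-9.67
stepwise selected:       ['B_2digit']
onset slope per C*06:02 dose: -8.58 y
PsA - PsC median onset gap:   12.0 y
```

Reading: in the naive PsA-vs-PsC scan the onset allele is a massive hit
(p ≈ 1e-13, protective) even though the generator gave it **zero** direct
PsA effect — the association is manufactured entirely by onset-dependent
PsC recruitment.  With onset age in the model it collapses to p ≈ 0.6,
while the HLA-B position-97 group (the real planted effect, OR 2.46 for
asparagine, 1.45 for serine) stays far beyond the threshold; stepwise
selection picks a single B-locus signal and stops.  The onset analyses
show the two ingredients of the bias: each HLA-C\*06:02 copy lowers onset
by ~9 years and the selected PsC group's onset median sits ~12 years
below PsA's.

The same pipeline runs from the shell:

```
mhcmap simulate --seed 7 --out-prefix out/cohort
mhcmap run --seed 7 --out-dir results/
```

with further subcommands `qc`, `associate`, `stepwise`, `interact` and
`onset` for the individual stages (see `mhcmap --help`).

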