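# Methods

## Scope and model

`trioburden` evaluates whether rare, predicted-damaging, biallelic
missense variation in a candidate gene is enriched in a cohort of
trio-sequenced affected families, relative to (a) a comparator trio
cohort, and (b) a closed-form population-genetic expectation.  The
analysis assumes autosomal variants, a fully penetrant recessive model,
trusted pedigrees, and statistically independent variants (no linkage
between the rare variants of a gene).

### Variant scoring

Two per-variant summary scores aggregate in-silico evidence:

* **damage prediction proportion** — of the predictors with a call
  (SIFT, LRT, MutationTaster, MutationAssessor, Polyphen2, FATHMM,
  Provean as categorical labels; CADD as a numeric score), the fraction
  calling the variant damaging.  Qualifying labels are "damaging",
  "possibly damaging", "probably damaging", "disease causing",
  "deleterious" and "medium" (compared case-insensitively, with
  underscores treated as spaces since VCF INFO values cannot contain
  spaces); CADD qualifies iff strictly > 12.
* **conservation prediction proportion** — fraction of available
  conservation metrics strictly above SiPhy 12, GERP 4.4, phyloP 1.6,
  phastCons 0.5.

When a predictor has no call the denominator shrinks (the variant is not
penalised for missing annotation); the number available is recorded for
audit, and a variant with zero calls in a class is flagged unscoreable and
never qualifies.  A variant qualifies for the burden analysis iff it is
missense/LoF, rare, scores ≥ 0.25 and ≥ 0.5 on the two proportions
(non-strict, matching the cohort filter), lies in the configured protein
domain (when domain filtering is on), and is on the priority gene list
(when one is configured).

QC is applied before scoring: sites failing the VCF FILTER or with indel
length |len(ref) − len(alt)| > 15 bp are dropped; calls with depth ≤ 10×
or an alt-allele fraction ≤ 4:10 become missing.  All threshold readings
(strict vs non-strict) are pinned by unit tests at the exact boundary
values.  Rarity defaults to max-over-populations MAF ≤ 0.01 (conservative;
a `global` mode checks a single combined-population entry instead).

### Phasing and detection

For a proband heterozygous at two variants of one gene, the phase is
classified by which parental haplotype configurations are consistent with
all five genotypes: only opposite-parent transmission → *in trans*; only
same-parent transmission → *in cis*; both possible, a missing parental
genotype, or no Mendelian-consistent configuration → *ambiguous*.  The
rule accounts for forced transmission by hom-alt parents and is verified
exhaustively against brute-force haplotype enumeration over all 81
parental genotype combinations.  Detected events are in-trans compound
hets, AR homozygotes (proband hom-alt, both parents het), and de novo
candidates (proband carrier, both parents genotyped hom-ref).  Under full
penetrance an event is suppressed when a genotyped unaffected relative
carries the same combination; a relative with a missing genotype skips the
check (logged), and probands with more than two qualifying variants
contribute every in-trans pair but count once in cohort summaries.
Cohort proportions are reported as 100·k/n rounded half-up to one decimal.

### Biallelic inheritance probability

For rare-variant frequencies f₁…fₙ of a gene in one population, under
Hardy–Weinberg equilibrium in an outbred population:

    A = ∏ᵢ (1 − fᵢ),   B = A(1 − A),   P = 0.25·B²

A is evaluated in log space (`exp(Σ log1p(−fᵢ))`) and 1 − A via `expm1`,
which keeps full relative precision when A ≈ 1; the implementation agrees
with exact rational arithmetic to better than 1e-12 relative error.  P is
bounded by 0.25·(1/4)² = 0.015625.

The formula is applied exactly as written.  Note that B is *not* the
standard heterozygote-carrier probability 2A(1 − A): a direct Monte-Carlo
simulation of the described mating scheme — two parents with exactly one
carrier haplotype each, offspring receiving a carrier haplotype from both
— converges to (2A(1 − A)/2)² = (A(1 − A))² = B², which is 4× the formula's
0.25·B².  The package computes both, reports the MC estimate with a
Clopper–Pearson 95% CI, and surfaces the MC/formula ratio as a diagnostic
rather than silently reconciling the two.  The Monte-Carlo reading of
"heterozygous carrier" defaults to exactly-one-carrier-haplotype (the
strictest reading); an `any`-haplotype mode is selectable.

Observed cohort counts are compared to P with an exact binomial test,
one-sided upper tail by default (the enrichment direction); two-sided is
available via the `alternative` flag.  Degenerate P (0 or 1) is handled
directly and flagged.

### Enrichment statistics

* Fisher's exact test: two-sided by the point-probability method (sum of
  hypergeometric probabilities of tables no more probable than observed),
  the common convention; pinned by an exhaustive exact-Fraction
  enumeration oracle over all 2×2 tables with total ≤ 30.
* χ² proportion test: Pearson, 1 df, continuity correction **off** by
  default, making the statistic identical to the squared pooled
  two-proportion z; an expected-cell < 5 warning is attached when
  relevant.  On the published biobank multi-variant carrier counts
  (4/104 vs 343/10,939) the uncorrected test gives p = 0.679 and the
  corrected 0.896; neither reproduces the printed p = 0.6 exactly, so the
  correction is configurable and the default documented here.
* Population comparison: input restricted to rare (MAF < 0.01, strict,
  per the database filter), damaging (CADD > 12) missense variants; one
  way ANOVA across population groups plus all pairwise Welch t-tests,
  Bonferroni-corrected over the number of pairs actually tested.
  Populations with fewer than two variants are excluded with a warning.
* Bonferroni: min(1, m·p), m ≥ number of p-values.

## Synthetic data generator

The generator emulates: rare-variant MAF spectra (truncated exponential,
scale 5e-4 on (1e-5, 0.01), resembling a rarity-skewed gnomAD-like tail —
the exact shape is configurable and irrelevant to correctness);
per-population frequency scaling via multipliers with i.i.d. clipped
lognormal jitter (σ = 0.3, clipped at 2σ, so the expected ratio of
population means equals the multiplier ratio and every MAF stays below
0.01); Hardy–Weinberg parental genotypes from the family's population MAF
and Mendelian transmission to probands; planted in-trans pairs (father het
at v₁, mother het at v₂, proband het at both with opposite origins) in
⌊planted_fraction × n_case_families⌋ case families and, independently at
`control_planted_fraction` per family, among controls; and predictor
annotations that pass the damaging/conservation thresholds with
probability `predictor_damaging_rate` for planted variants (4–8 of 8
qualifying predictor calls, 2–4 of 4 strong conservation scores) and
`background_damaging_rate` for the rest (at most 1 of each, hence below
the 0.25/0.5 cut-offs), with scores drawn to straddle the thresholds.
De novo planting is off by default and available behind a flag.  Het calls
are written with alt-read fractions that pass the 4:10 QC rule by
construction; `qc_fail_rate` injects low-depth calls to exercise the QC
audit trail.

Default study conditions: 16 case families with planted fraction 3/16,
1,700 control families at 1.2% — the scale of the discovery and comparator
cohorts.  Defaults elsewhere: 5 genes × 30 variants, three populations
with equal multipliers, read depth 25–80×.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing/genotyping error, allele-frequency
estimation noise, linkage between variants, population substructure within
a labelled group, variant-calling artifacts, X-linked inheritance, and
annotation disagreement structure between predictors (calls are sampled
independently given the damaging state).  Identical seed + config produce
byte-identical output files; VCF INFO floats round-trip at float32
precision through the VCF parser (genotypes and depths round-trip
exactly).

## Numerical and design choices

* Percentages use decimal half-up rounding to one decimal, matching how
  cohort proportions are conventionally printed (3/16 → 18.8).
* Indel length is |len(ref) − len(alt)|, retained when ≤ 15; depth and
  allelic-ratio thresholds are strict (>10×, >4:10); CADD and conservation
  thresholds are strict; the two proportion cut-offs are non-strict.
* Monte-Carlo mating simulates in chunks of 250k replicates to bound
  memory; seeds accept numpy seed sequences.
* The Monte-Carlo agreement test uses single-variant frequencies between
  0.01 and 0.5 so that expected event counts at 10⁶ replicates are large
  enough for a 3-standard-error normal band to be a meaningful 99.7%
  criterion (at f ≈ 0.001 the event count is Poisson with mean ~1 and the
  band is not meaningful).
* Pipeline reports are deterministic under fixed config + seed: no
  timestamps, sorted JSON keys, and a provenance hash over analysis
  parameters only (filesystem paths excluded).
* Unphased (no-trio) probands carrying two qualifying variants are not
  counted as confirmed biallelic; only phase-confirmed in-trans and AR
  homozygous genotypes enter cohort proportions.  De novo events are
  reported but never counted in biallelic summaries.

## Problem sizes

The test suite runs cohorts of up to 16 case + 1,700 control trios with
150 variants across 5 genes (100 replicates for recovery/power checks,
1,000 table-level replicates for calibration), and 10⁶-replicate
Monte-Carlo runs; the full suite completes in about a minute on one CPU.
These sizes give exact planted-event recovery and rejection rates
estimated to ±2–5% — adequate for the ≥95% power and ≤5% type-I
criteria they check.

## Known limitations

* The closed-form P is implemented exactly as printed, including the
  missing factor 2 discussed above; users comparing observed cohorts to P
  should be aware the formula is ~4× smaller than the simulated mating
  probability and inspect the reported MC/formula ratio.
* The full-penetrance filter can only use genotyped relatives; ungenotyped
  unaffected carriers are invisible to it.
* Phasing uses parental genotypes only; population-LD statistical phasing
  is out of scope, so pairs in families without both parents remain
  ambiguous.
* Kinship verification, ancestry inference (PCA/MDS), and variant calling
  are upstream of this package; the PED file is trusted as given.
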