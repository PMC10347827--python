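# Methods

## The audit model

The audit treats a healthy reference cohort as a null population for
screened, highly penetrant recessive and X-linked disorders. An individual
is *indicated affected* at a snapshot date if, restricted to a chosen
variant set, they are

- **homozygous** for one set variant (both alleles alternate at a diploid
  site; females homozygous in X-linked genes count here too),
- **hemizygous** — a male with at least one alternate allele at a variant in
  an X-linked panel gene (pseudoautosomal regions are not modeled), or
- **compound heterozygous** — carrying two distinct set variants in the same
  gene with the alternate alleles on opposite haplotypes. Phase is required;
  an opt-in mode presumes trans phase for unphased pairs but is off by
  default because the intended cohorts are phased.

With an aggregate disorder incidence near 1/3200 (configurable), the
expected number of truly affected individuals in a 2 504-person cohort is
cohort_size × incidence ≈ 0.78 < 1, so indicated affected individuals are,
with high probability, evidence of variant misclassification rather than
disease. The assumption that matters is penetrance: the disorders must be
severe and early-onset enough that an affected adult could not plausibly
have enrolled healthy.

Four variant sets are audited per date. *Select* sets demand higher
curation confidence (ClinVar: class P with ≥ 1 review star; HGMD: DM);
*Full* sets take the broad pathogenic call (ClinVar: P or LP, aggregate
Conflicting excluded; HGMD: DM or DM?). Select ⊆ Full holds by construction
and is asserted in tests. Yearly burden is the maximum distinct-individual
count over the year's snapshots, and the false-positive proxy is
1000 × affected / cataloged variants, reported to one decimal.

## Classification ladders and harmonization

Snapshots arrive in three dialects. Numeric-coded archive VCFs map
0/2/3/4/5 → VUS/B/LB/LP/P; per-submission codes aggregate to Conflicting
when two or more of the groups {B, LB}, {VUS}, {P, LP} are present.
String-labelled archive VCFs carry aggregate labels; comma-separated
multi-labels resolve only when exactly one component is a recognized
category. Review-status strings group into 0, 1, or 2+ stars, with the
2+ group checked first so that a status naming both criteria provision and
multiple submitters counts as 2+. Star annotation in the numeric-coded era
is unreliable before 2015-06-15 (the configurable cutover): such entries
carry "stars unassessed", are excluded from star-dependent set selection,
and a per-variant star-override file can supply manually assessed values.
HGMD rows with multiple labels take the most severe under
DM > DM? > DFP > DP > R. Somatic-only records and null alternate alleles
are dropped; multiallelic records are split before normalization.

Variant identity is the minimal, left-aligned (chrom, pos, ref, alt):
shared trailing bases are trimmed, rotating the variant leftward through
the reference when trimming would empty an allele, then shared leading
bases are trimmed. The operation is idempotent and is verified against a
brute-force oracle that enumerates every equivalent VCF representation and
picks the shortest, leftmost one.

## Allele-frequency filtering and ancestry assignment

The stand-alone-benign criterion is applied with strict inequality
("MAF > 5%"): the 2015 rule removes variants whose *global* MAF exceeds
0.05 in any configured reference dataset; the 2018 revision also removes
variants exceeding 0.05 in any single continental population of the
population-resolved dataset, gated by a minimum allele count (default
2000 alleles — the only constraint of the revised rule that is
operationalized here). On tables whose global MAF is the sample-size
weighted mean of population MAFs, the 2018 removal set provably contains
the 2015 one (pigeonhole); this is a property test.

For ancestry-normalized analyses each variant is assigned the population
with its highest MAF, after flooring: population MAFs strictly below
1/(2·min population N) are set to zero (with default gnomAD v2.1 exome
sizes — 8128/17296/9197/56885/15308 — the floor is 1/(2·8128) ≈
6.152×10⁻⁵, the smallest observable African-ancestry frequency). All-zero
variants get no ancestry and leave the analysis. Exact MAF ties resolve to
the lexicographically first population label and are logged; ties are
measure-zero in real data but possible in synthetic fixtures.

## Exact inference

2×2 p-values use Fisher's exact test with the probability-mass two-sided
criterion (sum of fixed-margin tables no more probable than the observed
one); odds ratios are conditional maximum-likelihood estimates under the
noncentral hypergeometric likelihood, with central exact confidence
intervals inverting the tail probabilities at (1−level)/2 per side. These
choices reproduce R's `fisher.test`, which defined the published numbers;
scipy provides both primitives and full-enumeration oracles verify them in
the tests. Note the exact CI does not collapse onto the point estimate as
the level shrinks — discreteness leaves a limiting width — so the tested
property is monotone narrowing onto a neighbourhood of the estimate.

The 5×2 omnibus (per-ancestry affected vs cohort counts, or events vs
variant-months) uses Pearson's chi-squared without continuity correction
when every expected count exceeds 40; otherwise an exact probability-mass
test by full enumeration whenever the number of fixed-margin tables
(compositions of the smaller column total over rows, ≤ 2×10⁶ by default)
permits, else Monte Carlo with 10⁶ resamples under a fixed default seed
(20150615) using the (1 + hits)/(1 + B) estimator. Probability comparisons
carry a 10⁻⁷ relative tolerance to absorb floating-point noise in the
"no more probable than observed" criterion.

Follow-up protocol: a significant omnibus triggers one-sided per-population
2×2 tests of (population affected, other affected) against (population
cohort, other cohort) — the table construction consistent with the
published odds ratios. Zero-height bars and zero-event comparisons are not
tested. The Bonferroni divisor is the count of tests actually recorded in
the run's ledger, not a hard-coded constant; the published threshold
arises as 0.05/222 ≈ 2.25×10⁻⁴ (printed as 2.2×10⁻⁴).

## Recategorization and variant-months

Timelines are downsampled to one representative snapshot per calendar
month; the representative is the last snapshot of the month by default
(configurable: first | last | nearest-to-month-end) — the choice is
immaterial for already-monthly series. Events are adjacent category
changes on the monthly grid. Removal from the open archive is not an
event; re-entry under a different category emits one event from the
pre-removal category. A variant absent from a curated-catalog (HGMD-style)
snapshot after first appearing is treated as retired (R), so its removal
*is* a category change. Events in the open archive are only counted from
the star cutover (2015-06-15) onward. VUS and Conflicting are adjacent,
unordered levels: changes between them are recategorizations with neither
increasing nor decreasing confidence, while direction everywhere follows
the sign of the ladder-index change.

Exposure is measured in variant-months: one variant classified in one
monthly snapshot contributes one variant-month, summed within the analysis
window (default 2015-06-15 to 2020-12-31). Rates divide confidence-class
events (decreasing: P/LP∪B/LB → VUS/Conflicting; increasing: the reverse)
by the variant-months of the *source* categories, with Wald intervals
p ± 1.96·√(p(1−p)/n) clipped at zero. Cross-ancestry comparison runs the
5×2 omnibus on (events, variant-months) and all ordered-pair one-sided 2×2
tests; zero-exposure ancestries are excluded and logged. For comparisons
against star-free catalogs, helpers collapse star levels (so star-only
changes vanish) and restrict to the dates on which both databases were
sampled.

## The synthetic study generator

The generator's defaults encode the study conditions: a phased diploid
cohort in the five-continental composition 661 AFR / 347 AMR / 504 EAS /
503 EUR / 489 SAS (2 504 individuals), frequency tables with gnomAD v2.1
exome sample sizes, and snapshot series spanning 2016–2020. Planted
signals are recorded in a JSON ground-truth ledger: affected individuals
(one per requested mechanism × ancestry), recategorization transitions
(the variant carries the source category strictly before the transition
date and the target category from it onward), and stand-alone-benign
variants (derived arithmetically from the planted frequencies). Non-planted
samples receive pathogenic-classified alleles only as isolated
heterozygotes (default rate 0.01 per gene per sample, never in X-linked
genes for males), so they can never form a pathogenic genotype and ground
truth is exact. Male X genotypes are haploid; female genotypes and all
autosomes are phased diploid. Every generator is byte-deterministic for a
fixed seed.

The generator does **not** emulate linkage structure, realistic site
spectra, submission-level conditions beyond a single label per record,
archive metadata richness, or sequencing error. Passing tests therefore
demonstrate the pipeline's correctness on its defined contracts — not that
real archives are free of dialect quirks beyond those modeled.

## Problem sizes

The test suite uses cohorts of 50–140 individuals with 3–10 genes for
oracle-equivalence and end-to-end checks, plus one full-composition
(2 504-sample) sample-sheet check; enumeration oracles cover all 2×2
alternatives on tables with totals up to 30 and 5×2 tables with small
margins. The acceptance script runs the end-to-end audit on a full-size
2 504-individual synthetic cohort with 10 panel genes and 60 variant sites
across four variant sets and 13 snapshot dates. The whole suite completes
in well under a minute on one CPU.

## Known limitations

- The revised allele-frequency rule's "additional constraints" beyond the
  allele-count gate are not modeled.
- The per-variant star-override file replaces the manual star re-assessment
  that no automatic rule can replicate.
- Ancestry assignment is fixed per run from one frequency table; variants
  whose assignment would drift as reference panels grow keep their initial
  assignment.
- Comphet detection assumes biallelic sites after splitting; structural
  variants are out of scope.
- The Wald interval is anti-conservative at very low event counts; it is
  retained because it is the audit's published interval form.
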