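# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical choices a maintainer would want to know about.

## Inputs and coordinate conventions

The pipeline starts at *annotated* variant calls: population frequencies,
functional classes and predictor calls (SIFT, PolyPhen2 HVAR/HDIV,
MutationTaster, CADD, dbscSNV) are INFO fields of the input VCF, read under
an ANNOVAR-style key dialect that can be remapped per input. Upstream
alignment, calling and annotation are out of scope. All in-memory
coordinates are 1-based inclusive; BED masks (0-based half-open) are
converted at read time so a variant at 1-based position *p* is masked iff
some interval [start, end) has start < p ≤ end. Absent annotations stay
absent — filters declare their own missing-value policy rather than
imputing defaults. Float INFO values are normalized to 6 significant digits
on read because htslib stores them as float32; this matches annotation
tools' printed precision and makes write∘read the identity.

## Site QC

Calls are kept when depth > 4, RMS mapping quality > 30 and variant quality
> 20, all strict, all site-level (INFO DP/MQ and QUAL — the thresholds
describe site confidence, not per-sample genotype quality). A variant
missing any metric is rejected with reason `missing_metric`: unknown
quality is treated as unacceptable rather than acceptable. The rejection
log records the first criterion failed, in the fixed order depth, MQ, QUAL.

## Filter cascade

Stage order is QC → MAF → region/consequence → deleteriousness vote →
segregation. The first four stages are subset maps on independent
annotation fields, so MAF and region/consequence commute (a property the
suite checks); segregation needs genotypes and therefore runs last.

* **MAF.** A variant passes when its frequency is < 0.01 in *every*
  configured panel that reports it. Absence from all panels passes by
  default: a variant too rare for reference panels cannot exceed the
  threshold. The strict alternative (`missing_freq_policy="fail"`) exists
  for analyses that require positive evidence of rarity.
* **Region/consequence.** The splice window is 10 bp. Non-exonic
  splice-region variants farther than 2 bp from the junction additionally
  need a splice-effect score ≥ 0.6 (dbscSNV convention) — near-junction
  (≤ 2 bp) variants are kept unconditionally since they disrupt the
  canonical dinucleotides. Non-frameshift indels shorter than 10 bp inside
  repeat-masked sequence are discarded as likely alignment artifacts.
* **Vote.** Four voters, not five columns: PolyPhen's HVAR and HDIV models
  are one voter via OR, which is what makes "more than half of four"
  coherent with five reported score columns. Harmful calls: SIFT D;
  PolyPhen D or P; MutationTaster D or A; CADD phred ≥ 20 (a conventional
  cutoff; configurable — no published threshold accompanies the rule). The
  default `vote_harm_min=3` encodes "more than half of 4". A missing
  predictor counts as not-harmful by default. The vote is monotone: adding
  a harmful call can only raise the count.

Note on the packaged family fixture: its middle variant scores 2 of 4
(MutationTaster + CADD only) and is removed by the strict vote, breaking
the compound-het pair of one affected sister. The published carrier table
nevertheless retains it; which stage admitted it is not recoverable.
Reproducing the full family candidate therefore uses `vote_harm_min=2`,
and the report always records per-variant vote counts rather than silently
dropping loci.

## ACMG classification

Only the combining logic is implemented; evidence codes are caller-supplied
(how evidence was assigned for any particular variant is an input, not a
computation of this package). The rule table is transcribed literally:
Pathogenic = PVS1 + (≥1 PS | ≥2 PM | PM+PP | ≥2 PP), or ≥2 PS, or
PS + (≥3 PM | 2 PM + ≥2 PP | PM + ≥4 PP); Likely pathogenic = PVS1 + PM,
PS + 1–2 PM, PS + ≥2 PP, ≥3 PM, 2 PM + ≥2 PP, or PM + ≥4 PP; Benign = BA1
or ≥2 BS; Likely benign = BS + BP or ≥2 BP; anything else — including
simultaneous pathogenic- and benign-side hits — is uncertain significance.
The suite verifies the implementation against an independent flat
enumeration of the rule rows over thousands of evidence subsets.

## Segregation models

Per variant: *hom_recessive* requires every affected homozygous-alternate
and no unaffected homozygous-alternate; *dominant* requires every affected
to carry the alternate and every unaffected to carry none. Per gene:
*compound_het* requires every affected to carry ≥ 2 distinct heterozygous
variants in the gene and no unaffected to do so. When both parents of a
sample are genotyped the rule is phased by transmission: there must exist
two variants attributable to different parents (a parent can transmit a
variant it carries); two hets inherited in cis from one parent do not
qualify. Without parental links (as in the packaged family fixture, whose
internal kinship is unrecorded) the phase-free rule applies — affected
≥ 2 hets, unaffected ≤ 1. Missing genotypes never disqualify a candidate;
they mark it `incomplete`, because absence of data is not evidence of
non-segregation.

## IBD estimation

Identity-by-state counts (IBS 0/1/2 per site pair) are converted to IBD
state probabilities by the method of moments: expected IBS-class
probabilities conditional on IBD state are polynomial in the allele
frequency (e.g. P(IBS0 | IBD0) = 2p²q²), averaged over sites, and the
linear system is solved stage-wise (z0 from IBS0, z1 from the IBS1
residual, z2 as the remainder). When frequencies are *estimated* from a
finite reference sample of X chromosomes, each monomial is replaced by its
unbiased without-replacement estimator (p²q² → a(a−1)b(b−1)/X⁽⁴⁾ etc.) —
the finite-sample correction of the original moment estimator. The raw
solution can leave the simplex; negatives are clamped and the vector
renormalized, and PI_HAT = z1/2 + z2. A consequence worth knowing: for a
true parent–offspring pair (z = (0, 1, 0)) the clamped estimate is very
often exactly (0, 1, 0), so PI_HAT = 0.5 exactly, with occasional small
upward excursions when the z2 moment comes out positive.

Sites with frequency outside (0.01, 0.99) are excluded (degenerate
moments). Frequencies come from an explicit argument when the caller has
them (simulations know their truth); otherwise they are estimated from
pedigree founders, with a warning below 20 founders because the moments
become unstable. Declared parent–offspring pairs pass verification when
PI_HAT ∈ [0.45, 0.55] (the conventional acceptance band for first-degree
links); duplicates (~1) and unrelated substitutions (~0) fall far outside
it. Mendelian errors are counted per trio by exhaustive enumeration of
transmissible alleles.

## Association

The exposure is either carriage (≥ 1 alternate allele) or homozygosity.
Because the data are categorical, the module reports chi-square with and
without Yates continuity correction *and* the two-sided Fisher exact test
(sum of hypergeometric probabilities ≤ the observed table's), labelling
which one the headline `p_value` uses: Fisher whenever any expected cell
is < 5, chi-square otherwise. No single convention is asserted to be "the"
published one. Odds ratios apply the Haldane–Anscombe +0.5 correction when
a cell is zero. Percentages are rounded to one decimal for display only;
internal arithmetic keeps full precision. No multiple-testing correction is
applied across loci.

## Synthetic data

The fixtures are exact by construction and bit-identical across runs: the
family fixture encodes three heterozygous TTN missense variants (carriers
B1+B2, B1+B4+B5, B3+B5 among five members with B1 and B5 affected,
predictor strings D/D/D/D/24.0, T/B/B/D/20.2, T/P/D/D/23.7, and published
reference-panel frequencies 5.568e-5, 2.574e-3/1.92e-4, 3.269e-5 — all
below the 0.01 rarity threshold); the cohort fixtures encode the fixed
genotype counts of a 34-case/37-control comparison at RNF213 rs112735431
(8 vs 0 carriers), rs148731719 (4 vs 3) and the MMP3 5A/6A promoter indel,
modeled as a biallelic site with 6A as the alternate allele (cases
23/11/0, controls 2/35/0 for 6A6A/5A6A/5A5A). The per-population frequency
table's maxima are the published values; its remaining rows and the age-bin
carrier counts are synthetic filler, labelled as such in the docstring.

The simulators draw founder genotypes per site from Hardy-Weinberg at a
frequency sampled Uniform(0.2, 0.8) — chosen to keep sites informative for
IBD moments — and transmit one uniformly-chosen allele per parent per site.
Sites are independent: there is no linkage disequilibrium, no genotyping
error, no missingness unless injected, and no allele-frequency spectrum
realism. Passing tests on this substrate therefore demonstrate the
estimators' correctness under their own assumptions, not robustness to
real-exome artifacts (batch effects, LD between nearby exonic sites,
population stratification in association cohorts).

Problem sizes used by the suite and the acceptance script — 5,000 SNPs for
IBD estimates, 200 pedigrees for segregation recovery, 2,000 replicates
for the type-I-error check — are the package's chosen desk-scale defaults:
large enough that the stochastic checks sit many standard deviations from
their failure boundaries, small enough to run in seconds.

## Known limitations

* Compound-het phasing uses pedigree transmission only; read-backed
  phasing is out of scope, so a cis pair in a family without genotyped
  parents cannot be excluded.
* The IBD estimator is the classic moments method; it does not implement
  KING-robust kinship and inherits the moments method's sensitivity to
  allele-frequency misspecification.
* ACMG evidence assignment (the hard part of variant interpretation) is
  deliberately not automated.
* Multi-transcript HGVS strings are carried opaquely, never parsed.
* gVCF, BAM/FASTQ and CNV handling are out of scope; the pipeline begins
  and ends at annotated site-level calls.
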