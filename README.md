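# famtriage

Family-based whole-exome variant prioritization: from annotated variant
calls and a pedigree to candidate causal variants and genes.

## The problem

When a Mendelian-looking disease clusters in a family, whole-exome
sequencing of the family members yields tens of thousands of variant calls,
almost all of which are irrelevant. `famtriage` implements the standard
triage a clinical-genetics analyst performs to shrink that list to a
handful of candidates:

1. **Site QC** — keep calls with read depth > 4, RMS mapping quality > 30
   and variant quality > 20 (strict inequalities).
2. **Rarity** — keep variants with MAF < 0.01 in every reference panel that
   reports them (1000 Genomes, ESP6500, gnomAD all/EAS by default); absence
   from all panels counts as rarity.
3. **Region and consequence** — keep exonic variants and variants within
   10 bp of a splice junction; discard synonymous SNVs, short (< 10 bp)
   non-frameshift indels inside RepeatMasker repeats, and splice-region
   sites > 2 bp from the junction without splice-effect support
   (dbscSNV-style score ≥ 0.6).
4. **Deleteriousness vote** — four predictors vote: SIFT (D), PolyPhen
   (HVAR ∨ HDIV ∈ {D, P}), MutationTaster ({D, A}) and CADD (phred ≥ 20);
   a variant is retained when more than half (≥ 3 of 4 by default) call it
   harmful.
5. **Segregation** — per inheritance model, keep variants/genes whose
   genotypes co-segregate with affection status: homozygous-recessive,
   dominant, or compound-heterozygous (phase by parental transmission when
   pedigree links exist, the phase-free ≥2-hets rule otherwise).

Around the cascade the package provides:

- **ACMG classification** — the published combining rules reducing evidence
  codes (PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4, BP1–7) to the five-tier
  scale pathogenic … benign.
- **Relatedness verification** — PLINK-style method-of-moments IBD: from
  identity-by-state counts and allele frequencies, estimate (z0, z1, z2)
  and PI_HAT = z1/2 + z2; declared parent–offspring pairs must fall in the
  45–55 % sharing band. Mendelian-error counting per trio.
- **Case-control association** — carrier/genotype 2×2 tables with
  chi-square (± Yates) and two-sided Fisher exact tests, odds ratios with
  Haldane–Anscombe correction, allele-frequency tables, call-set
  concordance, and per-population frequency summaries.
- **Synthetic data** — deterministic fixtures (a five-member family with
  three heterozygous TTN missense variants; 34-case/37-control cohorts at
  RNF213/MMP3 loci) and seeded simulators (Hardy-Weinberg founders,
  Mendelian transmission, i.i.d. cohorts) used throughout the test suite.

## Worked example

```python
from famtriage import (
    make_family_fixture, run_cascade, deleteriousness_vote,
    make_cohort_fixture, genotype_association,
)
from famtriage.prioritize import FilterConfig

variants, genotypes, pedigree = make_family_fixture()
report = run_cascade(
    variants, genotypes, pedigree,
    FilterConfig(vote_harm_min=2),          # lenient 2-of-4 vote
    models=("compound_het", "hom_recessive", "dominant"),
)
print(report.stage_counts)
# {'input': 3, 'site_qc': 3, 'maf': 3, 'region_consequence': 3,
#  'deleteriousness': 3, 'segregation_compound_het': 3,
#  'segregation_hom_recessive': 0, 'segregation_dominant': 0}
print(report.candidate_genes)
# {'compound_het': ['TTN'], 'hom_recessive': [], 'dominant': []}
```

Under the compound-heterozygote model the two affected sisters each carry
two distinct heterozygous TTN variants while every unaffected relative
carries at most one — the classic recessive trans configuration:

```python
cand = report.models["compound_het"][0]
print({s: sorted(ks) for s, ks in cand.affected_carriers.items()})
# {'B1': ['2:179412799:C:T', '2:179466289:C:T'],
#  'B5': ['2:179466289:C:T', '2:179476144:C:T']}
```

The default strict 3-of-4 vote scores the three variants 4, 2 and 3
harmful calls respectively — the middle site (SIFT T, PolyPhen B/B,
MutationTaster D, CADD 20.2) is carried by only two voters, which is why
the example above relaxes `vote_harm_min` to 2 to keep the full
compound-het pattern in play:

```python
for v in variants:
    print(v.rsid, deleteriousness_vote(v, FilterConfig()))
# rs771533925 (4, 'harmful')
# rs559712998 (2, 'not_harmful')
# rs72677250 (3, 'harmful')
```

Case-control association on the cohort fixture:

```python
_, gm, labels = make_cohort_fixture("RNF213_rs112735431")
r = genotype_association(gm, labels, "carrier")
print(f"{r.case_rate:.1f}% vs {r.control_rate:.1f}%  OR={r.odds_ratio:.1f}  "
      f"fisher p={r.fisher_p:.4f}  test={r.test_used}")
# 23.5% vs 0.0%  OR=24.1  fisher p=0.0017  test=fisher
```

8 of 34 cases (23.5 %) carry the risk allele versus 0 of 37 controls; the
zero cell triggers the exact test and the Haldane–Anscombe-corrected odds
ratio.

## Command line

```bash
famtriage fixtures --out-dir fixtures/          # emit VCF/PED/TSV fixtures
famtriage prioritize --vcf family.vcf --ped family.ped \
    --model compound_het --vote-harm-min 2 --out report/
famtriage ibd --vcf cohort.vcf --ped cohort.ped --bounds 0.45,0.55
famtriage assoc --vcf cohort.vcf --labels labels.tsv --rule carrier
```

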