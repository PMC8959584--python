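"""Synthetic test inputs: exact desk-scale fixtures and seeded simulators.

Two kinds of data come out of this module. The *fixtures* are deterministic,
bit-identical encodings of the published family and cohort summaries this
package is exercised against: a five-member family (two affected sisters)
carrying three heterozygous missense variants in TTN, and a 34-case /
37-control cohort with fixed genotype counts at RNF213 and MMP3 loci. The
*simulators* generate pedigree genotypes under Hardy-Weinberg founders and
Mendelian transmission (independent sites, no linkage disequilibrium) and
i.i.d. case-control cohorts — the substrate for IBD, segregation and
association property tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    GENOTYPE_CODES,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AnnotatedVariant,
    GenotypeMatrix,
    Individual,
    Pedigree,
)

# ---------------------------------------------------------------------------
# family fixture: 3 het TTN missense variants across 5 samples (B1, B5 affected)

_TTN_VARIANTS = (
    # (pos, rsid, SIFT, HVAR, HDIV, MT, CADD, pop_freqs, het carriers)
    (179412799, "rs771533925", "D", "D", "D", "D", 24.0,
     {"gnomAD_EAS": 0.00005568}, ("B1", "B2")),
    (179466289, "rs559712998", "T", "B", "B", "D", 20.2,
     {"gnomAD_EAS": 0.002574, "gnomAD_ALL": 0.000192}, ("B1", "B4", "B5")),
    (179476144, "rs72677250", "T", "P", "D", "D", 23.7,
     {"gnomAD_SAS": 0.00003269}, ("B3", "B5")),
)

# plausible site QC metrics for a deep exome (mean coverage > 100x); synthetic,
# chosen only to clear the QC stage
_FIXTURE_QC = {"qual": 225.0, "depth": 120, "mq": 60.0}


def make_family_pedigree() -> Pedigree:
    """The five-member family: B1 and B5 affected females, B2-B4 unaffected males.

    Kinship links inside the family are not recorded (they are not
    recoverable from the published statuses alone), so compound-het
    selection on this fixture exercises the phase-free rule.
    """
    return Pedigree(
        [
            Individual("B1", sex="female", status="affected", family_id="FAM1"),
            Individual("B2", sex="male", status="unaffected", family_id="FAM1"),
            Individual("B3", sex="male", status="unaffected", family_id="FAM1"),
            Individual("B4", sex="male", status="unaffected", family_id="FAM1"),
            Individual("B5", sex="female", status="affected", family_id="FAM1"),
        ]
    )


def make_family_fixture() -> tuple[list[AnnotatedVariant], GenotypeMatrix, Pedigree]:
    """Deterministic family fixture: 3 TTN C>T variants x 5 samples.

    Heterozygous carriers are exactly {rs771533925: B1,B2},
    {rs559712998: B1,B4,B5}, {rs72677250: B3,B5}; all other calls hom_ref.
    """
    variants = []
    samples = ["B1", "B2", "B3", "B4", "B5"]
    calls = {}
    for pos, rsid, sift, hvar, hdiv, mt, cadd, freqs, carriers in _TTN_VARIANTS:
        v = AnnotatedVariant(
            chrom="2",
            pos=pos,
            ref="C",
            alt="T",
            rsid=rsid,
            gene="TTN",
            func_class="exonic",
            exonic_func="missense_SNV",
            pop_freqs=dict(freqs),
            predictor_calls={
                "SIFT": sift,
                "Polyphen2_HVAR": hvar,
                "Polyphen2_HDIV": hdiv,
                "MutationTaster": mt,
                "CADD": cadd,
            },
            **_FIXTURE_QC,
        )
        variants.append(v)
        for s in carriers:
            calls[(s, v.key)] = HET
    gm = GenotypeMatrix.from_calls(calls, samples, [v.key for v in variants])
    return variants, gm, make_family_pedigree()


# ---------------------------------------------------------------------------
# cohort fixtures: fixed genotype counts, 34 cases vs 37 controls

COHORT_KEYS = ("RNF213_rs112735431", "RNF213_rs148731719", "MMP3_rs3025058")

# genotype counts per group: (hom_ref, het, hom_alt)
_COHORT_COUNTS = {
    "RNF213_rs112735431": {
        "case": (26, 8, 0),
        "control": (37, 0, 0),
        "variant": ("17", 78319046, "C", "T", "rs112735431", "RNF213", "missense_SNV"),
    },
    "RNF213_rs148731719": {
        "case": (30, 4, 0),
        "control": (34, 3, 0),
        "variant": ("17", 78358945, "G", "A", "rs148731719", "RNF213", "missense_SNV"),
    },
    # MMP3 -1171 5A/6A promoter indel modeled as biallelic, 6A = alt:
    # cases 6A6A:23 5A6A:11 5A5A:0; controls 6A6A:2 5A6A:35 5A5A:0
    "MMP3_rs3025058": {
        "case": (0, 11, 23),
        "control": (0, 35, 2),
        "variant": ("11", 102715468, "A", "AA", "rs3025058", "MMP3", "nonframeshift_indel"),
    },
}


def make_cohort_fixture(
    key: str,
) -> tuple[list[AnnotatedVariant], GenotypeMatrix, dict[str, str]]:
    """Deterministic 71-sample case-control fixture for one locus.

    Returns (variants, genotypes, labels) with labels mapping each sample to
    'case' (C01..C34) or 'control' (N01..N37). Genotype counts per group are
    fixed; samples are assigned genotypes in id order (hom_alt first, then
    het), which is immaterial to any count-based statistic.
    """
    if key not in _COHORT_COUNTS:
        raise KeyError(f"unknown cohort fixture {key!r}; options: {COHORT_KEYS}")
    spec = _COHORT_COUNTS[key]
    chrom, pos, ref, alt, rsid, gene, exonic_func = spec["variant"]
    v = AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, rsid=rsid, gene=gene,
        func_class="exonic", exonic_func=exonic_func,
        **_FIXTURE_QC,
    )
    samples, genos, labels = [], [], {}
    for group, prefix, n in (("case", "C", 34), ("control", "N", 37)):
        hom_ref, het, hom_alt = spec[group]
        assert hom_ref + het + hom_alt == n
        codes = [HOM_ALT] * hom_alt + [HET] * het + [HOM_REF] * hom_ref
        for i, g in enumerate(codes, start=1):
            sid = f"{prefix}{i:02d}"
            samples.append(sid)
            genos.append(g)
            labels[sid] = group
    calls = np.array(genos, dtype=np.int8).reshape(-1, 1)
    gm = GenotypeMatrix(samples, [v.key], calls)
    return [v], gm, labels


def make_popfreq_fixture() -> pd.DataFrame:
    """Synthetic per-population / per-age frequency table for the TTN loci.

    The maximal per-population frequencies are the published reference-panel
    values (rs72677250 peaks in South Asians at 3.269e-5, rs559712998 in
    East Asians at 2.574e-3, rs771533925 in East Asians at 5.568e-5); the
    remaining populations and the age-bin carrier counts are synthetic
    filler shaped only to make the summaries well-defined.
    """
    rows = [
        ("rs72677250", "South_Asian", 0.00003269, None, None),
        ("rs72677250", "East_Asian", 0.0, None, None),
        ("rs72677250", "European", 0.0, None, None),
        ("rs72677250", "African", 0.0, None, None),
        ("rs559712998", "East_Asian", 0.002574, None, None),
        ("rs559712998", "South_Asian", 0.0000331, None, None),
        ("rs559712998", "European", 0.0, None, None),
        ("rs559712998", "African", 0.0, None, None),
        ("rs771533925", "East_Asian", 0.00005568, None, None),
        ("rs771533925", "South_Asian", 0.0, None, None),
        ("rs771533925", "European", 0.0, None, None),
        ("rs771533925", "African", 0.0, None, None),
        # age-bin carrier counts (synthetic): modal bins 50-55, 30-80 spread, 65-70
        ("rs72677250", "South_Asian", 0.00003269, "50-55", 3),
        ("rs72677250", "South_Asian", 0.00003269, "55-60", 1),
        ("rs559712998", "East_Asian", 0.002574, "30-80", 12),
        ("rs771533925", "East_Asian", 0.00005568, "65-70", 2),
        ("rs771533925", "East_Asian", 0.00005568, "40-45", 1),
    ]
    return pd.DataFrame(rows, columns=["variant_id", "population", "frequency", "age_bin", "carriers"])


def make_concordance_fixture() -> tuple[dict, dict]:
    """Two genotyping call sets (5 samples x 3 TTN loci) that agree everywhere.

    Derived from the family fixture genotypes: MUT for het/hom-alt carriers,
    WILD otherwise; both methods report identical columns.
    """
    variants, gm, _ = make_family_fixture()
    calls = {}
    for v in variants:
        for s in gm.sample_ids:
            calls[(s, v.rsid)] = "MUT" if gm.get(s, v.key) in (HET, HOM_ALT) else "WILD"
    return dict(calls), dict(calls)


# ---------------------------------------------------------------------------
# simulators


@dataclass(frozen=True)
class PedigreeSimConfig:
    """Pedigree genotype simulation: HW founders, Mendelian transmission."""

    pedigree: Pedigree
    n_snps: int = 5000
    freq_low: float = 0.2
    freq_high: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not (0.0 < self.freq_low <= self.freq_high < 1.0):
            raise ValueError("founder frequency support must lie inside (0, 1)")


def simulate_pedigree_genotypes(
    config: PedigreeSimConfig, return_freqs: bool = False
):
    """Simulate independent biallelic sites through a pedigree.

    Founder haplotypes are drawn per site from Hardy-Weinberg at an
    allele frequency sampled Uniform(freq_low, freq_high); each non-founder
    inherits one allele from each parent, chosen uniformly and independently
    per site, so transmission is Mendelian by construction. A sample with
    exactly one recorded parent is treated as founder on the missing side.
    Reproducible under a fixed seed.
    """
    import warnings as _warnings

    ped = config.pedigree
    rng = np.random.default_rng(config.seed)
    freqs = rng.uniform(config.freq_low, config.freq_high, size=config.n_snps)
    order = ped.topological_order()
    # haplotypes[sample] = (n_snps, 2) alleles in {0,1}
    haplotypes: dict[str, np.ndarray] = {}
    for sid in order:
        f, m = ped.parents_of(sid)
        if f is None and m is None:
            hap = (rng.random((config.n_snps, 2)) < freqs[:, None]).astype(np.int8)
        else:
            if f is None or m is None:
                _warnings.warn(
                    f"{sid} has one recorded parent; the missing side is drawn as founder",
                    stacklevel=2,
                )
            cols = []
            for parent in (f, m):
                if parent is None:
                    cols.append((rng.random(config.n_snps) < freqs).astype(np.int8))
                else:
                    pick = rng.integers(0, 2, size=config.n_snps)
                    cols.append(haplotypes[parent][np.arange(config.n_snps), pick])
            hap = np.stack(cols, axis=1)
        haplotypes[sid] = hap
    samples = list(order)
    calls = np.stack([haplotypes[s].sum(axis=1) for s in samples]).astype(np.int8)
    keys = [f"sim:{i + 1}:A:G" for i in range(config.n_snps)]
    gm = GenotypeMatrix(samples, keys, calls)
    if return_freqs:
        return gm, freqs
    return gm


INJECTION_MODELS = ("hom_recessive", "compound_het", "dominant")


def inject_candidate(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    model: str,
    gene: str = "GENE1",
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[AnnotatedVariant]]:
    """Add variant site(s) in ``gene`` segregating perfectly under ``model``.

    hom_recessive: one site, affected hom_alt, unaffected het (<= 1 alt
    allele). dominant: one site, affected het, unaffected hom_ref.
    compound_het: two sites; each affected het at both, each unaffected het
    at at most one (alternating sites across unaffecteds). Returns the
    extended matrix and the injected annotated variants.
    """
    if model not in INJECTION_MODELS:
        raise ValueError(f"unknown model {model!r}")
    affected = [s for s in pedigree.affected if s in genotypes.sample_ids]
    unaffected = [s for s in pedigree.unaffected if s in genotypes.sample_ids]
    if not affected:
        raise ValueError(f"model {model!r} unachievable: pedigree has no affected sample")
    rng = np.random.default_rng(seed)
    chrom = "99"
    base = 1_000_000 + int(rng.integers(0, 1000)) * 10
    n_sites = 2 if model == "compound_het" else 1
    cols = np.zeros((len(genotypes.sample_ids), n_sites), dtype=np.int8)
    idx = {s: i for i, s in enumerate(genotypes.sample_ids)}
    if model == "hom_recessive":
        for s in affected:
            cols[idx[s], 0] = HOM_ALT
        for s in unaffected:
            cols[idx[s], 0] = HET
    elif model == "dominant":
        for s in affected:
            cols[idx[s], 0] = HET
    else:  # compound_het
        for s in affected:
            cols[idx[s], :] = HET
        for j, s in enumerate(unaffected):
            cols[idx[s], j % 2] = HET
    variants = [
        AnnotatedVariant(
            chrom=chrom,
            pos=base + j,
            ref="C",
            alt="T",
            gene=gene,
            func_class="exonic",
            exonic_func="missense_SNV",
            predictor_calls={
                "SIFT": "D", "Polyphen2_HVAR": "D", "Polyphen2_HDIV": "D",
                "MutationTaster": "D", "CADD": 25.0,
            },
            **_FIXTURE_QC,
        )
        for j in range(n_sites)
    ]
    new_calls = np.concatenate([genotypes.calls, cols], axis=1)
    new_keys = genotypes.variant_keys + [v.key for v in variants]
    return GenotypeMatrix(genotypes.sample_ids, new_keys, new_calls), variants


@dataclass(frozen=True)
class CohortSimConfig:
    """Case-control cohort simulation at one biallelic site."""

    n_cases: int = 34
    n_controls: int = 37
    case_probs: tuple[float, float, float] = (0.7, 0.25, 0.05)  # hom_ref, het, hom_alt
    control_probs: tuple[float, float, float] = (0.7, 0.25, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be >= 0")
        for name in ("case_probs", "control_probs"):
            p = getattr(self, name)
            if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be 3 non-negative probabilities summing to 1")


def simulate_cohort(config: CohortSimConfig) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Draw genotypes i.i.d. per group from the configured genotype probabilities."""
    rng = np.random.default_rng(config.seed)
    samples, genos, labels = [], [], {}
    for group, prefix, n, probs in (
        ("case", "C", config.n_cases, config.case_probs),
        ("control", "N", config.n_controls, config.control_probs),
    ):
        draws = rng.choice([HOM_REF, HET, HOM_ALT], size=n, p=probs)
        for i, g in enumerate(draws, start=1):
            sid = f"{prefix}{i:03d}"
            samples.append(sid)
            genos.append(g)
            labels[sid] = group
    calls = np.array(genos, dtype=np.int8).reshape(-1, 1)
    gm = GenotypeMatrix(samples, ["sim:1:A:G"], calls)
    return gm, labels
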