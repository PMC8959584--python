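"""The candidate-selection cascade.

Order of stages: site QC -> rarity (MAF across reference panels) -> region
and consequence class -> four-predictor deleteriousness vote -> inheritance-
model segregation across the pedigree. Each stage returns a subset of its
input; the cascade report records per-stage counts so every drop is
attributable.

The deleteriousness rule is a consensus vote of four predictors — SIFT,
PolyPhen (HVAR and HDIV combined as one voter), MutationTaster and CADD —
with a variant kept when more than half of them (>= 3 of 4 by default) call
it harmful.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .acmg import EvidenceSet, acmg_classify
from .model import HET, HOM_ALT, HOM_REF, MISSING, AnnotatedVariant, GenotypeMatrix, Pedigree
from .qc import QcThresholds, site_qc_filter
from .variant_io import RepeatMask

DEFAULT_MAF_DATABASES = ("1000g2015aug_all", "esp6500siv2_all", "gnomAD_ALL", "gnomAD_EAS")

SEGREGATION_MODELS = ("hom_recessive", "compound_het", "dominant")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and policies of the filter cascade.

    ``missing_freq_policy`` / ``missing_predictor_policy`` decide how a
    filter treats an absent annotation: ``pass`` treats absence from a
    reference panel as evidence of rarity (and a missing predictor as a
    not-harmful vote), ``fail`` is the strict alternative.
    """

    maf_threshold: float = 0.01
    maf_databases: tuple[str, ...] = DEFAULT_MAF_DATABASES
    splice_window_bp: int = 10
    repeat_indel_max_len: int = 10  # exclusive: indels shorter than this, in repeats, drop
    vote_harm_min: int = 3
    cadd_harm_threshold: float = 20.0
    splice_score_threshold: float = 0.6
    splice_exonic_distance_bp: int = 2  # beyond this, non-exonic sites need splice support
    missing_freq_policy: str = "pass"
    missing_predictor_policy: str = "fail"

    def __post_init__(self) -> None:
        if not 0 <= self.maf_threshold <= 1:
            raise ValueError("maf_threshold must be in [0, 1]")
        if self.vote_harm_min > 4:
            raise ValueError("vote_harm_min cannot exceed the 4 predictors")
        if self.missing_freq_policy not in ("pass", "fail"):
            raise ValueError("missing_freq_policy must be 'pass' or 'fail'")
        if self.missing_predictor_policy not in ("pass", "fail"):
            raise ValueError("missing_predictor_policy must be 'pass' or 'fail'")


def maf_filter(
    variants: list[AnnotatedVariant], config: FilterConfig = FilterConfig()
) -> list[AnnotatedVariant]:
    """Keep variants rare (frequency < threshold) in every configured panel.

    Only panels with a recorded value constrain the variant; a variant
    absent from all panels follows ``missing_freq_policy`` (default: kept,
    since absence from reference panels cannot exceed the threshold).
    """
    if not config.maf_databases:
        raise ValueError("maf_filter requires at least one database")
    kept = []
    for v in variants:
        freqs = [v.pop_freqs[db] for db in config.maf_databases if db in v.pop_freqs]
        if not freqs:
            if config.missing_freq_policy == "pass":
                kept.append(v)
            continue
        if all(f < config.maf_threshold for f in freqs):
            kept.append(v)
    return kept


def region_consequence_filter(
    variants: list[AnnotatedVariant],
    config: FilterConfig = FilterConfig(),
    repeat_mask: RepeatMask | None = None,
) -> list[AnnotatedVariant]:
    """Keep exonic and splice-junction variants with a relevant consequence.

    Rules, in order: (1) keep only variants in exons or within
    ``splice_window_bp`` of a splice junction; (2) drop synonymous SNVs;
    (3) drop non-frameshift indels shorter than ``repeat_indel_max_len``
    falling in repeat-masked sequence; (4) non-exonic splice-region variants
    farther than ``splice_exonic_distance_bp`` from the junction must show a
    splice-effect score >= ``splice_score_threshold``.
    """
    if repeat_mask is not None:
        variants = apply_repeat_mask(variants, repeat_mask)
    kept = []
    for v in variants:
        near_splice = (
            v.splice_distance_bp is not None and v.splice_distance_bp <= config.splice_window_bp
        )
        if not (v.is_exonic or near_splice):
            continue
        if v.exonic_func == "synonymous_SNV":
            continue
        if (
            v.exonic_func == "nonframeshift_indel"
            and v.in_repeat
            and v.indel_length < config.repeat_indel_max_len
        ):
            continue
        if (
            not v.is_exonic
            and v.splice_distance_bp is not None
            and v.splice_distance_bp > config.splice_exonic_distance_bp
        ):
            if v.splice_effect_score is None or v.splice_effect_score < config.splice_score_threshold:
                continue
        kept.append(v)
    return kept


def apply_repeat_mask(
    variants: list[AnnotatedVariant], repeat_mask: RepeatMask
) -> list[AnnotatedVariant]:
    """Return variants with ``in_repeat`` set from mask membership."""
    out = []
    for v in variants:
        flag = (v.chrom, v.pos) in repeat_mask
        if flag != v.in_repeat:
            v = AnnotatedVariant(**{**v.__dict__, "in_repeat": flag})
        out.append(v)
    return out


_SIFT_HARM = {"D"}
_POLYPHEN_HARM = {"D", "P"}
_MT_HARM = {"D", "A"}
_SIFT_KNOWN = {"D", "T", "."}
_POLYPHEN_KNOWN = {"D", "P", "B", "."}
_MT_KNOWN = {"D", "A", "N", "P", "."}


def deleteriousness_vote(
    variant: AnnotatedVariant, config: FilterConfig = FilterConfig()
) -> tuple[int, str]:
    """Count harmful calls among the four predictors and apply the vote rule.

    Voters: SIFT (harmful on D/deleterious), PolyPhen — the HVAR and HDIV
    models OR-ed into a single voter (harmful on D/probably or P/possibly
    damaging), MutationTaster (harmful on D/disease-causing or
    A/disease-causing-automatic) and CADD (harmful at phred >=
    ``cadd_harm_threshold``). Returns ``(harm_count, verdict)`` with verdict
    ``harmful`` iff harm_count >= ``vote_harm_min``.
    """
    calls = variant.predictor_calls
    missing_harm = config.missing_predictor_policy == "pass"

    def categorical(keys: tuple[str, ...], harm: set, known: set) -> bool:
        votes = []
        for k in keys:
            if k not in calls:
                continue
            c = str(calls[k])
            if c not in known:
                raise ValueError(f"unknown {k} code {c!r} at {variant.key}")
            votes.append(c in harm)
        if not votes:
            return missing_harm
        return any(votes)

    harm_count = 0
    harm_count += categorical(("SIFT",), _SIFT_HARM, _SIFT_KNOWN)
    harm_count += categorical(("Polyphen2_HVAR", "Polyphen2_HDIV"), _POLYPHEN_HARM, _POLYPHEN_KNOWN)
    harm_count += categorical(("MutationTaster",), _MT_HARM, _MT_KNOWN)
    if "CADD" in calls:
        harm_count += float(calls["CADD"]) >= config.cadd_harm_threshold
    else:
        harm_count += missing_harm
    verdict = "harmful" if harm_count >= config.vote_harm_min else "not_harmful"
    return harm_count, verdict


@dataclass
class GeneCandidate:
    """One gene (or single-variant locus) qualifying under a segregation model."""

    gene: str
    model: str
    variant_keys: list[str]
    affected_carriers: dict[str, list[str]]  # affected sample -> qualifying variant keys
    incomplete: bool = False


def segregation_select(
    variants: list[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    model: str,
) -> list[GeneCandidate]:
    """Select variants/genes whose genotypes segregate with affection status.

    Models: ``hom_recessive`` — every affected homozygous-alternate, no
    unaffected homozygous-alternate; ``dominant`` — every affected carries
    the alternate allele, no unaffected does; ``compound_het`` — per gene,
    every affected carries two or more distinct heterozygous variants (with
    parental links, demonstrably transmitted from different parents) and no
    unaffected does (phase-free: unaffected carry at most one). A missing
    genotype in a decision-relevant sample never disqualifies but flags the
    candidate ``incomplete``.
    """
    if model not in SEGREGATION_MODELS:
        raise ValueError(f"unknown segregation model {model!r}")
    if len(pedigree) == 0:
        raise ValueError("empty pedigree")
    affected = [s for s in pedigree.affected if s in genotypes.sample_ids]
    unaffected = [s for s in pedigree.unaffected if s in genotypes.sample_ids]
    if not affected:
        raise ValueError("pedigree has no genotyped affected sample")

    if model == "compound_het":
        return _compound_het_select(variants, genotypes, pedigree, affected, unaffected)

    out: dict[str, GeneCandidate] = {}
    for v in variants:
        col = {s: genotypes.get(s, v.key) for s in affected + unaffected}
        incomplete = any(g == MISSING for g in col.values())
        if model == "hom_recessive":
            ok_aff = all(col[s] in (HOM_ALT, MISSING) for s in affected)
            ok_un = all(col[s] != HOM_ALT for s in unaffected)
        else:  # dominant
            ok_aff = all(col[s] in (HET, HOM_ALT, MISSING) for s in affected)
            ok_un = all(col[s] in (HOM_REF, MISSING) for s in unaffected)
        if ok_aff and ok_un:
            gene = v.gene or v.key
            cand = out.setdefault(gene, GeneCandidate(gene, model, [], {s: [] for s in affected}))
            cand.variant_keys.append(v.key)
            for s in affected:
                if col[s] != MISSING:
                    cand.affected_carriers[s].append(v.key)
            cand.incomplete = cand.incomplete or incomplete
    return list(out.values())


def _het_keys(genotypes: GenotypeMatrix, sample: str, keys: list[str]) -> list[str]:
    return [k for k in keys if genotypes.get(sample, k) == HET]


def _missing_keys(genotypes: GenotypeMatrix, sample: str, keys: list[str]) -> list[str]:
    return [k for k in keys if genotypes.get(sample, k) == MISSING]


def _phased_compound_het(
    genotypes: GenotypeMatrix, pedigree: Pedigree, sample: str, keys: list[str]
) -> bool | None:
    """True/False when both parents are genotyped, else None (phase unknowable)."""
    f, m = pedigree.parents_of(sample)
    if f is None or m is None or f not in genotypes.sample_ids or m not in genotypes.sample_ids:
        return None
    hets = _het_keys(genotypes, sample, keys)

    def parent_can_transmit(parent: str, k: str) -> bool:
        g = genotypes.get(parent, k)
        return g in (HET, HOM_ALT, MISSING)

    from_father = {k for k in hets if parent_can_transmit(f, k)}
    from_mother = {k for k in hets if parent_can_transmit(m, k)}
    # need two distinct variants assignable to distinct parents
    for k1 in from_father:
        if from_mother - {k1}:
            return True
    return False


def _compound_het_select(variants, genotypes, pedigree, affected, unaffected):
    by_gene: dict[str, list[str]] = {}
    for v in variants:
        by_gene.setdefault(v.gene or v.key, []).append(v.key)
    out = []
    for gene, keys in by_gene.items():
        incomplete = False
        ok = True
        carriers: dict[str, list[str]] = {}
        for s in affected:
            phased = _phased_compound_het(genotypes, pedigree, s, keys)
            hets = _het_keys(genotypes, s, keys)
            miss = _missing_keys(genotypes, s, keys)
            if phased is not None:
                qualifies = phased
            else:
                qualifies = len(hets) >= 2
            if not qualifies and len(hets) + len(miss) >= 2 and miss:
                qualifies, incomplete = True, True  # missing calls could complete the pair
            if not qualifies:
                ok = False
                break
            carriers[s] = hets
        if not ok:
            continue
        for s in unaffected:
            phased = _phased_compound_het(genotypes, pedigree, s, keys)
            hets = _het_keys(genotypes, s, keys)
            if phased is True or (phased is None and len(hets) >= 2):
                ok = False
                break
            if _missing_keys(genotypes, s, keys):
                incomplete = True  # unobserved calls cannot disqualify, but note them
        if ok:
            out.append(GeneCandidate(gene, "compound_het", keys, carriers, incomplete))
    return out


@dataclass
class CascadeReport:
    """Per-stage counts and the surviving candidates of one cascade run."""

    stage_counts: dict[str, int]
    models: dict[str, list[GeneCandidate]]
    final_variants: list[AnnotatedVariant]
    vote_results: dict[str, tuple[int, str]]  # variant key -> (harm_count, verdict)
    acmg_classes: dict[str, str]
    qc_rejections: list = field(default_factory=list)

    @property
    def candidate_genes(self) -> dict[str, list[str]]:
        return {m: sorted({c.gene for c in cands}) for m, cands in self.models.items()}


def run_cascade(
    variants: list[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    config: FilterConfig = FilterConfig(),
    repeat_mask: RepeatMask | None = None,
    models: tuple[str, ...] = ("compound_het",),
    qc_thresholds: QcThresholds = QcThresholds(),
    evidence: dict[str, EvidenceSet] | None = None,
) -> CascadeReport:
    """Run the full filter cascade and segregation selection.

    ACMG evidence, when supplied per variant key, is combined into a class
    for each surviving variant; variants without evidence are reported as
    uncertain_significance.
    """
    counts = {"input": len(variants)}
    kept, rejections = site_qc_filter(variants, qc_thresholds)
    counts["site_qc"] = len(kept)
    kept = maf_filter(kept, config)
    counts["maf"] = len(kept)
    kept = region_consequence_filter(kept, config, repeat_mask)
    counts["region_consequence"] = len(kept)
    votes = {v.key: deleteriousness_vote(v, config) for v in kept}
    kept = [v for v in kept if votes[v.key][1] == "harmful"]
    counts["deleteriousness"] = len(kept)

    model_hits: dict[str, list[GeneCandidate]] = {}
    for model in models:
        if kept:
            model_hits[model] = segregation_select(kept, genotypes, pedigree, model)
        else:
            model_hits[model] = []
        counts[f"segregation_{model}"] = sum(len(c.variant_keys) for c in model_hits[model])

    evidence = evidence or {}
    acmg = {
        v.key: acmg_classify(evidence.get(v.key, EvidenceSet()))
        for v in kept
    }
    return CascadeReport(
        stage_counts=counts,
        models=model_hits,
        final_variants=kept,
        vote_results={k: votes[k] for k in (v.key for v in kept)},
        acmg_classes=acmg,
        qc_rejections=rejections,
    )
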