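"""Readers and writers for the formats the pipeline touches.

Annotated VCF 4.2 (sites + per-sample genotypes, ANNOVAR-style INFO keys),
6-column PED pedigrees, BED3 repeat masks and TSV population-frequency
tables. Text-table readers accept gzip; VCF compression must be BGZF (the
standard ``.vcf.gz``).

Coordinate conventions: VCF and all in-memory types are 1-based inclusive;
BED is 0-based half-open and converted on read, so a variant at 1-based
position ``p`` falls in interval ``[start, end)`` iff ``start < p <= end``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .model import (
    EXONIC_FUNCS,
    FUNC_CLASSES,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AnnotatedVariant,
    GenotypeMatrix,
    Individual,
    Pedigree,
)


class VcfParseError(ValueError):
    """Raised for malformed VCF content; carries the offending record when known."""


@dataclass(frozen=True)
class AnnotationDialect:
    """Maps annotation fields of :class:`AnnotatedVariant` to VCF INFO keys.

    The defaults follow ANNOVAR output column names; override any entry to
    read VCFs annotated with a different convention.
    """

    gene: str = "Gene.refGene"
    func_class: str = "Func.refGene"
    exonic_func: str = "ExonicFunc.refGene"
    hgvs: str = "AAChange.refGene"
    sift: str = "SIFT_pred"
    polyphen_hvar: str = "Polyphen2_HVAR_pred"
    polyphen_hdiv: str = "Polyphen2_HDIV_pred"
    mutation_taster: str = "MutationTaster_pred"
    cadd: str = "CADD_phred"
    splice_effect: str = "dbscSNV_ADA_SCORE"
    splice_distance: str = "SPLICE_DIST"
    in_repeat: str = "IN_REPEAT"
    depth: str = "DP"
    mq: str = "MQ"
    #: population-frequency databases: field name -> INFO key
    freq_dbs: dict[str, str] = field(
        default_factory=lambda: {
            "1000g2015aug_all": "1000g2015aug_all",
            "esp6500siv2_all": "esp6500siv2_all",
            "gnomAD_ALL": "gnomAD_ALL",
            "gnomAD_EAS": "gnomAD_EAS",
            "gnomAD_SAS": "gnomAD_SAS",
        }
    )


DEFAULT_DIALECT = AnnotationDialect()

# ANNOVAR escapes ';' inside INFO values; we follow the same convention.
_SEMI = "\\x3b"


def _encode_info(s: str) -> str:
    return s.replace(";", _SEMI).replace(" ", "_")


def _decode_info(s: str) -> str:
    return s.replace(_SEMI, ";")


def _round6(x: float) -> float:
    """Normalize a float32 INFO value back to 6 significant digits."""
    return float(f"{x:.6g}")


def _exonic_func_from_annovar(s: str) -> str:
    s = _decode_info(s).replace(" ", "_")
    aliases = {
        "nonsynonymous_SNV": "missense_SNV",
        "missense_SNV": "missense_SNV",
        "synonymous_SNV": "synonymous_SNV",
        "stopgain": "stopgain",
        "stoploss": "stoploss",
        "frameshift_insertion": "frameshift_indel",
        "frameshift_deletion": "frameshift_indel",
        "frameshift_indel": "frameshift_indel",
        "nonframeshift_insertion": "nonframeshift_indel",
        "nonframeshift_deletion": "nonframeshift_indel",
        "nonframeshift_indel": "nonframeshift_indel",
        "unknown": "unknown",
        ".": "none",
        "none": "none",
    }
    return aliases.get(s, "unknown")


def _func_class_from_annovar(s: str) -> str:
    s = _decode_info(s)
    if s in FUNC_CLASSES:
        return s
    if s.startswith("UTR"):
        return "UTR"
    if s in ("upstream", "downstream", "ncRNA_exonic", "ncRNA_intronic"):
        return "other"
    return "other"


def read_annotated_vcf(
    path, dialect: AnnotationDialect = DEFAULT_DIALECT
) -> tuple[list[AnnotatedVariant], GenotypeMatrix]:
    """Read an annotated VCF into domain types.

    Multi-allelic records are split into one :class:`AnnotatedVariant` per
    ALT allele; each sample's genotype for a split allele is the count of
    that allele in the GT field (0 -> hom_ref, 1 -> het, 2 -> hom_alt,
    uncalled -> missing). Absent annotations stay absent — no defaults are
    fabricated.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as e:
        raise VcfParseError(f"cannot open VCF {path}: {e}") from e
    samples = list(vf.header.samples)
    if not samples:
        raise VcfParseError(f"{path}: no sample columns — the pipeline requires genotypes")

    variants: list[AnnotatedVariant] = []
    columns: list[np.ndarray] = []
    d = dialect
    for lineno, rec in enumerate(vf, start=1):
        info = rec.info
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            try:
                v = _variant_from_record(rec, alt, info, d)
            except (ValueError, KeyError) as e:
                raise VcfParseError(
                    f"{path}: malformed record #{lineno} at {rec.chrom}:{rec.pos}: {e}"
                ) from e
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for si, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                col[si] = sum(1 for a in gt if a == ai)
            variants.append(v)
            columns.append(col)
    vf.close()
    calls = (
        np.stack(columns, axis=1) if columns else np.zeros((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(samples, [v.key for v in variants], calls)
    return variants, gm


def _variant_from_record(rec, alt: str, info, d: AnnotationDialect) -> AnnotatedVariant:
    def get_str(key):
        if key in info:
            val = info[key]
            if isinstance(val, tuple):
                val = val[0]
            return _decode_info(str(val))
        return None

    def get_float(key):
        if key in info:
            val = info[key]
            if isinstance(val, tuple):
                val = val[0]
            return _round6(float(val))
        return None

    pop_freqs = {}
    for db, key in d.freq_dbs.items():
        f = get_float(key)
        if f is not None:
            pop_freqs[db] = f

    predictor_calls: dict[str, object] = {}
    for name, key in (
        ("SIFT", d.sift),
        ("Polyphen2_HVAR", d.polyphen_hvar),
        ("Polyphen2_HDIV", d.polyphen_hdiv),
        ("MutationTaster", d.mutation_taster),
    ):
        call = get_str(key)
        if call is not None and call != ".":
            predictor_calls[name] = call
    cadd = get_float(d.cadd)
    if cadd is not None:
        predictor_calls["CADD"] = cadd

    func_raw = get_str(d.func_class)
    exonic_raw = get_str(d.exonic_func)
    splice_dist = info.get(d.splice_distance) if d.splice_distance in info else None
    if isinstance(splice_dist, tuple):
        splice_dist = splice_dist[0]

    return AnnotatedVariant(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alt=alt,
        rsid=rec.id,
        gene=get_str(d.gene),
        func_class=_func_class_from_annovar(func_raw) if func_raw is not None else "other",
        exonic_func=_exonic_func_from_annovar(exonic_raw) if exonic_raw is not None else "none",
        splice_distance_bp=int(splice_dist) if splice_dist is not None else None,
        pop_freqs=pop_freqs,
        predictor_calls=predictor_calls,
        splice_effect_score=get_float(d.splice_effect),
        qual=rec.qual,
        depth=get_float(d.depth),
        mq=get_float(d.mq),
        in_repeat=d.in_repeat in info,
        hgvs=get_str(d.hgvs),
    )


def write_annotated_vcf(
    variants: list[AnnotatedVariant],
    genotypes: GenotypeMatrix | None,
    path,
    dialect: AnnotationDialect = DEFAULT_DIALECT,
) -> None:
    """Write domain types to a VCF 4.2 file (one biallelic record per variant).

    The header declares every INFO key the dialect can emit; absent
    annotations are omitted from INFO entirely. ``read_annotated_vcf`` on the
    output reproduces the inputs.
    """
    d = dialect
    header = pysam.VariantHeader()
    header.formats.add("GT", "1", "String", "Genotype")
    for chrom in dict.fromkeys(v.chrom for v in variants):
        header.contigs.add(chrom)
    str_keys = [d.gene, d.func_class, d.exonic_func, d.hgvs, d.sift, d.polyphen_hvar,
                d.polyphen_hdiv, d.mutation_taster]
    float_keys = [d.cadd, d.splice_effect, d.mq, *d.freq_dbs.values()]
    for k in str_keys:
        header.info.add(k, "1", "String", "annotation")
    for k in float_keys:
        header.info.add(k, "1", "Float", "annotation")
    header.info.add(d.depth, "1", "Integer", "site read depth")
    header.info.add(d.splice_distance, "1", "Integer", "distance to nearest splice junction (bp)")
    header.info.add(d.in_repeat, "0", "Flag", "site falls in a repeat-masked region")
    sample_ids = genotypes.sample_ids if genotypes is not None else []
    for s in sample_ids:
        header.add_sample(s)

    gt_of = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
                id=v.rsid,
            )
            rec.qual = v.qual
            if v.depth is not None:
                rec.info[d.depth] = int(v.depth)
            if v.mq is not None:
                rec.info[d.mq] = float(v.mq)
            if v.gene is not None:
                rec.info[d.gene] = _encode_info(v.gene)
            rec.info[d.func_class] = _encode_info(v.func_class)
            rec.info[d.exonic_func] = _encode_info(v.exonic_func)
            if v.hgvs is not None:
                rec.info[d.hgvs] = _encode_info(v.hgvs)
            for name, key in (
                ("SIFT", d.sift),
                ("Polyphen2_HVAR", d.polyphen_hvar),
                ("Polyphen2_HDIV", d.polyphen_hdiv),
                ("MutationTaster", d.mutation_taster),
            ):
                if name in v.predictor_calls:
                    rec.info[key] = _encode_info(str(v.predictor_calls[name]))
            if "CADD" in v.predictor_calls:
                rec.info[d.cadd] = float(v.predictor_calls["CADD"])
            for db, f in v.pop_freqs.items():
                if db in d.freq_dbs:
                    rec.info[d.freq_dbs[db]] = float(f)
            if v.splice_effect_score is not None:
                rec.info[d.splice_effect] = float(v.splice_effect_score)
            if v.splice_distance_bp is not None:
                rec.info[d.splice_distance] = int(v.splice_distance_bp)
            if v.in_repeat:
                rec.info[d.in_repeat] = True
            if genotypes is not None:
                col = genotypes.variant_column(v.key)
                for s, g in zip(sample_ids, col):
                    rec.samples[s]["GT"] = gt_of[int(g)]
            out.write(rec)


_SEX = {"1": "male", "2": "female"}
_STATUS = {"1": "unaffected", "2": "affected"}


def read_pedigree(path) -> Pedigree:
    """Read a whitespace-delimited 6-column PED file.

    Columns: family, individual, father, mother, sex, phenotype. Sex codes
    1/2 -> male/female; phenotype 1/2 -> unaffected/affected, 0 or -9 ->
    unknown; parent id "0" -> no link. A parental reference to an id not in
    the file is dropped with a warning.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: PED requires 6 columns, found {df.shape[1]}")
    ids = list(df[1])
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate sample id(s) {dupes}")
    known = set(ids)
    inds = []
    for _, row in df.iterrows():
        father, mother = row[2], row[3]
        for pid, which in ((father, "father"), (mother, "mother")):
            if pid != "0" and pid not in known:
                warnings.warn(
                    f"{row[1]}: {which} {pid!r} not in pedigree — link dropped", stacklevel=2
                )
        inds.append(
            Individual(
                id=row[1],
                sex=_SEX.get(row[4], "unknown"),
                status=_STATUS.get(row[5], "unknown"),
                father_id=father if father != "0" and father in known else None,
                mother_id=mother if mother != "0" and mother in known else None,
                family_id=row[0],
            )
        )
    return Pedigree(inds)


def write_pedigree(pedigree: Pedigree, path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    status_code = {"unaffected": "1", "affected": "2", "unknown": "0"}
    rows = [
        (
            i.family_id,
            i.id,
            i.father_id or "0",
            i.mother_id or "0",
            sex_code[i.sex],
            status_code[i.status],
        )
        for i in pedigree.members.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


class RepeatMask:
    """Set of genomic intervals queryable by 1-based position."""

    def __init__(self, trees: dict[str, IntervalTree] | None = None):
        self.trees = trees or {}

    def __contains__(self, locus: tuple[str, int]) -> bool:
        chrom, pos = locus
        tree = self.trees.get(chrom)
        # interval [start, end) in 0-based coords contains 1-based pos iff start < pos <= end
        return bool(tree is not None and tree.overlap(pos - 1, pos))

    @property
    def n_intervals(self) -> int:
        return sum(len(t) for t in self.trees.values())


def read_bed_mask(path) -> RepeatMask:
    """Read a BED3 file (0-based half-open) into a position-queryable mask."""
    trees: dict[str, IntervalTree] = {}
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype={0: str}, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise ValueError(f"{path}: malformed interval {row.chrom}:{start}-{end} (start >= end)")
        trees.setdefault(row.chrom, IntervalTree()).addi(start, end)
    return trees and RepeatMask(trees) or RepeatMask()


def read_freq_table(path) -> pd.DataFrame:
    """Read a TSV of per-population variant frequencies.

    Required columns: variant_id, population, frequency; optional: age_bin,
    carriers (carrier counts per age bin). Rows are indexed by variant_id.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "population", "frequency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: frequency table missing column(s) {sorted(missing)}")
    bad = df[(df["frequency"] < 0) | (df["frequency"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: frequencies outside [0, 1] for {list(bad['variant_id'])}")
    return df
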