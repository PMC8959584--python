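"""Round-trips and coordinate conventions of the file readers/writers."""
import textwrap

import numpy as np
import pytest

from famtriage.model import HET, HOM_ALT, HOM_REF, MISSING, AnnotatedVariant, GenotypeMatrix
from famtriage.variant_io import (
    VcfParseError,
    read_annotated_vcf,
    read_bed_mask,
    read_freq_table,
    read_pedigree,
    write_annotated_vcf,
    write_pedigree,
)


def _random_variants(rng, n):
    """Seeded generator of fully-annotated variants for round-trip checks."""
    out = []
    bases = ["A", "C", "G", "T"]
    positions = rng.choice(np.arange(1, 10_000_000), size=n, replace=False)
    for i in range(n):
        ref, alt = rng.choice(bases, size=2, replace=False)
        has = rng.random(8) < 0.7
        out.append(
            AnnotatedVariant(
                chrom=str(rng.integers(1, 23)),
                pos=int(positions[i]),
                ref=ref,
                alt=alt + "T" * int(rng.integers(0, 3)),
                rsid=f"rs{rng.integers(1, 10**8)}" if has[0] else None,
                gene=f"GENE{rng.integers(1, 50)}" if has[1] else None,
                func_class=str(rng.choice(["exonic", "splicing", "exonic;splicing", "intronic"])),
                exonic_func=str(rng.choice(["missense_SNV", "synonymous_SNV", "stopgain",
                                            "nonframeshift_indel", "none"])),
                splice_distance_bp=int(rng.integers(0, 50)) if has[2] else None,
                pop_freqs={
                    db: float(f"{rng.random():.6g}")
                    for db in rng.choice(
                        ["1000g2015aug_all", "esp6500siv2_all", "gnomAD_ALL", "gnomAD_EAS"],
                        size=rng.integers(0, 4),
                        replace=False,
                    )
                },
                predictor_calls=(
                    {
                        "SIFT": str(rng.choice(["D", "T"])),
                        "Polyphen2_HVAR": str(rng.choice(["D", "P", "B"])),
                        "MutationTaster": str(rng.choice(["D", "A", "N"])),
                        "CADD": float(f"{rng.uniform(0, 40):.4g}"),
                    }
                    if has[3]
                    else {}
                ),
                splice_effect_score=float(f"{rng.random():.6g}") if has[4] else None,
                qual=float(rng.integers(1, 1000)),
                depth=float(rng.integers(1, 300)),
                mq=float(rng.integers(10, 60)),
                in_repeat=bool(has[5]),
                hgvs="c.G123A;c.G456A" if has[6] else None,
            )
        )
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


def _random_matrix(rng, samples, variants):
    calls = rng.choice(
        [HOM_REF, HET, HOM_ALT, MISSING], size=(len(samples), len(variants)), p=[0.5, 0.25, 0.15, 0.1]
    ).astype(np.int8)
    return GenotypeMatrix(samples, [v.key for v in variants], calls)


def test_vcf_round_trip_preserves_all_fields(tmp_path, rng):
    variants = _random_variants(rng, 30)
    gm = _random_matrix(rng, ["S1", "S2", "S3"], variants)
    path = tmp_path / "rt.vcf"
    write_annotated_vcf(variants, gm, path)
    variants2, gm2 = read_annotated_vcf(path)
    assert [v.key for v in variants2] == [v.key for v in variants]
    for a, b in zip(variants, variants2):
        assert a == b, f"round-trip mismatch at {a.key}"
    assert gm2 == gm


def test_absent_annotations_stay_absent(tmp_path):
    v = AnnotatedVariant(chrom="1", pos=100, ref="A", alt="G", qual=50.0, depth=30, mq=60.0)
    gm = GenotypeMatrix(["S1"], [v.key], np.array([[HET]], dtype=np.int8))
    path = tmp_path / "sparse.vcf"
    write_annotated_vcf([v], gm, path)
    text = path.read_text()
    assert "CADD_phred" not in text.split("#CHROM")[1]  # INFO omits the key entirely
    (v2,), _ = read_annotated_vcf(path)
    assert "CADD" not in v2.predictor_calls
    assert v2.pop_freqs == {}
    assert v2.gene is None


def test_empty_variant_list_gives_header_only_vcf(tmp_path):
    gm = GenotypeMatrix(["S1"], [], np.zeros((1, 0), dtype=np.int8))
    path = tmp_path / "empty.vcf"
    write_annotated_vcf([], gm, path)
    body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert body == []
    variants, gm2 = read_annotated_vcf(path)
    assert variants == [] and gm2.sample_ids == ["S1"]


def test_multiallelic_record_splits_per_alt(tmp_path):
    path = tmp_path / "multi.vcf"
    path.write_text(
        textwrap.dedent(
            """\
            ##fileformat=VCFv4.2
            ##contig=<ID=1>
            ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
            1\t500\t.\tA\tG,T\t99\t.\t.\tGT\t1/2\t0/1
            """
        )
    )
    variants, gm = read_annotated_vcf(path)
    assert len(variants) == 2
    assert {(v.chrom, v.pos, v.ref) for v in variants} == {("1", 500, "A")}
    assert [v.alt for v in variants] == ["G", "T"]
    # GT 1/2 means one copy of each alt; 0/1 only the first
    assert gm.get("S1", variants[0].key) == HET
    assert gm.get("S1", variants[1].key) == HET
    assert gm.get("S2", variants[0].key) == HET
    assert gm.get("S2", variants[1].key) == HOM_REF


def test_vcf_without_samples_is_rejected(tmp_path):
    path = tmp_path / "nosamples.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=1>\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "1\t500\t.\tA\tG\t99\t.\t.\n"
    )
    with pytest.raises(VcfParseError, match="genotypes"):
        read_annotated_vcf(path)


def test_pedigree_parsing_statuses_and_links(tmp_path):
    path = tmp_path / "fam.ped"
    path.write_text(
        "FAM1 B1 0 0 2 2\n"
        "FAM1 B2 0 0 1 1\n"
        "FAM1 B3 0 0 1 1\n"
        "FAM1 B4 0 0 1 1\n"
        "FAM1 B5 0 0 2 2\n"
    )
    ped = read_pedigree(path)
    assert ped.affected == ["B1", "B5"]
    assert len(ped.unaffected) == 3
    assert ped.members["B1"].sex == "female"
    assert ped.members["B1"].father_id is None  # "0" means no link


def test_pedigree_unknown_status_and_dangling_parent(tmp_path):
    path = tmp_path / "odd.ped"
    path.write_text("F1 A 0 0 1 -9\nF1 B GHOST 0 1 2\n")
    with pytest.warns(UserWarning, match="GHOST"):
        ped = read_pedigree(path)
    assert ped.members["A"].status == "unknown"
    assert ped.members["B"].father_id is None


def test_pedigree_duplicate_id_rejected(tmp_path):
    path = tmp_path / "dup.ped"
    path.write_text("F1 A 0 0 1 1\nF1 A 0 0 1 2\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_pedigree(path)


def test_pedigree_round_trip(tmp_path, trio_pedigree):
    path = tmp_path / "trio.ped"
    write_pedigree(trio_pedigree, path)
    ped = read_pedigree(path)
    assert ped.members["C"].father_id == "F"
    assert ped.members["C"].mother_id == "M"
    assert ped.affected == ["C"]


def test_bed_mask_is_off_by_one_safe(tmp_path):
    path = tmp_path / "mask.bed"
    path.write_text("2\t100\t200\n")
    mask = read_bed_mask(path)
    # BED [100, 200) covers 1-based positions 101..200
    assert ("2", 100) not in mask
    assert ("2", 101) in mask
    assert ("2", 200) in mask
    assert ("2", 201) not in mask
    assert ("3", 150) not in mask


def test_empty_bed_masks_nothing(tmp_path):
    path = tmp_path / "empty.bed"
    path.write_text("")
    mask = read_bed_mask(path)
    assert ("1", 1) not in mask and mask.n_intervals == 0


def test_malformed_bed_interval_rejected(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("1\t200\t100\n")
    with pytest.raises(ValueError, match="start >= end"):
        read_bed_mask(path)


def test_freq_table_reads_and_validates(tmp_path):
    path = tmp_path / "freq.tsv"
    path.write_text(
        "variant_id\tpopulation\tfrequency\n"
        "rs72677250\tSouth_Asian\t0.00003269\n"
        "rs72677250\tEuropean\t0.0\n"
    )
    df = read_freq_table(path)
    row = df[(df.variant_id == "rs72677250") & (df.population == "South_Asian")]
    assert float(row.frequency.iloc[0]) == pytest.approx(0.00003269)
    bad = tmp_path / "bad.tsv"
    bad.write_text("variant_id\tpopulation\tfrequency\nrs1\tEUR\t1.5\n")
    with pytest.raises(ValueError, match="outside"):
        read_freq_table(bad)


def test_compressed_vcf_accepted(tmp_path, rng):
    """Block-gzipped VCF (the standard .vcf.gz) reads identically to plain text."""
    import pysam

    variants = _random_variants(rng, 5)
    gm = _random_matrix(rng, ["S1"], variants)
    plain = tmp_path / "x.vcf"
    write_annotated_vcf(variants, gm, plain)
    gz = tmp_path / "x.vcf.gz"
    pysam.tabix_compress(str(plain), str(gz))
    variants2, gm2 = read_annotated_vcf(gz)
    assert variants2 == variants and gm2 == gm
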