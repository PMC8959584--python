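"""Core domain types: annotated variants, genotype matrices and pedigrees.

All genomic coordinates in these types are 1-based inclusive (VCF
convention); BED input is converted at read time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: Functional region classes (ANNOVAR ``Func.refGene`` vocabulary, collapsed).
FUNC_CLASSES = frozenset(
    {"exonic", "splicing", "exonic;splicing", "intronic", "UTR", "intergenic", "other"}
)

#: Exonic consequence classes.
EXONIC_FUNCS = frozenset(
    {
        "missense_SNV",
        "synonymous_SNV",
        "stopgain",
        "stoploss",
        "frameshift_indel",
        "nonframeshift_indel",
        "unknown",
        "none",
    }
)

#: Categorical predictors carried on a variant, plus the numeric CADD phred score.
PREDICTOR_KEYS = ("SIFT", "Polyphen2_HVAR", "Polyphen2_HDIV", "MutationTaster", "CADD")

# Genotype codes used throughout (int8 in GenotypeMatrix.calls).
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GENOTYPE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}
GENOTYPE_CODES = {v: k for k, v in GENOTYPE_NAMES.items()}


@dataclass
class AnnotatedVariant:
    """One biallelic variant site with its annotations and site QC metrics.

    ``pop_freqs`` maps population-database names (e.g. ``gnomAD_EAS``) to
    alternate-allele frequencies in [0, 1]; absent databases are simply not
    present in the map — absence is never encoded as 0. ``predictor_calls``
    holds categorical calls for SIFT/PolyPhen/MutationTaster and the numeric
    phred-scaled CADD score.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None
    gene: str | None = None
    func_class: str = "other"
    exonic_func: str = "none"
    splice_distance_bp: int | None = None
    pop_freqs: dict[str, float] = field(default_factory=dict)
    predictor_calls: dict[str, object] = field(default_factory=dict)
    splice_effect_score: float | None = None
    qual: float | None = None
    depth: float | None = None
    mq: float | None = None
    in_repeat: bool = False
    hgvs: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown func_class {self.func_class!r}")
        if self.exonic_func not in EXONIC_FUNCS:
            raise ValueError(f"unknown exonic_func {self.exonic_func!r}")
        for db, f in self.pop_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"pop_freqs[{db!r}] = {f} outside [0, 1]")
        if self.splice_distance_bp is not None and self.splice_distance_bp < 0:
            raise ValueError("splice_distance_bp must be >= 0")

    @property
    def key(self) -> str:
        """Canonical variant key, ``chrom:pos:ref:alt``."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_length(self) -> int:
        """Absolute allele-length difference in bases (0 for SNVs)."""
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_exonic(self) -> bool:
        return "exonic" in self.func_class


class GenotypeMatrix:
    """Diploid genotype calls for ``sample_ids`` × ``variant_keys``.

    Calls are stored as an int8 matrix with codes 0=hom_ref, 1=het,
    2=hom_alt, -1=missing (samples are rows).
    """

    def __init__(self, sample_ids: Iterable[str], variant_keys: Iterable[str], calls: np.ndarray):
        self.sample_ids = list(sample_ids)
        self.variant_keys = list(variant_keys)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.sample_ids), len(self.variant_keys)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_keys)} variants"
            )
        bad = set(np.unique(calls)) - {HOM_REF, HET, HOM_ALT, MISSING}
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._variant_index = {v: j for j, v in enumerate(self.variant_keys)}
        if len(self._sample_index) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self._variant_index) != len(self.variant_keys):
            raise ValueError("duplicate variant keys")

    @classmethod
    def from_calls(cls, calls: Mapping[tuple[str, str], str | int],
                   sample_ids: Iterable[str], variant_keys: Iterable[str]) -> "GenotypeMatrix":
        """Build from a {(sample, variant_key): call} mapping; unmentioned cells are hom_ref."""
        sample_ids = list(sample_ids)
        variant_keys = list(variant_keys)
        m = np.zeros((len(sample_ids), len(variant_keys)), dtype=np.int8)
        si = {s: i for i, s in enumerate(sample_ids)}
        vi = {v: j for j, v in enumerate(variant_keys)}
        for (s, v), g in calls.items():
            code = GENOTYPE_CODES[g] if isinstance(g, str) else int(g)
            m[si[s], vi[v]] = code
        return cls(sample_ids, variant_keys, m)

    def get(self, sample: str, variant_key: str) -> int:
        return int(self.calls[self._sample_index[sample], self._variant_index[variant_key]])

    def sample_vector(self, sample: str) -> np.ndarray:
        """All calls for one sample, in variant order."""
        return self.calls[self._sample_index[sample], :]

    def variant_column(self, variant_key: str) -> np.ndarray:
        """All calls at one site, in sample order."""
        return self.calls[:, self._variant_index[variant_key]]

    def carriers(self, variant_key: str) -> list[str]:
        """Samples with >= 1 alternate allele at the site."""
        col = self.variant_column(variant_key)
        return [s for s, g in zip(self.sample_ids, col) if g in (HET, HOM_ALT)]

    def subset_variants(self, keys: Iterable[str]) -> "GenotypeMatrix":
        keys = list(keys)
        idx = [self._variant_index[k] for k in keys]
        return GenotypeMatrix(self.sample_ids, keys, self.calls[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variant_keys == other.variant_keys
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({len(self.sample_ids)} samples x {len(self.variant_keys)} variants)"


@dataclass
class Individual:
    id: str
    sex: str = "unknown"  # male / female / unknown
    status: str = "unknown"  # affected / unaffected / unknown
    father_id: str | None = None
    mother_id: str | None = None
    family_id: str = "FAM"


class Pedigree:
    """A set of individuals with sex, affection status and optional parental links."""

    def __init__(self, individuals: Iterable[Individual]):
        self.members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.members:
                raise ValueError(f"duplicate sample id {ind.id!r}")
            self.members[ind.id] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self.members.values():
            for pid, want_sex in ((ind.father_id, "male"), (ind.mother_id, "female")):
                if pid is not None and pid in self.members:
                    psex = self.members[pid].sex
                    if psex not in (want_sex, "unknown"):
                        raise ValueError(
                            f"parent {pid!r} of {ind.id!r} has sex {psex!r}, expected {want_sex}"
                        )
        # no sample may be its own ancestor
        for ind in self.members.values():
            seen: set[str] = set()
            stack = [p for p in (ind.father_id, ind.mother_id) if p]
            while stack:
                pid = stack.pop()
                if pid == ind.id:
                    raise ValueError(f"{ind.id!r} is its own ancestor")
                if pid in seen or pid not in self.members:
                    continue
                seen.add(pid)
                p = self.members[pid]
                stack.extend(q for q in (p.father_id, p.mother_id) if q)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.members)

    @property
    def affected(self) -> list[str]:
        return [i.id for i in self.members.values() if i.status == "affected"]

    @property
    def unaffected(self) -> list[str]:
        return [i.id for i in self.members.values() if i.status == "unaffected"]

    @property
    def founders(self) -> list[str]:
        """Samples with no recorded parent inside the pedigree."""
        return [
            i.id
            for i in self.members.values()
            if (i.father_id not in self.members) and (i.mother_id not in self.members)
        ]

    def parents_of(self, sample: str) -> tuple[str | None, str | None]:
        ind = self.members[sample]
        f = ind.father_id if ind.father_id in self.members else None
        m = ind.mother_id if ind.mother_id in self.members else None
        return f, m

    def parent_offspring_pairs(self) -> list[tuple[str, str]]:
        """(parent, child) for every declared link with both samples present."""
        pairs = []
        for ind in self.members.values():
            f, m = self.parents_of(ind.id)
            for p in (f, m):
                if p is not None:
                    pairs.append((p, ind.id))
        return pairs

    def trios(self) -> list[tuple[str, str, str]]:
        """(child, father, mother) for every sample with both parents present."""
        out = []
        for ind in self.members.values():
            f, m = self.parents_of(ind.id)
            if f is not None and m is not None:
                out.append((ind.id, f, m))
        return out

    def topological_order(self) -> list[str]:
        """Parents before children (founders first)."""
        order: list[str] = []
        placed: set[str] = set()
        pending = list(self.members)
        while pending:
            progressed = False
            rest = []
            for sid in pending:
                f, m = self.parents_of(sid)
                if (f is None or f in placed) and (m is None or m in placed):
                    order.append(sid)
                    placed.add(sid)
                    progressed = True
                else:
                    rest.append(sid)
            if not progressed:  # pragma: no cover - excluded by acyclicity check
                raise ValueError("pedigree contains a cycle")
            pending = rest
        return order

    def __len__(self) -> int:
        return len(self.members)

    def __repr__(self) -> str:
        return (
            f"Pedigree({len(self.members)} members, "
            f"{len(self.affected)} affected, {len(self.unaffected)} unaffected)"
        )
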