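"""ACMG/AMP five-tier variant classification from coded evidence.

Implements only the published combining rules: evidence codes (PVS1, PS1-4,
PM1-6, PP1-5, BA1, BS1-4, BP1-7) are caller-supplied inputs, and the
classifier reduces a set of codes to one of pathogenic, likely_pathogenic,
uncertain_significance, likely_benign or benign. Conflicting pathogenic and
benign evidence, or evidence matching no rule, yields uncertain_significance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

PATHOGENIC_CODES = (
    "PVS1",
    "PS1", "PS2", "PS3", "PS4",
    "PM1", "PM2", "PM3", "PM4", "PM5", "PM6",
    "PP1", "PP2", "PP3", "PP4", "PP5",
)
BENIGN_CODES = ("BA1", "BS1", "BS2", "BS3", "BS4", "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7")
ALL_CODES = PATHOGENIC_CODES + BENIGN_CODES

ACMG_CLASSES = (
    "pathogenic",
    "likely_pathogenic",
    "uncertain_significance",
    "likely_benign",
    "benign",
)


@dataclass(frozen=True)
class EvidenceSet:
    """A set of ACMG evidence codes observed for one variant."""

    codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.codes) - set(ALL_CODES)
        if unknown:
            raise ValueError(f"unknown ACMG evidence code(s) {sorted(unknown)}")

    @classmethod
    def of(cls, *codes: str) -> "EvidenceSet":
        return cls(frozenset(codes))

    # strength-tier counts
    @property
    def pvs(self) -> int:
        return int("PVS1" in self.codes)

    @property
    def ps(self) -> int:
        return sum(1 for c in self.codes if c.startswith("PS"))

    @property
    def pm(self) -> int:
        return sum(1 for c in self.codes if c.startswith("PM"))

    @property
    def pp(self) -> int:
        return sum(1 for c in self.codes if c.startswith("PP"))

    @property
    def ba(self) -> int:
        return int("BA1" in self.codes)

    @property
    def bs(self) -> int:
        return sum(1 for c in self.codes if c.startswith("BS"))

    @property
    def bp(self) -> int:
        return sum(1 for c in self.codes if c.startswith("BP"))


def _pathogenic(e: EvidenceSet) -> bool:
    if e.pvs >= 1 and (e.ps >= 1 or e.pm >= 2 or (e.pm == 1 and e.pp == 1) or e.pp >= 2):
        return True
    if e.ps >= 2:
        return True
    if e.ps == 1 and (e.pm >= 3 or (e.pm == 2 and e.pp >= 2) or (e.pm == 1 and e.pp >= 4)):
        return True
    return False


def _likely_pathogenic(e: EvidenceSet) -> bool:
    return (
        (e.pvs >= 1 and e.pm == 1)
        or (e.ps == 1 and 1 <= e.pm <= 2)
        or (e.ps == 1 and e.pp >= 2)
        or e.pm >= 3
        or (e.pm == 2 and e.pp >= 2)
        or (e.pm == 1 and e.pp >= 4)
    )


def _benign(e: EvidenceSet) -> bool:
    return e.ba >= 1 or e.bs >= 2


def _likely_benign(e: EvidenceSet) -> bool:
    return (e.bs == 1 and e.bp == 1) or e.bp >= 2


def acmg_classify(evidence: EvidenceSet) -> str:
    """Apply the ACMG combining rules to an evidence set.

    Returns one of :data:`ACMG_CLASSES`. A set satisfying both a
    pathogenic-side and a benign-side rule is contradictory and classified
    uncertain_significance, as is a set satisfying no rule.
    """
    path = _pathogenic(evidence) or _likely_pathogenic(evidence)
    ben = _benign(evidence) or _likely_benign(evidence)
    if path and ben:
        return "uncertain_significance"
    if _pathogenic(evidence):
        return "pathogenic"
    if _likely_pathogenic(evidence):
        return "likely_pathogenic"
    if _benign(evidence):
        return "benign"
    if _likely_benign(evidence):
        return "likely_benign"
    return "uncertain_significance"
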