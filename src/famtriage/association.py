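"""Case-control association summaries for candidate loci.

Carrier/genotype 2x2 tables with chi-square (with and without Yates
continuity correction) and two-sided Fisher exact tests, allele-frequency
tables for biallelic sites, per-population frequency summaries, and
agreement between two genotyping call sets.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .model import HET, HOM_ALT, GenotypeMatrix


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows case/control, columns exposed/unexposed."""

    case_exposed: int
    case_unexposed: int
    control_exposed: int
    control_unexposed: int
    exposure_label: str = "exposed"

    def __post_init__(self) -> None:
        if min(self.case_exposed, self.case_unexposed, self.control_exposed,
               self.control_unexposed) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.case_exposed, self.case_unexposed],
                [self.control_exposed, self.control_unexposed],
            ]
        )

    @property
    def n_cases(self) -> int:
        return self.case_exposed + self.case_unexposed

    @property
    def n_controls(self) -> int:
        return self.control_exposed + self.control_unexposed


@dataclass(frozen=True)
class AssociationResult:
    table: ContingencyTable
    case_rate: float  # percent
    control_rate: float  # percent
    odds_ratio: float  # Haldane-Anscombe corrected when a cell is zero
    chi2: float
    chi2_p: float
    chi2_yates: float
    chi2_yates_p: float
    fisher_p: float
    test_used: str  # 'fisher' when any expected cell < 5, else 'chi2'

    @property
    def p_value(self) -> float:
        return self.fisher_p if self.test_used == "fisher" else self.chi2_p


def _tests(table: ContingencyTable) -> AssociationResult:
    m = table.matrix
    if m.sum(axis=1).min() == 0 or m.sum(axis=0).min() == 0:
        # a zero margin makes the tests undefined
        raise ValueError("contingency table has a zero margin")
    chi2, chi2_p, _, expected = stats.chi2_contingency(m, correction=False)
    chi2_y, chi2_y_p, _, _ = stats.chi2_contingency(m, correction=True)
    fisher_p = float(stats.fisher_exact(m, alternative="two-sided")[1])
    a, b, c, d = (float(x) for x in m.ravel())
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    test_used = "fisher" if (expected < 5).any() else "chi2"
    return AssociationResult(
        table=table,
        case_rate=100.0 * table.case_exposed / table.n_cases,
        control_rate=100.0 * table.control_exposed / table.n_controls,
        odds_ratio=float(odds),
        chi2=float(chi2),
        chi2_p=float(chi2_p),
        chi2_yates=float(chi2_y),
        chi2_yates_p=float(chi2_y_p),
        fisher_p=fisher_p,
        test_used=test_used,
    )


EXPOSURE_RULES = ("carrier", "hom_alt")


def genotype_association(
    genotypes: GenotypeMatrix,
    labels: Mapping[str, str],
    exposure_rule: str = "carrier",
    variant_key: str | None = None,
) -> AssociationResult:
    """Test one site for case-control association.

    ``labels`` maps every sample to 'case' or 'control'. Exposure is either
    carrying >= 1 alternate allele (``carrier``) or being homozygous
    alternate (``hom_alt``). Carrier rates are reported as percentages. The
    headline test is Fisher exact when any expected cell count is below 5,
    chi-square otherwise; all conventions are reported.
    """
    if exposure_rule not in EXPOSURE_RULES:
        raise ValueError(f"unknown exposure rule {exposure_rule!r}")
    if variant_key is None:
        if len(genotypes.variant_keys) != 1:
            raise ValueError("variant_key required when the matrix has several sites")
        variant_key = genotypes.variant_keys[0]
    col = genotypes.variant_column(variant_key)
    exposed_codes = (HET, HOM_ALT) if exposure_rule == "carrier" else (HOM_ALT,)
    counts = {("case", True): 0, ("case", False): 0, ("control", True): 0, ("control", False): 0}
    for s, g in zip(genotypes.sample_ids, col):
        group = labels.get(s)
        if group not in ("case", "control"):
            raise ValueError(f"sample {s!r} has no case/control label")
        counts[(group, int(g) in exposed_codes)] += 1
    table = ContingencyTable(
        counts[("case", True)],
        counts[("case", False)],
        counts[("control", True)],
        counts[("control", False)],
        exposure_label=exposure_rule,
    )
    if table.n_cases == 0 or table.n_controls == 0:
        raise ValueError("both a case and a control group are required")
    return _tests(table)


def allele_frequencies(genotype_counts: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Per-group allele counts and frequencies for a biallelic site.

    ``genotype_counts`` maps group name to {'hom_ref': n, 'het': n,
    'hom_alt': n}. Allele count (alt) = 2*hom_alt + het out of 2*n_samples
    chromosomes; percentages carry full precision (round for display).
    """
    rows = []
    for group, counts in genotype_counts.items():
        hom_ref = int(counts.get("hom_ref", 0))
        het = int(counts.get("het", 0))
        hom_alt = int(counts.get("hom_alt", 0))
        n = hom_ref + het + hom_alt
        if n == 0:
            raise ValueError(f"group {group!r} has zero samples")
        alt = 2 * hom_alt + het
        ref = 2 * hom_ref + het
        rows.append(
            {
                "group": group,
                "n_samples": n,
                "alt_count": alt,
                "ref_count": ref,
                "alt_freq_percent": 100.0 * alt / (2 * n),
                "ref_freq_percent": 100.0 * ref / (2 * n),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def popfreq_summary(freq_table: pd.DataFrame, variant_id: str) -> dict:
    """Summarize a per-population frequency table for one variant.

    Returns the maximal-frequency population(s) (ties reported together,
    sorted) and, when per-age carrier counts are present, the age bin(s)
    with the most carriers.
    """
    sub = freq_table[freq_table["variant_id"] == variant_id]
    if sub.empty:
        raise KeyError(f"variant {variant_id!r} not in frequency table")
    by_pop = sub.groupby("population")["frequency"].max()
    fmax = by_pop.max()
    top = sorted(by_pop[by_pop == fmax].index)
    out = {
        "variant_id": variant_id,
        "top_populations": top,
        "top_frequency": float(fmax),
    }
    if "age_bin" in sub.columns and "carriers" in sub.columns:
        ages = sub.dropna(subset=["age_bin"]).groupby("age_bin")["carriers"].sum()
        if len(ages):
            cmax = ages.max()
            out["top_age_bins"] = sorted(ages[ages == cmax].index)
            out["top_age_carriers"] = int(cmax)
    return out


def callset_concordance(
    calls_a: Mapping[tuple[str, str], str], calls_b: Mapping[tuple[str, str], str]
) -> tuple[float, pd.DataFrame]:
    """Percent agreement between two {(sample, locus): 'MUT'|'WILD'} call sets.

    Also tallies MUT/WILD per locus per call set. The two sets must cover
    identical (sample, locus) pairs.
    """
    keys_a, keys_b = set(calls_a), set(calls_b)
    if keys_a != keys_b:
        missing = sorted(keys_a ^ keys_b)
        raise ValueError(f"call sets cover different (sample, locus) pairs: {missing[:10]}")
    if not keys_a:
        raise ValueError("empty call sets")
    for calls in (calls_a, calls_b):
        bad = {v for v in calls.values()} - {"MUT", "WILD"}
        if bad:
            raise ValueError(f"calls must be MUT or WILD, found {sorted(bad)}")
    keys = sorted(keys_a)
    agree = sum(calls_a[k] == calls_b[k] for k in keys)
    percent = 100.0 * agree / len(keys)
    rows = []
    loci = sorted({locus for _, locus in keys})
    for locus in loci:
        at = [k for k in keys if k[1] == locus]
        for name, calls in (("a", calls_a), ("b", calls_b)):
            n_mut = sum(calls[k] == "MUT" for k in at)
            rows.append(
                {
                    "locus": locus,
                    "callset": name,
                    "MUT": n_mut,
                    "WILD": len(at) - n_mut,
                    "MUT_percent": 100.0 * n_mut / len(at),
                }
            )
    return percent, pd.DataFrame(rows)
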