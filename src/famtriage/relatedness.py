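"""Pairwise relatedness from genome-wide genotypes.

Identity-by-state (IBS) counts are reduced to identity-by-descent (IBD)
state probabilities (z0, z1, z2) by the classic method of moments: expected
IBS-class probabilities conditional on IBD state are computed from allele
frequencies (with finite-sample correction factors when the frequencies are
estimated from a reference sample of known size), the linear system is
solved stage-wise, and the estimate is projected onto the probability
simplex by clamping negatives and renormalizing. The summary statistic is
PI_HAT = z1/2 + z2, ~0.5 for parent-offspring and full siblings, ~1 for
duplicates and ~0 for unrelated pairs. Declared parent-offspring pairs are
checked against an acceptance band (default 45-55% sharing).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, Pedigree


@dataclass(frozen=True)
class IBDEstimate:
    """Estimated IBD-state probabilities and the sharing proportion PI_HAT."""

    z0: float
    z1: float
    z2: float
    n_sites_used: int

    @property
    def pi_hat(self) -> float:
        return self.z1 / 2.0 + self.z2


def ibs_counts(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> tuple[int, int, int]:
    """Count sites by identity-by-state class for two genotype vectors.

    IBS 0: opposite homozygotes; IBS 1: het vs homozygote; IBS 2: identical
    genotypes (including het vs het). Sites missing in either sample are
    skipped; the three counts sum to the number of shared non-missing sites.
    """
    a = np.asarray(genotypes_a)
    b = np.asarray(genotypes_b)
    if a.shape != b.shape:
        raise ValueError(f"genotype vectors differ in length: {a.shape} vs {b.shape}")
    use = (a != MISSING) & (b != MISSING)
    diff = np.abs(a[use].astype(np.int16) - b[use].astype(np.int16))
    return int(np.sum(diff == 2)), int(np.sum(diff == 1)), int(np.sum(diff == 0))


def _monomials(p: np.ndarray, allele_count: float | None):
    """Mean expected IBS-class probabilities per IBD state over sites.

    With ``allele_count`` X (chromosomes used to estimate the frequencies),
    each frequency monomial is replaced by its unbiased estimator built from
    draws without replacement — the PLINK finite-sample correction.
    """
    q = 1.0 - p
    if allele_count is None:
        p2q2, p3q, pq3 = p**2 * q**2, p**3 * q, p * q**3
        p4, q4 = p**4, q**4
        p2q, pq2, p3, q3, pq = p**2 * q, p * q**2, p**3, q**3, p * q
    else:
        X = float(allele_count)
        a, b = p * X, q * X
        d4 = X * (X - 1) * (X - 2) * (X - 3)
        d3 = X * (X - 1) * (X - 2)
        d2 = X * (X - 1)
        p2q2 = a * (a - 1) * b * (b - 1) / d4
        p3q = a * (a - 1) * (a - 2) * b / d4
        pq3 = a * b * (b - 1) * (b - 2) / d4
        p4 = a * (a - 1) * (a - 2) * (a - 3) / d4
        q4 = b * (b - 1) * (b - 2) * (b - 3) / d4
        p2q = a * (a - 1) * b / d3
        pq2 = a * b * (b - 1) / d3
        p3 = a * (a - 1) * (a - 2) / d3
        q3 = b * (b - 1) * (b - 2) / d3
        pq = a * b / d2
    e = {
        ("ibs0", 0): 2 * p2q2,
        ("ibs1", 0): 4 * p3q + 4 * pq3,
        ("ibs2", 0): p4 + q4 + 4 * p2q2,
        ("ibs1", 1): 2 * p2q + 2 * pq2,
        ("ibs2", 1): p3 + q3 + p2q + pq2,
    }
    return {k: float(np.mean(v)) for k, v in e.items()}


def moment_ibd(
    counts: tuple[int, int, int],
    allele_freqs: np.ndarray,
    allele_count: float | None = None,
) -> IBDEstimate:
    """Method-of-moments IBD estimate from aggregate IBS counts.

    ``allele_freqs`` are the alternate-allele frequencies of exactly the
    sites the counts were taken over; ``allele_count`` is the number of
    chromosomes those frequencies were estimated from (omit for external /
    population-true frequencies).
    """
    n0, n1, n2 = counts
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("zero usable sites for IBD estimation")
    p = np.asarray(allele_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must lie strictly inside (0, 1)")
    e = _monomials(p, allele_count)
    o0, o1, o2 = n0 / n, n1 / n, n2 / n
    z0 = o0 / e[("ibs0", 0)]
    z1 = (o1 - z0 * e[("ibs1", 0)]) / e[("ibs1", 1)]
    z2 = o2 - z0 * e[("ibs2", 0)] - z1 * e[("ibs2", 1)]
    z = np.clip([z0, z1, z2], 0.0, None)
    total = z.sum()
    if total == 0:  # pragma: no cover - degenerate, all moments negative
        z = np.array([1.0, 0.0, 0.0])
    else:
        z = z / total
    return IBDEstimate(float(z[0]), float(z[1]), float(z[2]), n)


MIN_INFORMATIVE_FREQ = 0.01  # sites with MAF below this are excluded from estimation


def estimate_ibd(
    genotypes: GenotypeMatrix,
    sample_a: str,
    sample_b: str,
    allele_freqs: np.ndarray,
    allele_count: float | None = None,
) -> IBDEstimate:
    """IBD estimate for one sample pair, masking missing and degenerate sites."""
    a = genotypes.sample_vector(sample_a)
    b = genotypes.sample_vector(sample_b)
    p = np.asarray(allele_freqs, dtype=float)
    if p.shape[0] != len(genotypes.variant_keys):
        raise ValueError("allele_freqs length does not match variant count")
    informative = (p > MIN_INFORMATIVE_FREQ) & (p < 1 - MIN_INFORMATIVE_FREQ)
    if not informative.all():
        warnings.warn(
            f"excluding {int((~informative).sum())} monomorphic/near-monomorphic sites",
            stacklevel=2,
        )
    use = informative & (a != MISSING) & (b != MISSING)
    counts = ibs_counts(a[use], b[use])
    return moment_ibd(counts, p[use], allele_count)


def founder_allele_freqs(genotypes: GenotypeMatrix, pedigree: Pedigree) -> tuple[np.ndarray, float]:
    """Alternate-allele frequencies estimated from pedigree founders.

    Returns (freqs, mean allele count per site) for the finite-sample
    correction.
    """
    founders = [s for s in pedigree.founders if s in genotypes.sample_ids]
    if not founders:
        raise ValueError("no genotyped founders to estimate allele frequencies from")
    calls = np.stack([genotypes.sample_vector(s) for s in founders])
    known = calls != MISSING
    alt = np.where(known, calls, 0).sum(axis=0)
    chroms = 2 * known.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freqs = np.where(chroms > 0, alt / np.maximum(chroms, 1), np.nan)
    return freqs, float(chroms.mean())


@dataclass
class PairCheck:
    parent: str
    child: str
    estimate: IBDEstimate
    passed: bool


def pedigree_ibd_check(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    bounds: tuple[float, float] = (0.45, 0.55),
    allele_freqs: np.ndarray | None = None,
    min_founders_for_estimation: int = 20,
) -> list[PairCheck]:
    """Verify every declared parent-offspring pair by its IBD sharing.

    A pair passes when PI_HAT falls inside ``bounds``; pairs outside the
    band indicate sample swaps, duplicates or pedigree errors. Frequencies
    are taken from ``allele_freqs`` when given, else estimated from the
    cohort's founders (a warning is raised when fewer than
    ``min_founders_for_estimation`` founders back the estimate).
    """
    pairs = pedigree.parent_offspring_pairs()
    if not pairs:
        warnings.warn("pedigree declares no parent-offspring pairs", stacklevel=2)
        return []
    allele_count = None
    if allele_freqs is None:
        founders = [s for s in pedigree.founders if s in genotypes.sample_ids]
        if len(founders) < min_founders_for_estimation:
            warnings.warn(
                f"allele frequencies estimated from only {len(founders)} founders; "
                "supply external frequencies for stable moments",
                stacklevel=2,
            )
        allele_freqs, allele_count = founder_allele_freqs(genotypes, pedigree)
    lo, hi = bounds
    out = []
    for parent, child in pairs:
        est = estimate_ibd(genotypes, parent, child, allele_freqs, allele_count)
        out.append(PairCheck(parent, child, est, lo <= est.pi_hat <= hi))
    return out


# genotype -> transmissible allele sets (0 = ref, 1 = alt)
_ALLELES = {HOM_REF: (0,), HET: (0, 1), HOM_ALT: (1,)}


def mendelian_errors(genotypes: GenotypeMatrix, pedigree: Pedigree) -> dict[str, int]:
    """Count Mendelian-impossible sites per trio (keyed by child id).

    A site errs when no combination of one transmitted allele per parent can
    produce the child's genotype; sites with a missing call in the trio are
    skipped.
    """
    out = {}
    for child, father, mother in pedigree.trios():
        c = genotypes.sample_vector(child)
        f = genotypes.sample_vector(father)
        m = genotypes.sample_vector(mother)
        use = (c != MISSING) & (f != MISSING) & (m != MISSING)
        n_err = 0
        for gc, gf, gm in zip(c[use], f[use], m[use]):
            possible = {a + b for a in _ALLELES[int(gf)] for b in _ALLELES[int(gm)]}
            n_err += int(gc) not in possible
        out[child] = n_err
    return out
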