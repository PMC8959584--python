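"""IBS counting, method-of-moments IBD and pedigree verification."""
import numpy as np
import pytest

from famtriage.model import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, Individual, Pedigree
from famtriage.relatedness import (
    estimate_ibd,
    founder_allele_freqs,
    ibs_counts,
    mendelian_errors,
    moment_ibd,
    pedigree_ibd_check,
)
from famtriage.synthetic_data import PedigreeSimConfig, simulate_pedigree_genotypes


class TestIbsCounts:
    def test_identical_vectors_are_all_ibs2(self):
        v = np.array([HOM_REF, HET, HOM_ALT, HET])
        assert ibs_counts(v, v) == (0, 0, 4)

    def test_opposite_homozygotes_are_ibs0(self):
        a = np.full(10, HOM_REF)
        b = np.full(10, HOM_ALT)
        assert ibs_counts(a, b) == (10, 0, 0)

    def test_mixed_example_by_hand(self):
        a = np.array([HET, HOM_REF, HOM_ALT])
        b = np.array([HOM_REF, HOM_REF, HET])
        assert ibs_counts(a, b) == (0, 2, 1)

    def test_missing_sites_skipped_and_counts_sum(self):
        a = np.array([HET, MISSING, HOM_ALT, HOM_REF])
        b = np.array([HET, HET, MISSING, HOM_ALT])
        counts = ibs_counts(a, b)
        assert sum(counts) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ibs_counts(np.zeros(3), np.zeros(4))


def _pair_sim(pedigree, a, b, n_snps=5000, seed=0):
    gm, freqs = simulate_pedigree_genotypes(
        PedigreeSimConfig(pedigree, n_snps=n_snps, seed=seed), return_freqs=True
    )
    return estimate_ibd(gm, a, b, freqs), gm, freqs


class TestMomentIbd:
    def test_duplicate_pair_pi_hat_near_one(self):
        ped = Pedigree([Individual("A"), Individual("B")])
        gm, freqs = simulate_pedigree_genotypes(
            PedigreeSimConfig(ped, n_snps=5000, seed=11), return_freqs=True
        )
        est = estimate_ibd(gm, "A", "A", freqs)
        assert est.pi_hat > 0.95

    def test_unrelated_founders_pi_hat_near_zero(self):
        """Monte-Carlo oracle: sharing for unrelated founders is 0 in expectation."""
        ped = Pedigree([Individual("A"), Individual("B")])
        pis = [abs(_pair_sim(ped, "A", "B", seed=40 + s)[0].pi_hat) for s in range(10)]
        assert np.mean(pis) < 0.04
        assert max(pis) < 0.1

    def test_parent_offspring_in_printed_band(self, trio_pedigree):
        est, _, _ = _pair_sim(trio_pedigree, "F", "C", seed=13)
        assert 0.45 <= est.pi_hat <= 0.55
        assert est.z0 < 0.05  # a shared parent-child allele forbids IBD state 0

    def test_full_siblings_show_z2(self, quartet_pedigree):
        est, _, _ = _pair_sim(quartet_pedigree, "S1", "S2", seed=14)
        assert abs(est.pi_hat - 0.5) < 0.05
        assert abs(est.z2 - 0.25) < 0.08  # distinguishes siblings from parent-offspring

    def test_z_vector_on_simplex(self, quartet_pedigree):
        for seed in range(6):
            for pair in (("F", "M"), ("F", "S1"), ("S1", "S2")):
                est, _, _ = _pair_sim(quartet_pedigree, *pair, n_snps=800, seed=seed)
                z = np.array([est.z0, est.z1, est.z2])
                assert np.all(z >= 0) and np.all(z <= 1)
                assert np.isclose(z.sum(), 1.0)
                assert 0.0 <= est.pi_hat <= 1.0

    def test_error_convergence_is_root_n(self):
        """RMS deviation of pi_hat for unrelated pairs shrinks ~1/sqrt(n)."""
        ped = Pedigree([Individual("A"), Individual("B")])
        rms = {}
        for n in (500, 8000):
            devs = []
            for seed in range(12):
                gm, freqs = simulate_pedigree_genotypes(
                    PedigreeSimConfig(ped, n_snps=n, seed=100 + seed), return_freqs=True
                )
                devs.append(estimate_ibd(gm, "A", "B", freqs).pi_hat)
            rms[n] = float(np.sqrt(np.mean(np.square(devs))))
        assert rms[8000] < rms[500] / 2  # expected factor 4 for 16x the sites

    def test_zero_usable_sites_is_an_error(self):
        with pytest.raises(ValueError, match="zero usable"):
            moment_ibd((0, 0, 0), np.array([0.5]))

    def test_degenerate_frequencies_rejected(self):
        with pytest.raises(ValueError):
            moment_ibd((1, 1, 1), np.array([0.0, 0.5, 0.5]))

    def test_finite_sample_correction_shifts_moments(self):
        counts = (120, 1200, 3680)
        freqs = np.full(5000, 0.4)
        raw = moment_ibd(counts, freqs)
        corrected = moment_ibd(counts, freqs, allele_count=20)
        assert raw.pi_hat != corrected.pi_hat


class TestPedigreeCheck:
    def test_simulated_trio_passes_both_parent_pairs(self, trio_pedigree):
        gm, freqs = simulate_pedigree_genotypes(
            PedigreeSimConfig(trio_pedigree, n_snps=5000, seed=21), return_freqs=True
        )
        checks = pedigree_ibd_check(gm, trio_pedigree, allele_freqs=freqs)
        assert {(c.parent, c.child) for c in checks} == {("F", "C"), ("M", "C")}
        assert all(c.passed for c in checks)

    def test_sample_swap_detected(self, trio_pedigree):
        swapped = Pedigree(
            [
                Individual("F", sex="male"),
                Individual("M", sex="female"),
                Individual("C", father_id="F", mother_id="M"),
                Individual("X"),  # unrelated founder
            ]
        )
        gm, freqs = simulate_pedigree_genotypes(
            PedigreeSimConfig(swapped, n_snps=5000, seed=22), return_freqs=True
        )
        # substitute the unrelated founder's genotypes for the child
        calls = gm.calls.copy()
        calls[gm.sample_ids.index("C"), :] = calls[gm.sample_ids.index("X"), :]
        gm2 = GenotypeMatrix(gm.sample_ids, gm.variant_keys, calls)
        checks = pedigree_ibd_check(gm2, swapped, allele_freqs=freqs)
        assert all(not c.passed for c in checks)
        assert all(c.estimate.pi_hat < 0.45 for c in checks)

    def test_duplicate_as_parent_fails_high(self, trio_pedigree):
        gm, freqs = simulate_pedigree_genotypes(
            PedigreeSimConfig(trio_pedigree, n_snps=5000, seed=23), return_freqs=True
        )
        calls = gm.calls.copy()
        calls[gm.sample_ids.index("F"), :] = calls[gm.sample_ids.index("C"), :]
        gm2 = GenotypeMatrix(gm.sample_ids, gm.variant_keys, calls)
        checks = {(c.parent, c.child): c for c in
                  pedigree_ibd_check(gm2, trio_pedigree, allele_freqs=freqs)}
        assert not checks[("F", "C")].passed
        assert checks[("F", "C")].estimate.pi_hat > 0.55

    def test_no_declared_pairs_warns_and_returns_empty(self, family_fixture):
        variants, gm, ped = family_fixture
        with pytest.warns(UserWarning, match="no parent-offspring"):
            assert pedigree_ibd_check(gm, ped) == []

    def test_founder_frequency_estimation_warns_when_few_founders(self, trio_pedigree):
        gm = simulate_pedigree_genotypes(PedigreeSimConfig(trio_pedigree, n_snps=2000, seed=24))
        with pytest.warns(UserWarning, match="founders"):
            checks = pedigree_ibd_check(gm, trio_pedigree)
        assert len(checks) == 2


class TestMendelianErrors:
    def test_simulated_trio_has_zero_errors(self, trio_pedigree):
        gm = simulate_pedigree_genotypes(PedigreeSimConfig(trio_pedigree, n_snps=5000, seed=31))
        assert mendelian_errors(gm, trio_pedigree) == {"C": 0}

    def test_impossible_genotype_counted(self, trio_pedigree):
        keys = ["1:1:A:G", "1:2:A:G"]
        calls = {("C", keys[0]): HOM_ALT}  # parents hom_ref -> impossible
        gm = GenotypeMatrix.from_calls(calls, ["F", "M", "C"], keys)
        assert mendelian_errors(gm, trio_pedigree) == {"C": 1}

    def test_swapped_child_error_rate_near_unrelated_expectation(self, trio_pedigree):
        """An unrelated sample in the child slot errs at the analytic random-mating rate."""
        ped = Pedigree(
            [
                Individual("F", sex="male"),
                Individual("M", sex="female"),
                Individual("C", father_id="F", mother_id="M"),
                Individual("X"),
            ]
        )
        gm, freqs = simulate_pedigree_genotypes(
            PedigreeSimConfig(ped, n_snps=5000, seed=32), return_freqs=True
        )
        calls = gm.calls.copy()
        calls[gm.sample_ids.index("C"), :] = calls[gm.sample_ids.index("X"), :]
        gm2 = GenotypeMatrix(gm.sample_ids, gm.variant_keys, calls)
        n_err = mendelian_errors(gm2, ped)["C"]
        # per-site error probability by exact enumeration of HW trio genotypes
        p_err = _unrelated_error_rate(freqs)
        expect = p_err.sum()
        sd = np.sqrt(np.sum(p_err * (1 - p_err)))
        assert abs(n_err - expect) < 5 * sd


def _unrelated_error_rate(freqs: np.ndarray) -> np.ndarray:
    """Per-site probability that an unrelated HW child violates a HW trio."""
    from famtriage.relatedness import _ALLELES

    p = freqs
    q = 1 - p
    g_probs = {0: q**2, 1: 2 * p * q, 2: p**2}
    rate = np.zeros_like(p)
    for gf, pf in g_probs.items():
        for gm_, pm in g_probs.items():
            possible = {a + b for a in _ALLELES[gf] for b in _ALLELES[gm_]}
            for gc, pc in g_probs.items():
                if gc not in possible:
                    rate = rate + pf * pm * pc
    return rate


def test_founder_allele_freqs_match_truth(quartet_pedigree):
    gm, freqs = simulate_pedigree_genotypes(
        PedigreeSimConfig(quartet_pedigree, n_snps=3000, seed=41), return_freqs=True
    )
    est, n_chrom = founder_allele_freqs(gm, quartet_pedigree)
    assert n_chrom == 4.0  # two founders
    # 4 chromosomes give noisy per-site estimates but an unbiased mean and a
    # correlation near sqrt(var_true / (var_true + E[pq]/4)) ~ 0.59
    assert np.mean(est) == pytest.approx(np.mean(freqs), abs=0.02)
    assert 0.4 < np.corrcoef(est, freqs)[0, 1] < 0.8
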