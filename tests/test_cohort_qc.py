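from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popexclusive import (
    GenotypeCounts,
    QcThresholds,
    VariantKey,
    genotype_call_rate,
    hwe_exact_p,
    hwe_exact_test,
    ibd_mom,
    mask_low_quality_calls,
    pairwise_relatedness,
    select_unrelated,
    site_qc,
)

from conftest import make_matrix


# -- independent brute-force oracle for the HWE exact test ------------------

def hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Enumerate every genotype configuration with the same allele counts.

    P(h) = C(n, hom_r) C(n-hom_r, h) 2^h ... expressed via the standard
    conditional form: P(h) ∝ n! / (hom_r! h! hom_a!) * 2^h.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    configs = []
    for h in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        hom_a = (n_alt - h) // 2
        hom_r = n - h - hom_a
        if hom_r < 0 or hom_a < 0:
            continue
        w = comb(n, hom_r) * comb(n - hom_r, h) * 2**h
        configs.append((h, w))
    total = sum(w for _, w in configs)
    probs = {h: w / total for h, w in configs}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestHweExactTest:
    def test_monomorphic_site_p_one(self):
        assert hwe_exact_p(50, 0, 0) == 1.0

    def test_modal_heterozygote_count_gives_p_one(self):
        # counts (2,2,1): h in {0,2,4} has P {1/21, 12/21, 8/21}; observed h=2 is modal
        assert hwe_exact_p(2, 2, 1) == pytest.approx(1.0)

    def test_extreme_configuration(self):
        # counts (3,0,2): only h=0 is at most as probable as itself
        assert hwe_exact_p(3, 0, 2) == pytest.approx(1 / 21)

    def test_all_missing_site_raises(self):
        with pytest.raises(ValueError):
            hwe_exact_test(GenotypeCounts(0, 0, 0, n_missing=5))

    def test_matches_enumeration_oracle_small_n(self):
        for n in range(1, 16):
            for hom_r in range(n + 1):
                for het in range(n - hom_r + 1):
                    hom_a = n - hom_r - het
                    assert hwe_exact_p(hom_r, het, hom_a) == pytest.approx(
                        hwe_oracle(hom_r, het, hom_a), abs=1e-10
                    ), (hom_r, het, hom_a)

    def test_symmetric_under_allele_swap(self):
        for hom_r, het, hom_a in [(5, 3, 1), (10, 0, 7), (2, 8, 2), (30, 11, 4)]:
            assert hwe_exact_p(hom_r, het, hom_a) == pytest.approx(
                hwe_exact_p(hom_a, het, hom_r), abs=1e-12
            )

    @given(
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=0, max_value=60),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_p_in_unit_interval(self, hom_r, het, hom_a):
        if hom_r + het + hom_a == 0:
            return
        p = hwe_exact_p(hom_r, het, hom_a)
        assert 0.0 < p <= 1.0

    def test_false_positive_rate_under_hwe(self):
        # genotypes simulated under HWE should essentially never fail at 1e-5
        rng = np.random.default_rng(5)
        n, sites = 100, 20_000
        freqs = rng.uniform(0.05, 0.5, sites)
        dose = rng.binomial(2, freqs[None, :], (n, sites))
        fails = 0
        for j in range(sites):
            col = dose[:, j]
            p = hwe_exact_p(
                int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
            )
            fails += p < 1e-5
        assert fails / sites <= 1e-4


class TestCallLevelFilters:
    def test_call_rate_values(self):
        gm = make_matrix([[0], [1], [-1], [2]])
        v = gm.variants[0]
        assert genotype_call_rate(gm, v) == pytest.approx(0.75)

    def test_one_missing_fails_strict_call_rate(self):
        dose = np.zeros((358, 1), dtype=np.int8)
        dose[0, 0] = -1
        gm = make_matrix(dose)
        assert genotype_call_rate(gm, gm.variants[0]) == pytest.approx(357 / 358)
        kept, report = site_qc(gm, QcThresholds(min_call_rate=1.0))
        assert kept.n_variants == 0
        assert report["fail_reason"].iloc[0] == "call_rate"

    def test_mask_boundaries_are_strict(self):
        gm = make_matrix(
            [[1, 1, 2]],
            dp=[[9, 30, 10]],
            gq=[[99, 49, 50]],
        )
        masked = mask_low_quality_calls(gm, QcThresholds())
        assert list(masked.dose[0]) == [-1, -1, 2]

    def test_absent_dp_gq_fields_pass(self):
        gm = make_matrix([[1, 2]])
        masked = mask_low_quality_calls(gm, QcThresholds())
        np.testing.assert_array_equal(masked.dose, gm.dose)


class TestSiteQc:
    def _hwe_failing_counts(self):
        # all-het site at large n deviates wildly from HWE
        return [1] * 100

    def test_hwe_removal_and_strict_boundary(self):
        dose = np.array([self._hwe_failing_counts(), [0] * 50 + [1] * 30 + [2] * 20]).T
        gm = make_matrix(dose)
        kept, report = site_qc(gm, QcThresholds(min_call_rate=0.0))
        assert report["fail_reason"].tolist() == ["hwe", ""]
        assert kept.n_variants == 1

    def test_idempotent(self, small_study):
        thr = QcThresholds()
        once, _ = site_qc(small_study.discovery, thr)
        twice, rep = site_qc(once, thr)
        assert twice.variants == once.variants
        assert (rep["fail_reason"] == "").all()

    def test_planted_failures_detected(self):
        from popexclusive import QualityConfig, simulate_study
        from conftest import small_sim_config

        cfg = small_sim_config(
            seed=21,
            quality=QualityConfig(planted_low_dp_sites=5, planted_low_dp_fraction=0.2),
        )
        study = simulate_study(cfg)
        kept, report = site_qc(study.discovery, QcThresholds())
        planted = study.truth.variants["planted_low_dp"].to_numpy()
        failed = (report["fail_reason"] == "call_rate").to_numpy()
        # every planted low-depth site fails the 100% call-rate rule
        assert failed[planted].all()


@pytest.fixture(scope="module")
def related_matrix():
    rng = np.random.default_rng(17)
    sites = 5000
    p = rng.uniform(0.05, 0.5, sites)
    dose = rng.binomial(2, p[None, :], (8, sites)).astype(np.int8)
    dose[1] = dose[0]  # S1 duplicates S0
    a1 = rng.random(sites) < dose[2] / 2.0
    a2 = rng.random(sites) < dose[3] / 2.0
    dose[4] = a1.astype(np.int8) + a2.astype(np.int8)  # S4 child of S2,S3
    keys = [VariantKey("1", i + 1, "A", "G") for i in range(sites)]
    return make_matrix(dose, variants=keys), p


class TestRelatedness:
    def test_duplicate_pair(self, related_matrix):
        gm, p = related_matrix
        est = ibd_mom(gm, ("S0", "S1"), ref_freqs=p)
        assert est.pi_hat == pytest.approx(1.0, abs=0.05)

    def test_parent_offspring_pair(self, related_matrix):
        gm, p = related_matrix
        est = ibd_mom(gm, ("S2", "S4"), ref_freqs=p)
        assert est.pi_hat == pytest.approx(0.5, abs=0.05)

    def test_unrelated_pair(self, related_matrix):
        gm, p = related_matrix
        est = ibd_mom(gm, ("S5", "S6"), ref_freqs=p)
        assert est.pi_hat == pytest.approx(0.0, abs=0.05)

    def test_k_simplex(self, related_matrix):
        gm, p = related_matrix
        for pair in [("S0", "S1"), ("S2", "S4"), ("S5", "S7")]:
            e = ibd_mom(gm, pair, ref_freqs=p)
            assert e.k0 + e.k1 + e.k2 == pytest.approx(1.0, abs=1e-9)
            assert 0.0 <= e.pi_hat <= 1.0

    def test_too_few_sites_raises(self):
        gm = make_matrix(
            np.zeros((2, 100), dtype=np.int8),
            variants=[VariantKey("1", i + 1, "A", "G") for i in range(100)],
        )
        with pytest.raises(ValueError, match="informative"):
            ibd_mom(gm, ("S0", "S1"), ref_freqs=np.full(100, 0.3))


class TestSelectUnrelated:
    def test_no_related_pairs_keeps_all(self, related_matrix=None):
        from popexclusive import RelatednessEstimate

        ests = [
            RelatednessEstimate(("A", "B"), 1.0, 0.0, 0.0),
            RelatednessEstimate(("A", "C"), 1.0, 0.0, 0.0),
        ]
        assert select_unrelated(ests, 0.1875) == {"A", "B", "C"}

    def test_duplicate_pair_removes_exactly_one(self):
        from popexclusive import RelatednessEstimate

        ests = [RelatednessEstimate(("A", "B"), 0.0, 0.0, 1.0)]
        kept = select_unrelated(ests, 0.1875)
        assert len(kept) == 1

    def test_trio_resolution_exhaustive(self):
        # a trio (father-mother unrelated, two parent-offspring edges) plus
        # unrelated bystanders: selection must break every related edge
        from popexclusive import RelatednessEstimate

        def est(a, b, pi):
            return RelatednessEstimate((a, b), 1 - pi, 0.0, pi)

        ests = [
            est("father", "child", 0.5),
            est("mother", "child", 0.5),
            est("father", "mother", 0.01),
            est("father", "U1", 0.0),
            est("U1", "U2", 0.02),
        ]
        kept = select_unrelated(ests, 0.1875)
        related = {("father", "child"), ("mother", "child")}
        for a, b in related:
            assert not (a in kept and b in kept)
        assert {"U1", "U2"} <= kept
        # removing the child alone suffices; greedy should keep both parents
        assert kept == {"father", "mother", "U1", "U2"}

    def test_no_pair_above_threshold_after_selection(self, small_study):
        from popexclusive.synthetic_data import inject_related
        import numpy as np

        rng = np.random.default_rng(3)
        gm = inject_related(
            small_study.discovery, (("duplicate", 1), ("parent_offspring", 1)), rng
        )
        ests = pairwise_relatedness(gm.take_samples(range(12)))
        kept = select_unrelated(ests, 0.1875)
        for e in ests:
            a, b = e.sample_pair
            if a in kept and b in kept:
                assert e.pi_hat < 0.1875
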