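import numpy as np
import pytest

from popexclusive import (
    GenotypeCounts,
    VariantKey,
    fst_between,
    mean_pairwise_fst,
    pca,
    standardize_genotypes,
    weir_cockerham_site,
)

from conftest import make_matrix


def wc_oracle(genotype_counts):
    """Independent transcription of the Weir & Cockerham (1984) components.

    Written from the published equations in their original scalar form
    (sums over populations of sample sizes n_i, allele frequencies p_i and
    heterozygote proportions h_i), deliberately not sharing code with the
    implementation under test.
    """
    r = len(genotype_counts)
    n = [c.n_called for c in genotype_counts]
    p = [(c.n_het + 2 * c.n_hom_alt) / (2 * c.n_called) for c in genotype_counts]
    h = [c.n_het / c.n_called for c in genotype_counts]

    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    ssq = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)

    a = (nbar / nc) * (
        ssq - (pbar * (1 - pbar) - (r - 1) / r * ssq - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * ssq - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def two_pop_matrix(d1, d2, sites):
    keys = [VariantKey("1", i + 1, "A", "G") for i in range(sites)]
    ns1, ns2 = d1.shape[0], d2.shape[0]
    gm = make_matrix(
        np.vstack([d1, d2]),
        samples=[f"A{i}" for i in range(ns1)] + [f"B{i}" for i in range(ns2)],
        variants=keys,
    )
    pops = {"P1": [f"A{i}" for i in range(ns1)], "P2": [f"B{i}" for i in range(ns2)]}
    return gm, pops


class TestStandardize:
    def test_zero_mean_columns(self):
        gm = make_matrix([[0], [1], [2]])
        x, kept = standardize_genotypes(gm)
        assert kept.tolist() == [0]
        assert x[:, 0].mean() == pytest.approx(0.0, abs=1e-12)

    def test_identical_samples_identical_rows(self):
        gm = make_matrix([[0, 1, 2, 1], [0, 1, 2, 1], [2, 0, 0, 1]])
        x, _ = standardize_genotypes(gm)
        np.testing.assert_allclose(x[0], x[1])

    def test_monomorphic_and_all_missing_dropped(self):
        gm = make_matrix([[0, 1, -1], [0, 2, -1], [0, 1, -1]])
        x, kept = standardize_genotypes(gm)
        assert kept.tolist() == [1]


class TestPca:
    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(7)
        sites, n = 2000, 50
        p = rng.uniform(0.05, 0.5, sites)
        F = 0.1
        f1 = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        f2 = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        d1 = rng.binomial(2, f1[None, :], (n, sites)).astype(np.int8)
        d2 = rng.binomial(2, f2[None, :], (n, sites)).astype(np.int8)
        gm, _ = two_pop_matrix(d1, d2, sites)
        res = pca(gm, n_components=2)
        pc1 = res.coordinates[:, 0]
        gap = abs(pc1[:n].mean() - pc1[n:].mean())
        within = max(pc1[:n].std(), pc1[n:].std())
        assert gap > 4 * within

    def test_single_population_no_label_separation(self):
        rng = np.random.default_rng(8)
        sites, n = 1000, 60
        p = rng.uniform(0.05, 0.5, sites)
        dose = rng.binomial(2, p[None, :], (n, sites)).astype(np.int8)
        gm = make_matrix(dose, variants=[VariantKey("1", i + 1, "A", "G") for i in range(sites)])
        res = pca(gm, n_components=2)
        pc1 = res.coordinates[:, 0]
        labels = rng.permutation(n) < n // 2  # random split
        gap = abs(pc1[labels].mean() - pc1[~labels].mean())
        # under the null the standardized centroid gap is O(1/sqrt(n))
        assert gap < 4 * pc1.std() / np.sqrt(n // 2)

    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(9)
        dose = rng.binomial(2, 0.3, size=(20, 300)).astype(np.int8)
        dose[1] = dose[0]
        gm = make_matrix(dose, variants=[VariantKey("1", i + 1, "A", "G") for i in range(300)])
        res = pca(gm, n_components=3)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-8)

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(10)
        dose = rng.binomial(2, 0.3, size=(30, 200)).astype(np.int8)
        gm = make_matrix(dose, variants=[VariantKey("1", i + 1, "A", "G") for i in range(200)])
        res = pca(gm, n_components=5)
        ev = res.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1.0 + 1e-9

    def test_too_few_samples(self):
        gm = make_matrix([[0, 1]])
        with pytest.raises(ValueError):
            pca(gm, n_components=1)


class TestWeirCockerhamSite:
    def test_complete_fixation(self):
        c = [GenotypeCounts(10, 0, 0), GenotypeCounts(0, 0, 10)]
        a, b, cc = weir_cockerham_site(c)
        assert a / (a + b + cc) == pytest.approx(1.0)

    def test_no_differentiation_identical_pops(self):
        c = [GenotypeCounts(4, 12, 4), GenotypeCounts(4, 12, 4)]
        a, b, cc = weir_cockerham_site(c)
        assert a == pytest.approx(0.0, abs=0.05)
        assert a <= 0.0 + 1e-12 or a / (a + b + cc) < 0.05

    def test_matches_independent_transcription(self):
        counts = [GenotypeCounts(4, 2, 4), GenotypeCounts(8, 2, 0)]
        got = weir_cockerham_site(counts)
        want = wc_oracle(counts)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_matches_oracle_random_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            counts = []
            for _ in range(rng.integers(2, 5)):
                n = int(rng.integers(5, 40))
                hr = int(rng.integers(0, n + 1))
                het = int(rng.integers(0, n - hr + 1))
                counts.append(GenotypeCounts(hr, het, n - hr - het))
            alt_total = sum(c.alt_count for c in counts)
            tot = sum(c.total_count for c in counts)
            if alt_total == 0 or alt_total == tot:
                continue
            np.testing.assert_allclose(
                weir_cockerham_site(counts), wc_oracle(counts), atol=1e-10
            )

    def test_monomorphic_across_pops_zeroed(self):
        c = [GenotypeCounts(10, 0, 0), GenotypeCounts(10, 0, 0)]
        assert weir_cockerham_site(c) == (0.0, 0.0, 0.0)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            weir_cockerham_site([GenotypeCounts(5, 5, 0)])


class TestMeanPairwiseFst:
    def test_null_within_population(self):
        rng = np.random.default_rng(14)
        sites, n = 2000, 100
        p = rng.uniform(0.05, 0.5, sites)
        d1 = rng.binomial(2, p[None, :], (n, sites)).astype(np.int8)
        d2 = rng.binomial(2, p[None, :], (n, sites)).astype(np.int8)
        gm, pops = two_pop_matrix(d1, d2, sites)
        est = fst_between(gm, pops, ("P1", "P2"))
        assert abs(est.mean_fst) < 0.005

    def test_balding_nichols_parameter_recovery(self):
        rng = np.random.default_rng(15)
        sites, n, F = 5000, 100, 0.05
        p = rng.uniform(0.05, 0.5, sites)
        f1 = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        f2 = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        d1 = rng.binomial(2, f1[None, :], (n, sites)).astype(np.int8)
        d2 = rng.binomial(2, f2[None, :], (n, sites)).astype(np.int8)
        gm, pops = two_pop_matrix(d1, d2, sites)
        est = fst_between(gm, pops, ("P1", "P2"))
        assert est.mean_fst == pytest.approx(F, abs=0.01)

    def test_three_populations_symmetric(self):
        rng = np.random.default_rng(16)
        sites = 500
        p = rng.uniform(0.1, 0.5, sites)
        doses = [rng.binomial(2, p[None, :], (20, sites)).astype(np.int8) for _ in range(3)]
        keys = [VariantKey("1", i + 1, "A", "G") for i in range(sites)]
        samples = [f"{g}{i}" for g in "ABC" for i in range(20)]
        gm = make_matrix(np.vstack(doses), samples=samples, variants=keys)
        pops = {g: [f"{g}{i}" for i in range(20)] for g in "ABC"}
        ests = mean_pairwise_fst(gm, pops)
        assert len(ests) == 3
        fwd = fst_between(gm, pops, ("A", "B")).mean_fst
        rev = fst_between(gm, pops, ("B", "A")).mean_fst
        assert fwd == pytest.approx(rev, abs=1e-12)

    def test_divergence_rank_preserved(self):
        rng = np.random.default_rng(18)
        sites, n = 2000, 60
        p = rng.uniform(0.05, 0.5, sites)
        ests = []
        for F in (0.01, 0.05, 0.1, 0.2):
            f1 = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
            f2 = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
            d1 = rng.binomial(2, f1[None, :], (n, sites)).astype(np.int8)
            d2 = rng.binomial(2, f2[None, :], (n, sites)).astype(np.int8)
            gm, pops = two_pop_matrix(d1, d2, sites)
            ests.append(fst_between(gm, pops, ("P1", "P2")).mean_fst)
        assert ests == sorted(ests)
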