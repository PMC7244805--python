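"""Core statistics: distances, LD pruning, PCA, F_ST (against a
brute-force ANOVA oracle), folded SFS, and theta-from-homozygosity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gradientpanmixia as gp
from gradientpanmixia.datatypes import MISSING, AlleleCountTable, GenotypeMatrix
from gradientpanmixia.popgen import _pairwise_r2


def brute_force_wc_theta(x1, n1, x2, n2):
    """Two-level ANOVA on explicit allele indicator vectors.

    Builds the actual 0/1 allele arrays per population and locus, computes
    sums of squares from their definitions, and combines the per-locus
    variance components as a ratio of sums.  Independent of the
    production implementation, which works from sufficient statistics.
    """
    num = 0.0
    den = 0.0
    for l in range(len(x1)):
        groups = [
            np.array([1] * int(x1[l]) + [0] * int(n1[l] - x1[l]), dtype=float),
            np.array([1] * int(x2[l]) + [0] * int(n2[l] - x2[l]), dtype=float),
        ]
        sizes = np.array([len(g) for g in groups], dtype=float)
        if (sizes == 0).any() or sizes.sum() <= 2:
            continue
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssp = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssg = sum(((g - g.mean()) ** 2).sum() for g in groups)
        msp = ssp / (len(groups) - 1)
        msg = ssg / (sizes.sum() - len(groups))
        nc = (sizes.sum() - (sizes**2).sum() / sizes.sum()) / (len(groups) - 1)
        sigma_a = (msp - msg) / nc
        num += sigma_a
        den += sigma_a + msg
    return num / den if den != 0 else np.nan


def make_counts(x1, n1, x2, n2):
    L = len(x1)
    return AlleleCountTable(
        ref_count=np.array([x1, x2]),
        total_alleles=np.array([n1, n2]),
        population_ids=["A", "B"],
        locus_ids=[f"l{i}" for i in range(L)],
    )


class TestFst:
    def test_fixed_difference_is_one(self):
        counts = make_counts([4, 4], [4, 4], [0, 0], [4, 4])
        assert gp.pairwise_fst_wc(counts, "A", "B") == pytest.approx(1.0)

    def test_panmictic_pool_near_zero(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.2, 0.8, 500)
        x1 = rng.binomial(100, p)
        x2 = rng.binomial(100, p)
        counts = make_counts(x1, np.full(500, 100), x2, np.full(500, 100))
        fst = gp.pairwise_fst_wc(counts, 0, 1)
        assert abs(fst) < 0.01  # can be slightly negative

    def test_matches_bruteforce_oracle(self):
        """Tables with n <= 4 alleles: exhaustive for 1-2 loci, strided at 3.

        The full n <= 6 enumeration runs in the acceptance suite; this is
        the literal-allele-array oracle on a dense sweep.
        """
        n_checked = 0
        for n1, n2 in itertools.product(range(1, 5), repeat=2):
            if n1 + n2 <= 2:
                continue
            single = list(itertools.product(range(n1 + 1), range(n2 + 1)))
            for m in (1, 2, 3):
                stride = 1 if m <= 2 else 3
                for i, cfg in enumerate(itertools.product(single, repeat=m)):
                    if i % stride:
                        continue
                    x1 = [c[0] for c in cfg]
                    x2 = [c[1] for c in cfg]
                    expected = brute_force_wc_theta(x1, [n1] * m, x2, [n2] * m)
                    counts = make_counts(x1, [n1] * m, x2, [n2] * m)
                    if np.isnan(expected):
                        with pytest.raises(ValueError):
                            gp.pairwise_fst_wc(counts, 0, 1)
                    else:
                        got = gp.pairwise_fst_wc(counts, 0, 1)
                        assert got == pytest.approx(expected, abs=1e-12)
                        n_checked += 1
        assert n_checked > 10_000

    def test_global_fst_two_pops_matches_pairwise(self):
        rng = np.random.default_rng(3)
        x1 = rng.integers(0, 11, 50)
        x2 = rng.integers(0, 11, 50)
        counts = make_counts(x1, np.full(50, 10), x2, np.full(50, 10))
        assert gp.global_fst_wc(counts) == pytest.approx(
            gp.pairwise_fst_wc(counts, 0, 1)
        )


class TestDistances:
    def test_haversine_examples(self, gradient4):
        loc = gp.LocalityTable(
            pd.DataFrame(
                {
                    "locality_id": ["a", "b"],
                    "latitude": [0.0, 0.0],
                    "longitude": [0.0, 1.0],
                    "elevation": [0.0, 100.0],
                    "mean_annual_temperature": [20.0, 19.0],
                    "mean_annual_precipitation": [1000.0, 1100.0],
                    "n_individuals": [1, 1],
                }
            )
        )
        d = gp.haversine_distance_matrix(loc)
        assert d[0, 1] == pytest.approx(2 * np.pi * 6371 / 360, abs=1e-3)
        assert d[0, 0] == 0.0
        d4 = gp.haversine_distance_matrix(gradient4)
        assert np.allclose(d4, d4.T)

    def test_environmental_distance_single_variable(self):
        loc = gp.LocalityTable(
            pd.DataFrame(
                {
                    "locality_id": ["a", "b"],
                    "latitude": [0.0, 0.1],
                    "longitude": [0.0, 0.0],
                    "elevation": [0.0, 100.0],
                    "mean_annual_temperature": [20.0, 19.0],
                    "mean_annual_precipitation": [1000.0, 1100.0],
                    "n_individuals": [1, 1],
                }
            )
        )
        e = gp.environmental_distance_matrix(loc, ("elevation",))
        # z-scores with sample SD are +-1/sqrt(2); distance sqrt(2)
        assert e[0, 1] == pytest.approx(np.sqrt(2))
        shifted = loc.table.copy()
        shifted["mean_annual_temperature"] += 7.5
        e2 = gp.environmental_distance_matrix(
            gp.LocalityTable(shifted), ("elevation", "MAT")
        )
        e1 = gp.environmental_distance_matrix(loc, ("elevation", "MAT"))
        assert np.allclose(e1, e2)

    def test_zero_variance_variable_errors(self, gradient4):
        t = gradient4.table.copy()
        t["mean_annual_temperature"] = 12.0
        with pytest.raises(ValueError, match="MAT"):
            gp.environmental_distance_matrix(gp.LocalityTable(t), ("MAT",))

    def test_matrix_correlation(self):
        rng = np.random.default_rng(0)
        a = rng.random((5, 5))
        a = a + a.T
        np.fill_diagonal(a, 0)
        assert gp.matrix_correlation(a, a) == pytest.approx(1.0)
        assert gp.matrix_correlation(a, -a + 3) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            gp.matrix_correlation(a, np.zeros_like(a))


def _matrix(dosage, contigs=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    ids = [f"i{k}" for k in range(n)]
    return GenotypeMatrix(
        dosage=dosage,
        individual_ids=ids,
        locus_ids=[f"l{j}" for j in range(L)],
        contigs=contigs or ["c1"] * L,
        locality_of={i: "P1" for i in ids},
    )


class TestLDPrune:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, 30)
        g = _matrix(np.column_stack([col, col, rng.integers(0, 3, 30)]))
        pruned = gp.ld_prune(g, max_r2=0.1)
        assert pruned.locus_ids == ["l0", "l2"]

    def test_independent_loci_survive(self):
        rng = np.random.default_rng(3)
        g = _matrix(rng.binomial(2, 0.5, size=(200, 30)))
        pruned = gp.ld_prune(g, max_r2=0.2)
        assert pruned.n_loci >= 28  # chance correlations only

    def test_one_survivor_per_block(self):
        rng = np.random.default_rng(4)
        base = [rng.integers(0, 3, 100) for _ in range(3)]
        blocks = np.column_stack([b for b in base for _ in range(4)])
        pruned = gp.ld_prune(_matrix(blocks), max_r2=0.1)
        assert pruned.n_loci == 3
        assert pruned.locus_ids == ["l0", "l4", "l8"]

    def test_contig_boundaries_reset_window(self):
        col = np.tile([0, 1, 2, 1], 10)
        dosage = np.column_stack([col, col])
        g = _matrix(dosage, contigs=["c1", "c2"])
        assert gp.ld_prune(g).n_loci == 2  # identical but different contigs


class TestPCA:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(5)
        a = rng.binomial(2, 0.1, size=(20, 100))
        b = rng.binomial(2, 0.9, size=(20, 100))
        g = _matrix(np.vstack([a, b]))
        res = gp.genotype_pca(g, 4)
        side = res.scores[:, 0] > 0
        assert side[:20].all() != side[20:].all()
        assert (side[:20] == side[0]).all() and (side[20:] == side[20]).all()
        assert res.variance_fraction[0] > res.variance_fraction[1]

    def test_duplicated_individual_identical_scores(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.5, size=(10, 50))
        d[1] = d[0]
        res = gp.genotype_pca(_matrix(d), 3)
        assert np.allclose(res.scores[0], res.scores[1])

    def test_variance_fractions_monotone(self, small_dataset):
        genotypes = small_dataset[0]
        res = gp.genotype_pca(genotypes, 8)
        assert (np.diff(res.variance_fraction) <= 1e-12).all()
        assert res.variance_fraction.sum() <= 1 + 1e-9

    def test_group_recovery_rate_across_seeds(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.binomial(2, 0.3, size=(10, 80))
            b = rng.binomial(2, 0.7, size=(10, 80))
            res = gp.genotype_pca(_matrix(np.vstack([a, b])), 2)
            side = res.scores[:, 0] > np.median(res.scores[:, 0])
            hits += (side[:10] == side[0]).all() and (side[10:] == (~side[0])).all()
        assert hits >= 99

    def test_outlier_flagging(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.5, size=(30, 200))
        d[0] = 2  # an individual fixed for the reference everywhere
        res = gp.genotype_pca(_matrix(d), 2)
        flags = gp.flag_outlier_individuals(res, mad_factor=6)
        assert flags[0]
        assert flags.sum() <= 2
        assert not gp.flag_outlier_individuals(res, mad_factor=np.inf).any()


class TestSFS:
    def test_minimal_example(self):
        g = _matrix([[1, 0], [0, 0]])  # 4 haplotypes; locus 0 singleton
        sfs = gp.folded_sfs(g)
        assert sfs.n == 4
        assert list(sfs.xi) == [1, 0]

    def test_sum_equals_segregating_sites(self, small_dataset):
        genotypes = small_dataset[0]
        complete = genotypes.subset(
            loci=np.where((genotypes.dosage != MISSING).all(axis=0))[0]
        )
        sfs = gp.folded_sfs(complete)
        x = complete.dosage.sum(axis=0)
        n = 2 * complete.n_individuals
        expected = int(((x > 0) & (x < n)).sum())
        assert sfs.segregating_sites == expected

    def test_projection_rescues_sites_with_missingness(self):
        rng = np.random.default_rng(11)
        d = rng.integers(0, 3, size=(30, 400)).astype(np.int8)
        mask = rng.random(d.shape) < 0.1
        d[mask] = MISSING
        g = _matrix(d)
        complete = gp.folded_sfs(g)
        projected = gp.folded_sfs(g, project_to=48, seed=1)
        assert projected.n == 48
        assert projected.n_loci > 10 * max(complete.n_loci, 1)
        # deterministic under the seed
        again = gp.folded_sfs(g, project_to=48, seed=1)
        assert np.array_equal(projected.xi, again.xi)
        # projection of complete data preserves overall frequencies
        full = rng.integers(0, 3, size=(30, 2000)).astype(np.int8)
        gfull = _matrix(full)
        p_full = gp.folded_sfs(gfull).proportions()
        p_proj = gp.folded_sfs(gfull, project_to=40, seed=2).proportions()
        # compare mass in the low-frequency half
        assert p_proj[:10].sum() == pytest.approx(p_full[:15].sum(), abs=0.08)

    @given(st.integers(min_value=0, max_value=10 ** 6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fold_invariant_to_allele_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        flip = rng.random(40) < 0.5
        d2 = d.copy()
        d2[:, flip] = 2 - d2[:, flip]
        xi1 = gp.folded_sfs(_matrix(d)).xi
        xi2 = gp.folded_sfs(_matrix(d2)).xi
        assert np.array_equal(xi1, xi2)


class TestTheta:
    def test_closed_forms(self):
        counts = AlleleCountTable(
            ref_count=np.array([[5, 10, 0]]),
            total_alleles=np.array([[10, 10, 10]]),
            population_ids=["A"],
            locus_ids=["a", "b", "c"],
        )
        t = gp.theta_from_homozygosity(counts, "A")
        # p=0.5, n=10: H = (10/9)(1-0.5) = 0.5556, theta = H/(1-H) = 1.25
        assert t["H_hat"].iloc[0] == pytest.approx(0.55556, abs=1e-4)
        assert t["theta_hat"].iloc[0] == pytest.approx(1.25, abs=1e-4)
        assert t["theta_hat"].iloc[1] == 0.0  # monomorphic
        assert t["theta_hat"].iloc[2] == 0.0

    def test_h_half_gives_theta_one(self):
        # H = 0.5 exactly: solve (n/(n-1))(1-p^2-q^2) = 0.5 with n=100
        n = 100
        h2 = 1 - 0.5 * (n - 1) / n  # p^2 + q^2
        p = 0.5 + np.sqrt(h2 / 2 - 0.25)
        x = p * n
        counts = AlleleCountTable(
            ref_count=np.array([[x]]),
            total_alleles=np.array([[n]]),
            population_ids=["A"],
            locus_ids=["a"],
        )
        counts.ref_count = np.array([[x]])  # keep fractional for the check
        nvec = counts.total_alleles[0].astype(float)
        pv = counts.ref_count[0] / nvec
        h = (nvec / (nvec - 1)) * (1 - pv**2 - (1 - pv) ** 2)
        assert h[0] == pytest.approx(0.5)
        assert (h / (1 - h))[0] == pytest.approx(1.0)

    def test_relabeling_invariance_and_monotonicity(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 21, 200)
        counts = AlleleCountTable(
            ref_count=x[None, :],
            total_alleles=np.full((1, 200), 20),
            population_ids=["A"],
            locus_ids=[f"l{i}" for i in range(200)],
        )
        flipped = AlleleCountTable(
            ref_count=(20 - x)[None, :],
            total_alleles=np.full((1, 200), 20),
            population_ids=["A"],
            locus_ids=[f"l{i}" for i in range(200)],
        )
        t1 = gp.theta_from_homozygosity(counts, 0)["theta_hat"]
        t2 = gp.theta_from_homozygosity(flipped, 0)["theta_hat"]
        assert np.allclose(t1, t2)

    def test_median_theta_increases_with_diversity(self):
        medians = []
        for theta in (0.5, 2.0, 8.0):
            rng = np.random.default_rng(9)
            # stationary mutation-drift frequencies Beta(theta, theta):
            # larger theta concentrates p near 1/2 and raises heterozygosity
            p = np.clip(rng.beta(theta, theta, 300), 0.01, 0.99)
            x = rng.binomial(20, p)
            counts = AlleleCountTable(
                ref_count=x[None, :],
                total_alleles=np.full((1, 300), 20),
                population_ids=["A"],
                locus_ids=[f"l{i}" for i in range(300)],
            )
            medians.append(gp.theta_from_homozygosity(counts, 0)["theta_hat"].median())
        assert medians[0] < medians[1] < medians[2]


def test_tally_alleles_hand_count():
    dosage = np.array(
        [[0, 2, MISSING], [2, 1, 1], [1, 0, MISSING], [2, 2, 0], [0, 1, 2]],
        dtype=np.int8,
    )
    ids = [f"i{k}" for k in range(5)]
    g = GenotypeMatrix(
        dosage=dosage,
        individual_ids=ids,
        locus_ids=["a", "b", "c"],
        contigs=["c"] * 3,
        locality_of={"i0": "P1", "i1": "P1", "i2": "P1", "i3": "P2", "i4": "P2"},
    )
    counts = gp.tally_alleles(g)
    assert counts.population_ids == ["P1", "P2"]
    assert counts.ref_count.tolist() == [[3, 3, 1], [2, 3, 2]]
    assert counts.total_alleles.tolist() == [[6, 6, 2], [4, 4, 4]]


def test_pairwise_r2_handles_missing():
    x = np.array([0, 1, 2, np.nan, 2])
    y = np.array([0, 1, 2, 2, np.nan])
    assert _pairwise_r2(x, y) == pytest.approx(1.0)
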