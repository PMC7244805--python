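"""Coalescent engine against analytic and msprime oracles; rejection-ABC
mechanics, Bayes-factor identities, and cross-validation behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gradientpanmixia.datatypes import SFS
from gradientpanmixia.demography import (
    DemographicABC,
    DemographicModel,
    _simulate_branch_lengths,
    abc_model_choice,
    abc_rejection,
    build_reference_table,
    cv_model_choice,
    mean_total_branch_length,
    simulate_coalescent_sfs,
)


class TestCoalescentEngine:
    def test_model_validation(self):
        with pytest.raises(ValueError):
            DemographicModel("null", theta=5.0, alpha=1.0)
        with pytest.raises(ValueError):
            DemographicModel("growth", theta=-1.0)
        with pytest.raises(ValueError):
            DemographicModel("growth", theta=1.0, alpha=-2.0)

    def test_constant_size_total_branch_length(self):
        rng = np.random.default_rng(1)
        n = 12
        lengths = _simulate_branch_lengths(0.0, n, 30_000, rng)
        total = lengths.sum(axis=1)
        expected = mean_total_branch_length(n)
        se = total.std() / np.sqrt(len(total))
        assert total.mean() == pytest.approx(expected, abs=4 * se)

    def test_tiny_growth_indistinguishable_from_none(self):
        rng = np.random.default_rng(2)
        a = _simulate_branch_lengths(0.0, 10, 4000, rng).sum(axis=1)
        b = _simulate_branch_lengths(1e-9, 10, 4000, rng).sum(axis=1)
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_singleton_fraction_monotone_in_growth(self):
        fracs = []
        for i, alpha in enumerate((0.0, 1.0, 5.0, 20.0)):
            model = DemographicModel("growth" if alpha else "null", theta=5.0, alpha=alpha)
            sfs = simulate_coalescent_sfs(model, n_diploids=15, n_loci=10_000, seed=40 + i)
            fracs.append(sfs.xi[0] / sfs.segregating_sites)
        assert fracs == sorted(fracs)

    def test_growth_branch_lengths_match_msprime(self):
        msprime = pytest.importorskip("msprime")
        n, alpha, reps = 16, 5.0, 3000
        rng = np.random.default_rng(3)
        mine = _simulate_branch_lengths(alpha, n, 20_000, rng).mean(axis=0)
        dem = msprime.Demography()
        dem.add_population(initial_size=1.0, growth_rate=alpha)
        totals = np.zeros(n - 1)
        for ts in msprime.sim_ancestry(
            samples=n, ploidy=1, demography=dem, num_replicates=reps, random_seed=99
        ):
            t = ts.first()
            for node in t.nodes():
                if t.parent(node) != -1:
                    k = t.num_samples(node)
                    totals[k - 1] += t.branch_length(node)
        theirs = totals / reps
        # compare the dominant classes; Monte-Carlo error grows for rare ones
        assert np.allclose(mine[:6], theirs[:6], rtol=0.08)
        assert mine.sum() == pytest.approx(theirs.sum(), rel=0.05)

    def test_folded_spectrum_shape(self):
        sfs = simulate_coalescent_sfs(DemographicModel("null", theta=3.0), 10, 200, seed=4)
        assert sfs.folded and sfs.n == 20 and len(sfs.xi) == 10
        unfolded = simulate_coalescent_sfs(
            DemographicModel("null", theta=3.0), 10, 200, seed=4, folded=False
        )
        assert len(unfolded.xi) == 19
        assert unfolded.segregating_sites == sfs.segregating_sites


class TestReferenceTable:
    def test_shapes_and_prior_bounds(self):
        tab = build_reference_table("growth", n_sims=100, n_diploids=8, n_loci=20, seed=5)
        assert len(tab) == 100
        assert tab["theta"].between(0.1, 20).all()
        assert tab["alpha"].between(0, 10).all()
        assert tab.filter(like="xi").shape[1] == 8

    def test_null_table_has_zero_alpha(self):
        tab = build_reference_table("null", n_sims=50, n_diploids=5, n_loci=10, seed=6)
        assert (tab["alpha"] == 0).all()

    def test_fixed_seed_reproducible(self):
        a = build_reference_table("growth", n_sims=60, n_diploids=6, n_loci=10, seed=7)
        b = build_reference_table("growth", n_sims=60, n_diploids=6, n_loci=10, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_theta_marginal_matches_loguniform_prior(self):
        tab = build_reference_table("null", n_sims=10_000, n_diploids=3, n_loci=5, seed=8)
        logt = np.log(tab["theta"])
        ks = stats.kstest(
            logt, stats.uniform(np.log(0.1), np.log(20) - np.log(0.1)).cdf
        )
        assert ks.pvalue > 0.01


def _toy_table(values, thetas=None, model_extra=None):
    df = pd.DataFrame({"xi1": values})
    df.insert(0, "alpha", 0.0)
    df.insert(0, "theta", thetas if thetas is not None else np.arange(len(values), dtype=float) + 1)
    return df


class TestRejection:
    def test_accepts_closest_fraction(self):
        table = _toy_table([1.0, 2.0, 3.0, 4.0])
        obs = SFS(xi=[10], n=2, folded=True)  # proportions -> [1.0]
        res = abc_rejection(obs, table, tolerance=0.5)
        assert len(res.accepted) == 2
        assert set(res.accepted["xi1"]) == {1.0, 2.0}

    def test_exact_match_accepted_first(self):
        rng = np.random.default_rng(9)
        table = _toy_table(rng.uniform(0, 3, 200))
        table.loc[57, "xi1"] = 1.0  # equals the observed summary exactly
        obs = SFS(xi=[5], n=2, folded=True)
        res = abc_rejection(obs, table, tolerance=1 / 200)
        assert res.accepted["theta"].iloc[0] == table["theta"].iloc[57]
        assert res.distances[0] == 0.0

    def test_parameter_recovery_null_theta(self):
        table = build_reference_table("null", n_sims=4000, n_diploids=30, n_loci=50, seed=10)
        hits = 0
        for seed in range(10):
            obs = simulate_coalescent_sfs(
                DemographicModel("null", theta=5.0), 30, 50, seed=300 + seed
            )
            res = abc_rejection(obs, table, tolerance=0.05)
            hits += 2.5 <= res.posterior_median("theta") <= 10
        assert hits >= 9


class TestModelChoice:
    def test_identical_tables_give_bf_near_one(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 1, 2000)
        tables = {"null": _toy_table(vals), "growth": _toy_table(vals)}
        obs = SFS(xi=[3], n=2, folded=True)
        res = abc_model_choice(obs, tables, tolerance=0.1)
        bf = res.bayes_factors[("null", "growth")]
        assert 0.6 < bf < 1.7

    def test_bf_reciprocal_identity(self):
        rng = np.random.default_rng(12)
        tables = {
            "null": _toy_table(rng.uniform(0, 1, 500)),
            "growth": _toy_table(rng.uniform(0.5, 1.5, 500)),
        }
        obs = SFS(xi=[7], n=2, folded=True)
        res = abc_model_choice(obs, tables, tolerance=0.2)
        prod = (
            res.bayes_factors[("null", "growth")]
            * res.bayes_factors[("growth", "null")]
        )
        assert prod == pytest.approx(1.0)
        assert res.bayes_factors[("null", "null")] == 1.0

    def test_growth_model_recovered(self):
        tables = {
            m: build_reference_table(m, n_sims=3000, n_diploids=20, n_loci=50, seed=s)
            for m, s in (("null", 13), ("growth", 14))
        }
        wins = 0
        for seed in range(6):
            obs = simulate_coalescent_sfs(
                DemographicModel("growth", theta=5.0, alpha=8.0), 20, 50, seed=500 + seed
            )
            res = abc_model_choice(obs, tables, tolerance=0.05)
            wins += res.bayes_factors[("growth", "null")] > 1
        assert wins >= 5


class TestCrossValidation:
    def test_separated_toy_models_classified_perfectly(self):
        rng = np.random.default_rng(15)
        tables = {
            "null": _toy_table(rng.uniform(0, 0.4, 400)),
            "growth": _toy_table(rng.uniform(0.6, 1.0, 400)),
        }
        cv = cv_model_choice(tables, tolerances=(0.05,), n_pseudo=30, seed=16)
        cm = cv.confusion[0.05]
        assert cm.loc["null", "null"] == 30
        assert cm.loc["growth", "growth"] == 30

    def test_identical_models_near_chance(self):
        rng = np.random.default_rng(17)
        vals = rng.uniform(0, 1, 600)
        tables = {"null": _toy_table(vals.copy()), "growth": _toy_table(vals.copy())}
        cv = cv_model_choice(tables, tolerances=(0.05,), n_pseudo=40, seed=18)
        rate = (cv.correct_rate(0.05, "null") + cv.correct_rate(0.05, "growth")) / 2
        assert 0.25 < rate < 0.75

    def test_rows_sum_to_n_pseudo(self):
        rng = np.random.default_rng(19)
        tables = {
            "null": _toy_table(rng.uniform(0, 1, 300)),
            "growth": _toy_table(rng.uniform(0, 1.2, 300)),
        }
        cv = cv_model_choice(tables, tolerances=(0.01, 0.05), n_pseudo=20, seed=20)
        for cm in cv.confusion.values():
            assert (cm.sum(axis=1) == 20).all()


def test_model_results_surface():
    obs = simulate_coalescent_sfs(DemographicModel("null", theta=2.0), 10, 50, seed=21)
    abc = DemographicABC(obs)
    tables = abc.build_tables(n_sims=500, n_loci=50, seed=22)
    res = abc.fit(tables, tolerance=0.1)
    assert set(res.posterior_probabilities) == {"null", "growth"}
    assert res.summary()["n_accepted"].gt(0).all()
    assert set(res.parameter_posteriors) == {"null", "growth"}
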