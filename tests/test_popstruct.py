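"""Population-structure diagnostics: PCA, Weir–Cockerham theta and its
permutation test, diversity statistics, FDR, admixture splitting, merging
and balancing."""

import numpy as np
import pandas as pd
import pytest

from gsikit.core import MISSING, BaselineDefinition
from gsikit.popstruct import (
    FstResult,
    balance_and_trim,
    bh_fdr,
    diversity_stats,
    fit_admixture_k2,
    merge_indistinct_samples,
    pairwise_fst,
    pca_unscaled,
    split_by_ancestry,
    wc_theta,
)
from gsikit.simulate import (
    SimConfig,
    draw_population_freqs,
    simulate_baseline_genotypes,
    simulate_seasonal_sample,
)

from conftest import anova_theta, make_panel, make_table


def _grouping(table, basedef):
    return {i: basedef.site_to_population[s] for i, s in table.meta["sample_id"].items()}


class TestPca:
    def test_scores_match_eigendecomposition_oracle(self):
        """Scores agree (up to sign) with a direct eigendecomposition of the
        hand-built covariance matrix of the imputed, centred dosages."""
        X = np.array(
            [[0, 1, 2, 1], [2, 1, 0, 0], [1, 2, 1, 2], [0, 0, 2, 1], [2, 2, 0, 2]],
            dtype=np.int8,
        )
        table = make_table(X)
        res = pca_unscaled(table)
        Xc = X.astype(float) - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        oracle_scores = Xc @ vecs
        k = min(res.scores.shape[1], 4)
        assert np.allclose(np.abs(res.scores[:, :k]), np.abs(oracle_scores[:, :k]), atol=1e-8)
        assert np.allclose(res.explained_variance[:k], vals[:k], atol=1e-8)

    def test_fixed_difference_separates_groups_on_pc1(self):
        calls = np.array([[2, 1, 1], [2, 1, 1], [0, 1, 1], [0, 1, 1]], dtype=np.int8)
        res = pca_unscaled(make_table(calls))
        pc1 = res.scores[:, 0]
        assert np.sign(pc1[0]) == np.sign(pc1[1]) != np.sign(pc1[2])
        assert np.isclose(pc1[0], pc1[1]) and np.isclose(pc1[2], pc1[3])

    def test_constant_locus_has_zero_loading(self):
        calls = np.array([[2, 1], [2, 0], [2, 2], [2, 1]], dtype=np.int8)
        res = pca_unscaled(make_table(calls))
        assert np.allclose(res.loadings[0, :], 0.0, atol=1e-12)

    def test_missing_imputed_with_mean(self):
        calls = np.array([[2, MISSING], [0, 1], [2, 1]], dtype=np.int8)
        res = pca_unscaled(make_table(calls))  # must not raise
        assert res.scores.shape[0] == 3

    def test_monomorphic_table_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            pca_unscaled(make_table(np.full((3, 2), 2, dtype=np.int8)))

    def test_explained_variance_non_increasing(self, rng):
        calls = rng.integers(0, 3, size=(15, 8)).astype(np.int8)
        res = pca_unscaled(make_table(calls))
        assert np.all(np.diff(res.explained_variance) <= 1e-12)


class TestWcTheta:
    def test_matches_anova_oracle_on_fuzzed_tables(self, rng):
        """Ratio-of-sums theta equals the independent ANOVA mean-squares
        coding to 1e-10 on random tables with missing data."""
        for _ in range(30):
            r = rng.integers(2, 5)
            L = rng.integers(3, 9)
            ns = rng.integers(3, 11, size=r)
            groups = np.repeat(np.arange(r), ns)
            dosage = rng.integers(0, 3, size=(int(ns.sum()), L)).astype(float)
            dosage[rng.random(dosage.shape) < 0.1] = np.nan
            t = wc_theta(dosage, groups, int(r))
            o = anova_theta(dosage, groups)
            if np.isnan(o):
                assert np.isnan(t)
            else:
                assert t == pytest.approx(o, abs=1e-10)

    def test_fixed_difference_gives_theta_one(self):
        calls = np.vstack([np.full((10, 3), 2), np.zeros((10, 3))]).astype(np.int8)
        table = make_table(calls)
        grouping = {i: ("a" if k < 10 else "b") for k, i in enumerate(table.individuals)}
        res = pairwise_fst(table, grouping, n_permutations=99, seed=0)
        assert res.theta.loc["a", "b"] == pytest.approx(1.0)
        assert res.pvalues.loc["a", "b"] < 0.05

    def test_null_theta_near_zero_p_large(self):
        """Populations simulated from identical frequencies: theta ~ 0 and
        the permutation p-value is rarely significant."""
        hits = 0
        thetas = []
        for s in range(12):
            cfg = SimConfig(n_populations=2, n_loci=40, n_diagnostic=0, fst=0.2,
                            sample_sizes=50, missing_rate=0.0, seed=500 + s)
            freqs = draw_population_freqs(cfg)
            freqs[1] = freqs[0]
            table, bd, _ = simulate_baseline_genotypes(freqs, cfg)
            res = pairwise_fst(table, _grouping(table, bd), n_permutations=199, seed=s)
            thetas.append(res.theta.iloc[0, 1])
            hits += res.pvalues.iloc[0, 1] <= 0.05
        assert np.all(np.abs(thetas) < 0.02)
        assert hits <= 2

    def test_pair_without_shared_data_flagged_nan(self):
        calls = np.array(
            [[2, MISSING], [1, MISSING], [MISSING, 1], [MISSING, 0]], dtype=np.int8
        )
        table = make_table(calls)
        grouping = {i: ("a" if k < 2 else "b") for k, i in enumerate(table.individuals)}
        res = pairwise_fst(table, grouping, n_permutations=9, seed=0)
        assert np.isnan(res.theta.loc["a", "b"])

    def test_group_of_one_rejected(self):
        table = make_table(np.zeros((3, 2), dtype=np.int8))
        grouping = dict(zip(table.individuals, ["a", "a", "b"]))
        with pytest.raises(ValueError, match="fewer than two"):
            pairwise_fst(table, grouping, n_permutations=9)


class TestDiversity:
    def test_closed_form_uhe_and_fis(self):
        """p=0.5, Ho=0.4 from 10 genotyped individuals: uHe = 2pq * 2n/(2n-1)
        and Fis = 1 - Ho/uHe."""
        # 4 hets + three hom-ref + three hom-alt: dosage sum 10/20 -> p = 0.5, Ho = 0.4
        calls10 = np.array([[1], [1], [1], [1], [2], [2], [2], [0], [0], [0]], dtype=np.int8)
        stats_ = diversity_stats(make_table(calls10), {f"ind{i + 1:03d}": "g" for i in range(10)})
        row = stats_.per_population.loc["g"]
        uhe = (20 / 19) * 0.5
        assert row["Ho"] == pytest.approx(0.4)
        assert row["uHe"] == pytest.approx(uhe)
        assert row["Fis"] == pytest.approx(1 - 0.4 / uhe)

    def test_small_sample_uhe_formula(self):
        """n=5 at p=0.5 gives uHe = 0.5 * 10/9 = 0.5556."""
        calls = np.array([[1], [1], [2], [0], [1]], dtype=np.int8)
        # dosages 1,1,2,0,1 -> p = 0.5, n = 5
        stats_ = diversity_stats(make_table(calls), {f"ind{i + 1:03d}": "g" for i in range(5)})
        assert stats_.per_population.loc["g", "uHe"] == pytest.approx(0.5 * 10 / 9)

    def test_monomorphic_locus_excluded_from_fis(self):
        calls = np.array([[2, 1], [2, 1], [2, 0], [2, 2]], dtype=np.int8)
        stats_ = diversity_stats(make_table(calls), {f"ind{i + 1:03d}": "g" for i in range(4)})
        row = stats_.per_population.loc["g"]
        assert row["pct_polymorphic"] == pytest.approx(50.0)
        assert not np.isnan(row["Fis"])  # computed from the polymorphic locus only

    def test_excess_heterozygosity_gives_negative_fis(self):
        calls = np.full((6, 1), 1, dtype=np.int8)  # everyone heterozygous
        stats_ = diversity_stats(make_table(calls), {f"ind{i + 1:03d}": "g" for i in range(6)})
        row = stats_.per_population.loc["g"]
        assert row["Ho"] == 1.0 and row["Ho"] > row["uHe"] and row["Fis"] < 0


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_and_tied_pvalues_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_input_order_preserved(self):
        adj = bh_fdr([0.04, 0.01, 0.02])
        assert np.allclose(adj, [0.04, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


@pytest.fixture(scope="module")
def seasonal_fit():
    cfg = SimConfig(n_populations=2, n_loci=20, n_diagnostic=20, seed=21,
                    ecotypes=np.array([0, 1]))
    freqs = draw_population_freqs(cfg)
    table, truth = simulate_seasonal_sample(freqs, 40, 40, 20, seed=22)
    fit = fit_admixture_k2(table, n_restarts=4, seed=23)
    return table, truth, fit


class TestAdmixture:
    def test_loglik_monotone_within_restart(self, seasonal_fit):
        _, _, fit = seasonal_fit
        assert np.all(np.diff(fit.loglik_path) >= -1e-8)

    def test_pure_individuals_recovered(self, seasonal_fit):
        table, truth, fit = seasonal_fit
        q = pd.Series(fit.q, index=fit.individuals)
        a_ids = [i for i in table.individuals if truth.true_origin[i] == "cluster_A"]
        b_ids = [i for i in table.individuals if truth.true_origin[i] == "cluster_B"]
        qa, qb = q[a_ids].mean(), q[b_ids].mean()
        if qa < qb:  # label swap
            qa, qb = 1 - qa, 1 - qb
        assert qa >= 0.9 and (1 - qb) >= 0.9

    def test_admixed_q_recovered(self):
        cfg = SimConfig(n_populations=2, n_loci=20, n_diagnostic=20, seed=31,
                        ecotypes=np.array([0, 1]))
        freqs = draw_population_freqs(cfg)
        # anchor the clusters with pure individuals, then check the admixed
        table, truth = simulate_seasonal_sample(freqs, 30, 30, 40, seed=32)
        fit = fit_admixture_k2(table, n_restarts=4, seed=33)
        q = pd.Series(fit.q, index=fit.individuals)
        a_ids = [i for i in table.individuals if truth.true_origin[i] == "cluster_A"]
        if q[a_ids].mean() < 0.5:
            q = 1 - q
        mixed = [i for i in table.individuals if truth.true_origin[i] == "admixed"]
        half = [i for i in mixed if 0.45 <= truth.true_q[i] <= 0.55]
        if half:
            assert 0.35 <= q[half].mean() <= 0.65

    def test_relabeling_symmetry_of_likelihood(self):
        from gsikit.popstruct import _admixture_loglik

        rng = np.random.default_rng(3)
        G = rng.integers(0, 3, size=(6, 5)).astype(float)
        M = np.ones_like(G, dtype=bool)
        q = rng.uniform(0, 1, 6)
        f = rng.uniform(0.1, 0.9, size=(2, 5))
        assert _admixture_loglik(G, M, q, f) == pytest.approx(
            _admixture_loglik(G, M, 1 - q, f[::-1]), abs=1e-9
        )

    def test_split_threshold_inclusive(self):
        from gsikit.popstruct import AdmixtureFit

        fit = AdmixtureFit(
            q=np.array([0.70, 0.69, 0.30, 0.31, 0.5]),
            cluster_freqs=np.zeros((2, 1)),
            loglik=0.0,
            n_restarts=1,
            converged=True,
            individuals=list("abcde"),
        )
        split = split_by_ancestry(fit, 0.70)
        assert list(split.labels) == [
            "cluster_A", "unassigned", "cluster_B", "unassigned", "unassigned",
        ]
        assert sum(split.counts.values()) == 5

    def test_restarts_only_improve(self):
        cfg = SimConfig(n_populations=2, n_loci=15, n_diagnostic=10, seed=41,
                        ecotypes=np.array([0, 1]))
        freqs = draw_population_freqs(cfg)
        table, _ = simulate_seasonal_sample(freqs, 15, 15, 5, seed=42)
        one = fit_admixture_k2(table, n_restarts=1, seed=43)
        many = fit_admixture_k2(table, n_restarts=5, seed=43)
        assert many.loglik >= one.loglik - 1e-9


class TestMergeAndBalance:
    def _fst_from_pvalues(self, samples, pmatrix):
        idx = pd.Index(samples)
        theta = pd.DataFrame(np.zeros((len(samples),) * 2), index=idx, columns=idx)
        return FstResult(samples, theta, pd.DataFrame(pmatrix, index=idx, columns=idx), 999)

    def test_all_significant_gives_singletons(self):
        p = np.array([[np.nan, 1e-4, 1e-4], [1e-4, np.nan, 1e-4], [1e-4, 1e-4, np.nan]])
        res = merge_indistinct_samples(self._fst_from_pvalues(["a", "b", "c"], p))
        assert sorted(map(tuple, res.partition)) == [("a",), ("b",), ("c",)]
        assert res.merges == []

    def test_chain_merges_by_single_linkage(self):
        p = np.array(
            [[np.nan, 0.9, 1e-4], [0.9, np.nan, 0.8], [1e-4, 0.8, np.nan]]
        )
        res = merge_indistinct_samples(self._fst_from_pvalues(["a", "b", "c"], p))
        assert sorted(map(len, res.partition)) == [3]
        assert res.label_of["a"] == res.label_of["c"]

    def test_identical_populations_get_merged(self):
        merged = 0
        for s in range(10):
            cfg = SimConfig(n_populations=2, n_loci=30, n_diagnostic=0, fst=0.2,
                            sample_sizes=40, missing_rate=0.0, seed=600 + s)
            freqs = draw_population_freqs(cfg)
            freqs[1] = freqs[0]
            table, bd, _ = simulate_baseline_genotypes(freqs, cfg)
            fst = pairwise_fst(table, _grouping(table, bd), n_permutations=199, seed=s)
            res = merge_indistinct_samples(fst)
            merged += len(res.partition) == 1
        assert merged >= 9

    def test_balance_caps_large_population(self):
        cfg = SimConfig(n_populations=2, n_loci=10, n_diagnostic=0,
                        sample_sizes=np.array([205, 50]), seed=51)
        table, bd, _ = simulate_baseline_genotypes(draw_population_freqs(cfg), cfg)
        out = balance_and_trim(table, bd, cap=100, seed=52)
        tallies = out.meta["sample_id"].value_counts()
        assert tallies["pop1"] == 100 and tallies["pop2"] == 50
        again = balance_and_trim(table, bd, cap=100, seed=52)
        assert out.individuals == again.individuals

    def test_balance_noop_below_cap(self):
        cfg = SimConfig(n_populations=2, n_loci=10, n_diagnostic=0, sample_sizes=20, seed=53)
        table, bd, _ = simulate_baseline_genotypes(draw_population_freqs(cfg), cfg)
        assert balance_and_trim(table, bd, cap=140, seed=0).equals(table)
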