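import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_hyp

from methburden import burden as bd
from methburden import diffmeth as dm
from methburden import synthdata as sd
from conftest import toy_dmp
from oracles import (fisher_two_sided_bruteforce, hypergeom_tail_bruteforce,
                     overlap_bruteforce)


class TestDownsample:
    def test_deterministic_given_seed(self, default_cohort):
        coh = default_cohort
        a = bd.downsample_compare(coh.betas, coh.samples, n_iter=10, seed=4,
                                  annotation=coh.annotation)
        b = bd.downsample_compare(coh.betas, coh.samples, n_iter=10, seed=4,
                                  annotation=coh.annotation)
        assert np.array_equal(a.male_counts, b.male_counts)
        assert a.female_count == b.female_count

    def test_smaller_male_group_rejected(self, default_cohort):
        coh = default_cohort
        sheet = coh.samples.copy()
        sheet["sex"] = np.where(sheet["sex"] == "F", "M", "F")  # swap roles
        with pytest.raises(ValueError):
            bd.downsample_compare(coh.betas, sheet, n_iter=2, seed=0)

    def test_null_equal_effects_rarely_significant(self):
        """With equal planted effects in both sexes the down-sampling
        comparison should find no significant female excess in >= 90% of
        repeats."""
        hits = 0
        for s in range(20):
            cfg = sd.CohortConfig(
                n_probes=1000, frac_fdmp=0, frac_mdmp=0, frac_shared=0.03,
                frac_sdmp=0, delta_female=0.07, delta_male=0.07,
                n_batches=1, seed=300 + s)
            coh = sd.generate_cohort(cfg)
            res = bd.downsample_compare(coh.betas, coh.samples, n_iter=200,
                                        seed=s, annotation=coh.annotation)
            hits += (res.p >= 0.05)
        assert hits >= 18

    def test_power_with_asymmetric_effects(self):
        cfg = sd.CohortConfig(n_probes=2000, delta_female=0.10,
                              delta_male=0.04, n_batches=1, seed=77)
        coh = sd.generate_cohort(cfg)
        res = bd.downsample_compare(coh.betas, coh.samples, n_iter=200,
                                    seed=7, annotation=coh.annotation)
        assert res.female_count > np.median(res.male_counts)
        assert res.p < 0.05

    def test_difference_quantiles_stable_across_runs(self):
        # strong planted effects concentrate the per-iteration counts, so
        # the difference-distribution quantiles must stabilize by 1,000
        # iterations
        cfg = sd.CohortConfig(n_probes=1000, frac_fdmp=0, frac_mdmp=0,
                              frac_shared=0.03, frac_sdmp=0,
                              delta_female=0.12, delta_male=0.12,
                              noise_sd=0.25, n_batches=1, seed=55)
        coh = sd.generate_cohort(cfg)
        q = []
        for s in (1, 2):
            res = bd.downsample_compare(coh.betas, coh.samples, n_iter=1000,
                                        seed=s, annotation=coh.annotation)
            q.append(np.percentile(res.diff, [5, 95]))
        assert np.abs(q[0] - q[1]).max() < 0.5


class TestRRHO:
    @staticmethod
    def _table(scores, probes=None):
        scores = np.asarray(scores, float)
        probes = probes or [f"c{i:04d}" for i in range(len(scores))]
        return toy_dmp(probes, 10.0 ** (-np.abs(scores)),
                       np.sign(scores) + (np.sign(scores) == 0))

    def test_identical_lists_peak_on_diagonal_with_full_overlap(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 3, 1000)
        a = self._table(scores)
        res = bd.rrho_map(a, a.copy(), step=10)
        # overlap at any threshold k equals k on the diagonal
        diag = np.diag(res.overlap.to_numpy())
        assert np.array_equal(diag, res.overlap.index.to_numpy())
        i, j = res.max_at
        assert abs(i - j) <= res.step

    def test_reversed_list_concentrates_in_discordant_quadrants(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 3, 600)
        a = self._table(scores)
        b = self._table(-scores)
        res = bd.rrho_map(a, b, step=10)
        # anti-correlation: no concordant enrichment anywhere, only strong
        # depletion (signed negative) where the discordant tails collide
        assert bd.max_concordant_signal(res) < 5
        assert res.grid.to_numpy().max() < 5
        assert res.grid.to_numpy().min() < -20

    def test_independent_lists_stay_below_bonferroni(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            n = 800
            probes = [f"c{i}" for i in range(n)]
            a = toy_dmp(probes, rng.uniform(0, 1, n), rng.normal(0, 1, n))
            b = toy_dmp(probes, rng.uniform(0, 1, n), rng.normal(0, 1, n))
            res = bd.rrho_map(a, b, step=8)
            bonf = -np.log10(0.05 / res.grid.size)
            hits += (res.max_value <= bonf)
        assert hits >= 18

    def test_overlap_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(3)
        a = self._table(rng.normal(0, 2, 300))
        b = self._table(rng.normal(0, 2, 300))
        res = bd.rrho_map(a, b, step=7)
        o = res.overlap.to_numpy()
        assert (np.diff(o, axis=0) >= 0).all()
        assert (np.diff(o, axis=1) >= 0).all()

    def test_overlap_matches_bruteforce_sets(self):
        rng = np.random.default_rng(4)
        scores_a = rng.normal(0, 2, 40)
        scores_b = rng.normal(0, 2, 40)
        probes = [f"c{i:02d}" for i in range(40)]
        a = self._table(scores_a, probes)
        b = self._table(scores_b, probes)
        res = bd.rrho_map(a, b, step=5)
        order_a = [probes[i] for i in np.argsort(-scores_a, kind="mergesort")]
        order_b = [probes[i] for i in np.argsort(-scores_b, kind="mergesort")]
        for i in res.overlap.index:
            for j in res.overlap.columns:
                assert res.overlap.loc[i, j] == \
                    overlap_bruteforce(order_a, order_b, i, j)

    def test_hypergeometric_tail_matches_enumeration(self):
        from scipy.stats import hypergeom
        for (n, K, nd, a) in [(50, 10, 15, 4), (30, 12, 12, 8),
                              (20, 5, 10, 1), (50, 25, 25, 20)]:
            exact = hypergeom_tail_bruteforce(a, n, K, nd)
            assert hypergeom.sf(a - 1, n, K, nd) == pytest.approx(
                exact, rel=1e-10)

    def test_mismatched_probe_sets_rejected(self):
        a = self._table([1, 2, 3])
        b = self._table([1, 2, 3])
        b.index = ["x", "y", "z"]
        with pytest.raises(ValueError):
            bd.rrho_map(a, b)


class TestConcordant:
    def test_constructed_set_recovered(self):
        f = toy_dmp(list("abcdef"), [0.01, 0.01, 0.2, 0.01, 0.3, 0.01],
                    [0.1, -0.1, 0.1, 0.1, 0.1, 0.1])
        m = toy_dmp(list("abcdef"), [0.02, 0.03, 0.01, 0.4, 0.01, 0.04],
                    [0.1, -0.1, 0.1, 0.1, 0.1, -0.1])
        out = bd.concordant_cpgs(f, m)
        assert set(out.index) == {"a", "b"}
        assert out.loc["a", "direction"] == "up"
        assert out.loc["b", "direction"] == "down"

    def test_alpha_zero_empty(self):
        f = toy_dmp(list("ab"), [0.001, 0.001], [0.1, 0.1])
        assert len(bd.concordant_cpgs(f, f.copy(), alpha=0)) == 0

    def test_partition_sums(self, default_cohort):
        coh = default_cohort
        f = dm.fit_dmp(coh.betas, coh.samples, stratum="female",
                       annotation=coh.annotation)
        m = dm.fit_dmp(coh.betas, coh.samples, stratum="male",
                       annotation=coh.annotation)
        out = bd.concordant_cpgs(f, m)
        counts = out["direction"].value_counts()
        assert counts.get("up", 0) + counts.get("down", 0) == len(out)


class TestMagnitude:
    def test_equal_deltas_slope_one_t_zero(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 0.05, 100)
        f = toy_dmp([f"c{i}" for i in range(100)], np.full(100, 0.01), d)
        res = bd.magnitude_comparison(f, f.copy())
        assert res.slope == pytest.approx(1.0)
        assert res.paired_t == pytest.approx(0.0, abs=1e-12)

    def test_halved_deltas_slope_half(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0, 0.05, 100)
        f = toy_dmp([f"c{i}" for i in range(100)], np.full(100, 0.01), d)
        m = f.copy()
        m["delta_beta"] = 0.5 * d
        res = bd.magnitude_comparison(f, m)
        assert res.slope == pytest.approx(0.5)

    def test_noisy_slope_recovered(self):
        rng = np.random.default_rng(2)
        n = 10_000
        df = rng.normal(0, 0.05, n)
        dmle = 0.78 * df + rng.normal(0, 0.01, n)
        f = toy_dmp([f"c{i}" for i in range(n)], np.full(n, 0.01), df)
        m = f.copy()
        m["delta_beta"] = dmle
        res = bd.magnitude_comparison(f, m)
        assert res.slope == pytest.approx(0.78, abs=0.05)

    def test_tiny_subset_rejected(self):
        f = toy_dmp(list("ab"), [0.1, 0.1], [0.1, 0.1])
        with pytest.raises(ValueError):
            bd.magnitude_comparison(f, f.copy())


class TestSdmp:
    def test_planted_sex_differences_recovered(self):
        """Sensitivity >= 80% for planted baseline sex differences of 0.1
        at the study's control design (24 F / 72 M)."""
        cfg = sd.CohortConfig(
            n_probes=2000, n_female_cases=3, n_male_cases=3,
            n_female_controls=24, n_male_controls=72,
            frac_fdmp=0, frac_mdmp=0, frac_shared=0, frac_sdmp=0.05,
            sdmp_delta=0.10, n_batches=1, seed=60)
        coh = sd.generate_cohort(cfg)
        table = bd.call_sdmp(coh.betas, coh.samples)
        planted = coh.truth.index[coh.truth["is_sdmp"]]
        assert table.loc[planted, "adj_p"].lt(0.05).mean() >= 0.80

    def test_no_planted_effects_calibrated(self):
        cfg = sd.CohortConfig(
            n_probes=2000, frac_fdmp=0, frac_mdmp=0, frac_shared=0,
            frac_sdmp=0, n_batches=1, seed=61)
        coh = sd.generate_cohort(cfg)
        # restrict to autosomes: chrX/chrY carry genuine sex differences
        # by construction, which would dominate the BH family
        autosomal = ~coh.annotation["chrom"].isin(["X", "Y"]).to_numpy()
        table = bd.call_sdmp(coh.betas.loc[autosomal], coh.samples)
        raw_rate = (table["p"] < 0.05).mean()
        assert 0.02 < raw_rate < 0.08
        assert (table["adj_p"] < 0.05).sum() <= 2

    def test_sign_convention_female_hyper_positive(self, default_cohort):
        coh = default_cohort
        table = bd.call_sdmp(coh.betas, coh.samples)
        pos = coh.truth.index[coh.truth["true_sex_delta"] > 0]
        assert table.loc[pos, "delta_beta"].mean() > 0

    def test_single_sex_rejected(self, default_cohort):
        coh = default_cohort
        sheet = coh.samples.copy()
        sheet["sex"] = "F"
        with pytest.raises(ValueError):
            bd.call_sdmp(coh.betas, sheet)


class TestEnrichment:
    def test_female_sdmp_table_matches_printed_values(self):
        res = bd.enrichment_from_counts(11, 63, 9105, 240849)
        assert res.sample_odds_ratio == pytest.approx(4.618, abs=0.001)
        assert res.odds_ratio == pytest.approx(4.61, abs=0.01)
        assert res.p == pytest.approx(7.6e-05, rel=0.05)

    def test_male_sdmp_table_matches_printed_values(self):
        res = bd.enrichment_from_counts(4, 210, 9112, 240702)
        assert res.odds_ratio == pytest.approx(0.50, abs=0.01)
        assert res.p == pytest.approx(0.2, abs=0.05)

    def test_zero_overlap_gives_zero_sample_or(self):
        res = bd.enrichment_from_counts(0, 10, 20, 100)
        assert res.sample_odds_ratio == 0.0

    def test_set_interface_counts(self):
        universe = set(range(20))
        res = bd.enrichment_or({0, 1, 2, 3}, {2, 3, 4, 5}, universe)
        assert (res.a, res.b, res.c, res.d) == (2, 2, 2, 14)

    def test_fisher_p_matches_enumeration_on_tiny_universes(self):
        for (a, b, c, d) in [(2, 3, 1, 6), (0, 4, 4, 4), (3, 0, 2, 7),
                             (1, 1, 1, 1), (5, 2, 3, 2), (2, 2, 2, 2)]:
            res = bd.enrichment_from_counts(a, b, c, d)
            assert res.p == pytest.approx(
                fisher_two_sided_bruteforce(a, b, c, d), rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st_hyp.lists(st_hyp.integers(0, 60), min_size=4, max_size=4))
    def test_swapping_hit_and_reference_is_symmetric(self, counts):
        a, b, c, d = counts
        # degenerate margins make the conditional MLE undefined
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        r1 = bd.enrichment_from_counts(a, b, c, d)
        r2 = bd.enrichment_from_counts(a, c, b, d)  # transpose = swap sets
        assert r1.p == pytest.approx(r2.p, rel=1e-9)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-6) or \
            (np.isinf(r1.odds_ratio) and np.isinf(r2.odds_ratio))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            bd.enrichment_or(set(), set(), set())
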