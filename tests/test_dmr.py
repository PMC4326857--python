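import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import regionscan as rs
from regionscan.dmr import DMRResult
from regionscan.model import ProbeStatVector, ScoredRegion, Thresholds, ValidationError
from conftest import make_manifest


def _matrix(values, manifest=None, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"p{i}" for i in range(values.shape[0])], columns=samples)
    return rs.MethylationMatrix(df, manifest)


def _pheno(ages, samples=None):
    samples = samples or [f"s{i}" for i in range(len(ages))]
    return rs.PhenotypeTable(pd.DataFrame({"sample_id": samples, "age": ages}))


class TestFitProbeStatistics:
    def test_exact_linear_probe(self):
        ages = np.array([10.0, 20, 30, 40, 50])
        mat = _matrix([0.01 * ages, np.full(5, 0.4)])
        stats = rs.fit_probe_statistics(mat, _pheno(ages))
        assert stats.values.iloc[0] == pytest.approx(0.01, abs=1e-12)
        assert stats.values.iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_oracle(self):
        ages = np.array([1.0, 2, 3, 4, 5])
        y = np.array([0.1, 0.2, 0.2, 0.4, 0.5])
        beta_hand = np.sum((ages - ages.mean()) * (y - y.mean())) / np.sum(
            (ages - ages.mean()) ** 2
        )
        stats = rs.fit_probe_statistics(_matrix([y]), _pheno(ages))
        assert stats.values.iloc[0] == pytest.approx(beta_hand, abs=1e-12)

    @pytest.mark.parametrize("stat_type", ["beta", "t"])
    def test_matches_statsmodels_ols(self, stat_type):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        ages = rng.uniform(1, 80, 15)
        Y = np.clip(rng.normal(0.5, 0.1, (6, 15)), 0, 1)
        stats = rs.fit_probe_statistics(_matrix(Y), _pheno(ages), stat_type=stat_type)
        X = sm.add_constant(ages)
        for j in range(6):
            fit = sm.OLS(Y[j], X).fit()
            expected = fit.params[1] if stat_type == "beta" else fit.tvalues[1]
            assert stats.values.iloc[j] == pytest.approx(expected, rel=1e-9)

    def test_zero_age_variance_rejected(self):
        mat = _matrix(np.full((2, 4), 0.5))
        with pytest.raises(ValidationError):
            rs.fit_probe_statistics(mat, _pheno([30.0] * 4))

    def test_mostly_missing_probe_undefined(self):
        ages = np.arange(1.0, 11)
        Y = np.tile(0.01 * ages, (2, 1))
        Y[0, :4] = np.nan  # 40% missing > 20% cut
        stats = rs.fit_probe_statistics(_matrix(Y), _pheno(ages))
        assert np.isnan(stats.values.iloc[0])
        assert stats.values.iloc[1] == pytest.approx(0.01)


class TestPercentileThresholds:
    def test_positive_subset_linear_interpolation(self):
        v = pd.Series(
            np.concatenate([np.arange(1.0, 101), [-1.0]]),
            index=[f"p{i}" for i in range(101)],
        )
        th = rs.percentile_thresholds(ProbeStatVector(v, "beta"))
        assert th.q1 == pytest.approx(95.05)

    def test_negative_subset_symmetry(self):
        v = pd.Series(
            np.concatenate([-np.arange(1.0, 101), [1.0]]),
            index=[f"p{i}" for i in range(101)],
        )
        th = rs.percentile_thresholds(ProbeStatVector(v, "beta"))
        assert th.q2 == pytest.approx(-95.05)

    def test_constant_positives(self):
        v = pd.Series([2.0, 2.0, 2.0, -1.0], index=list("abcd"))
        th = rs.percentile_thresholds(ProbeStatVector(v, "beta"))
        assert th.q1 == 2.0

    def test_missing_side_error_names_side(self):
        v = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValidationError, match="negative"):
            rs.percentile_thresholds(ProbeStatVector(v, "beta"))


class TestHarmonizeThresholds:
    def test_least_extreme_on_each_side(self):
        ths = [Thresholds(2.0, -3.0), Thresholds(3.0, -2.0)]
        h = rs.harmonize_thresholds(ths)
        assert h.q1 == 2.0 and h.q2 == -2.0

    def test_single_dataset_identity(self):
        th = Thresholds(1.5, -0.5)
        assert rs.harmonize_thresholds([th]) == th


class TestDetectCandidates:
    def _setup(self, stats_values):
        m = make_manifest(list(range(100, 100 + 100 * len(stats_values), 100)))
        regions = rs.cluster_probes(m, 1000)
        sv = ProbeStatVector(pd.Series(stats_values, index=m.probe_ids), "beta")
        return m, regions, sv

    def test_all_above_q1_single_hyper_run(self):
        m, regions, sv = self._setup([2.0, 2.5, 3.0])
        cands = rs.detect_candidates(regions, sv, Thresholds(1.0, -1.0), manifest=m)
        assert len(cands) == 1
        assert cands[0].direction == "hyper" and cands[0].n_probes == 3

    def test_sign_switch_splits_runs(self):
        m, regions, sv = self._setup([2.0, 2.5, -3.0, -2.5])
        cands = rs.detect_candidates(regions, sv, Thresholds(1.0, -1.0), manifest=m)
        assert [c.direction for c in cands] == ["hyper", "hypo"]
        assert all(c.n_probes == 2 for c in cands)

    def test_broken_run_of_one_discarded(self):
        m, regions, sv = self._setup([2.0, 0.0, 2.0])
        cands = rs.detect_candidates(regions, sv, Thresholds(1.0, -1.0), manifest=m)
        assert cands == []

    def test_tie_at_threshold_does_not_pass(self):
        m, regions, sv = self._setup([1.0, 1.0, 1.0])
        cands = rs.detect_candidates(regions, sv, Thresholds(1.0, -1.0), manifest=m)
        assert cands == []


class TestRegionArea:
    def _candidate(self, pos, stats):
        return ScoredRegion(
            region_id="r", chrom="1", probe_ids=tuple(f"p{i}" for i in range(len(pos))),
            start=pos[0] - 1, end=pos[-1], direction="hyper",
            member_stats=tuple(stats), member_pos=tuple(pos), area=np.nan,
        )

    def test_two_probe_closed_form(self):
        assert rs.region_area(self._candidate([100, 200], [0.5, 0.7])) == pytest.approx(60.0)

    def test_three_probe_unit_stats(self):
        assert rs.region_area(self._candidate([1, 101, 301], [1, 1, 1])) == pytest.approx(300.0)

    def test_zero_stats_zero_area(self):
        assert rs.region_area(self._candidate([1, 101], [0, 0])) == 0.0

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValidationError):
            rs.region_area(self._candidate([100, 100], [1, 1]))

    def test_matches_numpy_trapezoid_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = rng.integers(2, 12)
            pos = np.sort(rng.choice(range(1, 10_000), n, replace=False))
            stats = rng.normal(0, 2, n)
            cand = self._candidate(pos.tolist(), stats.tolist())
            oracle = np.trapezoid(np.abs(stats), pos)
            assert rs.region_area(cand) == pytest.approx(oracle, abs=1e-9)


class TestPermutationNull:
    def _data(self, seed=0, n_probes=60, n_samples=12):
        scn = rs.SimScenario(n_probes=n_probes, n_chroms=1, seed=seed)
        man = rs.generate_manifest(scn)
        mat, ph, _ = rs.generate_age_series(scn, man, np.linspace(1, 80, n_samples))
        return man, mat, ph

    def test_identity_permutation_reproduces_observed(self):
        man, mat, ph = self._data()
        regions = rs.cluster_probes(man, 1000)
        stats = rs.fit_probe_statistics(mat, ph)
        th = rs.percentile_thresholds(stats)
        observed = rs.detect_candidates(regions, stats, th, manifest=man)
        null = rs.permutation_null(
            mat, ph, regions, man, K=1, seed=0, _identity=True
        )
        assert sorted(null.areas) == pytest.approx(sorted(r.area for r in observed))

    def test_same_seed_identical_pool(self):
        man, mat, ph = self._data()
        regions = rs.cluster_probes(man, 1000)
        a = rs.permutation_null(mat, ph, regions, man, K=5, seed=42)
        b = rs.permutation_null(mat, ph, regions, man, K=5, seed=42)
        assert np.array_equal(a.areas, b.areas)
        assert a.n_per_sim == b.n_per_sim

    def test_noise_null_nonempty_positive(self):
        man, mat, ph = self._data(seed=3, n_probes=200)
        regions = rs.cluster_probes(man, 1000)
        null = rs.permutation_null(mat, ph, regions, man, K=10, seed=1)
        assert null.areas.size > 0 and null.areas.mean() > 0


class TestEmpiricalP:
    def _cand(self, area):
        return ScoredRegion(
            region_id="r", chrom="1", probe_ids=("a", "b"), start=0, end=10,
            direction="hyper", member_stats=(1.0, 1.0), member_pos=(1, 10), area=area,
        )

    def _null(self):
        return rs.NullAreaDistribution(np.arange(1.0, 21), (20,))

    def test_direct_count(self):
        out = rs.empirical_pvalues([self._cand(10.0)], self._null())
        assert out[0].p == pytest.approx(0.55)

    def test_above_max_null_gives_zero(self):
        assert rs.empirical_pvalues([self._cand(100.0)], self._null())[0].p == 0.0

    def test_at_min_null_gives_one(self):
        assert rs.empirical_pvalues([self._cand(1.0)], self._null())[0].p == 1.0

    def test_laplace_smoothing(self):
        out = rs.empirical_pvalues([self._cand(100.0)], self._null(), laplace=True)
        assert out[0].p == pytest.approx(1 / 21)

    def test_empty_null_rejected(self):
        with pytest.raises(ValidationError):
            rs.empirical_pvalues([self._cand(1.0)], rs.NullAreaDistribution(np.empty(0), ()))


def hand_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestQValues:
    def test_hand_bh_example(self):
        q = rs.estimate_qvalues([0.01, 0.02, 0.03])
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert rs.estimate_qvalues([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_single_p_identity(self):
        assert rs.estimate_qvalues([0.2])[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_hand_bh_oracle(self, pvals):
        assert rs.estimate_qvalues(pvals) == pytest.approx(hand_bh(pvals))

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = rs.estimate_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestPowerComparison:
    def test_equal_test_counts_equal_power(self):
        a, b = rs.power_comparison(1.0, 20, 20, m_single=100, m_region=100)
        assert a == b

    def test_huge_effect_saturates(self):
        a, b = rs.power_comparison(50.0, 20, 20)
        assert a > 0.999 and b > 0.999

    def test_region_power_at_least_single(self):
        a, b = rs.power_comparison(0.8, 15, 15)
        assert b >= a

    def test_matches_monte_carlo_wmw_power(self):
        from scipy.stats import mannwhitneyu

        d, n = 1.0, 50
        power, _ = rs.power_comparison(d, n, n, alpha_family=0.05, m_single=1, m_region=1)
        rng = np.random.default_rng(12345)
        hits = 0
        reps = 4000
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + d
            if mannwhitneyu(x, y).pvalue < 0.05:
                hits += 1
        assert power == pytest.approx(hits / reps, abs=0.02)


class TestPipelineInvariance:
    def _run(self, mat, ph, man):
        return rs.run_dmr_pipeline(mat, ph, man, rs.RunConfig(K=10, seed=4))

    def test_invariant_to_sample_and_probe_order(self):
        scn = rs.SimScenario(n_probes=300, seed=9)
        man = rs.generate_manifest(scn)
        scn = rs.default_dmr_plan(scn, man, n_planted=2, slope=0.004, min_probes=2)
        mat, ph, _ = rs.generate_age_series(scn, man, np.linspace(1, 80, 16))
        base = self._run(mat, ph, man)
        rng = np.random.default_rng(0)
        shuffled_samples = list(rng.permutation(mat.sample_ids))
        shuffled_probes = list(rng.permutation(mat.values.index))
        mat2 = rs.MethylationMatrix(
            mat.values[shuffled_samples].loc[shuffled_probes], man
        )
        alt = self._run(mat2, ph, man)
        assert [r.region_id for r in base.significant] == [
            r.region_id for r in alt.significant
        ]
        assert [r.p for r in base.candidates] == [r.p for r in alt.candidates]
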