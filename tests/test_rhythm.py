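import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viradiel.core_io import AbundanceMatrix, HostTable
from viradiel.rhythm import (
    UmbrellaAlternative,
    bh_adjust,
    detrend,
    enumerate_alternatives,
    effective_test_count,
    host_summed_rhythms,
    jt_exact_distribution,
    jt_null_moments,
    jt_pvalue,
    jt_umbrella_statistic,
    rain_scan,
    umbrella_weights,
    _exact_distribution_dp,
    _exact_distribution_enumeration,
)
from viradiel.syndata import (
    Archetype,
    SyntheticConfig,
    simulate_abundance,
    sampling_scheme,
    umbrella_waveform,
)


class TestDetrend:
    def test_exact_linear_series_vanishes(self):
        t = np.arange(10, dtype=float)
        assert np.allclose(detrend(2 + 3 * t, t), 0.0, atol=1e-10)

    def test_constant_series_vanishes(self):
        t = np.arange(5, dtype=float)
        assert np.allclose(detrend(np.full(5, 7.0), t), 0.0, atol=1e-10)

    def test_cosine_plus_trend_equals_cosine_residual(self):
        t = np.linspace(0, 48, 13)
        cos = np.cos(2 * np.pi * t / 24)
        design = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(design, cos, rcond=None)
        expected = cos - design @ coef  # independent fit of the cosine alone
        observed = detrend(cos + (1.5 - 0.2 * t), t)
        assert np.allclose(observed, expected, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = np.arange(20, dtype=float)
        y = rng.normal(size=20) + 0.3 * t
        once = detrend(y, t)
        assert np.allclose(detrend(once, t), once, atol=1e-10)

    def test_mask_respected_and_minimum_points(self):
        t = np.arange(6, dtype=float)
        mask = np.array([True, True, False, False, False, False])
        with pytest.raises(ValueError, match=">= 3"):
            detrend(t, t, mask)


class TestAlternatives:
    @pytest.mark.parametrize("deltat,count", [(4, 30), (12, 2)])
    def test_alternative_count(self, deltat, count):
        assert len(enumerate_alternatives(24, deltat)) == count

    def test_rise_and_fall_partition_the_cycle(self):
        for alt in enumerate_alternatives(24, 4):
            rise, fall = alt.rise_path(), alt.fall_path()
            assert rise[0] == fall[0] == alt.trough_class
            assert rise[-1] == fall[-1] == alt.peak_class
            interior = set(rise[1:-1]) | set(fall[1:-1])
            assert set(rise) | set(fall) == set(range(6))
            assert not (set(rise[1:-1]) & set(fall[1:-1]))
            assert len(interior) == 4

    def test_indivisible_period_rejected(self):
        with pytest.raises(ValueError):
            enumerate_alternatives(24, 7)

    def test_all_sur_weight_matrices_distinct(self):
        assert effective_test_count(enumerate_alternatives(24, 4)) == 30


class TestUmbrellaStatistic:
    def setup_method(self):
        # three singleton classes: trough holds 1, peak holds 3, fall-side 2
        self.values = np.array([1.0, 3.0, 2.0])
        self.classes = np.array([0, 1, 2])
        self.alt = UmbrellaAlternative(peak_class=1, trough_class=0,
                                       n_classes=3)

    def test_perfect_umbrella_attains_maximum(self):
        s, sizes = jt_umbrella_statistic(self.values, self.classes, self.alt)
        # pairs: (T,P) on both arcs + (T,F) + (F,P), all concordant
        assert s == 4.0
        assert list(sizes) == [1, 1, 1]

    def test_reversed_alternative_attains_minimum(self):
        rev = UmbrellaAlternative(peak_class=0, trough_class=1, n_classes=3)
        s, _ = jt_umbrella_statistic(self.values, self.classes, rev)
        assert s == 0.0

    def test_statistic_plus_reversal_is_total_pair_count(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 4, size=12).astype(float)  # with ties
        classes = rng.integers(0, 4, size=12)
        classes[:4] = np.arange(4)  # every class nonempty
        for alt in enumerate_alternatives(24, 6):
            rev = UmbrellaAlternative(alt.trough_class, alt.peak_class, 4)
            s, sizes = jt_umbrella_statistic(values, classes, alt)
            s_rev, _ = jt_umbrella_statistic(values, classes, rev)
            w = umbrella_weights(alt)
            total = np.einsum("ij,i,j->", w, sizes, sizes)
            assert s + s_rev == pytest.approx(total)

    def test_null_mean_is_half_the_pair_count(self):
        # enumeration-based check on a small tied sample
        values = np.array([0.0, 1.0, 1.0, 2.0, 3.0])
        classes = np.array([0, 1, 1, 2, 2])
        alt = UmbrellaAlternative(peak_class=2, trough_class=0, n_classes=3)
        sup, cnt = jt_exact_distribution(values, classes, alt)
        mean = float((sup * cnt).sum() / cnt.sum())
        w = umbrella_weights(alt)
        sizes = np.bincount(classes)
        assert mean == pytest.approx(
            0.5 * np.einsum("ij,i,j->", w, sizes, sizes))


class TestExactNull:
    def test_dp_matches_enumeration_no_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            c = int(rng.integers(2, 5))
            sizes = rng.integers(1, 4, size=c)
            while sizes.sum() > 8:
                sizes[rng.integers(c)] = max(1, sizes[rng.integers(c)] - 1)
            n = int(sizes.sum())
            values = rng.permutation(n).astype(float)
            p = int(rng.integers(c))
            t = int((p + rng.integers(1, c)) % c)
            w = umbrella_weights(UmbrellaAlternative(p, t, c))
            s1, c1 = _exact_distribution_dp(sizes, w)
            s2, c2 = _exact_distribution_enumeration(values, sizes, w)
            import math

            scale = math.prod(math.factorial(int(x)) for x in sizes)
            assert np.allclose(s1, s2)
            assert np.array_equal(c1 * scale, c2)

    def test_moments_match_enumeration_with_ties(self):
        values = np.array([0.0, 0.0, 1.0, 2.0, 2.0, 3.0])
        classes = np.array([0, 0, 1, 1, 2, 2])
        alt = UmbrellaAlternative(peak_class=1, trough_class=0, n_classes=3)
        mean, var = jt_null_moments(values, classes, alt)
        sup, cnt = jt_exact_distribution(values, classes, alt)
        emp_mean = (sup * cnt).sum() / cnt.sum()
        emp_var = (cnt * (sup - emp_mean) ** 2).sum() / cnt.sum()
        assert mean == pytest.approx(emp_mean)
        assert var == pytest.approx(emp_var)


class TestPValue:
    def test_exact_p_at_the_maximum(self):
        values = np.array([1.0, 3.0, 2.0])
        classes = np.array([0, 1, 2])
        alt = UmbrellaAlternative(peak_class=1, trough_class=0, n_classes=3)
        s, _ = jt_umbrella_statistic(values, classes, alt)
        # only the observed arrangement achieves statistic 4 among 3! = 6
        assert jt_pvalue(s, values, classes, alt, "exact") == pytest.approx(1 / 6)

    def test_p_at_null_mean_is_at_least_half(self):
        values = np.arange(6, dtype=float)
        classes = np.array([0, 0, 1, 1, 2, 2])
        alt = UmbrellaAlternative(peak_class=1, trough_class=0, n_classes=3)
        mean, _ = jt_null_moments(values, classes, alt)
        assert jt_pvalue(mean, values, classes, alt, "exact") >= 0.5

    def test_exact_and_normal_agree_for_balanced_groups(self):
        # five balanced tie-free groups of 5; compare both methods
        rng = np.random.default_rng(9)
        values = rng.permutation(25).astype(float)
        classes = np.repeat(np.arange(5), 5)
        alt = UmbrellaAlternative(peak_class=2, trough_class=0, n_classes=5)
        s, _ = jt_umbrella_statistic(values, classes, alt)
        p_exact = jt_pvalue(s, values, classes, alt, "exact")
        p_norm = jt_pvalue(s, values, classes, alt, "normal")
        assert abs(p_exact - p_norm) < 0.02

    def test_constant_values_give_p_one(self):
        values = np.full(6, 2.0)
        classes = np.array([0, 0, 1, 1, 2, 2])
        alt = UmbrellaAlternative(peak_class=1, trough_class=0, n_classes=3)
        s, _ = jt_umbrella_statistic(values, classes, alt)
        mean, _ = jt_null_moments(values, classes, alt)
        assert s == pytest.approx(mean)  # all ties sit at the null center
        assert jt_pvalue(s, values, classes, alt, "normal") == 1.0


class TestBHAdjust:
    def test_step_up_hand_case(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=20))
    def test_adjusted_at_least_raw_and_monotone_discoveries(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        # discoveries shrink as alpha shrinks
        d1 = np.sum(adj <= 0.05)
        d2 = np.sum(adj <= 0.01)
        assert d2 <= d1


class TestRainScan:
    def _noiseless_matrix(self):
        samples = sampling_scheme("SUR")
        clock = np.array([s.clock_hours for s in samples])
        wave = umbrella_waveform(clock, peak=4.0, rise=8.0, amplitude=4.0)
        rng = np.random.default_rng(0)
        rows = [wave * np.exp(rng.normal(0, 0.01, size=clock.size))
                for _ in range(5)]
        rows.append(np.full(clock.size, 3.0))  # constant population
        return AbundanceMatrix(
            population_ids=[f"p{i}" for i in range(6)],
            samples=samples, values=np.array(rows))

    def test_clean_umbrella_signal_detected_with_correct_peak(self):
        results = rain_scan(self._noiseless_matrix())
        by_id = {r.population_id: r for r in results}
        for i in range(5):
            r = by_id[f"p{i}"]
            assert r.p_adjusted < 1e-3 and r.is_diel
            assert r.best_alternative.peak_class == 1  # class 1 = 04:00

    def test_constant_population_not_diel(self):
        results = rain_scan(self._noiseless_matrix())
        const = next(r for r in results if r.population_id == "p5")
        assert const.p_value == 1.0 and not const.is_diel

    def test_all_zero_population_excluded(self):
        m = self._noiseless_matrix()
        values = m.values.copy()
        values[2] = 0.0
        m2 = AbundanceMatrix(population_ids=m.population_ids,
                             samples=m.samples, values=values)
        results = rain_scan(m2)
        assert "p2" not in {r.population_id for r in results}

    def test_mixed_layer_matrix_rejected(self):
        from viradiel.syndata import sampling_scheme as scheme

        samples = scheme("SUR") + scheme("DCM")
        m = AbundanceMatrix(population_ids=["p"], samples=samples,
                            values=np.ones((1, len(samples))))
        with pytest.raises(ValueError, match="single depth layer"):
            rain_scan(m)


class TestHostSummedRhythms:
    def _diel_row(self, clock, peak):
        return umbrella_waveform(clock, peak=peak, rise=8.0, amplitude=4.0)

    def test_single_population_genus_matches_population_scan(self):
        samples = sampling_scheme("SUR")
        clock = np.array([s.clock_hours for s in samples])
        rng = np.random.default_rng(1)
        values = np.array([
            self._diel_row(clock, 4.0) * np.exp(rng.normal(0, 0.05, clock.size)),
            np.exp(rng.normal(0, 0.3, clock.size)),
        ])
        m = AbundanceMatrix(population_ids=["a", "b"], samples=samples,
                            values=values)
        hosts = HostTable(genus={"a": "Pelagibacter"})
        genus_res = host_summed_rhythms(m, hosts)
        pop_res = rain_scan(m.subset_populations(["a"]))
        assert len(genus_res) == 1
        assert genus_res[0].p_value == pytest.approx(pop_res[0].p_value)

    def test_in_phase_pair_is_diel_antiphase_pair_cancels(self):
        samples = sampling_scheme("SUR")
        clock = np.array([s.clock_hours for s in samples])
        in1 = self._diel_row(clock, 4.0)
        in2 = 2.0 * self._diel_row(clock, 4.0)
        # antiphase cosine pair sums to an exact constant
        a1 = 2.0 + np.cos(2 * np.pi * (clock - 4.0) / 24)
        a2 = 2.0 - np.cos(2 * np.pi * (clock - 4.0) / 24)
        m = AbundanceMatrix(
            population_ids=["i1", "i2", "a1", "a2"], samples=samples,
            values=np.array([in1, in2, a1, a2]))
        hosts = HostTable(genus={"i1": "InPhase", "i2": "InPhase",
                                 "a1": "AntiPhase", "a2": "AntiPhase"})
        res = {r.population_id: r for r in host_summed_rhythms(m, hosts)}
        assert res["InPhase"].is_diel
        assert res["AntiPhase"].p_value == 1.0
        assert not res["AntiPhase"].is_diel

    def test_no_predictions_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="host prediction"):
            host_summed_rhythms(tiny_matrix, HostTable(genus={}))
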