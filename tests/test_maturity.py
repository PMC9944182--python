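import numpy as np
import pytest
from scipy import stats

from switchgrow import (
    AlphaDistribution,
    DevelopmentParams,
    InvalidParameterError,
    SwitchRates,
    expected_feeding_fraction,
    sample_degradation_durations,
    simulate_feeding_times,
    simulate_instar4_gain,
    simulate_maturity,
    summarize_joint,
)
from switchgrow.maturity import MaturitySample, energy_distance_test, samples_to_frame


def joint_array(samples):
    return np.array([(s.age_h, s.mass_g) for s in samples if s.reached_wc])


class TestDegradationPhase:
    def test_gamma_moments(self):
        g = sample_degradation_durations(DevelopmentParams(), 100_000, seed=1)
        assert g.mean() == pytest.approx(48.0, abs=0.2)
        assert g.std() == pytest.approx(np.sqrt(48.0), abs=0.2)

    def test_stepwise_mode_same_distribution(self):
        dev = DevelopmentParams(j=10, mu=2.0)
        a = sample_degradation_durations(dev, 20_000, seed=2)
        b = sample_degradation_durations(dev, 20_000, seed=3, stepwise=True)
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_param_validation(self):
        with pytest.raises(InvalidParameterError):
            DevelopmentParams(w_c=-1)
        with pytest.raises(InvalidParameterError):
            DevelopmentParams(j=0)
        with pytest.raises(InvalidParameterError):
            DevelopmentParams(j=2.5)
        with pytest.raises(InvalidParameterError):
            DevelopmentParams(mu=0)


class TestSimulateFeedingTimes:
    def test_never_feeding(self):
        w = simulate_feeding_times(SwitchRates(10.0, 1e-9), 1.0, 200, seed=1)
        assert np.all(w == 0.0)

    def test_transient_mean(self, rates_d4):
        w = simulate_feeding_times(rates_d4, 1.0, 100_000, seed=4)
        expected = expected_feeding_fraction(rates_d4, 1.0)
        se = w.std() / np.sqrt(w.size)
        assert expected == pytest.approx(0.3034, abs=2e-3)
        assert abs(w.mean() - expected) < 3 * se


class TestInstar4Gain:
    def test_fast_switching_deterministic_limit(self):
        # rates so fast the feeding share pins to 1/2 over a 96-h instar
        rates = SwitchRates(5000.0, 5000.0)
        gains = simulate_instar4_gain(
            rates, AlphaDistribution(0.05, 0.0), [96.0], 2000, seed=5
        )
        assert gains.mean() == pytest.approx(0.05 * 48.0, rel=0.01)
        assert gains.std() < 0.05

    def test_variance_scales_with_alpha_squared(self, rates_d4):
        pool = [90.0]
        g1 = simulate_instar4_gain(
            rates_d4, AlphaDistribution(0.04, 0.0), pool, 5000, seed=6
        )
        g2 = simulate_instar4_gain(
            rates_d4, AlphaDistribution(0.08, 0.0), pool, 5000, seed=6
        )
        assert g2.var() / g1.var() == pytest.approx(4.0, rel=0.1)

    def test_low_quality_diet_gains_less(self):
        # shared alpha and durations: gain ordering follows the feeding share
        pool = [96.0]
        alpha = AlphaDistribution(0.04, 0.0)
        g_dc = simulate_instar4_gain(SwitchRates(56.22, 24.36), alpha, pool, 20_000, seed=7)
        g_ad = simulate_instar4_gain(SwitchRates(10.25, 4.93), alpha, pool, 20_000, seed=7)
        assert g_dc.mean() < g_ad.mean()

    def test_input_validation(self, rates_d4):
        with pytest.raises(InvalidParameterError):
            simulate_instar4_gain(rates_d4, AlphaDistribution(0.04, 0.01), [], 10)
        with pytest.raises(InvalidParameterError):
            simulate_instar4_gain(rates_d4, AlphaDistribution(0.04, 0.01), [-1.0], 10)

    def test_engines_agree(self, rates_d4):
        alpha = AlphaDistribution(0.04, 0.01)
        ev = simulate_instar4_gain(rates_d4, alpha, [48.0, 96.0], 20_000, seed=8, method="event")
        ck = simulate_instar4_gain(rates_d4, alpha, [48.0, 96.0], 20_000, seed=9, method="clock")
        assert stats.ks_2samp(ev, ck).pvalue > 0.005


class TestSimulateMaturity:
    def test_reproducible(self, rates_d5):
        kw = dict(
            alpha_dist=AlphaDistribution(0.15, 0.04),
            m0_dist=(1.8, 0.4),
            dev=DevelopmentParams(),
            n=500,
        )
        a = simulate_maturity(rates_d5, seed=10, **kw)
        b = simulate_maturity(rates_d5, seed=10, **kw)
        assert a == b

    def test_mass_above_initial(self, rates_d5):
        samples = simulate_maturity(
            rates_d5, AlphaDistribution(0.15, 0.04), (1.8, 0.4),
            DevelopmentParams(), 2000, seed=11,
        )
        assert all(s.mass_g >= s.m0_g - 1e-9 for s in samples if s.reached_wc)

    def test_start_above_critical_weight_age_is_degradation_time(self):
        # m0 >= w_c: the age distribution is exactly the gamma phase
        dev = DevelopmentParams(w_c=7.0, j=48, mu=1.0)
        samples = simulate_maturity(
            SwitchRates(10, 5), AlphaDistribution(0.1, 0.0), (8.0, 1e-9),
            dev, 20_000, seed=12,
        )
        ages = np.array([s.age_h for s in samples])
        ks = stats.kstest(ages, stats.gamma(a=48, scale=1.0).cdf)
        assert ks.pvalue > 0.01

    def test_engines_agree(self, rates_d5):
        kw = dict(
            alpha_dist=AlphaDistribution(0.15, 0.04),
            m0_dist=(1.8, 0.4),
            dev=DevelopmentParams(),
            n=10_000,
        )
        ev = joint_array(simulate_maturity(rates_d5, seed=13, method="event", **kw))
        ck = joint_array(simulate_maturity(rates_d5, seed=14, method="clock", **kw))
        assert stats.ks_2samp(ev[:, 0], ck[:, 0]).pvalue > 0.005
        assert stats.ks_2samp(ev[:, 1], ck[:, 1]).pvalue > 0.005

    def test_deterministic_limit(self):
        # x1000 rates with fixed alpha and m0: closed-form age and mass
        rates = SwitchRates(10250.0, 4930.0)
        pi = 4930.0 / (10250.0 + 4930.0)
        alpha = 0.15
        samples = simulate_maturity(
            rates, AlphaDistribution(alpha, 0.0), (2.0, 1e-12),
            DevelopmentParams(), 10_000, seed=15,
        )
        arr = joint_array(samples)
        assert arr[:, 0].mean() == pytest.approx(5.0 / (alpha * pi) + 48.0, rel=0.02)
        assert arr[:, 1].mean() == pytest.approx(7.0 + alpha * pi * 48.0, rel=0.02)

    def test_alpha_monotonicity(self, rates_d5):
        means = []
        for level in (0.08, 0.15, 0.30):
            samples = simulate_maturity(
                rates_d5, AlphaDistribution(level, 0.0), (1.8, 0.0),
                DevelopmentParams(), 4000, seed=16,
            )
            arr = joint_array(samples)
            means.append((arr[:, 0].mean(), arr[:, 1].mean()))
        ages = [m[0] for m in means]
        masses = [m[1] for m in means]
        assert ages[0] >= ages[1] >= ages[2]
        assert masses[0] <= masses[1] <= masses[2]

    def test_unreachable_critical_weight_censors(self):
        dev = DevelopmentParams(max_horizon_h=50.0)
        with pytest.warns(RuntimeWarning):
            samples = simulate_maturity(
                SwitchRates(10, 5), AlphaDistribution(0.0, 0.0), (1.0, 1e-9),
                dev, 50, seed=17,
            )
        assert all(not s.reached_wc for s in samples)
        assert all(s.age_h == 50.0 for s in samples)

    def test_frame_columns(self, rates_d5):
        samples = simulate_maturity(
            rates_d5, AlphaDistribution(0.15, 0.04), (1.8, 0.4),
            DevelopmentParams(), 200, seed=18,
        )
        df = samples_to_frame(samples)
        assert list(df.columns) == [
            "replicate", "m0_g", "alpha_g_per_h", "age_h", "mass_g", "reached_wc",
        ]
        assert len(df) == 200


class TestSummarizeJoint:
    @pytest.fixture(scope="module")
    def samples(self):
        return simulate_maturity(
            SwitchRates(16.85, 11.05), AlphaDistribution(0.15, 0.04), (1.8, 0.4),
            DevelopmentParams(), 6000, seed=19,
        )

    def test_requires_enough_samples(self, samples):
        with pytest.raises(InvalidParameterError):
            summarize_joint(samples[:50])

    def test_marginals_match_samples(self, samples):
        arr = joint_array(samples)
        summary = summarize_joint(samples)
        assert summary.marginals["age_h"]["mean"] == pytest.approx(arr[:, 0].mean())
        assert summary.marginals["mass_g"]["mean"] == pytest.approx(arr[:, 1].mean())
        assert summary.n_used == arr.shape[0]

    def test_hdr_split_sample_mass(self, samples):
        # threshold fit on one half should cover ~90% of the other half
        arr = joint_array(samples)
        half1, half2 = arr[::2], arr[1::2]
        kde = stats.gaussian_kde(half1.T)
        thresh = np.quantile(kde(half1.T), 0.10)
        frac = np.mean(kde(half2.T) >= thresh)
        assert frac == pytest.approx(0.90, abs=0.02)

    def test_contours_present_and_nested(self, samples):
        summary = summarize_joint(samples, levels=(0.5, 0.9))
        assert summary.contours is not None
        assert set(summary.contours) == {"0.5", "0.9"}
        assert all(len(polys) >= 1 for polys in summary.contours.values())

    def test_degenerate_geometry_skips_contours(self):
        line = [
            MaturitySample(i, 2.0, 0.1, 100.0 + i * 0.01, 9.0, True)
            for i in range(500)
        ]
        with pytest.warns(RuntimeWarning):
            summary = summarize_joint(line)
        assert summary.contours is None
        assert summary.marginals["mass_g"]["sd"] == pytest.approx(0.0)

    def test_json_roundtrip(self, samples):
        import json

        summary = summarize_joint(samples)
        payload = json.loads(json.dumps(summary.to_dict()))
        assert payload["n_used"] == summary.n_used


class TestEnergyDistance:
    def test_same_distribution_large_p(self, rng):
        x = rng.normal(size=(300, 2))
        y = rng.normal(size=(300, 2))
        _, p = energy_distance_test(x, y, seed=1)
        # p is ~uniform under the null; demand only a non-extreme value
        assert p > 0.01

    def test_shifted_distribution_small_p(self, rng):
        x = rng.normal(size=(300, 2))
        y = rng.normal(loc=1.0, size=(300, 2))
        _, p = energy_distance_test(x, y, seed=2)
        assert p < 0.05

    def test_needs_points(self):
        with pytest.raises(InvalidParameterError):
            energy_distance_test(np.zeros((1, 2)), np.zeros((5, 2)))
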