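"""Speed score, slopes, information, temporal shifts, shuffle null."""

import numpy as np
import pytest

from speedcells import speed_coding as sc
from speedcells import synthetic_session as ss
from speedcells.kinematics import BinnedSeries, SpeedSeries

DT = 0.0256


def series_pair(values, speed_values, mask=None):
    n = len(values)
    rate = sc.RateSeries(0.0, DT, np.asarray(values, float))
    speed = SpeedSeries(
        0.0, DT, np.asarray(speed_values, float),
        np.ones(n, bool) if mask is None else mask,
    )
    return rate, speed


@pytest.fixture(scope="module")
def simulated_unit(trajectory_long, covariates_long, speed_long):
    truth = ss.SyntheticGroundTruth(
        baseline_rate=5.0, speed_gain=0.5, unit_index=0
    )
    unit = ss.simulate_unit(truth, trajectory_long, None, 1200.0, seed=3, covariates=covariates_long)
    rate = sc.instantaneous_rate(unit.spike_times, len(speed_long), speed_long.t0)
    return unit, rate, speed_long


class TestInstantaneousRate:
    def test_regular_train_flat_rate(self):
        spikes = np.arange(0.05, 120, 0.1)  # 10 Hz
        rate = sc.instantaneous_rate(spikes, int(120 / DT))
        assert np.allclose(rate.values[200:-200], 10.0, atol=0.1)

    def test_empty_train_zero(self):
        rate = sc.instantaneous_rate(np.empty(0), 1000)
        assert np.all(rate.values == 0)

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 120, 600))
        rate = sc.instantaneous_rate(spikes, int(120 / DT))
        # smoothing (with edge renormalisation) preserves total counts
        # up to edge effects
        assert rate.values.mean() * 120 == pytest.approx(600, rel=2e-3)


class TestSpeedScore:
    def test_perfect_correlation(self):
        v = np.linspace(5, 40, 500)
        rate, speed = series_pair(v.copy(), v)
        assert sc.speed_score(rate, speed) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        v = np.linspace(5, 40, 500)
        rate, speed = series_pair(-v + 60, v)
        assert sc.speed_score(rate, speed) == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self, simulated_unit):
        _, rate, speed = simulated_unit
        ok = speed.valid & np.isfinite(rate.values)
        r, v = rate.values[ok], speed.values[ok]
        oracle = np.sum((r - r.mean()) * (v - v.mean())) / np.sqrt(
            np.sum((r - r.mean()) ** 2) * np.sum((v - v.mean()) ** 2)
        )
        assert sc.speed_score(rate, speed) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_flagged(self):
        v = np.linspace(5, 40, 500)
        rate, speed = series_pair(np.full(500, 3.0), v)
        assert np.isnan(sc.speed_score(rate, speed))

    def test_too_few_bins_flagged(self):
        v = np.linspace(5, 40, 50)
        rate, speed = series_pair(v.copy(), v)
        assert np.isnan(sc.speed_score(rate, speed))

    def test_affine_invariance(self, simulated_unit):
        _, rate, speed = simulated_unit
        scaled = sc.RateSeries(rate.t0, rate.dt, 3.7 * rate.values + 11.0)
        assert sc.speed_score(scaled, speed) == pytest.approx(
            sc.speed_score(rate, speed), abs=1e-12
        )


class TestSpeedSlope:
    def test_exact_linear_relation(self):
        v = np.linspace(5, 40, 500)
        rate, speed = series_pair(2 + 0.5 * v, v)
        slope, norm_slope = sc.speed_slope(rate, speed)
        assert slope == pytest.approx(0.5, abs=1e-12)
        assert norm_slope == pytest.approx(0.5 / (2 + 0.5 * v).mean(), abs=1e-12)

    def test_constant_rate_zero_slope(self):
        v = np.linspace(5, 40, 500)
        rate, speed = series_pair(np.full(500, 4.0), v)
        slope, norm_slope = sc.speed_slope(rate, speed)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert norm_slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_cov_var_oracle(self, simulated_unit):
        _, rate, speed = simulated_unit
        ok = speed.valid & np.isfinite(rate.values)
        r, v = rate.values[ok], speed.values[ok]
        oracle = np.cov(v, r, ddof=0)[0, 1] / np.var(v)
        slope, _ = sc.speed_slope(rate, speed)
        assert slope == pytest.approx(oracle, abs=1e-10)


class TestSpeedInformation:
    def test_flat_tuning_zero_bits(self):
        v = np.repeat(np.linspace(3, 49, 12), 50)
        rate, speed = series_pair(np.full(600, 5.0), v)
        per_spike, per_sec, _ = sc.speed_information(rate, speed)
        assert per_spike == pytest.approx(0.0, abs=1e-12)
        assert per_sec == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_closed_form(self):
        # p = (0.5, 0.5), lambda = (0, 2) Hz -> 1 bit/spike and 1 bit/s
        from speedcells.spatial_coding import skaggs_information

        per_spike, per_sec = skaggs_information(
            np.array([0.5, 0.5]), np.array([0.0, 2.0]), 1.0
        )
        assert per_spike == 1.0
        assert per_sec == 1.0

    def test_matches_brute_force_oracle(self, simulated_unit):
        _, rate, speed = simulated_unit
        per_spike, per_sec, tuning = sc.speed_information(rate, speed)
        occ = tuning.occupancy_p > 0
        p, lam = tuning.occupancy_p[occ], tuning.rate[occ]
        lam_bar = tuning.mean_rate
        oracle_spike = sum(
            pi * (li / lam_bar) * np.log2(li / lam_bar) for pi, li in zip(p, lam) if li > 0
        )
        oracle_sec = sum(
            pi * li * np.log2(li / lam_bar) for pi, li in zip(p, lam) if li > 0
        )
        assert per_spike == pytest.approx(oracle_spike, abs=1e-12)
        assert per_sec == pytest.approx(oracle_sec, abs=1e-12)

    def test_per_sec_identity(self, simulated_unit):
        _, rate, speed = simulated_unit
        per_spike, per_sec, tuning = sc.speed_information(rate, speed)
        assert per_sec == pytest.approx(tuning.mean_rate * per_spike, abs=1e-10)


class TestTemporalShift:
    def test_identity_signal_zero_shift(self):
        rng = np.random.default_rng(5)
        v = np.clip(20 + 8 * rng.standard_normal(3000), 3, 49)
        rate, speed = series_pair(v.copy(), v)
        lags, curve, pref, excluded, norm = sc.temporal_shift_curve(rate, speed)
        assert len(curve) == 121
        assert pref == 0.0
        assert not excluded
        assert curve[60] == pytest.approx(1.0)

    def test_zero_lag_equals_speed_score_bitwise(self, simulated_unit):
        _, rate, speed = simulated_unit
        _, curve, _, _, _ = sc.temporal_shift_curve(rate, speed)
        assert curve[60] == sc.speed_score(rate, speed)

    def test_prospective_sign_convention(self):
        # rate leads speed by k bins -> preferred shift positive
        rng = np.random.default_rng(6)
        v = np.clip(20 + 8 * np.convolve(rng.standard_normal(3200), np.ones(40) / 40, "same"), 3, 49)
        k = 10
        rate_vals = np.roll(v, -k)  # rate(t) = v(t + k*dt)
        rate, speed = series_pair(rate_vals[:3000], v[:3000])
        _, _, pref, excluded, _ = sc.temporal_shift_curve(rate, speed)
        assert not excluded
        assert pref == pytest.approx(k * DT, abs=1e-9)

    def test_recovers_simulated_lag(self, trajectory_long, covariates_long, speed_long):
        truth = ss.SyntheticGroundTruth(
            baseline_rate=5.0, speed_gain=0.5, speed_lag_s=0.256, unit_index=4
        )
        u = ss.simulate_unit(truth, trajectory_long, None, 1200.0, seed=4, covariates=covariates_long)
        rate = sc.instantaneous_rate(u.spike_times, len(speed_long), speed_long.t0)
        _, _, pref, excluded, _ = sc.temporal_shift_curve(rate, speed_long)
        assert not excluded
        assert abs(pref - 0.256) <= 0.0257 * 2  # within two bins per-unit

    def test_out_of_range_lag_excluded(self):
        # rate leads speed by 2000 ms -> argmax pinned at +1536 ms boundary
        rng = np.random.default_rng(7)
        v = np.clip(20 + 8 * np.convolve(rng.standard_normal(3600), np.ones(40) / 40, "same"), 3, 49)
        k = int(round(2.0 / DT))
        rate_vals = np.roll(v, -k)
        rate, speed = series_pair(rate_vals[:3000], v[:3000])
        _, _, pref, excluded, _ = sc.temporal_shift_curve(rate, speed)
        assert excluded
        assert np.isnan(pref)

    def test_normalized_curve_unity_at_zero(self, simulated_unit):
        _, rate, speed = simulated_unit
        _, curve, _, _, norm = sc.temporal_shift_curve(rate, speed)
        assert norm[60] == pytest.approx(1.0)
        assert np.allclose(norm, curve / curve[60], equal_nan=True)


class TestShuffleNull:
    def test_shuffle_preserves_count_and_circular_isi(self, speed_short):
        rng = np.random.default_rng(8)
        spikes = np.sort(rng.uniform(0, 120, 500))
        shift = 45.0
        surrogate = np.sort(np.mod(spikes + shift, 120.0))
        assert len(surrogate) == len(spikes)
        # circular ISI multiset is invariant
        def circ_isi(s):
            isi = np.diff(np.append(s, s[0] + 120.0))
            return np.sort(isi)
        assert np.allclose(circ_isi(spikes), circ_isi(surrogate), atol=1e-9)

    def test_fixed_seed_reproducible(self, speed_short):
        rng_spk = np.random.default_rng(9)
        spikes = np.sort(rng_spk.uniform(0, 120, 600))
        a = sc.shuffle_null(spikes, 120.0, speed_short, rng=np.random.default_rng(1))
        b = sc.shuffle_null(spikes, 120.0, speed_short, rng=np.random.default_rng(1))
        assert np.array_equal(a.scores, b.scores)

    def test_null_centred_for_unmodulated_unit(self, trajectory_long, covariates_long, speed_long):
        truth = ss.SyntheticGroundTruth(baseline_rate=5.0, unit_index=5)
        u = ss.simulate_unit(truth, trajectory_long, None, 1200.0, seed=5, covariates=covariates_long)
        rate = sc.instantaneous_rate(u.spike_times, len(speed_long), speed_long.t0)
        observed = sc.speed_score(rate, speed_long)
        null = sc.shuffle_null(u.spike_times, 1200.0, speed_long, rng=np.random.default_rng(2))
        # by exchangeability the observed score is one draw from the null
        sd = null.scores.std(ddof=1)
        assert abs(observed - null.scores.mean()) < 3 * sd
        assert abs(null.scores.mean()) < 3 * sd / np.sqrt(len(null.scores)) + 0.01

    def test_short_session_fatal(self, speed_short):
        with pytest.raises(ValueError):
            sc.shuffle_null(np.array([1.0, 2.0]), 50.0, speed_short)


class TestClassification:
    def test_threshold_rules(self):
        rng = np.random.default_rng(10)
        nulls = [sc.ShuffleNull(rng.normal(0, 0.03, 100), 100) for _ in range(30)]
        pool = np.concatenate([n.scores for n in nulls])
        hi = np.percentile(pool, 99)
        lo = np.percentile(pool, 1)
        scores = np.array([hi + 0.01, lo - 0.01, 0.0])
        result = sc.classify_speed_cells(scores, nulls)
        assert result.classes == ["p-Speed", "n-Speed", "non-speed"]
        assert result.upper == pytest.approx(hi)
        assert result.lower == pytest.approx(lo)
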