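"""Rate maps, information measures, spatial autocorrelation, gridness."""

import numpy as np
import pytest
from scipy import stats

from speedcells import kinematics as kin
from speedcells import spatial_coding as sp
from speedcells import synthetic_session as ss

from conftest import speed_from_trajectory


def hex_map(nb=40, bs=3.0, spacing=40.0, orient=0.0):
    yy, xx = np.mgrid[0:nb, 0:nb] * bs
    k = 4 * np.pi / (np.sqrt(3) * spacing)
    g = np.zeros((nb, nb))
    for ang in (orient, orient + np.pi / 3, orient + 2 * np.pi / 3):
        g += np.cos(k * np.cos(ang) * xx + k * np.sin(ang) * yy)
    return sp.RateMap2D(bs, np.ones((nb, nb)), g, g + 1.5, np.ones((nb, nb), bool))


class TestSkaggsInformation:
    def test_flat_map_zero(self):
        per_spike, per_sec = sp.skaggs_information(np.full(10, 0.1), np.full(10, 3.0), 3.0)
        assert per_spike == pytest.approx(0.0, abs=1e-12)
        assert per_sec == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_closed_form(self):
        per_spike, per_sec = sp.skaggs_information(
            np.array([0.5, 0.5]), np.array([0.0, 2.0]), 1.0
        )
        assert per_spike == 1.0 and per_sec == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(24))
        lam = rng.uniform(0, 12, 24)
        lam_bar = float(np.sum(p * lam))
        per_spike, per_sec = sp.skaggs_information(p, lam, lam_bar)
        oracle_spike = sum(
            pi * li / lam_bar * np.log2(li / lam_bar) for pi, li in zip(p, lam) if li > 0
        )
        oracle_sec = sum(
            pi * li * np.log2(li / lam_bar) for pi, li in zip(p, lam) if li > 0
        )
        assert per_spike == pytest.approx(oracle_spike, abs=1e-12)
        assert per_sec == pytest.approx(oracle_sec, abs=1e-12)

    def test_nonnegative_for_random_tunings(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(2, 30)
            p = rng.dirichlet(np.ones(n))
            lam = rng.uniform(0, 20, n)
            lam_bar = float(np.sum(p * lam))
            if lam_bar == 0:
                continue
            per_spike, _ = sp.skaggs_information(p, lam, lam_bar)
            assert per_spike >= -1e-12  # Jensen

    def test_zero_mean_rate_flagged(self):
        per_spike, per_sec = sp.skaggs_information(np.array([1.0]), np.array([0.0]), 0.0)
        assert np.isnan(per_spike) and np.isnan(per_sec)


@pytest.fixture(scope="module")
def run_setup():
    traj = ss.simulate_trajectory(ss.TrajectoryModel(), 1800.0, seed=21)
    x_raw, y_raw = kin.interpolate_position(traj)
    x = kin.smooth_position(x_raw)
    y = kin.smooth_position(y_raw)
    speed = kin.compute_speed(x, y)
    run_mask = speed.valid & (speed.values > 2.0)
    return traj, x, y, run_mask


class TestRateMap:
    def test_uniform_poisson_is_flat(self, run_setup):
        _, x, y, run_mask = run_setup
        rng = np.random.default_rng(4)
        spikes = np.sort(rng.uniform(0, 1800, 9000))  # 5 Hz
        m = sp.rate_map(spikes, x, y, run_mask, 120.0)
        vals = m.smoothed_rate[np.isfinite(m.smoothed_rate)]
        assert vals.std() / vals.mean() < 0.10

    def test_point_source_peaks_at_location(self, run_setup):
        _, x, y, run_mask = run_setup
        # spikes whenever the animal passes near (60, 60)
        near = run_mask & (np.hypot(x.values - 60, y.values - 60) < 5)
        spikes = x.times[near]
        m = sp.rate_map(spikes, x, y, run_mask, 120.0)
        iy, ix = np.unravel_index(np.nanargmax(np.where(np.isfinite(m.smoothed_rate), m.smoothed_rate, -np.inf)), m.smoothed_rate.shape)
        assert abs((ix + 0.5) * 3.0 - 60) < 6
        assert abs((iy + 0.5) * 3.0 - 60) < 6

    def test_spike_count_conserved_in_raw_map(self, run_setup):
        _, x, y, run_mask = run_setup
        rng = np.random.default_rng(5)
        spikes = np.sort(rng.uniform(0, 1800, 2000))
        m = sp.rate_map(spikes, x, y, run_mask, 120.0)
        idx = np.floor(spikes / x.dt).astype(int)
        ok = (idx >= 0) & (idx < len(x)) & run_mask[np.clip(idx, 0, len(x) - 1)]
        assert m.spike_count.sum() == ok.sum()

    def test_empty_occupancy_fatal(self, run_setup):
        _, x, y, run_mask = run_setup
        with pytest.raises(ValueError):
            sp.rate_map(np.empty(0), x, y, np.zeros_like(run_mask), 120.0)


class TestDirectionalMap:
    def test_sixty_bins_cover_circle(self, run_setup):
        traj, x, y, run_mask = run_setup
        hd = kin.head_direction(traj)
        centers, rate, _, _ = sp.directional_rate_map(np.array([10.0, 20.0]), hd)
        assert len(centers) == 60
        assert centers[0] == pytest.approx(np.deg2rad(3.0))
        assert centers[-1] == pytest.approx(np.deg2rad(357.0))

    def test_von_mises_unit_preferred_direction(self, run_setup):
        traj, *_ = run_setup
        hd = kin.head_direction(traj)
        true_dir = np.deg2rad(200.0)
        rng = np.random.default_rng(6)
        # thin a head-direction-modulated rate on the binned grid
        gain = np.exp(2.5 * np.cos(hd.values - true_dir))
        p = np.clip(gain / gain.max(), 0, 1)
        spikes = hd.times[(rng.uniform(size=len(hd)) < p) & hd.valid]
        centers, rate, per_spike, _ = sp.directional_rate_map(spikes, hd)
        pref = centers[np.nanargmax(rate)]
        assert abs(np.angle(np.exp(1j * (pref - true_dir)))) < np.deg2rad(6.0)
        assert per_spike > 0.1

    def test_uniform_firing_low_information(self, run_setup):
        traj, *_ = run_setup
        hd = kin.head_direction(traj)
        rng = np.random.default_rng(7)
        spikes = np.sort(rng.uniform(0, 1800, 10000))
        _, _, per_spike, _ = sp.directional_rate_map(spikes, hd)
        assert per_spike < 0.01


class TestAutocorrelogram2D:
    def test_center_is_one_and_symmetric(self):
        m = hex_map(20)
        ac = sp.autocorrelogram_2d(m)
        cy, cx = np.array(ac.r.shape) // 2
        assert ac.r[cy, cx] == pytest.approx(1.0, abs=1e-10)
        flipped = ac.r[::-1, ::-1]
        both = np.isfinite(ac.r) & np.isfinite(flipped)
        assert np.allclose(ac.r[both], flipped[both], atol=1e-10)

    def test_matches_per_lag_pearson_oracle(self):
        rng = np.random.default_rng(8)
        for ny, nx in [(8, 8), (9, 12), (16, 16)]:
            lam = rng.uniform(0, 10, (ny, nx))
            lam[rng.uniform(size=(ny, nx)) < 0.1] = np.nan  # unvisited holes
            m = sp.RateMap2D(3.0, np.ones((ny, nx)), lam, lam, np.isfinite(lam))
            ac = sp.autocorrelogram_2d(m, min_overlap=5)
            for ty in (-3, 0, 2):
                for tx in (-2, 1, 4):
                    a, b = [], []
                    for yy in range(ny):
                        for xx in range(nx):
                            y2, x2 = yy - ty, xx - tx
                            if 0 <= y2 < ny and 0 <= x2 < nx:
                                if np.isfinite(lam[yy, xx]) and np.isfinite(lam[y2, x2]):
                                    a.append(lam[yy, xx])
                                    b.append(lam[y2, x2])
                    got = ac.r[ty + ny - 1, tx + nx - 1]
                    if len(a) < 5 or np.std(a) == 0 or np.std(b) == 0:
                        assert not np.isfinite(got)
                    else:
                        assert got == pytest.approx(stats.pearsonr(a, b).statistic, abs=1e-10)

    def test_low_overlap_undefined(self):
        m = hex_map(10)
        ac = sp.autocorrelogram_2d(m)
        assert not np.isfinite(ac.r[0, 0])  # corner lag has overlap 1

    def test_constant_map_all_undefined(self):
        m = sp.RateMap2D(3.0, np.ones((8, 8)), np.ones((8, 8)), np.full((8, 8), 2.0), np.ones((8, 8), bool))
        ac = sp.autocorrelogram_2d(m, min_overlap=5)
        assert not np.isfinite(ac.r).any()


class TestGridness:
    def test_hexagonal_map_high_gridness(self):
        g = sp.gridness(sp.autocorrelogram_2d(hex_map()), 120.0)
        assert g.defined
        assert g.gridness > 1.0
        assert g.gridness == pytest.approx(np.max(g.annulus_scores))

    def test_isotropic_bump_nonpositive(self):
        nb, bs = 40, 3.0
        yy, xx = np.mgrid[0:nb, 0:nb] * bs
        bump = np.exp(-((xx - 60) ** 2 + (yy - 60) ** 2) / (2 * 20**2))
        m = sp.RateMap2D(bs, np.ones((nb, nb)), bump, bump, np.ones((nb, nb), bool))
        g = sp.gridness(sp.autocorrelogram_2d(m), 120.0)
        assert g.gridness <= 0.0

    def test_square_lattice_negative(self):
        nb, bs = 40, 3.0
        yy, xx = np.mgrid[0:nb, 0:nb] * bs
        sq = np.cos(2 * np.pi * xx / 40) + np.cos(2 * np.pi * yy / 40)
        m = sp.RateMap2D(bs, np.ones((nb, nb)), sq, sq + 2, np.ones((nb, nb), bool))
        g = sp.gridness(sp.autocorrelogram_2d(m), 120.0)
        assert g.gridness < 0.0

    def test_sixty_degree_rotation_invariance(self):
        from scipy.ndimage import rotate

        base = hex_map()
        ac = sp.autocorrelogram_2d(base)
        g0 = sp.gridness(ac, 120.0).gridness
        rot = rotate(base.smoothed_rate, 60.0, reshape=False, order=1, cval=np.nan)
        # crop to the valid rotated interior
        m = sp.RateMap2D(3.0, np.ones_like(rot), rot, rot, np.isfinite(rot))
        g60 = sp.gridness(sp.autocorrelogram_2d(m), 120.0).gridness
        assert g60 > 1.0
        assert abs(g60 - g0) < 0.05
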