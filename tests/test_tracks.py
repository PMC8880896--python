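"""Trajectory statistics: unwrapping, speed, MSD, clusters, projections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import adhact.tracks as T
from adhact.tracks import (
    MSDCurve,
    Trajectory,
    adhesion_clusters,
    diffusion_coefficient,
    ensemble_msd,
    front_rear_projection,
    instantaneous_speed,
    ks_statistic,
    msld,
    unwrap_centroid,
)


def make_traj(pos, dt=5, adh=None):
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    return Trajectory(
        mcs=np.arange(n) * dt,
        position=pos,
        adhesion_fraction=np.zeros(n) if adh is None else adh,
    )


class TestUnwrap:
    def test_stationary_series_unchanged(self):
        raw = np.tile([12.0, 34.0], (10, 1))
        np.testing.assert_allclose(unwrap_centroid(raw, (300, 300)), raw)

    def test_wrap_jump_becomes_small_step(self):
        raw = np.array([[299.5, 10.0], [0.5, 10.0]])
        out = unwrap_centroid(raw, (300, 300))
        np.testing.assert_allclose(out[1], [300.5, 10.0])

    def test_uniform_drift_across_several_wraps(self):
        # constant velocity (1, 0) for 1000 steps wraps three times on a
        # width-300 lattice; unwrapping must recover the full displacement
        true = np.stack([np.arange(1000.0) + 7.3, np.full(1000, 5.0)], axis=1)
        raw = true % [300, 300]
        out = unwrap_centroid(raw, (300, 300))
        np.testing.assert_allclose(out, true, atol=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_walk_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        steps = rng.uniform(-49.9, 49.9, size=(50, 2))
        true = np.cumsum(np.vstack([[10.0, 20.0], steps]), axis=0)
        out = unwrap_centroid(true % [100, 100], (100, 100))
        np.testing.assert_allclose(out, true, atol=1e-8)


class TestSpeed:
    def test_ballistic_track_has_constant_speed(self):
        traj = make_traj(np.stack([np.arange(50.0), np.zeros(50)], 1), dt=5)
        speed = instantaneous_speed(traj, window=25)
        valid = speed[~np.isnan(speed)]
        np.testing.assert_allclose(valid, 0.2)

    def test_stationary_track_has_zero_speed(self):
        traj = make_traj(np.tile([4.0, 4.0], (30, 1)))
        speed = instantaneous_speed(traj, window=25)
        assert np.nanmax(speed) == 0.0

    def test_back_and_forth_cancels_over_even_window(self):
        pos = np.zeros((20, 2))
        pos[1::2, 0] = 1.0  # +1 / -1 alternation per sample
        traj = make_traj(pos, dt=5)
        speed = instantaneous_speed(traj, window=10)
        assert np.nanmax(speed) == 0.0

    def test_window_must_be_multiple_of_sampling(self):
        traj = make_traj(np.zeros((30, 2)), dt=5)
        with pytest.raises(ValueError):
            instantaneous_speed(traj, window=7)


class TestEnsembleMSD:
    def test_deterministic_ballistic_msd_is_quadratic(self):
        v = 0.3
        trajs = [make_traj(np.stack([v * 5 * np.arange(100.0), np.zeros(100)], 1))
                 for _ in range(3)]
        curve = ensemble_msd(trajs, burn_in=0)
        np.testing.assert_allclose(curve.msd, (v * curve.lag) ** 2, atol=1e-9)

    def test_lattice_random_walk_matches_2t(self):
        # 2D walk with +/-1 per axis per step: MSD(t) = 2 t (per step var 1
        # per axis), checked against the brute-force ensemble
        rng = np.random.default_rng(0)
        n_rep, n_step = 10_000, 60
        steps = rng.choice([-1.0, 1.0], size=(n_rep, n_step, 2))
        pos = np.cumsum(steps, axis=1)
        d2 = (pos**2).sum(axis=2).mean(axis=0)
        trajs = [
            Trajectory(mcs=np.arange(n_step + 1),
                       position=np.vstack([[0, 0], pos[i]]),
                       adhesion_fraction=np.zeros(n_step + 1))
            for i in range(200)
        ]
        curve = ensemble_msd(trajs, burn_in=0)
        t = curve.lag[1:]
        # closed form on the big ensemble
        np.testing.assert_allclose(d2, 2 * np.arange(1, n_step + 1), rtol=0.05)
        # the MSDCurve implementation on a subset agrees with 2t within noise
        np.testing.assert_allclose(curve.msd[1:], 2 * t, rtol=0.35)
        assert curve.msd[0] == 0.0

    def test_single_constant_track_gives_zero(self):
        traj = make_traj(np.tile([5.0, 5.0], (40, 1)))
        curve = ensemble_msd([traj], burn_in=0)
        assert np.all(curve.msd == 0.0)

    def test_shuffled_increments_lose_superdiffusive_curvature(self):
        # persistent (velocity-correlated, drift-free) walks are
        # superdiffusive below the persistence time; time-shuffling their
        # steps destroys the correlation and the exponent drops to ~1
        rng = np.random.default_rng(3)
        gamma, sigma, n, n_rep = 20.0, 1.0, 20_000, 60
        a = np.exp(-1 / gamma)

        def exponent(trajs):
            c = ensemble_msd(trajs, burn_in=0)
            m = (c.lag >= 2) & (c.lag <= 15)
            return np.polyfit(np.log(c.lag[m]), np.log(c.msd[m]), 1)[0]

        # vectorised over replicates; the series is long relative to gamma
        # so each track's empirical mean step (a drift surviving the
        # shuffle) is negligible
        v = np.empty((n, n_rep, 2))
        v[0] = rng.normal(0, sigma, (n_rep, 2))
        noise = rng.normal(0, sigma * np.sqrt(1 - a * a), (n, n_rep, 2))
        for k in range(1, n):
            v[k] = a * v[k - 1] + noise[k]
        persistent, shuffled = [], []
        for i in range(n_rep):
            persistent.append(make_traj(np.cumsum(v[:, i], axis=0), dt=1))
            perm = rng.permutation(n)
            shuffled.append(make_traj(np.cumsum(v[perm, i], axis=0), dt=1))
        assert exponent(persistent) > 1.7
        assert abs(exponent(shuffled) - 1.0) < 0.15


class TestDiffusionCoefficient:
    def test_exact_line_recovers_d(self):
        lag = np.arange(0, 24001, 5.0)
        curve = MSDCurve(lag=lag, msd=4 * 0.01 * lag)
        assert diffusion_coefficient(curve) == pytest.approx(0.01)

    def test_offset_absorbed_by_intercept(self):
        lag = np.arange(0, 24001, 5.0)
        curve = MSDCurve(lag=lag, msd=4 * 0.01 * lag + 123.0)
        assert diffusion_coefficient(curve) == pytest.approx(0.01)

    def test_furth_curve_slope_in_late_window(self):
        from adhact.msdmodels import furth

        lag = np.arange(0, 24001, 5.0)
        curve = MSDCurve(lag=lag, msd=furth(lag, 0.1, 500))
        # long-time limit: slope -> 4 nu^2 gamma, so D -> nu^2 gamma = 5
        assert diffusion_coefficient(curve) == pytest.approx(5.0, rel=0.02)

    def test_window_outside_data_raises(self):
        curve = MSDCurve(lag=np.arange(100.0), msd=np.arange(100.0))
        with pytest.raises(ValueError):
            diffusion_coefficient(curve)


def brute_force_clusters(adh):
    """Flood-fill oracle with periodic Moore connectivity."""
    h, w = adh.shape
    seen = np.zeros_like(adh, dtype=bool)
    sizes = []
    for y0 in range(h):
        for x0 in range(w):
            if adh[y0, x0] and not seen[y0, x0]:
                stack = [(y0, x0)]
                seen[y0, x0] = True
                size = 0
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = (y + dy) % h, (x + dx) % w
                            if adh[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                sizes.append(size)
    return sorted(sizes)


class TestClusters:
    def test_empty_layer(self):
        assert adhesion_clusters(np.zeros((10, 10), bool)).sizes.size == 0

    def test_diagonal_pair_is_one_moore_cluster(self):
        adh = np.zeros((10, 10), bool)
        adh[3, 3] = adh[4, 4] = True
        assert list(adhesion_clusters(adh).sizes) == [2]

    def test_block_plus_isolated_site(self):
        adh = np.zeros((12, 12), bool)
        adh[2:5, 2:5] = True
        adh[9, 9] = True
        assert sorted(adhesion_clusters(adh).sizes) == [1, 9]

    def test_cluster_wrapping_the_periodic_seam(self):
        adh = np.zeros((8, 8), bool)
        adh[0, 3] = adh[7, 3] = adh[7, 4] = True  # touches across the seam
        assert list(adhesion_clusters(adh).sizes) == [3]
        assert sorted(adhesion_clusters(adh, periodic=False).sizes) == [1, 2]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.5))
    def test_matches_flood_fill_oracle(self, seed, density):
        rng = np.random.default_rng(seed)
        adh = rng.random((15, 15)) < density
        got = sorted(adhesion_clusters(adh).sizes)
        assert got == brute_force_clusters(adh)
        assert sum(got) == int(adh.sum())


class TestFrontRearProjection:
    def _setup(self, offsets, centre=(50.0, 50.0), w=100, h=100):
        # cell moving along +x at 0.2 sites/MCS; adhesions at fixed offsets
        # from the centroid at snapshot time
        mcs = np.arange(0, 201, 5)
        pos = np.stack([centre[0] - 50 + 0.2 * mcs, np.full(mcs.size, centre[1])], 1)
        traj = Trajectory(mcs=mcs, position=pos,
                          adhesion_fraction=np.zeros(mcs.size))
        t_snap = 100
        c = pos[mcs == t_snap][0] % [w, h]
        sites = np.array(
            [int(round(c[1] + dy)) % h * w + int(round(c[0] + dx)) % w
             for dx, dy in offsets], dtype=np.int64)
        return [(t_snap, sites)], traj

    def test_single_adhesion_ahead_projects_positive(self):
        snaps, traj = self._setup([(5, 0)])
        ap = front_rear_projection(snaps, traj, (100, 100))
        np.testing.assert_allclose(ap.projections, [5.0], atol=0.5)

    def test_symmetric_adhesions_average_to_zero(self):
        snaps, traj = self._setup([(4, 0), (-4, 0), (0, 3), (0, -3)])
        ap = front_rear_projection(snaps, traj, (100, 100))
        assert ap.projections.mean() == pytest.approx(0.0, abs=1e-9)

    def test_axis_reversal_flips_sign(self):
        snaps, traj = self._setup([(5, 0), (2, 2)])
        fwd = front_rear_projection(snaps, traj, (100, 100))
        # play the same positions backwards in time: the centroid at the
        # snapshot (the series midpoint) is unchanged, the axis reverses
        rev_traj = Trajectory(mcs=traj.mcs, position=traj.position[::-1],
                              adhesion_fraction=np.zeros(traj.mcs.size))
        rev = front_rear_projection(snaps, rev_traj, (100, 100))
        np.testing.assert_allclose(rev.projections, -fwd.projections, atol=1e-6)

    def test_translation_invariance(self):
        snaps_a, traj_a = self._setup([(5, 0), (-2, 1)], centre=(50.0, 50.0))
        snaps_b, traj_b = self._setup([(5, 0), (-2, 1)], centre=(20.0, 80.0))
        a = front_rear_projection(snaps_a, traj_a, (100, 100))
        b = front_rear_projection(snaps_b, traj_b, (100, 100))
        np.testing.assert_allclose(sorted(a.projections), sorted(b.projections),
                                   atol=1e-6)

    def test_stationary_snapshot_is_skipped(self):
        mcs = np.arange(0, 201, 5)
        pos = np.tile([50.0, 50.0], (mcs.size, 1))
        traj = Trajectory(mcs=mcs, position=pos, adhesion_fraction=np.zeros(mcs.size))
        ap = front_rear_projection([(100, np.array([5050]))], traj, (100, 100))
        assert ap.n_skipped == 1
        assert ap.projections.size == 0


class TestScalarStats:
    def test_ks_identical_samples(self):
        d, p = ks_statistic([1, 2, 3, 4], [1, 2, 3, 4])
        assert d == 0.0

    def test_ks_disjoint_supports(self):
        d, _ = ks_statistic([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_ks_partial_overlap_edf_gap(self):
        # EDFs differ by 1 - 1/2 at x = 3
        d, _ = ks_statistic([1, 2, 3], [1, 2, 3, 4, 5, 6])
        assert d == pytest.approx(0.5)

    def test_ks_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1, 2])

    def test_msld_constant_speed_is_zero(self):
        assert msld(np.full(50, 0.3)) == 0.0

    def test_msld_alternating_doubling(self):
        v = np.tile([0.2, 0.4], 25)
        assert msld(v) == pytest.approx(np.log(2) ** 2)

    def test_msld_scale_invariant(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.1, 1.0, 100)
        assert msld(v) == pytest.approx(msld(10 * v))

    def test_msld_all_zero_raises(self):
        with pytest.raises(ValueError):
            msld(np.zeros(10))


class TestTrackIO:
    def test_roundtrip_through_csv(self, tmp_path):
        rng = np.random.default_rng(2)
        pos = np.cumsum(rng.normal(0, 1, (200, 2)), axis=0) + [150, 150]
        traj = make_traj(pos, dt=5, adh=rng.uniform(0, 1, 200))
        traj.speed = instantaneous_speed(traj, 25)
        path = tmp_path / "tracks.csv"
        T.write_track_csv(path, [traj], (300, 300))
        back = T.read_track_csv(path, (300, 300))
        assert len(back) == 1
        # positions reconstructed up to the CSV float precision
        np.testing.assert_allclose(back[0].position, traj.position, atol=1e-4)
        np.testing.assert_allclose(back[0].adhesion_fraction,
                                   traj.adhesion_fraction, atol=1e-5)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("mcs,x,y\n0,1,2\n")
        with pytest.raises(ValueError, match="missing columns"):
            T.read_track_csv(path, (300, 300))
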