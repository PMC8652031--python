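import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timecycle.state_space import (
    delay_embed,
    embed_over_lags,
    laplacian_eigenmap,
)
from timecycle.topology import rips_h1_max_persistence
from timecycle.types import PointCloud, Series

from conftest import make_series


class TestDelayEmbed:
    def test_constant_series(self):
        pc = delay_embed(make_series(np.full(24, 3.0)), dim=3, lag_samples=3)
        assert pc.n_points == 18
        assert np.all(pc.points == 3.0)

    def test_enumerated_coordinates(self):
        pc = delay_embed(make_series(np.arange(10.0)), dim=3, lag_samples=2)
        assert pc.n_points == 6
        assert np.array_equal(pc.points[0], [4.0, 2.0, 0.0])
        assert np.array_equal(pc.points[-1], [9.0, 7.0, 5.0])
        # linear series embeds onto a line
        centered = pc.points - pc.points.mean(axis=0)
        assert np.linalg.matrix_rank(centered, tol=1e-9) == 1

    def test_too_short_error_names_minimum(self):
        with pytest.raises(ValueError, match="at least 13"):
            delay_embed(make_series(np.arange(10.0)), dim=3, lag_samples=5)

    @settings(max_examples=50, deadline=None)
    @given(n=st.integers(8, 60), lag=st.integers(1, 8),
           dim=st.integers(2, 3))
    def test_point_count_formula(self, n, lag, dim):
        if n < (dim - 1) * lag + 3:
            return
        pc = delay_embed(make_series(np.sin(np.arange(n))), dim, lag)
        assert pc.n_points == n - (dim - 1) * lag
        assert pc.dimension == dim

    def test_commutes_with_affine_maps(self, rng):
        x = rng.normal(size=20)
        a, b = 2.5, -1.75
        p1 = delay_embed(make_series(a * x + b), 3, 2).points
        p2 = a * delay_embed(make_series(x), 3, 2).points + b
        assert np.allclose(p1, p2)

    def test_missing_values_rejected(self):
        vals = np.arange(12.0)
        vals[3] = np.nan
        with pytest.raises(ValueError):
            delay_embed(make_series(vals), 3, 2)


def circle_points_3d(n, radius=1.0):
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(th), radius * np.sin(th),
                            np.zeros(n)])


def cyclic_order_preserved(points_2d):
    """True if the angular order of points matches their index order."""
    c = points_2d - points_2d.mean(axis=0)
    ang = np.arctan2(c[:, 1], c[:, 0])
    order = np.argsort(ang)
    pos = np.empty(len(order), dtype=int)
    pos[order] = np.arange(len(order))
    diffs = np.diff(pos)
    n = len(points_2d)
    forward = np.count_nonzero((diffs % n) == 1)
    backward = np.count_nonzero((diffs % n) == n - 1)
    return max(forward, backward) == n - 1


class TestLaplacianEigenmap:
    def test_planar_circle_preserves_cyclic_order(self):
        pc = PointCloud(circle_points_3d(24), source_lag=1)
        out = laplacian_eigenmap(pc, k_neighbors=6)
        assert out is not None and out.dimension == 2
        assert cyclic_order_preserved(out.points)

    def test_ring_graph_gives_circle(self):
        # k=2 on evenly spaced circle points makes the kNN graph a cycle
        # graph; its Laplacian eigenvectors are cos/sin, so the output is
        # a circle (equal radii) up to rotation/reflection.
        n = 24
        pc = PointCloud(circle_points_3d(n), source_lag=1)
        out = laplacian_eigenmap(pc, k_neighbors=2)
        c = out.points - out.points.mean(axis=0)
        radii = np.hypot(c[:, 0], c[:, 1])
        assert radii.std() / radii.mean() < 1e-6
        assert cyclic_order_preserved(out.points)
        ang = np.arctan2(c[:, 1], c[:, 0])
        steps = np.abs(np.diff(np.unwrap(ang)))
        assert np.allclose(steps, 2 * np.pi / n, atol=1e-6)

    def test_helix_recovers_circle_better_than_projection(self):
        # drifting oscillation: helix in 3-D; NLDR output should carry a
        # stronger H1 feature than naively dropping the third coordinate.
        # The trend must stay moderate relative to the oscillation: when
        # drift dominates the local geometry, the NLDR deliberately picks
        # the drift coordinate and no circle appears.
        t = np.arange(0.0, 48.0, 1.0)
        x = np.sin(2 * np.pi * t / 24.0) + 0.02 * t
        x = (x - x.mean()) / x.std(ddof=1)
        pc3 = delay_embed(Series(t, x), 3, 4)
        out = laplacian_eigenmap(pc3)
        # rescale both clouds to unit rms so scores are comparable
        proj = pc3.points[:, :2]
        proj = (proj - proj.mean(0)) / np.sqrt((proj ** 2).mean())
        emb = (out.points - out.points.mean(0))
        emb = emb / np.sqrt((emb ** 2).mean())
        assert rips_h1_max_persistence(emb) > rips_h1_max_persistence(proj)

    def test_dominant_drift_suppresses_circle(self):
        t = np.arange(0.0, 48.0, 1.0)

        def le_score(x):
            x = (x - x.mean()) / x.std(ddof=1)
            out = laplacian_eigenmap(delay_embed(Series(t, x), 3, 4))
            emb = out.points - out.points.mean(0)
            emb = emb / np.sqrt((emb ** 2).mean())
            return rips_h1_max_persistence(emb)

        sine = np.sin(2 * np.pi * t / 24.0)
        assert le_score(sine + 0.08 * t) < le_score(sine)

    def test_degenerate_cloud_sentinel(self):
        pc = PointCloud(np.zeros((10, 3)), source_lag=2)
        assert laplacian_eigenmap(pc) is None


class TestEmbedOverLags:
    def test_cloud_sizes(self):
        s = make_series(np.sin(np.arange(24) * 0.5))
        out = embed_over_lags(s, (2, 3, 4, 5))
        assert [lag for lag, _ in out] == [2, 3, 4, 5]
        assert [pc.n_points for _, pc in out] == [20, 18, 16, 14]

    def test_infeasible_lag_errors(self):
        s = make_series(np.sin(np.arange(24) * 0.5))
        with pytest.raises(ValueError):
            embed_over_lags(s, (50,))

    def test_infeasible_lags_skipped(self):
        s = make_series(np.sin(np.arange(12) * 0.5))
        out = embed_over_lags(s, (2, 3, 4, 5))
        assert [lag for lag, _ in out] == [2, 3, 4]

    def test_constant_series_degenerate(self):
        out = embed_over_lags(make_series(np.zeros(24)), (2, 3))
        assert all(pc is None for _, pc in out)


class TestSinusoidVsShuffles:
    def test_sine_beats_shuffled_versions(self, sine_series_2h48h, rng):
        from timecycle.preprocess import standardize
        s = standardize(sine_series_2h48h)
        for lag in (2, 3, 4, 5):
            pc = laplacian_eigenmap(delay_embed(s, 3, lag))
            score = rips_h1_max_persistence(pc)
            for _ in range(20):
                x = rng.permutation(s.values)
                spc = laplacian_eigenmap(
                    delay_embed(Series(s.times, x), 3, lag))
                assert score > rips_h1_max_persistence(spc)
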