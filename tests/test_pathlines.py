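"""Pathline tracing and residence-time sums against analytic flows."""

import numpy as np
import pytest

from spongeflow.lbm import MacroFields
from spongeflow.pathlines import (
    Pathline,
    PathlineSet,
    cavity_seed_grid,
    clip_to_region,
    filter_cavity_contained,
    pathline_stats,
    residence_stats,
    trace_pathlines,
)


def make_field(u_func, shape=(32, 32, 8)):
    """MacroFields with u sampled from an analytic function of (x, y, z)."""
    g = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"))
    u = np.asarray(u_func(*g), dtype=float)
    return MacroFields(rho=np.ones(shape), u=u,
                       solid=np.zeros(shape, dtype=bool))


class TestTracing:
    def test_uniform_field_gives_straight_line_of_known_length(self):
        v = 0.05
        field = make_field(lambda x, y, z: (v * np.ones_like(x, float),
                                            np.zeros_like(x, float),
                                            np.zeros_like(x, float)))
        ds = 0.5
        paths = trace_pathlines(field, np.array([[2.0, 16.0, 4.0]]), ds=ds,
                                u_ref=v, max_steps=20, bidirectional=False)
        (line,) = paths.lines
        d = np.diff(line.points, axis=0)
        assert np.allclose(d[:, 1:], 0.0, atol=1e-12)
        assert np.allclose(np.linalg.norm(d, axis=1), ds, rtol=1e-12)
        assert line.length() == pytest.approx(ds * (line.n - 1), rel=1e-12)

    def test_solid_body_rotation_stays_on_circle(self):
        omega = 0.01
        c = 31.5

        def u(x, y, z):
            return (-omega * (y - c), omega * (x - c), np.zeros_like(x, float))

        field = make_field(u, shape=(64, 64, 4))
        r0 = 12.0
        seed = np.array([[c + r0, c, 2.0]])
        n_turn = int(np.ceil(2 * np.pi * r0 / 0.25))
        paths = trace_pathlines(field, seed, ds=0.25, u_ref=omega * r0,
                                max_steps=n_turn + 10, bidirectional=False)
        (line,) = paths.lines
        r = np.hypot(line.points[:, 0] - c, line.points[:, 1] - c)
        assert np.abs(r / r0 - 1).max() < 1e-3

    def test_seed_inside_solid_rejected(self):
        field = make_field(lambda x, y, z: (np.ones_like(x, float),
                                            np.zeros_like(x, float),
                                            np.zeros_like(x, float)))
        field.solid[10:14, 10:14, :] = True
        paths = trace_pathlines(field, np.array([[11.0, 11.0, 3.0],
                                                 [2.0, 2.0, 3.0]]),
                                u_ref=1.0, max_steps=5, bidirectional=False)
        assert paths.rejected_seeds == 1
        assert len(paths) == 1

    def test_refinement_consistency_of_length_and_time(self):
        # halving the integrator step changes l and t_res by < 1%
        omega = 0.01
        c = 31.5

        def u(x, y, z):
            return (-omega * (y - c), omega * (x - c), np.zeros_like(x, float))

        field = make_field(u, shape=(64, 64, 4))
        seed = np.array([[c + 10.0, c, 2.0]])
        out = {}
        for ds in (0.5, 0.25):
            n = int(np.ceil(2 * np.pi * 10 / ds))
            paths = trace_pathlines(field, seed, ds=ds, u_ref=omega * 10,
                                    max_steps=n, bidirectional=False)
            out[ds] = pathline_stats(paths.lines[0])
        # compare per-unit-arc residence (lines have ~1 turn each)
        (l1, t1), (l2, t2) = out[0.5], out[0.25]
        assert abs((t1 / l1) / (t2 / l2) - 1) < 0.01


class TestContainmentFilter:
    def _line(self, pts):
        pts = np.asarray(pts, dtype=float)
        return Pathline(points=pts, velocities=np.ones_like(pts),
                        seed_index=0, termination="cap")

    def test_constructed_membership_is_exact(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[5:15, 5:15, 5:15] = True
        rng = np.random.default_rng(7)
        inside, crossing = [], []
        for _ in range(40):
            p0 = rng.uniform(6, 13, size=3)
            inside.append(self._line([p0, p0 + 0.5]))
        for _ in range(60):
            p0 = rng.uniform(6, 13, size=3)
            crossing.append(self._line([p0, [1.0, 1.0, 1.0]]))
        paths = PathlineSet(lines=inside + crossing)
        kept = filter_cavity_contained(paths, mask)
        assert len(kept) == 40

    def test_single_outside_point_excludes_line(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        line = self._line([[3, 3, 3], [4, 4, 4], [9, 9, 9]])
        assert len(filter_cavity_contained(PathlineSet([line]), mask)) == 0
        inside = self._line([[3, 3, 3], [4, 4, 4]])
        kept = filter_cavity_contained(PathlineSet([inside]), mask)
        assert len(kept) == 1
        assert kept.lines[0] is inside

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_cavity_contained(PathlineSet([]), np.zeros((3, 3, 3), bool))

    def test_clip_keeps_in_mask_run_around_seed(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        pts = [[0, 5, 5], [3, 5, 5], [4, 5, 5], [5, 5, 5], [9, 5, 5]]
        line = Pathline(points=np.array(pts, float),
                        velocities=np.ones((5, 3)), seed_index=2,
                        termination="exit")
        clipped = clip_to_region(PathlineSet([line]), mask)
        assert len(clipped) == 1
        assert len(clipped.lines[0].points) == 3
        assert clipped.lines[0].seed_index == 1


class TestResidenceStats:
    def _line(self, pts, speeds):
        pts = np.asarray(pts, dtype=float)
        v = np.zeros((len(pts), 3))
        v[:, 0] = speeds
        return Pathline(points=pts, velocities=v, seed_index=0,
                        termination="cap")

    def test_constant_speed_gives_length_over_speed(self):
        L, v = 7.0, 0.2
        line = self._line([[0, 0, 0], [L / 2, 0, 0], [L, 0, 0]], [v, v, v])
        l, t = pathline_stats(line)
        assert l == pytest.approx(L, rel=1e-14)
        assert t == pytest.approx(L / v, rel=1e-14)

    def test_two_segment_trapezoidal_speeds(self):
        # speeds (v, v, v/2): t = (L/2)/v + (L/2)/(3v/4)
        L, v = 4.0, 0.1
        line = self._line([[0, 0, 0], [L / 2, 0, 0], [L, 0, 0]],
                          [v, v, v / 2])
        _, t = pathline_stats(line)
        assert t == pytest.approx((L / 2) / v + (L / 2) / (0.75 * v), rel=1e-14)

    def test_zero_speed_segment_warns_and_skips(self):
        line = self._line([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [0.1, 0.0, 0.0])
        with pytest.warns(UserWarning, match="zero-speed"):
            _, t = pathline_stats(line)
        assert t == pytest.approx(1.0 / 0.05, rel=1e-14)

    def test_harmonic_bound_on_residence_time(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(3, 12)
            pts = np.cumsum(rng.uniform(0.1, 1.0, size=(n, 3)), axis=0)
            v = np.zeros((n, 3))
            v[:, 0] = rng.uniform(0.01, 1.0, size=n)
            line = Pathline(points=pts, velocities=v, seed_index=0,
                            termination="cap")
            l, t = pathline_stats(line)
            sp = np.linalg.norm(v, axis=1)
            assert t >= l / sp.max() - 1e-12
            assert t <= l / sp.min() + 1e-12

    def test_distribution_aggregation_and_density(self):
        rng = np.random.default_rng(5)
        lines = []
        for _ in range(50):
            L = rng.uniform(1, 10)
            v = rng.uniform(0.05, 0.5)
            lines.append(self._line([[0, 0, 0], [L, 0, 0]], [v, v]))
        dist = residence_stats(PathlineSet(lines), t_cross=2.0)
        assert len(dist.samples) == 50
        assert (dist.samples > 0).all()
        assert dist.t_cross == 2.0
        # density integrates to 1 over log-spaced support
        widths = np.diff(np.log10(dist.bin_edges))
        assert (dist.density * widths).sum() == pytest.approx(1.0, rel=1e-6)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="no retained"):
            residence_stats(PathlineSet([]))


class TestSeedGrid:
    def test_seeds_land_inside_mask_and_are_reproducible(self):
        mask = np.zeros((20, 20, 30), dtype=bool)
        mask[4:16, 4:16, 5:25] = True
        a = cavity_seed_grid(mask, 100, seed=3)
        b = cavity_seed_grid(mask, 100, seed=3)
        assert np.array_equal(a, b)
        vox = np.round(a).astype(int)
        assert mask[vox[:, 0], vox[:, 1], vox[:, 2]].all()
        assert 50 <= len(a) <= 200
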