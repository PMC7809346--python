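"""FEL reconstruction, projection, minima, minimax paths, protocols."""

import math

import numpy as np
import pytest

from glypath import fel as fl
from glypath import sampling as sp
from glypath import synthetic as syn


def make_log(hills, cv_names=("x",), bias_factor=10.0):
    log = sp.HillsLog(cv_names=cv_names)
    for i, (center, widths, height) in enumerate(hills):
        log.append(sp.Hill(time=float(i + 1), center=center, widths=widths,
                           height=height, bias_factor=bias_factor))
    return log


class TestReconstruct:
    def test_single_hill_closed_form(self):
        # F = -(gamma/(gamma-1)) * bias, normalized: (10/9)*w far away, 0 at center
        w = 0.9
        log = make_log([((0.0,), (0.1,), w)])
        grid = fl.reconstruct_fel(log, axes=(fl.Axis("x", -2.0, 2.0, 401),))
        assert grid.values.min() == pytest.approx(0.0, abs=1e-12)
        center_idx = grid.nearest_index([0.0])
        assert grid.values[center_idx] == pytest.approx(0.0, abs=1e-9)
        far_idx = grid.nearest_index([2.0])
        assert grid.values[far_idx] == pytest.approx((10.0 / 9.0) * w, abs=1e-6)

    def test_empty_log_rejected(self):
        with pytest.raises(fl.FELError, match="empty"):
            fl.reconstruct_fel(sp.HillsLog(cv_names=("x",)))

    def test_bias_linearity_in_hills(self, rng):
        hills = [(tuple(rng.uniform(-1, 1, 1)), (0.1,), float(rng.uniform(0.2, 1)))
                 for _ in range(40)]
        log_ab = make_log(hills)
        log_a, log_b = make_log(hills[:25]), make_log(hills[25:])
        pts = rng.uniform(-1, 1, size=(30, 1))
        total = sp.evaluate_bias_grid(log_ab, pts)
        parts = sp.evaluate_bias_grid(log_a, pts) + sp.evaluate_bias_grid(log_b, pts)
        assert np.allclose(total, parts, atol=1e-12)

    def test_converged_1d_double_well_barrier_recovery(self, converged_1d_run):
        # metadynamics on a known 3.0 kcal/mol barrier: recovered within 0.5
        log, _ = converged_1d_run
        barrier, delta_f = fl.barrier_from_run(log, depth_threshold=0.8)
        assert barrier == pytest.approx(3.0, abs=0.5)
        assert delta_f == pytest.approx(0.5, abs=0.5)


class TestProjection:
    def _separable_grid(self):
        ax = fl.Axis("a", -1, 1, 41)
        bx = fl.Axis("b", -1, 1, 41)
        cx = fl.Axis("c", -1, 1, 41)
        A, B, C = np.meshgrid(ax.values, bx.values, cx.values, indexing="ij")
        f = (A**2 + 0.5 * B**2)
        g = 3.0 * C**2
        return fl.FELGrid((ax, bx, cx), f + g), f[:, :, 0]

    def test_constant_axis_projection_equals_slice(self):
        ax = fl.Axis("a", -1, 1, 21)
        bx = fl.Axis("b", -1, 1, 21)
        A, _ = np.meshgrid(ax.values, bx.values, indexing="ij")
        grid = fl.FELGrid((ax, bx), A**2)  # constant along b
        proj = fl.project_fel(grid, ["a"], temperature=300.0)
        assert np.allclose(proj.values, A[:, 0] ** 2 - (A[:, 0] ** 2).min(), atol=1e-9)

    def test_separable_landscape_projects_exactly(self):
        grid, f_ab = self._separable_grid()
        proj = fl.project_fel(grid, ["a", "b"], temperature=300.0)
        assert np.allclose(proj.values, f_ab - f_ab.min(), atol=1e-9)

    def test_projection_never_raises_minimax_barrier(self, reaction_landscape,
                                                     reaction_grid):
        t = reaction_landscape.truth
        minima3 = fl.find_minima(reaction_grid, depth_threshold=1.0)
        path3 = fl.trace_mfep(reaction_grid, minima3[0], minima3[1])
        proj = fl.project_fel(reaction_grid, ["CV1", "CV3"], temperature=300.0)
        minima2 = fl.find_minima(proj, depth_threshold=0.5)
        assert len(minima2) >= 2
        path2 = fl.trace_mfep(proj, minima2[0], minima2[1])
        assert path2.energies.max() - path2.energies[0] <= \
            path3.energies.max() - path3.energies[0] + 1e-9

    def test_bad_requests_rejected(self):
        grid, _ = self._separable_grid()
        with pytest.raises(fl.FELError):
            fl.project_fel(grid, ["nope"])
        with pytest.raises(fl.FELError):
            fl.project_fel(grid, ["a", "b", "c"])


class TestMinima:
    def test_single_paraboloid(self):
        ax = fl.Axis("x", -1, 1, 51)
        bx = fl.Axis("y", -1, 1, 51)
        X, Y = np.meshgrid(ax.values, bx.values, indexing="ij")
        minima = fl.find_minima(fl.FELGrid((ax, bx), X**2 + Y**2), depth_threshold=0.1)
        assert len(minima) == 1
        assert np.allclose(minima[0].point, [0, 0], atol=1e-9)

    def test_flat_grid_has_no_minima(self):
        ax = fl.Axis("x", -1, 1, 11)
        assert fl.find_minima(fl.FELGrid((ax,), np.zeros(11))) == []

    def test_analytic_minima_recovered_within_one_cell(self, conf_landscape):
        grid = fl.grid_from_potential(conf_landscape, n=101)
        minima = fl.find_minima(grid, depth_threshold=1.0)
        assert len(minima) == 2
        spacing = grid.axes[0].spacing
        truth_pts = conf_landscape.truth.minima
        for m in minima:
            best = min(np.linalg.norm(m.point - t) for t in truth_pts)
            assert best <= spacing * math.sqrt(2) + 1e-9

    def test_shallow_noise_minima_filtered(self, rng):
        ax = fl.Axis("x", -1, 1, 201)
        base = 4.0 * (ax.values**2 - 0.25) ** 2  # two wells, barrier 0.25 kcal/mol
        noisy = base + 0.02 * rng.standard_normal(201)
        minima = fl.find_minima(fl.FELGrid((ax,), noisy), depth_threshold=0.1)
        assert len(minima) == 2


def minimax_oracle(values, start, end):
    """Independent minimax-barrier oracle: bisect the connection threshold."""
    from scipy import ndimage
    levels = np.unique(values)
    lo, hi = 0, len(levels) - 1
    structure = np.ones((3,) * values.ndim)
    while lo < hi:
        mid = (lo + hi) // 2
        lab, _ = ndimage.label(values <= levels[mid], structure=structure)
        if lab[start] and lab[start] == lab[end]:
            hi = mid
        else:
            lo = mid + 1
    return levels[lo]


class TestMFEP:
    def test_flat_surface_zero_barrier(self):
        ax = fl.Axis("x", 0, 1, 9)
        bx = fl.Axis("y", 0, 1, 9)
        grid = fl.FELGrid((ax, bx), np.zeros((9, 9)))
        res = fl.trace_mfep(grid, (0, 0), (8, 8))
        assert res.barrier == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_random_grid_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 10, size=(8, 8))
        start, end = (0, 0), (7, 7)
        vals[start] = 0.0
        ax = fl.Axis("x", 0, 1, 8)
        bx = fl.Axis("y", 0, 1, 8)
        grid = fl.FELGrid((ax, bx), vals)
        res = fl.trace_mfep(grid, start, end)
        assert res.energies.max() == pytest.approx(
            minimax_oracle(vals, start, end), abs=1e-12)

    def test_barrier_invariant_under_constant_shift(self):
        rng = np.random.default_rng(42)
        vals = rng.uniform(0, 5, size=(8, 8))
        ax = fl.Axis("x", 0, 1, 8)
        bx = fl.Axis("y", 0, 1, 8)
        r1 = fl.trace_mfep(fl.FELGrid((ax, bx), vals), (0, 0), (7, 7))
        r2 = fl.trace_mfep(fl.FELGrid((ax, bx), vals + 17.0), (0, 0), (7, 7))
        assert r1.barrier == pytest.approx(r2.barrier, abs=1e-12)
        assert r1.saddle_energy + 17.0 == pytest.approx(r2.saddle_energy, abs=1e-12)

    def test_reaction_saddle_within_one_cell(self, reaction_landscape, reaction_grid):
        minima = fl.find_minima(reaction_grid, depth_threshold=1.0)
        assert len(minima) == 2
        path = fl.trace_mfep(reaction_grid, minima[0], minima[1])
        spacing = reaction_grid.axes[0].spacing
        offset = np.linalg.norm(path.saddle_point - reaction_landscape.truth.saddle)
        assert offset <= spacing * math.sqrt(3) + 1e-9
        assert abs(path.saddle_energy - (reaction_landscape.truth.saddle_energy
                                         - min(reaction_landscape.truth.minima_energies))) < 0.1

    def test_disconnected_regions_error(self):
        ax = fl.Axis("x", 0, 1, 7)
        vals = np.zeros(7)
        vals[3] = np.inf
        grid = fl.FELGrid.__new__(fl.FELGrid)  # bypass finite check deliberately
        grid.axes = (ax,)
        grid.values = vals
        with pytest.raises(fl.FELError, match="unreachable"):
            fl.trace_mfep(grid, (0,), (6,))


class TestProtocols:
    def test_convergence_check_on_converged_run(self, converged_1d_run):
        log, _ = converged_1d_run
        report = fl.convergence_check(log, checkpoints=[600, 1200, 1800, 2400, 3000],
                                      tolerance=0.25, basin_radius=0.15, n=121)
        assert report.converged
        tail = report.delta_f[-3:]
        assert max(tail) - min(tail) < 0.25

    def test_early_fraction_not_converged(self, converged_1d_run):
        log, _ = converged_1d_run
        early = log[:300]  # first 10% of the deposits
        report = fl.convergence_check(early, checkpoints=[60, 120, 180, 240, 300],
                                      tolerance=0.25, basin_radius=0.15, n=121)
        assert not report.converged

    def test_duplicate_log_has_zero_variation(self):
        log = make_log([((0.3,), (0.1,), 0.5), ((0.3001,), (0.1,), 0.5)] * 10)
        # identical landscape at every checkpoint multiple of the pattern
        f1 = fl.reconstruct_fel(log[:10], axes=(fl.Axis("x", -1, 1, 101),))
        f2 = fl.reconstruct_fel(log[:20], axes=(fl.Axis("x", -1, 1, 101),))
        # doubling identical hills rescales the bias but not the argmin structure
        assert np.argmin(f1.values) == np.argmin(f2.values)

    def test_too_few_checkpoints_rejected(self, converged_conf_run):
        hills, _ = converged_conf_run
        with pytest.raises(fl.FELError):
            fl.convergence_check(hills, checkpoints=[2000])

    def test_hill_heights_decay_in_deepest_well(self, converged_conf_run, conf_landscape):
        # well-tempered convergence: late hills deposited near the global
        # minimum are far smaller than the initial height
        hills, _ = converged_conf_run
        target = conf_landscape.truth.minima[1]
        last_quarter = hills[1500:]
        near = [h.height for h in last_quarter.hills
                if np.linalg.norm(np.array(h.center) - target) < 0.15]
        assert near, "deepest well revisited during the last quartile"
        assert max(near) < 0.2 * 1.0

    def test_height_sensitivity_protocol(self, double_well_1d):
        params = sp.LangevinParams(seed=13)
        metad = sp.MetadParams(height=0.3, widths=(0.05,), pace=100,
                               bias_factor=10.0, max_hills=2000)
        res = fl.height_sensitivity(double_well_1d, heights=[0.3, 0.5],
                                    langevin=params, metad=metad,
                                    start=double_well_1d.truth.minima[1],
                                    reference_barrier=3.0, fill_fraction=0.55)
        for h, b in res.barriers.items():
            assert b == pytest.approx(3.0, abs=0.75), f"height {h}"
        assert res.basin_order_consistent

    def test_height_sensitivity_deterministic(self, double_well_1d):
        params = sp.LangevinParams(seed=13)
        metad = sp.MetadParams(height=0.3, widths=(0.05,), pace=100,
                               bias_factor=10.0, max_hills=400)
        kwargs = dict(heights=[0.3, 0.5], langevin=params, metad=metad,
                      start=double_well_1d.truth.minima[1],
                      reference_barrier=3.0)
        r1 = fl.height_sensitivity(double_well_1d, **kwargs)
        r2 = fl.height_sensitivity(double_well_1d, **kwargs)
        assert r1.barriers == r2.barriers
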