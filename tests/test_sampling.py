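"""Langevin propagation, well-tempered deposition, hills-log I/O."""

import math

import numpy as np
import pytest

from glypath import sampling as sp
from glypath import synthetic as syn


class Harmonic:
    """V = k/2 x^2 in 1-D."""

    cv_names = ("x",)

    def __init__(self, k=10.0):
        self.k = k

    def energy(self, x):
        return 0.5 * self.k * np.asarray(x) ** 2

    def gradient(self, x):
        return self.k * np.asarray(x)


class TestLangevin:
    def test_zero_temperature_stays_at_minimum(self):
        params = sp.LangevinParams(temperature=1e-12, friction=0.01, seed=0)
        traj = sp.run_langevin(Harmonic(), params, [0.0], 500)
        assert np.abs(traj).max() < 1e-6

    def test_equipartition_in_harmonic_well(self):
        # configurational variance kT/k within 10% over a long run
        k = 10.0
        params = sp.LangevinParams(temperature=300.0, friction=0.1, seed=4)
        traj = sp.run_langevin(Harmonic(k), params, [0.0], 100_000)
        assert traj[5000:].var() == pytest.approx(params.kt / k, rel=0.10)

    def test_seed_determinism(self):
        params = sp.LangevinParams(seed=11)
        a = sp.run_langevin(Harmonic(), params, [0.3], 1000)
        b = sp.run_langevin(Harmonic(), params, [0.3], 1000)
        assert np.array_equal(a, b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sp.LangevinParams(timestep=0.0)
        with pytest.raises(ValueError):
            sp.LangevinParams(temperature=-1.0)


class TestBiasEvaluation:
    def test_empty_log_is_zero(self):
        log = sp.HillsLog(cv_names=("qx", "qy"))
        assert sp.evaluate_bias(log, [0.1, 0.2]) == 0.0

    def test_single_hill_center_value(self):
        log = sp.HillsLog(cv_names=("x",))
        log.append(sp.Hill(time=1.0, center=(0.3,), widths=(0.1,), height=0.8,
                           bias_factor=10.0))
        assert sp.evaluate_bias(log, [0.3]) == pytest.approx(0.8, abs=1e-15)

    def test_matches_bruteforce_sum(self, rng):
        log = sp.HillsLog(cv_names=("a", "b"))
        for i in range(500):
            log.append(sp.Hill(time=float(i + 1),
                               center=tuple(rng.uniform(-1, 1, 2)),
                               widths=tuple(rng.uniform(0.05, 0.3, 2)),
                               height=float(rng.uniform(0.1, 1.0)),
                               bias_factor=10.0))
        pt = rng.uniform(-1, 1, 2)
        brute = sum(
            h.height * math.exp(-sum((pt[d] - h.center[d]) ** 2 / (2 * h.widths[d] ** 2)
                                     for d in range(2)))
            for h in log.hills
        )
        assert abs(sp.evaluate_bias(log, pt) - brute) < 1e-10

    def test_dimension_mismatch_rejected(self):
        log = sp.HillsLog(cv_names=("x",))
        log.append(sp.Hill(time=1.0, center=(0.0,), widths=(0.1,), height=1.0,
                           bias_factor=10.0))
        with pytest.raises(sp.HillsError):
            sp.evaluate_bias(log, [0.0, 0.0])


@pytest.fixture()
def frozen_langevin():
    """Effectively frozen dynamics: hills pile up at the start point."""
    return sp.LangevinParams(temperature=300.0, friction=1e9, timestep=1e-9,
                             mass=1e9, seed=1)


class Flat:
    cv_names = ("x",)

    def energy(self, x):
        return np.zeros(np.asarray(x).shape[:-1] or ())

    def gradient(self, x):
        return np.zeros_like(np.asarray(x))


class TestWellTempered:
    def test_colocated_hill_decay_closed_form(self, frozen_langevin):
        # second hill at a revisited point: w*exp(-w/(kB*(gamma-1)*T))
        metad = sp.MetadParams(height=1.0, widths=(0.1,), pace=5,
                               bias_factor=10.0, max_hills=2)
        log, _ = sp.run_wt_metadynamics(Flat(), frozen_langevin, metad, [0.0])
        assert log[0].height == pytest.approx(1.0, abs=1e-12)
        expected = math.exp(-1.0 / (0.0019872 * (10.0 - 1.0) * 300.0))
        assert log[1].height == pytest.approx(expected, abs=1e-6)
        assert log[1].height == pytest.approx(0.830, abs=5e-4)

    def test_infinite_bias_factor_keeps_full_height(self, frozen_langevin):
        metad = sp.MetadParams(height=0.7, widths=(0.1,), pace=5,
                               bias_factor=math.inf, max_hills=5)
        log, _ = sp.run_wt_metadynamics(Flat(), frozen_langevin, metad, [0.0])
        assert all(h.height == pytest.approx(0.7, abs=1e-12) for h in log.hills)

    def test_invalid_bias_factor_rejected(self):
        with pytest.raises(ValueError, match="bias factor"):
            sp.MetadParams(bias_factor=0.9)

    def test_heights_nonincreasing_at_fixed_point(self, frozen_langevin):
        metad = sp.MetadParams(height=1.0, widths=(0.1,), pace=5,
                               bias_factor=5.0, max_hills=30)
        log, _ = sp.run_wt_metadynamics(Flat(), frozen_langevin, metad, [0.0])
        heights = [h.height for h in log.hills]
        assert all(b < a for a, b in zip(heights, heights[1:]))

    def test_biased_run_crosses_unbiased_run_does_not(self):
        # 5 kcal/mol barrier at kT = 0.596: unaided dynamics stays in the
        # start basin over 10^5 steps, metadynamics escapes
        well = syn.make_double_well_1d(delta_f=0.5, barrier=5.0)
        start = well.truth.minima[1]  # deeper basin
        saddle_x = well.truth.saddle[0]
        params = sp.LangevinParams(seed=7)
        free = sp.run_langevin(well, params, start, 100_000)
        assert free.min() > saddle_x  # never crossed to the left basin
        metad = sp.MetadParams(height=1.0, widths=(0.1,), pace=100,
                               bias_factor=10.0, max_hills=500)
        log, traj = sp.run_wt_metadynamics(well, params, metad, start)
        assert traj.min() < saddle_x  # crossed at least once

    def test_metadynamics_determinism(self, double_well_1d):
        params = sp.LangevinParams(seed=3)
        metad = sp.MetadParams(height=0.5, widths=(0.1,), pace=50,
                               bias_factor=10.0, max_hills=20)
        log1, t1 = sp.run_wt_metadynamics(double_well_1d, params,
                                          metad, double_well_1d.truth.minima[0])
        log2, t2 = sp.run_wt_metadynamics(double_well_1d, params,
                                          metad, double_well_1d.truth.minima[0])
        assert np.array_equal(t1, t2)
        assert [h.height for h in log1.hills] == [h.height for h in log2.hills]


class TestHillsIO:
    def _sample_log(self, n=50, d=2, seed=0):
        rng = np.random.default_rng(seed)
        log = sp.HillsLog(cv_names=("qx", "qy")[:d])
        for i in range(n):
            log.append(sp.Hill(time=24.0 * (i + 1),
                               center=tuple(rng.uniform(-0.8, 0.8, d)),
                               widths=(0.1,) * d,
                               height=float(rng.uniform(0.2, 1.0)),
                               bias_factor=10.0))
        return log

    def test_roundtrip_is_field_exact(self, tmp_path):
        log = self._sample_log(n=200)
        path = sp.write_hills(log, tmp_path / "HILLS")
        back = sp.read_hills(path)
        assert back.cv_names == log.cv_names
        for a, b in zip(log.hills, back.hills):
            assert a.time == pytest.approx(b.time, abs=1e-4)
            assert np.allclose(a.center, b.center, atol=1e-8)
            assert a.height == pytest.approx(b.height, abs=1e-8)
            assert a.bias_factor == b.bias_factor

    def test_kj_per_mol_heights_converted(self, tmp_path):
        log = self._sample_log(n=5)
        path = sp.write_hills(log, tmp_path / "HILLS")
        text = path.read_text().replace("units_energy kcal/mol", "units_energy kJ/mol")
        kj = tmp_path / "HILLS_kj"
        kj.write_text(text)
        back = sp.read_hills(kj)
        for a, b in zip(log.hills, back.hills):
            assert b.height == pytest.approx(a.height / 4.184, rel=1e-7)

    def test_nonmonotonic_times_rejected_with_line_number(self, tmp_path):
        log = self._sample_log(n=3)
        lines = sp.write_hills(log, tmp_path / "HILLS").read_text().splitlines()
        lines[4], lines[5] = lines[5], lines[4]  # swap two hill rows
        bad = tmp_path / "BAD"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(sp.HillsError, match=":6"):
            sp.read_hills(bad)

    def test_malformed_line_reported(self, tmp_path):
        path = sp.write_hills(self._sample_log(n=2), tmp_path / "HILLS")
        bad = tmp_path / "BAD"
        bad.write_text(path.read_text() + "1.0 nonsense\n")
        with pytest.raises(sp.HillsError, match="BAD:6"):
            sp.read_hills(bad)

    def test_undeclared_units_rejected(self, tmp_path):
        path = sp.write_hills(self._sample_log(n=2), tmp_path / "HILLS")
        text = "\n".join(l for l in path.read_text().splitlines()
                         if "units_energy" not in l)
        bad = tmp_path / "BAD"
        bad.write_text(text + "\n")
        with pytest.raises(sp.HillsError, match="units"):
            sp.read_hills(bad)
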