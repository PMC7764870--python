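import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import filmrheo as fr
from filmrheo.errors import OverlapError, ValidationError
from filmrheo.isotherm_analysis import IsothermBranch, IsothermCycle
from filmrheo.transients_io import TroughRecording

from conftest import squeeze_out_oracle


def triangular_recording(n_cycles=10, n_per_branch=40, jitter=None):
    down = np.linspace(100.0, 50.0, n_per_branch)
    up = np.linspace(50.0, 100.0, n_per_branch)[1:]
    segs = [down]
    for k in range(n_cycles):
        if k > 0:
            segs.append(down[1:])
        segs.append(up)
    area = np.concatenate(segs[:2 * n_cycles])
    if jitter is not None:
        area = area + jitter(area.size)
    pi = 40.0 - 0.3 * area
    return TroughRecording(time=np.arange(area.size, dtype=float),
                           area=area, pi=pi)


class TestSplitCycles:
    def test_ten_periods_ten_cycles(self):
        cycles = fr.split_cycles(triangular_recording(10))
        assert len(cycles) == 10
        assert [c.index for c in cycles] == list(range(1, 11))
        assert cycles[0].compression.direction == "compression"

    def test_monotone_compression_no_complete_cycle(self):
        area = np.linspace(100.0, 50.0, 60)
        rec = TroughRecording(time=np.arange(60.0), area=area, pi=40 - 0.3 * area)
        with pytest.warns(UserWarning, match="no complete"):
            cycles = fr.split_cycles(rec)
        assert len(cycles) == 0
        assert len(cycles.partial_branches) == 1

    def test_jitter_near_turning_point_filtered(self):
        """Sub-excursion noise around an area extremum must not split the
        cycle into spurious branches."""
        rng = np.random.default_rng(5)
        rec = triangular_recording(3, jitter=lambda n: rng.normal(0, 0.3, n))
        cycles = fr.split_cycles(rec)
        assert len(cycles) == 3

    def test_reconcatenation_preserves_every_sample_once(self, isotherm_pair):
        ref, _ = isotherm_pair
        cycles = fr.split_cycles(ref)
        pieces = []
        for c in cycles:
            pieces += [c.compression, c.expansion]
        pieces += cycles.partial_branches
        total = sum(b.area.size for b in pieces)
        assert total == ref.area.size
        np.testing.assert_array_equal(
            np.concatenate([b.pi for b in pieces]), ref.pi)


class TestStationarity:
    def test_geometric_drift_schedule(self, isotherm_pair):
        """Drift halves each cycle from 4 mN/m; consecutive compression
        branches then differ by 2, 1, 0.5 ... so with tol = 1 the curve is
        stationary from cycle 3 (the first pair strictly below tolerance)."""
        ref, _ = isotherm_pair
        cycles = fr.split_cycles(ref)
        assert fr.stationarity_index(cycles, tol=1.0) == 3

    def test_identical_cycles_index_one(self):
        cycles = fr.split_cycles(triangular_recording(5))
        assert fr.stationarity_index(cycles, tol=0.5) == 1

    def test_never_stationary(self):
        rec = triangular_recording(6)
        # constant large per-cycle offset: consecutive branches always differ
        period = 2 * 39
        cycle_no = (np.arange(rec.pi.size) // period)
        rec = TroughRecording(time=rec.time, area=rec.area,
                              pi=rec.pi + 5.0 * cycle_no)
        cycles = fr.split_cycles(rec)
        assert fr.stationarity_index(cycles, tol=1.0) is None

    def test_needs_two_cycles(self):
        cycles = fr.split_cycles(triangular_recording(1))
        with pytest.raises(ValidationError):
            fr.stationarity_index(cycles)


class TestAverageIsotherms:
    def _branch(self, offset=0.0, n=50):
        area = np.linspace(100.0, 50.0, n)
        return IsothermBranch(area=area, pi=40 - 0.3 * area + offset,
                              direction="compression")

    def test_identical_branches(self):
        avg = fr.average_isotherms([self._branch()] * 3)
        np.testing.assert_allclose(avg.pi_sd, 0.0, atol=1e-12)
        np.testing.assert_allclose(avg.pi_mean, 40 - 0.3 * avg.area_grid,
                                   rtol=1e-12)
        assert avg.max_pairwise_relative_deviation == 0.0

    def test_symmetric_offsets_cancel(self):
        avg = fr.average_isotherms([self._branch(+1.0), self._branch(-1.0)])
        np.testing.assert_allclose(avg.pi_mean, 40 - 0.3 * avg.area_grid,
                                   rtol=1e-12)

    def test_mixed_grids_match_bruteforce_interpolation(self):
        b1 = self._branch(n=37)
        b2 = self._branch(offset=0.5, n=61)
        avg = fr.average_isotherms([b1, b2])
        a1, p1 = b1.as_increasing_area()
        a2, p2 = b2.as_increasing_area()
        brute = 0.5 * (np.interp(avg.area_grid, a1, p1)
                       + np.interp(avg.area_grid, a2, p2))
        np.testing.assert_allclose(avg.pi_mean, brute, rtol=0, atol=1e-12)

    def test_disjoint_ranges_rejected(self):
        b1 = self._branch()
        area = np.linspace(40.0, 20.0, 30)
        b2 = IsothermBranch(area=area, pi=40 - 0.3 * area,
                            direction="compression")
        with pytest.raises(OverlapError):
            fr.average_isotherms([b1, b2])


class TestPressureShift:
    def _branch(self, f, n=80, lo=50.0, hi=100.0):
        area = np.linspace(hi, lo, n)
        return IsothermBranch(area=area, pi=f(area), direction="compression")

    def test_constant_offset(self):
        ref = self._branch(lambda a: 40 - 0.3 * a)
        test = self._branch(lambda a: 43 - 0.3 * a)
        cmp_ = fr.pressure_shift(ref, test)
        np.testing.assert_allclose(cmp_.shift, 3.0, rtol=1e-12)
        assert cmp_.mean_shift == pytest.approx(3.0)

    def test_identical_branches_zero_shift(self):
        ref = self._branch(lambda a: 40 - 0.3 * a)
        cmp_ = fr.pressure_shift(ref, ref)
        np.testing.assert_allclose(cmp_.shift, 0.0, atol=1e-12)

    def test_generator_shift_recovered(self, isotherm_pair):
        from filmrheo.synthetic_data import base_isotherm_template, logistic_shift
        ref, test = isotherm_pair
        rc, tc = fr.split_cycles(ref), fr.split_cycles(test)
        cmp_ = fr.pressure_shift(rc[-1].compression, tc[-1].compression)
        truth = ref.meta["truth"]
        tmpl = base_isotherm_template(truth["waypoints"])
        expected = logistic_shift(tmpl(cmp_.area_grid), truth["shift_amplitude"],
                                  truth["vanish_pressure"], truth["vanish_width"])
        np.testing.assert_allclose(cmp_.shift, expected, atol=0.02)

    def test_antisymmetry(self, isotherm_pair):
        ref, test = isotherm_pair
        rc, tc = fr.split_cycles(ref), fr.split_cycles(test)
        ab = fr.pressure_shift(rc[-1].compression, tc[-1].compression)
        ba = fr.pressure_shift(tc[-1].compression, rc[-1].compression)
        np.testing.assert_allclose(ab.shift, -ba.shift, atol=1e-12)

    def test_unit_mismatch_rejected(self):
        ref = self._branch(lambda a: 40 - 0.3 * a)
        test = self._branch(lambda a: 42 - 0.3 * a)
        test.area_unit = "A^2/molecule"
        with pytest.raises(ValidationError, match="unit"):
            fr.pressure_shift(ref, test)


class TestSqueezeOut:
    def test_generator_truth_recovered(self, isotherm_pair):
        ref, test = isotherm_pair
        rc, tc = fr.split_cycles(ref), fr.split_cycles(test)
        cmp_ = fr.pressure_shift(rc[-1].compression, tc[-1].compression)
        detected = fr.squeeze_out_pressure(cmp_, threshold=0.5)
        expected = squeeze_out_oracle(ref.meta["truth"], 0.5)
        assert detected == pytest.approx(expected, abs=0.5)

    def test_persistent_shift_absent(self):
        """A CKC-like constant incorporation shift never vanishes."""
        ref, test = fr.gen_isotherm_pair(vanish_pressure=None,
                                         shift_amplitude=3.0)
        rc, tc = fr.split_cycles(ref), fr.split_cycles(test)
        cmp_ = fr.pressure_shift(rc[-1].compression, tc[-1].compression)
        assert fr.squeeze_out_pressure(cmp_, threshold=0.5) is None

    def test_zero_shift_returns_lowest_pressure(self):
        area = np.linspace(100.0, 50.0, 60)
        b = IsothermBranch(area=area, pi=40 - 0.3 * area,
                           direction="compression")
        cmp_ = fr.pressure_shift(b, b)
        out = fr.squeeze_out_pressure(cmp_, threshold=0.5)
        assert out == pytest.approx(float((40 - 0.3 * area).min()))

    @given(st.floats(0.1, 3.5), st.floats(0.1, 3.5))
    def test_monotone_in_threshold(self, thr_a, thr_b):
        """A larger threshold never yields a larger squeeze-out pressure.

        Holds when the incorporation shift decays more gently than the film
        pressure rises (|d shift / d pi| < 1 along the compression, here
        amplitude/(4 width) = 0.5): the detected pressure is then monotone
        in the threshold.  Steeper squeeze-out transitions make the test
        branch locally non-monotone in pressure, and the detected value can
        move by up to the threshold difference."""
        ref, test = fr.gen_isotherm_pair(n_cycles=1, n_per_branch=200,
                                         shift_amplitude=4.0, vanish_width=2.0,
                                         drift_amplitude=0.0)
        rc, tc = fr.split_cycles(ref), fr.split_cycles(test)
        cmp_ = fr.pressure_shift(rc[0].compression, tc[0].compression)
        lo_thr, hi_thr = sorted([thr_a, thr_b])
        p_lo = fr.squeeze_out_pressure(cmp_, threshold=lo_thr)
        p_hi = fr.squeeze_out_pressure(cmp_, threshold=hi_thr)
        if p_lo is not None:
            assert p_hi is not None and p_hi <= p_lo + 1e-9


class TestHysteresis:
    def test_identical_branches_zero(self):
        area = np.linspace(100.0, 50.0, 40)
        comp = IsothermBranch(area, 40 - 0.3 * area, "compression")
        exp = IsothermBranch(area[::-1], (40 - 0.3 * area)[::-1], "expansion")
        cyc = IsothermCycle(1, comp, exp)
        assert fr.hysteresis_area(cyc) == pytest.approx(0.0, abs=1e-12)

    def test_rectangle_loop(self):
        comp = IsothermBranch([60.0, 50.0], [12.0, 12.0], "compression")
        exp = IsothermBranch([50.0, 60.0], [10.0, 10.0], "expansion")
        assert fr.hysteresis_area(IsothermCycle(1, comp, exp)) == pytest.approx(20.0)

    def test_matches_shoelace_bruteforce(self):
        """Trapezoidal loop area equals the shoelace polygon area for a
        closed loop built from the recorded samples."""
        area = np.linspace(100.0, 50.0, 123)
        pi_c = 45.0 - 0.35 * area + 0.001 * (area - 70) ** 2
        frac = (area - 50.0) / 50.0
        pi_e = pi_c - 2.0 * 4 * frac * (1 - frac)  # closes at the turns
        comp = IsothermBranch(area, pi_c, "compression")
        exp = IsothermBranch(area[::-1], pi_e[::-1], "expansion")
        got = fr.hysteresis_area(IsothermCycle(1, comp, exp))
        poly_a = np.concatenate([comp.area, exp.area])
        poly_p = np.concatenate([comp.pi, exp.pi])
        shoelace = 0.5 * abs(np.sum(poly_a * np.roll(poly_p, -1)
                                    - np.roll(poly_a, -1) * poly_p))
        assert got == pytest.approx(shoelace, abs=1e-9)
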