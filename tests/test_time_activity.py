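import math

import numpy as np
import pytest

from ricdosim import (
    BiodistMeasurement,
    activity_at,
    integrate_to_T,
    load_organ_masses,
    tail_integral,
    time_integrated_activity,
)
from ricdosim.errors import MissingDataError, ValidationError
from ricdosim.timeactivity import TimeActivityCurve


def _curve(points, nuclide, rule="plateau"):
    return TimeActivityCurve("blood", nuclide, tuple(points), 1e6, rule)


class TestActivityAt:
    def test_simple_fractions(self, lu177):
        assert activity_at(10.0, 1e6, 1.0, lu177, 0.0) == pytest.approx(1e5)

    def test_one_half_life(self, lu177):
        a = activity_at(10.0, 1e6, 1.0, lu177, lu177.half_life_s)
        assert a == pytest.approx(5e4, rel=1e-12)

    def test_cu64_example(self, cu64):
        a = activity_at(14.9, 1e6, 0.5, cu64, 86_400.0)
        assert a == pytest.approx(2.01e4, rel=1e-2)

    def test_missing_mass_is_explicit(self, cu64):
        with pytest.raises(MissingDataError):
            activity_at(10.0, 1e6, None, cu64, 0.0)

    def test_decay_can_be_disabled(self, cu64):
        a = activity_at(10.0, 1e6, 1.0, cu64, 86_400.0, apply_decay=False)
        assert a == pytest.approx(1e5)


class TestIntegrateToT:
    def test_constant_curve(self, lu177):
        c = _curve([(0.0, 100.0), (1000.0, 100.0)], lu177)
        assert integrate_to_T(c, 1000.0) == pytest.approx(1e5)

    def test_triangle(self, lu177):
        c = _curve([(0.0, 0.0), (100.0, 100.0)], lu177)
        assert integrate_to_T(c, 100.0) == pytest.approx(5000.0)

    def test_piecewise_with_plateau_boundary(self, cu64):
        c = _curve([(21_600.0, 1000.0), (86_400.0, 500.0), (172_800.0, 250.0)], cu64)
        assert integrate_to_T(c, 172_800.0) == pytest.approx(1.026e8, rel=1e-12)

    def test_zero_boundary(self, cu64):
        c = _curve([(100.0, 100.0)], cu64, rule="zero")
        assert integrate_to_T(c, 100.0) == pytest.approx(5000.0)

    def test_linear_boundary_back_extrapolates(self, cu64):
        # slope -1 per s through (100, 100) -> A(0) = 200
        c = _curve([(100.0, 100.0), (200.0, 0.0)], cu64, rule="linear")
        assert integrate_to_T(c, 100.0) == pytest.approx((200 + 100) / 2 * 100)

    def test_linear_boundary_floored_at_zero(self, cu64):
        # rising curve extrapolates negative at t=0 -> floored
        c = _curve([(100.0, 10.0), (200.0, 1000.0)], cu64, rule="linear")
        assert integrate_to_T(c, 100.0) == pytest.approx((0 + 10) / 2 * 100)

    def test_T_before_first_point_rejected(self, cu64):
        c = _curve([(100.0, 10.0)], cu64)
        with pytest.raises(ValidationError):
            integrate_to_T(c, 50.0)

    def test_T_between_points_interpolates(self, cu64):
        c = _curve([(0.0, 100.0), (100.0, 0.0)], cu64)
        assert integrate_to_T(c, 50.0) == pytest.approx((100 + 50) / 2 * 50)


class TestTailIntegral:
    def test_division(self, cu64):
        assert tail_integral(500.0, cu64) == pytest.approx(3.298e7, rel=1e-3)

    def test_zero_activity(self, cu64):
        assert tail_integral(0.0, cu64) == 0.0

    def test_simple_rate(self, lu177):
        assert tail_integral(1000.0, lu177) == pytest.approx(1000.0 / lu177.decay_constant)


def _measurements(pct_by_time, organ="liver", injected=6.5):
    return [
        BiodistMeasurement("m1", "g", organ, t, p, injected_activity_MBq=injected)
        for t, p in pct_by_time.items()
    ]


class TestTimeIntegratedActivity:
    def test_single_point_plateau_is_rectangle_plus_tail(self, lu177):
        ms = _measurements({48.0: 10.0})
        tia = time_integrated_activity(ms, "liver", lu177, 1e6, 1.0, 48 * 3600.0)
        A = activity_at(10.0, 1e6, 1.0, lu177, 48 * 3600.0)
        assert tia.auc_0_T_Bq_s == pytest.approx(A * 48 * 3600.0)
        assert tia.tail_Bq_s == pytest.approx(A / lu177.decay_constant)
        assert tia.total_Bq_s == tia.auc_0_T_Bq_s + tia.tail_Bq_s

    def test_pure_decay_recovers_closed_form(self, lu177):
        # constant %ID/g -> activity curve is A0·exp(−λt); Ã should be A0/λ
        ms = _measurements({6.0: 10.0, 24.0: 10.0, 48.0: 10.0})
        tia = time_integrated_activity(ms, "liver", lu177, 1e6, 1.0, 48 * 3600.0)
        a0 = activity_at(10.0, 1e6, 1.0, lu177, 0.0)
        assert tia.total_Bq_s == pytest.approx(a0 / lu177.decay_constant, rel=0.02)

    def test_convergence_with_sampling_density(self, cu64):
        a0 = activity_at(10.0, 1e6, 1.0, cu64, 0.0)
        closed = a0 / cu64.decay_constant
        errors = []
        for n in (4, 16, 64):
            times_h = np.linspace(0, 48, n)
            ms = _measurements({t: 10.0 for t in times_h})
            tia = time_integrated_activity(ms, "liver", cu64, 1e6, 1.0, 48 * 3600.0)
            errors.append(abs(tia.total_Bq_s - closed) / closed)
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-3

    def test_trapezoid_convexity_bound_with_t0_sample(self, cu64):
        # sampled from t=0 the trapezoid overestimates a convex decay curve
        ms = _measurements({0.0: 10.0, 6.0: 10.0, 24.0: 10.0, 48.0: 10.0})
        tia = time_integrated_activity(ms, "liver", cu64, 1e6, 1.0, 48 * 3600.0)
        a0 = activity_at(10.0, 1e6, 1.0, cu64, 0.0)
        lam = cu64.decay_constant
        exact = a0 * (1 - math.exp(-lam * 48 * 3600.0)) / lam + tia.tail_Bq_s
        assert tia.total_Bq_s >= exact

    def test_linearity_in_injected_activity(self, lu177):
        ms = _measurements({6.0: 8.0, 24.0: 6.0, 48.0: 4.0})
        t1 = time_integrated_activity(ms, "liver", lu177, 1e6, 1.0, 48 * 3600.0)
        t2 = time_integrated_activity(ms, "liver", lu177, 2e6, 1.0, 48 * 3600.0)
        assert t2.total_Bq_s == pytest.approx(2 * t1.total_Bq_s, rel=1e-12)

    def test_last_point_before_T_attaches_tail_there(self, lu177):
        ms = _measurements({6.0: 8.0, 24.0: 6.0})
        with pytest.warns(UserWarning, match="tail attached"):
            tia = time_integrated_activity(ms, "liver", lu177, 1e6, 1.0, 48 * 3600.0)
        assert tia.T_s == 24 * 3600.0

    def test_components_non_negative(self, lu177, noiseless_biodist):
        tia = time_integrated_activity(
            noiseless_biodist, "blood", lu177, 1e6, 2.3, 48 * 3600.0
        )
        assert tia.auc_0_T_Bq_s >= 0 and tia.tail_Bq_s >= 0
        assert tia.total_Bq_s >= max(tia.auc_0_T_Bq_s, tia.tail_Bq_s)


class TestOrganMassRegistry:
    def test_bundled_registry(self, organ_masses):
        assert organ_masses["liver"] > 0
        assert set(organ_masses) >= {"blood", "tumour", "whole_body"}

    def test_user_table(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("organ,mass_g\nliver,2.0\n")
        assert load_organ_masses(p) == {"liver": 2.0}

    def test_nonpositive_mass_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("organ,mass_g\nliver,0\n")
        with pytest.raises(ValidationError):
            load_organ_masses(p)
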