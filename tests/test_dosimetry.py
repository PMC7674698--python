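import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedidose.biokinetics import Scenario
from pedidose.constants import DECAYS_PER_MCI_MIN, MGY_PER_MEV_PER_G
from pedidose.dosimetry import (DoseRateSeries, IntegrationSpec,
                                compartment_dose_maps, decay_weight,
                                integrate_organ_dose, integrate_with_maps,
                                run_scenario, simulate_series)
from pedidose.biokinetics import build_time_activity, extend_to_horizon
from pedidose.nuclide import tc99m
from pedidose.transport import DoseRateMap

LAMBDA = tc99m().decay_constant_per_min


def synthetic_series(values_by_frame, rel=0.0, dt=1.0):
    frames = tuple(DoseRateMap({o: v for o, v in frame.items()},
                               {o: rel for o in frame}, 1000)
                   for frame in values_by_frame)
    return DoseRateSeries(frames, dt)


class TestDecayWeight:
    def test_no_decay_limit(self):
        assert decay_weight(0, 0.0, 1.0) == 1.0
        assert decay_weight(7, 0.0, 2.5) == 2.5

    def test_first_frame_closed_form(self):
        assert decay_weight(0, 1.9221e-3, 1.0) == pytest.approx(0.99904, abs=1e-5)

    def test_weights_sum_to_inverse_lambda(self):
        total = sum(decay_weight(m, LAMBDA, 1.0) for m in range(40000))
        assert total == pytest.approx(1.0 / LAMBDA, rel=1e-6)
        # the printed 520.26 min figure (from the rounded decay constant)
        assert 1.0 / LAMBDA == pytest.approx(520.26, rel=1e-4)

    def test_partial_frame_truncation(self):
        full = decay_weight(3, LAMBDA, 1.0)
        half = decay_weight(3, LAMBDA, 1.0, t_stop=3.5)
        rest = (math.exp(-LAMBDA * 3.5) - math.exp(-LAMBDA * 4.0)) / LAMBDA
        assert half + rest == pytest.approx(full)
        assert decay_weight(5, LAMBDA, 1.0, t_stop=4.0) == 0.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            decay_weight(0, -1.0)


class TestIntegrator:
    def test_constant_series_no_decay_closed_form(self):
        a, T, b0 = 3.2e-6, 17.0, 2.5
        series = synthetic_series([{"organ": a}] * 20)
        out = integrate_organ_dose(series, IntegrationSpec(T, b0, 0.0))
        assert out.dose_mgy["organ"] == pytest.approx(
            a * DECAYS_PER_MCI_MIN * MGY_PER_MEV_PER_G * b0 * T)

    def test_matches_fine_grid_quadrature(self):
        rng = np.random.default_rng(4)
        values = [{"o1": float(v), "o2": float(w)}
                  for v, w in rng.uniform(0, 1e-5, size=(25, 2))]
        series = synthetic_series(values)
        T = 21.37
        out = integrate_organ_dose(series, IntegrationSpec(T, 1.0, LAMBDA))
        # oracle: trapezoid at 0.001-min steps, frame by frame
        for organ in ("o1", "o2"):
            total = 0.0
            t = 0.0
            m = 0
            while t < T - 1e-12:
                t1 = min(t + 1.0, T)
                grid = np.linspace(t, t1, max(int((t1 - t) / 0.001), 2) + 1)
                total += values[m][organ] * np.trapezoid(np.exp(-LAMBDA * grid), grid)
                t, m = t1, m + 1
            total *= DECAYS_PER_MCI_MIN * MGY_PER_MEV_PER_G
            assert out.dose_mgy[organ] == pytest.approx(total, rel=1e-6)

    def test_linear_in_administered_activity(self):
        series = synthetic_series([{"o": 1e-5}] * 10)
        d1 = integrate_organ_dose(series, IntegrationSpec(10, 1.0, LAMBDA))
        d2 = integrate_organ_dose(series, IntegrationSpec(10, 2.0, LAMBDA))
        assert d2.dose_mgy["o"] == pytest.approx(2 * d1.dose_mgy["o"])

    @given(st.floats(min_value=0.5, max_value=9.5),
           st.floats(min_value=0.5, max_value=9.5))
    @settings(max_examples=30, deadline=None)
    def test_dose_monotone_in_horizon(self, t1, t2):
        series = synthetic_series([{"o": 2e-6}] * 10)
        lo, hi = sorted((t1, t2))
        d_lo = integrate_organ_dose(series, IntegrationSpec(lo, 1.0, LAMBDA))
        d_hi = integrate_organ_dose(series, IntegrationSpec(hi, 1.0, LAMBDA))
        assert d_hi.dose_mgy["o"] >= d_lo.dose_mgy["o"] - 1e-15

    @given(st.floats(min_value=0.0, max_value=0.1),
           st.floats(min_value=0.0, max_value=0.1))
    @settings(max_examples=30, deadline=None)
    def test_dose_non_increasing_in_decay_constant(self, l1, l2):
        series = synthetic_series([{"o": 2e-6}] * 10)
        lo, hi = sorted((l1, l2))
        d_lo = integrate_organ_dose(series, IntegrationSpec(8.0, 1.0, lo))
        d_hi = integrate_organ_dose(series, IntegrationSpec(8.0, 1.0, hi))
        assert d_hi.dose_mgy["o"] <= d_lo.dose_mgy["o"] + 1e-15

    def test_series_shorter_than_horizon_errors(self):
        series = synthetic_series([{"o": 1e-6}] * 5)
        with pytest.raises(ValueError, match="extend"):
            integrate_organ_dose(series, IntegrationSpec(10.0, 1.0, LAMBDA))

    def test_inconsistent_organ_sets_rejected(self):
        frames = (DoseRateMap({"a": 1e-6}, {"a": 0.0}, 1000),
                  DoseRateMap({"b": 1e-6}, {"b": 0.0}, 1000))
        with pytest.raises(ValueError, match="organ"):
            DoseRateSeries(frames, 1.0)


class TestScenarioPipeline:
    def test_deduplication_changes_nothing(self, male_phantom, male_engine):
        sc = Scenario(1.0, 1.0, sex="male")
        a = simulate_series(male_phantom, sc, 30, 1000, seed=5,
                            engine=male_engine, deduplicate=True)
        b = simulate_series(male_phantom, sc, 30, 1000, seed=5,
                            engine=male_engine, deduplicate=False)
        for fa, fb in zip(a.frames, b.frames):
            assert fa.values == fb.values

    def test_svalue_route_agrees_with_frame_route(self, male_phantom, male_engine,
                                                  male_maps):
        sc = Scenario(1.0, 1.0, sex="male")
        frames = run_scenario(male_phantom, sc, histories_per_frame=20_000,
                              seed=2, engine=male_engine, method="frames")
        ta = extend_to_horizon(build_time_activity(sc), 100)
        sval = integrate_with_maps(ta, male_maps, IntegrationSpec(100, 1.0, LAMBDA))
        for organ in ("kidney_L", "kidney_R", "liver", "bladder_wall"):
            tol = 4 * math.hypot(frames.rel_err[organ], sval.rel_err[organ])
            assert frames.dose_mgy[organ] == pytest.approx(
                sval.dose_mgy[organ], rel=max(tol, 0.02))

    def test_horizon_selection_modes(self, male_phantom, male_engine):
        normal = run_scenario(male_phantom, Scenario(1.0, 1.0, sex="male"),
                              histories_per_frame=1000, seed=1,
                              engine=male_engine, method="svalue")
        degraded = run_scenario(male_phantom, Scenario(0.5, 1.0, sex="male"),
                                histories_per_frame=1000, seed=1,
                                engine=male_engine, method="svalue")
        window = run_scenario(male_phantom, Scenario(1.0, 1.0, sex="male"),
                              histories_per_frame=1000, seed=1,
                              engine=male_engine, method="svalue",
                              mode="test_window")
        assert (normal.T, degraded.T, window.T) == (100.0, 1000.0, 60.0)

    def test_same_seed_reproduces_report(self, male_phantom, male_engine):
        sc = Scenario(0.5, 1.0, sex="male")
        a = run_scenario(male_phantom, sc, 2000, seed=9, engine=male_engine)
        b = run_scenario(male_phantom, sc, 2000, seed=9, engine=male_engine)
        assert a.dose_mgy == b.dose_mgy

    def test_all_doses_non_negative(self, male_phantom, male_engine):
        res = run_scenario(male_phantom, Scenario(1.0, 1.0, sex="male"),
                           2000, seed=3, engine=male_engine, method="svalue")
        assert all(v >= 0 for v in res.dose_mgy.values())
        assert res.dose_mgy["bladder_wall"] > 0
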