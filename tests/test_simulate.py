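import numpy as np
import pandas as pd
import pytest

from rhizosense.device import DeviceGeometry
from rhizosense.simulate import (
    IrrigationEvent,
    IrrigationSchedule,
    RootContactModel,
    SoilParams,
    TreatmentSpec,
    TrialConfig,
    inject_root_events,
    iter_device_sims,
    moisture_to_rc,
    sample_root_events,
    simulate_moisture,
    simulate_trial,
    wetting_slope,
)


class TestMoistureToRC:
    def test_endpoints(self):
        soil = SoilParams()
        res, cap = moisture_to_rc(1.0, soil)
        assert res == pytest.approx(soil.res_at_wet)
        assert cap == pytest.approx(soil.cap_at_wet)
        res, cap = moisture_to_rc(0.0, soil)
        assert res == pytest.approx(soil.res_at_dry)
        assert cap == pytest.approx(soil.cap_at_dry)

    def test_drying_sweep_raises_res_lowers_cap(self):
        soil = SoilParams()
        m = np.linspace(1.0, 0.0, 101)
        res, cap = moisture_to_rc(m, soil)
        assert np.all(np.diff(res) > 0)
        assert np.all(np.diff(cap) < 0)

    def test_out_of_range_clipped_with_warning(self):
        soil = SoilParams()
        with pytest.warns(UserWarning, match="clipped"):
            res, _ = moisture_to_rc(1.5, soil)
        assert res == pytest.approx(soil.res_at_wet)

    def test_inconsistent_endpoints_rejected(self):
        with pytest.raises(ValueError):
            SoilParams(res_at_wet=5e4, res_at_dry=5e3)


class TestSimulateMoisture:
    def test_pure_relaxation_decays_monotonically(self):
        soil = SoilParams(diurnal_amplitude=0.0)
        m = simulate_moisture(IrrigationSchedule(), soil, n_days=10)
        assert m[0] == pytest.approx(soil.moisture_wet)
        assert np.all(np.diff(m) <= 0)
        assert m[-1] > soil.moisture_dry  # approaches but does not cross

    def test_single_event_creates_local_maximum_at_event_end(self):
        soil = SoilParams(diurnal_amplitude=0.0)
        ev = IrrigationEvent(start_minutes=5 * 1440, duration_hours=6.0)
        m = simulate_moisture(IrrigationSchedule((ev,)), soil, n_days=10)
        t = np.arange(m.size) * 5.0
        end_idx = np.searchsorted(t, ev.start_minutes + 360.0) - 1
        # local maximum: rising into the event end, decaying afterwards
        assert m[end_idx] > m[end_idx - 400]
        assert m[end_idx] > m[end_idx + 400]
        peak = np.argmax(m[end_idx - 400 : end_idx + 400]) + end_idx - 400
        assert abs(peak - end_idx) <= 3

    def test_shared_schedule_prefix_gives_identical_moisture(self):
        soil = SoilParams()
        ev1 = IrrigationEvent(start_minutes=2 * 1440, duration_hours=3.0)
        ev2 = IrrigationEvent(start_minutes=6 * 1440, duration_hours=3.0)
        m_a = simulate_moisture(IrrigationSchedule((ev1, ev2)), soil, n_days=10)
        m_b = simulate_moisture(IrrigationSchedule((ev1,)), soil, n_days=10)
        t = np.arange(m_a.size) * 5.0
        before = t < ev2.start_minutes
        np.testing.assert_array_equal(m_a[before], m_b[before])
        assert not np.array_equal(m_a[~before], m_b[~before])

    def test_events_below_depth_reach_are_ignored(self):
        soil = SoilParams(diurnal_amplitude=0.0)
        ev = IrrigationEvent(start_minutes=1440, duration_hours=3.0,
                             depth_reach_cm=5.0)
        deep = simulate_moisture(IrrigationSchedule((ev,)), soil, n_days=4,
                                 depth_cm=12.0)
        dry = simulate_moisture(IrrigationSchedule(), soil, n_days=4,
                                depth_cm=12.0)
        np.testing.assert_array_equal(deep, dry)


class TestInjectRootEvents:
    @pytest.fixture
    def base_arrays(self, geometry):
        n_el = geometry.n_paddles * geometry.electrodes_per_paddle
        n_t = 2 * geometry.samples_per_day
        return np.zeros((n_el, n_t)), np.zeros((n_el, n_t))

    def test_zero_events_is_identity(self, base_arrays, geometry):
        lr, lc = base_arrays
        events = pd.DataFrame(columns=["time_minutes", "paddle_index", "depth_index"])
        out_r, out_c = inject_root_events(lr, lc, events, RootContactModel(), geometry)
        np.testing.assert_array_equal(out_r, lr)
        np.testing.assert_array_equal(out_c, lc)

    def test_single_event_touches_exactly_one_electrode(self, base_arrays, geometry):
        lr, lc = base_arrays
        events = pd.DataFrame(
            [{"time_minutes": 600.0, "paddle_index": 3, "depth_index": 7}]
        )
        model = RootContactModel()
        out_r, out_c = inject_root_events(lr, lc, events, model, geometry)
        el = 3 * geometry.electrodes_per_paddle + 7
        changed = np.flatnonzero(np.any(out_r != lr, axis=1) | np.any(out_c != lc, axis=1))
        np.testing.assert_array_equal(changed, [el])
        assert out_r[el, -1] == pytest.approx(model.delta_logres)
        assert out_c[el, -1] == pytest.approx(model.delta_logcap)

    def test_deflection_direction_differs_from_wetting_trajectory(self):
        soil = SoilParams()
        model = RootContactModel()
        slope = wetting_slope(soil)
        contact_ratio = abs(model.delta_logres / model.delta_logcap)
        assert contact_ratio < slope
        # angle between the contact vector and the wetting line
        wet = np.array([np.log(soil.res_at_wet / soil.res_at_dry),
                        np.log(soil.cap_at_wet / soil.cap_at_dry)])
        contact = np.array([model.delta_logres, model.delta_logcap])
        cos = abs(wet @ contact) / (np.linalg.norm(wet) * np.linalg.norm(contact))
        assert np.degrees(np.arccos(cos)) > 20.0

    def test_event_outside_span_is_rejected_with_warning(self, base_arrays, geometry):
        lr, lc = base_arrays
        events = pd.DataFrame(
            [{"time_minutes": 1e9, "paddle_index": 0, "depth_index": 0}]
        )
        with pytest.warns(UserWarning, match="outside trial span"):
            out_r, _ = inject_root_events(lr, lc, events, RootContactModel(), geometry)
        np.testing.assert_array_equal(out_r, lr)


class TestSampleRootEvents:
    def test_zero_rate_yields_no_events(self, geometry):
        spec = TreatmentSpec(root_arrival_rate=0.0)
        rng = np.random.default_rng(0)
        assert sample_root_events(spec, geometry, 10, rng).empty

    def test_poisson_count_matches_programmed_rate(self, geometry):
        # 2 roots/day * 10 days * 50 draws: total within 3 sd of 1000
        spec = TreatmentSpec(root_arrival_rate=2.0)
        rng = np.random.default_rng(123)
        total = sum(
            len(sample_root_events(spec, geometry, 10, rng)) for _ in range(50)
        )
        assert abs(total - 1000) < 3 * np.sqrt(1000) + 50  # + thinning slack

    def test_rate_multiplier_window_reduces_arrivals(self, geometry):
        spec = TreatmentSpec(
            root_arrival_rate=2.0, rate_multipliers=((5, 10, 0.0),)
        )
        rng = np.random.default_rng(5)
        ev = sample_root_events(spec, geometry, 10, rng)
        assert (ev["day"] < 5).all()


class TestSimulateTrial:
    def test_same_seed_same_output(self, tiny_config):
        s1, t1, m1 = simulate_trial(tiny_config)
        s2, t2, m2 = simulate_trial(tiny_config)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_zero_rate_gives_empty_truth_log(self, tiny_geometry):
        cfg = TrialConfig(
            n_days=2, seed=3, geometry=tiny_geometry,
            treatments={"ww": TreatmentSpec(root_arrival_rate=0.0)},
            n_devices={"ww": 2},
        )
        _, truth, _ = simulate_trial(cfg)
        assert truth.empty

    def test_no_downtime_gives_full_cadence_coverage(self, tiny_geometry):
        cfg = TrialConfig(
            n_days=2, seed=3, geometry=tiny_geometry,
            treatments={"ww": TreatmentSpec(root_arrival_rate=0.0)},
            n_devices={"ww": 1},
        )
        stream, _, _ = simulate_trial(cfg)
        n_el = tiny_geometry.n_paddles * tiny_geometry.electrodes_per_paddle
        assert len(stream) == 2 * tiny_geometry.samples_per_day * n_el
        per_day = stream.groupby(
            [stream["timestamp"].dt.date, "paddle_index", "depth_index"]
        ).size()
        assert (per_day == tiny_geometry.samples_per_day).all()

    def test_drying_phenomenology_in_daily_averages(self, tiny_geometry):
        # no roots, no irrigation: daily-mean estimated R rises, C falls
        from rhizosense.circuit import estimate_rc_arrays

        cfg = TrialConfig(
            n_days=6, seed=3, geometry=tiny_geometry,
            soil=SoilParams(noise_sd=0.005),
            treatments={"ww": TreatmentSpec(root_arrival_rate=0.0)},
            n_devices={"ww": 1},
        )
        sim = next(iter_device_sims(cfg))
        res, cap, _ = estimate_rc_arrays(sim.V1, sim.V2, cfg.constants)
        spd = tiny_geometry.samples_per_day
        daily_res = res.reshape(res.shape[0], -1, spd).mean(axis=2).mean(axis=0)
        daily_cap = cap.reshape(cap.shape[0], -1, spd).mean(axis=2).mean(axis=0)
        assert np.all(np.diff(daily_res) > 0)
        assert np.all(np.diff(daily_cap) < 0)

    def test_event_injection_is_localized_to_event_electrodes(self, geometry):
        # identical seeds, one config with events and one without: streams
        # agree exactly except at the touched electrodes
        soil = SoilParams(noise_sd=0.0)
        base = dict(n_days=2, seed=9, soil=soil, n_devices={"ww": 1})
        cfg_ev = TrialConfig(
            treatments={"ww": TreatmentSpec(root_arrival_rate=3.0)}, **base
        )
        cfg_no = TrialConfig(
            treatments={"ww": TreatmentSpec(root_arrival_rate=0.0)}, **base
        )
        sim_ev = next(iter_device_sims(cfg_ev))
        sim_no = next(iter_device_sims(cfg_no))
        diff_el = np.flatnonzero(
            np.any(sim_ev.V1 != sim_no.V1, axis=1)
            | np.any(sim_ev.V2 != sim_no.V2, axis=1)
        )
        truth_el = sorted(
            sim_ev.truth["paddle_index"] * geometry.electrodes_per_paddle
            + sim_ev.truth["depth_index"]
        )
        assert len(sim_ev.truth) > 0
        np.testing.assert_array_equal(diff_el, np.unique(truth_el))
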