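import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trapcount import (
    ConsumptionProfile,
    GeneratorConfig,
    MockTransport,
    Phase,
    StickyTrapSceneProvider,
    TrapState,
    bank_from_config,
    daily_consumption_mAh,
    estimate_battery_life,
    load_profile,
    run_daily_cycle,
    should_upload,
    simulate_deployment,
)


class _OracleCounter:
    """Perfect counter: counts dark pixels' connected components."""

    def predict(self, image):
        from scipy import ndimage

        # procedural sprites are <= 158 luminance, trap floors >= ~199
        dark = np.asarray(image) < 180
        return float(ndimage.label(dark, structure=np.ones((3, 3), int))[1])


class TestTrigger:
    @pytest.mark.parametrize(
        "prev,new,expected",
        [(2, 2, False), (1, 3, True), (None, 0, True), (None, 5, True), (0, 0, False), (3, 2, True)],
    )
    def test_should_upload_cases(self, prev, new, expected):
        assert should_upload(prev, new) is expected

    @given(st.lists(st.integers(0, 6), min_size=1, max_size=50))
    def test_uploads_equal_one_plus_changes(self, schedule):
        """Over any schedule, an oracle counter uploads once at start plus once
        per day-to-day change."""
        state = TrapState()
        uploads = 0
        for c in schedule:
            up = should_upload(state.last_count, c)
            uploads += int(up)
            state.last_count = c
        changes = sum(a != b for a, b in zip(schedule, schedule[1:]))
        assert uploads == 1 + changes


class TestEnergyModel:
    @pytest.fixture()
    def esp32(self):
        return load_profile("esp32")

    def test_esp32_battery_life_from_fixture(self, esp32):
        """Two 3,350 mAh cells at the ESP32 duty figures: the active window
        displaces sleep, giving ~145.5 mAh/day and ~46 days."""
        assert esp32.battery_capacity_mAh == 6700
        assert esp32.active_seconds == pytest.approx(63.0)
        days = estimate_battery_life(esp32)
        assert days == pytest.approx(6700 / ((6 * (86400 - 63) + 5675) / 3600))
        assert 45 <= days <= 51

    def test_one_hour_phase_at_capacity_lasts_one_day(self):
        p = ConsumptionProfile("x", 0.0, [Phase("work", 240.0, 3600.0)], battery_capacity_mAh=240.0)
        assert estimate_battery_life(p) == pytest.approx(1.0)

    def test_days_linear_in_capacity(self, esp32):
        double = dataclasses.replace(esp32, battery_capacity_mAh=2 * esp32.battery_capacity_mAh)
        assert estimate_battery_life(double) == pytest.approx(2 * estimate_battery_life(esp32))

    def test_monotone_decreasing_in_currents_and_cycles(self, esp32):
        base = estimate_battery_life(esp32)
        more_sleep = dataclasses.replace(esp32, sleep_current_mA=esp32.sleep_current_mA + 1)
        assert estimate_battery_life(more_sleep) < base
        hot_phase = dataclasses.replace(
            esp32,
            phases=[Phase(p.name, p.avg_current_mA + 10, p.duration_s) for p in esp32.phases],
        )
        assert estimate_battery_life(hot_phase) < base
        busy = dataclasses.replace(esp32, cycles_per_day=2)
        assert estimate_battery_life(busy) < base

    def test_zero_consumption_signals_infinite_life(self):
        p = ConsumptionProfile("idle", 0.0, [], battery_capacity_mAh=100.0, cycles_per_day=0)
        assert math.isinf(estimate_battery_life(p))

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            ConsumptionProfile("x", -1.0, [], battery_capacity_mAh=10.0)
        with pytest.raises(ValueError):
            ConsumptionProfile("x", 1.0, [], battery_capacity_mAh=0.0)

    @pytest.mark.parametrize("name", ["esp32", "rpi4", "coral", "coral_tpu"])
    def test_bundled_profiles_load_and_sum_to_63s(self, name):
        p = load_profile(name)
        assert p.active_seconds == pytest.approx(63.0, abs=0.01)
        assert estimate_battery_life(p) > 0

    def test_yaml_roundtrip(self, tmp_path):
        p = load_profile("esp32")
        p.to_yaml(tmp_path / "p.yaml")
        q = ConsumptionProfile.from_yaml(tmp_path / "p.yaml")
        assert q == p


@pytest.fixture()
def provider():
    cfg = GeneratorConfig.desk_scale(seed=4, train_pool_per_class=1, test_per_class=1)
    return StickyTrapSceneProvider(cfg, bank_from_config(cfg), seed=4)


class TestDailyCycle:

    def test_first_day_always_uploads(self):
        state = TrapState()
        transport = MockTransport()
        img = np.full((64, 64), 210, dtype=np.uint8)
        state, uploaded = run_daily_cycle(state, img, _OracleCounter(), transport)
        assert uploaded and len(transport.posts) == 1
        assert state.last_count == 0 and state.day_index == 1

    def test_unchanged_count_does_not_upload(self):
        state = TrapState()
        img = np.full((64, 64), 210, dtype=np.uint8)
        run_daily_cycle(state, img, _OracleCounter())
        _, uploaded = run_daily_cycle(state, img, _OracleCounter())
        assert not uploaded

    def test_failed_inference_logged_and_day_advances(self):
        class Broken:
            def predict(self, image):
                raise RuntimeError("sensor glitch")

        state = TrapState()
        state, uploaded = run_daily_cycle(state, np.zeros((8, 8), np.uint8), Broken())
        assert not uploaded
        assert state.day_index == 1 and state.last_count is None
        assert state.upload_log == [(0, -1, False)]

    def test_deployment_schedule_triggers(self, provider):
        """Arrivals [0,0,1,1,3] with an oracle counter upload on days 1, 3 and
        5 (1-based), matching the count-change rule."""
        profile = load_profile("esp32")
        log = simulate_deployment([0, 0, 1, 1, 3], _OracleCounter(), provider, profile)
        uploaded_days = [r["day"] for r in log.rows if r["uploaded"]]
        assert uploaded_days == [0, 2, 4]
        assert [r["inferred_count"] for r in log.rows] == [0, 0, 1, 1, 3]

    def test_constant_schedule_uploads_once(self):
        cfg = GeneratorConfig.desk_scale(seed=6, train_pool_per_class=1, test_per_class=1)
        provider = StickyTrapSceneProvider(cfg, bank_from_config(cfg), seed=6)
        log = simulate_deployment([2, 2, 2], _OracleCounter(), provider, load_profile("esp32"))
        assert log.n_uploads == 1

    def test_energy_is_additive(self):
        cfg = GeneratorConfig.desk_scale(seed=7, train_pool_per_class=1, test_per_class=1)
        provider = StickyTrapSceneProvider(cfg, bank_from_config(cfg), seed=7)
        profile = load_profile("esp32")
        n_days = 5
        log = simulate_deployment([0] * n_days, _OracleCounter(), provider, profile)
        assert log.total_energy_mAh == pytest.approx(n_days * daily_consumption_mAh(profile))

    def test_sticky_provider_rejects_bad_schedules(self, provider):
        cfg = GeneratorConfig.desk_scale(seed=8, train_pool_per_class=1, test_per_class=1)
        p = StickyTrapSceneProvider(cfg, bank_from_config(cfg), seed=8)
        with pytest.raises(ValueError, match="invalid class range"):
            p.scene_for(cfg.max_count + 1)
        p.scene_for(3)
        with pytest.raises(ValueError, match="non-decreasing"):
            p.scene_for(2)

    def test_mock_transport_writes_payloads(self, tmp_path):
        transport = MockTransport(tmp_path)
        img = np.full((16, 16), 200, dtype=np.uint8)
        transport.post({"day": 0, "count": 2, "image": img})
        assert (tmp_path / "upload_day0000.json").exists()
        assert (tmp_path / "upload_day0000.png").exists()
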