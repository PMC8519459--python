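import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from terrapin.motion_signal import (
    GRAVITY,
    angles,
    decompose,
    integrate_vedba,
    motion_series,
    odba,
    posture_to_gravity,
    pressure_to_depth,
    vedba,
)

FS = 10.0


def _t(n):
    return np.arange(n) / FS


class TestDecompose:
    def test_constant_gravity_passes_to_static(self):
        n = 1200
        t = _t(n)
        static, dynamic, edge = decompose(
            t, np.zeros(n), np.zeros(n), np.full(n, GRAVITY)
        )
        assert np.allclose(static[:, 2], GRAVITY, atol=1e-9)
        assert np.allclose(static[:, :2], 0.0, atol=1e-9)
        assert np.allclose(dynamic, 0.0, atol=1e-9)
        assert edge[:20].all() and edge[-20:].all()

    def test_static_plus_dynamic_reconstructs_raw(self, rng):
        n = 4000
        raw = rng.normal(0, 1, (n, 3)) + [0, 0, GRAVITY]
        static, dynamic, _ = decompose(_t(n), *raw.T)
        assert np.allclose(static + dynamic, raw, atol=1e-10)

    def test_band_split_against_fourier_oracle(self):
        # 2 Hz sinusoid, amplitude 1, should land >=90% in dynamic and
        # <=10% in static given the 0.5 Hz cutoff of a 2 s window
        n = 6000
        t = _t(n)
        sine = np.sin(2 * np.pi * 2.0 * t)
        static, dynamic, edge = decompose(
            t, sine, np.zeros(n), np.full(n, GRAVITY)
        )
        keep = ~edge

        def power_at_2hz(x):
            c = np.cos(2 * np.pi * 2.0 * t[keep])
            s = np.sin(2 * np.pi * 2.0 * t[keep])
            m = keep.sum()
            amp2 = (2 * np.dot(x, c) / m) ** 2 + (2 * np.dot(x, s) / m) ** 2
            return amp2 / 2.0

        total = power_at_2hz(sine[keep])
        assert power_at_2hz(dynamic[keep, 0]) >= 0.9 * total
        assert power_at_2hz(static[keep, 0]) <= 0.1 * total

    def test_moving_average_alternative_is_dc_exact(self):
        n = 1200
        static, dynamic, _ = decompose(
            _t(n), np.zeros(n), np.zeros(n), np.full(n, GRAVITY),
            method="moving_average",
        )
        assert np.allclose(static[:, 2], GRAVITY, atol=1e-12)

    def test_short_stream_raises(self):
        n = 50  # < 4 windows at 10 Hz
        with pytest.raises(ValueError):
            decompose(_t(n), np.zeros(n), np.zeros(n), np.zeros(n))


class TestVedba:
    @pytest.mark.parametrize("dyn,expected", [
        ((0.0, 0.0, 0.0), 0.0),
        ((3.0, 4.0, 0.0), 5.0),
        ((1.0, 1.0, 1.0), np.sqrt(3.0)),
    ])
    def test_closed_forms(self, dyn, expected):
        assert vedba(*dyn) == pytest.approx(expected)

    def test_odba_is_manhattan_sum(self):
        assert odba(1.0, -2.0, 3.0) == pytest.approx(6.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        dyn = rng.normal(0, 0.3, (200, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = dyn @ q.T
        assert np.allclose(
            vedba(*dyn.T), vedba(*rotated.T), rtol=1e-10, atol=1e-12
        )


class TestIntegrateVedba:
    def test_constant_over_one_hour(self):
        t = np.arange(0.0, 3601.0)
        assert integrate_vedba(t, np.full(len(t), 0.16), 0, 3600) == \
            pytest.approx(576.0)

    def test_digging_level_matches_field_hourly_magnitude(self):
        # 0.31 m/s^2 over an hour: 1116 m/s, within 1% of the 1111.7 m/s
        # field mean for egg-laying bouts
        t = np.arange(0.0, 3601.0)
        total = integrate_vedba(t, np.full(len(t), 0.31), 0, 3600)
        assert total == pytest.approx(1116.0)
        assert abs(total - 1111.7) / 1111.7 < 0.01

    def test_zero_series(self):
        t = np.arange(0.0, 100.0)
        assert integrate_vedba(t, np.zeros(len(t)), 0, 99) == 0.0

    def test_additive_over_adjacent_intervals(self, rng):
        t = np.arange(0.0, 1000.0)
        v = rng.uniform(0, 1, len(t))
        whole = integrate_vedba(t, v, 10.3, 800.7)
        parts = (integrate_vedba(t, v, 10.3, 400.5)
                 + integrate_vedba(t, v, 400.5, 800.7))
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_interval_outside_coverage_raises(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError):
            integrate_vedba(t, np.zeros(len(t)), 0, 200)


class TestAngles:
    @pytest.mark.parametrize("static,expected", [
        ((0.0, 0.0, GRAVITY), (0.0, 0.0)),
        ((GRAVITY, 0.0, 0.0), (90.0, 0.0)),
        ((0.0, GRAVITY * np.sin(np.radians(30)),
          GRAVITY * np.cos(np.radians(30))), (0.0, 30.0)),
    ])
    def test_reference_postures(self, static, expected):
        pitch, roll, flagged = angles(*static)
        assert not flagged
        assert pitch == pytest.approx(expected[0], abs=1e-9)
        assert roll == pytest.approx(expected[1], abs=1e-9)

    def test_near_zero_static_flagged_not_raised(self):
        pitch, roll, flagged = angles(0.01, 0.01, 0.01)
        assert flagged
        assert np.isnan(pitch) and np.isnan(roll)

    @pytest.mark.parametrize("p", [-84.0, -45.0, 0.0, 30.0, 84.9])
    @pytest.mark.parametrize("r", [-179.0, -90.0, 0.0, 60.0, 180.0])
    def test_round_trip_recovers_posture(self, p, r):
        pitch, roll, _ = angles(*posture_to_gravity(p, r))
        assert pitch == pytest.approx(p, abs=0.1)
        assert roll == pytest.approx(r, abs=0.1)


def test_quiescent_gravity_bounds():
    # slowly tilting pure-gravity segment: the static norm stays at g and
    # VeDBA stays near zero outside the filter transients
    n = 6000
    t = _t(n)
    pitch = 5.0 * np.sin(2 * np.pi * t / 120.0)
    roll = 3.0 * np.sin(2 * np.pi * t / 200.0)
    sx, sy, sz = posture_to_gravity(pitch, roll)
    static, dynamic, edge = decompose(t, sx, sy, sz)
    keep = ~edge
    norm = np.linalg.norm(static[keep], axis=1)
    assert np.mean(np.abs(norm - GRAVITY)) < 0.01
    assert np.mean(vedba(*dynamic[keep].T)) < 0.02


class TestPressureToDepth:
    @pytest.mark.parametrize("bar,cm", [
        (0.0, 0.0),
        (0.037, 37.0),
        (0.0044, 4.4),
        (0.1, 100.0),
    ])
    def test_linear_transform(self, bar, cm):
        assert pressure_to_depth(bar) == pytest.approx(cm)

    def test_negative_pressure_clipped_and_flagged(self):
        depth, clipped = pressure_to_depth(np.array([-0.005, 0.01]),
                                           return_clipped=True)
        assert depth[0] == 0.0 and not clipped[1] and clipped[0]


def test_motion_series_frame_has_all_channels(rng):
    import pandas as pd

    n = 1200
    accel = pd.DataFrame({
        "time": _t(n),
        "ax": rng.normal(0, 0.1, n),
        "ay": rng.normal(0, 0.1, n),
        "az": GRAVITY + rng.normal(0, 0.1, n),
    })
    ms = motion_series(accel)
    frame = ms.to_frame()
    assert {"vedba", "pitch_deg", "roll_deg", "edge", "low_g"} <= \
        set(frame.columns)
    assert (ms.vedba >= 0).all()


def test_minute_summary_decimates_to_one_row_per_minute(rng):
    import pandas as pd

    from terrapin.motion_signal import minute_summary

    n = 3 * 600  # three minutes at 10 Hz
    accel = pd.DataFrame({
        "time": _t(n),
        "ax": rng.normal(0, 0.1, n),
        "ay": rng.normal(0, 0.1, n),
        "az": GRAVITY + rng.normal(0, 0.1, n),
    })
    out = minute_summary(motion_series(accel))
    assert len(out) == 3
    assert {"time", "vedba", "pitch_deg", "roll_deg"} <= set(out.columns)
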