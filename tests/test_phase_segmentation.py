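import numpy as np
import pandas as pd
import pytest

from terrapin.phase_segmentation import (
    PhaseBout,
    SegmentationConfig,
    classify_epochs,
    epoch_stats,
    labels_from_bouts,
    segment_cycles,
)


def _env(times, temp, pressure, light):
    return pd.DataFrame({
        "time": times, "temp_c": temp, "pressure_bar": pressure,
        "light_lux": light,
    })


class TestEpochStats:
    def test_constant_temperature_gives_zero_sd(self):
        env = _env(np.arange(60.0), np.full(60, 20.0), np.full(60, 0.037),
                   np.full(60, 100.0))
        stats = epoch_stats(env)
        assert stats["sd_t"].iloc[0] == 0.0
        assert stats["valid"].iloc[0]

    def test_alternating_lux_median_and_mean(self):
        lux = np.tile([0.0, 2000.0], 30)
        env = _env(np.arange(60.0), np.full(60, 20.0), np.full(60, 0.037),
                   lux)
        stats = epoch_stats(env)
        assert stats["median_l"].iloc[0] == pytest.approx(1000.0)
        assert stats["mean_l"].iloc[0] == pytest.approx(1000.0)

    def test_sd_matches_direct_recomputation(self, rng):
        x = rng.normal(18.0, 0.7, 60)
        env = _env(np.arange(60.0), x, np.full(60, 0.037),
                   np.full(60, 10.0))
        stats = epoch_stats(env)
        # brute-force oracle with the n-1 denominator
        oracle = np.sqrt(np.sum((x - x.mean()) ** 2) / (len(x) - 1))
        assert stats["sd_t"].iloc[0] == pytest.approx(oracle, rel=1e-12)

    def test_sparse_epoch_flagged_invalid(self):
        env = _env(np.arange(0.0, 60.0, 2.0), np.full(30, 20.0),
                   np.full(30, 0.037), np.full(30, 10.0))
        stats = epoch_stats(env)
        assert not stats["valid"].iloc[0]

    def test_running_24h_minimum_tracks_past_only(self):
        t = np.arange(0.0, 3 * 60.0)
        temp = np.concatenate([np.full(60, 15.0), np.full(60, 12.0),
                               np.full(60, 20.0)])
        env = _env(t, temp, np.full(len(t), 0.037), np.full(len(t), 10.0))
        stats = epoch_stats(env)
        assert list(stats["min24_t"]) == [15.0, 12.0, 12.0]


class TestClassifyEpochs:
    def _stats(self, median_l, sd_t, sd_p, mean_l=0.0, excess=0.0):
        return pd.DataFrame({
            "t_start": [0.0], "n": [60], "valid": [True],
            "median_l": [median_l], "mean_l": [mean_l], "sd_t": [sd_t],
            "sd_p": [sd_p], "mean_t": [15.0 + excess], "min24_t": [15.0],
        })

    def test_dark_quiet_epoch_is_night(self):
        stats = self._stats(500.0, 0.2, 0.001)
        assert classify_epochs(stats)[0] == "night"

    def test_variable_pressure_breaks_the_night_rule(self):
        stats = self._stats(500.0, 0.2, 0.02)
        assert classify_epochs(stats)[0] == "other"

    def test_bright_warm_epoch_is_midday(self):
        stats = self._stats(25000.0, 2.0, 0.02, mean_l=30000.0, excess=3.0)
        assert classify_epochs(stats)[0] == "midday"

    def test_bright_but_cool_epoch_is_other(self):
        stats = self._stats(25000.0, 2.0, 0.02, mean_l=30000.0, excess=1.0)
        assert classify_epochs(stats)[0] == "other"

    def test_invalid_epoch_stays_invalid(self):
        stats = self._stats(500.0, 0.2, 0.001)
        stats.loc[0, "valid"] = False
        assert classify_epochs(stats)[0] == "invalid"


def _constructed_day(midday=True):
    """Two Nights bracketing a day, optionally with a clean Midday block.

    Night 0: epochs 0-239 (4 h); morning until epoch 480; midday 480-779
    (5 h) when requested; evening/morning until Night at 1080 (4 h).
    """
    n_epochs = 1440
    labels = np.full(n_epochs, "other", dtype=object)
    labels[:240] = "night"
    if midday:
        labels[480:780] = "midday"
    labels[1080:1320] = "night"
    stats = pd.DataFrame({
        "t_start": np.arange(n_epochs) * 60.0,
        "valid": True,
    })
    return stats, labels


class TestSegmentCycles:
    def test_clean_day_yields_four_ordered_bouts(self):
        stats, labels = _constructed_day()
        bouts, flags = segment_cycles(stats, labels)
        cycle = [b for b in bouts if b.t_start < 1080 * 60.0]
        assert [b.label for b in cycle] == ["Night", "Morning", "Midday",
                                            "Evening"]
        assert cycle[0].duration_h == pytest.approx(4.0)
        assert cycle[2].duration_h == pytest.approx(5.0)
        assert not flags["unsegmentable"]

    def test_overcast_day_yields_morning_then_night(self):
        stats, labels = _constructed_day(midday=False)
        bouts, _ = segment_cycles(stats, labels)
        cycle = [b for b in bouts if b.t_start < 1080 * 60.0]
        assert [b.label for b in cycle] == ["Night", "Morning"]

    def test_bouts_tile_the_cycle(self):
        stats, labels = _constructed_day()
        bouts, _ = segment_cycles(stats, labels)
        cycle = [b for b in bouts if b.t_start < 1080 * 60.0]
        total = sum(b.t_end - b.t_start for b in cycle)
        assert total == pytest.approx(1080 * 60.0)
        for a, b in zip(cycle, cycle[1:]):
            assert a.t_end == pytest.approx(b.t_start)

    def test_flicker_is_smoothed_away(self):
        stats, labels = _constructed_day()
        labels[100:103] = "other"      # 3-min hole inside Night: closed
        labels[400:405] = "midday"     # 5-min stray run: dissolved
        bouts, _ = segment_cycles(stats, labels)
        cycle = [b for b in bouts if b.t_start < 1080 * 60.0]
        assert [b.label for b in cycle] == ["Night", "Morning", "Midday",
                                            "Evening"]
        assert cycle[0].duration_h == pytest.approx(4.0)

    def test_no_night_flags_unsegmentable(self):
        stats = pd.DataFrame({"t_start": np.arange(100) * 60.0,
                              "valid": True})
        labels = np.full(100, "other", dtype=object)
        bouts, flags = segment_cycles(stats, labels)
        assert bouts == [] and flags["unsegmentable"]

    def test_longest_midday_run_wins(self):
        stats, labels = _constructed_day()
        labels[840:900] = "midday"  # second, shorter midday run
        bouts, _ = segment_cycles(stats, labels)
        midday = [b for b in bouts if b.label == "Midday"]
        assert len(midday) == 1
        assert midday[0].duration_h == pytest.approx(5.0)

    def test_raising_night_light_threshold_never_shortens_night(self):
        rng = np.random.default_rng(5)
        n = 1440
        stats = pd.DataFrame({
            "t_start": np.arange(n) * 60.0, "n": 60, "valid": True,
            "median_l": rng.uniform(0, 3000, n),
            "mean_l": np.zeros(n),
            "sd_t": np.full(n, 0.1), "sd_p": np.full(n, 1e-3),
            "mean_t": np.full(n, 15.0), "min24_t": np.full(n, 15.0),
        })
        totals = []
        for thr in (500.0, 1000.0, 2000.0):
            cfg = SegmentationConfig(night_max_median_l=thr)
            bouts, _ = segment_cycles(stats, classify_epochs(stats, cfg),
                                      cfg)
            totals.append(sum(b.t_end - b.t_start for b in bouts
                              if b.label == "Night"))
        assert totals[0] <= totals[1] <= totals[2]


def test_synthetic_epochs_mostly_match_truth(small_evaluation):
    """On labelled synthetic data the detector recovers the scheduled phase
    of nearly every 1-min epoch."""
    assert small_evaluation["phase_epoch_accuracy_pct"] >= 95.0


def test_labels_from_bouts_round_trip():
    stats = pd.DataFrame({"t_start": np.arange(10) * 60.0, "valid": True})
    bouts = [PhaseBout("Night", 0.0, 300.0, 0),
             PhaseBout("Morning", 300.0, 600.0, 0)]
    lab = labels_from_bouts(bouts, stats)
    assert list(lab[:5]) == ["Night"] * 5
    assert list(lab[5:10]) == ["Morning"] * 5
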