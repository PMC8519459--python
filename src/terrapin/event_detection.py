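"""Detection of breathing, basking, diving and nest-digging events.

Breathing: during nocturnal rest just below the surface, each inhalation
shows as a transient pressure decrease (the animal rises a few cm); spikes
cluster into breathing bouts separated by tens of minutes of apnoea.

Basking: during Midday, emersion shows as a sustained monotone rise of the
tag temperature; sudden temperature drops or pressure increases mark dives.

Nest digging: stereotyped rear-leg digging oscillates the body around its
pitch axis while roll stays stable; a 2-min window is flagged when
(var[roll] < 50 and var[pitch] > 120) or (var[roll] < 10 and
var[pitch] > 40), variances in degrees squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .motion_signal import pressure_to_depth


@dataclass
class InhalationEvent:
    t: float
    pre_pressure: float   # running-median baseline just before the spike, bar
    min_pressure: float   # pressure at the spike minimum, bar
    rise_cm: float        # pressure_to_depth(pre - min)


@dataclass
class BreathingBout:
    t_start: float
    t_end: float
    inhalations: list = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_inhalations(self) -> int:
        return len(self.inhalations)


@dataclass
class BaskingEvent:
    t_start: float
    t_end: float
    delta_t: float        # total temperature rise, degC


@dataclass
class DivingEvent:
    t_start: float
    t_end: float
    delta_t: float        # temperature drop magnitude, degC
    trigger: str          # 'temperature' | 'pressure'


@dataclass
class NestingEvent:
    t_start: float
    t_end: float
    mean_vedba: float
    phase_label: str = ""
    success: bool = False

    @property
    def duration_min(self) -> float:
        return (self.t_end - self.t_start) / 60.0


def detect_inhalations(t, p, min_rise_cm: float = 2.0,
                       baseline_window_s: float = 120.0,
                       refractory_s: float = 5.0) -> list[InhalationEvent]:
    """Inhalation spikes in a Night-phase 1 Hz pressure segment.

    The baseline is a centred running median over ``baseline_window_s``; an
    inhalation is a local maximum of (baseline - P) of at least
    ``min_rise_cm``/1000 bar, with successive events at least
    ``refractory_s`` apart so one surfacing is never double-counted.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(t) < 3:
        return []
    dt = float(np.median(np.diff(t)))
    win = max(3, int(round(baseline_window_s / dt)) | 1)
    baseline = (
        pd.Series(p).rolling(win, center=True, min_periods=1).median()
        .to_numpy()
    )
    deficit = baseline - p
    distance = max(1, int(round(refractory_s / dt)))
    peaks, _ = find_peaks(deficit, height=min_rise_cm / 1000.0,
                          distance=distance)
    return [
        InhalationEvent(
            t=float(t[i]),
            pre_pressure=float(baseline[i]),
            min_pressure=float(p[i]),
            rise_cm=pressure_to_depth(baseline[i] - p[i]),
        )
        for i in peaks
    ]


def group_breathing_bouts(events: list[InhalationEvent],
                          max_gap_s: float = 60.0) -> list[BreathingBout]:
    """Cluster time-sorted inhalations into bouts.

    Events with inter-event gap <= ``max_gap_s`` belong to one bout; a bout
    spans first to last event; a lone event forms a 1-inhalation bout of
    zero duration.
    """
    if not events:
        return []
    events = sorted(events, key=lambda e: e.t)
    bouts = []
    current = [events[0]]
    for ev in events[1:]:
        if ev.t - current[-1].t <= max_gap_s:
            current.append(ev)
        else:
            bouts.append(BreathingBout(current[0].t, current[-1].t, current))
            current = [ev]
    bouts.append(BreathingBout(current[0].t, current[-1].t, current))
    return bouts


def breathing_rise_stats(bouts: list[BreathingBout]):
    """Per-bout surfacing rise and inter-bout intervals.

    The rise of a bout is the depth equivalent of (pressure just before the
    bout - minimum pressure during the bout), in cm.  Returns
    ``(rises_cm, intervals_s)`` where intervals are between consecutive bout
    starts (empty with a single bout).
    """
    if not bouts:
        raise ValueError("at least one bout required")
    bouts = sorted(bouts, key=lambda b: b.t_start)
    rises = np.array([
        pressure_to_depth(
            b.inhalations[0].pre_pressure
            - min(e.min_pressure for e in b.inhalations)
        )
        for b in bouts
    ])
    starts = np.array([b.t_start for b in bouts])
    return rises, np.diff(starts)


def detect_basking(t, temp, min_duration_s: float = 300.0,
                   min_slope_c_per_min: float = 0.2,
                   smooth_s: float = 60.0) -> list[BaskingEvent]:
    """Basking events: maximal runs of continuously increasing temperature.

    Temperature is smoothed over ``smooth_s`` first; a run qualifies when it
    is non-decreasing (small tolerance for sensor noise), lasts at least
    ``min_duration_s`` and has a run-average slope of at least
    ``min_slope_c_per_min``.
    """
    t = np.asarray(t, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if len(t) < 3:
        return []
    dt = float(np.median(np.diff(t)))
    n = max(1, int(round(smooth_s / dt)))
    sm = uniform_filter1d(temp, size=n, mode="nearest")
    nondec = np.diff(sm) >= -1e-4
    events = []
    for s, e in _bool_runs(nondec):
        i0, i1 = s, e  # run over diff indices -> samples i0 .. i1 inclusive
        dur = t[i1] - t[i0]
        if dur < min_duration_s:
            continue
        rise = sm[i1] - sm[i0]
        slope = rise / dur * 60.0
        if slope >= min_slope_c_per_min and rise > 0:
            events.append(BaskingEvent(float(t[i0]), float(t[i1]),
                                       float(rise)))
    return events


def detect_dives(t, temp, p, dt_drop_c: float = 2.0,
                 dt_window_s: float = 60.0, dp_rise_bar: float = 0.01,
                 dp_window_s: float = 30.0,
                 merge_s: float = 60.0) -> list[DivingEvent]:
    """Dives near basking periods: sudden temperature drop or pressure rise.

    A temperature trigger fires at sample i when T(i) - T(i + window) >=
    ``dt_drop_c``; a pressure trigger when P(i + window) - P(i) >=
    ``dp_rise_bar``.  Triggers within ``merge_s`` merge into one event whose
    recorded trigger is the earliest one.
    """
    t = np.asarray(t, dtype=float)
    temp = np.asarray(temp, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(t) < 3:
        return []
    dt = float(np.median(np.diff(t)))
    kT = max(1, int(round(dt_window_s / dt)))
    kP = max(1, int(round(dp_window_s / dt)))
    trig = []
    if len(temp) > kT:
        hits = np.nonzero(temp[:-kT] - temp[kT:] >= dt_drop_c)[0]
        trig += [(float(t[i]), "temperature", i, kT) for i in hits]
    if len(p) > kP:
        hits = np.nonzero(p[kP:] - p[:-kP] >= dp_rise_bar)[0]
        trig += [(float(t[i]), "pressure", i, kP) for i in hits]
    if not trig:
        return []
    trig.sort(key=lambda x: x[0])
    events = []
    cur = [trig[0]]
    for tr in trig[1:]:
        if tr[0] - cur[-1][0] <= merge_s:
            cur.append(tr)
        else:
            events.append(_make_dive(cur, t, temp, dt))
            cur = [tr]
    events.append(_make_dive(cur, t, temp, dt))
    return events


def _make_dive(trigs, t, temp, dt):
    t_start = trigs[0][0]
    last_i, last_k = trigs[-1][2], trigs[-1][3]
    t_end = float(t[min(last_i + last_k, len(t) - 1)])
    i0 = trigs[0][2]
    i1 = min(last_i + last_k, len(t) - 1)
    drop = float(temp[i0] - np.min(temp[i0:i1 + 1])) if i1 > i0 else 0.0
    return DivingEvent(t_start, t_end, drop, trigs[0][1])


def nesting_window_flag(var_roll, var_pitch,
                        roll_hi: float = 50.0, pitch_hi: float = 120.0,
                        roll_lo: float = 10.0, pitch_lo: float = 40.0):
    """The pure digging rule on one window's angle variances (degrees^2):
    (var_roll < 50 and var_pitch > 120) or (var_roll < 10 and
    var_pitch > 40)."""
    var_roll = np.asarray(var_roll, dtype=float)
    var_pitch = np.asarray(var_pitch, dtype=float)
    return ((var_roll < roll_hi) & (var_pitch > pitch_hi)) | (
        (var_roll < roll_lo) & (var_pitch > pitch_lo)
    )


def _windowed_variance(x: np.ndarray, w: int, step: int) -> np.ndarray:
    """Sample variance (n-1) over sliding windows via cumulative sums."""
    n = len(x)
    starts = np.arange(0, n - w + 1, step)
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    s1 = c1[starts + w] - c1[starts]
    s2 = c2[starts + w] - c2[starts]
    return (s2 - s1 * s1 / w) / (w - 1), starts


def detect_nesting(t, pitch, roll, vedba=None, window_s: float = 120.0,
                   step_s: float = 30.0, min_event_s: float = 300.0,
                   merge_gap_s: float = 600.0,
                   exclude_mask=None) -> list[NestingEvent]:
    """Nest-digging events from 10 Hz pitch/roll series.

    Sliding 2-min windows (30 s stride) are flagged by
    :func:`nesting_window_flag`; flagged windows are merged across gaps up
    to ``merge_gap_s`` and merged spans of at least ``min_event_s`` become
    events.  ``mean_vedba`` is computed over the event span when a VeDBA
    series is supplied.  ``exclude_mask`` (e.g. filter edge transients)
    removes samples from consideration.
    """
    t = np.asarray(t, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    roll = np.asarray(roll, dtype=float)
    if len(t) < 3:
        return []
    dt = float(np.median(np.diff(t)))
    w = max(2, int(round(window_s / dt)))
    step = max(1, int(round(step_s / dt)))
    if len(t) < w:
        return []
    vp, starts = _windowed_variance(pitch, w, step)
    vr, _ = _windowed_variance(roll, w, step)
    flags = nesting_window_flag(vr, vp)
    flags = np.where(np.isnan(vp) | np.isnan(vr), False, flags)
    if exclude_mask is not None:
        em = np.asarray(exclude_mask, dtype=bool)
        c = np.concatenate(([0], np.cumsum(em.view(np.int8))))
        has_excluded = (c[starts + w] - c[starts]) > 0
        flags &= ~has_excluded
    idx = np.nonzero(flags)[0]
    if len(idx) == 0:
        return []
    # merge flagged window intervals [start, start + w)
    intervals = []
    cur_s, cur_e = starts[idx[0]], starts[idx[0]] + w
    for i in idx[1:]:
        s, e = starts[i], starts[i] + w
        if t[min(s, len(t) - 1)] - t[min(cur_e, len(t) - 1) - 1] <= merge_gap_s:
            cur_e = max(cur_e, e)
        else:
            intervals.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    intervals.append((cur_s, cur_e))
    events = []
    for s, e in intervals:
        e = min(e, len(t))
        t0, t1 = float(t[s]), float(t[e - 1])
        if t1 - t0 < min_event_s:
            continue
        mv = float(np.nanmean(vedba[s:e])) if vedba is not None else np.nan
        events.append(NestingEvent(t0, t1, mv))
    return events


def confusion_percentages(tp: int, fp: int, fn: int) -> dict:
    """False positive/negative percentages from confusion counts.

    FP% = FP/(TP+FP) x 100 and FN% = FN/(TP+FN) x 100, rounded to one
    decimal (NaN when the denominator is zero).
    """
    fp_pct = round(100.0 * fp / (tp + fp), 1) if tp + fp else float("nan")
    fn_pct = round(100.0 * fn / (tp + fn), 1) if tp + fn else float("nan")
    return {"tp": tp, "fp": fp, "fn": fn, "fp_pct": fp_pct, "fn_pct": fn_pct}


def validate_detections(detected, truth) -> dict:
    """Confusion counts of detected vs ground-truth intervals.

    ``detected`` and ``truth`` are sequences of (start, end) pairs.  A
    detection overlapping any truth interval is a true positive; an
    unmatched detection a false positive; an unmatched truth interval a
    false negative.
    """
    det = [(float(s), float(e)) for s, e in detected]
    tru = [(float(s), float(e)) for s, e in truth]

    def overlaps(a, b):
        return a[0] <= b[1] and b[0] <= a[1]

    tp = sum(1 for d in det if any(overlaps(d, g) for g in tru))
    fp = len(det) - tp
    fn = sum(1 for g in tru if not any(overlaps(g, d) for d in det))
    return confusion_percentages(tp, fp, fn)


def _bool_runs(mask: np.ndarray):
    """(start, end) pairs over a boolean array of interval flags: a run of
    k consecutive True diffs spans samples start .. start + k inclusive."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8),
                                                   [0]))))
    return [(s, e) for s, e in zip(edges[::2], edges[1::2])]
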