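"""Segmentation of each 24-h cycle into Night / Morning / Midday / Evening.

The rules operate on 1-minute windowed statistics of the 1 Hz environmental
stream.  Night is dark and quiet (low median light, near-constant logger
temperature and pressure); Midday is bright and warm (high mean light,
logger temperature well above the running 24-h minimum); Morning fills the
interval from Night end to Midday start, Evening from Midday end to the
next Night start.  On days where no epoch passes the Midday rule the whole
inter-Night interval is labelled Morning and no Evening is emitted.

Cycles are anchored on Night onsets (not calendar midnight) because all
four phases are defined relative to Night.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SegmentationConfig:
    """Thresholds of the phase rules.

    Defaults are the field-calibrated values: Night requires
    median light < 1000 lux, sd(T) < 1 degC and sd(P) < 5e-3 bar over one
    minute; Midday requires mean light > 20000 lux and logger temperature
    at least ``midday_min_t_excess`` (default 2 degC) above the running
    24-h minimum.  Raw 1-min labels flicker at dawn/dusk, so label runs are
    smoothed by closing gaps <= ``smoothing_gap_min`` and dissolving runs
    < ``min_bout_min``.
    """

    night_max_median_l: float = 1000.0
    night_max_sd_t: float = 1.0
    night_max_sd_p: float = 5e-3
    midday_min_mean_l: float = 20000.0
    midday_min_t_excess: float = 2.0
    min_bout_min: float = 10.0
    smoothing_gap_min: float = 5.0
    epoch_s: float = 60.0
    min_valid_samples: int = 50

    def __post_init__(self):
        for name in ("night_max_median_l", "night_max_sd_t", "night_max_sd_p",
                     "midday_min_mean_l", "midday_min_t_excess",
                     "min_bout_min", "smoothing_gap_min", "epoch_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class PhaseBout:
    """One labelled interval within a Night-anchored 24-h cycle."""

    label: str            # Night | Morning | Midday | Evening
    t_start: float
    t_end: float
    cycle_date: int       # calendar day index at the cycle's Night onset

    @property
    def duration_h(self) -> float:
        return (self.t_end - self.t_start) / 3600.0


def epoch_stats(env: pd.DataFrame,
                config: SegmentationConfig | None = None) -> pd.DataFrame:
    """Consecutive non-overlapping 60 s epoch statistics of the env stream.

    Returns one row per epoch with ``t_start``, sample counts, median and
    mean light, sample standard deviations (n-1 denominator) of temperature
    and pressure, the epoch mean temperature and its running 24-h minimum
    (``min24_t``), plus a ``valid`` flag (>= 50 samples present).
    """
    config = config or SegmentationConfig()
    t = np.asarray(env["time"], dtype=float)
    epoch = np.floor(t / config.epoch_s).astype(np.int64)
    g = env.groupby(epoch, sort=True)
    stats = pd.DataFrame({
        "n": g["time"].count(),
        "median_l": g["light_lux"].median(),
        "mean_l": g["light_lux"].mean(),
        "sd_t": g["temp_c"].std(ddof=1),
        "sd_p": g["pressure_bar"].std(ddof=1),
        "mean_t": g["temp_c"].mean(),
    })
    # re-index onto a contiguous epoch grid so gaps become invalid epochs
    full = np.arange(stats.index.min(), stats.index.max() + 1)
    stats = stats.reindex(full)
    stats["t_start"] = stats.index.to_numpy() * config.epoch_s
    stats["n"] = stats["n"].fillna(0).astype(int)
    stats["valid"] = stats["n"] >= config.min_valid_samples
    epochs_per_day = int(round(86400.0 / config.epoch_s))
    stats["min24_t"] = (
        stats["mean_t"].rolling(epochs_per_day, min_periods=1).min()
    )
    cols = ["t_start", "n", "valid", "median_l", "mean_l", "sd_t", "sd_p",
            "mean_t", "min24_t"]
    return stats[cols].reset_index(names="epoch")


def classify_epochs(stats: pd.DataFrame,
                    config: SegmentationConfig | None = None) -> np.ndarray:
    """Raw per-epoch label: 'night', 'midday', 'other' or 'invalid'.

    An epoch (pathologically) matching both rules is labelled night: the
    night rule conjoins three conditions and is the more specific.
    """
    config = config or SegmentationConfig()
    night = (
        (stats["median_l"] < config.night_max_median_l)
        & (stats["sd_t"] < config.night_max_sd_t)
        & (stats["sd_p"] < config.night_max_sd_p)
    )
    midday = (
        (stats["mean_l"] > config.midday_min_mean_l)
        & ((stats["mean_t"] - stats["min24_t"]) >= config.midday_min_t_excess)
    )
    labels = np.where(night, "night", np.where(midday, "midday", "other"))
    labels = np.where(stats["valid"].to_numpy(), labels, "invalid")
    return labels.astype(object)


def _close_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Morphological closing: fill False gaps of length <= max_gap between
    True runs."""
    out = mask.copy()
    idx = np.nonzero(mask)[0]
    if len(idx) < 2:
        return out
    gaps = np.diff(idx) - 1
    for k in np.nonzero((gaps > 0) & (gaps <= max_gap))[0]:
        out[idx[k] + 1:idx[k + 1]] = True
    return out


def _remove_short_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Morphological opening: dissolve True runs shorter than min_len."""
    out = mask.copy()
    for s, e in _runs(mask):
        if e - s < min_len:
            out[s:e] = False
    return out


def _runs(mask: np.ndarray):
    """Yield (start, end) index pairs of True runs, end exclusive."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8),
                                                   [0]))))
    return list(zip(edges[::2], edges[1::2]))


def segment_cycles(stats: pd.DataFrame, labels: np.ndarray,
                   config: SegmentationConfig | None = None):
    """Turn raw epoch labels into ordered phase bouts per cycle.

    Returns ``(bouts, flags)`` where bouts is a list of :class:`PhaseBout`
    and flags is a dict of bookkeeping (``unsegmentable`` is True when no
    Night could be found at all).  Bouts of one cycle tile the cycle:
    Night -> Morning -> (Midday -> Evening)? -> next Night.
    """
    config = config or SegmentationConfig()
    gap = int(round(config.smoothing_gap_min * 60.0 / config.epoch_s))
    minb = int(round(config.min_bout_min * 60.0 / config.epoch_s))

    labels = np.asarray(labels, dtype=object)
    night = labels == "night"
    night = _remove_short_runs(_close_gaps(night, gap), minb)
    midday = (labels == "midday") & ~night
    midday = _remove_short_runs(_close_gaps(midday, gap), minb)
    midday &= ~night

    t0 = stats["t_start"].to_numpy()
    es = config.epoch_s

    night_runs = _runs(night)
    if not night_runs:
        return [], {"unsegmentable": True, "n_cycles": 0}

    bouts: list[PhaseBout] = []
    mid_runs = _runs(midday)
    for k in range(len(night_runs) - 1):
        ns, ne = night_runs[k]
        next_ns = night_runs[k + 1][0]
        # cycles are dated by the day at Night end (the dawn day), i.e. the
        # calendar day whose Morning/Midday/Evening the cycle contains; this
        # keeps individual-day keys unique when a record starts mid-night
        cycle_date = int(np.floor((t0[ne - 1] + es) / 86400.0))
        bouts.append(PhaseBout("Night", t0[ns], t0[ne - 1] + es, cycle_date))
        inter = [(max(s, ne), min(e, next_ns)) for s, e in mid_runs
                 if s < next_ns and e > ne]
        inter = [(s, e) for s, e in inter if e > s]
        if inter:
            ms, me = max(inter, key=lambda se: se[1] - se[0])
            if ms > ne:
                bouts.append(PhaseBout("Morning", t0[ne - 1] + es, t0[ms],
                                       cycle_date))
            bouts.append(PhaseBout("Midday", t0[ms], t0[me - 1] + es,
                                   cycle_date))
            if next_ns > me:
                bouts.append(PhaseBout("Evening", t0[me - 1] + es,
                                       t0[next_ns], cycle_date))
        else:
            if next_ns > ne:
                bouts.append(PhaseBout("Morning", t0[ne - 1] + es,
                                       t0[next_ns], cycle_date))
    # the trailing Night run anchors no further cycle but is still a bout
    ns, ne = night_runs[-1]
    bouts.append(PhaseBout("Night", t0[ns], t0[ne - 1] + es,
                           int(np.floor((t0[ne - 1] + es) / 86400.0))))
    return bouts, {"unsegmentable": False, "n_cycles": len(night_runs) - 1}


def bouts_to_frame(bouts, individual: str | None = None) -> pd.DataFrame:
    rows = [{
        "individual": individual,
        "cycle_date": b.cycle_date,
        "label": b.label,
        "t_start": b.t_start,
        "t_end": b.t_end,
        "duration_h": b.duration_h,
    } for b in bouts]
    return pd.DataFrame(rows, columns=["individual", "cycle_date", "label",
                                       "t_start", "t_end", "duration_h"])


def labels_from_bouts(bouts, stats: pd.DataFrame,
                      config: SegmentationConfig | None = None) -> np.ndarray:
    """Per-epoch phase label implied by a bout list ('' where uncovered).

    Convenience for comparing a segmentation against ground-truth phase
    intervals epoch by epoch.
    """
    config = config or SegmentationConfig()
    out = np.full(len(stats), "", dtype=object)
    t0 = stats["t_start"].to_numpy()
    centres = t0 + config.epoch_s / 2.0
    for b in bouts:
        out[(centres >= b.t_start) & (centres < b.t_end)] = b.label
    return out
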