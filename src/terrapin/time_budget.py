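"""Daily time and activity budgets, aligned to each individual's laying date.

For each Night-anchored cycle the budget records per-phase durations, the
per-phase *hourly VeDBA* (time integral of VeDBA over the bout divided by
the bout duration in hours, m s⁻¹ — a constant VeDBA of 0.16 m s⁻² gives
576 m s⁻¹), the 24-h VeDBA integral, basking time and event counts.  When
phase bouts tile a cycle the per-phase integrals sum exactly to the daily
integral.

Budgets are aligned on the first successful egg laying (day offset 0) to
expose the pre- / peri- / post-nesting structure of the season.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .motion_signal import integrate_vedba

PHASES = ("Night", "Morning", "Midday", "Evening")


def budget_day(bouts, t, vedba, individual: str, cycle_date: int,
               breathing_bouts=(), basking_events=(), nesting_events=(),
               min_coverage: float = 0.8,
               nominal_dt: float | None = None) -> dict:
    """One DailyBudget row for one Night-anchored cycle.

    Parameters
    ----------
    bouts : list of PhaseBout belonging to this cycle (they tile it)
    t, vedba : 10 Hz motion series covering the cycle
    breathing_bouts, basking_events, nesting_events :
        events of this cycle; only counts/durations are used.
    min_coverage : budgets with less motion coverage are flagged partial.
    nominal_dt : nominal sampling interval used for the coverage fraction
        (default: the stream's median interval, so only gaps reduce it).
    """
    bouts = sorted(bouts, key=lambda b: b.t_start)
    c0, c1 = bouts[0].t_start, bouts[-1].t_end
    row: dict = {"individual": individual, "cycle_date": cycle_date}
    total_integral = 0.0
    for phase in PHASES:
        phase_bouts = [b for b in bouts if b.label == phase]
        dur_h = sum(b.duration_h for b in phase_bouts)
        integral = sum(
            integrate_vedba(t, vedba, b.t_start, b.t_end)
            for b in phase_bouts
        )
        total_integral += integral
        key = phase.lower()
        row[f"{key}_h"] = dur_h
        row[f"{key}_vedba_integral"] = integral
        row[f"{key}_hourly_vedba"] = integral / dur_h if dur_h > 0 else np.nan
    row["daily_vedba"] = integrate_vedba(t, vedba, c0, c1)
    row["phase_vedba_sum"] = total_integral
    row["basking_h"] = sum(
        (e.t_end - e.t_start) / 3600.0 for e in basking_events
    )
    row["n_breathing_bouts"] = len(breathing_bouts)
    row["n_inhalations"] = sum(b.n_inhalations for b in breathing_bouts)
    row["n_nesting_events"] = len(nesting_events)
    # motion coverage of the cycle at the nominal 10 Hz cadence
    tt = np.asarray(t, dtype=float)
    inside = (tt >= c0) & (tt <= c1)
    n_in = int(inside.sum())
    if nominal_dt is None:
        nominal_dt = float(np.median(np.diff(tt))) if len(tt) > 1 else np.nan
    coverage = min(1.0, n_in * nominal_dt / (c1 - c0)) if c1 > c0 else 0.0
    row["coverage"] = coverage
    row["partial"] = coverage < min_coverage
    row["complete"] = coverage >= 0.95
    row["cycle_start"] = c0
    row["cycle_end"] = c1
    return row


def align_to_laying(budgets: pd.DataFrame, nesting_events,
                    observed_times=()) -> pd.DataFrame:
    """Add ``days_from_laying`` and a pre/peri/post ``period`` per row.

    ``nesting_events`` are the detected digging events of this individual.
    An event is a *success* when flagged so, or when it brackets (within one
    day) an observed laying time from the metadata; otherwise it is an
    attempt.  Day 0 is the first success; individuals without one keep NaN
    offsets and are flagged unaligned.  The peri period spans first attempt
    to last nesting event.
    """
    out = budgets.copy()
    events = sorted(nesting_events, key=lambda e: e.t_start)
    successes = []
    for e in events:
        is_success = getattr(e, "success", False) or any(
            abs(0.5 * (e.t_start + e.t_end) - ot) <= 86400.0
            for ot in observed_times
        )
        if is_success:
            successes.append(e)
    if not successes:
        out["days_from_laying"] = np.nan
        out["period"] = "unaligned"
        out.attrs["aligned"] = False
        return out
    anchor_day = int(np.floor(successes[0].t_start / 86400.0))
    first_attempt_day = int(np.floor(events[0].t_start / 86400.0))
    last_event_day = int(np.floor(events[-1].t_end / 86400.0))
    out["days_from_laying"] = out["cycle_date"].astype(int) - anchor_day
    day = out["cycle_date"].astype(int)
    out["period"] = np.where(
        day < first_attempt_day, "pre",
        np.where(day > last_event_day, "post", "peri"),
    )
    out.attrs["aligned"] = True
    return out


def activity_temperature_relation(budgets: pd.DataFrame,
                                  daily_temp: pd.DataFrame,
                                  min_days: int = 10) -> dict:
    """Per-period OLS of daily VeDBA on daily mean air temperature.

    ``daily_temp`` has columns ``day`` and ``t_air``.  Fits are returned per
    period ('pre', 'peri', 'post') as dicts with intercept, slope, its
    standard error, r2 and n; periods with fewer than ``min_days`` matched
    days are skipped.
    """
    merged = budgets.merge(daily_temp, left_on="cycle_date", right_on="day",
                           how="inner")
    fits = {}
    for period, grp in merged.groupby("period"):
        grp = grp.dropna(subset=["daily_vedba", "t_air"])
        if len(grp) < min_days:
            continue
        res = sstats.linregress(grp["t_air"], grp["daily_vedba"])
        fits[period] = {
            "intercept": float(res.intercept),
            "slope": float(res.slope),
            "slope_se": float(res.stderr),
            "r2": float(res.rvalue ** 2),
            "n": int(len(grp)),
        }
    return fits


def hourly_vedba_temperature_profile(hourly_temp, hourly_vedba,
                                     bin_width: float = 2.0,
                                     quantile: float = 0.9) -> dict:
    """Nonlinear activity-temperature profile by temperature binning.

    Hourly VeDBA values are binned by air temperature (``bin_width`` degC)
    and the upper-decile VeDBA is reported per bin; the peak bin summarises
    where maximal activity culminates (activity rises with temperature up to
    the peak bin, then falls).
    """
    temp = np.asarray(hourly_temp, dtype=float)
    v = np.asarray(hourly_vedba, dtype=float)
    ok = np.isfinite(temp) & np.isfinite(v)
    temp, v = temp[ok], v[ok]
    if len(temp) == 0:
        raise ValueError("no paired hourly samples")
    lo = np.floor(temp.min() / bin_width) * bin_width
    bins = np.arange(lo, temp.max() + bin_width, bin_width)
    idx = np.digitize(temp, bins) - 1
    centres, upper, counts = [], [], []
    for b in range(len(bins)):
        sel = idx == b
        if sel.sum() < 5:
            continue
        centres.append(bins[b] + bin_width / 2.0)
        upper.append(float(np.quantile(v[sel], quantile)))
        counts.append(int(sel.sum()))
    if not centres:
        raise ValueError("no temperature bin has enough samples")
    peak = int(np.argmax(upper))
    return {
        "bin_centres": np.array(centres),
        "upper_decile_vedba": np.array(upper),
        "counts": np.array(counts),
        "peak_bin_centre": float(centres[peak]),
        "peak_bin_range": (float(centres[peak] - bin_width / 2.0),
                           float(centres[peak] + bin_width / 2.0)),
    }


def summarize_budgets(budgets: pd.DataFrame) -> pd.DataFrame:
    """Mean +- sd of phase durations and hourly VeDBA across all rows.

    One row per phase plus basking and daily totals — the summary companion
    of the budget table.
    """
    rows = []
    for phase in PHASES:
        key = phase.lower()
        rows.append({
            "quantity": phase,
            "duration_h_mean": budgets[f"{key}_h"].mean(),
            "duration_h_sd": budgets[f"{key}_h"].std(ddof=1),
            "hourly_vedba_mean": budgets[f"{key}_hourly_vedba"].mean(),
            "hourly_vedba_sd": budgets[f"{key}_hourly_vedba"].std(ddof=1),
            "n": int(budgets[f"{key}_h"].gt(0).sum()),
        })
    rows.append({
        "quantity": "Basking",
        "duration_h_mean": budgets["basking_h"].mean(),
        "duration_h_sd": budgets["basking_h"].std(ddof=1),
        "hourly_vedba_mean": np.nan, "hourly_vedba_sd": np.nan,
        "n": int(budgets["basking_h"].gt(0).sum()),
    })
    return pd.DataFrame(rows)


def conservation_error(row: dict | pd.Series) -> float:
    """Relative difference between the summed per-phase VeDBA integrals and
    the daily integral (0 when phase bouts tile the cycle)."""
    daily = float(row["daily_vedba"])
    if daily == 0:
        return abs(float(row["phase_vedba_sum"]))
    return abs(float(row["phase_vedba_sum"]) - daily) / abs(daily)
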