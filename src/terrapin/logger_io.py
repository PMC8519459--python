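"""Reading, writing and time alignment of logger deployments.

A deployment consists of a 1 Hz environmental stream (temperature, pressure,
light), a 10 Hz tri-axial acceleration stream, and a metadata record for one
tagged individual, plus site-level reference temperature and weather series.
All internal times are float seconds since a per-deployment epoch in UTC;
ISO-8601 timestamps in input files are converted on read.

The logger's internal real-time clock drifts slowly against true time;
:func:`correct_clock_drift` remaps timestamps through the GPS-anchored
(logger time, true time) pairs recorded at tag attachment and retrieval.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ENV_COLUMNS = ["time", "temp_c", "pressure_bar", "light_lux"]
ACCEL_COLUMNS = ["time", "ax", "ay", "az"]
REFERENCE_COLUMNS = ["time", "t_air", "t_surface", "t_20cm", "t_bottom"]
WEATHER_COLUMNS = ["time", "t_air_mulhouse", "cloud_frac", "rain_mm"]

#: temperature strata available in the reference series, in the order
#: air / water surface / water at 20 cm / pond bottom
STRATA = ("air", "surface", "20cm", "bottom")
STRATUM_COLUMNS = {
    "air": "t_air",
    "surface": "t_surface",
    "20cm": "t_20cm",
    "bottom": "t_bottom",
}


class FormatError(ValueError):
    """An input file does not match the expected delimited-text schema."""


class ConfigurationError(ValueError):
    """Deployment metadata is missing or inconsistent."""


@dataclass
class DeploymentMeta:
    """Per-deployment metadata.

    Parameters
    ----------
    individual_id : str
        Label of the tagged individual.
    body_mass_g, carapace_length_mm, logger_mass_g : float
        Biometrics and tag mass.
    rtc_anchor_pairs : list of (logger_time, true_time)
        At least two anchors spanning the record, seconds.
    observed_nesting_times : list of float
        Times (true seconds) at which the individual was seen laying,
        possibly empty.
    """

    individual_id: str
    body_mass_g: float
    carapace_length_mm: float
    logger_mass_g: float
    rtc_anchor_pairs: list = field(default_factory=list)
    observed_nesting_times: list = field(default_factory=list)

    def __post_init__(self):
        if self.body_mass_g <= 0:
            raise ConfigurationError("body_mass_g must be positive")
        if len(self.rtc_anchor_pairs) < 2:
            raise ConfigurationError(
                "at least 2 RTC anchor pairs are required for drift correction"
            )


def _parse_times(col: pd.Series) -> pd.Series:
    """Parse a time column, auto-detecting float seconds vs ISO-8601.

    Returns float seconds; ISO timestamps are converted to Unix seconds
    (UTC).  Unparseable entries become NaN and are dropped by the caller.
    """
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().mean() >= 0.5:
        return numeric
    stamps = pd.to_datetime(col, errors="coerce", utc=True, format="ISO8601")
    return (stamps - pd.Timestamp(0, tz="UTC")).dt.total_seconds()


def read_stream(path: str, columns: list[str]) -> pd.DataFrame:
    """Read one delimited logger stream, sorted and de-duplicated.

    Rows with unparseable fields are dropped and counted; duplicated
    timestamps keep the first occurrence.  Missing required columns raise
    :class:`FormatError` naming the column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for c in columns:
        if c not in df.columns:
            raise FormatError(f"missing required column {c!r} in {path}")
    df = df[columns].copy()
    df["time"] = _parse_times(df["time"])
    for c in columns[1:]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    n0 = len(df)
    df = df.dropna()
    n_dropped = n0 - len(df)
    df = df.sort_values("time", kind="mergesort")
    dup = df["time"].duplicated(keep="first")
    n_dup = int(dup.sum())
    df = df[~dup].reset_index(drop=True)
    if n_dropped:
        logger.info("%s: dropped %d unparseable rows", path, n_dropped)
    if n_dup:
        logger.info("%s: collapsed %d duplicate timestamps", path, n_dup)
    df.attrs["n_dropped"] = n_dropped
    df.attrs["n_duplicates"] = n_dup
    return df


def read_env(path: str) -> pd.DataFrame:
    return read_stream(path, ENV_COLUMNS)


def read_accel(path: str) -> pd.DataFrame:
    return read_stream(path, ACCEL_COLUMNS)


def read_reference(path: str) -> pd.DataFrame:
    return read_stream(path, REFERENCE_COLUMNS)


def read_weather(path: str) -> pd.DataFrame:
    return read_stream(path, WEATHER_COLUMNS)


def read_sun_table(path: str) -> pd.DataFrame:
    """Read the sunrise/sunset table: columns date, sunrise, sunset.

    ``date`` is an integer day index (days since deployment epoch) or an
    ISO date; sunrise/sunset are float seconds since the epoch.
    """
    df = pd.read_csv(path)
    for c in ("date", "sunrise", "sunset"):
        if c not in df.columns:
            raise FormatError(f"missing required column {c!r} in {path}")
    return df


def read_meta(path: str) -> DeploymentMeta:
    """Read one YAML metadata file into a :class:`DeploymentMeta`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return DeploymentMeta(
            individual_id=str(raw["individual_id"]),
            body_mass_g=float(raw["body_mass_g"]),
            carapace_length_mm=float(raw["carapace_length_mm"]),
            logger_mass_g=float(raw["logger_mass_g"]),
            rtc_anchor_pairs=[
                (float(a), float(b)) for a, b in raw.get("rtc_anchor_pairs", [])
            ],
            observed_nesting_times=[
                float(t) for t in raw.get("observed_nesting_times", []) or []
            ],
        )
    except KeyError as exc:  # pragma: no cover - message formatting
        raise FormatError(f"missing metadata field {exc} in {path}") from exc


def read_deployment(env_path: str, accel_path: str, meta_path: str):
    """Read one full deployment: (env stream, accel stream, metadata)."""
    env = read_env(env_path)
    accel = read_accel(accel_path)
    meta = read_meta(meta_path)
    return env, accel, meta


def correct_clock_drift(stream, rtc_anchor_pairs) -> pd.DataFrame:
    """Remap logger timestamps onto true time through the RTC anchors.

    The remapping is piecewise linear through all anchor pairs (exactly
    linear with two anchors) and linearly extrapolated beyond the outermost
    anchors with the adjacent segment's slope.  Corrected times are exact at
    every anchor.

    Parameters
    ----------
    stream : DataFrame with a ``time`` column, or 1-d array of times
    rtc_anchor_pairs : sequence of (logger_time, true_time)

    Raises
    ------
    ConfigurationError
        Fewer than two anchors, or anchors implying a non-monotone remap.
    """
    anchors = sorted((float(a), float(b)) for a, b in rtc_anchor_pairs)
    if len(anchors) < 2:
        raise ConfigurationError("drift correction needs >= 2 anchor pairs")
    lt = np.array([a for a, _ in anchors])
    tt = np.array([b for _, b in anchors])
    if np.any(np.diff(lt) <= 0) or np.any(np.diff(tt) <= 0):
        raise ConfigurationError("RTC anchors imply a non-monotone time remap")

    is_frame = isinstance(stream, pd.DataFrame)
    t = np.asarray(stream["time"], dtype=float) if is_frame else np.asarray(
        stream, dtype=float
    )
    corrected = np.interp(t, lt, tt)
    # linear extrapolation outside the anchor span
    lo = t < lt[0]
    if lo.any():
        s = (tt[1] - tt[0]) / (lt[1] - lt[0])
        corrected[lo] = tt[0] + s * (t[lo] - lt[0])
    hi = t > lt[-1]
    if hi.any():
        s = (tt[-1] - tt[-2]) / (lt[-1] - lt[-2])
        corrected[hi] = tt[-1] + s * (t[hi] - lt[-1])
    if np.any(np.diff(corrected) <= 0):
        raise ConfigurationError("corrected times are not strictly increasing")
    if is_frame:
        out = stream.copy()
        out["time"] = corrected
        return out
    return corrected


def find_gaps(times, nominal: float = 1.0, max_gap: float = 5.0):
    """Return [(t_before, t_after), ...] where the sampling gap exceeds
    ``max_gap`` seconds.  Gaps are recorded, never interpolated."""
    t = np.asarray(times, dtype=float)
    d = np.diff(t)
    idx = np.nonzero(d > max_gap)[0]
    return [(t[i], t[i + 1]) for i in idx]


def write_stream(df: pd.DataFrame, path: str) -> None:
    """Write a stream with full-precision floats (lossless text round trip)."""
    df.to_csv(path, index=False, lineterminator="\n")


def write_meta(meta: DeploymentMeta, path: str) -> None:
    raw = {
        "individual_id": meta.individual_id,
        "body_mass_g": meta.body_mass_g,
        "carapace_length_mm": meta.carapace_length_mm,
        "logger_mass_g": meta.logger_mass_g,
        "rtc_anchor_pairs": [[float(a), float(b)]
                             for a, b in meta.rtc_anchor_pairs],
        "observed_nesting_times": [float(t)
                                   for t in meta.observed_nesting_times],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


BUDGET_COLUMNS = [
    "individual", "cycle_date", "night_h", "morning_h", "midday_h",
    "evening_h", "night_hourly_vedba", "morning_hourly_vedba",
    "midday_hourly_vedba", "evening_hourly_vedba", "daily_vedba",
    "basking_h", "n_breathing_bouts", "n_inhalations", "n_nesting_events",
    "days_from_laying", "coverage", "complete",
]

EVENT_COLUMNS = [
    "individual", "type", "start", "end", "duration_s", "metric1", "metric2",
]


def write_tables(budgets: pd.DataFrame, events: pd.DataFrame, out_dir: str):
    """Write the budget and event tables with deterministic order/format.

    Re-running on the same input yields byte-identical files.  Missing
    columns are emitted empty so the schema is stable.
    """
    os.makedirs(out_dir, exist_ok=True)
    b = budgets.copy() if budgets is not None else pd.DataFrame()
    e = events.copy() if events is not None else pd.DataFrame()
    for col in BUDGET_COLUMNS:
        if col not in b.columns:
            b[col] = pd.Series(dtype=float)
    for col in EVENT_COLUMNS:
        if col not in e.columns:
            e[col] = pd.Series(dtype=float)
    b = b[BUDGET_COLUMNS].sort_values(["individual", "cycle_date"],
                                      kind="mergesort")
    e = e[EVENT_COLUMNS].sort_values(["individual", "start", "type"],
                                     kind="mergesort")
    bpath = os.path.join(out_dir, "daily_budgets.csv")
    epath = os.path.join(out_dir, "events.csv")
    b.to_csv(bpath, index=False, float_format="%.6g", lineterminator="\n")
    e.to_csv(epath, index=False, float_format="%.6g", lineterminator="\n")
    return bpath, epath
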