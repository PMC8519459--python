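"""Acceleration decomposition, VeDBA, body angles and depth conversion.

The raw tri-axial signal of a carapace-mounted tag mixes two sources: a
slowly varying *static* component due to gravity (hence posture) and a
*dynamic* component due to changes of the animal's velocity.  A zero-phase
low-pass filter separates the two; the Euclidean norm of the dynamic vector
is the Vectorial Dynamic Body Acceleration (VeDBA, m s⁻²), a standard proxy
for locomotor activity and energy expenditure.  Time-integrating VeDBA over
a window yields an activity index in m s⁻¹.

Axis convention (configurable upstream): x = surge (anterior–posterior),
y = sway (left–right), z = heave, with z reading +g when the animal is
level.  Pitch is positive nose-up; roll is positive right-side-down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

#: gravity magnitude used throughout, m s⁻²
GRAVITY = 9.81


def _sampling_rate(t: np.ndarray) -> float:
    dt = np.median(np.diff(t))
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError("cannot infer sampling rate from timestamps")
    return 1.0 / dt


def lowpass(x: np.ndarray, fs: float, window_s: float = 2.0,
            method: str = "butter") -> np.ndarray:
    """Zero-phase low-pass with cutoff 1/window_s Hz.

    ``butter``: 4th-order Butterworth applied forward-backward
    (no phase shift of features).  ``moving_average``: centred boxcar of
    ``window_s`` (config alternative).
    """
    if method == "butter":
        sos = signal.butter(4, 1.0 / window_s, btype="low", fs=fs,
                            output="sos")
        return signal.sosfiltfilt(sos, x)
    if method == "moving_average":
        n = max(1, int(round(window_s * fs)))
        return uniform_filter1d(np.asarray(x, dtype=float), size=n,
                                mode="nearest")
    raise ValueError(f"unknown low-pass method {method!r}")


def decompose(t, ax, ay, az, window_s: float = 2.0, method: str = "butter"):
    """Split raw acceleration into static (low-pass) and dynamic parts.

    Returns ``(static, dynamic, edge_mask)`` where static and dynamic are
    (n, 3) arrays with ``static + dynamic == raw`` exactly per sample, and
    ``edge_mask`` flags one filter window at each end of the stream where
    the zero-phase filter's transient is not trustworthy.

    Raises ``ValueError`` if the stream is shorter than 4 windows.
    """
    t = np.asarray(t, dtype=float)
    raw = np.column_stack([np.asarray(a, dtype=float) for a in (ax, ay, az)])
    fs = _sampling_rate(t)
    if len(t) < 4 * window_s * fs:
        raise ValueError(
            f"stream of {len(t)} samples is shorter than 4 x {window_s} s "
            f"at {fs:.1f} Hz"
        )
    static = np.column_stack(
        [lowpass(raw[:, i], fs, window_s, method) for i in range(3)]
    )
    dynamic = raw - static
    edge = np.zeros(len(t), dtype=bool)
    n_edge = int(round(window_s * fs))
    edge[:n_edge] = True
    edge[len(t) - n_edge:] = True
    return static, dynamic, edge


def vedba(dyn_x, dyn_y, dyn_z) -> np.ndarray:
    """Vectorial dynamic body acceleration: Euclidean norm of the dynamic
    vector, m s⁻² (the standard VeDBA)."""
    return np.sqrt(
        np.square(np.asarray(dyn_x, dtype=float))
        + np.square(np.asarray(dyn_y, dtype=float))
        + np.square(np.asarray(dyn_z, dtype=float))
    )


def odba(dyn_x, dyn_y, dyn_z) -> np.ndarray:
    """Manhattan-sum alternative metric (ODBA); off by default downstream."""
    return (np.abs(np.asarray(dyn_x, dtype=float))
            + np.abs(np.asarray(dyn_y, dtype=float))
            + np.abs(np.asarray(dyn_z, dtype=float)))


def integrate_vedba(t, v, t_start: float, t_end: float) -> float:
    """Trapezoidal time integral of VeDBA over [t_start, t_end], m s⁻¹.

    Endpoints inside the sampling span are linearly interpolated so the
    integral is exactly additive over adjacent intervals.  A constant VeDBA
    of ``c`` over one hour integrates to ``c * 3600``.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")
    if t_start < t[0] or t_end > t[-1]:
        raise ValueError("integration interval exceeds series coverage")
    i0, i1 = np.searchsorted(t, [t_start, t_end])
    tt = np.concatenate(([t_start], t[i0:i1], [t_end]))
    vv = np.concatenate((
        [np.interp(t_start, t, v)], v[i0:i1], [np.interp(t_end, t, v)]
    ))
    keep = np.concatenate(([True], np.diff(tt) > 0))
    return float(np.trapezoid(vv[keep], tt[keep]))


def angles(static_x, static_y, static_z, min_norm_frac: float = 0.1):
    """Pitch and roll (degrees) from the static (gravity) vector.

    pitch = atan2(surge, hypot(sway, heave)), positive nose-up, in
    [-90, 90]; roll = atan2(sway, heave) in (-180, 180].  Samples whose
    static norm is below ``min_norm_frac * g`` have undefined posture: they
    are returned as NaN together with a boolean flag array (no exception).
    """
    sx = np.asarray(static_x, dtype=float)
    sy = np.asarray(static_y, dtype=float)
    sz = np.asarray(static_z, dtype=float)
    norm = np.sqrt(sx * sx + sy * sy + sz * sz)
    flagged = norm < min_norm_frac * GRAVITY
    pitch = np.degrees(np.arctan2(sx, np.hypot(sy, sz)))
    roll = np.degrees(np.arctan2(sy, sz))
    pitch = np.where(flagged, np.nan, pitch)
    roll = np.where(flagged, np.nan, roll)
    return pitch, roll, flagged


def posture_to_gravity(pitch_deg, roll_deg, g: float = GRAVITY):
    """Inverse of :func:`angles`: the static vector of a posture.

    Useful for constructing synthetic postures;
    ``angles(*posture_to_gravity(p, r))`` recovers (p, r) for |p| < 90.
    """
    p = np.radians(np.asarray(pitch_deg, dtype=float))
    r = np.radians(np.asarray(roll_deg, dtype=float))
    sx = g * np.sin(p)
    sy = g * np.cos(p) * np.sin(r)
    sz = g * np.cos(p) * np.cos(r)
    return sx, sy, sz


def pressure_to_depth(pressure_bar, return_clipped: bool = False):
    """Surface-referenced pressure (bar) to depth in cm: 0.1 bar = 1 m.

    depth_cm = 1000 x P.  Negative pressures (sensor noise above the
    surface) are clipped to 0; pass ``return_clipped=True`` to also get the
    flag mask.
    """
    p = np.asarray(pressure_bar, dtype=float)
    depth = p * 1000.0
    clipped = depth < 0
    depth = np.where(clipped, 0.0, depth)
    if np.ndim(pressure_bar) == 0:
        depth = float(depth)
        clipped = bool(clipped)
    if return_clipped:
        return depth, clipped
    return depth


@dataclass
class MotionSeries:
    """Per-sample 10 Hz motion quantities for one deployment."""

    t: np.ndarray
    static: np.ndarray   # (n, 3)
    dynamic: np.ndarray  # (n, 3)
    vedba: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    edge_mask: np.ndarray
    low_g_mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.t,
            "static_x": self.static[:, 0],
            "static_y": self.static[:, 1],
            "static_z": self.static[:, 2],
            "dyn_x": self.dynamic[:, 0],
            "dyn_y": self.dynamic[:, 1],
            "dyn_z": self.dynamic[:, 2],
            "vedba": self.vedba,
            "pitch_deg": self.pitch,
            "roll_deg": self.roll,
            "edge": self.edge_mask,
            "low_g": self.low_g_mask,
        })


def minute_summary(ms: "MotionSeries") -> pd.DataFrame:
    """Decimated 1-min summaries: mean VeDBA, mean pitch/roll per minute."""
    minute = np.floor(ms.t / 60.0).astype(np.int64)
    df = pd.DataFrame({
        "minute": minute, "vedba": ms.vedba, "pitch_deg": ms.pitch,
        "roll_deg": ms.roll,
    })
    out = df.groupby("minute").mean()
    out.index = out.index * 60.0
    return out.reset_index(names="time")


def motion_series(accel: pd.DataFrame, window_s: float = 2.0,
                  method: str = "butter",
                  axis_map: tuple = ("ax", "ay", "az")) -> MotionSeries:
    """Full decomposition of an acceleration stream into a MotionSeries.

    ``axis_map`` names the columns carrying the surge, sway and heave axes
    in that order — the logger-to-anatomy mapping is hardware-dependent and
    defaults to (ax, ay, az).
    """
    t = np.asarray(accel["time"], dtype=float)
    sx, sy, sz = (accel[c] for c in axis_map)
    static, dynamic, edge = decompose(t, sx, sy, sz, window_s, method)
    v = vedba(dynamic[:, 0], dynamic[:, 1], dynamic[:, 2])
    pitch, roll, lowg = angles(static[:, 0], static[:, 1], static[:, 2])
    return MotionSeries(t, static, dynamic, v, pitch, roll, edge, lowg)
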