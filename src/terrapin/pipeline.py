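"""End-to-end annotation of one deployment.

Glue over the analysis modules: drift-correct both streams, segment the
24-h cycles, run the event detectors per phase, infer the Night stratum
from temperature matching and assemble daily budgets.  Used by the CLI and
by the acceptance evaluation; each stage remains individually importable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import depth_inference, event_detection, phase_segmentation
from .logger_io import DeploymentMeta, correct_clock_drift
from .motion_signal import motion_series
from .phase_segmentation import SegmentationConfig, bouts_to_frame
from .time_budget import align_to_laying, budget_day


@dataclass
class AnnotationResult:
    individual: str
    bouts: pd.DataFrame
    budgets: pd.DataFrame
    breathing_bouts: list = field(default_factory=list)
    basking_events: list = field(default_factory=list)
    diving_events: list = field(default_factory=list)
    nesting_events: list = field(default_factory=list)
    strata: pd.DataFrame | None = None
    epoch_stats: pd.DataFrame | None = None
    epoch_labels: np.ndarray | None = None
    flags: dict = field(default_factory=dict)


def _slice(t, *arrays, t0, t1):
    i0, i1 = np.searchsorted(t, [t0, t1])
    return (t[i0:i1], *(a[i0:i1] for a in arrays))


def annotate_individual(env: pd.DataFrame, accel: pd.DataFrame,
                        meta: DeploymentMeta,
                        reference: pd.DataFrame | None = None,
                        seg_config: SegmentationConfig | None = None,
                        keep_epochs: bool = False) -> AnnotationResult:
    """Annotate one individual's deployment end to end."""
    cfg = seg_config or SegmentationConfig()
    env = correct_clock_drift(env, meta.rtc_anchor_pairs)
    accel = correct_clock_drift(accel, meta.rtc_anchor_pairs)

    stats = phase_segmentation.epoch_stats(env, cfg)
    raw_labels = phase_segmentation.classify_epochs(stats, cfg)
    bouts, flags = phase_segmentation.segment_cycles(stats, raw_labels, cfg)

    ms = motion_series(accel)
    t10, vedba, pitch, roll, edge = (ms.t, ms.vedba, ms.pitch, ms.roll,
                                     ms.edge_mask)
    del ms  # free the static/dynamic components early

    tenv = env["time"].to_numpy(dtype=float)
    temp = env["temp_c"].to_numpy(dtype=float)
    pres = env["pressure_bar"].to_numpy(dtype=float)

    breathing, basking, dives = [], [], []
    strata_rows = []
    for b in bouts:
        if b.label == "Night":
            ts, ps = _slice(tenv, pres, t0=b.t_start, t1=b.t_end)
            inh = event_detection.detect_inhalations(ts, ps)
            breathing += event_detection.group_breathing_bouts(inh)
            if reference is not None and len(ts) >= 30:
                _, tt = _slice(tenv, temp, t0=b.t_start, t1=b.t_end)[0:2]
                try:
                    win, _, amb = depth_inference.best_stratum(
                        ts, tt, reference
                    )
                    strata_rows.append({
                        "individual": meta.individual_id,
                        "cycle_date": b.cycle_date, "phase": b.label,
                        "stratum": win.stratum, "intercept": win.intercept,
                        "slope": win.slope, "r2": win.r2,
                        "ambiguous": amb,
                    })
                except (depth_inference.DegenerateFitError, ValueError):
                    pass
        elif b.label == "Midday":
            ts, tt, ps = _slice(tenv, temp, pres, t0=b.t_start, t1=b.t_end)
            basking += event_detection.detect_basking(ts, tt)
            dives += event_detection.detect_dives(ts, tt, ps)

    nesting = event_detection.detect_nesting(
        t10, pitch, roll, vedba=vedba, exclude_mask=edge
    )
    for e in nesting:
        mid = 0.5 * (e.t_start + e.t_end)
        for b in bouts:
            if b.t_start <= mid < b.t_end:
                e.phase_label = b.label
                break
        e.success = any(
            abs(mid - ot) <= 86400.0 for ot in meta.observed_nesting_times
        )

    # budgets: one row per Night-anchored cycle
    budget_rows = []
    cycle: list = []
    for b in bouts:
        if b.label == "Night" and cycle:
            budget_rows.append(_cycle_budget(cycle, t10, vedba, meta,
                                             breathing, basking, nesting))
            cycle = []
        cycle.append(b)
    if cycle and len(cycle) > 1:
        budget_rows.append(_cycle_budget(cycle, t10, vedba, meta,
                                         breathing, basking, nesting))
    budgets = pd.DataFrame(budget_rows)
    if len(budgets):
        budgets = align_to_laying(budgets, nesting,
                                  meta.observed_nesting_times)

    return AnnotationResult(
        individual=meta.individual_id,
        bouts=bouts_to_frame(bouts, meta.individual_id),
        budgets=budgets,
        breathing_bouts=breathing,
        basking_events=basking,
        diving_events=dives,
        nesting_events=nesting,
        strata=pd.DataFrame(strata_rows) if strata_rows else None,
        epoch_stats=stats if keep_epochs else None,
        epoch_labels=(
            phase_segmentation.labels_from_bouts(bouts, stats, cfg)
            if keep_epochs else None
        ),
        flags=flags,
    )


def _cycle_budget(cycle_bouts, t10, vedba, meta, breathing, basking,
                  nesting):
    c0 = cycle_bouts[0].t_start
    c1 = cycle_bouts[-1].t_end
    t0c, t1c = max(c0, t10[0]), min(c1, t10[-1])
    # clip bouts to motion coverage so integration stays in range
    clipped = []
    for b in cycle_bouts:
        s, e = max(b.t_start, t0c), min(b.t_end, t1c)
        if e > s:
            clipped.append(phase_segmentation.PhaseBout(b.label, s, e,
                                                        b.cycle_date))
    inside = lambda t: c0 <= t < c1  # noqa: E731
    return budget_day(
        clipped, t10, vedba,
        individual=meta.individual_id,
        cycle_date=cycle_bouts[0].cycle_date,
        breathing_bouts=[x for x in breathing if inside(x.t_start)],
        basking_events=[x for x in basking if inside(x.t_start)],
        nesting_events=[x for x in nesting if inside(x.t_start)],
    )


def events_to_frame(result: AnnotationResult) -> pd.DataFrame:
    """Flatten all detected events into the common event table schema."""
    rows = []
    for b in result.breathing_bouts:
        rows.append((result.individual, "breathing_bout", b.t_start, b.t_end,
                     b.duration_s, b.n_inhalations, np.nan))
    for e in result.basking_events:
        rows.append((result.individual, "basking", e.t_start, e.t_end,
                     e.t_end - e.t_start, e.delta_t, np.nan))
    for e in result.diving_events:
        rows.append((result.individual, "diving", e.t_start, e.t_end,
                     e.t_end - e.t_start, e.delta_t,
                     0.0 if e.trigger == "temperature" else 1.0))
    for e in result.nesting_events:
        rows.append((result.individual, "nesting", e.t_start, e.t_end,
                     e.t_end - e.t_start, e.mean_vedba,
                     1.0 if e.success else 0.0))
    return pd.DataFrame(rows, columns=["individual", "type", "start", "end",
                                       "duration_s", "metric1", "metric2"])
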