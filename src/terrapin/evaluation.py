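"""Detector-recovery evaluation on labelled synthetic deployments.

Runs the full annotation pipeline over a generated deployment one animal at
a time and scores it against the generator's ground truth: per-epoch phase
accuracy, breathing-bout confusion, nest-digging recall and false alarms,
budget conservation, and the headline field-style summaries (night depth,
surfacing rise, bout structure, state VeDBA levels).
"""

from __future__ import annotations

import numpy as np

from . import event_detection
from .phase_segmentation import SegmentationConfig
from .pipeline import annotate_individual
from .synthetic_data import GeneratorConfig, SyntheticDeployment, generate
from .time_budget import conservation_error


def _truth_epoch_labels(phases, stats, epoch_s=60.0):
    out = np.full(len(stats), "", dtype=object)
    centres = stats["t_start"].to_numpy() + epoch_s / 2.0
    for row in phases.itertuples(index=False):
        out[(centres >= row.t_start) & (centres < row.t_end)] = row.phase
    return out


def evaluate_deployment(config: GeneratorConfig | None = None,
                        seed: int = 0,
                        dep: SyntheticDeployment | None = None) -> dict:
    """Generate (or accept) a deployment, annotate it and score recovery."""
    dep = dep or generate(config or GeneratorConfig(), seed)
    cfg = dep.config
    truth = dep.truth

    epoch_match = 0
    epoch_total = 0
    bt_tp = bt_fp = bt_fn = 0
    truth_bouts_total = 0
    dig_truth_total = dig_truth_hit = 0
    false_dig_days = 0
    cons_errors = []
    night_h = []
    night_pressure_means = []
    rises_all = []
    inhal_rises = []
    bout_durations = []
    bout_sizes = []
    bouts_per_night = []
    dig_vedba = []
    dig_durations_min = []
    daily_mean_vedba = []
    basking_detected_s = 0.0
    basking_truth_s = 0.0
    n_attempts = []

    for i, meta in enumerate(dep.meta):
        ind = meta.individual_id
        env = dep.env_stream(i)
        accel = dep.accel_stream(i)
        res = annotate_individual(env, accel, meta,
                                  reference=dep.reference,
                                  keep_epochs=True)
        del accel

        # ---- phase accuracy over epochs covered by both labellings ----
        tp = truth.phases[truth.phases["individual"] == ind]
        t_lab = _truth_epoch_labels(tp, res.epoch_stats)
        d_lab = res.epoch_labels
        both = (t_lab != "") & (d_lab != "")
        epoch_match += int((t_lab[both] == d_lab[both]).sum())
        epoch_total += int(both.sum())

        # ---- breathing bouts ----
        tb = truth.breathing_bouts[truth.breathing_bouts["individual"] == ind]
        truth_iv = list(zip(tb["t_start"], tb["t_end"]))
        det_iv = [(b.t_start, b.t_end) for b in res.breathing_bouts]
        conf = event_detection.validate_detections(det_iv, truth_iv)
        bt_tp += conf["tp"]
        bt_fp += conf["fp"]
        bt_fn += conf["fn"]
        truth_bouts_total += len(truth_iv)

        # ---- digging ----
        td = truth.digs[truth.digs["individual"] == ind]
        n_attempts.append(len(td))
        det_digs = [(e.t_start, e.t_end) for e in res.nesting_events]
        for row in td.itertuples(index=False):
            if row.duration_min >= 30.0:
                dig_truth_total += 1
                if any(s <= row.t_end and row.t_start <= e
                       for s, e in det_digs):
                    dig_truth_hit += 1
        dig_days = set(int(d // 86400) for d in td["t_start"])
        for s, e in det_digs:
            day = int((0.5 * (s + e)) // 86400)
            if day not in dig_days and (day - 1) not in dig_days:
                false_dig_days += 1
        dig_vedba += [e.mean_vedba for e in res.nesting_events]
        dig_durations_min += [e.duration_min for e in res.nesting_events]

        # ---- budgets ----
        if len(res.budgets):
            cons_errors += [conservation_error(r)
                            for _, r in res.budgets.iterrows()]
            # boundary-truncated nights (censored by the record edges) are
            # excluded from the duration statistic
            full = res.budgets["cycle_start"] > 60.0
            night_h += res.budgets.loc[full, "night_h"].dropna().tolist()
            daily = res.budgets
            dur_h = (daily["cycle_end"] - daily["cycle_start"]) / 3600.0
            daily_mean_vedba += (daily["daily_vedba"] / (dur_h * 3600.0)
                                 ).tolist()
            bouts_per_night += res.budgets["n_breathing_bouts"].tolist()

        # ---- breathing summaries ----
        if res.breathing_bouts:
            rises, _ = event_detection.breathing_rise_stats(
                res.breathing_bouts
            )
            rises_all += rises.tolist()
            inhal_rises += [e.rise_cm for b in res.breathing_bouts
                            for e in b.inhalations]
            bout_durations += [b.duration_s for b in res.breathing_bouts
                               if b.n_inhalations > 1]
            bout_sizes += [b.n_inhalations for b in res.breathing_bouts]
        night_rows = res.bouts[res.bouts["label"] == "Night"]
        tenv = np.interp(env["time"].to_numpy(),
                         [m[0] for m in meta.rtc_anchor_pairs],
                         [m[1] for m in meta.rtc_anchor_pairs])
        pres = env["pressure_bar"].to_numpy()
        for row in night_rows.itertuples(index=False):
            i0, i1 = np.searchsorted(tenv, [row.t_start, row.t_end])
            if i1 > i0:
                night_pressure_means.append(float(pres[i0:i1].mean()))
        del env

        # ---- basking time ----
        th = truth.heating[truth.heating["individual"] == ind]
        basking_truth_s += float((th["t_end"] - th["t_start"]).sum())
        basking_detected_s += sum(e.t_end - e.t_start
                                  for e in res.basking_events)

    out = {
        "n_individuals": cfg.n_individuals,
        "n_days": cfg.n_days,
        "phase_epoch_accuracy_pct": 100.0 * epoch_match / max(1, epoch_total),
        "n_epochs_scored": epoch_total,
        "breathing_bout_fp_pct": round(100.0 * bt_fp / max(1, bt_tp + bt_fp),
                                       1),
        "breathing_bout_fn_pct": round(100.0 * bt_fn / max(1, bt_tp + bt_fn),
                                       1),
        "breathing_bout_recall_pct":
            100.0 * (truth_bouts_total - bt_fn) / max(1, truth_bouts_total),
        "n_truth_breathing_bouts": truth_bouts_total,
        "dig_events_total": dig_truth_total,
        "dig_detection_pct":
            100.0 * dig_truth_hit / max(1, dig_truth_total),
        "false_dig_detections_on_digfree_days": false_dig_days,
        "max_conservation_rel_error": float(np.max(cons_errors))
            if cons_errors else float("nan"),
        "night_duration_mean_h": float(np.mean(night_h)) if night_h
            else float("nan"),
        "night_pressure_mean_bar": float(np.mean(night_pressure_means))
            if night_pressure_means else float("nan"),
        "breathing_bout_rise_mean_cm": float(np.mean(rises_all))
            if rises_all else float("nan"),
        "inhalation_rise_mean_cm": float(np.mean(inhal_rises))
            if inhal_rises else float("nan"),
        "breathing_bout_duration_mean_s": float(np.mean(bout_durations))
            if bout_durations else float("nan"),
        "inhalations_per_bout_mean": float(np.mean(bout_sizes))
            if bout_sizes else float("nan"),
        "breathing_bouts_per_night_mean": float(np.mean(bouts_per_night))
            if bouts_per_night else float("nan"),
        "dig_mean_vedba": float(np.mean(dig_vedba)) if dig_vedba
            else float("nan"),
        "dig_duration_mean_min": float(np.mean(dig_durations_min))
            if dig_durations_min else float("nan"),
        "overall_mean_vedba": float(np.mean(daily_mean_vedba))
            if daily_mean_vedba else float("nan"),
        "nesting_attempts_mean": float(np.mean(n_attempts)) if n_attempts
            else float("nan"),
        "basking_time_ratio": basking_detected_s / basking_truth_s
            if basking_truth_s else float("nan"),
    }
    return out
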