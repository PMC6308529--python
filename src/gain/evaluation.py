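"""Leave-one-subject-out evaluation of gait inference and recognition.

The protocol holds out each participant in turn, trains on the rest, and
aggregates: mean absolute shank-angle error in degrees (overall, per
activity, per gait phase, around activity transitions), event-level
precision/recall/F1 for intention recognition, and detection latency.
Aggregate errors are unweighted means over folds; per-activity errors pool
frames across participants and the headline figure is the unweighted mean
across activities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import compute_angular_series
from .gait_inference import GaitLstmRegressor, train_gait_model
from .io_hugadb import ACTIVITIES, ACTIVITY_CODES, RawRecording, scale_raw
from .recognition import (
    ContextWindowGmmClassifier,
    calibrate_threshold,
    event_decisions_metrics,
)
from .features import raw_feature_columns, fit_minmax_bounds, apply_minmax

#: Activities over which gait inference is trained and scored.
GAIT_ACTIVITIES = ("walking", "running", "going_up", "going_down", "standing")
#: Activities considered in the transition-error analysis.
TRANSITION_ACTIVITIES = GAIT_ACTIVITIES


@dataclass
class PRF:
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


@dataclass
class EvalReport:
    per_fold_mae: dict[str, float] = field(default_factory=dict)
    overall_mae: float = float("nan")
    per_activity: dict[str, tuple[float, float]] = field(default_factory=dict)
    activity_mean: float = float("nan")
    phase_errors: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    transition_errors: dict[tuple[str, str], tuple[float, float, int]] = field(
        default_factory=dict
    )
    transition_mean: float = float("nan")
    classification: dict[str, dict[str, PRF]] = field(default_factory=dict)
    classification_mean: dict[str, PRF] = field(default_factory=dict)
    latency_s: dict[str, list[float]] = field(default_factory=dict)
    missed_events: dict[str, int] = field(default_factory=dict)


def loso_folds(participants: list[str]) -> list[tuple[list[str], str]]:
    """One (train, test) split per participant."""
    participants = list(participants)
    if len(participants) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 participants")
    return [
        ([p for p in participants if p != test], test)
        for test in participants
    ]


def mean_abs_degree_error(
    true: np.ndarray, pred: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Mean and population STD of |true - pred| over masked frames."""
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if len(true) != len(pred):
        raise ValueError("length mismatch")
    err = np.abs(true - pred)
    if mask is not None:
        err = err[np.asarray(mask, dtype=bool)]
    if len(err) == 0:
        raise ValueError("empty frame selection")
    return float(err.mean()), float(err.std())


def precision_recall_f1(tp: int, fp: int, fn: int) -> PRF:
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        return PRF(precision, recall, 0.0, True)
    f1 = 2 * precision * recall / (precision + recall)
    return PRF(precision, recall, f1, degenerate)


def segment_phases(
    shank_angle: np.ndarray, smooth_window: int = 5, min_run: int = 3
) -> np.ndarray:
    """Label frames stance (0) / swing (1) from the sign of the slope.

    Upward segments of the shank angle are swing, downward segments
    stance; zero-slope frames inherit the previous phase (stance at the
    very start); runs shorter than ``min_run`` merge into their left
    neighbor.
    """
    x = np.asarray(shank_angle, dtype=float)
    if len(x) <= smooth_window:
        raise ValueError("series too short to segment")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.convolve(x, kernel, mode="same")
        den = np.convolve(np.ones_like(x), kernel, mode="same")
        sm = sm / den
    else:
        sm = x
    d = np.diff(sm)
    labels = np.empty(len(x), dtype=int)
    prev = 0  # stance by convention until the first defined slope
    labels[0] = prev
    for t in range(1, len(x)):
        if d[t - 1] > 0:
            prev = 1
        elif d[t - 1] < 0:
            prev = 0
        labels[t] = prev
    # merge short runs into the preceding run
    if min_run > 1:
        boundaries = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(labels)]])
        for s, e in zip(starts, ends):
            if e - s < min_run and s > 0:
                labels[s:e] = labels[s - 1]
    return labels


def transition_error(
    true: np.ndarray,
    pred: np.ndarray,
    labels: np.ndarray,
    halfwidth: int = 15,
) -> dict[tuple[str, str], tuple[float, float, int]]:
    """Per ordered activity pair, |true-pred| stats over +-halfwidth frames
    around each true label change between gait activities."""
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels)
    gait_codes = {ACTIVITY_CODES[a] for a in TRANSITION_ACTIVITIES}
    pooled: dict[tuple[str, str], list[np.ndarray]] = {}
    for t in np.flatnonzero(np.diff(labels)) + 1:
        a, b = int(labels[t - 1]), int(labels[t])
        if a not in gait_codes or b not in gait_codes:
            continue
        lo, hi = max(0, t - halfwidth), min(len(true), t + halfwidth + 1)
        pooled.setdefault((ACTIVITIES[a], ACTIVITIES[b]), []).append(
            np.abs(true[lo:hi] - pred[lo:hi])
        )
    return {
        pair: (float(np.concatenate(vals).mean()), float(np.concatenate(vals).std()), len(vals))
        for pair, vals in pooled.items()
    }


def detection_latency(
    true_events: list[tuple[int, int]],
    decisions: np.ndarray,
    fs: float,
    slack: int = 0,
) -> tuple[list[float], int]:
    """Per-event lag in seconds from onset to the first positive decision
    inside the event span (extended by ``slack`` trailing frames for the
    recognizer's lag); undetected events are counted separately."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    decisions = np.asarray(decisions, dtype=bool)
    lags: list[float] = []
    missed = 0
    for start, end in true_events:
        end = min(len(decisions), end + slack)
        hits = np.flatnonzero(decisions[start:end])
        if hits.size:
            lags.append(float(hits[0]) / fs)
        else:
            missed += 1
    return lags, missed


# ---------------------------------------------------------------------------
# Full LOSO pipelines on in-memory cohorts


def _gait_xy(rec: RawRecording, truth=None):
    """Model inputs/targets for gait inference from one recording.

    Inputs are always sensor-derived; targets come from the shank sensors,
    while scoring may use ground-truth angles when available.
    """
    scaled = scale_raw(rec)
    ang = compute_angular_series(scaled)
    X = np.column_stack([ang.theta_L, ang.theta_R, ang.omega_TL, ang.omega_TR])
    y = np.column_stack([ang.phi_L, ang.phi_R])
    return X, y, ang


def _gait_mask(labels: np.ndarray) -> np.ndarray:
    codes = {ACTIVITY_CODES[a] for a in GAIT_ACTIVITIES}
    return np.isin(labels, list(codes))


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    mask = np.asarray(mask, dtype=bool)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [len(mask)]])
    return list(zip(starts, ends))


def run_loso_gait_evaluation(
    cohort: list,
    seed: int = 0,
    model_config: dict | None = None,
    use_truth_targets_for_scoring: bool = True,
) -> EvalReport:
    """LOSO-train the gait model and collect degree-error statistics.

    ``cohort`` is a list of ``(participant_id, RawRecording, GroundTruth
    or None)``.  Scoring uses the ground-truth shank angles when present,
    otherwise the sensor-derived ones.
    """
    report = EvalReport()
    prepared = {}
    for pid, rec, truth in cohort:
        X, y, _ = _gait_xy(rec)
        mask = _gait_mask(rec.labels)
        runs = _contiguous_runs(mask)
        prepared[pid] = {
            "X": X, "y": y, "labels": np.asarray(rec.labels), "runs": runs,
            "truth": truth, "fs": rec.fs,
        }
    fold_maes = []
    pooled_by_activity: dict[str, list[np.ndarray]] = {}
    pooled_by_phase: dict[str, dict[str, list[np.ndarray]]] = {
        "stance": {}, "swing": {}
    }
    pooled_transitions: dict[tuple[str, str], list[tuple[float, float, int]]] = {}
    trans_frames: dict[tuple[str, str], list[np.ndarray]] = {}
    for train_ids, test_id in loso_folds(list(prepared)):
        X_parts, y_parts, lengths, groups = [], [], [], []
        for pid in train_ids:
            d = prepared[pid]
            for s, e in d["runs"]:
                X_parts.append(d["X"][s:e])
                y_parts.append(d["y"][s:e])
                lengths.append(e - s)
                groups.append(pid)
        model = GaitLstmRegressor(random_state=seed, **(model_config or {}))
        model.fit(np.concatenate(X_parts), np.concatenate(y_parts),
                  lengths=lengths, groups=groups)
        d = prepared[test_id]
        model.reset_state()
        pred = model.predict(d["X"])
        if use_truth_targets_for_scoring and d["truth"] is not None:
            true = np.column_stack([d["truth"].phi_L, d["truth"].phi_R])
        else:
            true = d["y"]
        mask = _gait_mask(d["labels"])
        err_both = []
        for leg in (0, 1):
            err_both.append(np.abs(true[:, leg] - pred[:, leg]))
        err = np.mean(err_both, axis=0)
        fold_mae = float(err[mask].mean())
        report.per_fold_mae[test_id] = fold_mae
        fold_maes.append(fold_mae)
        # per-activity pooling (frames across users)
        for act in GAIT_ACTIVITIES:
            sel = d["labels"] == ACTIVITY_CODES[act]
            if sel.any():
                pooled_by_activity.setdefault(act, []).append(err[sel])
        # per-phase pooling over locomotion activities, per leg
        for leg, col in ((0, "phi_L"), (1, "phi_R")):
            phases = segment_phases(true[:, leg])
            for act in ("walking", "running", "going_up", "going_down"):
                sel = d["labels"] == ACTIVITY_CODES[act]
                if not sel.any():
                    continue
                for code, name in ((0, "stance"), (1, "swing")):
                    m = sel & (phases == code)
                    if m.any():
                        pooled_by_phase[name].setdefault(act, []).append(err_both[leg][m])
        # transition windows
        tr = transition_error(true[:, 1], pred[:, 1], d["labels"])
        for pair, (mean, std, cnt) in tr.items():
            pooled_transitions.setdefault(pair, []).append((mean, std, cnt))
        for t in np.flatnonzero(np.diff(d["labels"])) + 1:
            a, b = int(d["labels"][t - 1]), int(d["labels"][t])
            names = ACTIVITIES.get(a), ACTIVITIES.get(b)
            if names[0] in TRANSITION_ACTIVITIES and names[1] in TRANSITION_ACTIVITIES:
                lo, hi = max(0, t - 15), min(len(err), t + 16)
                trans_frames.setdefault(names, []).append(err[lo:hi])
    report.overall_mae = float(np.mean(fold_maes))
    for act, chunks in pooled_by_activity.items():
        allv = np.concatenate(chunks)
        report.per_activity[act] = (float(allv.mean()), float(allv.std()))
    report.activity_mean = float(np.mean([m for m, _ in report.per_activity.values()]))
    for phase_name, by_act in pooled_by_phase.items():
        report.phase_errors[phase_name] = {
            act: (float(np.concatenate(chunks).mean()), float(np.concatenate(chunks).std()))
            for act, chunks in by_act.items()
        }
    for pair, chunks in trans_frames.items():
        allv = np.concatenate(chunks)
        report.transition_errors[pair] = (float(allv.mean()), float(allv.std()), len(chunks))
    if report.transition_errors:
        report.transition_mean = float(
            np.mean([m for m, _, _ in report.transition_errors.values()])
        )
    return report


def _intention_setup(kind: str):
    if kind == "stand_up":
        return "standing_up", "sitting", ("sitting",)
    return "sitting_down", "standing", ("standing", "walking")


def _context_mask(labels: np.ndarray, kind: str) -> np.ndarray:
    """Frames on which the module operates (the controller gates each
    intention recognizer by posture: stand-up only while sitting, sit-down
    only while standing or in locomotion)."""
    labels = np.asarray(labels)
    if kind == "stand_up":
        acts = ("sitting", "standing_up")
    else:
        acts = ("standing", "sitting_down", "walking", "running", "going_up", "going_down")
    return np.isin(labels, [ACTIVITY_CODES[a] for a in acts])


def intention_frames(rec: RawRecording, truth, kind: str):
    """Feature matrix and class labels for one intention module."""
    scaled = scale_raw(rec)
    feat_kind, _, neg_activities = _intention_setup(kind)
    raw = raw_feature_columns(scaled, feat_kind)
    spans = truth.intention_spans[kind]
    labels = np.asarray(rec.labels)
    y = np.full(len(labels), "", dtype=object)
    for act in neg_activities:
        y[labels == ACTIVITY_CODES[act]] = "other" if kind == "sit_down" else "sitting"
    for s, e in spans:
        y[s:e] = "intention"
    return raw, y


def run_loso_intention_evaluation(
    cohort: list,
    kind: str = "sit_down",
    seed: int = 0,
    target_precision: float = 0.99,
    match_slack: int = 30,
) -> dict:
    """LOSO evaluation of one intention-recognition module.

    Per fold: fit the per-class mixtures and feature scaling on the
    training subjects, calibrate the decision threshold for the target
    event precision on the training traces, then score the held-out
    subject's events.  Returns pooled event counts, precision/recall/F1,
    latencies and the per-fold thresholds.
    """
    module_kind = "standing_up" if kind == "stand_up" else "sitting_down"
    prepared = {}
    for pid, rec, truth in cohort:
        raw, y = intention_frames(rec, truth, kind)
        prepared[pid] = {
            "raw": raw, "y": y, "spans": truth.intention_spans[kind], "fs": rec.fs,
            "context": _context_mask(rec.labels, kind),
        }
    tp = fp = fn = 0
    lags_all: list[float] = []
    thresholds = {}
    for train_ids, test_id in loso_folds(list(prepared)):
        train_raw = [prepared[p]["raw"] for p in train_ids]
        bounds = fit_minmax_bounds(pd.concat(train_raw, ignore_index=True))
        X_parts, y_parts = [], []
        for p in train_ids:
            Xp = apply_minmax(prepared[p]["raw"], bounds).to_numpy()
            yp = prepared[p]["y"]
            keep = yp != ""
            X_parts.append(Xp[keep])
            y_parts.append(yp[keep])
        clf = ContextWindowGmmClassifier(module_kind=module_kind, random_state=seed)
        clf.fit(np.concatenate(X_parts), np.concatenate(y_parts))
        # calibrate on full (unfiltered) training traces
        cal_scores, cal_spans = [], []
        for p in train_ids:
            Xp = apply_minmax(prepared[p]["raw"], bounds).to_numpy()
            sc = clf.decision_score(Xp, "intention")
            sc[~prepared[p]["context"]] = -np.inf  # module gated off-context
            cal_scores.append(sc)
            cal_spans.append(prepared[p]["spans"])
        thr = calibrate_threshold(cal_scores, cal_spans, target_precision, slack=match_slack)
        thresholds[test_id] = thr
        d = prepared[test_id]
        Xt = apply_minmax(d["raw"], bounds).to_numpy()
        sc_t = clf.decision_score(Xt, "intention")
        sc_t[~d["context"]] = -np.inf
        decisions = sc_t >= thr
        t, f, n = event_decisions_metrics(decisions, d["spans"], slack=match_slack)
        tp += t
        fp += f
        fn += n
        lags, _missed = detection_latency(d["spans"], decisions, d["fs"], slack=match_slack)
        lags_all.extend(lags)
    prf = precision_recall_f1(tp, fp, fn)
    return {
        "kind": kind,
        "tp": tp, "fp": fp, "fn": fn,
        "precision": prf.precision, "recall": prf.recall, "f1": prf.f1,
        "latency_s": lags_all,
        "mean_latency_s": float(np.mean(lags_all)) if lags_all else float("nan"),
        "thresholds": thresholds,
    }
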