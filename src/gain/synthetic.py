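"""Synthetic gait/EMG cohort generator with ground truth.

Generates HuGaDB-format recordings that emulate the statistical structure
the downstream models rely on:

* periodic thigh trajectories per locomotion activity (two-harmonic
  sinusoids in cycle phase), with the left leg half a cycle out of phase;
* shank angles produced from the thigh cycle through a subject-specific
  nonlinear lagged coupling ``phi = c0 + a*(theta(u - lag) - offset) +
  b*(theta(u - lag) - offset)**2``, so the (theta, phi) scatter forms a
  closed loop and the shank is inferable from thigh history;
* a stance/swing time warp so stance occupies a configurable fraction
  (default 62%) of each cycle, with cycle-to-cycle shank variability
  larger in swing than in stance (inter-subject variability on top);
* accelerometer traces that are the gravity projection of the segment
  angle (so the tilt/integration pipeline inverts them), gyroscope traces
  that are the angle derivative plus white noise and slow bias drift, both
  quantized at the hardware sensitivities (16384 LSB/g, 16.4 LSB/(deg/s));
* EMG bursts spanning stand-up/sit-down intention windows that precede the
  corresponding activity labels;
* label sequences restricted to the legal activity-transition graph.

Everything is deterministic given the seed; one global seed fans out to
per-subject substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .features import ACC_LSB_PER_G, GYRO_LSB_PER_DPS
from .io_hugadb import (
    ACTIVITY_CODES,
    DEFAULT_FS,
    RawRecording,
    write_recording,
)

PHASE_STANCE, PHASE_SWING, PHASE_UNDEFINED = 0, 1, 2

MOVEMENT = ("walking", "running", "going_up", "going_down")
STATIC = ("sitting", "standing")
PROCEDURES = ("standing_up", "sitting_down")

#: Legal adjacencies for generated label scripts (self-runs implicit).
SCRIPT_EDGES = frozenset(
    {("sitting", "standing_up"), ("standing_up", "standing"),
     ("standing", "sitting_down"), ("sitting_down", "sitting")}
    | {("standing", m) for m in MOVEMENT}
    | {(m, "standing") for m in MOVEMENT}
    | {(a, b) for a in MOVEMENT for b in MOVEMENT if a != b}
)


@dataclass
class GaitParams:
    """Thigh trajectory of one locomotion activity (degrees, seconds)."""

    cycle_s: float
    thigh_offset: float
    thigh_amp: float
    thigh_amp2: float
    harm2_phase: float


@dataclass
class SyntheticConfig:
    fs: float = DEFAULT_FS
    stance_fraction: float = 0.62
    activities: dict = field(default_factory=lambda: {
        "walking": GaitParams(1.1, 65.0, 17.0, 4.0, 0.6),
        "running": GaitParams(0.8, 62.0, 24.0, 5.0, 0.8),
        "going_up": GaitParams(1.3, 63.0, 20.0, 5.0, 0.5),
        "going_down": GaitParams(1.2, 66.0, 15.0, 4.0, 0.7),
    })
    # shank coupling phi = c0 + a*d + b*d^2, d = theta(u - lag) - offset
    coupling_c0: float = 40.0
    coupling_a: float = 1.3
    coupling_b: float = 0.015
    coupling_lag: float = 0.08  # cycles
    # static postures (thigh, shank) in degrees
    sitting_pose: tuple[float, float] = (8.0, -70.0)
    standing_pose: tuple[float, float] = (83.0, 78.0)
    # inter-subject variability (STDs of per-subject parameter draws)
    amp_scale_std: float = 0.06
    offset_shift_std: float = 2.0
    cycle_scale_std: float = 0.05
    coupling_a_std: float = 0.08
    coupling_b_std: float = 0.003
    coupling_lag_std: float = 0.012
    coupling_c0_std: float = 2.0
    # within-subject cycle-to-cycle shank jitter (deg); swing is looser
    stance_jitter_std: float = 0.8
    swing_jitter_multiplier: float = 2.0
    thigh_jitter_std: float = 0.5
    # sensor noise
    acc_noise_g: float = 0.02
    gyro_noise_dps: float = 1.0
    gyro_bias_dps: float = 0.01
    gyro_drift_dps_per_sqrt_s: float = 0.002
    # EMG model (uint8 counts)
    emg_baseline_std: float = 1.5
    emg_burst_std: float = 30.0
    emg_burst_ramp_s: float = 0.15
    intention_duration_s: float = 1.0
    # trajectory construction
    sway_deg: float = 0.3
    sway_hz: float = 0.3
    blend_s: float = 0.4
    smooth_sigma_frames: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def zero_noise(self) -> "SyntheticConfig":
        """Copy with all sensor-noise sources switched off (gait
        variability is part of the motion, not the sensors, and stays)."""
        return replace(
            self,
            acc_noise_g=0.0,
            gyro_noise_dps=0.0,
            gyro_bias_dps=0.0,
            gyro_drift_dps_per_sqrt_s=0.0,
            emg_baseline_std=0.0,
        )


DEFAULT_SCRIPT: tuple[tuple[str, float], ...] = (
    ("sitting", 4.0), ("standing_up", 1.5), ("standing", 4.0),
    ("walking", 20.0), ("running", 10.0), ("walking", 6.0),
    ("going_up", 9.0), ("walking", 5.0), ("going_down", 9.0),
    ("walking", 6.0), ("standing", 4.0), ("sitting_down", 1.5),
    ("sitting", 4.0), ("standing_up", 1.5), ("standing", 3.0),
    ("walking", 8.0), ("standing", 3.0), ("sitting_down", 1.5),
    ("sitting", 4.0),
)


@dataclass
class GroundTruth:
    theta_L: np.ndarray
    theta_R: np.ndarray
    phi_L: np.ndarray
    phi_R: np.ndarray
    phase_L: np.ndarray
    phase_R: np.ndarray
    labels: np.ndarray
    intention_spans: dict[str, list[tuple[int, int]]]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SubjectParams:
    """Per-subject draws around the population defaults."""

    activities: dict
    coupling_c0: float
    coupling_a: float
    coupling_b: float
    coupling_lag: float


def draw_subject_params(config: SyntheticConfig, rng: np.random.Generator) -> SubjectParams:
    acts = {}
    amp_scale = 1.0 + rng.normal(0, config.amp_scale_std)
    cycle_scale = 1.0 + rng.normal(0, config.cycle_scale_std)
    offset_shift = rng.normal(0, config.offset_shift_std)
    for name, gp in config.activities.items():
        acts[name] = GaitParams(
            cycle_s=gp.cycle_s * cycle_scale,
            thigh_offset=gp.thigh_offset + offset_shift,
            thigh_amp=gp.thigh_amp * amp_scale,
            thigh_amp2=gp.thigh_amp2 * amp_scale,
            harm2_phase=gp.harm2_phase,
        )
    return SubjectParams(
        activities=acts,
        coupling_c0=config.coupling_c0 + rng.normal(0, config.coupling_c0_std),
        coupling_a=config.coupling_a + rng.normal(0, config.coupling_a_std),
        coupling_b=config.coupling_b + rng.normal(0, config.coupling_b_std),
        coupling_lag=config.coupling_lag + rng.normal(0, config.coupling_lag_std),
    )


def _warp(p: np.ndarray, stance_fraction: float) -> np.ndarray:
    """Map cycle fraction so stance fills [0, 0.5) of the shape phase."""
    p = np.mod(p, 1.0)
    sf = stance_fraction
    return np.where(p < sf, 0.5 * p / sf, 0.5 + 0.5 * (p - sf) / (1.0 - sf))


def _thigh_shape(u: np.ndarray, gp: GaitParams) -> np.ndarray:
    return (
        gp.thigh_offset
        + gp.thigh_amp * np.cos(2 * np.pi * u)
        + gp.thigh_amp2 * np.cos(4 * np.pi * u + gp.harm2_phase)
    )


def thigh_shank_trajectory(
    activity: str,
    phase,
    subject: SubjectParams,
    stance_fraction: float = 0.62,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless (theta, phi) at the given cycle fraction(s) in [0, 1).

    ``phi`` is a lagged nonlinear function of the same cycle, so plotting
    phi against theta over a cycle traces a closed loop rather than a
    single-valued curve.
    """
    if activity not in subject.activities:
        raise ValueError(f"unknown activity {activity!r}")
    gp = subject.activities[activity]
    p = np.asarray(phase, dtype=float)
    theta = _thigh_shape(_warp(p, stance_fraction), gp)
    d = _thigh_shape(_warp(p - subject.coupling_lag, stance_fraction), gp) - gp.thigh_offset
    phi = subject.coupling_c0 + subject.coupling_a * d + subject.coupling_b * d**2
    return theta, phi


class _CycleJitter:
    """Deterministic per-(leg, cycle) additive shank/thigh perturbations."""

    def __init__(self, rng: np.random.Generator, config: SyntheticConfig):
        self.rng = rng
        self.cfg = config
        self.cache: dict[tuple[str, int, str], float] = {}

    def get(self, leg: str, cycle: int, which: str) -> float:
        key = (leg, cycle, which)
        if key not in self.cache:
            std = {
                "phi_stance": self.cfg.stance_jitter_std,
                "phi_swing": self.cfg.stance_jitter_std * self.cfg.swing_jitter_multiplier,
                "theta": self.cfg.thigh_jitter_std,
            }[which]
            self.cache[key] = float(self.rng.normal(0.0, std))
        return self.cache[key]

    def arrays(self, leg: str, cycles: np.ndarray, which: str) -> np.ndarray:
        return np.array([self.get(leg, int(c), which) for c in cycles])


def _movement_leg(
    p: np.ndarray,
    activity: str,
    subject: SubjectParams,
    config: SyntheticConfig,
    jitter: _CycleJitter,
    leg: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """theta, phi, phase labels for one leg over phase samples ``p``."""
    sf = config.stance_fraction
    theta, phi = thigh_shank_trajectory(activity, np.mod(p, 1.0), subject, sf)
    frac = np.mod(p, 1.0)
    cycles = np.floor(p).astype(int)
    u = _warp(p, sf)
    w_st = np.where(u < 0.5, np.sin(2 * np.pi * u) ** 2, 0.0)
    w_sw = np.where(u >= 0.5, np.sin(2 * np.pi * (u - 0.5)) ** 2, 0.0)
    phi = phi + jitter.arrays(leg, cycles, "phi_stance") * w_st \
        + jitter.arrays(leg, cycles, "phi_swing") * w_sw
    theta = theta + jitter.arrays(leg, cycles, "theta") * (w_st + w_sw)
    phase = np.where(frac < sf, PHASE_STANCE, PHASE_SWING)
    return theta, phi, phase


def _smooth(x: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return x
    radius = max(1, int(round(3 * sigma)))
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    k /= k.sum()
    num = np.convolve(x, k, mode="same")
    den = np.convolve(np.ones_like(x), k, mode="same")
    return num / den


def _pick_start_phase(theta_prev: float, activity: str, subject: SubjectParams,
                      sf: float) -> float:
    grid = np.linspace(0.0, 1.0, 64, endpoint=False)
    theta, _ = thigh_shank_trajectory(activity, grid, subject, sf)
    return float(grid[np.argmin(np.abs(theta - theta_prev))])


def build_trajectory(
    script,
    subject: SubjectParams,
    config: SyntheticConfig,
    rng: np.random.Generator,
):
    """Per-frame ground-truth angles, phases, labels and intention spans."""
    fs = config.fs
    dt = 1.0 / fs
    jitter = _CycleJitter(rng, config)
    th_L, th_R, ph_L, ph_R = [], [], [], []
    phase_L, phase_R, labels = [], [], []
    spans: dict[str, list[tuple[int, int]]] = {"stand_up": [], "sit_down": []}
    # current pose: start from the script's first static activity
    first = script[0][0]
    if first not in STATIC:
        raise ValueError("script must start from a static posture (sitting or standing)")
    pose = config.sitting_pose if first == "sitting" else config.standing_pose
    cur = (pose[0], pose[0], pose[1], pose[1])  # thetaL, thetaR, phiL, phiR
    t_global = 0
    blend_n = max(1, int(round(config.blend_s * fs)))
    prev_act = None
    gait_phase = rng.uniform(0.0, 1.0)  # right-leg cycle phase accumulator
    for act, duration in script:
        if prev_act is not None and prev_act != act and (prev_act, act) not in SCRIPT_EDGES:
            raise ValueError(f"illegal activity transition {prev_act!r} -> {act!r}")
        n = int(round(duration * fs))
        tt = (t_global + np.arange(n)) * dt
        sway = config.sway_deg * np.sin(2 * np.pi * config.sway_hz * tt)
        if act in STATIC:
            pose = config.sitting_pose if act == "sitting" else config.standing_pose
            seg = [pose[0] + sway, pose[0] - sway, pose[1] + 0.5 * sway, pose[1] - 0.5 * sway]
            segphase = [np.full(n, PHASE_UNDEFINED)] * 2
        elif act in PROCEDURES:
            target = config.standing_pose if act == "standing_up" else config.sitting_pose
            ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(1, n + 1) / n)))
            seg = [
                cur[0] + (target[0] - cur[0]) * ramp,
                cur[1] + (target[0] - cur[1]) * ramp,
                cur[2] + (target[1] - cur[2]) * ramp,
                cur[3] + (target[1] - cur[3]) * ramp,
            ]
            segphase = [np.full(n, PHASE_UNDEFINED)] * 2
        else:  # locomotion
            gp = subject.activities[act]
            if prev_act not in MOVEMENT:
                gait_phase = _pick_start_phase(cur[1], act, subject, config.stance_fraction)
            p = gait_phase + np.arange(1, n + 1) * dt / gp.cycle_s
            gait_phase = float(p[-1])
            tR, pR, phR = _movement_leg(p, act, subject, config, jitter, "R")
            tL, pL, phL = _movement_leg(p + 0.5, act, subject, config, jitter, "L")
            seg = [tL, tR, pL, pR]
            segphase = [phL, phR]
        # crossfade the first frames of the segment from the previous pose
        m = min(blend_n, n)
        alpha = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, m + 1) / m))
        for j in range(4):
            seg[j] = np.asarray(seg[j], dtype=float).copy()
            seg[j][:m] = (1 - alpha) * cur[j] + alpha * seg[j][:m]
        cur = tuple(float(s[-1]) for s in seg)
        th_L.append(seg[0]); th_R.append(seg[1]); ph_L.append(seg[2]); ph_R.append(seg[3])
        phase_L.append(segphase[0]); phase_R.append(segphase[1])
        labels.append(np.full(n, ACTIVITY_CODES[act]))
        if act in PROCEDURES:
            kind = "stand_up" if act == "standing_up" else "sit_down"
            w = int(round(config.intention_duration_s * fs))
            spans[kind].append((max(0, t_global - w), t_global))
        t_global += n
        prev_act = act
    sig = config.smooth_sigma_frames
    return GroundTruth(
        theta_L=_smooth(np.concatenate(th_L), sig),
        theta_R=_smooth(np.concatenate(th_R), sig),
        phi_L=_smooth(np.concatenate(ph_L), sig),
        phi_R=_smooth(np.concatenate(ph_R), sig),
        phase_L=np.concatenate(phase_L),
        phase_R=np.concatenate(phase_R),
        labels=np.concatenate(labels),
        intention_spans=spans,
    )


def _quantize(x: np.ndarray, lsb_per_unit: float, lo: int, hi: int) -> np.ndarray:
    return np.clip(np.rint(x * lsb_per_unit), lo, hi).astype(np.int64)


def sensor_model(
    truth: GroundTruth, config: SyntheticConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Emit integer sensor channels consistent with the ground-truth angles.

    The accelerometer carries the unit-gravity projection of the segment
    angle (y along the segment, x perpendicular in the sagittal plane),
    the z-gyroscope the backward-difference angular rate; both quantized
    at the hardware sensitivities.  EMG is baseline noise around the uint8
    midpoint plus bursts over intention spans.
    """
    fs = config.fs
    n = len(truth)
    channels: dict[str, np.ndarray] = {}
    segments = {
        "lt": truth.theta_L, "rt": truth.theta_R, "ls": truth.phi_L, "rs": truth.phi_R,
    }
    for site, angle in segments.items():
        rad = np.radians(angle)
        noise = lambda: rng.normal(0.0, config.acc_noise_g, size=n)  # noqa: E731
        channels[f"acc_{site}_x"] = _quantize(np.cos(rad) + noise(), ACC_LSB_PER_G, -32768, 32767)
        channels[f"acc_{site}_y"] = _quantize(np.sin(rad) + noise(), ACC_LSB_PER_G, -32768, 32767)
        channels[f"acc_{site}_z"] = _quantize(noise(), ACC_LSB_PER_G, -32768, 32767)
        omega = np.empty(n)
        omega[1:] = np.diff(angle) * fs
        omega[0] = omega[1] if n > 1 else 0.0
        bias = rng.normal(0.0, config.gyro_bias_dps)
        drift = np.cumsum(rng.normal(0.0, config.gyro_drift_dps_per_sqrt_s / np.sqrt(fs), size=n))
        white = rng.normal(0.0, config.gyro_noise_dps, size=n)
        channels[f"gyro_{site}_z"] = _quantize(
            omega + bias + drift + white, GYRO_LSB_PER_DPS, -32768, 32767
        )
        for axis in ("x", "y"):
            channels[f"gyro_{site}_{axis}"] = _quantize(
                rng.normal(0.0, config.gyro_noise_dps, size=n), GYRO_LSB_PER_DPS, -32768, 32767
            )
    ramp_n = max(1, int(round(config.emg_burst_ramp_s * fs)))
    envelope = np.zeros(n)
    for spans in truth.intention_spans.values():
        for start, end in spans:
            envelope[start:end] = 1.0
            k = min(ramp_n, end - start)
            envelope[start : start + k] = np.maximum(
                envelope[start : start + k] * np.linspace(0, 1, k), envelope[start : start + k] * 0
            )
    for name in ("EMG_r", "EMG_l"):
        base = rng.normal(0.0, config.emg_baseline_std, size=n)
        burst = rng.normal(0.0, config.emg_burst_std, size=n) * envelope
        channels[name] = np.clip(np.rint(127.5 + base + burst), 0, 255).astype(np.int64)
    return channels


def generate_subject(
    config: SyntheticConfig,
    participant_id: str,
    seed: int | np.random.SeedSequence,
    script=None,
) -> tuple[RawRecording, GroundTruth]:
    """Synthesize one participant's recording plus its ground truth."""
    rng = np.random.default_rng(seed)
    subject = draw_subject_params(config, rng)
    truth = build_trajectory(script or DEFAULT_SCRIPT, subject, config, rng)
    channels = sensor_model(truth, config, rng)
    rec = RawRecording(
        channels=channels,
        labels=truth.labels.copy(),
        fs=config.fs,
        participant_id=participant_id,
        metadata={"participant_id": participant_id, "synthetic": "true"},
    )
    return rec, truth


def generate_cohort(
    config: SyntheticConfig,
    n: int,
    seed: int,
    out_dir: str | Path | None = None,
    script=None,
) -> list[tuple[str, RawRecording, GroundTruth]]:
    """Generate ``n`` participants with independent per-subject substreams."""
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(seed)
    cohort = []
    for pid_seq in zip(range(1, n + 1), root.spawn(n)):
        pid = f"S{pid_seq[0]:02d}"
        rec, truth = generate_subject(config, pid, pid_seq[1], script=script)
        cohort.append((pid, rec, truth))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pid, rec, truth in cohort:
            write_recording(rec, out_dir / f"{pid}.tsv")
            _write_truth(truth, out_dir / f"{pid}_truth.tsv")
    return cohort


def _write_truth(truth: GroundTruth, path: Path) -> None:
    header = ["theta_L", "theta_R", "phi_L", "phi_R", "phase_L", "phase_R", "act"]
    lines = []
    for kind, spans in truth.intention_spans.items():
        joined = ",".join(f"{s}:{e}" for s, e in spans)
        lines.append(f"# {kind}_spans={joined}")
    lines.append("\t".join(header))
    table = np.column_stack(
        [truth.theta_L, truth.theta_R, truth.phi_L, truth.phi_R,
         truth.phase_L, truth.phase_R, truth.labels]
    )
    for row in table:
        lines.append("\t".join(f"{v:.6f}" if i < 4 else f"{int(v)}" for i, v in enumerate(row)))
    path.write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> GroundTruth:
    """Read back a ground-truth TSV written by :func:`generate_cohort`."""
    spans: dict[str, list[tuple[int, int]]] = {"stand_up": [], "sit_down": []}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            key, _, value = body.partition("=")
            kind = key.replace("_spans", "").strip()
            if value.strip():
                spans[kind] = [tuple(map(int, se.split(":"))) for se in value.split(",")]
            continue
        if line.strip() and not line.startswith("theta"):
            rows.append([float(v) for v in line.split("\t")])
    arr = np.asarray(rows)
    return GroundTruth(
        theta_L=arr[:, 0], theta_R=arr[:, 1], phi_L=arr[:, 2], phi_R=arr[:, 3],
        phase_L=arr[:, 4].astype(int), phase_R=arr[:, 5].astype(int),
        labels=arr[:, 6].astype(int), intention_spans=spans,
    )
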