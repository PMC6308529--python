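"""Prosthesis controller state machine.

The controller moves between five states — sitting, standing_up, standing,
moving, sitting_down — along a fixed transition graph: sitting and standing
are only connected through the stand-up/sit-down procedures, locomotion is
reachable only from standing, and there is no direct sitting<->moving edge.
While sitting, gait inference is disabled and the legs stay motionless;
inference is enabled only in the moving state.  Invalid requests (e.g. a
sit-down intention while moving) are ignored by design and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

STATES = ("sitting", "standing_up", "standing", "moving", "sitting_down")

#: Legal (from, to) edges of the transition graph; self loops are implicit.
EDGES = frozenset(
    {
        ("sitting", "standing_up"),
        ("standing_up", "standing"),
        ("standing", "sitting_down"),
        ("sitting_down", "sitting"),
        ("standing", "moving"),
        ("moving", "standing"),
    }
)

#: Default duration of the stand-up / sit-down procedures, frames (~1.5 s).
DEFAULT_PROCEDURE_FRAMES = 85


@dataclass(frozen=True)
class ControllerState:
    current: str = "sitting"
    frames_in_state: int = 0
    pending_action: str | None = None

    def __post_init__(self) -> None:
        if self.current not in STATES:
            raise ValueError(f"unknown state {self.current!r}")


@dataclass(frozen=True)
class RecognizerFrame:
    """Per-frame recognition-module outputs consumed by the controller."""

    stand_up_intent: bool = False
    sit_down_intent: bool = False
    swing_detected: bool = False
    stillness_detected: bool = False


def controller_step(
    state: ControllerState,
    inputs: RecognizerFrame,
    procedure_frames: int = DEFAULT_PROCEDURE_FRAMES,
) -> tuple[ControllerState, str | None]:
    """Advance the controller by one frame.

    Returns the new state and the action emitted on this frame (one of
    ``stand_up``, ``sit_down``, ``start_gait_inference``,
    ``stop_gait_inference``, or None).
    """
    cur = state.current
    if cur == "sitting" and inputs.stand_up_intent:
        return ControllerState("standing_up"), "stand_up"
    if cur == "standing":
        if inputs.sit_down_intent:
            return ControllerState("sitting_down"), "sit_down"
        if inputs.swing_detected:
            return ControllerState("moving"), "start_gait_inference"
    if cur == "moving" and inputs.stillness_detected:
        return ControllerState("standing"), "stop_gait_inference"
    if cur == "standing_up" and state.frames_in_state + 1 >= procedure_frames:
        return ControllerState("standing"), None
    if cur == "sitting_down" and state.frames_in_state + 1 >= procedure_frames:
        return ControllerState("sitting"), None
    ignored = []
    if inputs.stand_up_intent and cur != "sitting":
        ignored.append("stand_up_intent")
    if inputs.sit_down_intent and cur != "standing":
        ignored.append("sit_down_intent")
    if ignored:
        logger.debug("ignored %s in state %s", ",".join(ignored), cur)
    return replace(state, frames_in_state=state.frames_in_state + 1), None


def detect_swing(
    omega_L: np.ndarray,
    omega_R: np.ndarray,
    speed_threshold: float = 20.0,
    min_frames: int = 3,
) -> np.ndarray:
    """Leg-swing onset: |thigh angular speed| above threshold for
    ``min_frames`` consecutive frames on either leg."""
    fast = (np.abs(np.asarray(omega_L)) > speed_threshold) | (
        np.abs(np.asarray(omega_R)) > speed_threshold
    )
    return _held(fast, min_frames)


def detect_stillness(
    omega_L: np.ndarray,
    omega_R: np.ndarray,
    speed_threshold: float = 5.0,
    hold_frames: int = 56,
) -> np.ndarray:
    """Stillness: both thigh angular speeds below threshold for a hold
    period (default ~1 s at the nominal sampling rate)."""
    slow = (np.abs(np.asarray(omega_L)) < speed_threshold) & (
        np.abs(np.asarray(omega_R)) < speed_threshold
    )
    return _held(slow, hold_frames)


def _held(flags: np.ndarray, n: int) -> np.ndarray:
    """True where ``flags`` has been True for the last ``n`` frames."""
    if n <= 1:
        return flags.astype(bool)
    f = flags.astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(f)])
    out = np.zeros(len(f), dtype=bool)
    t = np.arange(n - 1, len(f))
    out[t] = (csum[t + 1] - csum[t + 1 - n]) == n
    return out


def run_controller(
    frames: list[RecognizerFrame],
    initial: ControllerState | None = None,
    procedure_frames: int = DEFAULT_PROCEDURE_FRAMES,
) -> tuple[list[str], list[str | None]]:
    """Drive the state machine over a frame stream; returns per-frame
    states and actions."""
    state = initial or ControllerState()
    states: list[str] = []
    actions: list[str | None] = []
    for frame in frames:
        state, action = controller_step(state, frame, procedure_frames)
        states.append(state.current)
        actions.append(action)
    return states, actions
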