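"""Winner-take-all action decoding and the 1-D virtual arm.

Every 26 ms the decoder bins each MSN's spikes over a trailing 104-ms window
(events arrive with a 3-ms transmission delay) and the MSN with the highest
count wins; its action steps the arm base joint by one degree toward its
side.  Any tie — including the all-zero case — leaves the arm stationary.

The sensory error S is +1 when the last commanded step moved the arm tip
toward the selected target and -1 otherwise; a stationary arm therefore
scores -1, since "otherwise" covers it.  Targets sit at +/-38 deg from the
default position so that an ideal run of one-degree steps reaches a target
in about one second, and a trial ends as soon as either target is within
half a degree of the arm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

ACTIONS = ("left", "right")


@dataclass(frozen=True)
class DecoderConfig:
    tick_ms: float = 26.0
    window_ms: float = 104.0          # 4 ticks
    enable_delay_ms: float = 40.0     # robot control enable after trial start
    msn_to_decoder_delay_ms: float = 3.0
    step_deg: float = 1.0
    target_deg: float = 38.0          # |angle| of both targets
    reach_tol_deg: float = 0.5
    inertia_tau_ms: float | None = None   # optional first-order lag, off by default

    def __post_init__(self):
        if abs(self.window_ms - 4 * self.tick_ms) > 1e-9:
            raise ValueError("window must span exactly 4 decoder ticks")

    @property
    def target_angle(self):
        return {"left": -self.target_deg, "right": +self.target_deg}

    def min_correct_duration_s(self) -> float:
        """Ideal-kinematics lower bound on a correct trial's length."""
        n_steps = int(np.ceil((self.target_deg - self.reach_tol_deg)
                              / self.step_deg))
        return (self.enable_delay_ms + n_steps * self.tick_ms) / 1000.0


@dataclass(frozen=True)
class ArmState:
    """Single moving base joint; the tip is (L cos, L sin) of the angle."""

    angle: float = 0.0            # commanded angle, deg
    actual_angle: float = 0.0     # equals angle unless inertia is enabled
    default_angle: float = 0.0
    length: float = 1.0

    @property
    def tip(self) -> tuple[float, float]:
        th = np.deg2rad(self.actual_angle)
        return (self.length * np.cos(th), self.length * np.sin(th))


def decode_action(counts) -> str:
    """Argmax over per-MSN window counts; 'stationary' on any tie."""
    counts = np.asarray(counts)
    if counts.shape[0] != len(ACTIONS):
        raise ValueError("expected one count per action MSN")
    if counts[0] == counts[1]:
        return "stationary"
    return ACTIONS[int(np.argmax(counts))]


def step_arm(arm: ArmState, action: str, config: DecoderConfig) -> ArmState:
    """Apply one decoder command: +/- one step, or hold."""
    delta = {"left": -config.step_deg, "right": +config.step_deg,
             "stationary": 0.0}[action]
    cmd = arm.angle + delta
    if config.inertia_tau_ms is not None:
        lam = 1.0 - float(np.exp(-config.tick_ms / config.inertia_tau_ms))
        actual = arm.actual_angle + lam * (cmd - arm.actual_angle)
    else:
        actual = cmd
    return replace(arm, angle=cmd, actual_angle=actual)


def sensory_error(prev_angle: float, new_angle: float,
                  target_angle: float) -> int:
    """S = +1 iff the arm moved strictly toward the target, else -1."""
    if abs(target_angle - new_angle) < abs(target_angle - prev_angle):
        return 1
    return -1


def check_reach(arm: ArmState, selected_target: str,
                config: DecoderConfig) -> str:
    """'correct' | 'wrong' | 'none' against the two target angles."""
    angles = config.target_angle
    if abs(arm.actual_angle - angles[selected_target]) <= config.reach_tol_deg:
        return "correct"
    other = "left" if selected_target == "right" else "right"
    if abs(arm.actual_angle - angles[other]) <= config.reach_tol_deg:
        return "wrong"
    return "none"
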