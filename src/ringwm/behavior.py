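"""Two-state Markov-chain locomotor model.

A fly alternates between forward movement and body rotation. State changes
happen only at 300-ms step boundaries, with memoryless switch probabilities
(forward -> rotation 0.40, rotation -> forward 0.60). Each rotation bout
carries a random direction; heading is constant during forward bouts and
changes at a fixed angular speed during rotation bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from ringwm.errors import FitError

__all__ = [
    "State",
    "MarkovParams",
    "BehaviorSequence",
    "BoutFit",
    "generate_behavior",
    "bout_durations",
    "fit_bout_distribution",
]


class State(str, Enum):
    FORWARD = "forward"
    ROTATION = "rotation"


@dataclass(frozen=True)
class MarkovParams:
    """Switch probabilities per 300-ms step plus kinematic speeds.

    The rotation angular speed is a free parameter; the default matches the
    calibrated bump-shift speed of the circuit model so heading and bump
    co-rotate (the synthetic-track generator overrides it with a faster,
    saccade-like value). The forward speed default (13 mm/s) matches the
    magnitude of wild-type walking.
    """

    p_forward_to_rotation: float = 0.40
    p_rotation_to_forward: float = 0.60
    step_ms: float = 300.0
    rotation_speed_deg_s: float = 20.0
    forward_speed_mm_s: float = 13.0

    def __post_init__(self) -> None:
        for p in (self.p_forward_to_rotation, self.p_rotation_to_forward):
            if not 0.0 <= p <= 1.0:
                raise ValueError("switch probabilities must lie in [0, 1]")
        if self.step_ms <= 0:
            raise ValueError("step must be positive")

    @property
    def step_s(self) -> float:
        return self.step_ms / 1000.0

    @property
    def stationary_forward_fraction(self) -> float:
        """Stationary probability of the forward state, p_rf/(p_fr + p_rf)."""
        denom = self.p_forward_to_rotation + self.p_rotation_to_forward
        if denom == 0:
            return np.nan
        return self.p_rotation_to_forward / denom


@dataclass
class BehaviorSequence:
    """Per-step states, rotation directions and headings.

    ``states`` holds one entry per 300-ms step; ``rotation_direction`` is +1
    (counterclockwise) or -1 (clockwise) during rotation steps and 0 during
    forward steps; ``heading_deg[i]`` is the heading at the start of step i.
    """

    params: MarkovParams
    states: np.ndarray  # int8: 0 = forward, 1 = rotation
    rotation_direction: np.ndarray  # int8 in {-1, 0, +1}
    heading_deg: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.states)

    @property
    def step_times_s(self) -> np.ndarray:
        return np.arange(len(self.states)) * self.params.step_s

    def state_at(self, i: int) -> State:
        return State.ROTATION if self.states[i] else State.FORWARD

    def heading_end_deg(self) -> float:
        """Heading after the final step."""
        last = len(self.states) - 1
        h = self.heading_deg[last]
        if self.states[last]:
            h += (
                self.rotation_direction[last]
                * self.params.rotation_speed_deg_s
                * self.params.step_s
            )
        return float(h)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step_index": np.arange(len(self.states)),
                "time_s": self.step_times_s,
                "state": np.where(self.states == 1, State.ROTATION.value, State.FORWARD.value),
                "heading_deg": self.heading_deg,
            }
        )


@dataclass(frozen=True)
class BoutFit:
    """Exponential fit y(x) = alpha * beta**(x / 0.3) to bout-duration frequencies."""

    alpha: float
    beta: float
    r_squared: float


def generate_behavior(duration_s: float, params: MarkovParams, seed: int) -> BehaviorSequence:
    """Simulate the Markov chain for ``duration_s`` seconds.

    The initial state is drawn from the stationary distribution; each
    rotation bout draws its direction uniformly from {clockwise,
    counterclockwise}; transitions are memoryless at step boundaries.
    """
    step_s = params.step_s
    n_steps = int(round(duration_s / step_s))
    if n_steps < 1:
        raise ValueError("duration must cover at least one step")
    rng = np.random.default_rng(seed)
    states = np.zeros(n_steps, dtype=np.int8)
    rot_dir = np.zeros(n_steps, dtype=np.int8)
    heading = np.zeros(n_steps, dtype=float)

    p_fwd = params.stationary_forward_fraction
    if not np.isfinite(p_fwd):
        p_fwd = 0.5
    state = 0 if rng.random() < p_fwd else 1
    direction = 0
    if state == 1:
        direction = 1 if rng.random() < 0.5 else -1
    h = 0.0
    turn_per_step = params.rotation_speed_deg_s * step_s
    for i in range(n_steps):
        states[i] = state
        heading[i] = h
        if state == 1:
            rot_dir[i] = direction
            h += direction * turn_per_step
        # transition for the next step
        if state == 0:
            if rng.random() < params.p_forward_to_rotation:
                state = 1
                direction = 1 if rng.random() < 0.5 else -1
        else:
            if rng.random() < params.p_rotation_to_forward:
                state = 0
                direction = 0
    return BehaviorSequence(params, states, rot_dir, heading, seed)


def bout_durations(seq: BehaviorSequence, state: State | str) -> np.ndarray:
    """Durations (s) of maximal runs of ``state``, in order of occurrence."""
    code = 1 if State(state) is State.ROTATION else 0
    s = seq.states
    out = []
    run = 0
    for v in s:
        if v == code:
            run += 1
        elif run:
            out.append(run)
            run = 0
    if run:
        out.append(run)
    return np.asarray(out, dtype=float) * seq.params.step_s


def fit_bout_distribution(durations_s, step_s: float = 0.3) -> BoutFit:
    """Least-squares fit of bout-duration frequencies to y = alpha * beta**(x/0.3).

    Frequencies are counts per duration bin (one bin per step) normalized to
    sum to one; the fit is linear in log-frequency over bins with positive
    counts. Raises :class:`FitError` when fewer than two distinct duration
    values are present.
    """
    durations_s = np.asarray(durations_s, dtype=float)
    if durations_s.size == 0:
        raise FitError("no bouts to fit")
    k = np.rint(durations_s / step_s).astype(int)
    if np.unique(k).size < 2:
        raise FitError("need at least two distinct duration values")
    counts = np.bincount(k)[1:]  # bin j -> duration (j+1)*step
    freqs = counts / counts.sum()
    x = (np.arange(1, len(counts) + 1)) * step_s
    pos = freqs > 0
    logy = np.log(freqs[pos])
    # count-weighted fit: sparse tail bins carry high log-scale variance
    wts = np.sqrt(counts[pos])
    slope, intercept = np.polyfit(x[pos] / step_s, logy, 1, w=wts)
    beta = float(np.exp(slope))
    alpha = float(np.exp(intercept))
    pred = intercept + slope * (x[pos] / step_s)
    ss_res = float(np.sum(wts**2 * (logy - pred) ** 2))
    mean_w = np.average(logy, weights=wts**2)
    ss_tot = float(np.sum(wts**2 * (logy - mean_w) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BoutFit(alpha, beta, float(np.clip(r2, 0.0, 1.0)))
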