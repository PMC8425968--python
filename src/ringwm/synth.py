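"""Synthetic inputs with known ground truth.

Two generators: (1) synthetic fly tracks on the platform driven by the
two-state Markov locomotor model with a tunable bias of rotation bouts
toward landmark azimuths — bias 0 gives an isotropic random walk, bias 1
aims every rotation at a landmark; (2) synthetic wedge rate profiles with a
von-Mises-shaped bump of known center, width and peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ringwm.behavior import MarkovParams
from ringwm.bump import RateProfile
from ringwm.network import N_WEDGES
from ringwm.trajectory import (
    DEFAULT_STAGE_SCHEDULE,
    STAGE_NAMES,
    ArenaGeometry,
    Track,
)

__all__ = [
    "SyntheticFlyParams",
    "SyntheticBumpParams",
    "synth_track",
    "synth_cohort",
    "synth_rate_profile",
    "vonmises_fwhm_rad",
]


@dataclass(frozen=True)
class SyntheticFlyParams:
    """Parameters of one synthetic fly.

    ``fixation_bias`` is the probability that a rotation bout turns toward
    the nearer fixation target instead of a uniformly random direction; the
    chosen target is corrupted by wrapped Gaussian noise (SD
    ``aim_noise_deg``) so full bias does not collapse the histogram onto a
    single direction. One bias per stage may be given via
    ``stage_biases``.
    """

    markov: MarkovParams = field(
        default_factory=lambda: MarkovParams(rotation_speed_deg_s=300.0)
    )
    fixation_bias: float = 0.0
    stage_biases: tuple[float, float, float] | None = None  # pre, stim, post
    fixation_targets_deg: tuple[float, ...] = (0.0, 180.0)
    stage_targets_deg: tuple[tuple[float, ...], ...] | None = None  # per-stage override
    stage_schedule_s: tuple[float, float, float] = DEFAULT_STAGE_SCHEDULE
    frame_rate_hz: float = 25.0
    aim_noise_deg: float = 10.0
    #: heading wobble during forward bouts (deg per sqrt(s)); decorrelates
    #: successive movement directions the way real walking does
    forward_wobble_deg: float = 40.0
    #: centroid jitter of the recorded positions (mm per frame), emulating
    #: video tracking noise; without it successive directions are so
    #: correlated that even unbiased walks look anisotropic
    position_noise_mm: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        biases = self.stage_biases or (self.fixation_bias,) * 3
        for b in biases:
            if not 0.0 <= b <= 1.0:
                raise ValueError("fixation bias must lie in [0, 1]")

    def bias_for_stage(self, stage: str) -> float:
        if self.stage_biases is None:
            return self.fixation_bias
        return self.stage_biases[STAGE_NAMES.index(stage)]

    def targets_for_stage(self, stage: str) -> tuple[float, ...]:
        if self.stage_targets_deg is None:
            return self.fixation_targets_deg
        return self.stage_targets_deg[STAGE_NAMES.index(stage)]


def _wrap180(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def synth_track(
    params: SyntheticFlyParams, geometry: ArenaGeometry | None = None
) -> Track:
    """Simulate one fly walking on the platform.

    Positions integrate heading x forward speed during forward bouts;
    rotation bouts either spin in a random direction or (with probability
    ``fixation_bias``) turn toward the nearer landmark and hold once aimed.
    The fly reflects off the platform edge.
    """
    geometry = geometry or ArenaGeometry()
    rng = np.random.default_rng(params.seed)
    mk = params.markov
    dt = 1.0 / params.frame_rate_hz
    total_s = sum(params.stage_schedule_s)
    n_frames = int(round(total_s * params.frame_rate_hz))
    step_frames = max(1, int(round(mk.step_s * params.frame_rate_hz)))
    edges = np.cumsum(params.stage_schedule_s)

    def stage_at(t: float) -> str:
        if t < edges[0]:
            return STAGE_NAMES[0]
        if t < edges[1]:
            return STAGE_NAMES[1]
        return STAGE_NAMES[2]

    x = np.zeros(n_frames)
    y = np.zeros(n_frames)
    t = np.arange(n_frames) * dt
    heading = rng.uniform(0.0, 360.0)
    px = py = 0.0
    state = 0 if rng.random() < mk.stationary_forward_fraction else 1
    rot_dir = 0.0
    rot_target: float | None = None

    def begin_rotation(now_s: float) -> tuple[float, float | None]:
        stage = stage_at(now_s)
        bias = params.bias_for_stage(stage)
        if rng.random() < bias:
            diffs = [_wrap180(tgt - heading) for tgt in params.targets_for_stage(stage)]
            d = min(diffs, key=abs)
            d += rng.normal(0.0, params.aim_noise_deg)
            return (1.0 if d >= 0 else -1.0), heading + d
        return (1.0 if rng.random() < 0.5 else -1.0), None

    for f in range(n_frames):
        now = f * dt
        if f % step_frames == 0 and f > 0:  # step boundary: Markov transition
            if state == 0:
                if rng.random() < mk.p_forward_to_rotation:
                    state = 1
                    rot_dir, rot_target = begin_rotation(now)
            else:
                if rng.random() < mk.p_rotation_to_forward:
                    state = 0
                    rot_target = None
        if state == 1:
            turn = rot_dir * mk.rotation_speed_deg_s * dt
            if rot_target is not None:
                remaining = _wrap180(rot_target - heading)
                if abs(turn) >= abs(remaining):
                    turn = remaining  # aimed: hold heading at the target
            heading += turn
        else:
            heading += rng.normal(0.0, params.forward_wobble_deg * np.sqrt(dt))
            h = np.radians(heading)
            px += mk.forward_speed_mm_s * dt * np.cos(h)
            py += mk.forward_speed_mm_s * dt * np.sin(h)
            r = np.hypot(px, py)
            if r > geometry.platform_radius_mm:  # reflect at the edge
                nx, ny = px / r, py / r
                dx, dy = np.cos(h), np.sin(h)
                dot = dx * nx + dy * ny
                heading = np.degrees(np.arctan2(dy - 2 * dot * ny, dx - 2 * dot * nx))
                over = r - geometry.platform_radius_mm
                px -= 2 * over * nx
                py -= 2 * over * ny
        x[f] = px
        y[f] = py
    if params.position_noise_mm > 0:
        x = x + rng.normal(0.0, params.position_noise_mm, n_frames)
        y = y + rng.normal(0.0, params.position_noise_mm, n_frames)
        r = np.hypot(x, y)
        over = r > geometry.platform_radius_mm
        x[over] *= geometry.platform_radius_mm / r[over]
        y[over] *= geometry.platform_radius_mm / r[over]
    stages = np.array([stage_at(tt) for tt in t], dtype=object)
    return Track(t, x, y, stages, params.frame_rate_hz)


def synth_cohort(
    n: int,
    params: SyntheticFlyParams,
    geometry: ArenaGeometry | None = None,
) -> list[Track]:
    """Independent seeded flies sharing ``params`` (seeds derived from params.seed)."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    seeds = np.random.SeedSequence(params.seed).generate_state(n)
    return [synth_track(replace(params, seed=int(s)), geometry) for s in seeds]


@dataclass(frozen=True)
class SyntheticBumpParams:
    """Ground truth of a synthetic rate profile with a von-Mises-shaped bump."""

    center_deg: float | np.ndarray = 90.0  # scalar or per-bin trace
    kappa: float = 4.0
    peak_rate_hz: float = 40.0
    noise_sd_hz: float = 0.0
    duration_s: float = 10.0
    bin_ms: float = 100.0
    n_wedges: int = N_WEDGES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_rate_hz < 0:
            raise ValueError("peak rate must be non-negative")


def vonmises_fwhm_rad(kappa: float) -> float:
    """Closed-form FWHM of exp(kappa*(cos(x) - 1))."""
    return 2.0 * np.arccos(1.0 + np.log(0.5) / kappa)


def synth_rate_profile(params: SyntheticBumpParams) -> RateProfile:
    """Wedge-sampled bump profile with seeded additive noise (clipped at 0)."""
    n_bins = int(round(params.duration_s * 1e3 / params.bin_ms))
    centers = (np.arange(params.n_wedges) + 0.5) * (360.0 / params.n_wedges)
    c = np.broadcast_to(np.atleast_1d(np.asarray(params.center_deg, dtype=float)), (n_bins,)) \
        if np.ndim(params.center_deg) == 0 else np.asarray(params.center_deg, dtype=float)
    if len(c) != n_bins:
        raise ValueError("center trace length must equal the number of bins")
    dth = np.radians(centers[:, None] - c[None, :])
    rates = params.peak_rate_hz * np.exp(params.kappa * (np.cos(dth) - 1.0))
    if params.noise_sd_hz > 0:
        rng = np.random.default_rng(params.seed)
        rates = rates + rng.normal(0.0, params.noise_sd_hz, rates.shape)
    rates = np.clip(rates, 0.0, None)
    return RateProfile(rates, params.bin_ms, centers)
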