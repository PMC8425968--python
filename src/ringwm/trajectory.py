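"""Trajectory statistics for the Buridan-arena task.

Implements the behavioral measures computed from (x, y) tracks of a fly
walking on a water-surrounded circular platform inside a cylindrical LED
screen: screen-projected movement directions, sliding-window direction
histograms, fixation density and performance index, radar pairing, the
closed-form fixation deviation angle (sigma_f) and fixation strength (FS),
fixation classification, locomotion metrics and the laser-escape rate.

Angle convention: degrees, counterclockwise positive, 0 deg at the first
landmark. Internal math uses radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ringwm.errors import MetricUndefinedError

__all__ = [
    "ArenaGeometry",
    "Track",
    "DirectionHistogram",
    "FixationResult",
    "LocomotionMetrics",
    "BIN_CENTERS_DEG",
    "N_BINS",
    "PAIR_CENTERS_DEG",
    "FS_CRITERION",
    "movement_directions",
    "direction_histograms",
    "pair_occupancy",
    "fixation_density",
    "performance_index",
    "estimated_memory_duration",
    "radar_profile",
    "pair_histogram",
    "aggregate_histogram",
    "fixation_geometry",
    "fs_criterion",
    "classify_fixation",
    "uniform_pair_occupancy",
    "locomotion_metrics",
    "escape_rate",
    "analyze_track",
    "read_track",
    "write_track",
]

#: Number of direction quantiles covering 360 deg.
N_BINS = 12

#: Quantile centers in degrees (each bin spans [center - 15, center + 15)).
BIN_CENTERS_DEG = np.arange(N_BINS) * 30.0

#: Centers used for the six radar pairs.
PAIR_CENTERS_DEG = (0.0, 30.0, 60.0, 90.0, -30.0, -60.0)

#: Default fixation-strength criterion: control mean (0.0544) + 2 SD (0.0273).
FS_CRITERION = 0.1090

#: Default per-frame displacement (mm) below which the fly counts as stationary.
MOVEMENT_THRESHOLD_MM = 0.25

#: Default stage schedule in seconds (prestimulus, stimulus, poststimulus).
DEFAULT_STAGE_SCHEDULE = (90.0, 60.0, 90.0)

STAGE_NAMES = ("pre", "stim", "post")


@dataclass(frozen=True)
class ArenaGeometry:
    """Dimensions of the walking platform and the surrounding LED screen."""

    platform_radius_mm: float = 42.5
    screen_radius_mm: float = 100.0
    landmark_azimuths_deg: tuple[float, ...] = (0.0, 180.0)
    landmark_width_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.screen_radius_mm <= self.platform_radius_mm:
            raise ValueError("screen radius must exceed platform radius")


@dataclass
class Track:
    """Timestamped positions of one fly on the platform.

    ``stages`` labels each sample with one of ``pre``/``stim``/``post``.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    stages: np.ndarray
    frame_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.stages = np.asarray(self.stages, dtype=object)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.stages)):
            raise ValueError("track columns must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def stage_slice(self, stage: str) -> "Track":
        m = self.stages == stage
        return Track(self.t[m], self.x[m], self.y[m], self.stages[m], self.frame_rate_hz)

    def stage_interval(self, stage: str) -> tuple[float, float]:
        m = self.stages == stage
        if not np.any(m):
            raise ValueError(f"no samples in stage {stage!r}")
        ts = self.t[m]
        return float(ts[0]), float(ts[-1])


def assign_stages(t: np.ndarray, schedule: Sequence[float] = DEFAULT_STAGE_SCHEDULE) -> np.ndarray:
    """Label each timestamp with its stage given cumulative stage durations."""
    edges = np.cumsum(schedule)
    out = np.empty(len(t), dtype=object)
    out[:] = STAGE_NAMES[-1]
    t = np.asarray(t, dtype=float)
    out[t < edges[1]] = STAGE_NAMES[1]
    out[t < edges[0]] = STAGE_NAMES[0]
    return out


@dataclass
class DirectionHistogram:
    """Direction occupancy for one 15-s epoch.

    ``p`` holds 12 probabilities over 30-deg quantiles centered at
    0, 30, ..., 330 deg, or ``None`` when the epoch contains no movement.
    """

    t0: float
    n_samples: int
    p: np.ndarray | None

    @property
    def occupied(self) -> bool:
        return self.p is not None

    def p_at(self, center_deg: float) -> float:
        if self.p is None:
            raise MetricUndefinedError("empty epoch has no direction histogram")
        idx = int(round((center_deg % 360.0) / 30.0)) % N_BINS
        return float(self.p[idx])


@dataclass(frozen=True)
class FixationResult:
    """Closed-form fixation geometry of a paired direction histogram."""

    sigma_f_deg: float
    fs: float
    m_min: float
    m_max: float
    isotropic: bool = False


@dataclass(frozen=True)
class LocomotionMetrics:
    activity_percent: float
    speed_mm_s: float
    moved: bool


# ---------------------------------------------------------------------------
# movement direction
# ---------------------------------------------------------------------------

def movement_directions(
    track: Track,
    geometry: ArenaGeometry,
    threshold_mm: float = MOVEMENT_THRESHOLD_MM,
    convention: str = "screen",
) -> tuple[np.ndarray, np.ndarray]:
    """Movement direction series of a track.

    For each consecutive sample pair with displacement at or above
    ``threshold_mm``, the direction is the screen azimuth of the point where
    the forward ray from the current position (along the displacement)
    intersects the screen circle. ``convention='velocity'`` instead returns
    the plain azimuth of the displacement vector.

    Returns ``(theta_deg, times_s)``; ``theta_deg`` is in [0, 360) and
    ``times_s`` is the timestamp of the later sample of each pair.
    """
    if len(track) < 2:
        raise ValueError("need at least two samples")
    if convention not in ("screen", "velocity"):
        raise ValueError(f"unknown convention {convention!r}")
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    disp = np.hypot(dx, dy)
    moving = disp >= threshold_mm
    if not np.any(moving):
        return np.empty(0), np.empty(0)
    dx, dy, disp = dx[moving], dy[moving], disp[moving]
    times = track.t[1:][moving]
    if convention == "velocity":
        theta = np.degrees(np.arctan2(dy, dx)) % 360.0
        return theta, times
    # ray-circle intersection from the current (later) position
    px = track.x[1:][moving]
    py = track.y[1:][moving]
    ux, uy = dx / disp, dy / disp
    b = px * ux + py * uy
    r2 = geometry.screen_radius_mm**2
    tt = -b + np.sqrt(b * b - (px * px + py * py) + r2)
    ix = px + tt * ux
    iy = py + tt * uy
    theta = np.degrees(np.arctan2(iy, ix)) % 360.0
    return theta, times


# ---------------------------------------------------------------------------
# direction histograms, FD, PI
# ---------------------------------------------------------------------------

def _bin_indices(theta_deg: np.ndarray) -> np.ndarray:
    return (np.floor(((np.asarray(theta_deg) + 15.0) % 360.0) / 30.0)).astype(int) % N_BINS


def direction_histograms(
    theta_deg: np.ndarray,
    times_s: np.ndarray,
    interval: tuple[float, float],
    window_s: float = 15.0,
    step_s: float = 5.0,
) -> list[DirectionHistogram]:
    """Sliding-window direction histograms over ``interval``.

    One histogram every ``step_s`` seconds using a ``window_s`` window; the
    number of epochs in a span of length T is floor((T - window)/step) + 1.
    Epochs with no moving samples are returned with ``p=None``.
    """
    t0, t1 = interval
    span = t1 - t0
    n_epochs = int(np.floor((span - window_s) / step_s + 1e-9)) + 1
    if n_epochs < 1:
        return []
    theta_deg = np.asarray(theta_deg, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    idx = _bin_indices(theta_deg)
    out: list[DirectionHistogram] = []
    for k in range(n_epochs):
        lo = t0 + k * step_s
        hi = lo + window_s
        m = (times_s >= lo) & (times_s < hi)
        n = int(np.count_nonzero(m))
        if n == 0:
            out.append(DirectionHistogram(lo, 0, None))
            continue
        counts = np.bincount(idx[m], minlength=N_BINS)
        out.append(DirectionHistogram(lo, n, counts / n))
    return out


def pair_occupancy(hist: DirectionHistogram, pair_deg: tuple[float, float] = (0.0, 180.0)) -> float:
    """P(a;b) = p(a) + p(b) for one epoch."""
    return hist.p_at(pair_deg[0]) + hist.p_at(pair_deg[1])


def fixation_density(
    histograms: Iterable[DirectionHistogram],
    pair_deg: tuple[float, float] = (0.0, 180.0),
    threshold: float = 1.0 / 6.0,
) -> float:
    """Fraction of occupied epochs with pair occupancy strictly above 1/6."""
    hists = [h for h in histograms if h.occupied]
    if not hists:
        raise MetricUndefinedError("fixation density undefined: no occupied epochs")
    hits = sum(1 for h in hists if pair_occupancy(h, pair_deg) > threshold)
    return hits / len(hists)


def performance_index(fd_stage3: float, fd_stage1: float) -> float:
    """PI = FD(0;180) of the poststimulus stage minus that of the prestimulus stage."""
    for v in (fd_stage3, fd_stage1):
        if not 0.0 <= v <= 1.0:
            raise ValueError("fixation densities must lie in [0, 1]")
    return fd_stage3 - fd_stage1


def estimated_memory_duration(pi: float, poststimulus_s: float) -> float:
    """Memory-duration estimate: PI times the poststimulus-stage duration."""
    return pi * poststimulus_s


def uniform_pair_occupancy(n_bins: int = N_BINS, pair_size: int = 2) -> float:
    """Expected pair occupancy under uniform movement direction (fraction)."""
    return pair_size / n_bins


# ---------------------------------------------------------------------------
# radar pairing and fixation geometry
# ---------------------------------------------------------------------------

def pair_histogram(p: np.ndarray) -> np.ndarray:
    """Replace each histogram value with the mean of its antipodal pair."""
    p = np.asarray(p, dtype=float)
    if p.shape != (N_BINS,):
        raise ValueError(f"expected a {N_BINS}-bin histogram")
    half = N_BINS // 2
    paired = 0.5 * (p + np.roll(p, half))
    return paired


def radar_profile(p: np.ndarray) -> dict[float, float]:
    """Six paired radar values at centers 0, 30, 60, 90, -30 and -60 deg."""
    paired = pair_histogram(p)
    out = {}
    for c in PAIR_CENTERS_DEG:
        idx = int(round((c % 360.0) / 30.0)) % N_BINS
        out[c] = float(paired[idx])
    return out


def aggregate_histogram(histograms: Iterable[DirectionHistogram]) -> np.ndarray:
    """Sample-weighted mean histogram over occupied epochs."""
    ps, ws = [], []
    for h in histograms:
        if h.occupied:
            ps.append(h.p)
            ws.append(h.n_samples)
    if not ps:
        raise MetricUndefinedError("no occupied epochs to aggregate")
    ps = np.asarray(ps)
    ws = np.asarray(ws, dtype=float)
    return (ps * ws[:, None]).sum(axis=0) / ws.sum()


def _second_moment(p_paired: np.ndarray, sigma_deg: float) -> float:
    th = np.radians(BIN_CENTERS_DEG - sigma_deg)
    return float(np.sum(p_paired**2 * np.sin(th) ** 2))


def fixation_geometry(p: np.ndarray, isotropy_tol: float = 1e-12) -> FixationResult:
    """Closed-form fixation deviation angle and fixation strength.

    The histogram is antipodally paired, then the axis sigma minimizing the
    second moment M(sigma) = sum_i p(theta_i)^2 sin^2(theta_i - sigma) is
    found in closed form: with A = sum p^2 cos(2 theta) and
    B = -sum p^2 sin(2 theta) (written over the six pair centers with a
    factor 2, equivalently over all 12 bins), K = sqrt(A^2 + B^2) and
    phi = atan2(B/K, A/K), the stationary axes are -phi/2 and -phi/2 + 90
    deg. M is evaluated at both; the argmin is sigma_f and
    FS = 1 - M_min/M_max.

    An isotropic histogram (K ~ 0) returns FS = 0 with sigma_f = nan and
    ``isotropic=True``.
    """
    q = pair_histogram(p)
    th2 = 2.0 * np.radians(BIN_CENTERS_DEG)
    a = float(np.sum(q**2 * np.cos(th2)))
    b = -float(np.sum(q**2 * np.sin(th2)))
    k = float(np.hypot(a, b))
    scale = float(np.sum(q**2))
    if k <= isotropy_tol * max(scale, 1.0) or scale == 0.0:
        m = _second_moment(q, 0.0)
        return FixationResult(np.nan, 0.0, m, m, isotropic=True)
    phi = np.degrees(np.arctan2(b, a))
    cand = (-phi / 2.0, -phi / 2.0 + 90.0)
    m0, m1 = (_second_moment(q, s) for s in cand)
    if m0 <= m1:
        sigma_f, m_min, m_max = cand[0], m0, m1
    else:
        sigma_f, m_min, m_max = cand[1], m1, m0
    sigma_f = (sigma_f + 90.0) % 180.0 - 90.0  # normalize to [-90, 90)
    fs = 1.0 - m_min / m_max if m_max > 0 else 0.0
    return FixationResult(float(sigma_f), float(fs), m_min, m_max)


def fs_criterion(control_mean: float, control_sd: float, n_sd: float = 2.0) -> float:
    """Fixation classification criterion: control mean plus ``n_sd`` SDs."""
    return control_mean + n_sd * control_sd


def classify_fixation(fs: float, criterion: float = FS_CRITERION) -> bool:
    """True iff FS strictly exceeds the criterion."""
    if not 0.0 <= fs <= 1.0:
        raise ValueError("FS must lie in [0, 1]")
    return fs > criterion


# ---------------------------------------------------------------------------
# locomotion and escape
# ---------------------------------------------------------------------------

def locomotion_metrics(
    track: Track, threshold_mm: float = MOVEMENT_THRESHOLD_MM
) -> LocomotionMetrics:
    """Activity level (% frames moving) and mean speed over moving frames."""
    if len(track) < 2:
        raise ValueError("need at least two samples")
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    dt = np.diff(track.t)
    disp = np.hypot(dx, dy)
    moving = disp >= threshold_mm
    activity = 100.0 * np.count_nonzero(moving) / len(moving)
    if not np.any(moving):
        return LocomotionMetrics(activity, np.nan, False)
    speed = float(disp[moving].sum() / dt[moving].sum())
    return LocomotionMetrics(float(activity), speed, True)


def escape_rate(n_escapes: int, n_events: int) -> float:
    """Laser-escape rate in percent: 100 * escapes / approach events."""
    if n_events < 1:
        raise ValueError("need at least one approach event")
    if not 0 <= n_escapes <= n_events:
        raise ValueError("escape count must lie in [0, n_events]")
    return 100.0 * n_escapes / n_events


# ---------------------------------------------------------------------------
# per-track pipeline and I/O
# ---------------------------------------------------------------------------

def analyze_track(
    track: Track,
    geometry: ArenaGeometry | None = None,
    threshold_mm: float = MOVEMENT_THRESHOLD_MM,
    convention: str = "screen",
) -> pd.DataFrame:
    """Per-stage fixation and locomotion summary of one track.

    Returns one row per stage with FD, sigma_f, FS, fixation flag, activity
    and speed, plus the PI (post minus pre) attached to every row.
    """
    geometry = geometry or ArenaGeometry()
    theta, times = movement_directions(track, geometry, threshold_mm, convention)
    rows = []
    fd_by_stage: dict[str, float] = {}
    for stage in STAGE_NAMES:
        if not np.any(track.stages == stage):
            continue
        interval = track.stage_interval(stage)
        hists = direction_histograms(theta, times, interval)
        sub = track.stage_slice(stage)
        loco = locomotion_metrics(sub, threshold_mm)
        try:
            fd = fixation_density(hists)
        except MetricUndefinedError:
            fd = np.nan
        fd_by_stage[stage] = fd
        try:
            geom = fixation_geometry(aggregate_histogram(hists))
            sigma_f, fs = geom.sigma_f_deg, geom.fs
        except MetricUndefinedError:
            sigma_f, fs = np.nan, np.nan
        rows.append(
            {
                "stage": stage,
                "n_epochs": len(hists),
                "fd": fd,
                "sigma_f_deg": sigma_f,
                "fs": fs,
                "fixating": bool(classify_fixation(fs)) if np.isfinite(fs) else False,
                "activity_percent": loco.activity_percent,
                "speed_mm_s": loco.speed_mm_s,
            }
        )
    df = pd.DataFrame(rows)
    if {"pre", "post"} <= set(fd_by_stage):
        fd_post, fd_pre = fd_by_stage["post"], fd_by_stage["pre"]
        if np.isfinite(fd_post) and np.isfinite(fd_pre):
            df["pi"] = performance_index(fd_post, fd_pre)
        else:
            df["pi"] = np.nan
    return df


def read_track(
    path,
    frame_rate_hz: float = 25.0,
    schedule: Sequence[float] = DEFAULT_STAGE_SCHEDULE,
) -> Track:
    """Read a delimited track file with columns time_s, x_mm, y_mm[, stage].

    A missing stage column is filled from ``schedule``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"time_s", "x_mm", "y_mm"}
    if not required <= set(df.columns):
        raise ValueError(f"track file must have columns {sorted(required)}")
    if "stage" in df.columns:
        stages = df["stage"].to_numpy(dtype=object)
    else:
        stages = assign_stages(df["time_s"].to_numpy(), schedule)
    return Track(
        df["time_s"].to_numpy(),
        df["x_mm"].to_numpy(),
        df["y_mm"].to_numpy(),
        stages,
        frame_rate_hz,
    )


def write_track(track: Track, path) -> None:
    pd.DataFrame(
        {"time_s": track.t, "x_mm": track.x, "y_mm": track.y, "stage": track.stages}
    ).to_csv(path, sep="\t", index=False)
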