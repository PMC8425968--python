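"""Activity-bump metrics on wedge-wise EIP rate profiles.

A bump is a localized super-threshold region of the wedge firing-rate
profile. This module computes per-bin bump presence/position/amplitude,
the FWHM of the bump-aligned time-averaged profile, the angular deviation
between the bump trace and a reference angle trace, and the fraction of
trials that lose the bump within a window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ringwm.errors import MetricUndefinedError
from ringwm.network import N_WEDGES, WEDGE_DEG

__all__ = [
    "RateProfile",
    "BumpMetrics",
    "rate_profile",
    "detect_bump",
    "bump_trace",
    "smooth_positions",
    "fill_position_gaps",
    "bump_fwhm",
    "angular_deviation",
    "bump_loss_fraction",
    "has_loss",
    "PRESENCE_RATE_THRESHOLD",
    "PRESENCE_CONTRAST_FACTOR",
]

#: Bump presence requires a peak of at least this rate (spikes/s) ...
PRESENCE_RATE_THRESHOLD = 5.0
#: ... and at least this multiple of the mean rate on the opposite third of
#: the ring (a ring-wide median underestimates wide bumps, whose own
#: shoulders inflate the median).
PRESENCE_CONTRAST_FACTOR = 2.5

#: Moving-average window (ms) applied to bump positions before unwrapping.
POSITION_SMOOTH_MS = 500.0


@dataclass
class RateProfile:
    """Wedge x time firing-rate matrix (spikes/s) with its bin width."""

    rates: np.ndarray  # (n_wedges, n_bins)
    bin_ms: float
    wedge_centers_deg: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2:
            raise ValueError("rates must be a wedge x time matrix")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def bin_times_s(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_ms / 1e3

    def window_bins(self, window_s: tuple[float, float]) -> np.ndarray:
        t = self.bin_times_s
        return np.flatnonzero((t >= window_s[0]) & (t < window_s[1]))


@dataclass
class BumpMetrics:
    """Per-trial bump summary."""

    present: np.ndarray  # per-bin flags
    position_deg: np.ndarray  # per-bin circular position (nan when absent)
    amplitude: np.ndarray  # per-bin peak rate
    fwhm_rad: float
    mean_deviation_deg: float
    lost: bool


def rate_profile(
    spike_times_ms: np.ndarray,
    wedge_ids: np.ndarray,
    duration_ms: float,
    bin_ms: float = 100.0,
    n_wedges: int = N_WEDGES,
    units_per_wedge: int = 1,
) -> RateProfile:
    """Per-wedge firing rates: spike counts per time bin over a wedge's units.

    An empty spike record yields an all-zero profile.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(np.ceil(duration_ms / bin_ms - 1e-9))
    rates = np.zeros((n_wedges, max(n_bins, 1)))
    spike_times_ms = np.asarray(spike_times_ms, dtype=float)
    wedge_ids = np.asarray(wedge_ids, dtype=int)
    if spike_times_ms.size:
        b = np.minimum((spike_times_ms / bin_ms).astype(int), n_bins - 1)
        np.add.at(rates, (wedge_ids, b), 1.0)
        rates *= 1e3 / (bin_ms * units_per_wedge)
    centers = (np.arange(n_wedges) + 0.5) * (360.0 / n_wedges)
    return RateProfile(rates, bin_ms, centers)


def _circular_runs(mask: np.ndarray) -> list[np.ndarray]:
    """Maximal circularly-contiguous runs of True indices."""
    n = len(mask)
    if mask.all():
        return [np.arange(n)]
    if not mask.any():
        return []
    # rotate so position 0 is False, then split linearly
    start = int(np.argmin(mask))
    rot = np.roll(mask, -start)
    runs = []
    cur: list[int] = []
    for i, v in enumerate(rot):
        if v:
            cur.append((i + start) % n)
        elif cur:
            runs.append(np.asarray(cur))
            cur = []
    if cur:
        runs.append(np.asarray(cur))
    return runs


def circular_smooth(rates: np.ndarray, passes: int = 1) -> np.ndarray:
    """Circular [1/4, 1/2, 1/4] smoothing of a wedge rate vector."""
    out = np.asarray(rates, dtype=float)
    for _ in range(passes):
        out = 0.5 * out + 0.25 * (np.roll(out, 1) + np.roll(out, -1))
    return out


def antipodal_mean(rates: np.ndarray, peak_idx: int) -> float:
    """Mean rate over the third of the ring opposite ``peak_idx``."""
    n = len(rates)
    reach = max(1, n // 6)
    anti = (peak_idx + n // 2) % n
    idx = [(anti + d) % n for d in range(-reach, reach + 1)]
    return float(np.mean(rates[idx]))


def detect_bump(
    rates: np.ndarray,
    centers_deg: np.ndarray | None = None,
    rate_threshold: float = PRESENCE_RATE_THRESHOLD,
    contrast_factor: float = PRESENCE_CONTRAST_FACTOR,
    smooth_passes: int = 2,
) -> tuple[bool, float, float]:
    """Detect a bump in one time-bin rate vector.

    Present iff the peak rate reaches ``rate_threshold`` and
    ``contrast_factor`` times the mean rate on the opposite third of the
    ring, and the super-half-max region is circularly contiguous and spans
    less than half the ring. Position is the circular mean of rates over
    that region. Detection runs on a lightly smoothed copy of the vector to
    suppress single-bin spike noise (``smooth_passes=0`` disables).

    Returns (present, position_deg, amplitude).
    """
    rates = circular_smooth(np.asarray(rates, dtype=float), smooth_passes)
    n = len(rates)
    if centers_deg is None:
        centers_deg = (np.arange(n) + 0.5) * (360.0 / n)
    peak = float(rates.max())
    if peak < rate_threshold or peak < contrast_factor * antipodal_mean(
        rates, int(np.argmax(rates))
    ):
        return False, np.nan, peak
    mask = rates >= peak / 2.0
    runs = _circular_runs(mask)
    if len(runs) != 1 or len(runs[0]) >= n / 2.0:
        return False, np.nan, peak
    region = runs[0]
    th = np.radians(centers_deg[region])
    w = rates[region]
    pos = np.degrees(np.arctan2(np.sum(w * np.sin(th)), np.sum(w * np.cos(th)))) % 360.0
    return True, float(pos), peak


def bump_trace(profile: RateProfile, **kwargs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin (present, position_deg, amplitude) over a rate profile."""
    n_bins = profile.n_bins
    present = np.zeros(n_bins, dtype=bool)
    pos = np.full(n_bins, np.nan)
    amp = np.zeros(n_bins)
    for b in range(n_bins):
        p, x, a = detect_bump(profile.rates[:, b], profile.wedge_centers_deg, **kwargs)
        present[b] = p
        pos[b] = x
        amp[b] = a
    return present, pos, amp


def fill_position_gaps(
    position_deg: np.ndarray, bin_ms: float, max_gap_s: float = 2.0
) -> np.ndarray:
    """Circularly interpolate across short NaN gaps in a position trace.

    Unwrapping across detection gaps aliases the accumulated angle (any
    rotation of more than half a turn inside a gap wraps), which biases
    deviation estimates low for flickery traces; interpolation over gaps up
    to ``max_gap_s`` removes that.
    """
    pos = np.asarray(position_deg, dtype=float).copy()
    valid = np.flatnonzero(np.isfinite(pos))
    if valid.size < 2:
        return pos
    max_gap = int(round(max_gap_s * 1e3 / bin_ms))
    for a, b in zip(valid[:-1], valid[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap:
            d = (pos[b] - pos[a] + 180.0) % 360.0 - 180.0
            frac = np.arange(1, gap + 1) / (gap + 1)
            pos[a + 1 : b] = (pos[a] + frac * d) % 360.0
    return pos


def smooth_positions(position_deg: np.ndarray, bin_ms: float, smooth_ms: float = POSITION_SMOOTH_MS) -> np.ndarray:
    """Circular moving average of a position trace (NaN-aware)."""
    half = max(0, int(round(smooth_ms / bin_ms / 2)))
    if half == 0:
        return position_deg.copy()
    n = len(position_deg)
    rad = np.radians(position_deg)
    cs = np.where(np.isfinite(rad), np.cos(rad), 0.0)
    sn = np.where(np.isfinite(rad), np.sin(rad), 0.0)
    ok = np.isfinite(rad).astype(float)
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = ok[lo:hi].sum()
        if w > 0 and ok[i]:
            out[i] = np.degrees(np.arctan2(sn[lo:hi].sum(), cs[lo:hi].sum())) % 360.0
    return out


def _align_average(profile: RateProfile, bins: np.ndarray, positions_deg: np.ndarray) -> np.ndarray:
    """Average profile columns after rotating each bump to wedge 0."""
    n = profile.rates.shape[0]
    acc = np.zeros(n)
    cnt = 0
    for b in bins:
        p = positions_deg[b]
        if not np.isfinite(p):
            continue
        shift = int(np.round(p / WEDGE_DEG - 0.5)) % n
        acc += np.roll(profile.rates[:, b], -shift)
        cnt += 1
    if cnt == 0:
        raise MetricUndefinedError("no bump-bearing bins to align")
    return acc / cnt


def bump_fwhm(
    profile: RateProfile,
    window_s: tuple[float, float] | None = None,
    min_present_fraction: float = 0.8,
    **detect_kwargs,
) -> float:
    """FWHM (rad) of the time-averaged, bump-aligned rate profile.

    Requires the bump to be present in at least ``min_present_fraction`` of
    the bins in the window, else raises :class:`MetricUndefinedError`.
    Half-max crossings are located by linear interpolation between wedge
    centers.
    """
    if window_s is None:
        window_s = (0.0, profile.n_bins * profile.bin_ms / 1e3)
    bins = profile.window_bins(window_s)
    if bins.size == 0:
        raise MetricUndefinedError("empty window")
    present, pos, _ = bump_trace(profile, **detect_kwargs)
    frac = present[bins].mean()
    if frac < min_present_fraction:
        raise MetricUndefinedError(
            f"bump present in only {100 * frac:.0f}% of bins (need {100 * min_present_fraction:.0f}%)"
        )
    aligned = _align_average(profile, bins[present[bins]], pos)
    return _profile_fwhm_rad(aligned)


def _profile_fwhm_rad(aligned: np.ndarray) -> float:
    """Half-max width of a profile whose peak sits near wedge 0."""
    n = len(aligned)
    peak_idx = int(np.argmax(aligned))
    peak = aligned[peak_idx]
    if peak <= 0:
        raise MetricUndefinedError("flat profile")
    half = peak / 2.0
    centered = np.roll(aligned, n // 2 - peak_idx)  # peak at n//2
    angles = (np.arange(n) - n // 2 + 0.5) * (360.0 / n)  # deg relative to peak wedge center
    c = n // 2
    right = None
    for i in range(c, n - 1):
        if centered[i] >= half > centered[i + 1]:
            f = (centered[i] - half) / (centered[i] - centered[i + 1])
            right = angles[i] + f * (angles[i + 1] - angles[i])
            break
    left = None
    for i in range(c, 0, -1):
        if centered[i] >= half > centered[i - 1]:
            f = (centered[i] - half) / (centered[i] - centered[i - 1])
            left = angles[i] - f * (angles[i] - angles[i - 1])
            break
    if right is None or left is None:
        raise MetricUndefinedError("profile does not cross half maximum")
    return float(np.radians(right - left))


def angular_deviation(
    trace_deg: np.ndarray, reference_deg: np.ndarray
) -> tuple[np.ndarray, float]:
    """|accumulated trace - accumulated reference| after offset alignment.

    Both inputs are wrapped angle traces on a shared time base; each is
    unwrapped to accumulated angle, the initial offset is removed, and the
    absolute difference is returned per time point together with its mean
    over valid points. Trailing NaNs in ``trace_deg`` (bump lost) yield NaNs
    in the deviation trace.
    """
    trace_deg = np.asarray(trace_deg, dtype=float)
    reference_deg = np.asarray(reference_deg, dtype=float)
    if trace_deg.shape != reference_deg.shape:
        raise ValueError("traces must share the time base")
    valid = np.isfinite(trace_deg) & np.isfinite(reference_deg)
    if not valid.any():
        raise MetricUndefinedError("no valid samples in deviation trace")
    first = int(np.argmax(valid))
    dev = np.full(trace_deg.shape, np.nan)
    vt = np.flatnonzero(valid)
    acc_t = np.degrees(np.unwrap(np.radians(trace_deg[vt])))
    acc_r = np.degrees(np.unwrap(np.radians(reference_deg[vt])))
    d = np.abs((acc_t - acc_t[0]) - (acc_r - acc_r[0]))
    dev[vt] = d
    return dev, float(np.nanmean(dev))


def has_loss(
    present: np.ndarray,
    bin_ms: float,
    window_s: tuple[float, float],
    min_loss_s: float = 2.0,
) -> bool:
    """True when the present flag turns false and stays false >= ``min_loss_s``."""
    t = (np.arange(len(present)) + 0.5) * bin_ms / 1e3
    m = (t >= window_s[0]) & (t < window_s[1])
    absent = ~np.asarray(present, dtype=bool)[m]
    need = int(np.ceil(min_loss_s * 1e3 / bin_ms))
    run = 0
    for a in absent:
        run = run + 1 if a else 0
        if run >= need:
            return True
    return False


def bump_loss_fraction(
    present_traces: Iterable[np.ndarray],
    bin_ms: float,
    window_s: tuple[float, float],
    min_loss_s: float = 2.0,
) -> float:
    """Percent of trials whose bump disappears for >= 2 s within the window."""
    traces = list(present_traces)
    if not traces:
        raise ValueError("need at least one trial")
    lost = sum(1 for p in traces if has_loss(p, bin_ms, window_s, min_loss_s))
    return 100.0 * lost / len(traces)
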