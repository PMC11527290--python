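"""Summary measures of sleep/wake series.

Converts simulated trajectories or empirical records into the quantities the
fitting pipeline compares: total sleep duration (TSD, hours per midnight-to-
midnight day), sleep bouts per day (BPD, state transitions per 24 h divided
by two), half-hour sleep-probability profiles, and the observed circadian
pacemaker period from phase accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import SECONDS_PER_DAY, SECONDS_PER_HOUR
from .model import SimulationResult

__all__ = [
    "WakeSeries", "SleepProbabilityProfile", "SleepSummary",
    "resample_uniform", "total_sleep_duration", "bouts_per_day",
    "sleep_probability_profile", "observed_period",
    "BIN_SECONDS", "N_BINS",
]

BIN_SECONDS = 1800.0
N_BINS = 48


@dataclass
class WakeSeries:
    """Uniformly sampled binary arousal state.

    ``start_s`` is seconds since the clock-midnight origin of sample 0, so
    samples are aligned to clock time.  ``missing`` (optional) marks samples
    without observation; missing samples are excluded from probabilities.
    """

    start_s: float
    dt: float
    wake: np.ndarray
    missing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.wake = np.asarray(self.wake, dtype=bool)
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.wake.shape:
                raise ValueError("missing mask must match wake shape")

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.wake.size) * self.dt

    @property
    def end_s(self) -> float:
        return self.start_s + self.wake.size * self.dt


@dataclass
class SleepProbabilityProfile:
    """Probability of being asleep in each of the 48 half-hour clock bins."""

    probs: np.ndarray
    coverage: np.ndarray
    window_center_day: float = float("nan")

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.probs.shape != (N_BINS,) or self.coverage.shape != (N_BINS,):
            raise ValueError(f"profiles have {N_BINS} half-hour bins")
        covered = self.coverage > 0
        if np.any((self.probs[covered] < 0) | (self.probs[covered] > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def mean_tsd_h(self) -> float:
        """Mean daily TSD implied by the profile (full coverage assumed)."""
        return float(np.sum(self.probs) * BIN_SECONDS / SECONDS_PER_HOUR)


@dataclass(frozen=True)
class SleepSummary:
    tsd_h: float
    bpd: float


def resample_uniform(result: SimulationResult, dt: float = 60.0) -> WakeSeries:
    """Wake state on a uniform midnight-aligned grid.

    ``Vm - Vv`` is linearly interpolated onto the grid and thresholded at 0,
    so the wake indicator stays pointwise consistent with ``Vm > Vv``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if result.times.size == 0:
        raise ValueError("empty simulation result")
    margin = np.asarray(result.Vm) - np.asarray(result.Vv)
    t0 = np.ceil(result.times[0] / dt) * dt
    n = int(np.floor((result.times[-1] - t0) / dt)) + 1
    if n <= 0:
        raise ValueError("simulation too short for requested dt")
    grid = t0 + np.arange(n) * dt
    wake = np.interp(grid, result.times, margin) > 0.0
    return WakeSeries(start_s=float(t0), dt=float(dt), wake=wake)


def _day_slice(series: WakeSeries, day: int) -> slice:
    lo = day * SECONDS_PER_DAY
    hi = (day + 1) * SECONDS_PER_DAY
    i0 = int(np.ceil((lo - series.start_s) / series.dt))
    i1 = int(np.ceil((hi - series.start_s) / series.dt))
    return slice(max(i0, 0), min(i1, series.wake.size))


def total_sleep_duration(series: WakeSeries, day: int) -> float:
    """Hours asleep during calendar ``day`` (midnight to midnight)."""
    sl = _day_slice(series, day)
    expected = int(round(SECONDS_PER_DAY / series.dt))
    if sl.stop - sl.start != expected:
        raise ValueError(f"day {day} not fully covered by the series")
    chunk = series.wake[sl]
    if series.missing is not None and np.any(series.missing[sl]):
        raise ValueError(f"day {day} has missing samples")
    return float(np.sum(~chunk) * series.dt / SECONDS_PER_HOUR)


def bouts_per_day(series: WakeSeries, days: int = 14) -> float:
    """Sleep bouts per 24 h: state transitions over the last ``days`` full
    days of the series, divided by 2, divided by ``days``."""
    if days < 1:
        raise ValueError("days must be >= 1")
    end_day = int(np.floor(series.end_s / SECONDS_PER_DAY))
    start_day = end_day - days
    sl = slice(_day_slice(series, start_day).start, _day_slice(series, end_day - 1).stop)
    expected = int(round(days * SECONDS_PER_DAY / series.dt))
    if start_day * SECONDS_PER_DAY < series.start_s - 1e-9 or sl.stop - sl.start != expected:
        raise ValueError(f"series does not contain {days} full days")
    w = series.wake[sl]
    transitions = int(np.sum(w[1:] != w[:-1]))
    return transitions / 2.0 / days


def sleep_probability_profile(series: WakeSeries, last_days: int = 7,
                              window_center_day: float = float("nan")) -> SleepProbabilityProfile:
    """Per-clock-bin probability of sleep over the last ``last_days`` full days.

    Each sample is assigned to the half-hour clock bin containing it; the
    probability is the asleep fraction among non-missing samples, and
    ``coverage`` the non-missing fraction per bin.
    """
    end_day = int(np.floor(series.end_s / SECONDS_PER_DAY))
    start_day = end_day - last_days
    i0 = _day_slice(series, start_day).start
    i1 = _day_slice(series, end_day - 1).stop
    expected = int(round(last_days * SECONDS_PER_DAY / series.dt))
    if start_day * SECONDS_PER_DAY < series.start_s - 1e-9 or i1 - i0 != expected:
        raise ValueError(f"series does not contain {last_days} full days")
    t = series.start_s + np.arange(i0, i1) * series.dt
    bins = ((t % SECONDS_PER_DAY) / BIN_SECONDS).astype(int)
    asleep = ~series.wake[i0:i1]
    observed = np.ones(i1 - i0, dtype=bool)
    if series.missing is not None:
        observed = ~series.missing[i0:i1]
    n_obs = np.bincount(bins, weights=observed, minlength=N_BINS)
    n_sleep = np.bincount(bins, weights=asleep & observed, minlength=N_BINS)
    n_tot = np.bincount(bins, minlength=N_BINS)
    if np.all(n_obs == 0):
        raise ValueError("window contains no observed samples")
    with np.errstate(invalid="ignore"):
        probs = np.where(n_obs > 0, n_sleep / np.maximum(n_obs, 1), np.nan)
    coverage = n_obs / np.maximum(n_tot, 1)
    probs = np.where(n_obs > 0, probs, 0.0)
    if np.isnan(window_center_day):
        window_center_day = start_day + (last_days - 1) / 2.0
    return SleepProbabilityProfile(probs=probs, coverage=coverage,
                                   window_center_day=window_center_day)


def observed_period(xs, ys, ts) -> float:
    """Circadian pacemaker period (hours) from the rate of phase accumulation.

    Unwraps the phase ``psi = atan2(y, x)`` along the trajectory and returns
    ``2 pi * (t_end - t_start) / |psi_end - psi_start|``.  The magnitude of
    the phase change is used so the result is independent of the rotation
    direction of ``(x, y)``.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    ts = np.asarray(ts, dtype=float)
    if xs.size < 3 or xs.size != ys.size or xs.size != ts.size:
        raise ValueError("need matching x, y, t arrays of length >= 3")
    psi = np.unwrap(np.arctan2(ys, xs))
    dpsi = abs(psi[-1] - psi[0])
    if dpsi < 4.0 * np.pi:
        raise ValueError("trajectory spans fewer than two full cycles")
    return float(2.0 * np.pi * (ts[-1] - ts[0]) / dpsi / SECONDS_PER_HOUR)


def summarize(series: WakeSeries, bpd_days: int = 14) -> SleepSummary:
    """TSD averaged over the BPD window plus BPD itself."""
    end_day = int(np.floor(series.end_s / SECONDS_PER_DAY))
    tsd = np.mean([total_sleep_duration(series, d)
                   for d in range(end_day - bpd_days, end_day)])
    return SleepSummary(tsd_h=float(tsd), bpd=bouts_per_day(series, bpd_days))
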