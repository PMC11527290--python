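"""Grid-search fitting of the four developmental parameters.

The pipeline: build the (mu, chi, nu_vc, b) grid, simulate every combination
once into a reusable library (half-hour sleep-probability profile of the
last 7 simulated days, bouts per day over the last 14, observed pacemaker
period), then slide a 7-day window over an empirical record and, per window,
pick the feasible library entry minimizing the sum-of-squares profile cost.

Feasibility filters (applied before cost ranking): average bouts per day of
at least 1.5, and an observed pacemaker period within [23.995, 24.005] h.
Cost ties are broken by the period closest to 24 h, then by grid order.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .params import LightSchedule, ModelParameters
from .model import SimulationError, simulate
from .metrics import (N_BINS, SleepProbabilityProfile, bouts_per_day,
                      observed_period, resample_uniform,
                      sleep_probability_profile)
from .records import MINUTES_PER_DAY, MISSING, SLEEP, SleepRecord

__all__ = [
    "GridSpec", "GridLibrary", "FitResult", "Trajectory",
    "build_grid", "precompute_library", "window_cost", "total_cost",
    "fit_window", "fit_trajectory", "constrained_scan", "loess_smooth",
    "record_profile", "DEFAULT_MIN_BPD", "DEFAULT_PERIOD_BAND",
]

PARAM_NAMES = ("mu", "chi", "nu_vc", "b")
DEFAULT_MIN_BPD = 1.5
DEFAULT_PERIOD_BAND = (23.995, 24.005)
_KEY_DECIMALS = 6  # rounding used to deduplicate and match grid values


def _dedup_sorted(values: Sequence[float]) -> tuple[float, ...]:
    rounded = np.round(np.asarray(values, dtype=float), _KEY_DECIMALS)
    return tuple(np.unique(rounded))


@dataclass(frozen=True)
class GridSpec:
    """Value sets for the four free parameters.

    The default reproduces the published search space: chi combines a linear
    sweep 15..45 h (step 1 h) with a logarithmic sweep exp(1.5)..exp(3.8)
    (step 0.1 in ln chi); mu runs 2.1..15.9 nM s in steps of 0.3; nu_vc
    combines -7..0 mV (step 0.5) with a refinement -3.5..-1.0 (step 0.25);
    b is {0.4, 0.5, 0.6, 0.7} plus 0.8..1.0 in steps of 0.05.
    """

    mu_values: tuple[float, ...] = tuple(np.round(np.linspace(2.1, 15.9, 47), 6))
    chi_values: tuple[float, ...] = _dedup_sorted(
        np.concatenate([np.arange(15.0, 46.0, 1.0),
                        np.exp(np.arange(1.5, 3.8 + 1e-9, 0.1))]))
    nu_vc_values: tuple[float, ...] = _dedup_sorted(
        np.concatenate([np.arange(-7.0, 0.0 + 1e-9, 0.5),
                        np.arange(-3.5, -1.0 + 1e-9, 0.25)]))
    b_values: tuple[float, ...] = _dedup_sorted(
        np.concatenate([[0.4, 0.5, 0.6, 0.7], np.arange(0.8, 1.0 + 1e-9, 0.05)]))

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if len(getattr(self, f"{name}_values")) == 0:
                raise ValueError(f"empty value set for {name}")

    @property
    def size(self) -> int:
        return (len(self.mu_values) * len(self.chi_values)
                * len(self.nu_vc_values) * len(self.b_values))

    def values(self, name: str) -> tuple[float, ...]:
        return getattr(self, f"{name}_values")


def build_grid(spec: Optional[GridSpec] = None) -> list[tuple[float, float, float, float]]:
    """Cartesian product of the four value sets, lexicographic in
    (mu, chi, nu_vc, b) ascending — the order also used as the final
    tie-break in :func:`fit_window`."""
    spec = spec or GridSpec()
    return list(itertools.product(spec.mu_values, spec.chi_values,
                                  spec.nu_vc_values, spec.b_values))


# ---------------------------------------------------------------------------
# simulation library
# ---------------------------------------------------------------------------

_PROB_COLS = [f"prob_{i:02d}" for i in range(N_BINS)]
_LIB_COLS = list(PARAM_NAMES) + ["sim_ok", "bpd", "tau_obs"] + _PROB_COLS


def _combo_key(combo) -> tuple:
    return tuple(np.round(np.asarray(combo, dtype=float), _KEY_DECIMALS))


def simulate_combo_entry(combo, fixed_params: ModelParameters,
                         schedule: LightSchedule,
                         transient_days: int = 28, run_days: int = 35,
                         profile_days: int = 7, bpd_days: int = 14,
                         **sim_kwargs) -> dict:
    """Simulate one grid combination and summarize it into a library row."""
    mu, chi, nu_vc, b = combo
    row = dict(zip(PARAM_NAMES, _combo_key(combo)))
    try:
        res = simulate(fixed_params.with_combo(mu, chi, nu_vc, b), schedule,
                       transient_days=transient_days, run_days=run_days,
                       **sim_kwargs)
        series = resample_uniform(res)
        profile = sleep_probability_profile(series, last_days=profile_days)
        row.update(sim_ok=True,
                   bpd=bouts_per_day(series, days=bpd_days),
                   tau_obs=observed_period(res.x, res.y, res.times))
        row.update(dict(zip(_PROB_COLS, profile.probs)))
    except (SimulationError, ValueError):
        row.update(sim_ok=False, bpd=np.nan, tau_obs=np.nan)
        row.update(dict.fromkeys(_PROB_COLS, np.nan))
    return row


@dataclass
class GridLibrary:
    """Precomputed per-combination summaries, in grid order.

    ``table`` columns: the four parameters, ``sim_ok``, ``bpd``, ``tau_obs``
    and the 48 profile probabilities.  ``manifest`` records the fixed
    parameters, light schedule and protocol needed to reproduce it.
    """

    table: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(_LIB_COLS) - set(self.table.columns)
        if missing:
            raise ValueError(f"library table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def profiles(self) -> np.ndarray:
        return self.table[_PROB_COLS].to_numpy(dtype=float)

    @property
    def combos(self) -> np.ndarray:
        return self.table[list(PARAM_NAMES)].to_numpy(dtype=float)

    def profile_of(self, combo) -> SleepProbabilityProfile:
        key = _combo_key(combo)
        match = np.all(np.isclose(self.combos, key, atol=10 ** -_KEY_DECIMALS), axis=1)
        if not match.any():
            raise KeyError(f"combo {combo} not in library")
        row = self.table.loc[match].iloc[0]
        return SleepProbabilityProfile(probs=row[_PROB_COLS].to_numpy(dtype=float),
                                       coverage=np.ones(N_BINS))

    def grid_values(self, name: str) -> np.ndarray:
        return np.unique(self.table[name].to_numpy(dtype=float))

    def save(self, path: str) -> None:
        self.table.to_csv(path, index=False)
        with open(self._manifest_path(path), "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)

    @staticmethod
    def _manifest_path(path: str) -> str:
        base, _ = os.path.splitext(path)
        return base + ".manifest.json"

    @classmethod
    def load(cls, path: str) -> "GridLibrary":
        table = pd.read_csv(path)
        manifest = {}
        mp = cls._manifest_path(path)
        if os.path.exists(mp):
            with open(mp) as fh:
                manifest = json.load(fh)
        return cls(table=table, manifest=manifest)


def _library_manifest(fixed_params, schedule, transient_days, run_days,
                      profile_days, bpd_days, sim_kwargs) -> dict:
    from dataclasses import asdict
    return {
        "fixed_parameters": {k: v for k, v in asdict(fixed_params).items()
                             if k not in PARAM_NAMES},
        "schedule": asdict(schedule),
        "transient_days": transient_days, "run_days": run_days,
        "profile_days": profile_days, "bpd_days": bpd_days,
        "solver": {"method": sim_kwargs.get("method", "rk4"),
                   "dt": sim_kwargs.get("dt", 1.0)},
    }


def precompute_library(grid: Sequence, fixed_params: Optional[ModelParameters] = None,
                       schedule: Optional[LightSchedule] = None,
                       cache_path: Optional[str] = None,
                       n_jobs: int = 1,
                       transient_days: int = 28, run_days: int = 35,
                       profile_days: int = 7, bpd_days: int = 14,
                       progress: bool = False,
                       **sim_kwargs) -> GridLibrary:
    """Simulate every grid combination once and summarize it.

    With ``cache_path`` the library is resumable: combinations already in
    the cache file are not re-simulated, and the file is updated in place.
    Individual solver failures are recorded as infeasible rows, not raised.
    """
    if len(grid) == 0:
        raise ValueError("empty grid")
    fixed_params = fixed_params or ModelParameters()
    schedule = schedule or LightSchedule()
    manifest = _library_manifest(fixed_params, schedule, transient_days,
                                 run_days, profile_days, bpd_days, sim_kwargs)

    done: dict[tuple, dict] = {}
    if cache_path and os.path.exists(cache_path):
        cached = GridLibrary.load(cache_path)
        if cached.manifest and cached.manifest != manifest:
            raise ValueError(f"cache at {cache_path} was built under a "
                             "different protocol (manifest mismatch)")
        for _, row in cached.table.iterrows():
            done[_combo_key([row[n] for n in PARAM_NAMES])] = row.to_dict()

    todo = [c for c in grid if _combo_key(c) not in done]
    kwargs = dict(transient_days=transient_days, run_days=run_days,
                  profile_days=profile_days, bpd_days=bpd_days, **sim_kwargs)
    if n_jobs != 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(
            delayed(simulate_combo_entry)(c, fixed_params, schedule, **kwargs)
            for c in todo)
    else:
        it = todo
        if progress:
            from tqdm import tqdm
            it = tqdm(todo, desc="library")
        rows = [simulate_combo_entry(c, fixed_params, schedule, **kwargs)
                for c in it]
    for combo, row in zip(todo, rows):
        done[_combo_key(combo)] = row

    table = pd.DataFrame([done[_combo_key(c)] for c in grid])[_LIB_COLS]
    library = GridLibrary(table=table.reset_index(drop=True), manifest=manifest)
    if cache_path:
        library.save(cache_path)
    return library


# ---------------------------------------------------------------------------
# cost and window fitting
# ---------------------------------------------------------------------------

def window_cost(profile_data: SleepProbabilityProfile,
                profile_model: SleepProbabilityProfile) -> float:
    """Sum of squared probability differences over covered half-hour bins.

    Bins with zero empirical coverage are excluded rather than imputed; the
    sum is not rescaled by the number of covered bins.
    """
    mask = profile_data.coverage > 0
    if not mask.any():
        raise ValueError("no covered bins in the data profile")
    d = profile_data.probs[mask] - profile_model.probs[mask]
    return float(np.sum(d * d))


def total_cost(costs: Sequence[float], n: Optional[int] = None) -> float:
    """Window costs normalized to a period of ``n`` days: (1/n) sum(costs)."""
    costs = np.asarray(costs, dtype=float)
    if n is None:
        n = costs.size
    if n < 1:
        raise ValueError("n must be >= 1")
    if costs.size != n:
        raise ValueError(f"expected {n} window costs, got {costs.size}")
    return float(np.sum(costs) / n)


@dataclass(frozen=True)
class FitResult:
    window_center_day: float
    best_combo: tuple[float, float, float, float]
    cost: float
    tau_obs: float
    n_ties: int
    feasible_count: int


class NoFeasibleEntry(ValueError):
    """No library entry survives the feasibility filters."""


def _feasible_mask(library: GridLibrary, min_bpd: float, period_band,
                   fixed: Optional[dict]) -> tuple[np.ndarray, dict]:
    t = library.table
    diag = {}
    # copy=True: to_numpy may hand back a view of the column, and the
    # in-place &= below must never write through into the library table
    mask = t["sim_ok"].to_numpy(dtype=bool, copy=True)
    diag["sim_ok"] = int(mask.sum())
    mask &= t["bpd"].to_numpy(dtype=float) >= min_bpd
    diag["after_bpd"] = int(mask.sum())
    tau = t["tau_obs"].to_numpy(dtype=float)
    mask &= (tau >= period_band[0]) & (tau <= period_band[1])
    diag["after_period"] = int(mask.sum())
    if fixed:
        for name, value in fixed.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            values = library.grid_values(name)
            if not np.any(np.isclose(values, value, atol=10 ** -_KEY_DECIMALS)):
                raise ValueError(f"fixed value {name}={value} is not on the grid")
            mask &= np.isclose(t[name].to_numpy(dtype=float), value,
                               atol=10 ** -_KEY_DECIMALS)
        diag["after_fixed"] = int(mask.sum())
    return mask, diag


def fit_window(profile_data: SleepProbabilityProfile, library: GridLibrary,
               min_bpd: float = DEFAULT_MIN_BPD,
               period_band=DEFAULT_PERIOD_BAND,
               fixed: Optional[dict] = None) -> FitResult:
    """Best-fitting grid combination for one empirical window.

    Among entries with BPD >= ``min_bpd``, pacemaker period inside
    ``period_band`` and matching any ``fixed`` constraints, returns the
    minimum-cost entry.  Exact cost ties are broken by |tau_obs - 24|
    smallest, remaining ties by grid order.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    mask, diag = _feasible_mask(library, min_bpd, period_band, fixed)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise NoFeasibleEntry(f"no feasible library entries (filter counts: {diag})")

    cov = profile_data.coverage > 0
    if not cov.any():
        raise ValueError("no covered bins in the data profile")
    diffs = library.profiles[idx][:, cov] - profile_data.probs[cov]
    costs = np.sum(diffs * diffs, axis=1)
    best_cost = costs.min()
    tied = np.flatnonzero(costs == best_cost)
    tau = library.table["tau_obs"].to_numpy(dtype=float)[idx]
    dev = np.abs(tau[tied] - 24.0)
    tied = tied[dev == dev.min()]
    pick = idx[tied[0]]  # grid order: libraries are stored in grid order
    combo = tuple(library.combos[pick])
    return FitResult(window_center_day=float(profile_data.window_center_day),
                     best_combo=combo, cost=float(best_cost),
                     tau_obs=float(tau[np.flatnonzero(idx == pick)[0]]),
                     n_ties=int(np.sum(costs == best_cost)),
                     feasible_count=int(idx.size))


# ---------------------------------------------------------------------------
# empirical profiles and sliding-window trajectories
# ---------------------------------------------------------------------------

def record_profile(record: SleepRecord, start_day: int,
                   window_days: int = 7) -> SleepProbabilityProfile:
    """Empirical sleep-probability profile for days [start, start+window).

    Days absent from the record contribute missing minutes; probabilities
    are the asleep fraction among observed minutes per half-hour clock bin,
    with the observed fraction recorded as coverage.
    """
    mats = [record.day_states(d) for d in range(start_day, start_day + window_days)]
    states = np.stack(mats)  # (window_days, 1440)
    minutes = np.tile(np.arange(MINUTES_PER_DAY), window_days)
    bins = minutes // 30
    observed = (states != MISSING).ravel()
    asleep = (states == SLEEP).ravel()
    n_obs = np.bincount(bins, weights=observed, minlength=N_BINS)
    n_sleep = np.bincount(bins, weights=asleep & observed, minlength=N_BINS)
    n_tot = np.bincount(bins, minlength=N_BINS)
    probs = np.where(n_obs > 0, n_sleep / np.maximum(n_obs, 1), 0.0)
    return SleepProbabilityProfile(probs=probs, coverage=n_obs / n_tot,
                                   window_center_day=start_day + (window_days - 1) / 2.0)


@dataclass
class Trajectory:
    """Per-day best-fit results from the sliding-window scan."""

    results: list[FitResult]
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        centers = [r.window_center_day for r in self.results]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("window centers must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"window_center_day": r.window_center_day,
                 **dict(zip(PARAM_NAMES, r.best_combo)),
                 "cost": r.cost, "tau_obs": r.tau_obs,
                 "n_ties": r.n_ties, "feasible_count": r.feasible_count}
                for r in self.results]
        return pd.DataFrame(rows)

    def smoothed_frame(self, alpha: float = 0.2) -> pd.DataFrame:
        df = self.to_frame()
        out = df[["window_center_day"]].copy()
        for name in PARAM_NAMES:
            out[name] = loess_smooth(df["window_center_day"].to_numpy(),
                                     df[name].to_numpy(), alpha=alpha)
        return out

    @property
    def costs(self) -> np.ndarray:
        return np.array([r.cost for r in self.results])


def fit_trajectory(record: SleepRecord, library: GridLibrary,
                   window_days: int = 7, step_days: int = 1,
                   min_bpd: float = DEFAULT_MIN_BPD,
                   period_band=DEFAULT_PERIOD_BAND,
                   fixed: Optional[dict] = None,
                   min_coverage: float = 0.0) -> Trajectory:
    """Sliding-window fit across the whole record (default 6-day overlap).

    Windows whose overall observed fraction is ``min_coverage`` or less, or
    that leave no feasible entries, are skipped and logged.
    """
    if record.n_days < window_days:
        raise ValueError(f"record spans {record.n_days} days; "
                         f"need at least {window_days}")
    results, skipped = [], []
    for start in range(int(record.days[0]),
                       int(record.days[-1]) - window_days + 2, step_days):
        profile = record_profile(record, start, window_days)
        if float(np.mean(profile.coverage)) <= min_coverage:
            skipped.append((start, "insufficient coverage"))
            continue
        try:
            results.append(fit_window(profile, library, min_bpd=min_bpd,
                                      period_band=period_band, fixed=fixed))
        except NoFeasibleEntry as exc:
            skipped.append((start, str(exc)))
    return Trajectory(results=results, skipped=skipped)


def constrained_scan(record: SleepRecord, library: GridLibrary,
                     subsets: Sequence[dict],
                     day_ranges: Optional[Sequence[tuple[float, float]]] = None,
                     **fit_kwargs) -> pd.DataFrame:
    """Fit trajectories under fixed-parameter constraints.

    ``subsets`` is a list of {parameter: fixed value} maps (the empty map
    reproduces the unconstrained fit).  Returns one row per subset with its
    per-window costs and, for each ``(lo, hi)`` in ``day_ranges``, the total
    cost over windows centred in that inclusive range.
    """
    rows = []
    for subset in subsets:
        traj = fit_trajectory(record, library, fixed=subset or None, **fit_kwargs)
        centers = np.array([r.window_center_day for r in traj.results])
        row = {"fixed": json.dumps(subset, sort_keys=True),
               "n_windows": len(traj.results),
               "mean_cost": total_cost(traj.costs) if traj.results else np.nan,
               "centers": centers, "costs": traj.costs}
        for lo, hi in (day_ranges or []):
            sel = (centers >= lo) & (centers <= hi)
            row[f"total_cost_{lo:g}_{hi:g}"] = (
                total_cost(traj.costs[sel]) if sel.any() else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def loess_smooth(x, y, alpha: float = 0.2) -> np.ndarray:
    """Loess smoothing with span ``alpha``; output aligned with the input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) abscissa")
    return lowess(y, x, frac=alpha, return_sorted=False)
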