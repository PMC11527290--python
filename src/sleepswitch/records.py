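"""Parsing of daily sleep records into a canonical per-minute representation.

Three input dialects are supported, matching the common ways infant sleep is
recorded:

* interval diaries — rows of sleep onset/offset timestamps,
* binned diaries — 15-min slots labelled awake / awake-and-feeding / asleep,
* actigraphy — per-minute activity counts scored by a count threshold.

Everything converges on :class:`SleepRecord`: a ternary per-minute state
(wake / sleep / missing) indexed by age day and minute of day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "WAKE", "SLEEP", "MISSING", "SleepRecord",
    "read_interval_diary", "read_binned_diary", "read_actigraphy",
    "read_binarized_matrix", "keep_complete_days",
]

WAKE, SLEEP, MISSING = 0, 1, 2
_STATE_CHARS = np.array(["W", "S", "M"])
_CHAR_STATES = {"W": WAKE, "S": SLEEP, "M": MISSING}
MINUTES_PER_DAY = 1440

_BINNED_LABELS = {"awake": WAKE, "awake and feeding": WAKE, "asleep": SLEEP}


@dataclass
class SleepRecord:
    """Per-minute ternary sleep/wake/missing states by age day.

    ``states`` has shape ``(len(days), 1440)`` with values WAKE/SLEEP/MISSING;
    ``days`` are nonnegative, strictly increasing age days (gaps allowed).
    """

    days: np.ndarray
    states: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (self.days.size, MINUTES_PER_DAY):
            raise ValueError("states must have shape (n_days, 1440)")
        if self.days.size and (np.any(np.diff(self.days) <= 0) or self.days[0] < 0):
            raise ValueError("age days must be nonnegative and strictly increasing")
        if not np.isin(self.states, [WAKE, SLEEP, MISSING]).all():
            raise ValueError("states must be WAKE(0)/SLEEP(1)/MISSING(2)")

    @property
    def n_days(self) -> int:
        return int(self.days.size)

    def day_states(self, day: int) -> np.ndarray:
        idx = np.where(self.days == day)[0]
        if idx.size == 0:
            return np.full(MINUTES_PER_DAY, MISSING, dtype=np.int8)
        return self.states[idx[0]]

    def tsd_h(self, day: int) -> float:
        """Hours asleep among observed minutes of ``day``."""
        s = self.day_states(day)
        return float(np.sum(s == SLEEP) / 60.0)

    # -- canonical long CSV: age_day, minute_of_day, state ------------------

    def to_long_frame(self) -> pd.DataFrame:
        day = np.repeat(self.days, MINUTES_PER_DAY)
        minute = np.tile(np.arange(MINUTES_PER_DAY), self.n_days)
        return pd.DataFrame({"age_day": day, "minute_of_day": minute,
                             "state": _STATE_CHARS[self.states.ravel()]})

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, meta: Optional[dict] = None) -> "SleepRecord":
        days = np.sort(df["age_day"].unique())
        states = np.full((days.size, MINUTES_PER_DAY), MISSING, dtype=np.int8)
        day_pos = {d: i for i, d in enumerate(days)}
        rows = df["age_day"].map(day_pos).to_numpy()
        cols = df["minute_of_day"].to_numpy()
        vals = df["state"].map(_CHAR_STATES)
        if vals.isna().any():
            bad = df.loc[vals.isna(), "state"].unique()
            raise ValueError(f"unknown state codes {bad}; expected W/S/M")
        states[rows, cols] = vals.to_numpy()
        return cls(days=days, states=states, meta=dict(meta or {}))

    @classmethod
    def from_csv(cls, path, meta: Optional[dict] = None) -> "SleepRecord":
        return cls.from_long_frame(pd.read_csv(path), meta=meta)

    # -- compact run-length CSV: age_day, start_minute, n_minutes, state ----

    def to_runlength_frame(self) -> pd.DataFrame:
        rows = []
        for day, s in zip(self.days, self.states):
            change = np.flatnonzero(np.diff(s)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [MINUTES_PER_DAY]))
            for a, b in zip(starts, ends):
                rows.append((day, a, b - a, _STATE_CHARS[s[a]]))
        return pd.DataFrame(rows, columns=["age_day", "start_minute", "n_minutes", "state"])

    @classmethod
    def from_runlength_frame(cls, df: pd.DataFrame, meta: Optional[dict] = None) -> "SleepRecord":
        days = np.sort(df["age_day"].unique())
        states = np.full((days.size, MINUTES_PER_DAY), MISSING, dtype=np.int8)
        day_pos = {d: i for i, d in enumerate(days)}
        for _, r in df.iterrows():
            states[day_pos[r["age_day"]],
                   int(r["start_minute"]):int(r["start_minute"]) + int(r["n_minutes"])] = \
                _CHAR_STATES[r["state"]]
        return cls(days=days, states=states, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# dialect readers
# ---------------------------------------------------------------------------

def _as_frame(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source)


def _parse_days(dates: pd.Series) -> np.ndarray:
    """Map a date-like or integer day column to nonnegative age days."""
    if pd.api.types.is_integer_dtype(dates):
        return dates.to_numpy()
    parsed = pd.to_datetime(dates)
    return (parsed - parsed.min()).dt.days.to_numpy()


def _parse_minutes(times: pd.Series) -> np.ndarray:
    """Clock times 'HH:MM' (or 'HH:MM:SS') to minute-of-day."""
    text = times.astype(str).str.strip()
    text = text.where(text.str.count(":") == 2, text + ":00")
    td = pd.to_timedelta(text)
    minutes = (td.dt.total_seconds() / 60).to_numpy()
    if np.any(minutes < 0) or np.any(minutes >= MINUTES_PER_DAY):
        raise ValueError("clock times must lie within 00:00-23:59")
    return minutes.astype(int)


def read_interval_diary(source: Union[str, pd.DataFrame],
                        meta: Optional[dict] = None) -> SleepRecord:
    """Interval diary (columns ``date``, ``onset_time``, ``offset_time``).

    Minutes inside any ``[onset, offset)`` interval are sleep; the remaining
    minutes of days that carry diary rows are wake.  An offset clock time at
    or before its onset is read as crossing midnight (the interval is split
    at the day boundary); a zero-length interval is an error.  Overlapping
    intervals are merged with a warning.
    """
    df = _as_frame(source)
    days = _parse_days(df["date"])
    onset = _parse_minutes(df["onset_time"])
    offset = _parse_minutes(df["offset_time"])
    if np.any(onset == offset):
        bad = df.loc[onset == offset]
        raise ValueError(f"zero-length sleep interval(s):\n{bad}")

    covered = set(days.tolist())
    all_days = np.arange(min(covered), max(covered) + 2)  # +1 for spillover
    states = np.full((all_days.size, MINUTES_PER_DAY), MISSING, dtype=np.int8)
    states[np.isin(all_days, list(covered))] = WAKE

    overlap = False
    for d, a, b in zip(days, onset, offset):
        row = d - all_days[0]
        if b > a:
            segs = [(row, a, b)]
        else:  # crosses midnight
            segs = [(row, a, MINUTES_PER_DAY), (row + 1, 0, b)]
        for r, lo, hi in segs:
            if np.any(states[r, lo:hi] == SLEEP):
                overlap = True
            sel = states[r, lo:hi]
            sel[sel != MISSING] = SLEEP
            # spillover into an otherwise unrecorded day: mark sleep only
            states[r, lo:hi][states[r, lo:hi] == MISSING] = SLEEP
    if overlap:
        warnings.warn("overlapping sleep intervals merged by union")

    keep = np.any(states != MISSING, axis=1)
    m = dict(meta or {})
    m.setdefault("dialect", "interval")
    return SleepRecord(days=all_days[keep], states=states[keep], meta=m)


def read_binned_diary(source: Union[str, pd.DataFrame],
                      meta: Optional[dict] = None) -> SleepRecord:
    """Binned diary (columns ``date``, ``slot_index`` 0-95, ``label``).

    Labels 'awake' and 'awake and feeding' map to wake, 'asleep' to sleep;
    each 15-min slot expands to 15 minutes.  Slots without a row are missing.
    """
    df = _as_frame(source)
    days = _parse_days(df["date"])
    slots = df["slot_index"].to_numpy().astype(int)
    if np.any((slots < 0) | (slots > 95)):
        raise ValueError("slot_index must lie in 0-95")
    labels = df["label"].astype(str).str.strip().str.lower()
    unknown = set(labels.unique()) - set(_BINNED_LABELS)
    if unknown:
        raise ValueError(f"unknown diary label(s): {sorted(unknown)}")
    vals = labels.map(_BINNED_LABELS).to_numpy()

    uniq = np.unique(days)
    states = np.full((uniq.size, MINUTES_PER_DAY), MISSING, dtype=np.int8)
    pos = {d: i for i, d in enumerate(uniq)}
    for d, s, v in zip(days, slots, vals):
        states[pos[d], s * 15:(s + 1) * 15] = v
    m = dict(meta or {})
    m.setdefault("dialect", "binned")
    return SleepRecord(days=uniq, states=states, meta=m)


def read_actigraphy(source: Union[str, pd.DataFrame],
                    cutoff: float = 5.0,
                    missing_gap_min: int = 60,
                    meta: Optional[dict] = None) -> SleepRecord:
    """Actigraphy (columns ``timestamp``, ``counts``), scored by threshold.

    Minutes with fewer than ``cutoff`` activity counts are rest (sleep), the
    remainder active (wake); a count exactly at the cutoff is wake.  Runs of
    ``missing_gap_min`` or more consecutive zero-count minutes are treated as
    the device not being worn and marked missing.  Minutes without a sample
    are missing.
    """
    df = _as_frame(source)
    counts = df["counts"].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("activity counts must be nonnegative")
    ts = pd.to_datetime(df["timestamp"])
    days = (ts.dt.normalize() - ts.dt.normalize().min()).dt.days.to_numpy()
    minutes = (ts.dt.hour * 60 + ts.dt.minute).to_numpy()

    uniq = np.unique(days)
    states = np.full((uniq.size, MINUTES_PER_DAY), MISSING, dtype=np.int8)
    observed = np.zeros_like(states, dtype=bool)
    zero = np.zeros_like(states, dtype=bool)
    pos = {d: i for i, d in enumerate(uniq)}
    rows = np.array([pos[d] for d in days])
    states[rows, minutes] = np.where(counts < cutoff, SLEEP, WAKE)
    observed[rows, minutes] = True
    zero[rows, minutes] = counts == 0

    # flag long zero runs as missing, scanning the record as one time line
    flat_zero = zero.ravel()
    flat_states = states.ravel()
    run_start = None
    for i in range(flat_zero.size + 1):
        z = flat_zero[i] if i < flat_zero.size else False
        if z and run_start is None:
            run_start = i
        elif not z and run_start is not None:
            if i - run_start >= missing_gap_min:
                flat_states[run_start:i] = MISSING
            run_start = None
    states = flat_states.reshape(states.shape)
    m = dict(meta or {})
    m.setdefault("dialect", "actigraphy")
    return SleepRecord(days=uniq, states=states, meta=m)


def read_binarized_matrix(source: Union[str, pd.DataFrame],
                          cutoff: float = 200.0,
                          meta: Optional[dict] = None) -> SleepRecord:
    """Already-binarized per-minute grey levels from a scanned diary image.

    Expects columns ``age_day``, ``minute_of_day``, ``value`` where value is
    a grey level (0 = black = sleep, 255 = white = wake) or a W/S character;
    grey levels below ``cutoff`` are sleep.  Image decoding itself is out of
    scope — this consumes the extracted matrix only.
    """
    df = _as_frame(source)
    if df["value"].dtype == object:
        df = df.assign(state=df["value"])
    else:
        df = df.assign(state=np.where(df["value"].to_numpy(float) < cutoff, "S", "W"))
    m = dict(meta or {})
    m.setdefault("dialect", "binarized")
    return SleepRecord.from_long_frame(df[["age_day", "minute_of_day", "state"]], meta=m)


def keep_complete_days(record: SleepRecord) -> SleepRecord:
    """Drop incomplete days, following the record's dialect.

    Diary dialects drop any day containing missing minutes.  Actigraphy
    keeps within-day missing spans (they are coverage-weighted downstream)
    and drops only days with no observations at all.
    """
    if record.meta.get("dialect") == "actigraphy":
        keep = np.any(record.states != MISSING, axis=1)
    else:
        keep = ~np.any(record.states == MISSING, axis=1)
    return SleepRecord(days=record.days[keep], states=record.states[keep],
                       meta=dict(record.meta))
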