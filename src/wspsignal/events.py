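"""Subject-level event tables and their delimited-text representation.

An :class:`EventTable` is the universal input of every signal test: one
row per subject with a nonnegative event/censoring time, a 0/1 event
indicator, and the end of the observation window.  Times are typically
expressed as a fraction of the observation period (window end 1.0), but
any positive time unit works — the shape parameters tested downstream
are scale-invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EventTable",
    "EventTableError",
    "concatenate",
    "read_event_table",
    "write_event_table",
]


class EventTableError(ValueError):
    """An event table (or file) violates its validity contract."""


@dataclass(frozen=True)
class EventTable:
    """Right-censored event data for a single-arm exposed cohort.

    Parameters
    ----------
    times:
        Per-subject event or censoring times, ``0 <= t_i <= window_end``.
    events:
        Event indicators, 1 = event observed at ``t_i``, 0 = censored.
    window_end:
        End of the observation window ``T`` (same units as ``times``).
    """

    times: np.ndarray
    events: np.ndarray
    window_end: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events)
        object.__setattr__(self, "times", times)
        if times.ndim != 1 or events.shape != times.shape:
            raise EventTableError("times and events must be 1-D and congruent")
        if not np.all(np.isfinite(times)):
            raise EventTableError("event times must be finite")
        if np.any(times < 0):
            raise EventTableError("event times must be nonnegative")
        if not np.all(np.isin(events, (0, 1))):
            raise EventTableError("event indicators must be 0 or 1")
        object.__setattr__(self, "events", events.astype(np.int8))
        end = float(self.window_end)
        object.__setattr__(self, "window_end", end)
        if not np.isfinite(end) or end <= 0:
            raise EventTableError("window_end must be a positive real")
        if times.size and times.max() > end * (1 + 1e-12):
            raise EventTableError("event times exceed the observation window")

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def event_times(self) -> np.ndarray:
        return self.times[self.events == 1]

    @property
    def censoring_times(self) -> np.ndarray:
        return self.times[self.events == 0]

    # -- transforms ------------------------------------------------------

    def censored_at(self, tau: float) -> "EventTable":
        """Administratively right-censor the cohort at time ``tau``.

        Subjects whose event falls after ``tau`` are recorded as
        event-free (censored) at ``tau``; subjects with events at or
        before ``tau`` are unchanged.  The subject count is preserved.
        """
        tau = float(tau)
        if not 0 < tau <= self.window_end:
            raise EventTableError("censoring time must lie inside the window")
        times = np.minimum(self.times, tau)
        events = np.where(self.times <= tau, self.events, 0)
        return EventTable(times, events, tau)

    def rescaled_to_unit(self) -> "EventTable":
        """Rescale times so the observation window becomes [0, 1]."""
        return EventTable(self.times / self.window_end, self.events, 1.0)

    def to_frame(self, ids=None) -> pd.DataFrame:
        if ids is None:
            ids = [f"s{i + 1}" for i in range(self.n)]
        return pd.DataFrame(
            {"id": ids, "time": self.times, "event": self.events.astype(int)}
        )


def concatenate(tables) -> EventTable:
    """Stack event tables observed over the same window."""
    tables = list(tables)
    if not tables:
        raise EventTableError("nothing to concatenate")
    end = tables[0].window_end
    if any(abs(t.window_end - end) > 1e-12 * end for t in tables):
        raise EventTableError("tables span different observation windows")
    return EventTable(
        np.concatenate([t.times for t in tables]),
        np.concatenate([t.events for t in tables]),
        end,
    )


def read_event_table(
    path,
    *,
    sep: str | None = None,
    window_end: float | None = None,
    strict: bool = True,
    time_col: str = "time",
    event_col: str = "event",
) -> EventTable:
    """Read a delimited event table (header ``id,time,event``).

    The delimiter is sniffed when ``sep`` is None (comma default, tab
    accepted).  Rows with missing, negative or unparseable times, or
    event indicators outside {0, 1}, are reported per row: under
    ``strict`` (default) the load fails listing the offending data rows;
    otherwise they are dropped with a warning.  When ``window_end`` is
    not given it is taken as the maximum time in the file (logged).
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    for col in (time_col, event_col):
        if col not in df.columns:
            raise EventTableError(f"{path}: missing required column {col!r}")
    times = pd.to_numeric(df[time_col], errors="coerce")
    events = pd.to_numeric(df[event_col], errors="coerce")
    bad = (
        times.isna()
        | ~np.isfinite(times.fillna(np.inf))
        | (times < 0)
        | ~events.isin((0, 1))
    )
    if bad.any():
        rows = ", ".join(str(i + 2) for i in np.flatnonzero(bad.to_numpy())[:20])
        msg = f"{path}: {int(bad.sum())} invalid row(s) at file line(s) {rows}"
        if strict:
            raise EventTableError(msg)
        logger.warning("%s — dropped (lenient mode)", msg)
        df = df[~bad]
        times, events = times[~bad], events[~bad]
    if window_end is None:
        window_end = float(times.max())
        logger.info("%s: window end not given, using max(time) = %g", path, window_end)
    table = EventTable(times.to_numpy(float), events.to_numpy(int), window_end)
    if table.n_events == 0:
        logger.warning("%s: no observed events — signal tests cannot fire", path)
    return table


def write_event_table(table: EventTable, path, *, ids=None, sep: str = ",") -> None:
    """Write a table as delimited text; round-trips through the reader exactly."""
    table.to_frame(ids).to_csv(path, sep=sep, index=False, float_format="%.17g")
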