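"""Event-coded behavior streams to per-second indicators and local densities.

Observational coding records the initiation timestamp of each utterance,
labelled positive (praise, reflection, description) or negative (commands,
questions, criticism).  Second ``s`` (the half-open interval ``[s, s+1)``)
gets a binary indicator of whether any event of a category initiates in it;
local density at a second is the count of indicator-1 seconds in the centered
5-s window, an integer in 0..5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EventLog",
    "CATEGORIES",
    "events_to_indicator",
    "local_density",
    "task_totals",
]

CATEGORIES = ("positive", "negative")
DEFAULT_DENSITY_WINDOW = 5


@dataclass
class EventLog:
    """Timestamped behavior events for one subject."""

    subject: str
    times: np.ndarray
    categories: np.ndarray
    codes: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.categories = np.asarray(self.categories, dtype=object)
        if self.times.shape != self.categories.shape:
            raise ValueError("times and categories must have equal length")
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise ValueError(
                f"subject {self.subject}: unknown categories {sorted(bad)}"
            )

    @property
    def n_events(self) -> int:
        return int(self.times.size)


def events_to_indicator(
    log: EventLog, task_length: float, category: str
) -> np.ndarray:
    """Per-second binary indicator: 1 iff >= 1 event of ``category`` initiates
    within second ``[s, s+1)``.  Multiple events in one second collapse to 1."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    t = log.times[log.categories == category]
    if t.size and (t.min() < 0 or t.max() >= task_length):
        raise ValueError(
            f"subject {log.subject}: event timestamp outside [0, {task_length})"
        )
    n = int(np.ceil(task_length))
    ind = np.zeros(n, dtype=int)
    if t.size:
        ind[np.floor(t).astype(int)] = 1
    return ind


def local_density(
    indicator: np.ndarray,
    window: int = DEFAULT_DENSITY_WINDOW,
    edges: str = "truncate",
) -> np.ndarray:
    """Centered moving-window count of indicator-1 seconds.

    ``density[t] = sum(indicator[t-h : t+h+1])`` with ``h = window // 2``,
    restricted to the task span.  ``edges="truncate"`` counts over the
    available span at the first/last ``h`` seconds (so the dynamic-model stage
    keeps them); ``edges="missing"`` returns NaN there instead.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd number of seconds")
    ind = np.asarray(indicator)
    if not np.isin(ind, (0, 1)).all():
        raise ValueError("indicator values must be 0 or 1")
    h = window // 2
    dens = np.convolve(ind, np.ones(window, dtype=int), mode="same")
    if edges == "truncate":
        return dens
    if edges == "missing":
        out = dens.astype(float)
        out[:h] = np.nan
        out[len(out) - h :] = np.nan
        return out
    raise ValueError(f"edges must be 'truncate' or 'missing', got {edges!r}")


def task_totals(log: EventLog) -> dict[str, int]:
    """Total event counts per category over the task (events, not
    indicator-seconds)."""
    return {c: int((log.categories == c).sum()) for c in CATEGORIES}
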