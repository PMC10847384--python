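"""Readers and writers for the pipeline's plain-text interchange formats.

Formats
-------
Segmented IBI files
    One directory per subject, files ``segment_0001.txt`` ... in task order,
    one inter-beat interval per line (seconds or milliseconds).  A lost
    segment is a file whose only content is the sentinel ``NA`` (or an empty
    file); it occupies 30 s of task clock with no beats.
Event log CSV
    Columns ``subject, time_s, category[, code]``; one row per coded utterance
    with its initiation timestamp and category (positive/negative).
Moderator CSV
    Column ``subject`` plus numeric score columns.
Per-second long CSV
    Columns ``subject, t, variable, value, missing`` — the interchange format
    between pipeline stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import CATEGORIES, EventLog
from .preprocess import BeatSeries, SEGMENT_LENGTH, compile_segments

__all__ = [
    "read_ibi_segments",
    "write_ibi_segments",
    "read_event_csv",
    "write_event_csv",
    "read_moderator_csv",
    "write_long_csv",
    "read_long_csv",
    "write_manifest",
]

MISSING_SENTINEL = "NA"


def read_ibi_segments(subject_dir: str | Path, unit: str = "s") -> BeatSeries:
    """Read one subject's segmented beat-interval files into a BeatSeries."""
    subject_dir = Path(subject_dir)
    files = sorted(subject_dir.glob("segment_*.txt"))
    if not files:
        raise FileNotFoundError(f"no segment_*.txt files in {subject_dir}")
    segments: list[list[float] | None] = []
    for f in files:
        lines = [ln.strip() for ln in f.read_text().splitlines() if ln.strip()]
        if not lines or lines == [MISSING_SENTINEL]:
            segments.append(None)
            continue
        try:
            segments.append([float(x) for x in lines])
        except ValueError as exc:
            raise ValueError(f"non-numeric record in {f}: {exc}") from exc
    return compile_segments(segments, unit=unit)


def write_ibi_segments(
    subject_dir: str | Path,
    beats: BeatSeries,
    segment_length: float = SEGMENT_LENGTH,
) -> None:
    """Write a BeatSeries as segmented interval files (seconds).

    Intervals are written relative to a reconstruction clock that advances by
    each written interval and by ``segment_length`` per lost segment, so
    ``read_ibi_segments`` recovers the original beat times to text precision.
    """
    subject_dir = Path(subject_dir)
    subject_dir.mkdir(parents=True, exist_ok=True)
    n_seg = int(np.ceil(beats.task_length / segment_length))
    gap_segments = set()
    for g0, g1 in beats.gap_intervals:
        k0 = int(np.floor(g0 / segment_length + 1e-9))
        k1 = int(np.ceil(g1 / segment_length - 1e-9))
        gap_segments.update(range(k0, k1))
    clock = 0.0
    idx = 0
    for k in range(n_seg):
        path = subject_dir / f"segment_{k + 1:04d}.txt"
        if k in gap_segments:
            path.write_text(MISSING_SENTINEL + "\n")
            clock += segment_length
            continue
        seg_end = (k + 1) * segment_length
        lines = []
        while idx < beats.n_beats and beats.beat_times[idx] <= seg_end + 1e-9:
            lines.append(f"{beats.beat_times[idx] - clock:.6f}")
            clock = float(beats.beat_times[idx])
            idx += 1
        path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_event_csv(path: str | Path) -> dict[str, EventLog]:
    """Read an event-log CSV into per-subject EventLogs.

    Malformed rows (bad category, non-numeric time) are reported with their
    1-based file line number.
    """
    df = pd.read_csv(path, dtype={"subject": str})
    required = {"subject", "time_s", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    bad = ~df["category"].isin(CATEGORIES)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header + 1-based
        raise ValueError(
            f"{path}: line {line}: unknown category {df.loc[bad, 'category'].iloc[0]!r}"
        )
    times = pd.to_numeric(df["time_s"], errors="coerce")
    if times.isna().any():
        line = int(df.index[times.isna()][0]) + 2
        raise ValueError(f"{path}: line {line}: non-numeric time_s")
    logs = {}
    for subject, grp in df.groupby("subject", sort=True):
        logs[str(subject)] = EventLog(
            subject=str(subject),
            times=grp["time_s"].to_numpy(dtype=float),
            categories=grp["category"].to_numpy(dtype=object),
            codes=grp["code"].to_numpy(dtype=object) if "code" in grp else None,
        )
    return logs


def write_event_csv(path: str | Path, logs: dict[str, EventLog]) -> None:
    rows = []
    for subject in sorted(logs):
        log = logs[subject]
        for i in range(log.n_events):
            rows.append(
                {
                    "subject": subject,
                    "time_s": log.times[i],
                    "category": log.categories[i],
                    "code": log.codes[i] if log.codes is not None else "",
                }
            )
    pd.DataFrame(
        rows, columns=["subject", "time_s", "category", "code"]
    ).to_csv(path, index=False)


def read_moderator_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject": str})
    if "subject" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column 'subject'")
    if df["subject"].duplicated().any():
        dup = df["subject"][df["subject"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate subject id {dup!r}")
    return df


def write_long_csv(path: str | Path, frames: dict[str, dict[str, tuple]]) -> None:
    """Write per-second series as a long CSV.

    ``frames[subject][variable] = (values, missing)`` with aligned 1 Hz
    arrays.
    """
    rows = []
    for subject in sorted(frames):
        for variable, (values, missing) in frames[subject].items():
            values = np.asarray(values, dtype=float)
            missing = np.asarray(missing, dtype=bool)
            for t in range(values.size):
                rows.append(
                    (subject, t, variable,
                     "" if missing[t] else f"{values[t]:.10g}",
                     int(missing[t]))
                )
    df = pd.DataFrame(
        rows, columns=["subject", "t", "variable", "value", "missing"]
    )
    df.to_csv(path, index=False)


def read_long_csv(path: str | Path) -> dict[str, dict[str, tuple]]:
    """Inverse of :func:`write_long_csv`."""
    df = pd.read_csv(path, dtype={"subject": str})
    out: dict[str, dict[str, tuple]] = {}
    for (subject, variable), grp in df.groupby(["subject", "variable"], sort=True):
        grp = grp.sort_values("t")
        values = pd.to_numeric(grp["value"], errors="coerce").to_numpy()
        missing = grp["missing"].astype(bool).to_numpy()
        values[missing] = np.nan
        out.setdefault(str(subject), {})[str(variable)] = (values, missing)
    return out


def write_manifest(path: str | Path, config: dict, seed: int | None) -> None:
    """Record package/library versions, the seed, and a config hash."""
    import hrvdyn

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "hrvdyn_version": getattr(hrvdyn, "__version__", "unknown"),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
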