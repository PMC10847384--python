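"""End-to-end pipeline driver: beats + events + moderators in, tables out.

Stage order: preprocess (compile, filter, resample) -> RSA -> behavior
density -> penalized-spline smoothing -> coupled-ODE mixed models ->
interaction probing -> report.  Every stage communicates through the declared
record types; the file-based entry point reads the interchange formats of
:mod:`hrvdyn.io` and writes per-second series, tidy parameter tables, and a
manifest, so a run is reproducible from (inputs, config, seed) alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .behavior import EventLog, events_to_indicator, local_density, task_totals
from .mlm import (
    PAIRS,
    FitResult,
    SimpleSlope,
    SubjectRecord,
    build_design,
    fit_pair,
    prepare_moderators,
    probe_interaction,
    report_tables,
)
from .preprocess import (
    BeatSeries,
    filter_outliers,
    interpolate_uniform,
    person_mean,
)
from .rsa import estimate_rsa
from .smoothing import DEFAULT_LAMBDAS, fit_penalized_spline

__all__ = ["PipelineConfig", "PipelineResult", "process_subject",
           "analyze_records", "run_pipeline"]

_PAIR_BY_LABEL = {p.label: p for p in PAIRS}


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run."""

    ibi_dir: str | None = None
    events_csv: str | None = None
    moderators_csv: str | None = None
    out_dir: str | None = None
    unit: str = "s"
    hard_range: tuple[float, float] = (0.2, 2.0)
    adaptive_rel_change: float = 0.25
    band: tuple[float, float] = (0.12, 0.40)
    window_s: int = 30
    lambdas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAMBDAS)
    )
    density_window: int = 5
    edges: str = "truncate"
    pairs: tuple[str, ...] = ("ibi-pos", "ibi-neg", "rsa-pos", "rsa-neg")
    moderators: tuple[str, ...] = ()
    probe_levels: tuple[float, ...] = (-1.0, 0.0, 1.0)
    random_effects: str = "diagonal"
    seed: int | None = None

    def validate(self, moderator_table: pd.DataFrame | None = None) -> None:
        if self.unit not in ("s", "ms"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.edges not in ("truncate", "missing"):
            raise ValueError(f"unknown edge policy {self.edges!r}")
        if self.random_effects not in ("diagonal", "unstructured", "none"):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")
        for p in self.pairs:
            if p not in _PAIR_BY_LABEL:
                raise ValueError(f"unknown pair {p!r}")
        for key, lam in self.lambdas.items():
            if lam < 0:
                raise ValueError(f"lambda for {key!r} must be non-negative")
        if not self.hard_range[0] < self.hard_range[1]:
            raise ValueError("hard_range low must be below high")
        if moderator_table is not None:
            cols = set(moderator_table.columns)
            for m in self.moderators:
                if m not in cols:
                    raise ValueError(
                        f"unknown moderator {m!r}; available: "
                        f"{sorted(c for c in cols if c.endswith('_z'))}"
                    )


@dataclass
class PipelineResult:
    records: list[SubjectRecord]
    fits: list[FitResult]
    probes: list[SimpleSlope]
    table: pd.DataFrame
    log: list[str]


def process_subject(
    subject: str,
    beats: BeatSeries,
    events: EventLog | None,
    config: PipelineConfig,
) -> tuple[SubjectRecord, dict]:
    """Preprocess one subject's raw records into a SubjectRecord.

    Returns the record plus a per-subject audit dict (beats filtered, seconds
    missing per channel) so missingness is traceable per stage.
    """
    filtered, report = filter_outliers(
        beats, config.hard_range, config.adaptive_rel_change
    )
    s1 = interpolate_uniform(filtered, fs=1)
    s4 = interpolate_uniform(filtered, fs=4)
    rsa = estimate_rsa(s4, band=config.band, window_s=config.window_s)

    n_sec = s1.n
    task_length = float(n_sec)
    channels: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "ibi": (s1.values, s1.missing),
        "rsa": (rsa.values, rsa.missing),
    }
    totals = {"positive": 0, "negative": 0}
    if events is not None:
        totals = task_totals(events)
        for cat, key in (("positive", "pos"), ("negative", "neg")):
            ind = events_to_indicator(events, task_length, cat)
            dens = local_density(ind, config.density_window, config.edges)
            channels[key] = (
                np.asarray(dens, dtype=float),
                ~np.isfinite(np.asarray(dens, dtype=float)),
            )

    trajectories = {}
    for key, (vals, miss) in channels.items():
        lam = config.lambdas.get(key, 1.0)
        trajectories[key] = fit_penalized_spline(vals, miss, lam=lam)

    means = {"ibi": person_mean(s1)}
    if (~rsa.missing).any():
        means["rsa"] = float(rsa.values[~rsa.missing].mean())
    record = SubjectRecord(
        subject=subject,
        trajectories=trajectories,
        person_means=means,
        totals=totals,
    )
    audit = {
        "subject": subject,
        "beats_in": report.n_input,
        "beats_removed": report.n_removed,
        "ibi_missing_s": int(s1.missing.sum()),
        "rsa_missing_s": int(rsa.missing.sum()),
        "events": sum(totals.values()),
    }
    return record, audit


def analyze_records(
    records: list[SubjectRecord],
    config: PipelineConfig,
    moderator_table: pd.DataFrame | None = None,
) -> PipelineResult:
    """Model stage: fit each configured pair, then each moderator, then probe."""
    fits: list[FitResult] = []
    probes: list[SimpleSlope] = []
    log: list[str] = []
    for label in config.pairs:
        pair = _PAIR_BY_LABEL[label]
        usable = [
            r for r in records
            if pair.phys in r.trajectories and pair.beh in r.trajectories
            and pair.phys in r.person_means
        ]
        if len(usable) < 2 and config.random_effects != "none":
            log.append(f"pair {label}: skipped ({len(usable)} usable subjects)")
            continue
        design = build_design(usable, pair, moderator_table)
        fit = fit_pair(design, pair, random_effects=config.random_effects)
        fits.append(fit)
        log.append(
            f"pair {label}: base fit on {fit.n_obs} rows / "
            f"{fit.n_subjects} subjects"
        )
        for mod in config.moderators:
            mfit = fit_pair(
                design, pair, moderator=mod,
                random_effects=config.random_effects,
            )
            fits.append(mfit)
            for which in ("c", "f"):
                probes.extend(
                    probe_interaction(mfit, which, config.probe_levels)
                )
            log.append(f"pair {label}: moderator {mod} fit")
    table = report_tables(fits)
    return PipelineResult(records=records, fits=fits, probes=probes,
                          table=table, log=log)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based end-to-end run per the configured stage order.

    Reads segmented IBI directories, the event CSV, and optionally a raw
    moderator CSV; writes per-second series, the tidy parameter table, probe
    table, stage log, and a manifest into ``config.out_dir``.
    """
    if config.ibi_dir is None:
        raise ValueError("config.ibi_dir is required for a file-based run")
    config.validate()

    root = Path(config.ibi_dir)
    subject_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not subject_dirs:
        raise ValueError(f"no subject directories under {root}")
    logs = (
        hio.read_event_csv(config.events_csv) if config.events_csv else {}
    )
    moderator_table = None
    if config.moderators_csv:
        raw = hio.read_moderator_csv(config.moderators_csv)
        moderator_table = prepare_moderators(raw)
    config.validate(moderator_table)

    records, audits = [], []
    for d in subject_dirs:
        subject = d.name
        try:
            beats = hio.read_ibi_segments(d, unit=config.unit)
            rec, audit = process_subject(
                subject, beats, logs.get(subject), config
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage preprocess failed for subject {subject}: {exc}"
            ) from exc
        records.append(rec)
        audits.append(audit)

    result = analyze_records(records, config, moderator_table)
    result.log = [f"{a}" for a in audits] + result.log

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = {
            r.subject: {
                key: (traj.level, traj.missing)
                for key, traj in r.trajectories.items()
            }
            for r in records
        }
        hio.write_long_csv(out / "smoothed_levels.csv", frames)
        result.table.to_csv(out / "parameters.csv", index=False)
        if result.probes:
            pd.DataFrame([vars(p) for p in result.probes]).to_csv(
                out / "simple_slopes.csv", index=False
            )
        (out / "run.log").write_text("\n".join(result.log) + "\n")
        hio.write_manifest(out / "manifest.json", asdict(config), config.seed)
    return result
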