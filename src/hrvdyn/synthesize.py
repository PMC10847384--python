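"""Synthetic cohorts with the statistical structure the analysis assumes.

A cohort is a set of subjects whose latent physiology (inter-beat interval or
RSA) and behavior local density follow a coupled pair of first-order
stochastic differential equations

    d Phys/dt = a_i + b_i (Phys - PhysBar_i) + c_i Beh + sigma_u xi(t)
    d Beh/dt  = d_i + e_i Beh + f_i (Phys - PhysBar_i) + sigma_v eta(t)

with subject coefficients drawn as fixed effect + moderator effect * Z_i +
random effect.  Trajectories are integrated by Euler-Maruyama at dt = 0.1 s
and observed at 1 Hz; at each observed second the realized instantaneous
derivative (drift plus that step's scaled noise) is recorded, so recovery
tests can regress exact derivatives on exact states.  Behavior density is
clipped to the observable range [0, 5].

Two fidelity levels are produced: "latent" cohorts hand the continuous series
(and exact derivatives) straight to the model stage for clean
parameter-recovery tests, while "observed" cohorts additionally render a
beat-level cardiac series with respiratory modulation and sample sparse event
logs from the latent density, exercising the full pipeline; event
discretization attenuates coupling estimates toward zero, so observed cohorts
support sign-recovery rather than point-recovery tests.  The event-sampling
link (per-second Bernoulli with a logistic link on latent density) and the
independence of random effects are modelling choices of this generator, not
features estimated from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .behavior import EventLog
from .preprocess import BeatSeries, SEGMENT_LENGTH, mask_interval

__all__ = [
    "TrueParams",
    "SubjectTruth",
    "SimulatedCohort",
    "simulate_latent_dynamics",
    "render_beats",
    "sample_events",
    "calibrate_event_intercept",
    "inject_missingness",
    "simulate_cohort",
]

#: integration step for the Euler-Maruyama scheme, s
DT = 0.1
#: observable range of behavior local density
DENSITY_RANGE = (0.0, 5.0)
#: plausible IBI range used by the divergence check, s
PLAUSIBLE_IBI = (0.2, 2.0)

# study-condition targets for event totals per 300-s task
TARGET_POSITIVE_EVENTS = 5.27
TARGET_NEGATIVE_EVENTS = 23.16


@dataclass
class TrueParams:
    """Generating parameters for one physiology-behavior pair.

    Rate coefficients are per second; ``b0`` and ``e0`` must be non-positive
    so both variables mean-revert to their set points (the person-mean
    physiology and zero/low behavior density).
    """

    a0: float = 0.0          # physiology-change intercept (units/s)
    b0: float = -0.05        # intrinsic physiology dynamics (1/s)
    c0: float = -0.0015      # behavior level -> physiology change
    d0: float = 0.05         # behavior-change intercept (density/s)
    e0: float = -0.05        # intrinsic behavior dynamics (1/s)
    f0: float = 0.03         # physiology level -> behavior change
    #: level-2 moderator effects on the subject coefficients (per SD of Z)
    mod_effects: dict[str, float] = field(default_factory=dict)
    #: random-effect SDs; only a, c, d, f carry random effects
    re_sd: dict[str, float] = field(
        default_factory=lambda: {"a": 0.002, "c": 0.0008, "d": 0.03, "f": 0.015}
    )
    sigma_u: float = 0.015   # physiology dynamic-noise SD (units/s at 1 s)
    sigma_v: float = 0.3     # behavior dynamic-noise SD (density/s at 1 s)
    phys_mean: float = 0.76  # person-mean physiology distribution, mean
    phys_sd: float = 0.12    # person-mean physiology distribution, SD
    resp_amp: float = 0.03   # respiratory IBI modulation amplitude (s)
    resp_freq: float = 0.25  # respiratory frequency (Hz)
    event_slope: float = 1.0       # logistic link slope on latent density
    event_intercept: float = -5.1  # logistic link intercept
    segment_drop_rate: float = 0.016  # per-30-s-segment drop probability
    task_length: float = 300.0
    n_subjects: int = 204
    phys: str = "ibi"
    beh: str = "pos"

    def validate(self) -> None:
        if self.b0 > 0 or self.e0 > 0:
            raise ValueError("b0 and e0 must be <= 0 (mean reversion)")
        if any(v < 0 for v in self.re_sd.values()):
            raise ValueError("random-effect SDs must be non-negative")
        if min(self.sigma_u, self.sigma_v, self.phys_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.task_length <= 0 or self.task_length % 1.0 != 0:
            raise ValueError("task_length must be a positive whole number of s")
        if not 0 <= self.segment_drop_rate <= 1:
            raise ValueError("segment_drop_rate must be a probability")


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject."""

    subject: str
    coeffs: dict[str, float]       # realized a..f for this subject
    phys_bar: float                # generating person-mean physiology
    z: float                       # level-2 moderator score
    phys: np.ndarray               # latent physiology at 1 Hz
    beh: np.ndarray                # latent behavior density at 1 Hz
    dphys: np.ndarray              # exact realized dPhys/dt at 1 Hz
    dbeh: np.ndarray               # exact realized dBeh/dt at 1 Hz
    beats: BeatSeries | None = None
    events: EventLog | None = None


@dataclass
class SimulatedCohort:
    params: TrueParams
    seed: int
    fidelity: str
    subjects: list[SubjectTruth]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def moderator_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"subject": [s.subject for s in self.subjects],
             "z": [s.z for s in self.subjects]}
        )


def simulate_latent_dynamics(
    params: TrueParams, seed: int
) -> list[SubjectTruth]:
    """Integrate the coupled pair for every subject at dt = 0.1 s.

    Subject coefficients are fixed effect + moderator effect * Z_i + random
    effect (random effects independent across coefficients).  Observations are
    kept at 1 Hz; ``dphys``/``dbeh`` hold the observed derivative at each
    second — the drift evaluated at the recorded state plus that step's
    unit-variance draw scaled by the per-second residual SD — so the recorded
    (state, derivative) pairs satisfy the generating equations exactly, with
    residuals of SD ``sigma_u`` / ``sigma_v`` independent of the states.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_subjects
    n_sec = int(params.task_length)
    steps_per_sec = int(round(1.0 / DT))
    n_steps = n_sec * steps_per_sec

    z = rng.standard_normal(n)
    me = params.mod_effects
    coeffs = {}
    for name, base in zip("abcdef", (params.a0, params.b0, params.c0,
                                     params.d0, params.e0, params.f0)):
        v = np.full(n, base) + me.get(name, 0.0) * z
        sd = params.re_sd.get(name, 0.0)
        if sd > 0:
            v = v + rng.normal(0.0, sd, n)
        coeffs[name] = v
    phys_bar = rng.normal(params.phys_mean, params.phys_sd, n)

    # start at the deterministic set point of each subject's system
    beh_eq = np.clip(
        -coeffs["d"] / np.where(coeffs["e"] != 0, coeffs["e"], -1e-12),
        *DENSITY_RANGE,
    )
    phys = phys_bar + np.where(
        coeffs["b"] != 0,
        -(coeffs["a"] + coeffs["c"] * beh_eq) / np.where(coeffs["b"] != 0, coeffs["b"], 1.0),
        0.0,
    )
    beh = beh_eq.copy()

    sqdt = np.sqrt(DT)
    phys_obs = np.empty((n, n_sec))
    beh_obs = np.empty((n, n_sec))
    dphys_obs = np.empty((n, n_sec))
    dbeh_obs = np.empty((n, n_sec))
    for k in range(n_steps):
        drift_p = (coeffs["a"] + coeffs["b"] * (phys - phys_bar)
                   + coeffs["c"] * beh)
        drift_b = (coeffs["d"] + coeffs["e"] * beh
                   + coeffs["f"] * (phys - phys_bar))
        xi = rng.standard_normal(n)
        eta = rng.standard_normal(n)
        if k % steps_per_sec == 0:
            s = k // steps_per_sec
            phys_obs[:, s] = phys
            beh_obs[:, s] = beh
            # observed derivative = drift at the recorded state plus a
            # unit-variance draw scaled by the per-second residual SD, so the
            # recorded (state, derivative) pairs satisfy the generating
            # equations with residual SD exactly sigma_u / sigma_v
            dphys_obs[:, s] = drift_p + params.sigma_u * xi
            dbeh_obs[:, s] = drift_b + params.sigma_v * eta
        phys = phys + drift_p * DT + params.sigma_u * sqdt * xi
        beh = beh + drift_b * DT + params.sigma_v * sqdt * eta
        np.clip(beh, *DENSITY_RANGE, out=beh)

    if params.phys == "ibi":
        frac_out = np.mean(
            (phys_obs < PLAUSIBLE_IBI[0]) | (phys_obs > PLAUSIBLE_IBI[1])
        )
        if frac_out > 0.10:
            raise ValueError(
                f"non-mean-reverting parameter set: {frac_out:.1%} of simulated "
                f"IBI samples fall outside {PLAUSIBLE_IBI} s"
            )

    width = len(str(n))
    return [
        SubjectTruth(
            subject=f"s{i:0{width}d}",
            coeffs={k: float(v[i]) for k, v in coeffs.items()},
            phys_bar=float(phys_bar[i]),
            z=float(z[i]),
            phys=phys_obs[i],
            beh=beh_obs[i],
            dphys=dphys_obs[i],
            dbeh=dbeh_obs[i],
        )
        for i in range(n)
    ]


def render_beats(
    latent_ibi: np.ndarray,
    resp_amp: float,
    resp_freq: float,
    seed: int | None = None,
    task_length: float | None = None,
) -> BeatSeries:
    """Generate a beat series whose intervals track the latent IBI trajectory.

    Each interval equals the latent IBI evaluated at the current beat time
    plus a respiratory modulation ``resp_amp * sin(2 pi resp_freq t + phi)``
    (phase drawn from ``seed``; zero when ``seed`` is None).  The downstream
    spectral stage should recover ``ln(resp_amp**2 / 2)`` as the RSA level.
    """
    latent = np.asarray(latent_ibi, dtype=float)
    if np.any(latent <= 0):
        raise ValueError("latent IBI trajectory must be strictly positive")
    if abs(resp_amp) >= latent.min():
        raise ValueError(
            "respiratory amplitude too large: modulated interval can reach zero"
        )
    if task_length is None:
        task_length = float(latent.size)
    phase = 0.0
    if seed is not None:
        phase = float(np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi))
    grid = np.arange(latent.size, dtype=float)
    times = []
    ibis = []
    t = 0.0
    while True:
        ibi = float(np.interp(t, grid, latent)) + resp_amp * np.sin(
            2.0 * np.pi * resp_freq * t + phase
        )
        if ibi <= 1e-6:
            raise ValueError(
                "respiratory amplitude too large: non-positive interval"
            )
        t += ibi
        if t > task_length:
            break
        times.append(t)
        ibis.append(ibi)
    return BeatSeries(
        np.array(times), np.array(ibis), task_length=float(task_length)
    )


def sample_events(
    latent_density: np.ndarray,
    intercept: float,
    slope: float,
    seed: int,
    subject: str = "s0",
    category: str = "positive",
) -> EventLog:
    """Sample a sparse event log from the latent density.

    Each second independently receives at most one event, with probability
    ``logistic(intercept + slope * density)``; the timestamp is uniform within
    the second.
    """
    rng = np.random.default_rng(seed)
    d = np.asarray(latent_density, dtype=float)
    p = 1.0 / (1.0 + np.exp(-(intercept + slope * d)))
    hit = rng.random(d.size) < p
    secs = np.nonzero(hit)[0]
    times = secs + rng.random(secs.size)
    return EventLog(
        subject=subject,
        times=times,
        categories=np.array([category] * secs.size, dtype=object),
    )


def calibrate_event_intercept(
    latent_density: np.ndarray, slope: float, target_mean_events: float
) -> float:
    """Intercept making the expected events per task match the target.

    Solves ``mean_t sum_s logistic(b0 + slope * d) = target`` by bisection over
    the pooled latent densities of a cohort (rows = subjects or one subject).
    """
    d = np.asarray(latent_density, dtype=float).ravel()
    n_sec = (
        latent_density.shape[-1]
        if np.ndim(latent_density) > 1
        else latent_density.size
    )

    def expected(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + slope * d)))) * n_sec)

    lo, hi = -30.0, 30.0
    if not expected(lo) < target_mean_events < expected(hi):
        raise ValueError("target event count unreachable with this link slope")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) < target_mean_events:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def inject_missingness(
    cohort: SimulatedCohort, segment_drop_rate: float, seed: int
) -> SimulatedCohort:
    """Drop each 30-s recording segment independently with the given rate.

    Dropped segments become gap intervals in the subject's beat series (lost
    recording, not deleted time).  Latent truth is untouched.
    """
    if not 0 <= segment_drop_rate <= 1:
        raise ValueError("segment_drop_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    new_subjects = []
    for sub in cohort.subjects:
        if sub.beats is None:
            new_subjects.append(sub)
            continue
        n_seg = int(np.ceil(sub.beats.task_length / SEGMENT_LENGTH))
        drop = rng.random(n_seg) < segment_drop_rate
        beats = sub.beats
        for k in np.nonzero(drop)[0]:
            beats = mask_interval(
                beats,
                k * SEGMENT_LENGTH,
                min((k + 1) * SEGMENT_LENGTH, sub.beats.task_length),
            )
        new_subjects.append(replace(sub, beats=beats))
    return replace(cohort, subjects=new_subjects)


def simulate_cohort(
    params: TrueParams, seed: int, fidelity: str = "latent"
) -> SimulatedCohort:
    """Generate a full cohort at the requested fidelity.

    ``"latent"`` keeps the exact 1 Hz trajectories and derivatives only;
    ``"observed"`` additionally renders beat series (with respiratory
    modulation and segment dropout) and samples event logs, the inputs the
    file-based pipeline consumes.
    """
    if fidelity not in ("latent", "observed"):
        raise ValueError("fidelity must be 'latent' or 'observed'")
    subjects = simulate_latent_dynamics(params, seed)
    cohort = SimulatedCohort(params, seed, fidelity, subjects)
    if fidelity == "observed":
        ss = np.random.SeedSequence(seed)
        child = ss.spawn(2 * len(subjects))
        cat = "positive" if params.beh == "pos" else "negative"
        for i, sub in enumerate(subjects):
            if params.phys == "ibi":
                sub.beats = render_beats(
                    sub.phys,
                    params.resp_amp,
                    params.resp_freq,
                    seed=int(child[2 * i].generate_state(1)[0] % (2**31)),
                    task_length=params.task_length,
                )
            sub.events = sample_events(
                sub.beh,
                params.event_intercept,
                params.event_slope,
                seed=int(child[2 * i + 1].generate_state(1)[0] % (2**31)),
                subject=sub.subject,
                category=cat,
            )
        cohort = inject_missingness(
            cohort, params.segment_drop_rate, seed=seed + 1_000_003
        )
    return cohort
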