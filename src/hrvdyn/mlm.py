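"""Coupled-ODE multilevel models for physiology-behavior dynamics.

Each of the four physiology x behavior pairs (IBI/RSA crossed with
positive/negative behavior density) is fit as two linear mixed models, one per
outcome equation of the pair:

    dPhys_i(t)/dt = a_i + b (Phys_i(t) - PhysBar_i) + c_i Beh_i(t) + u_i(t)
    dBeh_i(t)/dt  = d_i + e Beh_i(t) + f_i (Phys_i(t) - PhysBar_i) + v_i(t)

Random effects (independent, subject level) are estimated for the intercepts
and the cross-variable coupling slopes only (a & c in the physiology equation,
d & f in the behavior equation); the intrinsic-dynamics slopes b and e carry
none.  Moderator models add the standardized level-2 score's main effect and
its interaction with the coupling term, plus the task-total behavior frequency
as a covariate with the same two roles.  Estimation is REML via statsmodels
MixedLM; p-values are Wald-z (normal approximation).  Simple slopes at
moderator levels mean and +/-1 SD use delta-method standard errors from the
fixed-effect covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .smoothing import SmoothedTrajectory

__all__ = [
    "ODEPairSpec",
    "SubjectRecord",
    "EquationFit",
    "FitResult",
    "SimpleSlope",
    "prepare_moderators",
    "standardize",
    "build_design",
    "fit_pair",
    "probe_interaction",
    "simple_slopes",
    "report_tables",
    "PAIRS",
]


@dataclass(frozen=True)
class ODEPairSpec:
    """One physiology-behavior pair and its parameter naming."""

    phys: str  # "ibi" or "rsa"
    beh: str   # "pos" or "neg"
    index: int  # 1..4, the conventional pair numbering

    def __post_init__(self) -> None:
        if self.phys not in ("ibi", "rsa") or self.beh not in ("pos", "neg"):
            raise ValueError(f"unknown pair ({self.phys}, {self.beh})")

    @property
    def label(self) -> str:
        return f"{self.phys}-{self.beh}"

    @property
    def task_total_covariate(self) -> str:
        """Mandatory covariate: task-total frequency of the pair's behavior."""
        return f"total_{self.beh}"


#: the four canonical pairs
PAIRS = (
    ODEPairSpec("ibi", "pos", 1),
    ODEPairSpec("ibi", "neg", 2),
    ODEPairSpec("rsa", "pos", 3),
    ODEPairSpec("rsa", "neg", 4),
)


@dataclass
class SubjectRecord:
    """Aligned smoothed trajectories and summaries for one subject."""

    subject: str
    trajectories: dict[str, SmoothedTrajectory]  # keys ibi/rsa/pos/neg
    person_means: dict[str, float]               # task-average ibi / rsa
    totals: dict[str, int]                       # task-total pos / neg events


@dataclass
class SimpleSlope:
    moderator: str
    level: float  # in SD units of the moderator
    slope: float
    se: float
    z: float
    p: float


@dataclass
class EquationFit:
    """One outcome equation of a pair, with canonical parameter names."""

    outcome: str
    params: pd.DataFrame          # index: canonical names; est, se, z, p
    cov_params: pd.DataFrame      # fixed-effect covariance, canonical names
    random_variances: dict[str, float]
    resid_variance: float
    converged: bool
    n_obs: int = 0


@dataclass
class FitResult:
    pair: ODEPairSpec
    moderator: str | None
    phys_eq: EquationFit
    beh_eq: EquationFit
    n_obs: int
    n_subjects: int

    def coupling(self, which: str) -> pd.Series:
        """Row for the coupling coefficient: ``"c"`` (behavior -> physiology
        change) or ``"f"`` (physiology -> behavior change)."""
        if which == "c":
            return self.phys_eq.params.loc["c"]
        if which == "f":
            return self.beh_eq.params.loc["f"]
        raise KeyError(which)


# ---------------------------------------------------------------------------
# moderator preparation

def standardize(col: pd.Series) -> pd.Series:
    """Z-standardize on the sample mean/SD of non-missing entries."""
    v = col.astype(float)
    sd = v.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"column {col.name!r} has no variance to standardize")
    return (v - v.mean()) / sd


#: default composite recipes: output column -> (operation, input columns).
#: sum: add items; mean: average them; median_split: 1 if above the sample
#: median else 0; any_nonzero: 1 if the score is nonzero; identity: pass through
DEFAULT_RECIPES: dict[str, tuple[str, tuple[str, ...]]] = {
    "harsh_attributions": ("sum", ("attribution_control", "attribution_hostile")),
    "parenting_stress": ("mean", ("stress_difficult_child", "stress_dysfunction")),
    "mental_health": ("mean", ("depression_t", "anxiety_t")),
    "hit_rate_positive": ("median_split", ("hit_rate_happy",)),
    "false_alarm_anger": ("any_nonzero", ("false_alarm_angry",)),
    "reaction_time_happy": ("identity", ("reaction_time_happy",)),
    "reaction_time_angry": ("identity", ("reaction_time_angry",)),
    "inhibitory_control": ("identity", ("inhibit_t",)),
}


def prepare_moderators(
    raw: pd.DataFrame,
    recipes: dict[str, tuple[str, tuple[str, ...]]] | None = None,
) -> pd.DataFrame:
    """Build composite moderator scores and z-standardize every predictor.

    ``raw`` must carry a ``subject`` column; remaining columns are item or
    scale scores.  Composites follow the recipe table (sum of the two
    attribution items, mean of the two stress percentiles, mean of the two
    symptom T-scores, median split of the positive-emotion hit rate,
    any-nonzero split of anger false alarms).  Returns raw composites plus
    ``<name>_z`` standardized columns.  Missing subjects stay missing.
    """
    if "subject" not in raw.columns:
        raise ValueError("moderator table must have a 'subject' column")
    if raw["subject"].duplicated().any():
        raise ValueError("duplicate subject ids in moderator table")
    if recipes is None:
        recipes = {
            k: v for k, v in DEFAULT_RECIPES.items()
            if all(c in raw.columns for c in v[1])
        }
        # columns not consumed by a recipe pass through as their own predictor
        used = {c for _, cols in recipes.values() for c in cols}
        for c in raw.columns:
            if c != "subject" and c not in used and c not in recipes:
                recipes[c] = ("identity", (c,))

    out = pd.DataFrame({"subject": raw["subject"]})
    for name, (op, cols) in recipes.items():
        missing_cols = [c for c in cols if c not in raw.columns]
        if missing_cols:
            raise ValueError(f"recipe {name!r} needs missing columns {missing_cols}")
        block = raw[list(cols)].astype(float)
        if op == "sum":
            score = block.sum(axis=1, skipna=False)
        elif op == "mean":
            score = block.mean(axis=1, skipna=False)
        elif op == "median_split":
            v = block.iloc[:, 0]
            score = (v > v.median()).astype(float).where(v.notna())
        elif op == "any_nonzero":
            v = block.iloc[:, 0]
            score = (v != 0).astype(float).where(v.notna())
        elif op == "identity":
            score = block.iloc[:, 0]
        else:
            raise ValueError(f"unknown recipe operation {op!r}")
        if score.notna().sum() == 0:
            raise ValueError(f"moderator {name!r} is entirely missing")
        out[name] = score
        out[f"{name}_z"] = standardize(score)
    return out


# ---------------------------------------------------------------------------
# design construction

def build_design(
    records: list[SubjectRecord],
    pair: ODEPairSpec,
    moderators: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stack one row per subject-second with both equations' variables.

    Columns: ``subject``, ``t``, ``dphys``, ``dbeh``, ``phys_c`` (physiology
    centered on the person's task average), ``beh`` (local density), the
    standardized task totals of both behaviors, and any ``*_z`` moderator
    columns.  Rows with a missing element are dropped (listwise,
    missing-at-random treatment).
    """
    frames = []
    for rec in records:
        phys = rec.trajectories[pair.phys]
        beh = rec.trajectories[pair.beh]
        n = min(phys.n, beh.n)
        ok = ~(phys.missing[:n] | beh.missing[:n])
        if not ok.any():
            continue
        t = np.arange(n)[ok]
        frames.append(
            pd.DataFrame(
                {
                    "subject": rec.subject,
                    "t": t,
                    "dphys": phys.deriv[:n][ok],
                    "dbeh": beh.deriv[:n][ok],
                    "phys_c": phys.level[:n][ok] - rec.person_means[pair.phys],
                    "beh": beh.level[:n][ok],
                    "total_pos": rec.totals.get("positive", np.nan),
                    "total_neg": rec.totals.get("negative", np.nan),
                }
            )
        )
    if not frames:
        raise ValueError("empty design: no subject has overlapping observed runs")
    design = pd.concat(frames, ignore_index=True)
    for tot in ("total_pos", "total_neg"):
        per_sub = design.groupby("subject")[tot].first()
        if per_sub.notna().any() and per_sub.std(ddof=1) > 0:
            z = standardize(per_sub)
            design[f"{tot}_z"] = design["subject"].map(z)
    if moderators is not None:
        zcols = [c for c in moderators.columns if c.endswith("_z")]
        design = design.merge(
            moderators[["subject"] + zcols], on="subject", how="left"
        )
    return design.dropna(
        subset=["dphys", "dbeh", "phys_c", "beh"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# model fitting

def _canonical_names(
    eq: str, pair_index: int, moderator: str | None, covariate: str | None
) -> dict[str, str]:
    """Map patsy term names to canonical parameter names.

    Physiology equation terms map to a/b/c (+ gamma names for level-2 terms);
    behavior equation terms to d/e/f.
    """
    i = pair_index
    if eq == "phys":
        names = {"Intercept": "a", "phys_c": "b", "beh": "c"}
        inter = "beh"
        g = {"main": f"gamma_a{i}", "inter": f"gamma_c{i}"}
    else:
        names = {"Intercept": "d", "beh": "e", "phys_c": "f"}
        inter = "phys_c"
        g = {"main": f"gamma_d{i}", "inter": f"gamma_f{i}"}
    extras = []
    if moderator is not None:
        extras.append(("mod", moderator))
    if covariate is not None and covariate != moderator:
        extras.append(("cov", covariate))
    for kind, term in extras:
        suffix = "1" if kind == "mod" else "2"
        names[term] = f"{g['main']}{suffix}:{term}"
        names[f"{term}:{inter}"] = f"{g['inter']}{suffix}:{term}"
        names[f"{inter}:{term}"] = f"{g['inter']}{suffix}:{term}"
    return names


def _fit_equation(
    design: pd.DataFrame,
    eq: str,
    pair: ODEPairSpec,
    moderator: str | None,
    covariate: str | None,
    random_effects: str,
) -> EquationFit:
    outcome = "dphys" if eq == "phys" else "dbeh"
    if eq == "phys":
        base_terms = ["phys_c", "beh"]
        coupling_term = "beh"
    else:
        base_terms = ["beh", "phys_c"]
        coupling_term = "phys_c"
    terms = list(base_terms)
    for extra in (moderator, covariate):
        if extra is not None and extra not in terms:
            terms += [extra, f"{extra}:{coupling_term}"]
    formula = f"{outcome} ~ " + " + ".join(terms)

    # fit on internally standardized columns (native IBI units put the
    # variance components near 1e-7, where the REML optimizer stalls), then
    # map estimates, covariances and variances back to native units
    design = design.copy()
    sy = float(design[outcome].std(ddof=1)) or 1.0
    scales = {"phys_c": float(design["phys_c"].std(ddof=1)) or 1.0,
              "beh": float(design["beh"].std(ddof=1)) or 1.0}
    design[outcome] = design[outcome] / sy
    for colname, s in scales.items():
        design[colname] = design[colname] / s

    def term_scale(term: str) -> float:
        sf = 1.0
        for factor in term.split(":"):
            sf *= scales.get(factor, 1.0)
        return sf

    if random_effects == "none":
        model = smf.ols(formula, data=design, missing="drop")
        res = model.fit()
        fe = res.params
        cov = res.cov_params()
        rv: dict[str, float] = {}
        resid_var = float(res.mse_resid) * sy**2
        bse, zval, pval = res.bse, res.tvalues, res.pvalues
        converged = True
    elif random_effects in ("diagonal", "unstructured"):
        if random_effects == "diagonal":
            model = smf.mixedlm(
                formula,
                data=design,
                groups="subject",
                re_formula="0",
                vc_formula={
                    "intercept": "1",
                    "coupling": f"0 + {coupling_term}",
                },
                missing="drop",
            )
        else:
            model = smf.mixedlm(
                formula,
                data=design,
                groups="subject",
                re_formula=f"1 + {coupling_term}",
                missing="drop",
            )
        res = model.fit(reml=True, method=["powell", "lbfgs"])
        k = model.k_fe
        fe = res.params[:k]
        cov = res.cov_params().iloc[:k, :k]
        bse, zval, pval = res.bse[:k], res.tvalues[:k], res.pvalues[:k]
        sc = sy**2
        resid_var = float(res.scale) * sc
        if random_effects == "diagonal":
            v0 = float(res.vcomp[0]) if len(res.vcomp) else np.nan
            v1 = float(res.vcomp[1]) if len(res.vcomp) > 1 else np.nan
            rv = {
                "intercept": v0 * sc,
                "coupling": v1 * sc / scales[coupling_term] ** 2,
            }
        else:
            cre = res.cov_re
            rv = {
                "intercept": float(cre.iloc[0, 0]) * sc,
                "coupling": float(cre.iloc[1, 1]) * sc / scales[coupling_term] ** 2,
                "covariance": float(cre.iloc[0, 1]) * sc / scales[coupling_term],
            }
        converged = bool(res.converged)
    else:
        raise ValueError(
            "random_effects must be 'diagonal', 'unstructured' or 'none'"
        )

    # back-transform from standardized to native units
    sfs = np.array([sy / term_scale(t) for t in fe.index])
    fe = fe * sfs
    bse = bse * sfs
    cov = np.asarray(cov) * np.outer(sfs, sfs)

    rename = _canonical_names(eq, pair.index, moderator, covariate)
    mapped = [rename.get(t, t) for t in fe.index]
    params = pd.DataFrame(
        {
            "estimate": np.asarray(fe, dtype=float),
            "se": np.asarray(bse, dtype=float),
            "z": np.asarray(zval, dtype=float),
            "p": np.asarray(pval, dtype=float),
        },
        index=mapped,
    )
    cov = pd.DataFrame(cov, index=mapped, columns=mapped)
    return EquationFit(
        outcome=outcome,
        params=params,
        cov_params=cov,
        random_variances=rv,
        resid_variance=resid_var,
        converged=converged,
        n_obs=int(res.nobs),
    )


def fit_pair(
    design: pd.DataFrame,
    pair: ODEPairSpec,
    moderator: str | None = None,
    random_effects: str = "diagonal",
    include_task_total: bool | None = None,
) -> FitResult:
    """REML fit of both outcome equations of one physiology-behavior pair.

    ``moderator`` names a standardized (``*_z``) column of the design; when
    given, the standardized task-total frequency of the pair's behavior enters
    the same model as a covariate (both main effect and coupling interaction),
    unless it is itself the moderator or ``include_task_total=False``.
    ``random_effects``: ``"diagonal"`` (default; independent intercept and
    coupling-slope components), ``"unstructured"`` (correlated 2x2), or
    ``"none"`` (pooled least squares; equivalent to constraining the
    random-effect variances to zero).
    """
    n_sub = design["subject"].nunique()
    if n_sub < 2 and random_effects != "none":
        raise ValueError("need >= 2 subjects for a mixed model")
    covariate = None
    if moderator is not None:
        if moderator not in design.columns:
            raise ValueError(f"moderator {moderator!r} not in design")
        if include_task_total is None:
            include_task_total = True
        tot = f"{pair.task_total_covariate}_z"
        if include_task_total and tot in design.columns and tot != moderator:
            covariate = tot
    phys_eq = _fit_equation(design, "phys", pair, moderator, covariate, random_effects)
    beh_eq = _fit_equation(design, "beh", pair, moderator, covariate, random_effects)
    return FitResult(
        pair=pair,
        moderator=moderator,
        phys_eq=phys_eq,
        beh_eq=beh_eq,
        n_obs=phys_eq.n_obs,
        n_subjects=n_sub,
    )


# ---------------------------------------------------------------------------
# probing and reporting

def simple_slopes(
    base: float,
    interaction: float,
    cov: np.ndarray,
    levels: tuple[float, ...] = (-1.0, 0.0, 1.0),
    moderator: str = "moderator",
) -> list[SimpleSlope]:
    """Moderated coupling slope at fixed moderator levels (SD units).

    ``slope(level) = base + level * interaction`` with the delta-method SE
    ``sqrt(var_b + level^2 var_i + 2 level cov_bi)`` and a Wald-z p-value.
    """
    cov = np.asarray(cov, dtype=float)
    out = []
    for lev in levels:
        s = base + lev * interaction
        var = cov[0, 0] + lev**2 * cov[1, 1] + 2 * lev * cov[0, 1]
        se = float(np.sqrt(max(var, 0.0)))
        z = s / se if se > 0 else np.nan
        from scipy.stats import norm

        p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
        out.append(SimpleSlope(moderator, float(lev), float(s), se, float(z), p))
    return out


def probe_interaction(
    fit: FitResult,
    which: str = "c",
    levels: tuple[float, ...] = (-1.0, 0.0, 1.0),
) -> list[SimpleSlope]:
    """Probe a fitted moderator interaction at mean and +/-1 SD.

    ``which="c"`` probes how behavior density predicts physiology change;
    ``which="f"`` the reverse coupling.
    """
    if fit.moderator is None:
        raise ValueError("fit has no moderator to probe")
    eq = fit.phys_eq if which == "c" else fit.beh_eq
    i = fit.pair.index
    inter_name = f"gamma_{'c' if which == 'c' else 'f'}{i}1:{fit.moderator}"
    if inter_name not in eq.params.index:
        raise ValueError(f"interaction term {inter_name!r} missing from fit")
    base = float(eq.params.loc[which, "estimate"])
    inter = float(eq.params.loc[inter_name, "estimate"])
    cov = eq.cov_params.loc[[which, inter_name], [which, inter_name]].to_numpy()
    return simple_slopes(base, inter, cov, levels, moderator=fit.moderator)


def report_tables(fits: list[FitResult]) -> pd.DataFrame:
    """Tidy per-moderator table of coupling coefficients across pairs.

    One row per (moderator, pair); columns give the moderator's interaction
    with each coupling direction (estimate, SE, p), mirroring the layout used
    to report moderated intra-individual dynamics.  Base (no-moderator) fits
    report the couplings themselves.
    """
    rows = []
    for fit in fits:
        i = fit.pair.index
        if fit.moderator is None:
            c = fit.phys_eq.params.loc["c"]
            f = fit.beh_eq.params.loc["f"]
            label = "(base model)"
        else:
            c = fit.phys_eq.params.loc[f"gamma_c{i}1:{fit.moderator}"]
            f = fit.beh_eq.params.loc[f"gamma_f{i}1:{fit.moderator}"]
            label = fit.moderator
        rows.append(
            {
                "moderator": label,
                "pair": fit.pair.label,
                "c_estimate": c["estimate"],
                "c_se": c["se"],
                "c_p": c["p"],
                "f_estimate": f["estimate"],
                "f_se": f["se"],
                "f_p": f["p"],
                "n_obs": fit.n_obs,
                "n_subjects": fit.n_subjects,
            }
        )
    return pd.DataFrame(rows)


def records_from_cohort(cohort) -> list[SubjectRecord]:
    """SubjectRecords straight from a latent simulated cohort.

    Latent fidelity shortcut: the exact simulated states and derivatives
    stand in for the smoothed level/derivative, and the generating set point
    stands in for the person mean, so recovery tests isolate the estimator
    from set-point estimation error.  (Centering on the observed task average
    instead cancels the between-subject part of the coupling signal and
    attenuates the coupling estimates whenever behavior levels vary between
    subjects; see the methods note.)
    """
    recs = []
    for sub in cohort.subjects:
        n = sub.phys.size
        phys_traj = SmoothedTrajectory(
            level=sub.phys, deriv=sub.dphys,
            missing=np.zeros(n, bool), lam=0.0,
        )
        beh_traj = SmoothedTrajectory(
            level=sub.beh, deriv=sub.dbeh,
            missing=np.zeros(n, bool), lam=0.0,
        )
        recs.append(
            SubjectRecord(
                subject=sub.subject,
                trajectories={cohort.params.phys: phys_traj,
                              cohort.params.beh: beh_traj},
                person_means={cohort.params.phys: float(sub.phys_bar)},
                totals={},
            )
        )
    return recs
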