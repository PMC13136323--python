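"""Longitudinal clinical outcome models.

Two families of linear mixed-effects models are fit per outcome, both of
the form ``outcome ~ 1 + X * time + (1 + time | subject)`` with time
coded as visit index in 16-week units (weeks 0/16/32/48 -> 0/1/2/3):

* the treatment model, where X is an on-drug indicator (1 at weeks
  32/48, i.e. after the no-treatment lead-in phase), and
* the rho model, where X is the time-varying signature-shift score:
  each subject's lead-in rho is carried at weeks 0 and 16 and their
  treatment-phase rho at weeks 32 and 48.  The rho x time coefficient
  is the headline estimate: it measures how strongly a metabolic shift
  toward (positive rho) or away from (negative rho) the disease
  signature bends the outcome trajectory.

Fits use REML with Wald z tests on fixed effects; when the random-slope
model fails to converge the fit falls back to a random intercept only
and records that.  Counterfactual trajectories for a hypothetical rho
profile are population-level predictions with delta-method bands from
the fixed-effect covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

VISIT_WEEKS = (0, 16, 32, 48)
WEEKS_PER_UNIT = 16.0
OUTCOME_NAMES = ("IBM_FRS", "mTUG", "sixMWT", "grip", "knee_dyn", "MMT_knee", "CK", "Fi2", "falls")


@dataclass
class MixedModelResult:
    outcome_name: str
    model_type: str  # "treatment" | "rho"
    terms: list
    estimates: dict = field(default_factory=dict)
    ses: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)
    cov_fe: np.ndarray | None = None
    random_structure: str = "intercept_and_slope"
    converged: bool = False
    n_obs: int = 0
    n_subjects: int = 0
    audit: list = field(default_factory=list)

    def fixed_effects(self) -> pd.DataFrame:
        idx = self.terms if self.converged else []
        return pd.DataFrame(
            {
                "estimate": pd.Series(self.estimates, dtype=float),
                "se": pd.Series(self.ses, dtype=float),
                "p": pd.Series(self.pvalues, dtype=float),
            }
        ).reindex(idx)


@dataclass
class PhaseComparison:
    variable_name: str
    changes: pd.DataFrame  # subject_id, leadin_change, treatment_change
    mean_difference: float
    ci: tuple
    t: float
    p: float
    degenerate: bool = False


def _time_units(week) -> np.ndarray:
    return np.asarray(week, dtype=float) / WEEKS_PER_UNIT


def _fit_mixedlm(endog, exog, groups, exog_names, random_slope: bool, time):
    if random_slope:
        exog_re = np.column_stack([np.ones_like(time), time])
    else:
        exog_re = np.ones((len(time), 1))
    model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True, method=["lbfgs", "powell"], maxiter=500)
        ok = bool(fit.converged) and bool(np.all(np.isfinite(np.asarray(fit.bse_fe))))
    except (np.linalg.LinAlgError, ValueError):
        return None, False
    return fit, ok


def _run_model(records: pd.DataFrame, outcome_name: str, covariate: pd.Series, model_type: str) -> MixedModelResult:
    df = records[(records["outcome"] == outcome_name)].dropna(subset=["value"]).copy()
    if df.empty:
        raise ValueError(f"no records for outcome {outcome_name!r}")
    df["time"] = _time_units(df["visit_week"])
    df["x"] = covariate.reindex(pd.MultiIndex.from_frame(df[["subject_id", "visit_week"]])).to_numpy()
    dropped = sorted(df.loc[df["x"].isna(), "subject_id"].unique())
    audit = []
    if dropped:
        audit.append(f"subjects dropped (missing covariate): {dropped}")
        df = df.dropna(subset=["x"])

    per_subject = df.groupby("subject_id")["visit_week"].nunique()
    if (per_subject >= 2).sum() < 3:
        raise ValueError("need at least 3 subjects with at least 2 visits")

    label = "treatment" if model_type == "treatment" else "rho"
    terms = ["intercept", label, "time", f"{label}:time"]
    exog = np.column_stack([np.ones(len(df)), df["x"], df["time"], df["x"] * df["time"]])
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError(
            f"degenerate design: {label} is collinear with the other terms "
            f"(e.g. identical {label} for all subjects); {label}:time inestimable"
        )

    result = MixedModelResult(
        outcome_name=outcome_name,
        model_type=model_type,
        terms=terms,
        n_obs=len(df),
        n_subjects=df["subject_id"].nunique(),
        audit=audit,
    )
    time = df["time"].to_numpy()
    fit, ok = _fit_mixedlm(df["value"].to_numpy(), exog, df["subject_id"].to_numpy(), terms, True, time)
    structure = "intercept_and_slope"
    if not ok:
        fit, ok = _fit_mixedlm(df["value"].to_numpy(), exog, df["subject_id"].to_numpy(), terms, False, time)
        structure = "intercept_only"
        result.audit.append("random slope removed to improve model fit")
    result.random_structure = structure
    result.converged = ok
    if ok:
        k = len(terms)
        result.estimates = dict(zip(terms, np.asarray(fit.fe_params, dtype=float)))
        result.ses = dict(zip(terms, np.asarray(fit.bse_fe, dtype=float)))
        z = np.asarray(fit.fe_params, dtype=float) / np.asarray(fit.bse_fe, dtype=float)
        result.pvalues = dict(zip(terms, 2.0 * stats.norm.sf(np.abs(z))))
        result.cov_fe = np.asarray(fit.cov_params())[:k, :k]
        return result
    # mixed fits are singular when the data carry (essentially) no residual
    # variance; the mean structure is still exactly estimable
    y = df["value"].to_numpy(dtype=float)
    ols = sm.OLS(y, exog).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    if ols.ssr <= max(1e-10, 1e-12 * tss):
        result.converged = True
        result.random_structure = "none"
        result.estimates = dict(zip(terms, np.asarray(ols.params, dtype=float)))
        result.cov_fe = np.zeros((len(terms), len(terms)))
        result.audit.append("zero-residual data: exact least-squares coefficients, no uncertainties")
    else:
        result.audit.append("fit did not converge even without the random slope; no p-values reported")
    return result


def fit_treatment_model(records: pd.DataFrame, outcome_name: str) -> MixedModelResult:
    """Mixed model outcome ~ treatment*time + (1+time|subject); the
    treatment indicator is 1 at on-drug visits (weeks 32 and 48)."""
    idx = pd.MultiIndex.from_product(
        [records["subject_id"].unique(), VISIT_WEEKS], names=["subject_id", "visit_week"]
    )
    treat = pd.Series((idx.get_level_values("visit_week") >= 32).astype(float), index=idx)
    return _run_model(records, outcome_name, treat, "treatment")


def fit_rho_model(records: pd.DataFrame, outcome_name: str, rho_scores: pd.DataFrame) -> MixedModelResult:
    """Mixed model with the time-varying signature-shift score rho(t):
    lead-in rho at weeks 0/16, treatment-phase rho at weeks 32/48.

    ``rho_scores`` is the tidy table from ``projection.rho_table``;
    subjects lacking either phase score are dropped with an audit entry.
    """
    from .projection import LEAD_IN, TREATMENT

    usable = rho_scores[rho_scores.get("usable", True) == True]  # noqa: E712
    wide = usable.pivot_table(index="subject_id", columns="phase", values="rho", aggfunc="first")
    wide = wide.dropna(subset=[c for c in (LEAD_IN, TREATMENT) if c in wide.columns])
    pairs = {}
    for subject, row in wide.iterrows():
        if LEAD_IN not in row or TREATMENT not in row:
            continue
        for week in VISIT_WEEKS:
            pairs[(subject, week)] = row[LEAD_IN] if week <= 16 else row[TREATMENT]
    cov = pd.Series(pairs)
    cov.index = pd.MultiIndex.from_tuples(cov.index, names=["subject_id", "visit_week"])
    return _run_model(records, outcome_name, cov, "rho")


def predict_trajectory(model: MixedModelResult, profile: dict, level: float = 0.95) -> pd.DataFrame:
    """Population-level trajectory (random effects at zero) for a covariate
    profile, with delta-method confidence bands.

    ``profile`` maps visit week to the covariate value at that visit —
    for a rho model e.g. ``{0: 0.49, 16: 0.49, 32: -0.45, 48: -0.45}``.
    """
    if not model.converged:
        raise ValueError("cannot predict from a non-converged model")
    weeks = sorted(profile)
    x = np.asarray([profile[w] for w in weeks], dtype=float)
    if model.model_type == "rho" and (np.abs(x) > 1).any():
        raise ValueError("rho values must lie in [-1, 1]")
    t = _time_units(weeks)
    X = np.column_stack([np.ones_like(t), x, t, x * t])
    beta = np.asarray([model.estimates[term] for term in model.terms])
    pred = X @ beta
    var = np.einsum("ij,jk,ik->i", X, model.cov_fe, X)
    q = stats.norm.ppf(0.5 + level / 2.0)
    half = q * np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame(
        {"visit_week": weeks, "predicted": pred, "ci_low": pred - half, "ci_high": pred + half}
    )


def paired_phase_test(changes: pd.DataFrame, variable_name: str = "") -> PhaseComparison:
    """Paired t-test of per-subject treatment-phase change vs lead-in change.

    ``changes`` needs columns subject_id, leadin_change, treatment_change.
    All-zero differences yield the degenerate result p = 1 with a
    zero-width interval.
    """
    df = changes.dropna(subset=["leadin_change", "treatment_change"])
    if len(df) < 3:
        raise ValueError("need at least 3 subjects with both phase changes")
    diff = (df["treatment_change"] - df["leadin_change"]).to_numpy(dtype=float)
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    n = diff.size
    if sd == 0:
        return PhaseComparison(variable_name, df, mean, (mean, mean), np.nan, 1.0, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return PhaseComparison(variable_name, df, mean, (mean - half, mean + half), float(t), p)


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"subject_id", "visit_week", "outcome", "value"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"clinical file lacks columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "visit_week", "outcome"])
    if dup.any():
        raise ValueError("duplicate clinical records for a subject-visit-outcome")
    return df
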