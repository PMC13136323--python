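"""Ultrasound severity scoring and the severity x phase analysis.

Muscle ultrasound echointensity is graded on the Heckmatt scale (1-4)
for the flexor digitorum profundus (FDP), vastus lateralis (VL) and
rectus femoris (RF) on both sides.  The per-subject sum score is the
sum over the three muscles of the bilateral maximum grade (range 3-12);
severe disease is a sum score above 10 together with atrophy in at
least one muscle.

The phase x severity interaction on the per-patient rho scores is
tested with a classical two-way mixed ANOVA (phase within subject,
severity between subjects; with only two within-subject levels
sphericity holds trivially), followed by Tukey HSD over the four cell
means and a leave-one-out influence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

MUSCLES = ("FDP", "VL", "RF")
SIDES = ("left", "right")
SEVERE = "severe"
MILD = "mild_moderate"
DEFAULT_CUTOFF = 10


@dataclass
class UltrasoundAssessment:
    subject_id: str
    grades: dict  # (muscle, side) -> int in 1..4
    atrophy: dict = field(default_factory=dict)  # (muscle, side) -> bool


@dataclass
class MixedAnovaResult:
    F_interaction: float
    p_interaction: float
    df: tuple  # (df effect, df error)
    table: pd.DataFrame  # full SS decomposition
    tukey: pd.DataFrame | None = None


def sum_score(assessment: UltrasoundAssessment, cutoff: int = DEFAULT_CUTOFF, require_atrophy: bool = True) -> tuple[int, str]:
    """Bilateral-max Heckmatt sum over the three muscles and severity class."""
    total = 0
    for muscle in MUSCLES:
        grades = []
        for side in SIDES:
            g = assessment.grades.get((muscle, side))
            if g is None:
                raise ValueError(f"missing grade for {muscle} {side} (subject {assessment.subject_id})")
            if g not in (1, 2, 3, 4):
                raise ValueError(f"grade {g} out of Heckmatt range for {muscle} {side}")
            grades.append(int(g))
        total += max(grades)
    any_atrophy = any(bool(v) for v in assessment.atrophy.values())
    severe = total > cutoff and (any_atrophy or not require_atrophy)
    return total, (SEVERE if severe else MILD)


def _anova_frame(rho_scores: pd.DataFrame, severity: dict) -> pd.DataFrame:
    df = rho_scores[rho_scores.get("usable", True) == True]  # noqa: E712
    df = df[["subject_id", "phase", "rho"]].copy()
    complete = df.groupby("subject_id")["phase"].nunique()
    keep = complete[complete == 2].index
    df = df[df["subject_id"].isin(keep)]
    df["severity"] = df["subject_id"].map(severity)
    if df["severity"].isna().any():
        missing = sorted(df.loc[df["severity"].isna(), "subject_id"].unique())
        raise ValueError(f"no severity class for subject(s) {missing}")
    return df


def severity_anova(rho_scores: pd.DataFrame, severity: dict, tukey: bool = True) -> MixedAnovaResult:
    """Two-way mixed ANOVA of rho on phase (within) x severity (between).

    ``rho_scores`` is the tidy table from :func:`sigshift.projection.rho_table`;
    ``severity`` maps subject_id to class.  Reports the phase x severity
    interaction F and p plus Tukey HSD over the four cell means.
    """
    df = _anova_frame(rho_scores, severity)
    groups = sorted(df["severity"].unique())
    counts = df.groupby("severity")["subject_id"].nunique()
    if len(groups) < 2 or (counts < 2).any():
        raise ValueError("need at least 2 subjects in each severity class")

    y = df.set_index(["subject_id", "phase"])["rho"]
    subjects = sorted(df["subject_id"].unique())
    phases = sorted(df["phase"].unique())
    sev = {s: df.loc[df["subject_id"] == s, "severity"].iloc[0] for s in subjects}
    k = len(phases)
    n = len(subjects)

    grand = y.mean()
    subj_mean = y.groupby("subject_id").mean()
    phase_mean = y.groupby("phase").mean()
    group_mean = {g: y[[s for s in subjects if sev[s] == g]].groupby("phase").mean() for g in groups}
    group_overall = {g: float(np.mean([subj_mean[s] for s in subjects if sev[s] == g])) for g in groups}
    n_g = {g: sum(1 for s in subjects if sev[s] == g) for g in groups}

    ss_between_subj = k * float(((subj_mean - grand) ** 2).sum())
    ss_group = k * sum(n_g[g] * (group_overall[g] - grand) ** 2 for g in groups)
    ss_subj_within = ss_between_subj - ss_group
    ss_phase = n * float(((phase_mean - grand) ** 2).sum())
    ss_inter = sum(
        n_g[g] * (group_mean[g][ph] - group_overall[g] - phase_mean[ph] + grand) ** 2
        for g in groups
        for ph in phases
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = ss_total - ss_group - ss_subj_within - ss_phase - ss_inter

    df_group = len(groups) - 1
    df_subj = n - len(groups)
    df_phase = k - 1
    df_inter = df_group * df_phase
    df_error = df_subj * df_phase

    def f_and_p(ss_eff, df_eff, ss_err, df_err):
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        ms_eff = ss_eff / df_eff if df_eff > 0 else np.nan
        if not np.isfinite(ms_err) or ms_err <= 0:
            # degenerate: no residual variance; all-equal data -> F=0, p=1
            return (0.0, 1.0) if ss_eff <= 1e-14 else (np.inf, 0.0)
        F = ms_eff / ms_err
        return float(F), float(stats.f.sf(F, df_eff, df_err))

    F_g, p_g = f_and_p(ss_group, df_group, ss_subj_within, df_subj)
    F_p, p_p = f_and_p(ss_phase, df_phase, ss_error, df_error)
    F_i, p_i = f_and_p(ss_inter, df_inter, ss_error, df_error)

    table = pd.DataFrame(
        {
            "SS": [ss_group, ss_subj_within, ss_phase, ss_inter, ss_error],
            "df": [df_group, df_subj, df_phase, df_inter, df_error],
            "F": [F_g, np.nan, F_p, F_i, np.nan],
            "p": [p_g, np.nan, p_p, p_i, np.nan],
        },
        index=["severity", "subject(severity)", "phase", "phase:severity", "error"],
    )

    tukey_df = None
    if tukey:
        labels = df["phase"].astype(str) + "/" + df["severity"].astype(str)
        res = pairwise_tukeyhsd(df["rho"].to_numpy(), labels.to_numpy())
        tukey_df = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return MixedAnovaResult(F_interaction=F_i, p_interaction=p_i, df=(df_inter, df_error), table=table, tukey=tukey_df)


def leave_one_out(rho_scores: pd.DataFrame, severity: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Re-run the mixed ANOVA with each subject removed.

    A subject is flagged influential when the full-data interaction p
    crosses ``alpha`` upon their removal.  Deletions that empty a
    severity class are skipped with an audit note in the table.
    """
    full = severity_anova(rho_scores, severity, tukey=False)
    subjects = sorted(s for s in rho_scores["subject_id"].unique() if s in severity)
    rows = []
    for s in subjects:
        reduced = rho_scores[rho_scores["subject_id"] != s]
        try:
            res = severity_anova(reduced, severity, tukey=False)
        except ValueError as exc:
            rows.append({"subject_id": s, "p_interaction": np.nan, "influential": False, "note": str(exc)})
            continue
        crossed = (full.p_interaction < alpha) != (res.p_interaction < alpha)
        rows.append({"subject_id": s, "p_interaction": res.p_interaction, "influential": bool(crossed), "note": ""})
    out = pd.DataFrame(rows)
    out.attrs["p_full"] = full.p_interaction
    return out


def read_ultrasound_tsv(path) -> list:
    """Read ultrasound TSV (subject_id, muscle, side, grade, atrophy)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for subject, sub in df.groupby("subject_id", sort=True):
        grades = {(r.muscle, r.side): int(r.grade) for r in sub.itertuples()}
        atrophy = {(r.muscle, r.side): bool(r.atrophy) for r in sub.itertuples()}
        out.append(UltrasoundAssessment(subject_id=str(subject), grades=grades, atrophy=atrophy))
    return out


def write_ultrasound_tsv(assessments, path) -> None:
    rows = []
    for a in assessments:
        for (muscle, side), grade in sorted(a.grades.items()):
            rows.append(
                {
                    "subject_id": a.subject_id,
                    "muscle": muscle,
                    "side": side,
                    "grade": grade,
                    "atrophy": bool(a.atrophy.get((muscle, side), False)),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
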