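"""Per-patient signature projection.

Each patient's metabolic change over a study phase (lead-in: baseline to
week 16; treatment: week 16 to week 32) is summarised as a vector of
within-subject log2 fold changes and projected onto the disease
signature as a Spearman rho: positive rho means the patient drifted in
the direction of the disease signature, negative rho means a shift
toward the control profile.  Confidence intervals come from a
delete-one jackknife over metabolite pairs on the Fisher-z scale, and a
patient is called a responder when the lead-in and treatment intervals
do not overlap (by default also requiring the treatment interval to lie
below the lead-in interval, i.e. a shift away from disease).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LEAD_IN = "lead_in"
TREATMENT = "treatment"
PHASE_VISITS = {LEAD_IN: (0, 16), TREATMENT: (16, 32)}

DEFAULT_MIN_COMMON = 10
_ATANH_CLIP = 1.0 - 1e-12


@dataclass
class PatientDelta:
    """Within-subject metabolite log2FC over one phase (later - earlier)."""

    subject_id: str
    phase: str
    delta: pd.Series  # indexed by metabolite; pairwise-complete only

    @property
    def n_metabolites(self) -> int:
        return int(self.delta.size)


@dataclass
class RhoScore:
    subject_id: str
    phase: str
    rho: float
    ci_low: float
    ci_high: float
    n_used: int
    usable: bool = True
    method: str = "jackknife"


@dataclass
class ResponderCall:
    subject_id: str
    responder: bool
    direction: str  # toward_control | toward_disease | none


@dataclass
class SignatureCorrelation:
    rho: float
    p: float
    n: int
    table: pd.DataFrame  # fc_a, fc_b, quadrant (+ combined significance when given)


def patient_deltas(x, ann: pd.DataFrame, phases=(LEAD_IN, TREATMENT)) -> tuple[list, list]:
    """One log2FC vector per case subject and phase.

    Subjects missing either endpoint sample for a phase are omitted and
    recorded in the returned audit list (mirrors exclusion of
    poor-quality longitudinal biopsies).  Duplicate samples for one
    subject-visit are an error.
    """
    ok = ann[(ann["tissue"] == x.tissue) & (ann["group"] == "case") & (ann["quality_flag"] == "ok")]
    audit: list = []
    deltas: list = []
    for subject, sub in ok.groupby("subject_id", sort=True):
        dup = sub["visit_week"].duplicated()
        if dup.any():
            weeks = sorted(set(sub.loc[dup, "visit_week"]))
            raise ValueError(f"duplicate sample for subject {subject} at visit week(s) {weeks}")
        by_week = sub.set_index(sub["visit_week"].astype(float))["sample_id"]
        for phase in phases:
            w0, w1 = PHASE_VISITS[phase]
            if float(w0) not in by_week.index or float(w1) not in by_week.index:
                audit.append(f"subject {subject}: missing endpoint for {phase}, omitted")
                continue
            earlier = x.log2_values[by_week[float(w0)]]
            later = x.log2_values[by_week[float(w1)]]
            delta = (later - earlier).dropna()
            deltas.append(PatientDelta(subject_id=str(subject), phase=phase, delta=delta))
    return deltas, audit


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def spearman_rho(a, b) -> float:
    """Spearman rank correlation with average ranks for ties.

    Pairwise-complete: pairs with a missing value in either vector are
    dropped; constant vectors are an error (undefined correlation).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must be paired (equal length)")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    ra, rb = _rank(a), _rank(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))


def _delete_one_rhos(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All n delete-one Spearman correlations, vectorized.

    Uses the closed-form update of average ranks under deletion: with
    c_j = #{k: x_k < x_j} and tie-group size g_j, the rank of j after
    deleting i is c_j - [x_i < x_j] + (g_j - [x_i = x_j] + 1)/2.
    Returns NaN where a leave-one-out subvector is constant.
    """
    n = a.size

    def rank_matrix(x):
        lt = x[:, None] < x[None, :]
        eq = x[:, None] == x[None, :]
        c = lt.sum(axis=0).astype(float)
        g = eq.sum(axis=0).astype(float)
        return c[None, :] - lt + (g[None, :] - eq + 1.0) / 2.0

    ra = rank_matrix(a)
    rb = rank_matrix(b)
    idx = np.arange(n)
    diag_a = ra[idx, idx].copy()
    diag_b = rb[idx, idx].copy()
    m = n - 1
    sum_a = ra.sum(axis=1) - diag_a
    sum_b = rb.sum(axis=1) - diag_b
    sum_aa = (ra * ra).sum(axis=1) - diag_a**2
    sum_bb = (rb * rb).sum(axis=1) - diag_b**2
    sum_ab = (ra * rb).sum(axis=1) - diag_a * diag_b
    var_a = sum_aa - sum_a**2 / m
    var_b = sum_bb - sum_b**2 / m
    cov = sum_ab - sum_a * sum_b / m
    with np.errstate(divide="ignore", invalid="ignore"):
        rhos = cov / np.sqrt(var_a * var_b)
    rhos[(var_a <= 1e-12) | (var_b <= 1e-12)] = np.nan
    return rhos


def jackknife_ci(a, b, level: float = 0.95) -> tuple[float, float]:
    """Delete-one jackknife CI for Spearman rho over metabolite pairs.

    Pseudovalues are formed on the Fisher z scale; the interval is the
    normal-theory interval about z(rho) with the jackknife variance
    (n-1)/n * sum((z_i - zbar)^2), back-transformed and clamped to
    [-1, 1].  Leave-one-out subsets that are constant are skipped with a
    warning; fewer than 80% usable pseudovalues is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n < 10:
        raise ValueError("need at least 10 pairs for a jackknife interval")
    rho = spearman_rho(a, b)

    rhos = _delete_one_rhos(a, b)
    usable = ~np.isnan(rhos)
    z_loo = np.arctanh(np.clip(np.nan_to_num(rhos), -_ATANH_CLIP, _ATANH_CLIP))
    if not usable.all():
        n_bad = int((~usable).sum())
        warnings.warn(f"{n_bad} constant leave-one-out subset(s) skipped", stacklevel=2)
        if usable.sum() < 0.8 * n:
            raise ValueError("fewer than 80% of jackknife pseudovalues usable")
    z = z_loo[usable]
    m = z.size
    var_jack = (m - 1) / m * float(np.sum((z - z.mean()) ** 2))
    z0 = np.arctanh(np.clip(rho, -_ATANH_CLIP, _ATANH_CLIP))
    q = stats.norm.ppf(0.5 + level / 2.0)
    half = q * np.sqrt(var_jack)
    lo = float(np.clip(np.tanh(z0 - half), -1.0, 1.0))
    hi = float(np.clip(np.tanh(z0 + half), -1.0, 1.0))
    # snap bounds that are degenerate only through the atanh clip
    if hi >= 1.0 - 1e-9:
        hi = 1.0
    if lo <= -1.0 + 1e-9:
        lo = -1.0
    return lo, hi


def project_patient(
    delta: PatientDelta,
    sig,
    min_common: int = DEFAULT_MIN_COMMON,
    level: float = 0.95,
    fdr_filter: float | None = None,
) -> RhoScore:
    """Spearman rho of a patient's phase log2FC against the signature,
    over their common metabolites, with a jackknife CI.

    ``sig`` is a DiseaseSignature or a plain log2FC Series.  An optional
    ``fdr_filter`` restricts the projection to signature metabolites at
    or below that FDR.  Below ``min_common`` common metabolites the
    score is flagged unusable.
    """
    if hasattr(sig, "log2fc"):
        ref = sig.log2fc
        if fdr_filter is not None:
            ref = ref[sig.table["fdr"] <= fdr_filter]
    else:
        ref = sig
    ref = ref.dropna()
    common = delta.delta.index.intersection(ref.index)
    n = len(common)
    if n < max(min_common, 10):
        return RhoScore(delta.subject_id, delta.phase, np.nan, np.nan, np.nan, n, usable=False)
    a = delta.delta[common].to_numpy(dtype=float)
    b = ref[common].to_numpy(dtype=float)
    rho = spearman_rho(a, b)
    lo, hi = jackknife_ci(a, b, level=level)
    return RhoScore(delta.subject_id, delta.phase, rho, lo, hi, n, usable=True)


def classify_responder(leadin: RhoScore, treatment: RhoScore, directional: bool = True) -> ResponderCall:
    """Responder iff the two phase CIs are disjoint (optionally also
    requiring the treatment interval to lie entirely below the lead-in
    interval, i.e. a shift toward the control profile)."""
    if leadin.subject_id != treatment.subject_id:
        raise ValueError("phase scores belong to different subjects")
    if not (leadin.usable and treatment.usable):
        return ResponderCall(leadin.subject_id, False, "none")
    below = treatment.ci_high < leadin.ci_low
    above = treatment.ci_low > leadin.ci_high
    if below:
        return ResponderCall(leadin.subject_id, True, "toward_control")
    if above:
        return ResponderCall(leadin.subject_id, not directional, "toward_disease")
    return ResponderCall(leadin.subject_id, False, "none")


def correlate_signatures(fc_a: pd.Series, fc_b: pd.Series, p_a: pd.Series | None = None, p_b: pd.Series | None = None) -> SignatureCorrelation:
    """Cohort-level Spearman correlation of two log2FC vectors over their
    shared identifiers, with a per-metabolite quadrant table.

    When per-comparison p-values are supplied, Fisher-combined and
    BH-adjusted significance columns are added for labeling.
    """
    from .signature import fisher_combine

    common = fc_a.dropna().index.intersection(fc_b.dropna().index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared identifiers to correlate")
    a = fc_a[common].astype(float)
    b = fc_b[common].astype(float)
    rho, p = stats.spearmanr(a, b)
    table = pd.DataFrame({"fc_a": a, "fc_b": b})
    table["quadrant"] = np.where(np.sign(a) * np.sign(b) >= 0, "same_direction", "opposite")
    if p_a is not None and p_b is not None:
        both = pd.DataFrame({"p_a": p_a[common], "p_b": p_b[common]}).dropna()
        comb = fisher_combine(both)
        table = table.join(comb.table[["p_combined", "fdr_combined"]])
    return SignatureCorrelation(rho=float(rho), p=float(p), n=len(common), table=table)


def rho_table(scores) -> pd.DataFrame:
    """Tidy per-subject rho table (subject, phase, rho, ci_low, ci_high, n_used)."""
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "phase": s.phase,
                "rho": s.rho,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "n_used": s.n_used,
                "usable": s.usable,
            }
            for s in scores
        ]
    )
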