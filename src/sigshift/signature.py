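"""Disease metabolic signature: case-vs-control log2 fold changes with
empirical-Bayes moderated tests, combined significance and the PC1
group-separation check.

The moderated test shrinks per-metabolite pooled variances s_g^2 toward a
prior s0^2 with prior degrees of freedom d0, both estimated from the
observed variance distribution by moment matching on the log scale: if
s_g^2 | sigma_g^2 ~ sigma_g^2 * chi2_d / d and 1/sigma_g^2 ~ chi2_d0 /
(d0 s0^2), then e_g = log s_g^2 - digamma(d/2) + log(d/2) has variance
trigamma(d/2) + trigamma(d0/2), which is inverted for d0 (Newton on the
trigamma function), and mean log s0^2 + digamma(d0/2) - log(d0/2).  The
moderated statistic is

    t_g = log2FC_g / sqrt(s_post^2 (1/n1 + 1/n2)),
    s_post^2 = (d0 s0^2 + d s_g^2) / (d0 + d),

referred to a t distribution with d + d0 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests


@dataclass
class DiseaseSignature:
    """Per-metabolite case-vs-control statistics.

    ``table`` is indexed by metabolite with columns ``log2fc``, ``t``,
    ``p``, ``fdr``, ``n_case``, ``n_control``.
    """

    table: pd.DataFrame
    shrinkage: str
    prior_df: float | None = None
    prior_var: float | None = None
    audit: list | None = None

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]


@dataclass
class CombinedSignificance:
    """Fisher-combined p-values across k comparisons per metabolite."""

    table: pd.DataFrame  # columns: fisher_stat, p_combined, fdr_combined
    k: int


@dataclass
class Pc1SeparationResult:
    pc1_scores: pd.Series
    F: float
    df: tuple
    p: float
    mode: str


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _inv_trigamma(y: float) -> float:
    # Newton iteration on trigamma(x) = y; trigamma is convex decreasing.
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + delta
        if abs(delta) < 1e-10 * max(x, 1.0):
            break
    return x


def moderate_variances(s2, df: float) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 from per-metabolite
    pooled variances (log-scale moment matching).

    Returns ``(d0, s0_sq)``; ``d0`` may be ``inf`` when the observed
    variances are no more dispersed than sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need at least two positive variances to moderate")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _inv_trigamma(excess)
        s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _select_signature_samples(ann: pd.DataFrame, tissue: str) -> tuple[list, list]:
    ok = ann[(ann["tissue"] == tissue) & (ann["quality_flag"] == "ok")]
    cases = ok[(ok["group"] == "case")]
    if tissue == "muscle":
        cases = cases[cases["visit_week"].fillna(-1).astype(float) == 0]
    else:
        cases = cases[cases["visit_week"].fillna(0).astype(float) == 0]
    controls = ok[ok["group"] == "control"]
    return list(cases["sample_id"]), list(controls["sample_id"])


def estimate_signature(
    x,
    ann: pd.DataFrame,
    shrinkage: str = "moderated",
    prior_df: float | None = None,
    case_samples=None,
    control_samples=None,
) -> DiseaseSignature:
    """Case-vs-control log2FC with ordinary or moderated t per metabolite.

    Cases are baseline-visit case samples flagged ``ok``; controls are all
    ``ok`` control samples of the matrix's tissue.  ``prior_df`` overrides
    the moment-matched prior degrees of freedom (0 recovers the ordinary
    pooled t, ``inf`` full shrinkage to the prior variance).
    """
    if shrinkage not in ("ordinary", "moderated"):
        raise ValueError(f"unknown shrinkage mode {shrinkage!r}")
    if case_samples is None or control_samples is None:
        case_samples, control_samples = _select_signature_samples(ann, x.tissue)
    case_samples = [s for s in case_samples if s in x.log2_values.columns]
    control_samples = [s for s in control_samples if s in x.log2_values.columns]
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need at least two samples per group")

    a = x.log2_values[case_samples].to_numpy(dtype=float)
    b = x.log2_values[control_samples].to_numpy(dtype=float)
    n1 = (~np.isnan(a)).sum(axis=1)
    n2 = (~np.isnan(b)).sum(axis=1)
    usable = (n1 >= 2) & (n2 >= 2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(a, axis=1)
        m2 = np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
    log2fc = np.where(usable, m1 - m2, np.nan)
    df_resid = n1 + n2 - 2.0
    pooled = np.where(usable, ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(df_resid, 1), np.nan)
    scale = 1.0 / n1 + 1.0 / n2

    audit = []
    d0: float | None = None
    s0_sq: float | None = None
    if shrinkage == "moderated":
        # moment matching assumes a common residual df; use the modal df
        df_common = float(np.median(df_resid[usable]))
        if prior_df is None:
            d0, s0_sq = moderate_variances(pooled[usable], df_common)
        elif prior_df == 0:
            d0, s0_sq = 0.0, float(np.nanmedian(pooled[usable]))
        elif np.isinf(prior_df):
            _, s0_sq = moderate_variances(pooled[usable], df_common)
            d0 = np.inf
        else:
            d0 = float(prior_df)
            _, s0_sq = moderate_variances(pooled[usable], df_common)
        if np.isinf(d0):
            s_post = np.full_like(pooled, s0_sq)
            df_total = np.full_like(df_resid, np.inf, dtype=float)
        else:
            s_post = (d0 * s0_sq + df_resid * pooled) / (d0 + df_resid)
            df_total = df_resid + d0
        audit.append(f"moderated test: prior df {d0:.4g}, prior variance {s0_sq:.4g}")
    else:
        s_post = pooled
        df_total = df_resid.astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / np.sqrt(s_post * scale)
    t = np.where(usable & (s_post > 0), t, np.where(usable & (log2fc == 0), 0.0, np.nan))
    p = np.where(np.isnan(t), np.nan, 2.0 * stats.t.sf(np.abs(np.where(np.isnan(t), 0.0, t)), df_total))
    fdr = bh_fdr(p)

    n_dropped = int((~usable).sum())
    if n_dropped:
        audit.append(f"{n_dropped} metabolite(s) with <2 non-missing values per group: statistics missing")

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "n_case": n1,
            "n_control": n2,
        },
        index=x.log2_values.index,
    )
    return DiseaseSignature(table=table, shrinkage=shrinkage, prior_df=d0, prior_var=s0_sq, audit=audit)


def fisher_combine(p_lists: pd.DataFrame) -> CombinedSignificance:
    """Fisher's method across the k comparisons (columns) of ``p_lists``.

    fisher_stat = -2 sum(ln p_i), referred to chi-square with 2k df;
    BH applied across metabolites to the combined p-values.
    """
    p = p_lists.to_numpy(dtype=float)
    if p.ndim != 2 or p.shape[1] < 1:
        raise ValueError("p_lists must be metabolites x comparisons")
    if np.nanmax(p, initial=0.0) > 1 or np.nanmin(p, initial=1.0) < 0:
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p-value of 0 clamped to smallest positive float", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    k = p.shape[1]
    stat = -2.0 * np.sum(np.log(p), axis=1)
    p_comb = stats.chi2.sf(stat, 2 * k)
    table = pd.DataFrame(
        {"fisher_stat": stat, "p_combined": p_comb, "fdr_combined": bh_fdr(p_comb)},
        index=p_lists.index,
    )
    return CombinedSignificance(table=table, k=k)


def pc1_separation(x, ann: pd.DataFrame, mode: str = "variance_ratio") -> Pc1SeparationResult:
    """PCA on samples and a two-sided test of case-vs-control PC1 spread.

    ``variance_ratio`` (default): F = var(case PC1) / var(control PC1)
    with two-sided p from F(n_case-1, n_control-1).  ``anova`` compares
    PC1 group means by one-way ANOVA instead.
    """
    case_samples, control_samples = _select_signature_samples(ann, x.tissue)
    samples = [s for s in case_samples + control_samples if s in x.log2_values.columns]
    case_samples = [s for s in case_samples if s in samples]
    control_samples = [s for s in control_samples if s in samples]
    if len(case_samples) < 3 or len(control_samples) < 3:
        raise ValueError("need at least three samples per group for PC1 separation")

    mat = x.log2_values[samples].dropna(axis=0, how="any")
    data = mat.to_numpy(dtype=float).T  # samples x metabolites; PCA centers features
    scores = PCA(n_components=1).fit_transform(data)[:, 0]
    pc1 = pd.Series(scores, index=samples)

    v_case = float(np.var(pc1[case_samples], ddof=1))
    v_ctrl = float(np.var(pc1[control_samples], ddof=1))
    if v_case == 0 or v_ctrl == 0:
        raise ValueError("degenerate (zero-variance) PC1 scores in a group")
    if mode == "variance_ratio":
        F = v_case / v_ctrl
        dfn, dfd = len(case_samples) - 1, len(control_samples) - 1
        upper = stats.f.sf(F, dfn, dfd)
        lower = stats.f.cdf(F, dfn, dfd)
        p = min(1.0, max(2.0 * min(upper, lower), float(np.finfo(float).tiny)))
    elif mode == "anova":
        F, p = stats.f_oneway(pc1[case_samples], pc1[control_samples])
        dfn, dfd = 1, len(samples) - 2
        F, p = float(F), float(p)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Pc1SeparationResult(pc1_scores=pc1, F=float(F), df=(dfn, dfd), p=float(p), mode=mode)


def write_signature_tsv(sig: DiseaseSignature, path) -> None:
    sig.table.to_csv(path, sep="\t", float_format="%.6g", na_rep="")


def read_signature_tsv(path) -> pd.Series:
    """Read an external log2FC table (metabolite/gene id + log2FC column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = "log2fc" if "log2fc" in df.columns else df.columns[0]
    return df[col].astype(float)
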