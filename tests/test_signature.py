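"""Signature estimation: moderated test limits and oracle, Fisher
combination, BH adjustment, PC1 separation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats

from sigshift import NormalizedMatrix, bh_fdr, estimate_signature, fisher_combine, pc1_separation
from sigshift.signature import moderate_variances


def _dataset(seed=0, n_met=20, n_case=6, n_ctrl=4, effect=0.0):
    rng = np.random.default_rng(seed)
    sds = np.exp(rng.normal(-1.0, 0.5, size=n_met))  # heterogeneous true variances
    case = rng.normal(effect, sds[:, None], size=(n_met, n_case))
    ctrl = rng.normal(0.0, sds[:, None], size=(n_met, n_ctrl))
    cols = [f"C{i}" for i in range(n_case)] + [f"H{i}" for i in range(n_ctrl)]
    df = pd.DataFrame(np.hstack([case, ctrl]), index=[f"M{i}" for i in range(n_met)], columns=cols)
    ann = pd.DataFrame(
        {
            "sample_id": cols,
            "subject_id": cols,
            "group": ["case"] * n_case + ["control"] * n_ctrl,
            "tissue": "muscle",
            "visit_week": [0] * n_case + [None] * n_ctrl,
            "quality_flag": "ok",
        }
    )
    return NormalizedMatrix(log2_values=df, tissue="muscle"), ann, n_case, n_ctrl


def _ordinary_t(df, n_case, n_ctrl):
    a = df.iloc[:, :n_case].to_numpy()
    b = df.iloc[:, n_case:].to_numpy()
    fc = a.mean(axis=1) - b.mean(axis=1)
    sp = ((n_case - 1) * a.var(axis=1, ddof=1) + (n_ctrl - 1) * b.var(axis=1, ddof=1)) / (n_case + n_ctrl - 2)
    return fc, fc / np.sqrt(sp * (1 / n_case + 1 / n_ctrl)), sp


def test_moderated_with_zero_prior_df_equals_ordinary_t():
    x, ann, n1, n2 = _dataset(seed=1)
    sig = estimate_signature(x, ann, shrinkage="moderated", prior_df=0)
    _, t_ref, _ = _ordinary_t(x.log2_values, n1, n2)
    np.testing.assert_allclose(sig.table["t"], t_ref, atol=1e-10)


def test_moderated_with_infinite_prior_df_uses_prior_variance_everywhere():
    x, ann, n1, n2 = _dataset(seed=2)
    sig = estimate_signature(x, ann, shrinkage="moderated", prior_df=np.inf)
    fc, _, _ = _ordinary_t(x.log2_values, n1, n2)
    expected = fc / np.sqrt(sig.prior_var * (1 / n1 + 1 / n2))
    np.testing.assert_allclose(sig.table["t"], expected, atol=1e-10)


def test_moderated_t_matches_independent_straightline_reference():
    """Scalar re-derivation of the moment-matched shrinkage: e_g =
    log s_g^2 - digamma(d/2) + log(d/2); var(e) = trigamma(d/2) +
    trigamma(d0/2) solved by root finding; posterior variance the
    precision-weighted combination."""
    x, ann, n1, n2 = _dataset(seed=3, n_met=20)
    sig = estimate_signature(x, ann, shrinkage="moderated")
    fc, _, sp = _ordinary_t(x.log2_values, n1, n2)
    d = n1 + n2 - 2
    e = [np.log(s) - special.digamma(d / 2) + np.log(d / 2) for s in sp]
    excess = np.var(e, ddof=1) - special.polygamma(1, d / 2)
    assert excess > 0  # heterogeneous variances in this fixture
    half_d0 = optimize.brentq(lambda x_: special.polygamma(1, x_) - excess, 1e-6, 1e8, xtol=1e-12)
    d0 = 2 * half_d0
    s0 = np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0))
    t_ref = np.array(
        [fc[g] / np.sqrt(((d0 * s0 + d * sp[g]) / (d0 + d)) * (1 / n1 + 1 / n2)) for g in range(len(fc))]
    )
    np.testing.assert_allclose(sig.table["t"], t_ref, atol=1e-8)
    p_ref = 2 * stats.t.sf(np.abs(t_ref), d + d0)
    np.testing.assert_allclose(sig.table["p"], p_ref, atol=1e-8)


def test_homogeneous_variances_give_infinite_prior_df():
    rng = np.random.default_rng(0)
    s2 = stats.chi2.rvs(8, size=500, random_state=rng) / 8 * 0.04
    d0, s0 = moderate_variances(s2, 8)
    assert np.isinf(d0)
    assert 0.02 < s0 < 0.08


def test_label_swap_negates_log2fc():
    x, ann, *_ = _dataset(seed=4)
    swapped = ann.copy()
    swapped["group"] = swapped["group"].map({"case": "control", "control": "case"})
    swapped["visit_week"] = [0 if g == "case" else None for g in swapped["group"]]
    a = estimate_signature(x, ann)
    b = estimate_signature(x, swapped)
    np.testing.assert_allclose(a.table["log2fc"], -b.table["log2fc"], atol=1e-12)


def test_identical_group_means_give_zero_stat():
    x, ann, n1, n2 = _dataset(seed=5)
    df = x.log2_values.copy()
    df.iloc[0, :] = list(np.tile([0.3, -0.1, 0.4], 2)) + [0.3, -0.1, 0.4, 0.2][: n1 + n2 - 6]
    # force equal group means for metabolite 0
    df.iloc[0, :n1] = [0.1, 0.2, 0.3, 0.1, 0.2, 0.3][:n1]
    df.iloc[0, n1:] = [0.15, 0.25, 0.1, 0.2][:n2]
    df.iloc[0, n1:] += np.mean(df.iloc[0, :n1]) - np.mean(df.iloc[0, n1:])
    sig = estimate_signature(NormalizedMatrix(log2_values=df), ann)
    assert abs(sig.table["log2fc"].iloc[0]) < 1e-12
    assert abs(sig.table["t"].iloc[0]) < 1e-12


def test_fdr_dominates_p(default_trial, default_norm):
    sig = estimate_signature(default_norm, default_trial.annotations)
    tab = sig.table.dropna()
    assert (tab["fdr"] >= tab["p"] - 1e-12).all()
    assert tab["fdr"].between(0, 1).all()


# --- Fisher combination ----------------------------------------------------


def test_fisher_combine_examples():
    p = pd.DataFrame({"a": [1.0, 0.05], "b": [1.0, 0.05]}, index=["m1", "m2"])
    res = fisher_combine(p)
    assert res.table.loc["m1", "fisher_stat"] == 0.0
    assert res.table.loc["m1", "p_combined"] == 1.0
    stat = -2 * (np.log(0.05) + np.log(0.05))
    np.testing.assert_allclose(res.table.loc["m2", "fisher_stat"], stat, rtol=1e-12)
    np.testing.assert_allclose(res.table.loc["m2", "p_combined"], stats.chi2.sf(stat, 4), rtol=1e-12)


def test_fisher_single_comparison_is_identity():
    p = pd.DataFrame({"a": [0.3, 0.007, 0.99]})
    res = fisher_combine(p)
    np.testing.assert_allclose(res.table["p_combined"], p["a"], atol=1e-12)


def test_fisher_zero_p_clamped_with_warning():
    with pytest.warns(UserWarning, match="clamped"):
        res = fisher_combine(pd.DataFrame({"a": [0.0], "b": [0.5]}))
    assert np.isfinite(res.table["fisher_stat"]).all()


def test_fisher_commutes_with_comparison_permutation():
    p = pd.DataFrame({"a": [0.1, 0.9], "b": [0.4, 0.02], "c": [0.6, 0.3]})
    res1 = fisher_combine(p)
    res2 = fisher_combine(p[["c", "a", "b"]])
    pd.testing.assert_frame_equal(res1.table, res2.table)


# --- BH --------------------------------------------------------------------


def test_bh_hand_example():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12)
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
    np.testing.assert_allclose(bh_fdr([0.123]), [0.123])


@settings(max_examples=50, deadline=None)
@given(p=st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=30))
def test_bh_properties(p):
    q = bh_fdr(p)
    assert (q <= 1.0 + 1e-12).all()
    assert (q >= np.asarray(p) - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()  # monotone in rank order


# --- PC1 separation --------------------------------------------------------


def _pc1_matrix(case_scores, ctrl_scores, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.concatenate([case_scores, ctrl_scores])
    u = rng.normal(size=30)
    data = np.outer(u, scores) + rng.normal(0, 1e-4, size=(30, scores.size))
    cols = [f"C{i}" for i in range(len(case_scores))] + [f"H{i}" for i in range(len(ctrl_scores))]
    df = pd.DataFrame(data, index=[f"M{i}" for i in range(30)], columns=cols)
    ann = pd.DataFrame(
        {
            "sample_id": cols,
            "subject_id": cols,
            "group": ["case"] * len(case_scores) + ["control"] * len(ctrl_scores),
            "tissue": "muscle",
            "visit_week": [0] * len(case_scores) + [None] * len(ctrl_scores),
            "quality_flag": "ok",
        }
    )
    return NormalizedMatrix(log2_values=df), ann


def test_pc1_variance_ratio_matches_f_distribution():
    rng = np.random.default_rng(1)
    ctrl = rng.normal(0, 1, size=5)
    case = rng.normal(0, 1, size=15)
    # rescale so the PC1 score variances have ratio exactly 4
    case = case / case.std(ddof=1) * 2.0 * ctrl.std(ddof=1)
    x, ann = _pc1_matrix(case, ctrl)
    res = pc1_separation(x, ann)
    np.testing.assert_allclose(res.F, 4.0, rtol=1e-3)
    expected = 2 * min(stats.f.sf(res.F, 14, 4), stats.f.cdf(res.F, 14, 4))
    np.testing.assert_allclose(res.p, expected, rtol=1e-12)
    assert res.df == (14, 4)


def test_pc1_equal_variances_give_f_one():
    rng = np.random.default_rng(2)
    ctrl = rng.normal(0, 1, size=8)
    case = rng.normal(0, 1, size=8)
    case = case / case.std(ddof=1) * ctrl.std(ddof=1)
    x, ann = _pc1_matrix(case, ctrl)
    res = pc1_separation(x, ann)
    np.testing.assert_allclose(res.F, 1.0, rtol=1e-3)
    assert res.p > 0.97


def test_pc1_invariant_to_sample_order():
    rng = np.random.default_rng(3)
    x, ann = _pc1_matrix(rng.normal(0, 2, 10), rng.normal(0, 1, 5))
    res1 = pc1_separation(x, ann)
    perm = rng.permutation(x.log2_values.columns)
    x2 = NormalizedMatrix(log2_values=x.log2_values[perm])
    res2 = pc1_separation(x2, ann)
    np.testing.assert_allclose(res1.F, res2.F, rtol=1e-9)
    np.testing.assert_allclose(res1.p, res2.p, rtol=1e-9)
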