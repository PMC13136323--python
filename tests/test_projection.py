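"""Per-patient projection: deltas, Spearman rho, jackknife CI,
responder calls, cohort-level fold-change correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sigshift import (
    LEAD_IN,
    TREATMENT,
    PatientDelta,
    RhoScore,
    SyntheticConfig,
    classify_responder,
    correlate_signatures,
    generate_trial,
    jackknife_ci,
    normalize,
    patient_deltas,
    project_patient,
    spearman_rho,
)


# --- patient deltas --------------------------------------------------------


def test_deltas_telescope_across_phases(default_trial, default_norm):
    deltas, audit = patient_deltas(default_norm, default_trial.annotations)
    assert audit == []
    by_subject = {}
    for d in deltas:
        by_subject.setdefault(d.subject_id, {})[d.phase] = d.delta
    x = default_norm.log2_values
    ann = default_trial.annotations
    for subject, phases in by_subject.items():
        sub = ann[(ann["subject_id"] == subject) & (ann["tissue"] == "muscle")]
        w = sub.set_index("visit_week")["sample_id"]
        total = x[w[32]] - x[w[0]]
        common = phases[LEAD_IN].index.intersection(phases[TREATMENT].index)
        np.testing.assert_allclose(
            (phases[LEAD_IN] + phases[TREATMENT])[common], total[common], atol=1e-9
        )


def test_delta_is_plain_subtraction():
    x = pd.DataFrame({"s0": [2.0, 1.0], "s16": [5.0, 1.0], "s32": [5.0, 0.0]}, index=["A", "B"])
    ann = pd.DataFrame(
        {
            "sample_id": ["s0", "s16", "s32"],
            "subject_id": "P1",
            "group": "case",
            "tissue": "muscle",
            "visit_week": [0, 16, 32],
            "quality_flag": "ok",
        }
    )
    from sigshift import NormalizedMatrix

    deltas, _ = patient_deltas(NormalizedMatrix(log2_values=x), ann)
    lead = next(d for d in deltas if d.phase == LEAD_IN)
    assert lead.delta["A"] == 3.0 and lead.delta["B"] == 0.0


def test_missing_endpoint_is_omitted_with_audit():
    x = pd.DataFrame({"s0": [2.0], "s16": [5.0]}, index=["A"])
    ann = pd.DataFrame(
        {
            "sample_id": ["s0", "s16"],
            "subject_id": "P1",
            "group": "case",
            "tissue": "muscle",
            "visit_week": [0, 16],
            "quality_flag": "ok",
        }
    )
    from sigshift import NormalizedMatrix

    deltas, audit = patient_deltas(NormalizedMatrix(log2_values=x), ann)
    assert [d.phase for d in deltas] == [LEAD_IN]
    assert audit and "treatment" in audit[0]


def test_duplicate_sample_for_visit_is_error():
    x = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["A"])
    ann = pd.DataFrame(
        {
            "sample_id": ["a", "b"],
            "subject_id": "P1",
            "group": "case",
            "tissue": "muscle",
            "visit_week": [0, 0],
            "quality_flag": "ok",
        }
    )
    from sigshift import NormalizedMatrix

    with pytest.raises(ValueError, match="duplicate"):
        patient_deltas(NormalizedMatrix(log2_values=x), ann)


# --- Spearman --------------------------------------------------------------


def _brute_spearman(a, b):
    def avg_ranks(x):
        x = np.asarray(x, dtype=float)
        r = np.empty(x.size)
        for i, v in enumerate(x):
            less = np.sum(x < v)
            ties = np.sum(x == v)
            r[i] = less + (ties + 1) / 2.0
        return r

    ra, rb = avg_ranks(a), avg_ranks(b)
    return np.corrcoef(ra, rb)[0, 1]


def test_spearman_examples():
    a = np.arange(1.0, 11.0)
    assert spearman_rho(a, a) == pytest.approx(1.0)
    assert spearman_rho(a, a[::-1]) == pytest.approx(-1.0)
    assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)


def test_spearman_ties_match_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.integers(0, 5, size=12).astype(float)
        b = rng.integers(0, 5, size=12).astype(float)
        if np.all(a == a[0]) or np.all(b == b[0]):
            continue
        assert spearman_rho(a, b) == pytest.approx(_brute_spearman(a, b), abs=1e-12)
    assert spearman_rho([1, 2, 2, 3], [1, 2, 3, 4]) == pytest.approx(
        _brute_spearman([1, 2, 2, 3], [1, 2, 3, 4]), abs=1e-12
    )


def test_spearman_constant_vector_error():
    with pytest.raises(ValueError, match="constant"):
        spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_spearman_invariant_to_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=15)
    b = rng.normal(size=15)
    r = spearman_rho(a, b)
    assert spearman_rho(np.exp(a), b) == pytest.approx(r, abs=1e-12)
    assert spearman_rho(a, 3.0 * b + 2.0) == pytest.approx(r, abs=1e-12)
    assert spearman_rho(a, -b) == pytest.approx(-r, abs=1e-12)


# --- jackknife -------------------------------------------------------------


def _brute_jackknife(a, b, level=0.95):
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = a.size
    zs = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        r = _brute_spearman(a[mask], b[mask])
        zs.append(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)))
    zs = np.asarray(zs)
    var = (n - 1) / n * np.sum((zs - zs.mean()) ** 2)
    z0 = np.arctanh(np.clip(_brute_spearman(a, b), -1 + 1e-12, 1 - 1e-12))
    q = stats.norm.ppf(0.5 + level / 2)
    return np.tanh(z0 - q * np.sqrt(var)), np.tanh(z0 + q * np.sqrt(var))


def test_jackknife_matches_brute_force_loop():
    rng = np.random.default_rng(4)
    a = rng.normal(size=12)
    b = 0.6 * a + rng.normal(size=12)
    lo, hi = jackknife_ci(a, b)
    blo, bhi = _brute_jackknife(a, b)
    assert lo == pytest.approx(blo, abs=1e-10)
    assert hi == pytest.approx(bhi, abs=1e-10)


def test_jackknife_with_ties_matches_brute_force():
    rng = np.random.default_rng(5)
    a = rng.integers(0, 4, size=15).astype(float)
    b = a + rng.integers(0, 3, size=15)
    lo, hi = jackknife_ci(a, b)
    blo, bhi = _brute_jackknife(a, b)
    assert (lo, hi) == pytest.approx((blo, bhi), abs=1e-10)


def test_perfectly_monotone_data_clamps_at_one():
    a = np.arange(12.0)
    lo, hi = jackknife_ci(a, a**3)
    assert hi == 1.0
    assert lo <= 1.0


def test_jackknife_needs_ten_pairs():
    with pytest.raises(ValueError, match="10"):
        jackknife_ci(np.arange(9.0), np.arange(9.0) + 0.5)


# --- projection and responder calls ---------------------------------------


def _sig_series(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(0, 1, n), index=[f"M{i}" for i in range(n)])


def test_projecting_signature_onto_itself_gives_unit_rho():
    sig = _sig_series()
    delta = PatientDelta("P1", LEAD_IN, sig.copy())
    score = project_patient(delta, sig)
    assert score.rho == pytest.approx(1.0)
    assert score.ci_high == 1.0
    anti = project_patient(PatientDelta("P1", LEAD_IN, -sig), sig)
    assert anti.rho == pytest.approx(-1.0)


def test_projection_below_threshold_is_unusable():
    sig = _sig_series(n=8)
    score = project_patient(PatientDelta("P1", LEAD_IN, sig), sig)
    assert not score.usable
    assert np.isnan(score.rho)


def test_projection_uses_common_metabolites_only():
    sig = _sig_series(n=40)
    delta = PatientDelta("P1", LEAD_IN, sig.iloc[:25] * 2)
    score = project_patient(delta, sig)
    assert score.n_used == 25
    assert score.rho == pytest.approx(1.0)


def test_phase_target_recovery_with_informative_signature():
    """Per-subject rho estimates land within 0.1 of the planted 0.49
    target in at least 90% of subjects when the whole signature is
    informative and noise is low."""
    hits = total = 0
    for seed in range(20):
        cfg = SyntheticConfig(
            seed=seed,
            n_cases=10,
            n_metabolites=200,
            n_shared_serum=10,
            n_serum_only=5,
            frac_dysregulated=1.0,
            noise_sd=0.05,
            leadin_drift=0.49,
            rho_target_sd=0.0,
            responder_shift=0.0,
        )
        trial = generate_trial(cfg)
        norm = normalize(trial.muscle)
        from sigshift import estimate_signature

        sig = estimate_signature(norm, trial.annotations)
        deltas, _ = patient_deltas(norm, trial.annotations)
        for d in deltas:
            if d.phase != LEAD_IN:
                continue
            score = project_patient(d, sig)
            total += 1
            hits += abs(score.rho - 0.49) <= 0.1
    assert total == 200
    assert hits / total >= 0.90


def test_classify_responder_rules():
    li = RhoScore("P1", LEAD_IN, 0.35, 0.2, 0.5, 100)
    tr_down = RhoScore("P1", TREATMENT, -0.3, -0.6, -0.1, 100)
    call = classify_responder(li, tr_down)
    assert call.responder and call.direction == "toward_control"

    same = classify_responder(li, RhoScore("P1", TREATMENT, 0.35, 0.2, 0.5, 100))
    assert not same.responder and same.direction == "none"

    up = RhoScore("P1", TREATMENT, 0.8, 0.6, 0.9, 100)
    assert not classify_responder(li, up).responder  # directional rule
    assert classify_responder(li, up, directional=False).responder

    unusable = RhoScore("P1", TREATMENT, np.nan, np.nan, np.nan, 3, usable=False)
    none_call = classify_responder(li, unusable)
    assert not none_call.responder and none_call.direction == "none"


def test_responder_monotone_in_interval_separation():
    li = RhoScore("P1", LEAD_IN, 0.3, 0.2, 0.4, 100)
    for widen in (0.0, 0.1, 0.2, 0.4):
        tr = RhoScore("P1", TREATMENT, -0.3, -0.4 - widen, -0.2 + widen, 100)
        call = classify_responder(li, tr)
        assert call.responder == (-0.2 + widen < 0.2)


def test_projection_is_deterministic(default_trial, default_norm):
    from sigshift import estimate_signature

    sig = estimate_signature(default_norm, default_trial.annotations)
    deltas, _ = patient_deltas(default_norm, default_trial.annotations)
    s1 = project_patient(deltas[0], sig)
    s2 = project_patient(deltas[0], sig)
    assert (s1.rho, s1.ci_low, s1.ci_high) == (s2.rho, s2.ci_low, s2.ci_high)


# --- cohort-level correlations ---------------------------------------------


def test_correlate_signatures_identity_and_intersection():
    a = _sig_series(n=30, seed=1)
    res = correlate_signatures(a, a.copy())
    assert res.rho == pytest.approx(1.0)

    b = _sig_series(n=30, seed=2)
    b.index = [f"M{i}" for i in range(27, 57)]  # only M27..M29 shared
    res = correlate_signatures(a, b)
    assert res.n == 3
    with pytest.raises(ValueError, match="shared|3"):
        correlate_signatures(a, pd.Series([1.0, 2.0], index=["X", "Y"]))


def test_correlate_signatures_matches_scipy_and_quadrants():
    rng = np.random.default_rng(9)
    a = pd.Series(rng.normal(size=50), index=[f"M{i}" for i in range(50)])
    b = 0.5 * a + rng.normal(size=50)
    res = correlate_signatures(a, b)
    rho, p = stats.spearmanr(a, b)
    assert res.rho == pytest.approx(rho)
    assert res.p == pytest.approx(p)
    same = (np.sign(a) * np.sign(b) >= 0).map({True: "same_direction", False: "opposite"})
    assert (res.table["quadrant"] == same).all()
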