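"""Synthetic lead-in/crossover trial generator with planted ground truth.

Emulates the structure of a single-arm trial in inclusion body myositis:
~15 case muscle biopsies at baseline / week 16 / week 32 against 5
healthy muscle controls, case sera against 10 control sera sharing a
subset of metabolite identifiers with muscle, per-muscle ultrasound
severity, and clinical outcomes at four visits driven by a planted
mixed model.

Every quantity the downstream pipeline estimates is planted explicitly:

* a disease signature (case-vs-control log2FC) on a configurable
  fraction of metabolites, amplified multiplicatively in severe
  subjects;
* per-subject, per-phase target Spearman rho values for the
  within-subject metabolite change against the signature.  The phase
  log2FC vector is built in rank space: a controlled Pearson
  correlation r = 2 sin(pi * rho_s / 6) against normal scores of the
  (perturbed) signature ranks yields an expected Spearman of rho_s;
* responder flags (treatment-phase target strictly below lead-in);
* clinical fixed effects, including the rho x time coefficient, with
  subject-level random intercepts and slopes.

Raw intensities are exponentiated from the log2 scale and multiplied by
a per-sample protein factor so that preprocessing must undo both.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MetaboliteMatrix
from .projection import LEAD_IN, TREATMENT
from .severity import MUSCLES, SEVERE, MILD, UltrasoundAssessment, write_ultrasound_tsv


@dataclass
class OutcomeCoefs:
    """Fixed-effect truth for one clinical outcome (time in 16-week units)."""

    intercept: float
    time_slope: float
    rho_main: float = 0.0
    rho_time: float = 0.0
    treat_main: float = 0.0
    treat_time: float = 0.0
    resid_sd: float = 1.0
    re_int_sd: float = 2.0
    re_slope_sd: float = 0.3


def default_outcomes() -> dict:
    """Trial-like defaults: a functional rating scale declining with
    disease-like metabolic drift, and a timed mobility test worsening
    (increasing) with it."""
    return {
        "IBM_FRS": OutcomeCoefs(intercept=29.0, time_slope=-0.2, rho_time=-3.32, resid_sd=1.0, re_int_sd=4.0, re_slope_sd=0.3),
        "mTUG": OutcomeCoefs(intercept=10.5, time_slope=0.15, rho_time=1.95, resid_sd=0.8, re_int_sd=2.5, re_slope_sd=0.2),
    }


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_cases: int = 15
    n_controls_muscle: int = 5
    n_controls_serum: int = 10
    n_metabolites: int = 211
    n_shared_serum: int = 124
    n_serum_only: int = 76
    frac_dysregulated: float = 0.3
    signature_effect_sd: float = 2.0
    noise_sd: float = 0.25
    leadin_drift: float = 0.0
    rho_target_sd: float = 0.25
    responder_fraction: float = 1.0 / 3.0
    responder_shift: float = -0.8
    responders_mild_only: bool = True
    frac_severe: float = 0.5
    severity_amplification: float = 1.5
    delta_scale: float = 0.5
    outcome_coefs: dict = field(default_factory=default_outcomes)
    protein_conc_range: tuple = (1.0, 3.0)
    dropout: float = 0.0

    def validate(self) -> None:
        for name in ("n_cases", "n_controls_muscle", "n_controls_serum", "n_metabolites"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for name in ("frac_dysregulated", "responder_fraction", "frac_severe", "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_shared_serum > self.n_metabolites:
            raise ValueError("n_shared_serum cannot exceed n_metabolites")
        if not -1.0 <= self.leadin_drift <= 1.0:
            raise ValueError("leadin_drift must lie in [-1, 1]")
        if not -2.0 <= self.responder_shift <= 0.0:
            raise ValueError("responder_shift must lie in [-2, 0] (negative = toward controls)")
        if self.severity_amplification < 1.0:
            raise ValueError("severity_amplification must be >= 1")
        lo, hi = self.protein_conc_range
        if not 0 < lo <= hi:
            raise ValueError("protein_conc_range must be a positive interval")


@dataclass
class GroundTruth:
    true_signature: pd.Series
    responder_flags: dict
    severity_class: dict
    phase_rho_targets: dict  # (subject, phase) -> target rho
    outcome_coefs: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_signature": {k: float(v) for k, v in self.true_signature.items()},
                "responder_flags": {k: bool(v) for k, v in self.responder_flags.items()},
                "severity_class": dict(self.severity_class),
                "phase_rho_targets": {f"{s}:{ph}": float(v) for (s, ph), v in self.phase_rho_targets.items()},
                "outcome_coefs": {k: asdict(v) for k, v in self.outcome_coefs.items()},
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SyntheticTrial:
    muscle: MetaboliteMatrix
    serum: MetaboliteMatrix
    annotations: pd.DataFrame
    ultrasound: list
    clinical: pd.DataFrame
    truth: GroundTruth


def _normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size)


def _targeted_delta(rng, zscores: np.ndarray, target_rho: float, scale: float) -> np.ndarray:
    """Vector whose expected Spearman correlation against the ordering
    behind ``zscores`` equals ``target_rho``."""
    n = zscores.size
    z = (zscores - zscores.mean())
    z = z / np.linalg.norm(z)
    e = rng.normal(size=n)
    e = e - e.mean()
    e = e - (e @ z) * z
    e = e / np.linalg.norm(e)
    r = 2.0 * math.sin(math.pi * target_rho / 6.0)
    d = r * z + math.sqrt(max(0.0, 1.0 - r * r)) * e
    return scale * math.sqrt(n) * d


def generate_trial(config: SyntheticConfig) -> SyntheticTrial:
    """Generate a complete synthetic trial; byte-identical for equal seeds."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    met_ids = [f"M{i:04d}" for i in range(1, config.n_metabolites + 1)]
    serum_ids = met_ids[: config.n_shared_serum] + [f"S{i:04d}" for i in range(1, config.n_serum_only + 1)]
    cases = [f"P{i:02d}" for i in range(1, config.n_cases + 1)]
    ctrl_mus = [f"CM{i:02d}" for i in range(1, config.n_controls_muscle + 1)]
    ctrl_ser = [f"CS{i:02d}" for i in range(1, config.n_controls_serum + 1)]

    # --- planted truths -----------------------------------------------------
    n_met = config.n_metabolites
    effects = np.zeros(n_met)
    n_dys = int(round(config.frac_dysregulated * n_met))
    dys_idx = rng.choice(n_met, size=n_dys, replace=False)
    effects[dys_idx] = rng.normal(0.0, config.signature_effect_sd, size=n_dys) if config.signature_effect_sd > 0 else 0.0
    est_noise = config.noise_sd * math.sqrt(1.0 / config.n_cases + 1.0 / config.n_controls_muscle)
    s_tilde = effects + rng.normal(0.0, max(est_noise, 1e-6), size=n_met)
    zscores = _normal_scores(s_tilde)

    n_severe = int(round(config.frac_severe * config.n_cases))
    severity = {s: (SEVERE if i < n_severe else MILD) for i, s in enumerate(cases)}

    n_resp = int(round(config.responder_fraction * config.n_cases)) if config.responder_shift < 0 else 0
    if config.responders_mild_only:
        pool = [s for s in cases if severity[s] == MILD] + [s for s in cases if severity[s] == SEVERE]
    else:
        pool = cases
    responders = set(pool[:n_resp])
    responder_flags = {s: (s in responders) for s in cases}

    targets = {}
    for s in cases:
        leadin = float(np.clip(rng.normal(config.leadin_drift, config.rho_target_sd), -0.9, 0.9))
        treat = leadin + (config.responder_shift if s in responders else 0.0)
        targets[(s, LEAD_IN)] = leadin
        targets[(s, TREATMENT)] = float(np.clip(treat, -0.99, 0.99))

    # --- muscle matrix ------------------------------------------------------
    base = rng.normal(10.0, 2.0, size=n_met)
    columns: dict = {}
    ann_rows: list = []

    def add_sample(sample_id, log2vals, subject, group, tissue, week):
        columns[sample_id] = log2vals
        ann_rows.append(
            {
                "sample_id": sample_id,
                "subject_id": subject,
                "group": group,
                "tissue": tissue,
                "visit_week": week,
                "quality_flag": "ok",
            }
        )

    for s in cases:
        mult = config.severity_amplification if severity[s] == SEVERE else 1.0
        v0 = base + mult * effects + rng.normal(0.0, config.noise_sd, size=n_met)
        d_lead = _targeted_delta(rng, zscores, targets[(s, LEAD_IN)], config.delta_scale)
        d_treat = _targeted_delta(rng, zscores, targets[(s, TREATMENT)], config.delta_scale)
        add_sample(f"{s}_mus_W0", v0, s, "case", "muscle", 0)
        add_sample(f"{s}_mus_W16", v0 + d_lead, s, "case", "muscle", 16)
        add_sample(f"{s}_mus_W32", v0 + d_lead + d_treat, s, "case", "muscle", 32)
    for c in ctrl_mus:
        add_sample(f"{c}_mus", base + rng.normal(0.0, config.noise_sd, size=n_met), c, "control", "muscle", None)

    muscle_log2 = pd.DataFrame(columns, index=met_ids)
    muscle_samples = list(muscle_log2.columns)

    # --- serum matrix (independent signature; no planted dynamics) ----------
    n_ser = len(serum_ids)
    base_ser = rng.normal(10.0, 2.0, size=n_ser)
    eff_ser = np.zeros(n_ser)
    n_dys_ser = int(round(config.frac_dysregulated * n_ser))
    idx_ser = rng.choice(n_ser, size=n_dys_ser, replace=False)
    eff_ser[idx_ser] = rng.normal(0.0, config.signature_effect_sd, size=n_dys_ser) if config.signature_effect_sd > 0 else 0.0
    ser_columns: dict = {}
    for s in cases:
        for week in (0, 16, 32):
            key = f"{s}_ser_W{week}"
            ser_columns[key] = base_ser + eff_ser + rng.normal(0.0, config.noise_sd, size=n_ser)
            ann_rows.append({"sample_id": key, "subject_id": s, "group": "case", "tissue": "serum", "visit_week": week, "quality_flag": "ok"})
    for c in ctrl_ser:
        key = f"{c}_ser"
        ser_columns[key] = base_ser + rng.normal(0.0, config.noise_sd, size=n_ser)
        ann_rows.append({"sample_id": key, "subject_id": c, "group": "control", "tissue": "serum", "visit_week": None, "quality_flag": "ok"})
    serum_log2 = pd.DataFrame(ser_columns, index=serum_ids)

    # --- exponentiate and apply per-sample protein factor -------------------
    lo, hi = config.protein_conc_range
    prot_mus = pd.Series(rng.uniform(lo, hi, size=muscle_log2.shape[1]), index=muscle_log2.columns)
    prot_ser = pd.Series(rng.uniform(lo, hi, size=serum_log2.shape[1]), index=serum_log2.columns)
    raw_mus = np.exp2(muscle_log2) * prot_mus
    raw_ser = np.exp2(serum_log2) * prot_ser
    if config.dropout > 0:
        raw_mus = raw_mus.where(rng.random(raw_mus.shape) >= config.dropout, 0.0)
        raw_ser = raw_ser.where(rng.random(raw_ser.shape) >= config.dropout, 0.0)

    ann = pd.DataFrame(ann_rows)
    ann["protein_conc"] = ann["sample_id"].map(pd.concat([prot_mus, prot_ser]))

    muscle = MetaboliteMatrix(intensities=raw_mus, protein_conc=prot_mus, tissue="muscle")
    serum = MetaboliteMatrix(intensities=raw_ser, protein_conc=prot_ser, tissue="serum")

    # --- ultrasound ---------------------------------------------------------
    ultrasound = []
    for s in cases:
        grades, atrophy = {}, {}
        if severity[s] == SEVERE:
            maxes = [4, 4, int(rng.integers(3, 5))]  # sum 11 or 12
            has_atrophy = True
        else:
            maxes = list(rng.integers(2, 4, size=3))  # sum 6..9
            has_atrophy = bool(rng.random() < 0.3)
        for muscle_name, mx in zip(MUSCLES, maxes):
            other = int(rng.integers(1, mx + 1))
            left_is_max = bool(rng.random() < 0.5)
            grades[(muscle_name, "left")] = mx if left_is_max else other
            grades[(muscle_name, "right")] = other if left_is_max else mx
            atrophy[(muscle_name, "left")] = has_atrophy and muscle_name == "VL"
            atrophy[(muscle_name, "right")] = has_atrophy and muscle_name == "VL"
        ultrasound.append(UltrasoundAssessment(subject_id=s, grades=grades, atrophy=atrophy))

    # --- clinical outcomes from the planted mixed model ---------------------
    clin_rows = []
    for s in cases:
        for name, cf in config.outcome_coefs.items():
            b0 = rng.normal(0.0, cf.re_int_sd) if cf.re_int_sd > 0 else 0.0
            b1 = rng.normal(0.0, cf.re_slope_sd) if cf.re_slope_sd > 0 else 0.0
            for week in (0, 16, 32, 48):
                t = week / 16.0
                rho_t = targets[(s, LEAD_IN)] if week <= 16 else targets[(s, TREATMENT)]
                treat = 1.0 if week >= 32 else 0.0
                mu = (
                    cf.intercept
                    + cf.rho_main * rho_t
                    + cf.time_slope * t
                    + cf.rho_time * rho_t * t
                    + cf.treat_main * treat
                    + cf.treat_time * treat * t
                    + b0
                    + b1 * t
                )
                eps = rng.normal(0.0, cf.resid_sd) if cf.resid_sd > 0 else 0.0
                clin_rows.append({"subject_id": s, "visit_week": week, "outcome": name, "value": mu + eps})
    clinical = pd.DataFrame(clin_rows)

    truth = GroundTruth(
        true_signature=pd.Series(effects, index=met_ids),
        responder_flags=responder_flags,
        severity_class=severity,
        phase_rho_targets=targets,
        outcome_coefs=dict(config.outcome_coefs),
    )
    return SyntheticTrial(muscle=muscle, serum=serum, annotations=ann, ultrasound=ultrasound, clinical=clinical, truth=truth)


def write_trial(trial: SyntheticTrial, out_dir) -> dict:
    """Write a trial in the pipeline's TSV input formats plus the
    ground-truth JSON; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}

    def write_matrix(m: MetaboliteMatrix, name: str):
        path = out / f"{name}_intensities.tsv"
        df = m.intensities.copy()
        df.index.name = "metabolite"
        df.to_csv(path, sep="\t", float_format="%.10g")
        manifest[f"{name}_intensities"] = str(path)

    write_matrix(trial.muscle, "muscle")
    write_matrix(trial.serum, "serum")

    meta = out / "metadata.tsv"
    ann = trial.annotations.copy()
    ann["visit_week"] = ann["visit_week"].astype("Int64")
    ann.to_csv(meta, sep="\t", index=False, float_format="%.10g")
    manifest["metadata"] = str(meta)

    clin = out / "clinical.tsv"
    trial.clinical.to_csv(clin, sep="\t", index=False, float_format="%.10g")
    manifest["clinical"] = str(clin)

    us = out / "ultrasound.tsv"
    write_ultrasound_tsv(trial.ultrasound, us)
    manifest["ultrasound"] = str(us)

    gt = out / "ground_truth.json"
    gt.write_text(trial.truth.to_json())
    manifest["ground_truth"] = str(gt)
    return manifest
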