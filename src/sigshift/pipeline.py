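"""End-to-end pipeline wiring and the run report.

Stage order follows the analysis: preprocess each tissue, estimate the
disease signature, project per-patient phase changes onto it, stratify
by ultrasound severity, and fit the longitudinal outcome models.  All
tabular outputs are TSV with a header row; the run report is JSON and
lists every output file with a checksum so deterministic reruns can be
verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess, signature, projection, severity as severity_mod, outcomes as outcomes_mod
from .projection import LEAD_IN, TREATMENT

log = logging.getLogger("sigshift")

DEFAULT_EXCLUSIONS = ["epinephrine"]


@dataclass
class RunConfig:
    muscle_tsv: str
    metadata_tsv: str
    out_dir: str
    serum_tsv: str | None = None
    clinical_tsv: str | None = None
    ultrasound_tsv: str | None = None
    external_signature_tsv: str | None = None
    exclusions: list = field(default_factory=lambda: list(DEFAULT_EXCLUSIONS))
    min_common_metabolites: int = 10
    fdr_level: float = 0.05
    ci_level: float = 0.95
    severity_cutoff: int = 10
    directional_responder: bool = True
    shrinkage: str = "moderated"
    anova_response: str = "per_phase_rho"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if not (isinstance(self.severity_cutoff, int) and self.severity_cutoff > 0):
            raise ValueError("severity_cutoff must be a positive integer")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    files: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    def record_file(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.files[name] = {"path": str(path), "sha256": digest}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=str)


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", na_rep="")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute preprocess -> signature -> projection -> severity -> outcomes.

    Deterministic given the config; a failing stage is recorded in the
    report and later stages that depend on it are skipped, while prior
    outputs are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            _run_stages(config, out, report)
        except Exception as exc:  # pragma: no cover - defensive
            log.error("[pipeline] aborted: %s", exc)
            report.errors.append(str(exc))
    seen = set()
    for w in caught:
        msg = str(w.message)
        if msg not in seen:
            seen.add(msg)
            report.warnings.append(msg)

    report_path = out / "run_report.json"
    report_path.write_text(report.to_json())
    return report


def _run_stages(config: RunConfig, out: Path, report: RunReport) -> None:
    # --- preprocess ---------------------------------------------------------
    log.info("[preprocess] reading inputs")
    meta = preprocess.read_metadata_tsv(config.metadata_tsv)
    matrices = {}
    for tissue, path in (("muscle", config.muscle_tsv), ("serum", config.serum_tsv)):
        if path is None:
            continue
        m = preprocess.read_intensity_tsv(path, meta, tissue)
        m = preprocess.exclude_metabolites(m, config.exclusions)
        norm = preprocess.normalize(m)
        matrices[tissue] = norm
        p = out / f"{tissue}_normalized.tsv"
        preprocess.write_normalized_tsv(norm, p)
        report.record_file(f"{tissue}_normalized", p)
        report.stages[f"preprocess_{tissue}"] = norm.audit

    # --- signature ----------------------------------------------------------
    sigs = {}
    for tissue, norm in matrices.items():
        sig = signature.estimate_signature(norm, meta, shrinkage=config.shrinkage)
        sigs[tissue] = sig
        p = out / f"{tissue}_signature.tsv"
        signature.write_signature_tsv(sig, p)
        report.record_file(f"{tissue}_signature", p)
        report.stages[f"signature_{tissue}"] = sig.audit or []
    pc1 = signature.pc1_separation(matrices["muscle"], meta)
    report.stages["pc1_separation"] = {"F": pc1.F, "df": list(pc1.df), "p": pc1.p, "mode": pc1.mode}

    if "serum" in matrices:
        common = preprocess.intersect_features(matrices["muscle"], matrices["serum"])
        cross = projection.correlate_signatures(
            sigs["muscle"].log2fc, sigs["serum"].log2fc, sigs["muscle"].table["p"], sigs["serum"].table["p"]
        )
        p = out / "muscle_serum_fc_correlation.tsv"
        _write_tsv(cross.table, p, index=True)
        report.record_file("muscle_serum_fc_correlation", p)
        report.stages["muscle_serum_correlation"] = {"rho": cross.rho, "p": cross.p, "n_shared": len(common)}

    # --- projection ---------------------------------------------------------
    deltas, delta_audit = projection.patient_deltas(matrices["muscle"], meta)
    report.stages["patient_deltas"] = delta_audit
    ref = sigs["muscle"]
    if config.external_signature_tsv:
        ref = signature.read_signature_tsv(config.external_signature_tsv)
    scores = [
        projection.project_patient(d, ref, min_common=config.min_common_metabolites, level=config.ci_level)
        for d in deltas
    ]
    rho_df = projection.rho_table(scores)
    p = out / "rho_scores.tsv"
    _write_tsv(rho_df, p)
    report.record_file("rho_scores", p)

    by_subject = {}
    for s in scores:
        by_subject.setdefault(s.subject_id, {})[s.phase] = s
    calls = []
    for subject, phases in sorted(by_subject.items()):
        if LEAD_IN in phases and TREATMENT in phases:
            call = projection.classify_responder(
                phases[LEAD_IN], phases[TREATMENT], directional=config.directional_responder
            )
            calls.append({"subject_id": subject, "responder": call.responder, "direction": call.direction})
    calls_df = pd.DataFrame(calls)
    p = out / "responder_calls.tsv"
    _write_tsv(calls_df, p)
    report.record_file("responder_calls", p)
    report.stages["responders"] = {"n_responders": int(calls_df["responder"].sum()) if len(calls_df) else 0, "n_called": len(calls_df)}

    # cohort-level phase correlations vs the signature
    phase_stats = {}
    for phase in (LEAD_IN, TREATMENT):
        vecs = [d.delta for d in deltas if d.phase == phase]
        if vecs:
            mean_delta = pd.concat(vecs, axis=1).mean(axis=1)
            res = projection.correlate_signatures(mean_delta, sigs["muscle"].log2fc)
            phase_stats[phase] = {"rho": res.rho, "p": res.p, "n": res.n}
    report.stages["cohort_phase_correlation"] = phase_stats

    # --- severity -----------------------------------------------------------
    if config.ultrasound_tsv:
        assessments = severity_mod.read_ultrasound_tsv(config.ultrasound_tsv)
        sev = {}
        rows = []
        for a in assessments:
            score, cls = severity_mod.sum_score(a, cutoff=config.severity_cutoff)
            sev[a.subject_id] = cls
            rows.append({"subject_id": a.subject_id, "sum_score": score, "severity": cls})
        p = out / "severity.tsv"
        _write_tsv(pd.DataFrame(rows), p)
        report.record_file("severity", p)
        try:
            anova = severity_mod.severity_anova(rho_df, sev)
            p = out / "severity_anova.tsv"
            _write_tsv(anova.table, p, index=True)
            report.record_file("severity_anova", p)
            loo = severity_mod.leave_one_out(rho_df, sev)
            p = out / "leave_one_out.json"
            p.write_text(json.dumps({"p_full": anova.p_interaction, "per_subject": loo.to_dict(orient="records")}, indent=1))
            report.record_file("leave_one_out", p)
            report.stages["severity_anova"] = {
                "F_interaction": anova.F_interaction,
                "p_interaction": anova.p_interaction,
            }
        except ValueError as exc:
            report.errors.append(f"severity stage: {exc}")

    # --- outcomes -----------------------------------------------------------
    if config.clinical_tsv:
        clinical = outcomes_mod.read_clinical_tsv(config.clinical_tsv)
        unknown = set(clinical["subject_id"]) - set(meta["subject_id"])
        if unknown:
            raise ValueError(f"clinical records for subject(s) absent from metadata: {sorted(unknown)}")
        results = {}
        for name in sorted(clinical["outcome"].unique()):
            entry = {}
            for label, fit in (
                ("treatment", lambda: outcomes_mod.fit_treatment_model(clinical, name)),
                ("rho", lambda: outcomes_mod.fit_rho_model(clinical, name, rho_df)),
            ):
                try:
                    res = fit()
                    entry[label] = {
                        "fixed_effects": {
                            t: {"estimate": res.estimates.get(t), "se": res.ses.get(t), "p": res.pvalues.get(t)}
                            for t in (res.terms if res.converged else [])
                        },
                        "random_structure": res.random_structure,
                        "converged": res.converged,
                        "n_obs": res.n_obs,
                        "n_subjects": res.n_subjects,
                        "audit": res.audit,
                    }
                except ValueError as exc:
                    entry[label] = {"error": str(exc)}
            results[name] = entry
        p = out / "outcome_models.json"
        p.write_text(json.dumps(results, indent=1, sort_keys=True, default=float))
        report.record_file("outcome_models", p)
        report.stages["outcomes"] = {"n_outcomes": len(results)}


def simulate(config, out_dir) -> dict:
    """Write a complete synthetic trial in pipeline input formats."""
    from .synthetic import generate_trial, write_trial

    trial = generate_trial(config)
    return write_trial(trial, out_dir)
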