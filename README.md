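# sigshift

Signature-shift analysis for single-arm lead-in trials with longitudinal
omics — built for untargeted metabolomics in inclusion body myositis
(IBM)-style studies, where each patient serves as their own comparator:
a 16-week observation (lead-in) phase precedes the on-drug phase, with
tissue sampled at baseline, week 16 and week 32 and clinical outcomes
followed to week 48.

The package is aimed at analysts of small crossover-by-time trials who
want to quantify, per patient, whether the molecular profile is moving
toward or away from a disease signature, and to connect that movement
to clinical trajectories.

## The method

1. **Preprocessing.** Raw metabolite intensities are divided by the
   per-sample protein concentration, log2-transformed (zeros become
   missing) and median-centered per sample. Known artifacts (e.g.
   anesthetic-derived epinephrine in biopsy tissue) are excluded first.
2. **Disease signature.** For each metabolite *g*, the case-vs-control
   log2 fold change and an empirical-Bayes moderated t statistic

   t_g = log2FC_g / sqrt( s̃²_g (1/n₁ + 1/n₂) ),   s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d),

   with the prior (d₀, s₀²) moment-matched to the observed variance
   distribution, Benjamini–Hochberg FDR across metabolites, Fisher's
   combined p (−2Σln pᵢ ~ χ²_{2k}) across paired comparisons, and an
   F test comparing case-vs-control variance of PC1 scores.
3. **Projection.** Each patient's per-phase metabolite change vector
   Δ (log2FC from baseline→W16 and W16→W32) is projected onto the
   signature as Spearman's ρ = corr_S(Δ, log2FC_signature): positive ρ
   means drifting toward the disease profile, negative ρ toward
   controls. A delete-one jackknife over metabolite pairs on the
   Fisher-z scale gives 95% CIs; a patient is a **responder** when the
   two phase CIs are disjoint with the treatment interval below the
   lead-in interval.
4. **Severity stratification.** Heckmatt echointensity grades (1–4) of
   FDP/VL/RF, bilateral maximum summed (range 3–12); severe = sum > 10
   with atrophy. A two-way mixed ANOVA tests the phase × severity
   interaction on ρ, with Tukey HSD and leave-one-out influence
   analysis.
5. **Outcomes.** Linear mixed models
   `outcome ~ 1 + X*time + (1 + time | subject)` with X either an
   on-drug indicator or the time-varying ρ(t) (lead-in ρ at weeks 0/16,
   treatment ρ at weeks 32/48); the ρ×time coefficient is the headline
   estimate, with counterfactual trajectory predictions for chosen ρ
   profiles.

A first-class synthetic-trial generator plants every quantity the
pipeline estimates (signature, per-phase ρ targets, responder flags,
severity classes, outcome coefficients), so each stage has a
parameter-recovery test.

## Worked example

```bash
sigshift simulate demo/trial --seed 11
sigshift run-all \
    --muscle-tsv demo/trial/muscle_intensities.tsv \
    --serum-tsv demo/trial/serum_intensities.tsv \
    --metadata-tsv demo/trial/metadata.tsv \
    --clinical-tsv demo/trial/clinical.tsv \
    --ultrasound-tsv demo/trial/ultrasound.tsv \
    --out-dir demo/out
head -4 demo/out/rho_scores.tsv
```

```
subject_id  phase      rho        ci_low      ci_high   n_used  usable
P01         lead_in    0.239569   0.0980909   0.371555  211     True
P01         treatment  0.222755   0.08374     0.353266  211     True
P02         lead_in    0.147315   0.0116843   0.277624  211     True
```

Each row is one patient-phase ρ with its jackknife CI over the 211
metabolites used. For this seed the run report shows 4 of 15 patients
called responders, a cohort-level lead-in stability check of ρ = 0.128
(p = 0.064, i.e. no drift without treatment) against a clear
treatment-phase shift away from the disease signature (ρ = −0.47,
p < 1e-12), and an IBM-FRS mixed model with a negative ρ×time estimate
(−5.46): patients whose metabolome moved toward the control profile
declined less. `demo/out/run_report.json` lists every output file with
its SHA-256 so reruns can be verified byte for byte.

The same machinery accepts an external log2FC table
(`--external-signature-tsv`, e.g. a transcriptomic disease signature)
in place of the internally estimated one.

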