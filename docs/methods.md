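# Methods

This note records the models implemented in `sigshift`, the choices
made where the design was genuinely open, and what the synthetic-data
calibrations do and do not demonstrate.

## Normalization

Order is fixed: (1) exclude listed artifact metabolites, (2) divide
each sample by its protein concentration (mg/mL scalar), (3) log2,
(4) subtract the per-sample median of log2 values. Exclusion precedes
normalization so an excluded row can never shift a sample median.
Nonpositive intensities become missing rather than pseudocounted;
pseudocounts distort low-abundance fold changes and every downstream
statistic handles missingness pairwise-complete. The centering target
(0) is arbitrary — any constant target yields identical downstream
correlations — and per-sample multiplicative rescaling of the raw data
is provably absorbed by the centering, which the tests assert.

## Moderated differential abundance

With n₁ cases and n₂ controls per metabolite, the pooled variance s²_g
on d = n₁+n₂−2 df is shrunk toward a scaled-inverse-chi-square prior
(d₀, s₀²): s̃²_g = (d₀s₀² + d s²_g)/(d₀+d), and t_g = log2FC_g /
sqrt(s̃²_g(1/n₁+1/n₂)) is referred to t with d+d₀ df. The prior is
moment-matched on the log scale: e_g = log s²_g − ψ(d/2) + log(d/2)
has Var(e) = ψ′(d/2) + ψ′(d₀/2) and mean log s₀² + ψ(d₀/2) − log(d₀/2);
the trigamma equation is inverted by Newton iteration. When the
observed variances are no more dispersed than sampling alone explains,
d₀ = ∞ and every metabolite uses s₀². With metabolite-wise missingness
the residual df varies; the moment matching uses the median df, which
is exact in the common complete-data case. Setting the prior df to 0
recovers the ordinary pooled t exactly (asserted to 1e-10). BH FDR is
applied within one analysis family: across metabolites of one tissue
comparison, or across metabolites of the Fisher-combined p values.

The group-separation check runs PCA on samples (per-metabolite
centering only, no unit-variance scaling, matching the median-centered
input scale) and compares case-vs-control variance of PC1 scores with
a two-sided variance-ratio F test; a one-way ANOVA on PC1 scores is
available behind a flag since the construction is not uniquely
determined by the phrase "F test on PC1".

## Projection and responder calls

Per-phase patient deltas are later-minus-earlier centered log2 values
over metabolites observed at both endpoints; lead-in and treatment
deltas telescope to the baseline→W32 delta by construction. The ρ
score is Spearman's correlation (average ranks for ties) between the
delta and the signature log2FC over their common metabolites; below 10
common metabolites a score is unusable rather than silently noisy. By
default all common metabolites enter the projection; an FDR filter on
the signature is available behind a flag but not default, since
filtering couples the projection to the significance calibration.

The CI is a delete-one jackknife over metabolite pairs on the Fisher-z
scale: z_i = atanh(ρ_(−i)), var = (n−1)/n Σ(z_i − z̄)², normal-theory
interval about atanh(ρ), back-transformed and clamped to [−1, 1].
The z scale is the standard variance-stabilizing choice when a CI
package's internals are unspecified. Delete-one ranks are computed by
a closed-form update of average ranks under deletion (validated
against an explicit loop to 1e-10); degenerate leave-one-out subsets
are skipped, and fewer than 80% usable pseudovalues is an error.
Empirical coverage for true Spearman ρ = 0.5 at n = 150 pairs is
~0.95 (500 Gaussian-copula simulations).

A responder has disjoint lead-in and treatment CIs. On top of the
bare no-overlap rule the default adds directionality — the treatment
interval must lie entirely below the lead-in interval (shift toward
the control profile) — because a responder is defined as moving away
from the disease signature; `directional=False` restores the bare
rule.

## Severity

Sum score = Σ over FDP/VL/RF of the bilateral maximum Heckmatt grade
(3–12). Severe = sum > 10 AND atrophy in at least one muscle; the
atrophy condition affects only the label, never the sum, and can be
dropped by flag. The phase × severity test is the classical
univariate mixed-ANOVA decomposition (phase within subject, severity
between); with two within-subject levels sphericity holds trivially,
so no correction is applied. The ANOVA response is the per-phase ρ
(phase as within factor); with two phases the interaction F is
equivalent to a two-sample test on ρ-change scores. Unbalanced group
sizes use cell means weighted by group n; the decomposition is
cross-checked against an independent implementation in the tests.
Tukey HSD runs over the four phase×severity cell labels. Leave-one-out
refits the ANOVA without each subject and flags a subject influential
when the interaction p crosses 0.05 in either direction, mirroring
sensitivity analysis practice for small cohorts.

## Outcome models

Time is coded as visit index in 16-week units (weeks 0/16/32/48 →
0/1/2/3) and the treatment indicator is 1 at the on-drug visits
(weeks 32/48); both codings are recorded in every result. The ρ model
carries ρ(t) as a time-varying covariate: lead-in ρ at weeks 0/16,
treatment ρ at weeks 32/48. Fits are REML with random intercept and
slope per subject and Wald z tests on fixed effects (the df method of
the original is unstated; Wald is the simplest defensible default at
these sizes, and the measured CI coverage below quantifies its cost).
If the random-slope fit fails to converge the model refits with a
random intercept only and records the fallback. Data with essentially
zero residual variance make any mixed fit singular; in that one
degenerate case the exact least-squares coefficients are reported
without uncertainties. Missing visits (e.g. remote-only final
assessments) are handled by likelihood-based fitting on available
records, no imputation. Counterfactual trajectories for a ρ profile
are population-level predictions (random effects at zero) with
delta-method bands from the fixed-effect covariance. The paired phase
test is a paired t on per-subject (treatment change − lead-in change).

## Synthetic trials

The generator emulates the trial structure: 15 cases with muscle
biopsies at baseline/W16/W32, 5 muscle controls, 10 serum controls,
211 muscle metabolites of which 124 share identifiers with serum,
ultrasound severity (half severe by default), and clinical outcomes
at 4 visits. Baseline log2 abundances are N(10, 2) per metabolite
(typical LC-MS dynamic range); 30% of metabolites carry case-vs-control
effects N(0, 2) in log2 units, multiplied by 1.5 in severe subjects;
measurement noise is N(0, 0.25); protein factors are Uniform(1, 3)
mg/mL applied multiplicatively on the raw scale so preprocessing must
undo them. Within-subject metabolite autocorrelation beyond the
planted phase changes is not modelled.

Per-phase ρ targets are planted in rank space: the phase log2FC is
r·z + √(1−r²)·e with z the normal scores of the (perturbation-broken)
signature ranks, e an orthogonalized random vector, and
r = 2 sin(πρ_s/6), so the expected Spearman against that ordering is
ρ_s. Lead-in targets are N(drift, 0.25) across subjects (drift 0 by
default: a stable lead-in); responders (a third of cases by default,
preferentially mild-disease subjects) have treatment targets shifted
by −0.8, non-responders identical targets. With only 30% of
metabolites dysregulated the target is exact against the planted
ordering but attenuated against the re-estimated signature, because
null metabolites rank arbitrarily; calibrations that need tight
target recovery therefore use a fully informative signature
(`frac_dysregulated=1`), and the operating-characteristic
calibrations run at the study-like 30% and absorb the attenuation.
Clinical outcomes come from the planted mixed model (functional-scale
defaults: intercept 29, time slope −0.2/16wk, ρ×time −3.32, residual
sd 1, random-effect sds 4 and 0.3) with the subject's phase targets
as covariate.

One RNG stream per trial, seeded once; identical seeds give
byte-identical files. What passing these calibrations shows is that
the estimators recover what was planted under this idealized
generative model; real data add batch structure, missingness,
annotation error and non-Gaussian noise that the generator does not
emulate.

## Calibration sizes and observed values

Chosen problem sizes: jackknife coverage 500 simulations × 150 pairs;
responder operating characteristics 200 trials (12 cases, 200
metabolites) per arm; signature recovery one 211-metabolite trial plus
200 null trials for test size; ρ×time recovery 200 trials of 12
subjects × 4 visits (plus 200 permuted refits); severity power 200
trials; lead-in null 200 trials. Representative measured values (seed
1): primitive-vs-oracle max |Δ| ≈ 2e-14; jackknife coverage 0.948;
responder sensitivity 0.976 at Δρ = −0.8 with false-positive rate 0.0
at Δρ = 0; signature recovery r = 0.995 with type-I error 0.048;
ρ×time mean estimate −3.35 for plant −3.32 with 93.5% Wald CI
coverage, and −0.53 after permuting ρ across subjects; severity
interaction power 1.0; lead-in null mean ρ = −0.003. The engineered
influence fixture uses exact alternating deviations so the
leave-one-out flag is deterministic.
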