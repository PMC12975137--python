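# Methods

This note documents the models, defaults, numerical conventions and known
limitations of the `wase` package: a simulator, scoring engine, validation
battery and sensor-QC pipeline for the WASe-∞ motor-intent-collapse risk
framework.

## The composite score

The score condenses seven physiological channels into one dimensionless
number,

    WASe-∞ = (α₁E + α₂ΔI + α₃Φ + α₄E_env)
             / ( max(β₁C, 0.1) · max(β₂S, 0.1) )
             · (1 + γT),        capped at 2.0,

with the published weights α = (0.4, 0.3, 0.2, 0.1), β = (0.6, 0.4),
γ = 0.2. Normalization maps physical units to dimensionless factors:
effort E divides by 100 % MVC; timing asymmetry ΔI by a 500 ms full
scale; the force-dissociation ratio Φ passes through unchanged (accepted
on [0, 2]); the environmental composite E_env and the temporal factor T
are already on [0, 1]; cognitive capacity C divides by 100 %; sleep is
hours on a 0–10 h scale (7.0 h → 0.70) after clamping to the
physiological 5–9 h range. The sleep convention follows the framework's
own worked arithmetic (0.70 for 7.0 h) rather than the alternative
`(hours − 5)/4` phrasing of its variable dictionary, which would give
0.50 and break the published example.

Numerical conventions:

* **Floors.** Each denominator *term* is floored at 0.1 (not the product,
  not the raw weights), so the protective product never falls below 0.01
  and the score is defined for every input. On the worked example the two
  readings are indistinguishable; the term-level reading is the one that
  matches the dictionary note `βᵢ = max(βᵢ, 0.1)`. The floor is
  configurable via `CoefficientSet.term_floor`.
* **Bands.** Left-closed, right-open bins on the capped score:
  low [0, 0.5), moderate [0.5, 0.8), high [0.8, 1.2), critical [1.2, 2.0].
  The boundary convention is a design choice; published prose gives the
  band edges without open/closed notation.
* **Cap bookkeeping.** `ScoredSample` retains the pre-cap value and the
  numerator/denominator/multiplier decomposition, so a capped 2.0 remains
  distinguishable from a native 2.0 and every score is auditable.
* **Precision.** All arithmetic is double precision; the worked example
  is compared at 5×10⁻⁴ because its printed intermediates (0.1092, 1.13)
  are themselves rounded.

## The virtual cohort generator

Default design: 60 athletes (15 per sport: running, cycling, swimming,
team), one 60-minute session each, scored on a 6,000-step grid (0.6 s
cadence), master seed 12,345. Athlete *i* consumes only
`default_rng(12345 + i)` with a fixed draw order, so the cohort is
bit-identical across runs and platforms for a given configuration; the
master seed itself is reserved for cohort-level use.

Per-athlete parameters (rejection-sampled within their stated ranges, to
preserve distribution shape rather than clipping):

| parameter | distribution | range | units |
|---|---|---|---|
| baseline effort E₀ | N(65, 15) | [50, 80] | % MVC |
| fatigue rate k | U(0.02, 0.05) | — | s⁻¹ |
| baseline asymmetry ΔI₀ | N(30, 12) | [10, 50] | ms |
| fatigue→asymmetry coupling α | U(0.5, 1.5) | — | ms per % MVC |
| Φ centre | N(0.80, 0.15) | [0.4, 1.2] | — |
| E_env centre | N(0.60, 0.15) | [0, 1] | — |
| sleep S | N(7.2, 0.8) | [5, 9] | h |

Signal models on the step grid (ε = Gaussian step noise with σ of 2 %
MVC, 5 ms, 0.05, 0.03, 3 %, 0.05 respectively):

* E(t) = E₀(1 − e^(−kt)) + ε
* ΔI(t) = ΔI₀ + α·E(t) + β_circ·sin(ωt) + ε, with circadian
  ω = 2π/86400 s⁻¹. The circadian amplitude β_circ has no published
  value; the default is 5 ms, the same order as the ΔI noise
  (configurable). The coupling uses E in percent, matching the ~100 ms
  magnitudes of the worked example.
* Φ(t) = athlete centre + ε, clipped to [0.4, 1.2].
* E_env(t) = athlete composite + ε, clipped to [0, 1]. The composite is
  drawn directly from N(0.60, 0.15); an equal-weighted three-component
  (temperature/humidity/friction) alternative sits behind
  `env_three_component=True`.
* C(t) = 95·e^(−0.001t) + ε, then clipped to [70, 100] %. The printed
  depletion rate drives the bare exponential to ≈2.6 % by the end of an
  hour, far outside the stated 70–100 % operating range; the package
  evaluates the formula and then clamps, with the clamp configurable.
* S constant within a session; T(t) = 0.5 + 0.2·t/t_total + ε, clipped
  to [0, 1].

**Correlation induction.** The step-level innovations of (E, Φ, ΔI, C)
are coupled through a Gaussian copula whose latent correlation matrix
carries the input targets (E–Φ 0.45, E–ΔI 0.35, E–C −0.28). Monotone
marginal transforms preserve the copula, so marginals are untouched.
Structural coupling (ΔI's dependence on E) then acts on top; the pooled
*emergent* correlations are whatever the mechanism produces and are
deliberately never forced.

**Sport modifiers.** How sport enters the generator is not specified
anywhere; the package applies zero-centred multiplicative offsets to the
E₀/ΔI₀/Φ means (running −5 %, cycling −1.5 %, team +1.5 %, swimming
+5 %). Centring preserves the pooled parameter means (so cohort-level
marginal checks remain valid) while keeping the plausible sport ordering
(swimming highest, running lowest). This is an invented calibration,
clearly flagged as such, and is excluded from any headline claim.

**Ground-truth collapse labels.** The latent "collapse" state is not
operationally defined in the source material beyond being independent of
the noisy observed score. The package's construction: each row's label is
Bernoulli with p = logistic((clean_score − 0.8)/τ), where the clean score
is the noise-free twin trace scored by the same engine, 0.8 is the
high-risk boundary and τ (default 0.05) is a softness constant; τ → 0
recovers a hard threshold. Labels depend only on the latent state, never
on the noisy observation, so ROC evaluation is not circular. A
calibration routine (`calibrate_label_softness`) can tune τ against a
target sensitivity; under the default conditions the calibration is
**non-identifiable** (see below) and the default τ is retained.

## A structural property the user must know: saturation at the cap

Under the default operating levels the score saturates. The protective
product is bounded: β₁c ≤ 0.6 and β₂s ≤ 0.4, so the denominator never
exceeds 0.24, and at typical levels (C ≈ 71 %, S ≈ 7.2 h) it is ≈ 0.12.
The numerator at typical levels (E ≈ 65 % MVC, ΔI ≈ 95 ms, Φ ≈ 0.8,
E_env ≈ 0.6) is ≈ 0.54. The ratio therefore sits near 4–6 before the
temporal multiplier, and **every** sample of the default cohort beyond
the first seconds of effort ramp-up caps at 2.0 (observed: pooled mean
1.9994, minimum 1.03, 100 % critical band). Consequently:

* the pooled score distribution under the default conditions is
  degenerate, not graded;
* the noise-free scores all sit far above the 0.8 label threshold, so
  the ground-truth labels are single-class (expected number of negative
  rows over the full 360,000-row cohort at τ = 0.05: ≈ 0.03), and AUC,
  specificity and perturbation-AUC are undefined there;
* the τ calibration target cannot be reached: sensitivity at any cutoff
  below 1.03 is 100 % for every τ.

This is a property of the equation plus the stated operating levels, not
of the implementation: no admissible setting of the genuinely free
pieces (copula targets, sport modifiers, circadian amplitude, E_env
mechanism, τ) can undo it, because the weighted risk sum would have to
fall below ≈ 0.14 while its Φ and E terms alone contribute ≈ 0.42 at the
stated means. A graded distribution with mean ≈ 0.66 would require an
effective protective product near 0.9 — impossible under β₁β₂ = 0.24.
The acceptance checks that target the graded distribution and the
discrimination metrics therefore fail under the faithful defaults, and
the package reports those failures rather than altering the stated
conditions.

For work that needs a graded score (illustration, method tests,
power studies), `SessionConfig.low_intensity()` provides a documented
recovery/technique-session preset (E₀ ≈ 8 % MVC, ΔI₀ ≈ 10 ms, Φ ≈ 0.06,
E_env ≈ 0.15) under which scores span all four bands and both label
classes occur. It is an illustrative regime, not the default study
condition.

## Validation battery

* **AUC** is the tie-corrected Mann–Whitney concordance probability
  (identical to trapezoidal ROC area); the unit suite verifies it against
  brute-force pair counting on datasets up to 1,000 rows. The default CI
  is a seeded stratified bootstrap (2,000 resamples, percentile
  interval); a DeLong asymptotic interval is available via
  `method="delong"`.
* **Operating points** use the convention positive ⟺ score ≥ cutoff
  (ties positive) and Wilson 95 % intervals; metrics with an empty
  denominator are reported not-available (NaN), never 0.
* **Sport comparison** runs on aggregated units — per-athlete
  per-10-minute-block means, 6 blocks × 60 athletes = 360 units under
  the default design — because row-level tests at n = 360,000 are
  meaningless (any difference is "significant") and the aggregated df
  match the framework's published ANOVA table. η² = SS_B/SS_T with a
  noncentral-F inversion CI; ω² alongside; Kruskal–Wallis H with
  ε² = (H − k + 1)/(n − k); Tukey HSD plus Bonferroni-adjusted pairwise
  t-tests (6 comparisons); Shapiro–Wilk, Levene and Breusch–Pagan
  diagnostics computed on the aggregated units.
* **Correlation analysis** reports Pearson r with Fisher-z intervals
  among factors and against the score, plus VIF from the cross-factor
  regressions; constant columns are not-available.

## Coefficient sensitivity

The perturbation Monte Carlo multiplies each of the seven coefficients
(α₁..α₄, β₁, β₂, γ; optionally the α's only) by independent uniform
factors on [1−m, 1+m] per iteration (Gaussian alternative behind a
flag), recomputes every score from the raw factor columns, and records
the AUC against the fixed labels. Floors and the cap are not perturbed;
magnitude 0 reproduces the baseline AUC exactly. The default desk run is
1,000 iterations (the 10,000-iteration setting is a flag; it changes
runtime, not fidelity). The grid search enumerates the ±20 % risk-weight
box (5 levels per axis, 625 combinations by default), maximizing AUC
with a small tie-break penalty for distance from the reference band
profile (20.5/58.2/20.0/1.4 %); α's are not re-normalized to sum to 1,
and ties break toward the lexicographically smallest tuple so the result
is invariant to grid ordering. The sample-size operation uses the
Hanley–McNeil variance approximation with a two-sided α; other published
power conventions exist, so its output is documented as
method-dependent.

## Sensor QC

* **Drift detection:** EWMA chart (λ = 0.2 default, unstated in the
  source; calibration segment = first 60 s) with steady-state 3σ limits,
  OR'd with a baseline-shift rule (rolling 10th-percentile baseline over
  5-minute windows, flagged when it moves > 10 % from its initial
  value). The report records which rule fired; a zero-variance
  calibration segment is flagged degenerate.
* **Drift correction:** corrected(t) = raw(t) − (baseline(t) −
  baseline(0)), baseline re-estimated every 5 min as the window 10th
  percentile with linear interpolation between estimates; exact identity
  whenever the windowed percentile is constant, and a single-window
  session is returned unchanged.
* **Gaps:** classes [0, 5) s → linear interpolation, [5, 30] s → LOCF
  with an uncertainty flag, (30, ∞) s → excluded and the session marked
  incomplete. Leading gaps have no left anchor and are excluded.
* **Plausibility:** inclusive bounds per channel (EMG < 150 % MVC
  implemented as ≤ 150; HR ∈ [40, 220] bpm), failures carry the violated
  bound. SNR gating accepts a provided per-sample metadata field (no
  waveform SNR estimation); the ICC ≥ 0.85 threshold is carried for
  report annotation only — ICC computation and MICE imputation are out
  of scope.
* **Session gate:** exclude iff any channel's missing fraction ≥ 5 % or
  any extended gap occurred; the decision is monotone (adding missing
  data can never rescue a session). Traffic-light status per rule.

## What the generator does and does not emulate

The generator reproduces the *stated* marginal distributions, noise
levels, input cross-correlations and seeds, and is bit-reproducible. It
does not emulate raw high-rate sensor waveforms (the 0.6 s scoring grid
is the modelled object; any 100 Hz raw stream is upstream of scope),
biomechanical forward dynamics, psychological/hormonal covariates, or
real sensor pathologies (those appear only through the QC module's
synthetic fixtures). Passing tests on simulated data demonstrate
internal consistency of the framework and correctness of the
implementation — not real-world predictive validity.

## Problem sizes used by the test and acceptance runs

The acceptance computations use the full default design (360,000 rows;
1,000 perturbation iterations). Unit and property tests use scaled
cohorts (4–16 athletes, 25–600 steps) chosen so the full suite completes
in seconds while still exercising every code path; the statistical
assertions at those sizes use 3-standard-error bands.
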