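# Methods

## Threshold extraction

A recording session is an abdominal-EMG trace together with the commanded
distention protocol: ~a rest epoch, then a linear balloon-volume ramp at
0.3 ml/min capped at 1 ml. Activity is quantified as the integral of the
rectified EMG in fixed 100 ms bins using the rectangular rule (sum of
absolute samples × sample period); a trailing partial bin is discarded,
never extrapolated. The rectangular rule is a declared choice — it matches
the literal "integral of the rectified signal" on sampled data and makes
the brute-force per-bin oracle an exact equality.

The baseline referent of the detection criterion is the **median** bin
integral over the final 60 s of the rest epoch (window configurable). The
median rather than the mean is deliberate: resting abdominal EMG contains
movement-artifact bursts, and a single contaminated bin must not raise the
referent that every subsequent bin is compared against. With the mean
estimator the pipeline reproduces the literal averaging convention.

VMR onset is the first bin at or after inflation onset opening a run of
`sustain_bins` (default 3, i.e. 300 ms) consecutive bins at ≥ `ratio`
(default 2.0, i.e. 200% of baseline). The sustain requirement rejects
single-bin artifacts; `sustain_bins=1` restores the plain first-crossing
rule. The reported threshold is the commanded ramp volume at the *start*
of the onset bin — conservative and reproducible; an onset exactly at
inflation start is reported as one bin-volume with a warning. If no
qualifying run starts while the volume is still below the cap, the session
is right-censored at the cap volume. Censored sessions are excluded from
stage means by default (with counts reported); a cap-substitution policy
is available as a sensitivity analysis. Volumes always come from the
commanded ramp, not a recorded pressure channel: the pump ramp is exact by
construction, and thresholds are reported on the volume scale throughout.

Detection is scale- and sign-invariant in the EMG (the criterion is a
ratio of rectified integrals), monotone in the criterion ratio, and fully
deterministic given a session and options.

## Synthetic cohorts

The generator exists so that the entire pipeline — file I/O, binning,
baseline, detection, statistics — can be exercised on data whose ground
truth is known, with the effect structure of the telemetric
vaginal-distention study it models.

**Latent thresholds.** Each (group, stage, treatment) cell has a mean
threshold: shamENDO rats sit at `reference_threshold` in every stage
(no estrous modulation); the ENDO proestrus mean is
`reference × (1 − 42.4/100)`; other ENDO stage means place proestrus
15/17/19% (DI/DII/E) below them; treatment multiplies the cell mean by
`1 + effect/100` (+81% indomethacin 10 mg/kg i.p., +93.5% s.c., +28%
i.p. vehicle, +40% for 5 mg/kg i.p. — the last is a free parameter, the
study reporting only dose-dependence). Each rat carries a persistent
lognormal multiplier (CV 0.15) and each session an independent lognormal
multiplier (CV 0.08), both mean-one; the product is clipped to
(0, 1 ml]. Multiplicative noise keeps thresholds positive and composes
naturally with percent effects. Treatment effects are applied only to
sessions flagged treated — the study's observation that the drug effect
had washed out days later is modelled as arm membership, not as a
pharmacokinetic decay.

**Threshold scale.** The study reports all of its effects as percentages,
not absolute volumes, so the absolute scale is a free parameter. The
default `reference_threshold` is 0.5 ml: mid-ramp, and far enough below
the 1 ml cap that even the strongest treated cell (ENDO proestrus ×1.935
≈ 0.56 ml) stays >4 SD below it at the default CVs. That matters because
censoring at the cap is not scale-invariant: a reference high enough to
push treated sessions near 1 ml would right-censor a material fraction of
them and bias every percent-recovery estimate downward, a regime the
modelled study never reports (no non-responders appear in it).

**EMG.** Resting EMG is `amplitude × envelope × N(0,1)` with the envelope
`floor + shot noise` (Poisson impulses at 60 s⁻¹, height 0.4, exponential
decay τ = 30 ms), initialised at its stationary mean. The envelope gives
burst-like, non-Gaussian texture while keeping the expected rectified bin
integral in closed form (`amplitude × E[env] × √(2/π) × bin width`),
which the tests verify by Monte Carlo. Parameters were chosen so that a
gain-free ramp essentially never triggers the 200%/300 ms criterion
(<10⁻³ per session, checked on null simulations): the study's thresholds
were stable within rat, so spurious detections are a generator defect,
not realism. Once the ramp volume crosses the session's latent threshold
the amplitude rises to `vmr_gain` × baseline within half a bin and stays
there. The default gain is 6×: a 100 ms rectified-integral bin carries
~20–25% relative noise at practical sampling rates, so a gain of ~3 would
leave individual response bins dipping below the 2× criterion often
enough to delay the sustained run past one bin-volume; 6× keeps
noise-free-cohort recovery within one bin-volume (0.0005 ml at 0.3 ml/min
and 100 ms bins) with margin, while remaining a modest reflexive response.

**Seeding.** Random streams are split hierarchically with
`np.random.SeedSequence(seed, spawn_key=(rat, session))`: the same seed
reproduces byte-identical trace files, and enlarging a cohort never
perturbs existing rats' draws.

**What the generator does not emulate.** Balloon pressure–volume
mechanics, hormone dynamics, electrode drift, heartbeat or respiration
artifacts, pharmacokinetics, and any within-session nonstationarity of
baseline EMG. Passing recovery tests therefore show that the *analysis*
is correct and unbiased under the stated noise model — not that the model
captures every failure mode of real telemetry.

## Statistics

Sessions are averaged per rat within stage first; the rat is the unit of
analysis everywhere. The stage comparison defaults to a one-way ANOVA on
per-rat stage means with a Tukey HSD table, matching the averaging
convention; a repeated-measures flavour (rat as subject, closed-form
two-way F without replication, cross-checked against
`statsmodels.AnovaRM`) is available and is the calibrated choice under
the generator's shared rat effect: with a persistent rat multiplier the
one-way test's within-stage variance is inflated relative to the
between-stage signal, making it conservative (type-I rate below nominal),
while the repeated-measures test rejects at the nominal 5% — both
behaviours are asserted over 1000 simulated null cohorts.

Treatment arms dispatch on arity: exactly one comparison uses a paired
t-test; two or more non-control arms use a one-way ANOVA followed by
Dunnett many-to-one comparisons against the control
(`scipy.stats.dunnett`, checked against R `multcomp::glht` on a frozen
fixture). Identical paired arms report t = 0, p = 1 rather than the 0/0
NaN. Drug effects are summarised as per-rat percent changes
`100 × (post − pre)/pre` against the rat's own untreated proestrus
baseline mean, aggregated as mean ± SEM (SD/√n) — the study's ± values
are assumed to be SEMs. No multiplicity correction is applied beyond
Tukey/Dunnett.

## Recovery experiments and problem sizes

`vmrpipe.experiments` simulates cohorts of 200 rats per group (4 baseline
sessions per stage, plus one treated proestrus session per arm), runs the
full pipeline on every trace, and recovers the configured percentages.
Four baselines — the upper end of the study's two-to-four — are used
because the paired percent-change estimator carries a small Jensen bias
from its noisy per-rat denominator (~+0.6 points on an 81% effect with
two baselines, ~+0.3 with four). Recovery cohorts run at 200 Hz sampling
with a 90 s rest epoch and a 10 s post-ramp tail: the detected threshold
depends only on ramp timing and the activity ratio, so acquisition rate
and rest-epoch length are pure cost knobs (the generator's default rate
is 500 Hz). At these sizes a five-experiment recovery run completes in
roughly half a minute on one CPU.

With 200 rats per group the sampling SEM of a recovered treatment effect
is ~1.2 percentage points and of the group gap ~0.9, so recovered values
normally land within ±2 points of the configured 42.4/15–19/81/93.5/28.

## Known limitations

- Censored thresholds are excluded or cap-substituted, never modelled;
  survival-style estimation is out of scope.
- The detection criterion presumes a positive baseline; genuinely silent
  traces raise an error rather than a threshold.
- Session files are plain CSV at 6 significant digits; native telemetry
  formats are not read.
- The 5 mg/kg i.p. effect size and the absolute threshold scale are
  free parameters; conclusions about them are conditional on the chosen
  defaults.
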