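# Methods

This note documents the models, conventions and numerical choices behind
`puretone`, and what the simulated results do and do not say about real
listeners.

## Threshold engines

### 2-down-1-up staircase

The index engine is a transformed up-down staircase: presentation starts
at 60 dB HL; after 2 consecutive hits the level drops 10 dB, after each
miss it rises 5 dB. The asymmetric step regime applies from the first
trial (there is no separate initial-descent phase with its own step
size). The consecutive-hit counter resets on any miss and after each
down-step. Tracking stops at the 5th reversal and the threshold is the
arithmetic mean of the final 3 reversal levels, reported unrounded — the
mean of reversal levels generally falls off the 5-dB grid, and rounding
would mask sub-dB biases in the agreement statistics.

*Reversal bookkeeping.* A reversal is recorded when a level-change
decision has the opposite sign to the previous level-change decision, and
the reversal level is the level of the trial that triggered the change
(standard Levitt convention). Hand-tracing an ideal listener with a
40 dB threshold gives reversals 30, 40, 30, 40, 30 and a threshold of
33.33 dB in 15 trials — the test suite pins this trace and checks it
against an independent decision-list oracle.

*Convergence bias.* A 2-down-1-up rule targets the ~70.7% point of the
psychometric function, and the 10-down/5-up asymmetry with
last-3-reversal averaging pulls the estimate a further few dB down (the
33.33-vs-40 trace above is the clean illustration). This is a documented
property of the procedure as specified, not corrected for.

*False positives.* Each presentation has a 0–3 s randomized onset delay;
a tap in the pre-onset window is a false positive. The trial is logged
and repeated at the same level without advancing the staircase state, so
false positives inflate the FP count and the trial count but not the
threshold. Whether a real implementation lets spurious taps advance the
track is unknowable from published descriptions; the FP-robust choice
keeps the estimator unbiased under high tap rates.

*Bounds and non-convergence.* Levels are clamped to [−10, 100] dB HL (a
typical air-conduction audiometer range). Two consecutive level-change
decisions clamped at a bound flag the run "pinned": not converged, with
the bound as provisional threshold. A cap of 80 trials per frequency is a
safety net; non-converged runs are recorded, never raised, and excluded
pairwise from statistics downstream.

### Modified Hughson-Westlake

The reference engine descends 10 dB after every response until the first
miss, then ascends in 5 dB steps until a response; each ascending-phase
presentation counts as an ascent at its level, a response there is one
confirmation, and after a confirmation the level drops 10 dB and
re-ascends. The threshold is the lowest level accumulating 2
confirmations within its first 3 ascents (BSA-style dialect; published
procedure descriptions leave the dialect underspecified, so the
recommended clinical variant is implemented). For an ideal listener the
result is exactly the smallest 5-dB grid level at or above the true
threshold — the suite checks this closed form and the published
9-presentation trace for a 40 dB listener.

### Session gates

Conditioning presents a suprathreshold 60 dB HL tone at 1000 Hz for up to
3 attempts; a pre-onset tap repeats the presentation (capped at 5 per
attempt) without consuming an attempt, mirroring the engines' FP policy.
Failure excludes the ear. The ambient gate requires noise strictly below
40 dB.

## Listener model

Detection is Bernoulli with probability
`(1 − λ) · Φ((L − θ)/σ)`: θ the effective threshold of the tested ear, σ
the psychometric spread, λ the lapse rate. σ = 0 gives the ideal
step-function listener used wherever a hand-traceable oracle is wanted.
Independently of detection, each presentation is a false positive with
probability `fp_rate`. Defaults: σ = 4 dB and λ = 0.02 (a compliant adult
in a quiet room); `fp_rate` 0.05 for the hand-responder reference session
and 0.10 for the tap-to-respond staircase session, echoing the higher
spurious-tap counts tap interfaces elicit. All are tunable per run.

An ear is a per-frequency map of true thresholds plus a plug flag and an
attenuation profile; plugging is exactly additive per frequency. The
default cohort is 30 adults with no history of hearing impairment: true
thresholds drawn i.i.d. per ear and frequency from Normal(5, 5) dB HL
truncated (by rejection) to [−10, 20]. The left ear wears a foam plug
with attenuation {250: 25, 500: 28, 1000: 30, 2000: 33, 4000: 38,
8000: 40} dB — rising with frequency as foam plugs do, and everywhere
above the 20 dB screening criterion so that plugged ears are unambiguous
positives. These are synthetic, configurable values. Plug-seal drift
within a session is not modeled by default; an optional per-session
Gaussian jitter on the attenuation (`attenuation_jitter_sd`) is provided.
Interaural crossover and masking are not modeled.

## Study protocol

Per ear: conditioning gate, then the reference engine at all six
frequencies and the staircase at all six (order 2000, 4000, 8000, 1000,
500, 250 Hz), with reference-first vs index-first randomized per
participant; the staircase retest (2000, 4000, 8000, 500 Hz) follows the
index test immediately, same listener parameters, fresh random draws. A
30-participant run yields 360 reference/index threshold pairs and
58 retest ears per frequency when one participant skips the retest.
Ear-level screening truth/prediction uses the >20 dB criterion (strictly
greater) at 250, 1000, 2000 and 4000 Hz under an any-frequency rule — the
combination rule consistent with perfect reported sensitivity; the
criterion and frequency set are configurable.

## Statistics

* **Bland–Altman**: differences b − a; bias ± 1.96·s limits of agreement;
  bias CI `t_{n−1} · s/√n`; LoA CI `t_{n−1} · s·√(3/n)` (the classical
  approximation). The symmetry identity `lloa + uloa = 2·bias` holds to
  1e−9 by construction. Degenerate samples (all differences equal) give
  zero-width CIs.
* **ICC**: ICC(A,1) (absolute agreement) and ICC(C,1) (consistency) from
  two-way ANOVA mean squares; F-based CIs, Satterthwaite df for the
  agreement form. When the Satterthwaite df collapses toward zero (a
  strongly negative ICC in a tiny sample) the CI bound uses the analytic
  f → ∞ limit of the interval formula, and bounds are clipped to contain
  the point estimate within [−1, 1]. A zero-variance matrix is flagged
  degenerate with ICC defined as 1. ICC(A,1) is the headline value;
  qualitative bands: moderate ≥ 0.50, good ≥ 0.75, excellent ≥ 0.90.
* **Proportions**: exact Clopper–Pearson (beta-quantile) intervals —
  chosen because Wilson intervals do not reproduce the published
  screening CIs, and the exact interval does (19/20 → 75.13–99.87, kept
  as a regression test). Tolerance comparison is inclusive
  (|diff| ≤ 10 dB).
* **t test**: pooled Student by default, Welch by flag; zero-pooled-
  variance inputs are flagged degenerate. p-values render as 3 dp with a
  "<.001" floor.

## What the simulation shows — and does not

With the default psychometrics the simulated study reproduces the
qualitative pattern of plugged-ear validation studies: good-to-excellent
ICCs at every frequency, all plugged ears screened positive, specificity
below 100% more often than not, and several-fold more false-positive taps
in the staircase session (t test p < .001). Two quantitative differences
from field data are structural and worth understanding:

1. **Sign of the bias.** The simulated staircase reads a few dB *below*
   the reference (downward staircase bias vs upward grid quantization).
   Real devices can show the opposite sign when transducer output or
   SPL→HL calibration dominates; this package deliberately models no
   calibration error.
2. **Marginal ears.** Open ears with true thresholds near 20 dB are
   sometimes pushed over the criterion by reference-measurement noise
   while the downward-biased staircase stays below it. Across 100
   replicate studies this caps the fraction of replicates with perfect
   sensitivity near two-thirds rather than ~1. A real index test with a
   positive bias is protected from exactly this failure mode, which is
   why perfect sensitivity is easier to observe in the field than in a
   faithfully unbiased-by-construction simulation.

Simulated limits of agreement are also tighter than field values — human
threshold variability includes attention drift, plug-seal changes and
calibration error that the default listener does not carry.

## Problem sizes

The default study is 30 participants (60 ears), ~950 engine runs and
~25k simulated presentations, and completes in well under a second; the
replicate experiment in the acceptance suite runs 100 such studies. The
acceptance script runs one full study plus a 29-participant retest-count
check and the two ideal-listener traces, all seeded from `--seed`.
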