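# puretone

Simulation and statistics toolkit for validating automated pure-tone
audiometry. The package re-creates, end to end and in silico, a
plugged-ear validation study of a self-administered hearing test: two
automated air-conduction threshold engines, a psychometric model of the
listeners, the study protocol that pairs their measurements, and the
agreement / diagnostic-accuracy battery used to judge the result.

It is aimed at people building or evaluating automated audiometry —
hearing-screening developers, audiology methods researchers — who need a
reproducible harness to ask: *if a tap-to-respond adaptive test with these
parameters were run against a clinical reference procedure on a cohort
like this, what agreement and screening accuracy should we expect?*

## What is inside

**Threshold engines** (`puretone.engines`)

* `run_staircase` — a transformed adaptive staircase: start 60 dB HL,
  10 dB down after 2 consecutive hits, 5 dB up after each miss
  (2-down-1-up), stop after 5 reversals; the threshold is the mean of the
  final 3 reversal levels. Tone onset is randomized 0–3 s; a tap before
  onset is logged as a false positive and the presentation repeats without
  moving the track.
* `run_hughson_westlake` — the modified Hughson-Westlake reference:
  descend 10 dB per response, ascend in 5 dB steps after a miss; the
  threshold is the lowest level confirmed on 2 of up to 3 ascents.
* Conditioning (suprathreshold 1000 Hz tone, 3 attempts) and ambient-noise
  (< 40 dB) gates.

**Listener model** (`puretone.listeners`) — detection probability
`(1 − λ)·Φ((L − θ)/σ)` with lapse rate λ, slope σ, per-trial
false-positive rate, and a foam-earplug attenuation profile that converts
one ear of each simulated adult into a conductive-loss ear.

**Study harness** (`puretone.harness`) — 30 participants × 2 ears tested
by both engines at 250–8000 Hz (order 2000, 4000, 8000, 1000, 500,
250 Hz), immediate staircase retest at 2000/4000/8000/500 Hz, randomized
test order, non-convergence flagging, CSV round trip.

**Statistics** (`puretone.stats`) — Bland–Altman bias and 95% limits of
agreement with t-based CIs (LoA SE `s·√(3/n)`), two-way single-measure
ICCs — ICC(A,1) and ICC(C,1) — with F-based CIs, bias-vs-mean Pearson r,
the fraction of pairs within 10 dB, exact (Clopper–Pearson)
sensitivity/specificity for the >20 dB screening criterion at 250, 1000,
2000 and 4000 Hz (an ear is positive if *any* screening frequency
exceeds the criterion), and a Student t test on false-positive counts.

**Reporting and CLI** (`puretone.reporting`, `puretone.cli`) — YAML/JSON
run configuration, deterministic CSV/markdown report tables, and a thin
`puretone` command (`threshold`, `simulate-study`, `stats`, `report`).

## Worked example

```bash
python examples/simulate_study.py
```

prints (abridged):

```
threshold pairs analysed: 360

per-frequency agreement (staircase vs reference):
    250 Hz  bias  -5.14 dB  LoA [-12.73,  2.45]  ICC(A,1) 0.89 (good)
    ...
   8000 Hz  bias  -4.58 dB  LoA [-12.87,  3.70]  ICC(A,1) 0.95 (excellent)

mean LLoA -12.60 dB (SD 1.17); mean ULoA 4.34 dB (SD 1.50)
within 10 dB of reference: 343/360 (95%)

screening (>20 dB at 250/1000/2000/4000 Hz, any-frequency rule):
  sensitivity 96.77% (95% CI 83.30-99.92)
  specificity 96.55% (95% CI 82.24-99.91)

false positives per session: reference 8.40 vs staircase 23.37 (t test p <.001)
```

The negative bias is a real property of the staircase as specified: a
10-down/5-up 2-down-1-up track averaged over its last three reversals
converges below the 50% point, while the ascending reference quantizes
*upward* to the 5-dB grid. The ICCs still grade good-to-excellent, plugged
ears (≥ 25 dB simulated conductive loss) are flagged reliably, and the
tap-to-respond staircase produces several-fold more false-positive taps —
the qualitative signature such validation studies report.

Other examples: `examples/threshold_trace.py` (trial-by-trial engine
traces), `examples/psychometric_listener.py` (estimate spread for a noisy
listener), `examples/agreement_from_csv.py` (CSV workflow and report
tables).

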