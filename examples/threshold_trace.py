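"""Trace both threshold engines on an ideal (step-function) listener.

Runs the 2-down-1-up staircase and the modified Hughson-Westlake procedure
against a listener who hears a tone exactly when its level reaches 40 dB HL,
and prints every presentation so the two decision rules can be compared.
"""

from puretone import DeterministicListener, run_hughson_westlake, run_staircase

listener = DeterministicListener(40)

for name, runner in (("staircase", run_staircase), ("hughson-westlake", run_hughson_westlake)):
    result = runner(listener, 1000, rng=0)
    print(f"== {name} ==")
    for i, trial in enumerate(result.trials, 1):
        mark = "hit " if trial.responded else "miss"
        print(f"  trial {i:2d}: {trial.stimulus.level:5.1f} dB HL  {mark}")
    if result.reversal_levels:
        print("  reversal levels:", result.reversal_levels)
    print(f"  threshold: {result.threshold:.2f} dB HL ({result.n_trials} trials)\n")

# The staircase lands at 33.33 dB (mean of the final three reversal levels
# 30/40/30): the asymmetric 10-down/5-up track tends to sit below the true
# threshold. The ascending procedure returns 40 dB, the smallest 5-dB grid
# level the listener can confirm twice, and needs fewer presentations.
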