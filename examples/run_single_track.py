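"""Run one adaptive threshold track against a simulated listener.

A two-down/one-up staircase adapts the SNR of 3AFC word trials; the speech
recognition threshold (SRT) is the mean of the last six of eight reversal
levels, which converges on the 70.7%-correct point of the listener's
psychometric function.
"""

import numpy as np

from bildsim import (
    Condition,
    ListenerProfile,
    default_masked_config,
    run_adaptive_track,
    true_srt,
)

listener = ListenerProfile(
    age_years=9.5,
    group="child",
    mu_m0t0=-9.0,
    bild_true=6.0,
    mu_quiet=-34.0,
)
rng = np.random.default_rng(0)

for cond in (Condition.M0T0, Condition.M0TPI):
    run = run_adaptive_track(listener, cond, default_masked_config(), rng)
    print(f"{cond.value}: {len(run.trials)} trials, "
          f"reversals at {[f'{r:+.0f}' for r in run.reversal_levels]}")
    print(f"  SRT = {run.srt:+.2f} dB SNR "
          f"(convergence point {true_srt(listener, cond):+.2f} dB)")

bild = true_srt(listener, Condition.M0T0) - true_srt(listener, Condition.M0TPI)
print(f"listener's true BILD (antiphasic advantage): {bild:.1f} dB")
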