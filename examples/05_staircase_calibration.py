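"""Psychophysical calibration with a one-up, one-down staircase.

Simulates an observer whose detection probability is a logistic
function of stimulus level and runs the adaptive staircase used to set
stimulus intensity before a detection experiment: level down after a
detection, up after a miss, stopping after five reversals. The rule
converges to the 50% point of the psychometric function.
"""

import numpy as np

from plsp import ObserverModel, simulate_staircase

observer = ObserverModel(threshold=0.5, slope=10.0)

# short calibration run, as used before an experiment
short = simulate_staircase(observer, start_level=0.8, step=0.05,
                           max_reversals=5, seed=3)
print(f"five-reversal staircase: {len(short.levels)} trials, "
      f"converged level {short.converged_level:.3f} "
      f"(true 50% point: {observer.threshold})")

# long run with termination disabled: the equilibrium check
long = simulate_staircase(observer, start_level=0.8, step=0.05,
                          max_reversals=None, seed=3, max_trials=2000)
level = float(np.mean(long.reversal_levels[10:]))
rng = np.random.default_rng(4)
rate = np.mean(rng.random(100_000) < observer.p_detect(level))
print(f"2000-trial run: convergence level {level:.3f}, "
      f"empirical detection rate there {100 * rate:.1f}% (expected ~50%)")
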