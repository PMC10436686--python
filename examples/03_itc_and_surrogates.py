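"""Intertrial phase coherence against a cut-and-swap surrogate null.

Builds a set of trials whose alpha phase is aligned to a simulated
event, computes the cosine-similarity intertrial phase coherence
(ITC_CS) over time, and contrasts it with the chance level from
cut-and-swap surrogates (each trial circularly rotated at a random
cut, destroying event alignment while preserving phase dynamics).
"""

import numpy as np

from plsp import itc_cs_timecourse, phases_from_trials, surrogate_itc_null

fs = 1000.0
n_trials, n_samp = 15, 800
rng = np.random.default_rng(0)
t = np.arange(n_samp) / fs

# alpha oscillation phase-aligned at t = 0 plus trial-unique noise
trials = np.vstack([
    np.cos(2 * np.pi * 10.0 * t) + 0.8 * rng.standard_normal(n_samp)
    for _ in range(n_trials)
])

angles = phases_from_trials(trials, band=(8.0, 12.0), fs=fs)
itc = itc_cs_timecourse(angles)
null = surrogate_itc_null(trials, band=(8.0, 12.0), fs=fs, n_rep=500, seed=1)

mid = slice(200, 600)
print(f"ITC_CS over the interior: mean {itc[mid].mean():.3f} "
      f"(range {itc[mid].min():.3f} .. {itc[mid].max():.3f})")
print(f"surrogate chance level:   mean {null.chance[mid].mean():.3f} "
      f"(range {null.chance[mid].min():.3f} .. {null.chance[mid].max():.3f})")
print("ITC_CS is the mean cosine of all pairwise phase differences across")
print("trials: 1 = identical phases in every trial, 0 = uniform spread.")
print("Aligned trials stay far above the rotation null, which hovers near 0.")
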