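"""Validate the spike/burst detector on surrogates with known ground truth.

Builds noisy synthetic burst trains (Gaussian spike bumps on a baseline,
optionally with pseudo-plateau morphology) and checks that the default
detector recovers the construction exactly.
"""
import numpy as np

import cscburst as cb

for pattern, plateau in [((5, 3, 5, 3), False), ((4, 4, 4), True)]:
    spec = cb.SurrogateSpec(spikes_per_burst=pattern, plateau=plateau,
                            noise_sd=2.0, seed=42)
    trace = cb.generate_surrogate_trace(spec)
    detected = cb.detect_spikes(trace.times, trace.V)
    bursts = cb.segment_bursts(detected)
    tp = sum(1 for ts in trace.spike_times
             if np.min(np.abs(detected - ts)) <= 1.0)
    f1 = 2 * tp / (len(trace.spike_times) + len(detected))
    print(f"pattern {pattern} (plateau={plateau}, noise 2 mV): "
          f"recovered {[len(b) for b in bursts]}, F1 = {f1:.2f}")

# F1 = 1.0 means every constructed spike was found at its construction
# time and nothing spurious was added, even at 2 mV measurement noise.
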