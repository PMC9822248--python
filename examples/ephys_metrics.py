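"""Per-cell electrophysiology metrics from simulated voltage-clamp sweeps.

Builds one trace per protocol — a paired pulse, a 10-s hypertonic-sucrose
response, and a 100-s miniature-event recording — and computes the
corresponding metric, comparing each against the generator's ground truth.
"""

import numpy as np

from synapkit import detect_minis, paired_pulse_ratio, sucrose_charge
from synapkit.synthetic import simulate_minis, simulate_sucrose_step, simulate_trace

# paired-pulse ratio from four noisy sweeps, averaged sample-wise
sweeps = [simulate_trace("evoked_pair", a1=100.0, a2=150.0, interval_ms=50.0,
                         noise_sd=5.0, seed=s)[0] for s in range(4)]
ppr = paired_pulse_ratio(sweeps, interval_ms=50.0)
print(f"paired-pulse ratio (true 1.50):   {ppr:.3f}")

# readily releasable pool: charge in the first 10 s of the sucrose response
trace, truth = simulate_sucrose_step(plateau_pa=100.0, plateau_s=10.0,
                                     noise_sd=2.0, seed=1)
charge = sucrose_charge(trace, window=10.0)
print(f"sucrose charge (true {truth.charge:.0f} pC):   {charge:.1f} pC")

# miniature events: template search over a 100-s window
times = tuple(np.linspace(5.0, 95.0, 10))
mini_trace, mini_truth = simulate_minis(event_times=times, amplitude_pa=30.0,
                                        noise_sd=3.75, seed=2)
res = detect_minis(mini_trace)
print(f"mini frequency (true 0.100 Hz):   {res.frequency:.3f} Hz")
print(f"mean mini amplitude (true 30 pA): {res.mean_amplitude:.1f} pA")
# frequency = events per second over the window; amplitudes are the fitted
# template scales, robust to baseline noise.
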