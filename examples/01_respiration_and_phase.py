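"""Generate a synthetic respiration trace and extract its phase.

Builds five minutes of quasi-periodic breathing (4-s cycles with 0.5-s
jitter), computes the instantaneous phase via the Hilbert transform and
detects inhalation peaks. Phase zero marks peak inhalation, so the
phase at detected events should be near zero.
"""

import numpy as np

from breathmod import coupling, synth

trace = synth.gen_respiration(
    duration_s=300.0, rate_hz=300.0, period_mean_s=4.0,
    period_jitter_s=0.5, seed=1,
)
phase = coupling.extract_phase(trace)
events = coupling.detect_inhalation_peaks(phase)

intervals = np.diff(events) / trace.rate_hz
print(f"breaths detected:        {events.size}")
print(f"mean cycle length:       {intervals.mean():.2f} s (target 4.0 s)")
print(f"cycle length SD:         {intervals.std():.2f} s (jitter 0.5 s)")
print(f"|phase| at inhalation:   {np.abs(phase.phase_rad[events]).max():.3f} rad")
# ~75 breaths in 5 min; phase at events close to 0 confirms the
# convention that zero phase = peak inhalation.
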