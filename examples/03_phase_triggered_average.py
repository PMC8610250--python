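"""Phase-triggered average: envelope dynamics locked to inhalation.

Averages the 36-frequency amplitude envelope in +/-1000-sample windows
centred on every peak-inhalation event and z-scores each frequency row,
yielding the 36 x 2000 matrix of oscillatory power across the
respiratory cycle. With a planted preferred phase of 0 the carrier
row's maximum falls at the window centre.
"""

import numpy as np

from breathmod import coupling, spectral, synth

grid = spectral.frequency_grid()
trace = synth.gen_respiration(300.0, 300.0, 4.0, 0.5, seed=4)
phase = coupling.extract_phase(trace)
x = synth.gen_coupled_signal(phase.phase_rad, 10.0, 1.0, 0.0,
                             snr=np.inf, seed=5)

env = spectral.amplitude_envelope(
    spectral.morlet_cwt(x, 300.0, grid), 300.0, grid
).values[0]
events = coupling.detect_inhalation_peaks(phase)
pta = coupling.phase_triggered_average(env, events, halfwin=1000)

row = np.flatnonzero(grid.freqs_hz == 10.0)[0]
peak_s = (np.argmax(pta.values[row]) - 1000) / 300.0
print(f"PTA matrix: {pta.values.shape[0]} frequencies x "
      f"{pta.values.shape[1]} samples")
print(f"events used: {pta.n_events} (dropped near edges: "
      f"{pta.n_dropped_events})")
print(f"10-Hz power peaks {peak_s:+.2f} s from peak inhalation")
# A peak offset near 0 s shows the envelope is maximal at inhalation,
# as planted.
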