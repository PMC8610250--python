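"""Group-level inference on MI spectra with cluster permutation.

Simulates 15 subjects' normalised MI spectra over the 36-frequency
grid, plants an effect in frequencies 10-15, and tests against each
subject's surrogate reference spectrum. Adjacent suprathreshold
frequencies form clusters whose summed t statistic is compared with a
permutation null of maximum cluster statistics, controlling the
family-wise error across the spectrum.
"""

import numpy as np

from breathmod import inference, spectral

rng = np.random.default_rng(6)
grid = spectral.frequency_grid()

observed = rng.standard_normal((15, 36))
reference = rng.standard_normal((15, 36))  # surrogate 95th percentiles
observed[:, 10:16] += 2.5  # planted band of genuine modulation

result = inference.cluster_permutation_test(
    observed, reference, n_perm=5000, thresh_p=0.05, alpha=0.05, seed=7
)
for c in result.clusters:
    lo, hi = grid.freqs_hz[c.freq_lo_idx], grid.freqs_hz[c.freq_hi_idx]
    flag = "significant" if c.p_value < result.alpha else "n.s."
    print(f"cluster {lo:5.0f}-{hi:5.0f} Hz  sum t = {c.sum_t:7.2f}  "
          f"p = {c.p_value:.4f}  ({flag})")
# The planted 25-70 Hz cluster comes out significant; chance clusters
# elsewhere do not survive the family-wise correction.
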