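"""Mixed model of band modulation against distance to head centre.

Simulates per-subject, per-component band MI values whose expectation
grows with the component's Euclidean distance r to the head centre
(fixed slope 0.5) plus subject-specific random slopes, then fits
MI = b0 + (b1 + S_1j) * r + e by maximum likelihood and reports the
slope t-test.
"""

import numpy as np

from breathmod import inference

rng = np.random.default_rng(10)
n_subj, n_comp = 28, 18
coords = rng.uniform(-70, 70, size=(n_comp, 3))  # component MNI (mm)
r = inference.head_centre_distance(coords) / 100.0  # decimetres

subject_slopes = 0.5 + 0.1 * rng.standard_normal(n_subj)
y = (1.0 + subject_slopes[:, None] * r[None, :]
     + 0.1 * rng.standard_normal((n_subj, n_comp))).ravel()

fit = inference.fit_distance_lmem(
    y, np.tile(r, n_subj), np.repeat(np.arange(n_subj), n_comp)
)
print(f"fixed slope estimate: {fit.beta1:.3f} (planted 0.5)")
print(f"slope test: t({fit.dof}) = {fit.t_value:.2f}, p = {fit.p_value:.2g}")
print(f"random slope variance: {fit.random_slope_var:.4f} (planted 0.01)")
# A slope estimate near 0.5 with a large t confirms that more distal
# components carry systematically stronger modulation in this world.
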