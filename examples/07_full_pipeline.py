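"""End-to-end pipeline on a small planted-coupling dataset.

Two subjects, six entities, a 10-Hz coupling planted on entities 0-2:
simulate -> envelopes -> MI maps -> PTA -> cluster test -> sparse NMF
-> profiles -> mixed model, all from one seeded configuration. Takes
about half a minute.
"""

import numpy as np

from breathmod import RunConfig, run_pipeline, synth

config = RunConfig(
    seed=11,
    n_subjects=2,
    n_entities=6,
    duration_s=120.0,
    couplings=[synth.Coupling(10.0, 1.0, 0.0, (0, 1, 2))],
    n_surrogates=50,
    n_perm=500,
    nmf_k=2,
    n_restarts=3,
    nmf_max_iter=60,
    percentile=50.0,
)
result = run_pipeline(config)

mi = np.mean([r.mi_norm for r in result.mi_results], axis=0)
print(f"normalised MI map: {mi.shape[0]} entities x {mi.shape[1]} freqs")
print(f"strongest cell: entity {np.unravel_index(np.argmax(mi), mi.shape)[0]}"
      f", max normalised MI = {mi.max():.1f}")
print(f"PTA: {result.pta.values.shape}, events {result.pta.n_events}")
comp = np.argmax(result.nmf.coefficients[:, :3].sum(axis=1))
top = np.argsort(result.nmf.coefficients[comp])[-3:]
print(f"NMF component {comp} top entities: {sorted(top.tolist())} "
      f"(planted: [0, 1, 2])")
print(f"config hash: {result.manifest['config_hash']}")
# Rerunning with the same config reproduces identical outputs; the
# manifest records every parameter, seed and stage wall time.
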