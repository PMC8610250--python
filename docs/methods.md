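# Methods

This note documents the models and procedures `breathmod` implements,
the defaults it ships with, and the numerical decisions taken where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The coupling model

The quantity of interest is phase–amplitude coupling between
respiration (~0.25 Hz) and faster neural oscillations: the respiration
phase φ(t) modulates the amplitude envelope of a carrier oscillation.
The synthetic generator states this world explicitly:

    signal(t) = [1 + d·cos(φ(t) − φ₀)] · cos(2π f_c t + ψ) + ε(t)/snr,

with modulation depth d ∈ [0, 1], preferred phase φ₀ (envelope maximal
where φ = φ₀), carrier f_c, random carrier phase ψ, and 1/f^α noise ε
scaled so the carrier-RMS-to-noise-RMS ratio equals `snr`.

Defaults follow the recording conditions the analysis is designed for:
300-Hz sampling, 4-s mean breath period with 0.5-s cycle jitter
(~0.25 Hz breathing), 5-minute runs, α = 1 broadband background,
snr = 1. Subject-level variability multiplies each subject's modulation
depth and mean breath period by N(1, 0.1) factors — enough to make
group statistics meaningful without changing the planted structure.

Respiration is synthesised as concatenated raised-cosine cycles whose
periods are drawn from a truncated normal (floor 1 s), low-pass
smoothed at 1 Hz (zero-phase). This guarantees exactly one well-defined
inhalation peak per cycle, which the peak detector and the
phase-triggered average rely on.

What the generator does **not** emulate: realistic sensor geometry or
noise covariance, cardiac/muscle artifacts, head movement coupled to
respiration, non-sinusoidal breath shapes (fast inhale / slow exhale),
and non-stationary coupling. A green planted-recovery test therefore
establishes correctness of the estimators under the stated model, not
robustness to every physiological confound.

## Spectral decomposition

The analytic Morlet wavelet is defined in the frequency domain as
Ψ(ω) = π^(−1/4) exp(−(ω − ω₀)²/2) H(ω), with H the Heaviside step; the
transform is computed by FFT multiplication with the dilated Ψ, scale
a = ω₀/(2π f/rate) per analysis frequency f. The centre parameter
defaults to ω₀ = 6 rad (the common choice; exposed as `omega0`).
Amplitude normalisation is L1-like: a unit sinusoid at a row's centre
frequency yields unit envelope in that row, independent of frequency.

Consequence of ω₀ = 6 worth knowing: the Gaussian passband SD is f/6,
so at 10 Hz (~1.7 Hz) it exceeds the 2-Hz grid spacing — adjacent rows
of the envelope tensor carry nearly identical modulation. Because the
modulation index is scale-invariant, single-bin frequency attribution
is ill-posed to within one grid step; tests and the recovery criteria
assert carrier frequencies to that resolution.

Envelopes are smoothed with a centred moving average of
round(300 ms · rate) samples, shrinking symmetrically at the edges
(constant rows stay constant, no padding artifacts). Envelope samples
within one wavelet e-folding time of an edge are used by the MI (no
exclusion is applied) while the PTA drops events whose ±1,000-sample
window is incomplete, reporting the dropped count.

Frequency bands: delta [2, 4), theta [4, 8), alpha [8, 12), beta
[12, 30), low gamma [30, 70), high gamma [70, 150] Hz. Shared
boundaries belong to the upper band (half-open intervals); the global
top edge is inclusive so the 36-point grid is exactly partitioned.

## Modulation index and surrogates

MI = (ln N − H(p))/ln N over N = 20 equal-width phase bins on [−π, π),
with natural-log Shannon entropy and 0·ln 0 := 0. MI is invariant to
amplitude rescaling and to phase rotations by whole bin widths; an
empty bin raises an error (it signals a recording much shorter than the
5-minute design length) rather than silently imputing.

Surrogates circularly shift the phase series by uniform random offsets
restricted to [0.1 T, 0.9 T] samples. The restriction avoids
near-identity shifts that would deflate the surrogate variance; with
jittered breathing ~200 such shifts give a well-calibrated null (the
test suite verifies normalised MI ≈ N(0, 1) under independence,
KS < 0.1 at n = 1,000). Note that for *perfectly periodic* respiration
circular shifts do not destroy coupling — cycle jitter is what makes
the surrogate null informative, which is why the generator defaults to
0.5-s jitter.

Per-cell seeds in `mi_map` derive from (master seed, entity index,
frequency index), so maps are reproducible and independent of iteration
order.

## Inhalation peaks

Peak inhalation corresponds to phase 0. Finding local maxima of a phase
series wrapped to [−π, π) would lock onto the +π → −π wrap — half a
cycle away from the inhalation peak. The detector therefore rewraps the
phase to [0, 2π), placing the sawtooth discontinuity at the peak
itself; local maxima of that series (refractory separation
`min_period_s`, default 2 s ≈ half the shortest plausible breath;
prominence floor π to reject noise bumps on the ramp) mark each cycle
end and are refined to the nearest sample of the upward zero crossing.

## Cluster permutation

Per frequency, a paired one-tailed t statistic (observed normalised MI
minus the surrogate 95th percentile expressed in normalised units) is
thresholded at p = 0.05; maximal runs of adjacent suprathreshold
frequencies form clusters scored by summed t. The permutation null
interchanges each subject's observed and reference spectra with
probability ½ (a per-subject sign flip of the difference), 5,000 draws
by default; each cluster's Monte-Carlo p is
(1 + #{null max ≥ observed})/(n_perm + 1). Multi-component correction
uses one sign flip per subject per draw applied to every component and
pools the maximum cluster statistic across components.

Degenerate inputs: a frequency where every subject's difference is
exactly zero is excluded (warned); zero variance with nonzero mean
yields t = ±inf, which keeps the documented behaviour that a uniform
positive shift produces a full-spectrum cluster at the smallest
attainable p.

## Head-movement nuisance regression

Six head position/rotation signals plus their first differences, each
raised to powers 1–3, give 36 regressors; each column is drift-removed
by subtracting its least-squares third-order polynomial fit. Removal is
a least-squares projection (minimum-norm under rank deficiency, which
is flagged), hence idempotent. The regression applies to
frequency-specific envelope time courses before MI by default; applying
it to spectra instead is a caller-side choice since `regress_nuisance`
is agnostic to what the series represents.

## Sparse NMF

Objective: ‖X − AY‖²_F + η‖A‖²_F + λ Σ_i ‖y_i‖₁², nonnegative A, Y.
Both penalties fold into augmented least-squares problems — for Y,
rows [A; √λ·1ᵀ] (valid because ‖y‖₁² = (1ᵀy)² for y ≥ 0); for A,
columns [Y, √η·I] — solved exactly per column by active-set NNLS, so
the objective is non-increasing at every half step (asserted by a
logged trace in tests). Restarts (default 100) use seeded nonnegative
random initialisations; the restart with the smallest data residual is
selected. η and λ are not canonical: defaults are η = (max X)² and
λ = 0.01 (conventions of the sparse-NMF family this follows), always
recorded in the run manifest.

Rank selection: smallest k whose leading singular values account for
90% of the singular-value mass. Applied per subject and aggregated by
the median (a group-matrix mode exists); both the aggregate and the
per-subject ranks are returned. On planted low-rank matrices the rule
recovers the planted rank; on noisy matrices it counts the noise floor
too, which is inherent to the rule, not a defect of the implementation.

Map thresholding retains the top ceil((1 − p/100)·n) voxels by weight,
ties broken by ascending voxel id — this top-m rule reproduces 202
retained voxels out of 20,173 at the 99th percentile exactly;
interpolating percentile variants do not.

## Profiles, clustering, mixed model

Component profiles are means over the thresholded voxel set of the
group-average amplitude-by-phase distributions (each entity × frequency
cell's 20 bin means normalised to unit mean first, removing the 1/f
scale), aggregated into the 6 bands and z-scored per profile
(6 × 20 matrix). Hierarchical clustering uses Euclidean distance with
average linkage (switchable); the cluster count is the first local
maximum of the mean silhouette over the candidate counts, falling back
to the global maximum for monotone curves. Identical profiles make the
silhouette undefined and raise a diagnostic error.

The distance model MI_j = β0 + (β1 + S_1j)·r + e_j is fitted by maximum
likelihood (statsmodels MixedLM, BFGS — the default L-BFGS occasionally
collapses the random-slope variance to a degenerate optimum on this
model family). As printed, the model has a random slope and no random
intercept; a `random_intercept` switch exists for sensitivity checks.
The slope test reports t = β1/se with residual degrees of freedom
n_obs − 2; non-convergence returns an explicit failure status, never a
silent fallback.

## LCMV beamformer

w = C⁻¹l (lᵀC⁻¹l)⁻¹ with λ = 0 and a pseudo-inverse fallback for
singular covariances; free-orientation (3-column) leadfields are
reduced to the orientation maximising output power (eigenvector of
lᵀC⁻¹l with the smallest eigenvalue). One broadband filter per voxel;
forward modelling is out of scope — filters are exercised on toy
instantaneous-mixing fixtures with known sources.

## Reproducibility

Every stochastic routine takes an explicit seed; `RunConfig` refuses to
run without one. The pipeline manifest records all parameters, a config
hash, and per-stage wall times; fixed configs reproduce identical
outputs (asserted in tests). Scaled-down defaults in the test suite
(shorter recordings, fewer surrogates/permutations/restarts) keep the
suite within a desktop budget; the stated-world defaults (300 s,
200 surrogates, 5,000 permutations, 100 restarts) remain the library
defaults.

## Known limitations

- Surrogate normalisation loses power when breathing is (near-)
  perfectly periodic; this is a property of circular-shift nulls, not
  of the implementation.
- Exact frequency attribution is limited to one grid step by the
  Morlet bandwidth at ω₀ = 6 (see above).
- Group t tests at very small n (2–3 subjects, df ≤ 2) have essentially
  no power at the 0.05 cluster-forming threshold; the synthetic demos
  at that scale validate estimator mechanics, not group-level power.
- The LMEM degrees-of-freedom convention is the residual one; no
  Satterthwaite/Kenward–Roger machinery is provided.
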