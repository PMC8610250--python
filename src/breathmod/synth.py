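"""Synthetic multi-subject datasets with planted respiration-amplitude coupling.

Generates quasi-periodic respiration traces (raised-cosine cycles with
per-cycle period jitter), oscillatory carriers whose amplitude envelope
is driven by respiration phase, 1/f background noise, and multi-entity
datasets with known spatial component structure — so every downstream
stage (envelopes, modulation indices, phase-triggered averages, NMF)
has a recoverable ground truth. Every generator is a pure function of
its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "RespirationTrace",
    "Coupling",
    "SyntheticGroundTruth",
    "SubjectDataset",
    "MultiSubjectDataset",
    "gen_respiration",
    "gen_coupled_signal",
    "gen_subject_dataset",
    "gen_toy_mixing",
    "one_over_f_noise",
]


@dataclass
class RespirationTrace:
    """Uniformly sampled respiration-belt signal (arbitrary units)."""

    samples: np.ndarray
    rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size < 2:
            raise ValueError("respiration trace needs >= 2 samples")
        if not np.all(np.isfinite(s)):
            raise ValueError("respiration trace must be finite")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.samples = s

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples.size) / self.rate_hz


@dataclass(frozen=True)
class Coupling:
    """One planted phase-amplitude coupling: a carrier oscillation whose
    envelope is maximal at ``preferred_phase_rad`` of respiration."""

    carrier_freq_hz: float
    modulation_depth: float
    preferred_phase_rad: float
    entity_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Stated world for a synthetic multi-subject dataset."""

    breath_period_mean_s: float = 4.0
    breath_period_jitter_s: float = 0.5
    couplings: list[Coupling] = field(default_factory=list)
    noise_exponent: float = 1.0
    spatial_maps: np.ndarray | None = None  # components x entities, >= 0
    snr: float = 1.0
    subject_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.breath_period_jitter_s < 0:
            raise ValueError("breath_period_jitter_s must be >= 0")
        if self.spatial_maps is not None:
            m = np.asarray(self.spatial_maps, dtype=float)
            if np.any(m < 0):
                raise ValueError("spatial map weights must be nonnegative")
            self.spatial_maps = m


@dataclass
class SubjectDataset:
    """One subject's respiration trace plus an entity x time signal matrix."""

    respiration: RespirationTrace
    signals: np.ndarray
    subject_id: int = 0

    @property
    def rate_hz(self) -> float:
        return self.respiration.rate_hz


@dataclass
class MultiSubjectDataset:
    subjects: list[SubjectDataset]
    ground_truth: SyntheticGroundTruth


def gen_respiration(
    duration_s: float,
    rate_hz: float,
    period_mean_s: float = 4.0,
    period_jitter_s: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> RespirationTrace:
    """Quasi-periodic respiration trace with one inhalation peak per cycle.

    Cycle lengths are drawn from a normal distribution around
    ``period_mean_s`` with SD ``period_jitter_s``, truncated below at
    1 s; each cycle is a raised-cosine (trough-to-trough, single
    mid-cycle peak) and the concatenation is low-pass smoothed at 1 Hz
    (zero-phase) to round the cycle joins without moving the peaks.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration_s and rate_hz must be positive")
    if duration_s <= 2 * period_mean_s:
        raise ValueError("duration_s must exceed two breathing periods")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration_s * rate_hz))
    # draw enough cycles to cover the trace
    n_cycles = int(np.ceil(duration_s / max(period_mean_s - 3 * period_jitter_s, 1.0))) + 2
    periods = rng.normal(period_mean_s, period_jitter_s, size=n_cycles)
    periods = np.maximum(periods, 1.0)
    # within-cycle phase ramps 0 -> 2*pi; signal = -cos(ramp) peaks mid-cycle
    edges = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(n) / rate_hz
    cycle_idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_cycles - 1)
    frac = (t - edges[cycle_idx]) / periods[cycle_idx]
    x = -np.cos(2.0 * np.pi * frac)
    if rate_hz > 4.0:  # smooth only when the band exists below Nyquist
        sos = butter(2, 1.0, btype="low", fs=rate_hz, output="sos")
        x = sosfiltfilt(sos, x)
    return RespirationTrace(samples=x, rate_hz=rate_hz)


def one_over_f_noise(
    n: int, exponent: float = 1.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Unit-variance 1/f^alpha noise by spectral shaping of white noise."""
    rng = rng or np.random.default_rng()
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity
    spec = spec / f ** (exponent / 2.0)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_coupled_signal(
    resp_phase: np.ndarray,
    carrier_freq_hz: float,
    depth: float,
    preferred_phase: float = 0.0,
    snr: float = np.inf,
    seed: int | np.random.Generator = 0,
    rate_hz: float = 300.0,
    noise_exponent: float = 1.0,
) -> np.ndarray:
    """Oscillation whose envelope follows respiration phase.

    signal = [1 + depth*cos(phase - preferred_phase)] * cos(2*pi*f*t + phi0)
             + noise / snr,

    where phi0 is a random carrier phase and the additive noise is
    1/f^alpha shaped with RMS equal to the carrier RMS divided by
    ``snr`` (``snr=inf`` -> noiseless). The envelope is maximal where
    the respiration phase equals ``preferred_phase``.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    phase = np.asarray(resp_phase, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = phase.size
    t = np.arange(n) / rate_hz
    phi0 = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + depth * np.cos(phase - preferred_phase)
    carrier = np.cos(2.0 * np.pi * carrier_freq_hz * t + phi0)
    x = envelope * carrier
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive or inf")
        noise = one_over_f_noise(n, noise_exponent, rng)
        x = x + noise * (np.sqrt(np.mean(x**2)) / snr)
    return x


def gen_subject_dataset(
    ground_truth: SyntheticGroundTruth,
    n_subjects: int,
    n_entities: int,
    duration_s: float = 300.0,
    rate_hz: float = 300.0,
) -> MultiSubjectDataset:
    """Multi-subject dataset with planted couplings on known entities.

    Per subject: a respiration trace (subject-specific mean breathing
    period drawn around the group mean), plus an entity x time matrix.
    Entities listed in a coupling (directly via ``entity_ids`` or via a
    positive weight in ``spatial_maps``) carry that coupling's
    modulated carrier scaled by the map weight; every entity receives
    1/f background noise at the stated signal-to-noise ratio.
    Subject-level variability multiplies each subject's modulation
    depth by N(1, subject_sd) clipped to [0, 1/depth].
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    gt = ground_truth
    weights = _coupling_weights(gt, n_entities)
    subjects = []
    for s in range(n_subjects):
        rng = np.random.default_rng([gt.seed, 0xB5EA7, s])
        period = gt.breath_period_mean_s * float(
            np.clip(rng.normal(1.0, gt.subject_sd), 0.5, 1.5)
        )
        trace = gen_respiration(
            duration_s, rate_hz, period, gt.breath_period_jitter_s, seed=rng
        )
        from .coupling import extract_phase  # deferred: avoids import cycle

        phase = extract_phase(trace).phase_rad
        n = trace.samples.size
        signals = np.empty((n_entities, n))
        depth_scale = float(np.clip(rng.normal(1.0, gt.subject_sd), 0.0, None))
        for e in range(n_entities):
            x = np.zeros(n)
            for c, coup in enumerate(gt.couplings):
                w = weights[c, e]
                if w <= 0:
                    continue
                depth = float(np.clip(coup.modulation_depth * depth_scale, 0.0, 1.0))
                x += w * gen_coupled_signal(
                    phase, coup.carrier_freq_hz, depth,
                    coup.preferred_phase_rad, snr=np.inf, seed=rng,
                    rate_hz=rate_hz, noise_exponent=gt.noise_exponent,
                )
            noise = one_over_f_noise(n, gt.noise_exponent, rng)
            rms = np.sqrt(np.mean(x**2)) if np.any(x) else 1.0
            signals[e] = x + noise * (rms / gt.snr)
        subjects.append(SubjectDataset(respiration=trace, signals=signals, subject_id=s))
    return MultiSubjectDataset(subjects=subjects, ground_truth=gt)


def _coupling_weights(gt: SyntheticGroundTruth, n_entities: int) -> np.ndarray:
    """Per-coupling entity weights from spatial maps and/or entity id lists."""
    n_coup = len(gt.couplings)
    weights = np.zeros((n_coup, n_entities))
    if gt.spatial_maps is not None:
        m = np.asarray(gt.spatial_maps, dtype=float)
        if m.shape != (n_coup, n_entities):
            raise ValueError(
                f"spatial_maps must be {n_coup} x {n_entities}, got {m.shape}"
            )
        weights += m
    for c, coup in enumerate(gt.couplings):
        for e in coup.entity_ids:
            if not 0 <= e < n_entities:
                raise ValueError(f"entity id {e} outside [0, {n_entities})")
            if gt.spatial_maps is None:
                weights[c, e] = 1.0
    return weights


def gen_toy_mixing(
    n_sensors: int,
    n_sources: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 2000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear instantaneous mixing fixture for beamformer tests.

    Returns ``(mixing, sources, sensors)`` with
    ``sensors = mixing @ sources + noise``. The mixing matrix has
    orthonormal columns (full column rank by construction); sources are
    unit-variance white Gaussian.
    """
    if n_sources < 1 or n_sensors <= n_sources:
        raise ValueError("need n_sensors > n_sources >= 1")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_sensors, n_sources))
    mixing, _ = np.linalg.qr(g)
    sources = rng.standard_normal((n_sources, n_samples))
    sensors = mixing @ sources
    if noise_sd > 0:
        sensors = sensors + noise_sd * rng.standard_normal(sensors.shape)
    return mixing, sources, sensors
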