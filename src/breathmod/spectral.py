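"""Time-frequency decomposition of electrophysiological signals.

Implements the analytic Morlet continuous wavelet transform on the
standard 36-frequency grid (2-20 Hz in 2-Hz steps, then 25-150 Hz in
5-Hz steps), amplitude envelopes with moving-average smoothing, global
field power (channel-averaged envelope), and aggregation of single
frequencies into canonical frequency bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyGrid",
    "EnvelopeTensor",
    "BandScheme",
    "DEFAULT_BANDS",
    "frequency_grid",
    "morlet_cwt",
    "amplitude_envelope",
    "global_field_power",
    "aggregate_bands",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing set of analysis frequencies in Hz."""

    freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D sequence")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        object.__setattr__(self, "freqs_hz", f)

    def __len__(self) -> int:
        return self.freqs_hz.size


@dataclass
class EnvelopeTensor:
    """Smoothed oscillatory amplitude, entities x frequencies x time.

    ``values`` are nonnegative; ``rate_hz`` is the sampling rate of the
    time axis; ``smoothed`` records whether moving-average smoothing was
    applied.
    """

    values: np.ndarray
    rate_hz: float
    grid: FrequencyGrid
    smoothed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2:  # single entity
            v = v[np.newaxis]
        if v.ndim != 3:
            raise ValueError("values must be entities x frequencies x time")
        if v.shape[1] != len(self.grid):
            raise ValueError("frequency axis does not match grid")
        if np.any(v < 0):
            raise ValueError("envelope values must be nonnegative")
        self.values = v


@dataclass(frozen=True)
class BandScheme:
    """Named half-open frequency intervals [lo, hi); the top edge of the
    last band is inclusive so the full range is covered."""

    bands: dict[str, tuple[float, float]]

    def membership(self, freqs_hz: np.ndarray) -> dict[str, np.ndarray]:
        """Indices of ``freqs_hz`` falling in each band.

        Boundaries shared by two bands belong to the upper band; the
        global upper edge is inclusive.
        """
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        lo_all = min(lo for lo, _ in self.bands.values())
        hi_all = max(hi for _, hi in self.bands.values())
        if np.any(freqs_hz < lo_all) or np.any(freqs_hz > hi_all):
            raise ValueError(
                f"frequencies outside [{lo_all}, {hi_all}] Hz are not covered"
            )
        out = {}
        for name, (lo, hi) in self.bands.items():
            mask = (freqs_hz >= lo) & (freqs_hz < hi)
            if hi == hi_all:
                mask |= freqs_hz == hi
            out[name] = np.flatnonzero(mask)
        return out


DEFAULT_BANDS = BandScheme(
    bands={
        "delta": (2.0, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 12.0),
        "beta": (12.0, 30.0),
        "low_gamma": (30.0, 70.0),
        "high_gamma": (70.0, 150.0),
    }
)


def frequency_grid() -> FrequencyGrid:
    """The default 36-frequency analysis grid.

    2 Hz to 20 Hz in steps of 2 Hz, then 25 Hz to 150 Hz in steps of
    5 Hz (36 frequencies in total).
    """
    freqs = np.concatenate([np.arange(2.0, 21.0, 2.0), np.arange(25.0, 151.0, 5.0)])
    return FrequencyGrid(freqs)


def _morlet_fourier(omega: np.ndarray, omega0: float) -> np.ndarray:
    """Fourier transform of the analytic Morlet wavelet.

    Psi(w) = pi^(-1/4) * exp(-(w - w0)^2 / 2) * H(w), with H the
    Heaviside step (strictly positive frequencies only), which makes
    the transform analytic.
    """
    psi = np.pi ** (-0.25) * np.exp(-0.5 * (omega - omega0) ** 2)
    psi[omega <= 0] = 0.0
    return psi


def morlet_cwt(
    signal: np.ndarray,
    rate_hz: float,
    grid: FrequencyGrid | None = None,
    omega0: float = 6.0,
) -> np.ndarray:
    """Continuous wavelet transform with the analytic Morlet wavelet.

    Computed by frequency-domain multiplication: for each analysis
    frequency f the wavelet is dilated so its Gaussian passband peaks at
    f, i.e. scale a = omega0 / (2*pi*f/rate). The wavelet is normalised
    in amplitude (L1 convention), so a unit sinusoid at a grid frequency
    produces a near-unit-modulus row at that frequency regardless of f.

    Parameters
    ----------
    signal : 1-D (time) or 2-D (entities x time) real array.
    rate_hz : sampling rate.
    grid : analysis frequencies, default :func:`frequency_grid`.
    omega0 : wavelet centre frequency in radians (default 6, the common
        choice trading time against frequency resolution).

    Returns
    -------
    complex array, frequencies x time (or entities x frequencies x time
    for 2-D input).
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if grid is None:
        grid = frequency_grid()
    single = x.ndim == 1
    x = np.atleast_2d(x)
    n = x.shape[-1]
    xf = np.fft.fft(x, axis=-1)
    omega = 2.0 * np.pi * np.fft.fftfreq(n)  # radians / sample
    scales = omega0 / (2.0 * np.pi * grid.freqs_hz / rate_hz)
    # (freq, time) filter bank; Heaviside mask keeps the result analytic
    bank = _morlet_fourier(scales[:, None] * omega[None, :], omega0)
    # normalise so a unit cosine at the row's centre frequency has unit
    # envelope: the analytic response to cos is Psi(peak)/2 * exp(iwt)
    bank = bank * (2.0 / (np.pi ** (-0.25)))
    out = np.fft.ifft(xf[:, None, :] * bank[None, :, :], axis=-1)
    return out[0] if single else out


def amplitude_envelope(
    cwt: np.ndarray,
    rate_hz: float,
    grid: FrequencyGrid | None = None,
    smooth_ms: float = 300.0,
) -> EnvelopeTensor:
    """Amplitude envelope: elementwise modulus of the CWT, then a
    centred moving average of ``round(smooth_ms * rate_hz / 1000)``
    samples (the window shrinks symmetrically at the edges, so a
    constant row stays constant everywhere).
    """
    if smooth_ms < 0:
        raise ValueError("smooth_ms must be nonnegative")
    if grid is None:
        grid = frequency_grid()
    amp = np.abs(np.asarray(cwt))
    win = int(round(smooth_ms * rate_hz / 1000.0))
    if win > 1:
        amp = _moving_average(amp, win)
    return EnvelopeTensor(values=amp, rate_hz=rate_hz, grid=grid, smoothed=win > 1)


def _moving_average(a: np.ndarray, win: int) -> np.ndarray:
    """Centred moving average along the last axis with edge shrinkage:
    each output sample averages the window samples that fall inside the
    array."""
    n = a.shape[-1]
    half_l = (win - 1) // 2
    half_r = win // 2
    csum = np.cumsum(a, axis=-1)
    csum = np.concatenate([np.zeros(a.shape[:-1] + (1,)), csum], axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - half_l, 0)
    hi = np.minimum(idx + half_r + 1, n)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def global_field_power(env: EnvelopeTensor) -> np.ndarray:
    """Unweighted mean of the amplitude envelope over the entity
    (channel/voxel) axis -> frequencies x time."""
    if env.values.shape[0] < 1:
        raise ValueError("need at least one entity")
    return env.values.mean(axis=0)


def aggregate_bands(
    values: np.ndarray,
    grid: FrequencyGrid | None = None,
    scheme: BandScheme = DEFAULT_BANDS,
    axis: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Average frequency-resolved values into frequency bands.

    ``values`` is indexed by ``grid`` along ``axis``; each band's value
    is the mean over its member grid frequencies (half-open intervals,
    upper edge of the top band inclusive). Returns the banded array and
    the band names in scheme order. Bands with no member frequency are
    dropped.
    """
    if grid is None:
        grid = frequency_grid()
    values = np.asarray(values)
    if values.shape[axis] != len(grid):
        raise ValueError("values axis does not match grid length")
    members = scheme.membership(grid.freqs_hz)
    names = [name for name, idx in members.items() if idx.size]
    banded = np.stack(
        [values.take(members[name], axis=axis).mean(axis=axis) for name in names],
        axis=axis,
    )
    return banded, names
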