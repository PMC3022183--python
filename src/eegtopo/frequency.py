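"""Frequency-domain topographies: windowed spectra, power maps, and the
single-phase approximation.

Spectral analysis of multichannel EEG usually compares band power per
electrode (power maps), but power maps are reference-dependent and
discard the phase relations between electrodes, so they cannot be fed
to source estimation. The *FFT-approximation* replaces the complex
Fourier coefficients at one frequency by a single real potential map
with one common phase: the first principal component of the
coefficients in the complex plane. Writing the N complex coefficients
as an N × 2 real matrix (real and imaginary parts; windows stacked as
additional column pairs), the dominant left singular vector is the
approximated map, and the squared dominant singular value over the
total gives the fraction of oscillatory power a single in-phase
topography explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Recording

__all__ = ["SpectralData", "ApproximatedMap", "stft_spectra", "power_maps",
           "fft_approximation"]


@dataclass(frozen=True)
class SpectralData:
    """One-sided windowed FFT coefficients: channels × bins × windows."""

    coefficients: np.ndarray
    freqs_hz: np.ndarray
    window_length_tf: int
    overlap_fraction: float
    sampling_rate: float
    taper: str

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients)
        if c.ndim != 3:
            raise ValueError("coefficients must be channels × bins × windows")
        if c.shape[1] != self.window_length_tf // 2 + 1:
            raise ValueError("bin count must be window_length/2 + 1")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap must be in [0, 1)")


@dataclass(frozen=True)
class ApproximatedMap:
    """Single-phase approximation of one frequency's complex topography.

    ``map`` is scaled so its squared norm equals the explained power;
    ``phase_rad`` is the common phase in the first window; ``degenerate``
    flags near-equal leading singular values (no preferred phase).
    """

    map: np.ndarray
    phase_rad: float
    freq_hz: float
    explained_power_fraction: float
    degenerate: bool


def stft_spectra(
    rec: Recording,
    window_tf: int,
    overlap: float = 0.5,
    taper: str = "hann",
) -> SpectralData:
    """Short-time FFT of an average-referenced recording.

    Windows of ``window_tf`` frames advance by ``window_tf × (1 −
    overlap)`` frames, giving ``1 + floor((T − window) / step)`` windows;
    each is tapered (``"hann"`` or ``"rect"``) and transformed with a
    one-sided FFT. Frequencies are ``k · rate / window_tf``.
    """
    if window_tf > rec.n_timeframes:
        raise ValueError("window longer than recording")
    if window_tf < 2:
        raise ValueError("window must span at least 2 timeframes")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    if taper == "hann":
        win = np.hanning(window_tf)
    elif taper == "rect":
        win = np.ones(window_tf)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    step = max(1, int(round(window_tf * (1.0 - overlap))))
    n_win = 1 + (rec.n_timeframes - window_tf) // step
    segs = np.stack(
        [data[:, s * step : s * step + window_tf] for s in range(n_win)],
        axis=2,
    )  # (N, window, W)
    coeffs = np.fft.rfft(segs * win[None, :, None], axis=1)
    freqs = np.fft.rfftfreq(window_tf, d=1.0 / rec.sampling_rate)
    return SpectralData(coefficients=coeffs, freqs_hz=freqs,
                        window_length_tf=window_tf,
                        overlap_fraction=overlap,
                        sampling_rate=rec.sampling_rate, taper=taper)


def power_maps(spec: SpectralData, band_hz: tuple[float, float]) -> np.ndarray:
    """Mean |coefficient|² per electrode over a frequency band.

    Note: unlike time-domain topographic measures, power maps depend on
    the recording reference.
    """
    lo, hi = band_hz
    sel = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
    if not np.any(sel):
        raise ValueError(f"no frequency bins inside [{lo}, {hi}] Hz")
    return np.mean(np.abs(spec.coefficients[:, sel, :]) ** 2, axis=(1, 2))


def fft_approximation(spec: SpectralData, freq_hz: float,
                      rtol_degenerate: float = 1e-6) -> ApproximatedMap:
    """Single-phase real map best approximating one frequency's
    complex coefficients.

    Stacks each window's real and imaginary parts as columns of an
    ``N × 2W`` matrix and takes its dominant left singular vector; the
    result is invariant to a global phase rotation of the coefficients.
    The map's sign makes the largest-|value| electrode positive, and its
    squared norm equals the explained power.
    """
    bin_ = int(np.argmin(np.abs(spec.freqs_hz - freq_hz)))
    C = spec.coefficients[:, bin_, :]  # (N, W)
    M = np.hstack([C.real, C.imag])  # (N, 2W)
    total = float(np.sum(M**2))
    if total <= 0:
        raise ValueError("zero total power at requested frequency")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    frac = float(s[0] ** 2 / (s**2).sum())
    degenerate = len(s) > 1 and (s[0] - s[1]) <= rtol_degenerate * s[0]
    m = U[:, 0] * s[0]
    i = int(np.argmax(np.abs(m)))
    sign = -1.0 if m[i] < 0 else 1.0
    m = sign * m
    W = C.shape[1]
    v = sign * Vt[0]
    phase = float(np.arctan2(v[W], v[0]))
    return ApproximatedMap(map=m, phase_rad=phase, freq_hz=float(
        spec.freqs_hz[bin_]), explained_power_fraction=frac,
        degenerate=degenerate)
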