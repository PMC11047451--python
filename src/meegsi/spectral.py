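"""Frequency-domain transforms and Hermitian cross-spectral estimation.

Three transforms produce per-frequency complex coefficients from multichannel
time series:

* FFT -- windowed non-overlapping segments; one coefficient per segment and
  frequency bin, scaled so that the summed squared moduli equal the segment
  energy (one-sided, interior bins carry the factor sqrt(2)).
* GF-HT -- Gaussian-filtered Hilbert transform: for each target frequency the
  analytic signal of the series filtered by a frequency-domain Gaussian
  centered there; one coefficient per time point, approaching the FFT
  periodogram as the bandwidth shrinks.
* BF-HT -- band-filtered Hilbert transform: the analytic signal per classical
  band (delta/theta/alpha/beta/gamma by default), giving one cross-spectral
  slice per band.

Cross-spectral tensors are Hermitian positive semidefinite by construction:
each frontal slice is (1/m) sum_k z_k z_k^H over the m coefficient samples at
that frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, get_window

DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, None),  # upper edge 0.9 * Nyquist, resolved per series
}


@dataclass
class TimeSeriesData:
    """Multichannel time series (channels x time) with a sampling rate."""

    data: np.ndarray
    sampling_rate: float
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels/channels mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]


@dataclass
class SpectralCoefficients:
    """Complex coefficients (channels x frequencies x samples)."""

    coeffs: np.ndarray
    frequencies: np.ndarray
    transform: str  # {"fft", "gfht", "bfht"}
    labels: list = field(default_factory=list)

    @property
    def samples_per_frequency(self) -> int:
        return self.coeffs.shape[2]


@dataclass
class CrossSpectralTensor:
    """Per-frequency Hermitian PSD covariance of spectral coefficients."""

    S: np.ndarray  # (n, n, F) complex
    frequencies: np.ndarray  # (F,) Hz, or band centers
    m: int  # effective sample count per slice
    labels: list = field(default_factory=list)
    band_names: list | None = None

    def validate(self) -> None:
        for fi in range(self.S.shape[2]):
            sl = self.S[:, :, fi]
            scale = max(np.linalg.norm(sl), 1e-300)
            if np.linalg.norm(sl - sl.conj().T) > 1e-10 * scale:
                raise ValueError(f"slice {fi} is not Hermitian")
            ev = np.linalg.eigvalsh(sl)
            if ev.min() < -1e-10 * max(ev.max(), 1e-300):
                raise ValueError(f"slice {fi} is not PSD")


def detrend(x: TimeSeriesData) -> TimeSeriesData:
    """Remove per-channel mean and linear trend (simple plumbing)."""
    from scipy.signal import detrend as _dt

    return TimeSeriesData(_dt(x.data, axis=1), x.sampling_rate, list(x.labels))


def fft_coefficients(
    x: TimeSeriesData, segment_length: int, window: str = "hann"
) -> SpectralCoefficients:
    """One-sided Fourier coefficients of non-overlapping windowed segments.

    Scaling: sum_k |c_k|^2 equals the (windowed) segment energy, i.e. interior
    bins are X_k * sqrt(2/N).
    """
    N = int(segment_length)
    if N > x.n_times:
        raise ValueError("segment_length exceeds series length")
    if N < 2:
        raise ValueError("segment_length must be >= 2")
    n_seg = x.n_times // N
    segs = x.data[:, : n_seg * N].reshape(x.n_channels, n_seg, N)
    if window in (None, "rectangular", "boxcar"):
        w = np.ones(N)
    else:
        w = get_window(window, N)
        w = w / np.sqrt(np.mean(w**2))  # preserve average power
    X = np.fft.rfft(segs * w[None, None, :], axis=2)  # (C, n_seg, N//2+1)
    scale = np.full(X.shape[2], np.sqrt(2.0 / N))
    scale[0] = np.sqrt(1.0 / N)
    if N % 2 == 0:
        scale[-1] = np.sqrt(1.0 / N)
    coeffs = np.transpose(X * scale[None, None, :], (0, 2, 1))  # (C, F, n_seg)
    freqs = np.fft.rfftfreq(N, 1.0 / x.sampling_rate)
    return SpectralCoefficients(coeffs, freqs, "fft", list(x.labels))


def gfht_coefficients(
    x: TimeSeriesData, frequencies, bandwidth_hz: float = 1.0
) -> SpectralCoefficients:
    """Gaussian-filtered Hilbert transform coefficients.

    For each target frequency f the series is filtered in the frequency domain
    by a Gaussian window centered at f (standard deviation = bandwidth/2) and
    the analytic signal is returned; sample count equals the number of time
    points.  Approaches the FFT periodogram as the bandwidth goes to zero.
    """
    if bandwidth_hz <= 0:
        raise ValueError("bandwidth must be positive")
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=np.float64))
    nyq = x.sampling_rate / 2.0
    if np.any(frequencies >= nyq):
        raise ValueError("frequency at or above Nyquist")
    T = x.n_times
    X = np.fft.fft(x.data, axis=1)  # (C, T)
    f_full = np.fft.fftfreq(T, 1.0 / x.sampling_rate)
    # analytic-signal mask
    h = np.zeros(T)
    if T % 2 == 0:
        h[0] = h[T // 2] = 1.0
        h[1 : T // 2] = 2.0
    else:
        h[0] = 1.0
        h[1 : (T + 1) // 2] = 2.0
    s = bandwidth_hz / 2.0
    out = np.empty((x.n_channels, len(frequencies), T), dtype=complex)
    for fi, f0 in enumerate(frequencies):
        g = np.exp(-0.5 * ((f_full - f0) / s) ** 2)
        out[:, fi, :] = np.fft.ifft(X * (h * g)[None, :], axis=1)
    return SpectralCoefficients(out, frequencies, "gfht", list(x.labels))


def resolve_default_bands(sampling_rate: float) -> dict:
    """The five classical bands with the gamma upper edge at 0.9 * Nyquist."""
    nyq = sampling_rate / 2.0
    bands = {}
    for name, (lo, hi) in DEFAULT_BANDS.items():
        hi = 0.9 * nyq if hi is None else hi
        if lo < nyq:
            bands[name] = (lo, min(hi, 0.99 * nyq))
    return bands


def bfht_coefficients(x: TimeSeriesData, bands: dict | None = None) -> SpectralCoefficients:
    """Band-filtered Hilbert transform: analytic signal per band.

    ``bands`` maps name -> (low, high) Hz; the default is the classical
    five-band partition (delta, theta, alpha, beta, gamma).
    """
    from scipy.signal import hilbert

    if bands is None:
        bands = resolve_default_bands(x.sampling_rate)
    nyq = x.sampling_rate / 2.0
    names, edges = list(bands.keys()), list(bands.values())
    for lo, hi in edges:
        if not (0 < lo < hi < nyq):
            raise ValueError(f"invalid band edges ({lo}, {hi}) for Nyquist {nyq}")
    out = np.empty((x.n_channels, len(names), x.n_times), dtype=complex)
    for bi, (lo, hi) in enumerate(edges):
        b, a = butter(4, [lo / nyq, hi / nyq], btype="band")
        filt = filtfilt(b, a, x.data, axis=1)
        out[:, bi, :] = hilbert(filt, axis=1)
    centers = np.array([(lo + hi) / 2.0 for lo, hi in edges])
    sc = SpectralCoefficients(out, centers, "bfht", list(x.labels))
    sc.band_names = names  # type: ignore[attr-defined]
    return sc


def cross_spectrum(coeffs: SpectralCoefficients) -> CrossSpectralTensor:
    """Hermitian covariance of the coefficients at each frequency,
    S_f = (1/m) sum_k z_k z_k^H (coefficients are zero-mean by construction)."""
    Z = coeffs.coeffs
    C, F, m = Z.shape
    if m < 2:
        import warnings

        warnings.warn("single spectral sample: rank-1 cross-spectral slices")
    S = np.einsum("cfm,dfm->cdf", Z, Z.conj()) / m
    # enforce exact Hermitian symmetry against rounding
    S = 0.5 * (S + np.transpose(S.conj(), (1, 0, 2)))
    t = CrossSpectralTensor(S, np.asarray(coeffs.frequencies), m, list(coeffs.labels))
    t.band_names = getattr(coeffs, "band_names", None)
    return t


def default_frequency_grid(fmax: float = 50.0, df: float = 0.5) -> np.ndarray:
    """Positive analysis frequencies {df, 2*df, ..., fmax}; 100 frequencies at
    the defaults (0-50 Hz, 0.5 Hz resolution, DC excluded)."""
    if df <= 0:
        raise ValueError("df must be positive")
    n = fmax / df
    if abs(n - round(n)) > 1e-9:
        raise ValueError("fmax must be an integer multiple of df")
    return np.arange(1, int(round(n)) + 1) * df
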