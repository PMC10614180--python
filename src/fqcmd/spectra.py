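"""Dipole absorption spectra from the dipole-derivative autocorrelation.

The spectrum is the one-sided cosine transform of C(t) = <mu_dot(0).mu_dot(t)>
damped by a Hann window cos^2(pi t / 2 tau) that reaches zero at t = tau.
Band positions, not absolute intensities, are the observables of interest,
so spectra are reported peak-normalized and the thermal/frequency prefactor
of the absorption cross section is omitted (it varies slowly across a band
and does not move the maxima).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq

from . import units


@dataclass
class DipoleTrajectory:
    """Uniformly sampled dipole-derivative segments.

    ``segments`` is a list of (nt, 3) arrays (e.g. independent NVE runs);
    a single array is accepted and wrapped.
    """

    dt_fs: float
    segments: list

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if isinstance(self.segments, np.ndarray) and self.segments.ndim == 2:
            self.segments = [self.segments]
        self.segments = [np.asarray(s, float) for s in self.segments]
        for s in self.segments:
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError("each segment must be (nt, 3)")

    @property
    def length_fs(self) -> float:
        return min(len(s) for s in self.segments) * self.dt_fs


@dataclass
class AbsorptionSpectrum:
    """Frequency grid (cm^-1) and peak-normalized intensity."""

    frequency_cm1: np.ndarray
    intensity: np.ndarray
    window_tau_fs: float

    def __post_init__(self):
        self.frequency_cm1 = np.asarray(self.frequency_cm1, float)
        self.intensity = np.asarray(self.intensity, float)


def _autocorrelation_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased autocorrelation of one series over lags 0..max_lag."""
    n = len(x)
    npad = 1 << int(np.ceil(np.log2(2 * n)))
    f = rfft(x, npad)
    acf = irfft(f * np.conj(f), npad)[:max_lag + 1]
    return acf / (n - np.arange(max_lag + 1))


def dipole_derivative_autocorrelation(traj: DipoleTrajectory,
                                      max_lag_fs: float):
    """C(t) = <mu_dot(0) . mu_dot(t)>, averaged over time origins and segments.

    All three Cartesian components are summed; origin averaging is unbiased
    (each lag is normalized by its own origin count).  Returns
    ``(lags_fs, C)``.
    """
    max_lag = int(round(max_lag_fs / traj.dt_fs))
    n_min = min(len(s) for s in traj.segments)
    if max_lag > n_min // 2:
        raise ValueError(
            f"max_lag {max_lag_fs} fs exceeds half the shortest segment "
            f"({n_min * traj.dt_fs / 2} fs)")
    C = np.zeros(max_lag + 1)
    for seg in traj.segments:
        for comp in range(3):
            C += _autocorrelation_fft(seg[:, comp], max_lag)
    C /= len(traj.segments)
    lags = np.arange(max_lag + 1) * traj.dt_fs
    return lags, C


def hann_window(t_fs: np.ndarray, tau_fs: float) -> np.ndarray:
    """cos^2(pi t / 2 tau) for t <= tau, zero beyond (zero-at-tau convention)."""
    w = np.cos(np.pi * t_fs / (2.0 * tau_fs)) ** 2
    return np.where(t_fs <= tau_fs, w, 0.0)


def windowed_spectrum(C: np.ndarray, dt_fs: float, window_tau_fs: float,
                      pad_factor: int = 4) -> AbsorptionSpectrum:
    """Hann-damped one-sided cosine transform of a correlation series.

    The windowed series is zero-padded (``pad_factor`` times the window
    length) for a finer frequency grid; tiny negative transform values
    (window sidelobes) are clipped to zero; the result is normalized to
    unit maximum.
    """
    C = np.asarray(C, float)
    T = (len(C) - 1) * dt_fs
    if window_tau_fs > T:
        raise ValueError(
            f"window tau {window_tau_fs} fs exceeds correlation length {T} fs")
    t = np.arange(len(C)) * dt_fs
    y = C * hann_window(t, window_tau_fs)
    n_win = int(np.floor(window_tau_fs / dt_fs)) + 1
    y = y[:n_win]
    npad = pad_factor * n_win
    # Even extension -> cosine transform via rfft.
    ext = np.concatenate([y, np.zeros(npad - n_win)])
    full = np.concatenate([ext, ext[-2:0:-1]])
    S = np.real(rfft(full)) * dt_fs
    S = np.clip(S, 0.0, None)
    freq_fs = rfftfreq(len(full), d=dt_fs)
    peak = S.max()
    if peak > 0:
        S = S / peak
    return AbsorptionSpectrum(frequency_cm1=freq_fs * units.INV_FS_TO_CM1,
                              intensity=S, window_tau_fs=window_tau_fs)


def spectrum_from_segments(segments, dt_fs: float, tau_fs: float,
                           pad_factor: int = 4) -> AbsorptionSpectrum:
    """Convenience: autocorrelate dipole-derivative segments and transform."""
    traj = DipoleTrajectory(dt_fs=dt_fs, segments=segments)
    _, C = dipole_derivative_autocorrelation(traj, tau_fs)
    return windowed_spectrum(C, dt_fs, tau_fs, pad_factor=pad_factor)


def find_band_peak(spectrum: AbsorptionSpectrum, search_range) -> float:
    """Frequency (cm^-1) of the band maximum within ``search_range``.

    The discrete maximum is refined by three-point parabolic interpolation.
    """
    lo, hi = search_range
    f = spectrum.frequency_cm1
    mask = (f >= lo) & (f <= hi)
    if not np.any(mask):
        raise ValueError(f"empty search range {search_range}")
    idx = np.nonzero(mask)[0]
    k = idx[np.argmax(spectrum.intensity[idx])]
    if 0 < k < len(f) - 1:
        y0, y1, y2 = spectrum.intensity[k - 1:k + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            shift = 0.5 * (y0 - y2) / denom
            if abs(shift) <= 1:
                return float(f[k] + shift * (f[1] - f[0]))
    return float(f[k])
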