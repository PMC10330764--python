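"""Phase-based chest-motion extraction and respiration/heart-rate estimation.

The complex range-FFT value at the selected bin carries the chest position in
its phase: phi = 4*pi*(R0 + x(t))/lambda, so a displacement x maps to a phase
swing of 4*pi*x/lambda radians.  The chain is: four-quadrant phase ->
unwrapping -> first difference (kills slow drift) -> 4th-order Butterworth
band-pass realised as two cascaded biquads (0.1-0.6 Hz respiration,
0.8-4 Hz heartbeat) -> zero-padded FFT peak pick, per 20-s sliding window
stepped by 1 s.

Heart-rate picking rejects respiratory harmonics: among the n_peaks largest
spectral peaks in the heartbeat band, any peak within ``harmonic_tol`` of an
integer multiple k*fr (k >= 2) of the current respiration estimate is
discarded before taking the largest survivor.  If every candidate is
discarded — e.g. the true heart rate itself sits on a harmonic — the largest
peak is returned and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal import butter, find_peaks, sosfilt

RESP_BAND = (0.1, 0.6)   # Hz
HEART_BAND = (0.8, 4.0)  # Hz

#: sentinel for "no estimate available"
NO_ESTIMATE = float("nan")

FLAG_FALLBACK = "fallback_harmonic"
FLAG_GAP = "gap"


@dataclass
class PhaseSignal:
    """Phase of the selected range bin across frames."""

    phi: np.ndarray        # wrapped phase (rad)
    unwrapped: np.ndarray  # continuous phase (rad)
    diffed: np.ndarray     # first difference (rad/frame), length n-1
    fs: float              # slow-time sampling rate (Hz)
    amplitude: np.ndarray | None = None  # |bin value|; carried, unused


@dataclass
class VitalSeries:
    """Windowed rate estimates in beats/breaths per minute."""

    timestamps: np.ndarray   # window end times (s)
    rr: np.ndarray           # respiration rate (BPM), NaN where absent
    hr: np.ndarray           # heart rate (BPM), NaN where absent
    flags: list[str]         # '' | 'gap' | 'fallback_harmonic'
    window: float = 20.0
    step: float = 1.0

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_end_s": self.timestamps,
            "rr_bpm": self.rr,
            "hr_bpm": self.hr,
            "quality_flags": self.flags,
        })


def extract_motion_signal(
    bin_values: np.ndarray, fs: float
) -> PhaseSignal:
    """Phase-process the selected bin's complex slow-time series.

    Four-quadrant arctangent, unwrap (correct any successive jump > pi by
    +/-2*pi), then first difference.
    """
    bin_values = np.asarray(bin_values)
    if bin_values.size < 2:
        raise ValueError("need at least 2 frames of bin values")
    phi = np.angle(bin_values)
    unwrapped = np.unwrap(phi)
    return PhaseSignal(
        phi=phi,
        unwrapped=unwrapped,
        diffed=np.diff(unwrapped),
        fs=fs,
        amplitude=np.abs(bin_values),
    )


def design_bandpass(band: tuple[float, float], fs: float) -> np.ndarray:
    """4th-order Butterworth band-pass as cascaded biquad (SOS) sections."""
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} outside (0, {fs / 2}) Hz")
    return butter(2, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(signal: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Band-pass a slow-time signal with zero initial conditions."""
    sos = design_bandpass(band, fs)
    return sosfilt(sos, np.asarray(signal, dtype=float))


def _spectrum(signal: np.ndarray, fs: float, n_fft_min: int = 4096):
    """Magnitude spectrum on a zero-padded grid (resolution <= 0.3 BPM)."""
    signal = np.asarray(signal, dtype=float)
    n_fft = max(n_fft_min, 1 << (len(signal) - 1).bit_length())
    mag = np.abs(rfft(signal * np.hanning(len(signal)), n=n_fft))
    freqs = rfftfreq(n_fft, d=1.0 / fs)
    return freqs, mag


def estimate_respiration_rate(resp_signal: np.ndarray, fs: float) -> float:
    """Respiration rate (BPM) as the largest spectral peak in 0.1-0.6 Hz.

    Returns NaN for an (effectively) all-zero signal.
    """
    resp_signal = np.asarray(resp_signal, dtype=float)
    if len(resp_signal) < 10 * fs:
        raise ValueError("need at least a 10-s window")
    if not np.any(np.abs(resp_signal) > 0):
        return NO_ESTIMATE
    freqs, mag = _spectrum(resp_signal, fs)
    band = (freqs >= RESP_BAND[0]) & (freqs <= RESP_BAND[1])
    return float(60.0 * freqs[band][np.argmax(mag[band])])


def estimate_heart_rate(
    heart_signal: np.ndarray,
    fs: float,
    fr_hz: float | None = None,
    n_peaks: int = 4,
    harmonic_tol: float = 0.04,
    rel_floor: float = 0.3,
) -> tuple[float, bool]:
    """Heart rate (BPM) with respiratory-harmonic rejection.

    Takes the ``n_peaks`` largest local maxima of the heartbeat-band
    spectrum, discards any within ``harmonic_tol`` Hz of k*fr_hz for integer
    k >= 2, and returns 60x the frequency of the largest survivor.  A
    survivor must also be a credible cardiac line — at least ``rel_floor``
    of the largest candidate's magnitude — so that when the true heart rate
    itself sits on a respiratory harmonic the estimator falls back to the
    largest peak instead of promoting a noise bump.

    Returns ``(bpm, fallback)``; ``fallback`` is True when the rejection
    eliminated every credible candidate.  NaN for an all-zero signal.
    """
    heart_signal = np.asarray(heart_signal, dtype=float)
    if not np.any(np.abs(heart_signal) > 0):
        return NO_ESTIMATE, False
    freqs, mag = _spectrum(heart_signal, fs)
    band = (freqs >= HEART_BAND[0]) & (freqs <= HEART_BAND[1])
    f_band, m_band = freqs[band], mag[band]

    peak_idx, _ = find_peaks(m_band)
    if peak_idx.size == 0:                 # monotone spectrum: use band max
        peak_idx = np.array([int(np.argmax(m_band))])
    order = peak_idx[np.argsort(m_band[peak_idx])[::-1][:n_peaks]]
    candidates = f_band[order]             # by descending magnitude
    magnitudes = m_band[order]

    if fr_hz is None or not np.isfinite(fr_hz) or fr_hz <= 0:
        return float(60.0 * candidates[0]), False

    ks = np.arange(2, int(np.floor(HEART_BAND[1] / fr_hz)) + 1)
    harmonics = ks * fr_hz
    for f, m in zip(candidates, magnitudes):
        is_harmonic = harmonics.size > 0 and np.min(np.abs(f - harmonics)) <= harmonic_tol
        if not is_harmonic and m >= rel_floor * magnitudes[0]:
            return float(60.0 * f), False
    return float(60.0 * candidates[0]), True


@dataclass(frozen=True)
class CardioConfig:
    """Windowing and peak-picking parameters for rate estimation."""

    window: float = 20.0        # analysis window (s)
    step: float = 1.0           # update step (s)
    resp_band: tuple[float, float] = RESP_BAND
    heart_band: tuple[float, float] = HEART_BAND
    n_peaks: int = 4
    harmonic_tol: float = 0.04  # Hz, around k*fr
    rel_floor: float = 0.3      # min peak magnitude relative to the largest


def sliding_vitals(
    phase: PhaseSignal,
    cfg: CardioConfig = CardioConfig(),
    stable_mask: np.ndarray | None = None,
) -> VitalSeries:
    """Sliding-window RR/HR over the differenced phase signal.

    Windows are placed at end times ``window, window+step, ...``; a window
    overlapping any non-stable frame (per ``stable_mask``, aligned with the
    phase samples) yields a gap record instead of estimates.
    """
    fs = phase.fs
    # re-align the (one-shorter) difference signal with the frame grid so
    # that window end times land on frame timestamps
    sig = np.concatenate([[0.0], phase.diffed])
    n_win = int(round(cfg.window * fs))
    n_step = max(1, int(round(cfg.step * fs)))
    if len(sig) < n_win:
        warnings.warn("signal shorter than one analysis window", stacklevel=2)
        return VitalSeries(np.array([]), np.array([]), np.array([]), [],
                           window=cfg.window, step=cfg.step)
    if stable_mask is not None:
        stable_mask = np.asarray(stable_mask, dtype=bool)

    times, rrs, hrs, flags = [], [], [], []
    for start in range(0, len(sig) - n_win + 1, n_step):
        end = start + n_win
        times.append(end / fs)
        if stable_mask is not None and not stable_mask[start:end].all():
            rrs.append(NO_ESTIMATE)
            hrs.append(NO_ESTIMATE)
            flags.append(FLAG_GAP)
            continue
        chunk = sig[start:end]
        resp = bandpass(chunk, cfg.resp_band, fs)
        heart = bandpass(chunk, cfg.heart_band, fs)
        rr = estimate_respiration_rate(resp, fs)
        fr_hz = rr / 60.0 if np.isfinite(rr) else None
        hr, fell_back = estimate_heart_rate(
            heart, fs, fr_hz=fr_hz, n_peaks=cfg.n_peaks,
            harmonic_tol=cfg.harmonic_tol, rel_floor=cfg.rel_floor)
        rrs.append(rr)
        hrs.append(hr)
        flags.append(FLAG_FALLBACK if fell_back else "")
    return VitalSeries(
        timestamps=np.array(times), rr=np.array(rrs), hr=np.array(hrs),
        flags=flags, window=cfg.window, step=cfg.step)


def interbeat_rate(signal: np.ndarray, fs: float) -> float:
    """Time-domain cross-check: 60 / median inter-peak interval (BPM).

    Optional sanity check on the spectral estimate; NaN with < 2 peaks.
    """
    signal = np.asarray(signal, dtype=float)
    peaks, _ = find_peaks(signal, height=0.0)
    if peaks.size < 2:
        return NO_ESTIMATE
    return float(60.0 * fs / np.median(np.diff(peaks)))
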