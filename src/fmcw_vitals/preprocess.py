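"""Raw IF cubes -> clutter-removed range profiles.

Per frame: average the M chirps into one (chirp integration, which cuts
uncorrelated phase noise variance by 1/M), window, zero-pad and FFT across
fast time (the range FFT), then run the recursive per-bin static-clutter
filter

    X'_m(k) = alpha * X_m(k) + (1 - alpha) * X'_{m-1}(k)
    Y_m(k)  = X_m(k) - X'_m(k)

which subtracts a running exponential average, i.e. a slow-time high-pass
whose cutoff scales with alpha.  alpha defaults to 0.05 so that at 20
frames/s the filter's corner sits well below the 0.1-Hz respiration band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft

from .sim import IFFrameCube

DEFAULT_ALPHA = 0.05


def integrate_chirps(frame: np.ndarray) -> np.ndarray:
    """Average the chirps of one frame into a single chirp.

    Parameters
    ----------
    frame : complex array, shape (chirps, samples)

    Returns
    -------
    complex array of length ``samples``.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.shape[0] < 1:
        raise ValueError("frame must be a non-empty chirps x samples array")
    return frame.mean(axis=0)


def range_fft(chirp: np.ndarray, n_fft: int, window: str | None = "hann") -> np.ndarray:
    """Range FFT of one integrated chirp.

    Bin ``k`` corresponds to IF frequency ``k*f_adc/n_fft`` and hence range
    ``k*c*f_adc/(2*gamma*n_fft)``.  A Hann window is applied by default to
    control leakage between adjacent range bins; ``window=None`` disables it.
    """
    chirp = np.asarray(chirp)
    n = chirp.shape[-1]
    if n_fft < n:
        raise ValueError(f"n_fft={n_fft} would truncate a {n}-sample chirp")
    if window is not None:
        if window != "hann":
            raise ValueError(f"unsupported window {window!r}")
        chirp = chirp * np.hanning(n)
    return fft(chirp, n=n_fft, axis=-1)


def remove_static_clutter(
    X_m: np.ndarray, prev_state: np.ndarray | None, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the recursive static-clutter filter.

    ``prev_state=None`` initialises the running average to ``X_m`` itself,
    so the first output is exactly zero and presence detection sees no
    startup transient.

    Returns ``(Y_m, new_state)``.
    """
    X_m = np.asarray(X_m)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if prev_state is None:
        prev_state = X_m
    else:
        prev_state = np.asarray(prev_state)
        if prev_state.shape != X_m.shape:
            raise ValueError("filter state shape does not match the profile")
    new_state = alpha * X_m + (1.0 - alpha) * prev_state
    return X_m - new_state, new_state


class ClutterFilter:
    """Stateful wrapper around :func:`remove_static_clutter` for streaming."""

    def __init__(self, alpha: float = DEFAULT_ALPHA):
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        self.alpha = alpha
        self.state: np.ndarray | None = None

    def __call__(self, X_m: np.ndarray) -> np.ndarray:
        Y, self.state = remove_static_clutter(X_m, self.state, self.alpha)
        return Y


@dataclass
class RangeProfileSeries:
    """Per-frame range-FFT rows before/after clutter removal."""

    X: np.ndarray               # frames x n_fft, raw range FFT
    Y: np.ndarray               # frames x n_fft, clutter-removed
    alpha: float
    frame_rate: float
    filter_state: np.ndarray | None = None  # running X' after the last frame

    @property
    def magnitude(self) -> np.ndarray:
        """|Y| per frame, the profile the detector scans."""
        return np.abs(self.Y)

    @property
    def n_fft(self) -> int:
        return self.X.shape[1]


def preprocess_cube(
    cube: IFFrameCube,
    alpha: float = DEFAULT_ALPHA,
    n_fft: int | None = None,
    window: str | None = "hann",
    init_state: np.ndarray | None = None,
) -> RangeProfileSeries:
    """Full preprocessing chain over a cube, threading filter state.

    ``n_fft`` defaults to the next power of two >= samples per chirp.
    ``init_state`` lets a caller resume a stream split across cubes.
    """
    n = cube.config.n_samples
    if n_fft is None:
        n_fft = 1 << (n - 1).bit_length()
    chirps = np.array([integrate_chirps(f) for f in cube.data])
    X = range_fft(chirps, n_fft, window=window)
    Y = np.empty_like(X)
    state = init_state
    for m in range(X.shape[0]):
        Y[m], state = remove_static_clutter(X[m], state, alpha)
    return RangeProfileSeries(X=X, Y=Y, alpha=alpha,
                              frame_rate=cube.config.frame_rate,
                              filter_state=state)
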