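"""Target-state detection and range-bin selection on range profiles.

The detector fuses two modalities computed per frame on the clutter-removed
magnitude profile:

* **Frequency domain** — a CFAR-style *confidence value*: the energy of the
  peak range bin divided by the averaged energy of the T training cells on
  each side of it (G guard cells excluded, edges handled circularly).
  Accumulated over a trailing window of v frames and compared with a
  threshold trained on an empty-room recording, it decides human presence.
* **Time domain** — the unbiased sample variance of the peak-bin index over
  a 2-s sliding window.  Low variance means the detected body is holding
  still (stable), high variance means large random motion.

Per-frame raw states (unmanned / motion / stable) enter a 2-s buffer; the
emitted state switches only when one raw state occupies more than 80% of the
buffer, otherwise the previous emitted state is retained.  Within stable
runs the selected target bin is the running median of the peak bin over a
2-s window, which suppresses single-frame outliers.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import RangeProfileSeries
from .sim import STATE_CODES, STATE_MOTION, STATE_NAMES, STATE_STABLE, STATE_UNMANNED


@dataclass(frozen=True)
class ConfidenceConfig:
    """Cell layout and accumulation for the presence test."""

    guard: int = 2            # single-side guard cells G
    train: int = 4            # single-side training cells T
    accum: int = 8            # accumulation span v (frames)
    window: int = 40          # presence window (frames) = 2 s at 20 Hz
    scan_start: int = 1       # first range bin scanned (0-based, inclusive)
    scan_end: int | None = None   # one past the last bin scanned; None = n_fft
    threshold: float = 1.0    # presence threshold on Vsum
    eps_scale: float = 1e-12  # training-energy floor, relative to max energy

    def __post_init__(self) -> None:
        if self.guard < 0 or self.train < 1 or self.accum < 1:
            raise ValueError("need guard >= 0, train >= 1, accum >= 1")
        if self.scan_end is not None and self.scan_start >= self.scan_end:
            raise ValueError("empty scan range")
        if self.threshold <= 0 or self.eps_scale <= 0:
            raise ValueError("threshold and eps_scale must be positive")


@dataclass(frozen=True)
class StateConfig:
    """Windows and thresholds for the three-state classifier."""

    var_window: int = 40      # frames feeding the range-bin variance
    var_threshold: float = 0.3  # bin^2; stable below, motion above
    buffer_len: int = 40      # state-buffer length (frames)
    proportion: float = 0.8   # fraction of the buffer needed to switch state
    median_window: int = 40   # bin median-smoothing window (frames)

    def __post_init__(self) -> None:
        if not 0.5 < self.proportion <= 1.0:
            raise ValueError("proportion must lie in (0.5, 1]")
        if min(self.var_window, self.buffer_len, self.median_window) < 2:
            raise ValueError("all windows must span at least 2 frames")


def confidence_value(mag: np.ndarray, cfg: ConfidenceConfig) -> tuple[float, int]:
    """Confidence value V and peak bin D for one magnitude profile.

    ``V = P(D) / (PT + eps)`` with ``P = mag**2``,
    ``PT = mean(left T training cells) + mean(right T training cells)``,
    training cells at offsets G+1 ... G+T from D on each side, indices
    wrapped circularly.  Ties in the argmax go to the lowest bin.
    """
    mag = np.asarray(mag, dtype=float)
    n = mag.shape[0]
    if n < 2 * (cfg.guard + cfg.train) + 1:
        raise ValueError(
            f"profile of {n} bins shorter than the {2*(cfg.guard+cfg.train)+1}-cell window")
    end = n if cfg.scan_end is None else cfg.scan_end
    if not 0 <= cfg.scan_start < end <= n:
        raise ValueError(f"scan range [{cfg.scan_start}, {end}) invalid for {n} bins")

    energy = mag * mag
    seg = energy[cfg.scan_start:end]
    D = cfg.scan_start + int(np.argmax(seg))  # argmax takes the first maximum

    offsets = np.arange(cfg.guard + 1, cfg.guard + cfg.train + 1)
    left = energy[(D - offsets) % n]
    right = energy[(D + offsets) % n]
    PT = left.mean() + right.mean()
    eps = cfg.eps_scale * energy.max() + np.finfo(float).tiny
    return float(energy[D] / (PT + eps)), D


def accumulate_confidence(V_history: np.ndarray, v: int) -> float:
    """Trailing sum of the most recent ``min(v, len)`` confidence values."""
    if v < 1:
        raise ValueError("accumulation span must be >= 1")
    V_history = np.asarray(V_history, dtype=float)
    if V_history.size == 0:
        raise ValueError("empty confidence history")
    return float(V_history[-v:].sum())


def calibrate_presence_threshold(background_Vsum: np.ndarray, k: float = 3.0) -> float:
    """Presence threshold from an empty-room recording: mean + k*sd.

    ``k`` trades miss rate against false alarms; lowering it keeps faint
    targets from being classed as noise.
    """
    v = np.asarray(background_Vsum, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 background samples")
    return float(v.mean() + k * v.std(ddof=1))


def range_bin_variance(bins: np.ndarray) -> float:
    """Unbiased sample variance of peak-bin indices over a window."""
    bins = np.asarray(bins, dtype=float)
    if bins.size < 2:
        raise ValueError("variance needs at least 2 frames")
    return float(np.var(bins, ddof=1))


@dataclass
class StateBuffer:
    """Raw-state history plus the last emitted state (hysteresis memory)."""

    maxlen: int
    raw: deque = field(default_factory=deque)
    emitted: str = STATE_UNMANNED

    def __post_init__(self) -> None:
        self.raw = deque(self.raw, maxlen=self.maxlen)


def update_state(
    Vsum: float,
    s2: float,
    cfg: ConfidenceConfig,
    scfg: StateConfig,
    buffer: StateBuffer,
) -> tuple[str, StateBuffer]:
    """Classify one frame and emit the buffered (hysteresis) state.

    Raw state: unmanned if ``Vsum <= threshold``, else stable if
    ``s2 < var_threshold``, else motion.  The raw state is pushed into the
    buffer; the emitted state switches to whichever raw state occupies more
    than ``proportion`` of the buffer, else the previous emitted state is
    retained.  The buffer is mutated in place and returned.
    """
    if Vsum <= cfg.threshold:
        raw = STATE_UNMANNED
    elif s2 < scfg.var_threshold:
        raw = STATE_STABLE
    else:
        raw = STATE_MOTION
    buffer.raw.append(raw)
    counts = {s: 0 for s in STATE_CODES}
    for s in buffer.raw:
        counts[s] += 1
    for state, count in counts.items():
        if count > scfg.proportion * len(buffer.raw):
            buffer.emitted = state
            break
    return buffer.emitted, buffer


def select_target_bin(
    D_series: np.ndarray, state_series: list[str], scfg: StateConfig
) -> np.ndarray:
    """Median-smoothed target bin per frame; NaN outside stable runs.

    Within each contiguous stable run the output is the running median of D
    over the trailing ``median_window`` frames, truncated at the run start.
    """
    D_series = np.asarray(D_series)
    if len(D_series) != len(state_series):
        raise ValueError("D and state series must be aligned per frame")
    out = np.full(len(D_series), np.nan)
    run: deque = deque(maxlen=scfg.median_window)
    for i, state in enumerate(state_series):
        if state == STATE_STABLE:
            run.append(D_series[i])
            out[i] = float(np.median(run))
        else:
            run.clear()
    return out


@dataclass
class StateTrack:
    """Per-frame detector outputs over a profile series."""

    V: np.ndarray
    Vsum: np.ndarray
    D: np.ndarray
    s2: np.ndarray
    state: list[str]
    selected_bin: np.ndarray    # NaN where no bin is emitted
    frame_rate: float

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.V)
        return pd.DataFrame({
            "frame": np.arange(n),
            "time_s": np.arange(n) / self.frame_rate,
            "V": self.V,
            "Vsum": self.Vsum,
            "D": self.D,
            "s2": self.s2,
            "state": self.state,
            "state_code": [STATE_CODES[s] for s in self.state],
            "selected_bin": self.selected_bin,
        })

    @property
    def state_codes(self) -> np.ndarray:
        return np.array([STATE_CODES[s] for s in self.state])


class StateTracker:
    """Streaming frame-by-frame detector; carries all sliding-window state.

    Feeding frames one at a time (possibly across separate profile chunks)
    produces exactly the same outputs as one batch pass.
    """

    def __init__(self, cfg: ConfidenceConfig, scfg: StateConfig):
        self.cfg = cfg
        self.scfg = scfg
        self._V = deque(maxlen=cfg.accum)
        self._bins = deque(maxlen=scfg.var_window)   # presence frames only
        self._buffer = StateBuffer(maxlen=scfg.buffer_len)
        self._median_run: deque = deque(maxlen=scfg.median_window)

    def step(self, mag: np.ndarray) -> dict:
        """Process one magnitude profile; returns the per-frame record."""
        V, D = confidence_value(mag, self.cfg)
        self._V.append(V)
        Vsum = accumulate_confidence(np.array(self._V), self.cfg.accum)

        present = Vsum > self.cfg.threshold
        if present:
            self._bins.append(D)
        else:
            self._bins.clear()
        s2 = range_bin_variance(np.array(self._bins)) if len(self._bins) >= 2 else 0.0

        state, self._buffer = update_state(Vsum, s2, self.cfg, self.scfg, self._buffer)

        if state == STATE_STABLE:
            self._median_run.append(D)
            selected = float(np.median(self._median_run))
        else:
            self._median_run.clear()
            selected = np.nan
        return {"V": V, "Vsum": Vsum, "D": D, "s2": s2,
                "state": state, "selected_bin": selected}

    def track(self, profiles: RangeProfileSeries) -> StateTrack:
        """Run the detector over a whole profile series."""
        records = [self.step(m) for m in profiles.magnitude]
        return StateTrack(
            V=np.array([r["V"] for r in records]),
            Vsum=np.array([r["Vsum"] for r in records]),
            D=np.array([r["D"] for r in records]),
            s2=np.array([r["s2"] for r in records]),
            state=[r["state"] for r in records],
            selected_bin=np.array([r["selected_bin"] for r in records]),
            frame_rate=profiles.frame_rate,
        )


def track_states(
    profiles: RangeProfileSeries, cfg: ConfidenceConfig, scfg: StateConfig
) -> StateTrack:
    """Batch convenience wrapper over :class:`StateTracker`."""
    return StateTracker(cfg, scfg).track(profiles)


def calibrate_from_profiles(
    profiles: RangeProfileSeries, cfg: ConfidenceConfig, k: float = 3.0
) -> float:
    """Train the presence threshold from an unmanned profile series."""
    V = np.array([confidence_value(m, cfg)[0] for m in profiles.magnitude])
    if V.size < 10:
        raise ValueError("need at least 10 background frames for calibration")
    Vsum = np.array([
        accumulate_confidence(V[: i + 1], cfg.accum) for i in range(V.size)
    ])
    return calibrate_presence_threshold(Vsum, k=k)
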