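"""Synthetic FMCW intermediate-frequency (IF) data cubes with ground truth.

The simulator generates the post-mixer IF model directly: for a reflector at
instantaneous range ``R = R0 + x(t)`` the round-trip delay is ``tau = 2R/c``,
the beat frequency is ``f_IF = gamma * tau`` and the IF phase offset is
``2*pi*fc*tau = 4*pi*R/lambda``.  Each ADC sample ``n`` of a chirp holds

    sum_reflectors  A * exp(j*2*pi*(f_IF*t_n + fc*tau))  +  noise

with ``t_n = n / f_adc``.  The quadratic delay term is negligible for
indoor ranges and is not generated.  Chest micro-displacement (< 5 Hz) is
quasi-static over one frame, so ``x(t)`` is frozen per frame.

Scenes are scripted through :class:`Scenario`: ordered segments tagged
``unmanned`` / ``stable`` / ``motion``, physiological frequencies for the
respiration and heartbeat sinusoids, static clutter reflectors and
circularly-symmetric complex Gaussian background noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

C_LIGHT = 299_792_458.0

STATE_UNMANNED = "unmanned"
STATE_MOTION = "motion"
STATE_STABLE = "stable"

#: integer codes used in file containers: 0=unmanned, 1=motion, 2=stable
STATE_CODES = {STATE_UNMANNED: 0, STATE_MOTION: 1, STATE_STABLE: 2}
STATE_NAMES = {v: k for k, v in STATE_CODES.items()}


class ScenarioError(ValueError):
    """Raised for ill-formed scene specifications."""


@dataclass(frozen=True)
class RadarConfig:
    """Chirp/frame timing and RF parameters of the FMCW front end.

    Defaults describe a 25.5-GHz radar (centre of a 23.5-27.5 GHz band)
    sweeping 2.5 GHz in 32 us, 32 chirps per 50-ms frame: the phase signal
    is sampled at 20 Hz and one range bin spans ~6 cm.
    """

    fc: float = 25.5e9          # carrier frequency (Hz)
    gamma: float = 7.8125e13    # chirp slope (Hz/s); 2.5 GHz over 32 us
    Tc: float = 40e-6           # chirp repetition period (s)
    n_samples: int = 64         # ADC samples per chirp (N)
    n_chirps: int = 32          # chirps per frame (M)
    frame_period: float = 0.05  # frame repetition interval (s)
    f_adc: float = 2e6          # ADC sampling rate (Hz)
    c: float = C_LIGHT          # propagation speed (m/s)

    def __post_init__(self) -> None:
        if self.fc <= 0 or self.gamma <= 0 or self.Tc <= 0:
            raise ValueError("fc, gamma and Tc must be positive")
        if self.n_samples < 2:
            raise ValueError("need at least 2 ADC samples per chirp")
        if self.n_chirps < 1:
            raise ValueError("need at least 1 chirp per frame")
        if self.frame_period < self.Tc * self.n_chirps:
            raise ValueError("frame_period shorter than the chirp train")
        if self.f_adc <= 0:
            raise ValueError("f_adc must be positive")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength c/fc (m)."""
        return self.c / self.fc

    @property
    def frame_rate(self) -> float:
        """Slow-time sampling rate 1/frame_period (Hz)."""
        return 1.0 / self.frame_period

    def beat_frequency(self, r: float) -> float:
        """IF (beat) frequency 2*gamma*r/c for a reflector at range r."""
        return 2.0 * self.gamma * r / self.c

    def range_bin(self, r: float, n_fft: int) -> int:
        """Nearest range-FFT bin for range r at the given FFT length."""
        return int(round(self.beat_frequency(r) * n_fft / self.f_adc))

    def bin_to_range(self, k: int, n_fft: int) -> float:
        """Centre range (m) of bin k: k*c*f_adc/(2*gamma*n_fft)."""
        return k * self.c * self.f_adc / (2.0 * self.gamma * n_fft)

    def to_dict(self) -> dict:
        return {
            "fc": self.fc, "gamma": self.gamma, "Tc": self.Tc,
            "n_samples": self.n_samples, "n_chirps": self.n_chirps,
            "frame_period": self.frame_period, "f_adc": self.f_adc,
            "c": self.c,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RadarConfig":
        d = dict(d)
        for key in ("n_samples", "n_chirps"):
            if key in d:
                d[key] = int(d[key])
        return cls(**{k: d[k] for k in (
            "fc", "gamma", "Tc", "n_samples", "n_chirps",
            "frame_period", "f_adc", "c") if k in d})


@dataclass
class Reflector:
    """A point reflector: static clutter or the human target.

    ``displacement`` is a per-frame micro-displacement trace in metres,
    all-zero (None) for static clutter.
    """

    R0: float
    amplitude: float = 1.0
    displacement: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("reflector range must be positive")
        if self.amplitude < 0:
            raise ValueError("reflector amplitude must be non-negative")


@dataclass
class Scenario:
    """A scripted scene: state segments, vital frequencies, clutter, noise.

    ``segments`` is an ordered list of ``(start_s, end_s, state)`` tuples
    tiling ``[0, duration]``.  Vitals are two sinusoids on the chest
    surface; the ``motion`` state adds a seeded Gaussian random walk with
    per-frame step sd ``motion_amp`` (clipped so the target stays in the
    radar's unambiguous range).
    """

    duration: float
    segments: list[tuple[float, float, str]]
    target_range: float = 1.0
    target_amplitude: float = 1.0
    fr: float = 0.25            # respiration frequency (Hz)
    fh: float = 1.25            # heartbeat frequency (Hz)
    resp_amp: float = 1e-3      # respiration displacement amplitude (m)
    heart_amp: float = 1e-4     # heartbeat displacement amplitude (m)
    motion_amp: float = 0.05    # random-walk step sd in motion state (m/frame)
    motion_rho: float = 0.95    # per-frame mean reversion of the motion walk
    motion_jitter: float = 0.05  # white frame-scale jitter in motion state (m)
    clutter: list[Reflector] = field(default_factory=list)
    noise_sigma: float = 0.1    # complex-noise standard deviation
    seed: int = 0
    range_limits: tuple[float, float] = (0.3, 2.2)

    def __post_init__(self) -> None:
        self._validate_segments()
        if self.resp_amp < 0 or self.heart_amp < 0:
            raise ValueError("displacement amplitudes must be non-negative")
        if self.resp_amp and self.heart_amp and self.resp_amp <= self.heart_amp:
            raise ValueError("respiration amplitude must exceed heartbeat amplitude")
        if self._has_vitals():
            if not 0.1 <= self.fr <= 0.6:
                warnings.warn(
                    f"respiration frequency {self.fr} Hz outside the "
                    "0.1-0.6 Hz filter band", stacklevel=2)
            if not 0.8 <= self.fh <= 4.0:
                warnings.warn(
                    f"heartbeat frequency {self.fh} Hz outside the "
                    "0.8-4 Hz filter band", stacklevel=2)

    def _has_vitals(self) -> bool:
        return any(s[2] != STATE_UNMANNED for s in self.segments) and (
            self.resp_amp > 0 or self.heart_amp > 0)

    def _validate_segments(self) -> None:
        if not self.segments:
            raise ScenarioError("scenario needs at least one segment")
        pos = 0.0
        for start, end, state in self.segments:
            if state not in STATE_CODES:
                raise ScenarioError(f"unknown state {state!r}")
            if abs(start - pos) > 1e-9:
                raise ScenarioError(
                    f"segments must tile [0, duration]: gap/overlap at {start} s")
            if end <= start:
                raise ScenarioError("segment end must exceed its start")
            pos = end
        if abs(pos - self.duration) > 1e-9:
            raise ScenarioError(
                f"segments end at {pos} s but duration is {self.duration} s")

    def state_at(self, t: float) -> str:
        if t < 0 or t > self.duration:
            raise ValueError(f"t={t} outside [0, {self.duration}]")
        for start, end, state in self.segments:
            if start <= t < end:
                return state
        return self.segments[-1][2]


@dataclass
class IFFrameCube:
    """Raw IF data: frames x chirps x samples, with optional ground truth."""

    data: np.ndarray
    config: RadarConfig
    truth_state: np.ndarray | None = None   # int codes per frame
    truth_bin: np.ndarray | None = None     # true target bin (-1 if absent)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("IF cube must be frames x chirps x samples")
        frames, chirps, samples = self.data.shape
        if chirps != self.config.n_chirps or samples != self.config.n_samples:
            raise ValueError(
                f"cube shape {self.data.shape[1:]} does not match config "
                f"({self.config.n_chirps}, {self.config.n_samples})")
        for name in ("truth_state", "truth_bin"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != frames:
                raise ValueError(f"{name} length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def build_scenario(spec: dict) -> Scenario:
    """Build a validated :class:`Scenario` from a plain-dict description.

    ``spec`` mirrors the YAML scene file: ``duration``, ``segments`` (list of
    ``[start, end, state]``), optional vitals/clutter/noise keys.  Clutter
    entries are ``{range: m, amplitude: a}`` dicts.
    """
    spec = dict(spec)
    clutter = [
        Reflector(R0=float(c["range"]), amplitude=float(c.get("amplitude", 1.0)))
        for c in spec.pop("clutter", [])
    ]
    segments = [(float(s[0]), float(s[1]), str(s[2])) for s in spec.pop("segments")]
    known = {
        "duration", "target_range", "target_amplitude", "fr", "fh",
        "resp_amp", "heart_amp", "motion_amp", "noise_sigma", "seed",
        "range_limits",
    }
    extra = set(spec) - known
    if extra:
        raise ScenarioError(f"unknown scenario keys: {sorted(extra)}")
    if "range_limits" in spec:
        spec["range_limits"] = tuple(spec["range_limits"])
    if "seed" in spec:
        spec["seed"] = int(spec["seed"])
    return Scenario(segments=segments, clutter=clutter, **spec)


def displacement_trace(
    scenario: Scenario, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chest displacement x(t) on a time grid, with per-sample truth.

    Returns ``(x, present, labels)``: displacement in metres (0 where the
    target is absent), a boolean presence mask, and the state label codes.
    In stable segments ``x = resp_amp*sin(2*pi*fr*t) + heart_amp*sin(2*pi*fh*t)``;
    motion segments add a seeded mean-reverting Gaussian random walk
    (per-step sd ``motion_amp``, reversion factor ``motion_rho`` toward the
    seat position — a pure walk would drift to the range clamp and sit
    there, reading as a stationary target rather than large random motion)
    plus white frame-scale jitter of sd ``motion_jitter``, reproducing the
    frame-to-frame scatter of detected bins that characterises a moving
    body.  The walk is clipped to keep ``R0 + x`` within ``range_limits``.
    """
    t = np.asarray(t, dtype=float)
    if t.size and (t.min() < 0 or t.max() > scenario.duration + 1e-9):
        raise ValueError("time grid outside the scenario duration")

    labels = np.array([STATE_CODES[scenario.state_at(ti)] for ti in t])
    present = labels != STATE_CODES[STATE_UNMANNED]

    x = np.zeros_like(t)
    vit = (scenario.resp_amp * np.sin(2 * np.pi * scenario.fr * t)
           + scenario.heart_amp * np.sin(2 * np.pi * scenario.fh * t))
    x[present] = vit[present]

    # seeded random walk over motion samples; walk resets on re-entry
    rng = np.random.default_rng(scenario.seed)
    lo = scenario.range_limits[0] - scenario.target_range
    hi = scenario.range_limits[1] - scenario.target_range
    walk = 0.0
    in_motion = labels == STATE_CODES[STATE_MOTION]
    for i in np.flatnonzero(in_motion):
        if i == 0 or not in_motion[i - 1]:
            walk = 0.0
        walk = float(np.clip(
            scenario.motion_rho * walk + rng.normal(0.0, scenario.motion_amp),
            lo, hi))
        x[i] += np.clip(walk + rng.normal(0.0, scenario.motion_jitter), lo, hi)
    return x, present, labels


def synthesize_if_cube(config: RadarConfig, scenario: Scenario) -> IFFrameCube:
    """Render a scenario into a raw IF frame cube with per-frame truth.

    Displacement is evaluated at each frame start and held constant over the
    frame's chirps.  Deterministic for a given ``scenario.seed``.
    """
    n_frames = int(np.floor(scenario.duration / config.frame_period))
    if n_frames < 1:
        raise ValueError("scenario shorter than one frame")
    if (not scenario.clutter and scenario.target_amplitude == 0
            and scenario.noise_sigma == 0):
        warnings.warn("empty scene with no noise: cube is all zero",
                      stacklevel=2)

    t_frames = np.arange(n_frames) * config.frame_period
    x, present, labels = displacement_trace(scenario, t_frames)

    tn = np.arange(config.n_samples) / config.f_adc  # fast time within a chirp
    cube = np.zeros((n_frames, config.n_chirps, config.n_samples),
                    dtype=np.complex128)

    # fc is the centre frequency of the sampled sweep (e.g. 25.5 GHz for a
    # 23.5-27.5 GHz radar); the chirp therefore starts at fc - B/2, which
    # makes the slow-time phase sensitivity of the range-FFT peak exactly
    # 4*pi/lambda at the quoted operating wavelength.
    f_start = config.fc - config.gamma * (config.n_samples - 1) / (2 * config.f_adc)

    def add_reflector(mask: np.ndarray, ranges: np.ndarray, amp: float) -> None:
        # tau per frame; one chirp row broadcast over the frame's chirps
        tau = 2.0 * ranges / config.c
        f_if = config.gamma * tau
        phase = 2.0 * np.pi * (np.outer(f_if, tn) + (f_start * tau)[:, None])
        cube[mask] += amp * np.exp(1j * phase)[:, None, :]

    if np.any(present) and scenario.target_amplitude > 0:
        add_reflector(present, scenario.target_range + x[present],
                      scenario.target_amplitude)
    for refl in scenario.clutter:
        r = np.full(n_frames, refl.R0)
        if refl.displacement is not None:
            r = r + np.asarray(refl.displacement)[:n_frames]
        add_reflector(np.ones(n_frames, dtype=bool), r, refl.amplitude)

    if scenario.noise_sigma > 0:
        rng = np.random.default_rng(scenario.seed + 1)
        scale = scenario.noise_sigma / np.sqrt(2.0)
        cube += rng.normal(0.0, scale, cube.shape) \
            + 1j * rng.normal(0.0, scale, cube.shape)

    n_fft = 1 << (config.n_samples - 1).bit_length()
    truth_bin = np.where(
        present,
        [config.range_bin(scenario.target_range + xi, n_fft) for xi in x],
        -1,
    )
    return IFFrameCube(data=cube, config=config,
                       truth_state=labels, truth_bin=truth_bin)
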