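"""Containers, configuration and the end-to-end pipeline driver.

IF cubes travel in HDF5: datasets ``if_real``/``if_imag`` (frames x chirps x
samples), optional ``truth_state`` (0=unmanned, 1=motion, 2=stable) and
``truth_bin`` (-1 = absent), radar parameters as root attributes, plus a
JSON sidecar mirroring the attributes for tool-agnostic reading.  Range-bin
coordinates in all outputs are 0-based.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import cardio, detect, metrics, preprocess
from .cardio import CardioConfig, VitalSeries
from .detect import ConfidenceConfig, StateConfig, StateTrack
from .preprocess import DEFAULT_ALPHA
from .sim import STATE_STABLE, IFFrameCube, RadarConfig

logger = logging.getLogger("fmcw_vitals")

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Raised when a cube container is missing required datasets."""


def write_if_cube(path: str | Path, cube: IFFrameCube) -> None:
    """Write a cube to HDF5 with a JSON config sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for key, val in cube.config.to_dict().items():
            f.attrs[key] = val
        f.create_dataset("if_real", data=cube.data.real)
        f.create_dataset("if_imag", data=cube.data.imag)
        if cube.truth_state is not None:
            f.create_dataset("truth_state", data=np.asarray(cube.truth_state, dtype=np.int8))
        if cube.truth_bin is not None:
            f.create_dataset("truth_bin", data=np.asarray(cube.truth_bin, dtype=np.int32))
    sidecar = {"schema_version": SCHEMA_VERSION,
               "range_bin_indexing": "0-based",
               **cube.config.to_dict()}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))


def read_if_cube(path: str | Path) -> IFFrameCube:
    """Read a cube container; truth datasets are optional."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unrecognised schema version {version}")
        for name in ("if_real", "if_imag"):
            if name not in f:
                raise SchemaError(f"missing dataset {name!r}")
        data = f["if_real"][()] + 1j * f["if_imag"][()]
        config = RadarConfig.from_dict({k: f.attrs[k] for k in (
            "fc", "gamma", "Tc", "n_samples", "n_chirps",
            "frame_period", "f_adc", "c")})
        truth_state = f["truth_state"][()] if "truth_state" in f else None
        truth_bin = f["truth_bin"][()] if "truth_bin" in f else None
    return IFFrameCube(data=data, config=config,
                       truth_state=truth_state, truth_bin=truth_bin)


@dataclass
class PipelineConfig:
    """All tunables of the processing chain in one round-trippable document."""

    radar: RadarConfig = field(default_factory=RadarConfig)
    clutter_alpha: float = DEFAULT_ALPHA
    confidence: ConfidenceConfig = field(default_factory=ConfidenceConfig)
    state: StateConfig = field(default_factory=StateConfig)
    cardio: CardioConfig = field(default_factory=CardioConfig)
    resp_tol_bpm: float = metrics.RESP_ACCURACY_TOL
    heart_tol_bpm: float = metrics.HEART_ACCURACY_TOL
    seed: int = 0

    def to_dict(self) -> dict:
        c = self.confidence
        s = self.state
        k = self.cardio
        return {
            "radar": self.radar.to_dict(),
            "clutter_alpha": self.clutter_alpha,
            "confidence": {
                "guard": c.guard, "train": c.train, "accum": c.accum,
                "window": c.window, "scan_start": c.scan_start,
                "scan_end": c.scan_end, "threshold": c.threshold,
                "eps_scale": c.eps_scale,
            },
            "state": {
                "var_window": s.var_window, "var_threshold": s.var_threshold,
                "buffer_len": s.buffer_len, "proportion": s.proportion,
                "median_window": s.median_window,
            },
            "cardio": {
                "window": k.window, "step": k.step,
                "resp_band": list(k.resp_band), "heart_band": list(k.heart_band),
                "n_peaks": k.n_peaks, "harmonic_tol": k.harmonic_tol,
                "rel_floor": k.rel_floor,
            },
            "eval": {"resp_tol_bpm": self.resp_tol_bpm,
                     "heart_tol_bpm": self.heart_tol_bpm},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kd = dict(d.get("cardio", {}))
        for key in ("resp_band", "heart_band"):
            if key in kd:
                kd[key] = tuple(kd[key])
        ev = d.get("eval", {})
        return cls(
            radar=RadarConfig.from_dict(d.get("radar", {})),
            clutter_alpha=d.get("clutter_alpha", DEFAULT_ALPHA),
            confidence=ConfidenceConfig(**d.get("confidence", {})),
            state=StateConfig(**d.get("state", {})),
            cardio=CardioConfig(**kd),
            resp_tol_bpm=ev.get("resp_tol_bpm", metrics.RESP_ACCURACY_TOL),
            heart_tol_bpm=ev.get("heart_tol_bpm", metrics.HEART_ACCURACY_TOL),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(
    cube: IFFrameCube, cfg: PipelineConfig
) -> tuple[StateTrack, VitalSeries, dict]:
    """Preprocess -> detect -> extract vitals, with a run report.

    The phase signal is read from the *raw* range FFT at the selected bin
    (clutter removal shifts the phase of the target bin; it only feeds the
    detector).  Windows overlapping non-stable frames become gap records.
    """
    report: dict = {"stages": {}}
    t0 = time.perf_counter()
    profiles = preprocess.preprocess_cube(cube, alpha=cfg.clutter_alpha)
    report["stages"]["preprocess_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    track = detect.track_states(profiles, cfg.confidence, cfg.state)
    report["stages"]["detect_s"] = time.perf_counter() - t0

    stable = np.array([s == STATE_STABLE for s in track.state])
    t0 = time.perf_counter()
    if stable.sum() >= 2:
        bins = np.where(
            np.isfinite(track.selected_bin),
            np.round(track.selected_bin), 0).astype(int)
        values = np.where(
            stable, profiles.X[np.arange(len(bins)), bins], 1.0 + 0.0j)
        phase = cardio.extract_motion_signal(values, fs=profiles.frame_rate)
        vitals = cardio.sliding_vitals(phase, cfg.cardio, stable_mask=stable)
    else:
        vitals = VitalSeries(np.array([]), np.array([]), np.array([]), [],
                             window=cfg.cardio.window, step=cfg.cardio.step)
    report["stages"]["cardio_s"] = time.perf_counter() - t0

    transitions = [
        {"frame": int(i), "time_s": i / profiles.frame_rate,
         "from": track.state[i - 1], "to": track.state[i]}
        for i in range(1, len(track.state))
        if track.state[i] != track.state[i - 1]
    ]
    report["transitions"] = transitions
    for tr in transitions:
        logger.info("state %s -> %s at %.2f s", tr["from"], tr["to"], tr["time_s"])
    report["n_frames"] = cube.n_frames
    report["n_windows"] = len(vitals)
    report["n_gap_windows"] = sum(f == cardio.FLAG_GAP for f in vitals.flags)

    if cube.truth_state is not None:
        codes = track.state_codes
        truth = np.asarray(cube.truth_state)
        confusion = np.zeros((3, 3), dtype=int)
        for t, p in zip(truth, codes):
            confusion[int(t), int(p)] += 1
        report["state_confusion"] = confusion.tolist()
        report["state_agreement"] = float(np.mean(codes == truth))
    return track, vitals, report
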