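"""Error metrics and accuracy definitions for rate-series evaluation.

MAE and RMSE in BPM against a reference sensor, plus banded accuracy: the
fraction of estimates within a tolerance (2 BPM for respiration, 5 BPM for
heart rate is the conventional choice).  RMSE here is the root mean square
of the errors — note MAE <= RMSE always holds under this definition; a
report with RMSE < MAE is using some other convention (e.g. the standard
deviation of the errors) and is not reproducible by this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RESP_ACCURACY_TOL = 2.0   # BPM
HEART_ACCURACY_TOL = 5.0  # BPM


@dataclass
class RateComparison:
    """Aligned radar-estimated vs reference rates."""

    y: np.ndarray           # radar estimates (BPM)
    x: np.ndarray           # reference (BPM)
    timestamps: np.ndarray  # aligned times (s)
    n_dropped: int = 0      # points without a reference match

    @property
    def e(self) -> np.ndarray:
        """Absolute errors |y - x| (BPM)."""
        return np.abs(self.y - self.x)


def error_metrics(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """(MAE, RMSE) of estimates ``y`` against reference ``x``, in BPM."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.size == 0:
        raise ValueError("y and x must be equal-length and non-empty")
    err = y - x
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err ** 2)))


def rate_accuracy(y: np.ndarray, x: np.ndarray, tol: float) -> float:
    """Fraction of estimates within ``tol`` BPM of the reference."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.size == 0:
        raise ValueError("y and x must be equal-length and non-empty")
    return float(np.mean(np.abs(y - x) <= tol))


def minute_average(
    timestamps: np.ndarray, values: np.ndarray, span: float = 60.0
) -> pd.DataFrame:
    """Average estimates over consecutive ``span``-second segments.

    Returns a frame with segment start time, mean value, count and a
    ``partial`` flag on a trailing segment shorter than ``span``.
    NaN values are excluded from the means.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values, dtype=float)
    if timestamps.size == 0:
        return pd.DataFrame(columns=["t_start_s", "mean_bpm", "n", "partial"])
    t0 = timestamps.min()
    seg = np.floor((timestamps - t0) / span).astype(int)
    t_total = timestamps.max() - t0
    rows = []
    for s in np.unique(seg):
        mask = seg == s
        vals = values[mask]
        vals = vals[np.isfinite(vals)]
        rows.append({
            "t_start_s": t0 + s * span,
            "mean_bpm": float(vals.mean()) if vals.size else float("nan"),
            "n": int(mask.sum()),
            "partial": bool((s + 1) * span > t_total + 1e-9),
        })
    return pd.DataFrame(rows)


def align_series(
    t_y: np.ndarray, y: np.ndarray,
    t_x: np.ndarray, x: np.ndarray,
    max_gap: float = 0.5,
) -> RateComparison:
    """Pair estimates with the nearest reference sample within ``max_gap`` s.

    Unmatched estimate points (no reference within the gap, or a NaN on
    either side) are dropped and counted.
    """
    t_y = np.asarray(t_y, dtype=float)
    t_x = np.asarray(t_x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    order = np.argsort(t_x)
    t_x, x = t_x[order], x[order]
    idx = np.searchsorted(t_x, t_y)
    yy, xx, tt = [], [], []
    dropped = 0
    for i, t in enumerate(t_y):
        cands = [j for j in (idx[i] - 1, idx[i]) if 0 <= j < len(t_x)]
        if not cands:
            dropped += 1
            continue
        j = min(cands, key=lambda j: abs(t_x[j] - t))
        if abs(t_x[j] - t) > max_gap or not (
                np.isfinite(y[i]) and np.isfinite(x[j])):
            dropped += 1
            continue
        yy.append(y[i])
        xx.append(x[j])
        tt.append(t)
    return RateComparison(
        y=np.array(yy), x=np.array(xx), timestamps=np.array(tt),
        n_dropped=dropped)


def evaluate_rates(
    comparison: RateComparison, tol: float
) -> dict:
    """Metrics report for one aligned rate series."""
    if comparison.y.size == 0:
        return {"n": 0, "n_dropped": comparison.n_dropped,
                "mae_bpm": None, "rmse_bpm": None, "accuracy": None}
    mae, rmse = error_metrics(comparison.y, comparison.x)
    return {
        "n": int(comparison.y.size),
        "n_dropped": comparison.n_dropped,
        "mae_bpm": mae,
        "rmse_bpm": rmse,
        "accuracy": rate_accuracy(comparison.y, comparison.x, tol),
    }
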