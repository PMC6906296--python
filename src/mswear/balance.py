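"""Postural sway metrics from the 30-s standing-balance window.

Two input paths are supported:

* a 2-D body-displacement track in mm (exact, analytically testable), or
* a tri-axial accelerometer trace in m/s^2 (the realistic path): gravity is
  estimated as the window-mean acceleration vector, the horizontal components
  are band-passed (0.1-2 Hz, zero phase) and doubly trapezoid-integrated with
  a linear detrend after each integration to control drift.

Per-axis metrics in the mediolateral (left-right) and anterior-posterior
directions: sway distance = cumulative 1-D path length (sum of |increments|),
sway displacement = max - min excursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, signal as sp_signal

from .config import SwayConfig
from .segmentation import TaskWindow


@dataclass(frozen=True)
class SwayMetrics:
    sway_distance_ml_mm: float
    sway_distance_ap_mm: float
    sway_displacement_ml_mm: float
    sway_displacement_ap_mm: float
    duration_s: float


def _axis_metrics(x_mm: np.ndarray) -> tuple[float, float]:
    distance = float(np.sum(np.abs(np.diff(x_mm))))
    displacement = float(np.max(x_mm) - np.min(x_mm)) if x_mm.size else 0.0
    return distance, displacement


def compute_sway(data: np.ndarray, fs: float,
                 window: TaskWindow | None = None,
                 config: SwayConfig | None = None,
                 t: np.ndarray | None = None) -> SwayMetrics:
    """Compute sway metrics from a balance-window signal.

    ``data`` with shape (n, 2) is a displacement track in mm (columns ML,
    AP); shape (n, 3) is an accelerometer trace in m/s^2 whose horizontal
    components are the ML and AP device axes after gravity removal.
    """
    config = config or SwayConfig()
    if window is not None and window.label != "balance_30s":
        raise ValueError("sway must be computed on a balance_30s window")
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] not in (2, 3):
        raise ValueError("expected an (n, 2) displacement or (n, 3) accel array")
    n = data.shape[0]
    duration = (n - 1) / fs if n else 0.0
    if duration < config.min_duration_s:
        raise ValueError(
            f"balance window too short: {duration:.1f} s < {config.min_duration_s:g} s")
    if t is not None:
        dt = np.diff(t)
        if dt.size and (np.max(dt) - np.min(dt)) > 0.5 / fs:
            raise ValueError("displacement input requires uniform sampling")

    if data.shape[1] == 2:
        xy_mm = data
    else:
        xy_mm = _displacement_from_accel(data, fs, config)

    d_ml, e_ml = _axis_metrics(xy_mm[:, 0])
    d_ap, e_ap = _axis_metrics(xy_mm[:, 1])
    return SwayMetrics(d_ml, d_ap, e_ml, e_ap, duration)


def _displacement_from_accel(accel: np.ndarray, fs: float,
                             config: SwayConfig) -> np.ndarray:
    """Gravity removal, band-pass, and drift-controlled double integration."""
    g_vec = accel.mean(axis=0)
    g_norm = np.linalg.norm(g_vec)
    if g_norm > 1e-9:
        g_hat = g_vec / g_norm
        horizontal = accel - np.outer(accel @ g_hat, g_hat)
    else:
        horizontal = accel
    # ML/AP = device x/y projected into the horizontal plane
    comps = horizontal[:, :2]
    if np.allclose(comps, 0.0):
        n = accel.shape[0]
        return np.zeros((n, 2))
    sos = sp_signal.butter(2, config.band_hz, "bandpass", fs=fs, output="sos")
    out = np.empty_like(comps)
    tgrid = np.arange(accel.shape[0]) / fs
    for k in range(2):
        a = sp_signal.sosfiltfilt(sos, comps[:, k])
        v = integrate.cumulative_trapezoid(a, tgrid, initial=0.0)
        v = sp_signal.detrend(v, type="linear")
        x = integrate.cumulative_trapezoid(v, tgrid, initial=0.0)
        x = sp_signal.detrend(x, type="linear")
        out[:, k] = x * 1000.0  # m -> mm
    return out
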