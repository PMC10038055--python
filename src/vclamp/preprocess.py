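"""Leak subtraction, baseline handling, filtering and peak extraction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .sweeps import SweepSet, SweepSegment, segment

__all__ = [
    "PeakMeasure",
    "p4_subtract",
    "offline_leak_subtract",
    "measure_peaks",
    "normalize_density",
    "lowpass",
    "baseline_subtract",
]


@dataclass
class PeakMeasure:
    sweep_index: int
    step_level: float  # mV
    peak: float  # pA, signed
    time_to_peak_ms: float  # from step onset
    steady: float  # pA, mean over terminal window


def _holding_baselines(s: SweepSet, epoch_index: int = 0) -> np.ndarray:
    """Per-sweep mean over the initial holding epoch (or first 5% of samples)."""
    if s.protocol is not None:
        b0, b1 = s.protocol.epoch_bounds()[epoch_index]
    else:
        b0, b1 = 0, max(1, s.n_samples // 20)
    return s.sweeps[:, b0:b1].mean(axis=1)


def p4_subtract(test: SweepSet, subpulses: SweepSet) -> SweepSet:
    """P/4 leak subtraction.

    ``subpulses`` must hold four quarter-amplitude sub-sweeps per test
    sweep (grouped consecutively).  Each trace is referenced to its own
    holding baseline, the four sub-responses are summed (equalling the
    full-amplitude linear response) and subtracted from the test trace.
    Any current component affine in voltage — ohmic leak plus capacitive
    transients — cancels exactly.
    """
    if subpulses.n_sweeps != 4 * test.n_sweeps:
        raise ValueError(
            f"alignment error: expected {4 * test.n_sweeps} sub-sweeps "
            f"(4 per test sweep), got {subpulses.n_sweeps}"
        )
    if subpulses.n_samples != test.n_samples:
        raise ValueError(
            f"alignment error: sub-sweeps have {subpulses.n_samples} samples, "
            f"test sweeps have {test.n_samples}"
        )
    bl_t = _holding_baselines(test)
    bl_s = _holding_baselines(subpulses)
    sub = subpulses.sweeps - bl_s[:, None]
    summed = sub.reshape(test.n_sweeps, 4, test.n_samples).sum(axis=1)
    corrected = (test.sweeps - bl_t[:, None]) - summed
    out = test.copy_with(sweeps=corrected, leak_subtracted="p4")
    out.annotations["leak_free"] = "true"
    _warn_if_residual_leak(out)
    return out


def _warn_if_residual_leak(s: SweepSet, subthreshold_mv: float = -60.0):
    """Heuristic scale check: a deeply subthreshold step should be ~flat zero."""
    if s.protocol is None:
        return
    try:
        var_epochs = [
            e for e, (lv, _) in enumerate(s.protocol.epochs) if lv is None
        ]
        if not var_epochs:
            return
        segs = segment(s, var_epochs[0])
    except Exception:
        return
    sub = [g for g in segs if g.step_level <= subthreshold_mv]
    if not sub:
        return
    noise = np.median([np.std(np.diff(g.values)) for g in sub]) / np.sqrt(2) + 1e-12
    resid = max(abs(np.mean(g.values[len(g.values) // 2 :])) for g in sub)
    if resid > 5.0 * noise + 1e-9:
        warnings.warn(
            f"residual leak after P/4 subtraction: subthreshold steady level "
            f"{resid:.3g} pA exceeds noise estimate {noise:.3g} pA "
            "(sub-pulse scaling suspect)",
            stacklevel=3,
        )


def offline_leak_subtract(
    s: SweepSet,
    subthreshold_mv: float = -60.0,
    steady_window_ms: float = 5.0,
    epoch_index: int = None,
) -> SweepSet:
    """Offline linear leak subtraction.

    Fits ``I_leak = g*V + c`` by least squares using the holding-epoch
    means of every sweep plus the steady window of all test steps at or
    below ``subthreshold_mv``, then subtracts ``g*V(t) + c`` sample-wise.
    """
    if s.protocol is None:
        raise ValueError("offline leak subtraction needs a protocol")
    proto = s.protocol
    if epoch_index is None:
        var_epochs = [e for e, (lv, _) in enumerate(proto.epochs) if lv is None]
        if not var_epochs:
            raise ValueError("no variable (test) epoch found in protocol")
        epoch_index = var_epochs[0]
    segs = segment(s, epoch_index)
    nw = max(1, int(round(steady_window_ms * s.sample_rate_khz)))
    v_pts, i_pts = [], []
    for j in range(s.n_sweeps):
        b0, b1 = proto.epoch_bounds()[0]
        v_pts.append(proto.epoch_level(0, j))
        i_pts.append(s.sweeps[j, b0:b1].mean())
    sub = [g for g in segs if g.step_level <= subthreshold_mv]
    for g in sub:
        v_pts.append(g.step_level)
        i_pts.append(g.values[-nw:].mean())
    v_pts = np.asarray(v_pts)
    i_pts = np.asarray(i_pts)
    if np.unique(v_pts).size < 2:
        raise ValueError(
            "insufficient subthreshold levels for leak fit (need >= 2 distinct "
            f"voltages at or below {subthreshold_mv} mV incl. holding)"
        )
    A = np.column_stack([v_pts, np.ones_like(v_pts)])
    (g_ns, c_pa), res, _, _ = np.linalg.lstsq(A, i_pts, rcond=None)
    # nonlinearity check: quadratic term should not dominate
    if np.unique(v_pts).size >= 3:
        q = np.polyfit(v_pts, i_pts, 2)
        ssr_lin = float(np.sum((i_pts - A @ np.array([g_ns, c_pa])) ** 2))
        ssr_quad = float(np.sum((i_pts - np.polyval(q, v_pts)) ** 2))
        scale = float(np.sum(i_pts**2)) + 1e-12
        if ssr_lin - ssr_quad > 0.01 * scale:
            warnings.warn(
                "leak-fit residuals are non-linear; activation may be "
                "contaminating the subthreshold window",
                stacklevel=2,
            )
    corrected = s.sweeps.copy()
    for j in range(s.n_sweeps):
        v_t = proto.voltage_trace(j)
        corrected[j] -= g_ns * v_t + c_pa
    out = s.copy_with(sweeps=corrected, leak_subtracted="offline")
    out.annotations["leak_fit_g_ns"] = repr(float(g_ns))
    out.annotations["leak_fit_c_pa"] = repr(float(c_pa))
    out.annotations["leak_free"] = "true"
    return out


def measure_peaks(
    s: SweepSet,
    epoch_index: int = 1,
    steady_window_ms: float = 5.0,
    blank_ms: float = 0.2,
    peak_window_ms: float = None,
) -> list:
    """Peak (signed extremum of largest magnitude) and steady level per sweep.

    The first ``blank_ms`` after step onset are excluded from the peak
    search to skip the capacitive spike; ``peak_window_ms`` optionally
    limits the search to an initial window of the epoch (useful when a
    slow secondary process re-grows the current late in the step).
    ``steady`` is the mean over the last ``steady_window_ms`` of the epoch.
    """
    if s.leak_subtracted == "none" and s.annotations.get("leak_free") != "true":
        warnings.warn(
            "measuring peaks on non-leak-subtracted sweeps", stacklevel=2
        )
    segs = segment(s, epoch_index)
    out = []
    for g in segs:
        if g.values.size == 0:
            raise ValueError(f"empty epoch for sweep {g.sweep_index}")
        k0 = min(int(round(blank_ms * s.sample_rate_khz)), g.values.size - 1)
        k1 = g.values.size
        if peak_window_ms is not None:
            k1 = min(k1, max(k0 + 1, int(round(peak_window_ms * s.sample_rate_khz))))
        win = g.values[k0:k1]
        if np.all(win == 0.0):
            warnings.warn(
                f"sweep {g.sweep_index}: all-zero epoch, peak reported at first sample",
                stacklevel=2,
            )
            k_peak = 0
        else:
            k_peak = int(np.argmax(np.abs(win)))
        peak = float(win[k_peak])
        t_peak = (k0 + k_peak) * s.dt_ms
        nw = max(1, int(round(steady_window_ms * s.sample_rate_khz)))
        steady = float(g.values[-nw:].mean())
        out.append(
            PeakMeasure(
                sweep_index=g.sweep_index,
                step_level=g.step_level,
                peak=peak,
                time_to_peak_ms=t_peak,
                steady=steady,
            )
        )
    return out


def normalize_density(value_pa: float, capacitance_pf: float) -> float:
    """Current density in pA/pF."""
    if capacitance_pf is None or capacitance_pf <= 0:
        raise ValueError("capacitance must be > 0 for density normalization")
    return value_pa / capacitance_pf


def lowpass(s: SweepSet, cutoff_khz: float = 2.0, order: int = 4) -> SweepSet:
    """Zero-phase Bessel low-pass smoothing (2 or 10 kHz presets typical)."""
    nyq = s.sample_rate_khz / 2.0
    if not 0 < cutoff_khz < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) kHz")
    b, a = signal.bessel(order, cutoff_khz / nyq)
    filtered = signal.filtfilt(b, a, s.sweeps, axis=1)
    return s.copy_with(sweeps=filtered, filter_cutoff_khz=cutoff_khz)


def baseline_subtract(s: SweepSet, epoch_index: int = 0) -> SweepSet:
    """Subtract each sweep's holding-epoch mean."""
    bl = _holding_baselines(s, epoch_index)
    return s.copy_with(sweeps=s.sweeps - bl[:, None])
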