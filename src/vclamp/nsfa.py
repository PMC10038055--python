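"""ON-gating-charge integration and non-stationary fluctuation analysis.

NSFA estimates the single-channel current ``i``, channel count ``N`` and
background variance ``b`` from the across-sweep variance of repeated
tail currents via the parabola

    sigma^2(I) = i*I - I^2/N + b

whose derivative ``d sigma^2 / dI = i - 2I/N`` equals ``i`` at I -> 0.
Open probability is the peak mean tail current over the theoretical
maximum ``i*N``; channel density uses the 1 uF/cm^2 convention
(1 pF of capacitance corresponds to 100 um^2 of membrane).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .sweeps import SweepSegment, SweepSet, segment

__all__ = [
    "GatingChargeResult",
    "NSFAResult",
    "NSFAError",
    "DerivativeCheck",
    "SlopeResult",
    "q_on",
    "q_imax_slope",
    "nsfa",
    "fit_variance_mean",
    "nsfa_derivative_check",
    "select_qon_sweep",
    "UM2_PER_PF",
]

UM2_PER_PF = 100.0


class NSFAError(RuntimeError):
    pass


@dataclass
class GatingChargeResult:
    q_on_pa_ms: float  # raw trapezoidal integral
    q_on_density: Optional[float]  # pA*ms/pF
    v_used: float  # mV, level of the integrated sweep
    integration_window_ms: tuple  # (start, end) relative to step onset


def q_on(
    seg: SweepSegment,
    window_ms: float = 2.0,
    capacitance_pf: Optional[float] = None,
    v_rev_fitted: Optional[float] = None,
    tolerance_mv: float = 2.0,
) -> GatingChargeResult:
    """Integrate the first ``window_ms`` of the test pulse (trapezoid rule).

    The segment should be the sweep at the reversal potential, where no
    net ionic current flows; a warning is raised when the step level is
    further than ``tolerance_mv`` from the fitted reversal potential.
    """
    if v_rev_fitted is not None and abs(seg.step_level - v_rev_fitted) > tolerance_mv:
        warnings.warn(
            f"integrating at {seg.step_level} mV, {abs(seg.step_level - v_rev_fitted):.2f} "
            f"mV away from the fitted reversal potential {v_rev_fitted} mV",
            stacklevel=2,
        )
    n = int(round(window_ms * seg.sample_rate_khz)) + 1
    if n > seg.values.size:
        raise ValueError(
            f"integration window {window_ms} ms exceeds segment "
            f"({seg.duration_ms} ms)"
        )
    integral = float(np.trapezoid(seg.values[:n], dx=seg.dt_ms))
    density = None
    if capacitance_pf is not None:
        if capacitance_pf <= 0:
            raise ValueError("capacitance must be > 0")
        density = integral / capacitance_pf
    return GatingChargeResult(
        q_on_pa_ms=integral,
        q_on_density=density,
        v_used=seg.step_level,
        integration_window_ms=(0.0, window_ms),
    )


def select_qon_sweep(s: SweepSet, v_rev: float, epoch_index: int = 1) -> SweepSegment:
    """Segment of the sweep whose step level is closest to ``v_rev``."""
    segs = segment(s, epoch_index)
    return min(segs, key=lambda g: abs(g.step_level - v_rev))


@dataclass
class SlopeResult:
    slope: float
    slope_se: float
    intercept: float
    slope_zero_intercept: float
    slope_zero_intercept_se: float
    n: int


def q_imax_slope(cells: Sequence) -> SlopeResult:
    """OLS slope of I_max on Q_ON across cells (free and zero intercept)."""
    pts = np.asarray([(float(q), float(im)) for q, im in cells], dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all Q_ON values are equal")
    n = x.size
    X = np.column_stack([x, np.ones(n)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 2
    sxx = float(np.sum((x - x.mean()) ** 2))
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else float("nan")
    b0 = float(np.sum(x * y) / np.sum(x**2))
    r0 = y - b0 * x
    dof0 = n - 1
    se0 = float(np.sqrt(np.sum(r0**2) / dof0 / np.sum(x**2)))
    return SlopeResult(
        slope=float(beta[0]),
        slope_se=se,
        intercept=float(beta[1]),
        slope_zero_intercept=b0,
        slope_zero_intercept_se=se0,
        n=n,
    )


@dataclass
class NSFAResult:
    i: float  # pA, signed single-channel current at the tail potential
    i_magnitude: float  # |i|
    n_channels: float
    b: float  # pA^2, variance offset
    p_open: float
    channel_density_per_um2: Optional[float]
    mean_curve: np.ndarray = field(repr=False, default=None)  # columns (I, sigma^2)
    coefficients: tuple = (0.0, 0.0, 0.0)  # (c2, c1, c0) of the fitted parabola
    n_sweeps_used: int = 0
    start_offset_ms: float = 0.1
    window_samples: tuple = (0, 0)
    ssr: float = float("nan")


def fit_variance_mean(mean_i: np.ndarray, var: np.ndarray) -> tuple:
    """Least-squares fit of sigma^2 = i*I - I^2/N + b.

    Returns ``(i, N, b, (c2, c1, c0), ssr)``.  The model is linear in
    its parameters, so an exact polynomial LS solve is used.
    """
    mean_i = np.asarray(mean_i, dtype=float)
    var = np.asarray(var, dtype=float)
    if mean_i.size < 4:
        raise NSFAError("too few variance-mean points for a parabola fit")
    if float(np.max(var)) <= 0.0:
        raise NSFAError("variance is identically zero (deterministic input?)")
    c2, c1, c0 = np.polyfit(mean_i, var, 2)
    if c2 >= 0:
        raise NSFAError(
            "variance-mean parabola opens upward: variance not saturating"
        )
    i_hat = float(c1)
    n_hat = float(-1.0 / c2)
    b_hat = float(c0)
    ssr = float(np.sum((np.polyval([c2, c1, c0], mean_i) - var) ** 2))
    return i_hat, n_hat, b_hat, (float(c2), float(c1), float(c0)), ssr


def _bin_equal_count(x, y, n_bins):
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    edges = np.linspace(0, xs.size, n_bins + 1).astype(int)
    bx, by = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            bx.append(xs[a:b].mean())
            by.append(ys[a:b].mean())
    return np.asarray(bx), np.asarray(by)


def nsfa(
    tails: SweepSet,
    tail_epoch: Optional[int] = None,
    start_offset_ms: float = 0.1,
    end_fraction: float = 0.05,
    n_bins: int = 50,
    min_sweeps: int = 50,
    policy_range: tuple = (250, 500),
) -> NSFAResult:
    """Non-stationary fluctuation analysis of repeated tail currents.

    Ensemble mean and unbiased variance are computed across sweeps at
    every tail sample; the analysis window runs from shortly after the
    mean-tail peak (``start_offset_ms``) until |mean| decays to
    ``end_fraction`` of the peak, and the (I, sigma^2) pairs (optionally
    binned to ``n_bins`` equal-count bins) are fitted with the NSFA
    parabola.
    """
    if tails.n_sweeps < min_sweeps:
        raise NSFAError(
            f"{tails.n_sweeps} sweeps < hard floor of {min_sweeps} for NSFA"
        )
    if not policy_range[0] <= tails.n_sweeps <= policy_range[1]:
        warnings.warn(
            f"{tails.n_sweeps} sweeps outside the {policy_range[0]}-"
            f"{policy_range[1]} policy range",
            stacklevel=2,
        )
    if tail_epoch is None:
        tail_epoch = int(tails.annotations.get("tail_epoch", 2))
    segs = segment(tails, tail_epoch)
    mat = np.stack([g.values for g in segs])
    mean_t = mat.mean(axis=0)
    var_t = mat.var(axis=0, ddof=1)

    k_peak = int(np.argmax(np.abs(mean_t)))
    peak_mean = mean_t[k_peak]
    k_start = k_peak + max(1, int(round(start_offset_ms * tails.sample_rate_khz)))
    if k_start >= mean_t.size - 3:
        raise NSFAError("analysis window starts too close to the tail end")
    below = np.nonzero(np.abs(mean_t[k_start:]) <= end_fraction * abs(peak_mean))[0]
    k_end = k_start + int(below[0]) if below.size else mean_t.size
    if below.size == 0:
        warnings.warn(
            "mean tail never decays to the end fraction; using the full tail",
            stacklevel=2,
        )
    ii = mean_t[k_start:k_end]
    vv = var_t[k_start:k_end]
    if n_bins and ii.size > 2 * n_bins:
        ib, vb = _bin_equal_count(ii, vv, n_bins)
    else:
        ib, vb = ii, vv
    i_hat, n_hat, b_hat, coeffs, ssr = fit_variance_mean(ib, vb)
    p_open = float(peak_mean / (i_hat * n_hat))
    density = None
    if tails.capacitance_pf is not None and tails.capacitance_pf > 0:
        density = n_hat / (tails.capacitance_pf * UM2_PER_PF)
    return NSFAResult(
        i=i_hat,
        i_magnitude=abs(i_hat),
        n_channels=n_hat,
        b=b_hat,
        p_open=p_open,
        channel_density_per_um2=density,
        mean_curve=np.column_stack([ib, vb]),
        coefficients=coeffs,
        n_sweeps_used=tails.n_sweeps,
        start_offset_ms=start_offset_ms,
        window_samples=(k_start, k_end),
        ssr=ssr,
    )


@dataclass
class DerivativeCheck:
    i_from_derivative: float  # d sigma^2/dI at I -> 0 (== fitted i exactly)
    apex_current: float  # root of the derivative, I = i*N/2
    fd_max_abs_dev: float  # worst |finite-diff slope - (i - 2I/N)|
    consistent: bool


def nsfa_derivative_check(result: NSFAResult, rel_tol: float = 0.5) -> DerivativeCheck:
    """Check the fitted parabola against its analytic derivative i - 2I/N.

    The derivative at the origin equals the fitted single-channel
    current by construction; the finite-difference slope of the
    (binned) variance-mean data is compared against the analytic
    derivative and flagged when it deviates by more than ``rel_tol``
    relative to |i| anywhere in the window (heteroscedastic noise).
    """
    c2, c1, c0 = result.coefficients
    i_at_zero = c1
    apex = -c1 / (2.0 * c2)  # == i*N/2
    curve = result.mean_curve
    fd_dev = 0.0
    if curve is not None and curve.shape[0] >= 3:
        x, y = curve[:, 0], curve[:, 1]
        order = np.argsort(x)
        x, y = x[order], y[order]
        fd = np.diff(y) / np.diff(x)
        mid = 0.5 * (x[:-1] + x[1:])
        analytic = result.i - 2.0 * mid / result.n_channels
        fd_dev = float(np.max(np.abs(fd - analytic)))
    consistent = fd_dev <= rel_tol * abs(result.i) + 1e-12
    return DerivativeCheck(
        i_from_derivative=float(i_at_zero),
        apex_current=float(apex),
        fd_max_abs_dev=fd_dev,
        consistent=bool(consistent),
    )
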