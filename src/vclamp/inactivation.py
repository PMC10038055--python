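"""Steady-state inactivation fitting, r250, 5-s residual fraction, CDI index.

Availability is the ratio of test-pulse peaks measured after versus
before the conditioning step, computed within the same sweep so that
slow rundown cancels.  The fitted relation is

    A(V) = I_ss + (1 - I_ss) / (1 + exp((V - V_0.5,inact) / |k|))

with the slope factor reported as a negative number (conventional sign
for inactivation curves); its magnitude parameterizes the math.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .preprocess import measure_peaks
from .sweeps import SweepSegment, SweepSet, segment

__all__ = [
    "SSIFitResult",
    "InactivationMetrics",
    "fit_ssi",
    "ssi_availability",
    "r_ratio",
    "residual_after",
    "cdi_index",
    "plateau_availability",
]


@dataclass
class SSIFitResult:
    v05_inact: float  # mV
    k_inact: float  # mV, negative by convention
    i_ss: float  # non-inactivating fraction, in [0, 1]
    residuals: np.ndarray = field(repr=False, default=None)
    ssr: float = float("nan")
    converged: bool = False

    def predict(self, v):
        v = np.asarray(v, dtype=float)
        b = 1.0 / (1.0 + np.exp((v - self.v05_inact) / abs(self.k_inact)))
        return self.i_ss + (1.0 - self.i_ss) * b


def fit_ssi(points: Sequence) -> SSIFitResult:
    """Least-squares Boltzmann fit of conditioning voltage vs availability."""
    pts = np.asarray([(float(a), float(b)) for a, b in points], dtype=float)
    order = np.argsort(pts[:, 0])
    v, a = pts[order, 0], pts[order, 1]
    if np.unique(v).size < 5:
        raise ValueError("need at least 5 distinct conditioning levels")
    if a.min() < -0.05 or a.max() > 1.1:
        raise ValueError(
            f"availability outside [-0.05, 1.1] (range {a.min():.3g}..{a.max():.3g}); "
            "sign or normalization suspected"
        )
    if a.max() - a.min() < 0.05:
        raise ValueError("no inactivation detected (availability nearly constant)")

    iss0 = float(np.clip(a.min(), 0.0, 0.99))
    half = iss0 + (1.0 - iss0) / 2.0
    idx = np.nonzero(a <= half)[0]
    v05_0 = float(v[idx[0]]) if idx.size else float(np.median(v))

    def resid(theta):
        v05, km, iss = theta
        b = 1.0 / (1.0 + np.exp((v - v05) / km))
        return iss + (1.0 - iss) * b - a

    lo = np.array([v.min() - 100.0, 0.1, 0.0])
    hi = np.array([v.max() + 100.0, 100.0, 1.0])
    x0 = np.clip(np.array([v05_0, 7.0, iss0]), lo + 1e-9, hi - 1e-9)
    sol = optimize.least_squares(
        resid, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000
    )
    v05, km, iss = sol.x
    return SSIFitResult(
        v05_inact=float(v05),
        k_inact=-float(km),
        i_ss=float(iss),
        residuals=sol.fun.copy(),
        ssr=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
    )


def ssi_availability(
    s: SweepSet,
    pre_epoch: Optional[int] = None,
    test_epoch: Optional[int] = None,
    cond_epoch: Optional[int] = None,
    blank_ms: float = 0.2,
    peak_window_ms: float = 10.0,
) -> list:
    """Per-sweep (conditioning level, availability) from an SSI family.

    Epoch indices default to the ``pre_test_epoch`` / ``test_epoch`` /
    ``cond_epoch`` annotations written by the simulator's SSI family.
    Peaks are searched within the first ``peak_window_ms`` of each test
    pulse, so that channels recovering from inactivation late in the
    test step do not masquerade as availability.
    """
    ann = s.annotations
    pre_epoch = int(ann.get("pre_test_epoch", 1)) if pre_epoch is None else pre_epoch
    test_epoch = int(ann.get("test_epoch", 4)) if test_epoch is None else test_epoch
    cond_epoch = int(ann.get("cond_epoch", 3)) if cond_epoch is None else cond_epoch
    pre = measure_peaks(s, pre_epoch, blank_ms=blank_ms, peak_window_ms=peak_window_ms)
    post = measure_peaks(s, test_epoch, blank_ms=blank_ms, peak_window_ms=peak_window_ms)
    cond = segment(s, cond_epoch)
    out = []
    for p0, p1, c in zip(pre, post, cond):
        if p0.peak == 0.0:
            raise ValueError(f"sweep {p0.sweep_index}: zero reference peak")
        out.append((c.step_level, abs(p1.peak) / abs(p0.peak)))
    return out


@dataclass
class InactivationMetrics:
    step_level: float
    r250: float = float("nan")
    residual_5s: float = float("nan")
    plateau_at_plus40: float = float("nan")
    cdi_index: float = float("nan")


def _peak_in(seg: SweepSegment, blank_ms: float):
    k0 = min(int(round(blank_ms * seg.sample_rate_khz)), seg.values.size - 1)
    win = seg.values[k0:]
    k = int(np.argmax(np.abs(win)))
    return float(win[k]), k0 + k


def r_ratio(
    seg: SweepSegment,
    at_ms: float = 250.0,
    blank_ms: float = 0.2,
    noise_floor_pa: float = 0.0,
) -> float:
    """Residual/peak current ratio at ``at_ms`` after step onset (r250).

    Returns NaN (with a warning) when the peak is at or below the noise
    floor; the peak is the global extremum of the step.
    """
    if seg.duration_ms < at_ms:
        raise ValueError(
            f"segment lasts {seg.duration_ms} ms; cannot evaluate at {at_ms} ms"
        )
    peak, _ = _peak_in(seg, blank_ms)
    if abs(peak) <= noise_floor_pa:
        warnings.warn("undefined r-ratio: peak below noise floor", stacklevel=2)
        return float("nan")
    k_at = min(int(round(at_ms * seg.sample_rate_khz)), seg.values.size - 1)
    return float(seg.values[k_at] / peak)


def residual_after(
    seg: SweepSegment,
    t_ms: float = 5000.0,
    blank_ms: float = 0.2,
    noise_floor_pa: float = 0.0,
) -> float:
    """Fraction of the peak current remaining ``t_ms`` into the pulse."""
    return r_ratio(seg, at_ms=t_ms, blank_ms=blank_ms, noise_floor_pa=noise_floor_pa)


def cdi_index(ca_metrics: Sequence, ba_metrics: Sequence) -> dict:
    """Ba-minus-Ca r250 difference per matched step level.

    Positive values indicate calcium-dependent inactivation.  Inputs are
    sequences of ``(step_level, r250)`` pairs; raises if the two families
    share no step level.
    """
    ca = {float(v): float(r) for v, r in ca_metrics}
    ba = {float(v): float(r) for v, r in ba_metrics}
    common = sorted(set(ca) & set(ba))
    if not common:
        raise ValueError("no matched step levels between Ca and Ba families")
    return {v: ba[v] - ca[v] for v in common}


def plateau_availability(fit: SSIFitResult, v_mv: float = 40.0) -> float:
    """Availability read from the fitted SSI curve (plateau measure at +40)."""
    return float(fit.predict(v_mv))
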