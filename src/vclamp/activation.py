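"""I-V curve fitting, conductance-voltage curves, and activation kinetics.

The peak I-V relation is fitted to

    I(V) = G_max * (V - V_rev) / (1 + exp((V_0.5 - V) / k))

by nonlinear least squares with deterministic multi-start initialization.
Derived quantities: V_max (measured grid level of largest |I|), the
activation threshold (voltage where the fitted curve reaches 5% of its
continuous peak magnitude, hyperpolarized branch) and the normalized
chord-conductance curve G(V) = I*1000/(V - V_rev).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .sweeps import SweepSegment

__all__ = [
    "IVFitResult",
    "ActivationKinetics",
    "FitError",
    "fit_iv",
    "gv_curve",
    "fit_activation_kinetics",
    "boltzmann_iv",
]


class FitError(RuntimeError):
    """Nonlinear fit failed or input admits no fit."""


def boltzmann_iv(v, g_max, v05, k, v_rev):
    """The I-V model; g_max in nS, voltages in mV, current in pA."""
    return g_max * (v - v_rev) / (1.0 + np.exp((v05 - v) / k))


@dataclass
class IVFitResult:
    g_max: float  # nS (pA/mV for pA input; per-pF if densities were fitted)
    v05_act: float  # mV
    k_act: float  # mV, > 0
    v_rev: float  # mV
    v_max: float  # measured grid level of max |I|
    v_max_continuous: float  # argmax of |fitted curve| (refinement)
    act_thresh: float  # mV, 5% point on the hyperpolarized flank
    cd_max: float  # |I| at v_max, in input units
    residuals: np.ndarray = field(repr=False, default=None)
    ssr: float = float("nan")
    n_iterations: int = 0
    converged: bool = False

    def predict(self, v):
        return boltzmann_iv(np.asarray(v, dtype=float), self.g_max,
                            self.v05_act, self.k_act, self.v_rev)


def _iv_initial_guess(v, i, k_peak):
    """Heuristic start values; see fit_iv for the jittered restarts."""
    v_max = v[k_peak]
    # reversal: first zero crossing above v_max, linearly interpolated
    v_rev0 = v[-1] + 10.0
    for a in range(k_peak, len(v) - 1):
        if i[a] == 0.0:
            v_rev0 = v[a]
            break
        if i[a] * i[a + 1] < 0:
            f = i[a] / (i[a] - i[a + 1])
            v_rev0 = v[a] + f * (v[a + 1] - v[a])
            break
    # half-rise of |I| on the hyperpolarized side
    mag = np.abs(i[: k_peak + 1])
    half = mag[-1] / 2.0
    idx = np.nonzero(mag >= half)[0]
    v05_0 = v[idx[0]] if idx.size else v_max - 10.0
    k0 = 8.0
    upper = v > v_max
    if np.count_nonzero(upper) >= 2:
        g0 = abs(np.polyfit(v[upper], i[upper], 1)[0])
    else:
        g0 = abs(i[k_peak] / (v_max - v_rev0 + 1e-9))
    return max(g0, 1e-6), v05_0, k0, v_rev0


def fit_iv(points: Sequence, capacitance_pf: Optional[float] = None) -> IVFitResult:
    """Fit the Boltzmann-scaled linear I-V to peak-current points.

    ``points`` is a sequence of ``(V_mV, I_peak)`` pairs (pA or pA/pF).
    Requires >= 6 distinct voltages with an interior extremum of |I|.
    """
    pts = np.asarray([(float(a), float(b)) for a, b in points], dtype=float)
    order = np.argsort(pts[:, 0])
    v, i = pts[order, 0], pts[order, 1]
    if np.unique(v).size < 6:
        raise FitError("need at least 6 distinct voltages")
    if np.all(i == 0.0):
        raise FitError("all currents are zero; no peak to fit")
    # the activation peak is the more hyperpolarized of the two extrema;
    # the branch beyond reversal may grow larger in |I| but is not "the peak"
    k_peak = min(int(np.argmin(i)), int(np.argmax(i)))
    if k_peak == 0 or k_peak == len(v) - 1:
        raise FitError("monotone |I-V| data: no interior peak")

    g0, v05_0, k0, vrev0 = _iv_initial_guess(v, i, k_peak)
    lo = np.array([1e-9, v[0] - 100.0, 0.1, v[0]])
    hi = np.array([np.inf, v[-1] + 100.0, 50.0, v[-1] + 200.0])

    # g_max is left sign-free so inward and outward families both fit
    def resid(theta):
        g, v05, kk, vr = theta
        return boltzmann_iv(v, g, v05, kk, vr) - i

    g_signed0 = g0 if i[k_peak] * (v[k_peak] - vrev0) > 0 else -g0
    rng = np.random.default_rng(12345)
    starts = [np.array([g_signed0, v05_0, k0, vrev0])]
    for _ in range(5):
        starts.append(
            np.array(
                [
                    g_signed0 * rng.uniform(0.7, 1.3),
                    v05_0 + rng.uniform(-5, 5),
                    k0 * rng.uniform(0.7, 1.3),
                    vrev0 + rng.uniform(-5, 5),
                ]
            )
        )
    best = None
    n_iter = 0
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=2000,
            )
        except Exception:
            continue
        n_iter += sol.nfev
        ssr = float(np.sum(sol.fun**2))
        if best is None or ssr < best[0]:
            best = (ssr, sol)
    if best is None:
        raise FitError("I-V fit failed to converge from every start")
    ssr, sol = best
    g_max, v05, k_act, v_rev = sol.x
    if k_act <= 0:
        raise FitError(f"non-physical slope factor k={k_act}")

    fit = IVFitResult(
        g_max=float(g_max),
        v05_act=float(v05),
        k_act=float(k_act),
        v_rev=float(v_rev),
        v_max=float("nan"),
        v_max_continuous=float("nan"),
        act_thresh=float("nan"),
        cd_max=float(np.abs(i[k_peak])),
        residuals=sol.fun.copy(),
        ssr=ssr,
        n_iterations=n_iter,
        converged=bool(sol.success),
    )
    # V_max on the measured grid (peak-sign branch below reversal);
    # ties go to the more hyperpolarized level
    branch = (np.sign(i) == np.sign(i[k_peak])) & (v < v_rev)
    mag = np.where(branch, np.abs(i), -np.inf)
    fit.v_max = float(v[np.nonzero(mag == mag.max())[0][0]])
    fit.v_max_continuous = _continuous_vmax(fit, v[0], v_rev)
    fit.act_thresh = _act_thresh(fit)
    return fit


def _continuous_vmax(fit: IVFitResult, v_lo, v_rev):
    res = optimize.minimize_scalar(
        lambda vv: -abs(float(fit.predict(vv))),
        bounds=(v_lo, v_rev - 1e-6),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def _act_thresh(fit: IVFitResult, fraction: float = 0.05, tol_mv: float = 1e-4):
    """Bisection for |I_fit| = fraction * |I_fit(v_max)| on the lower flank."""
    target = fraction * abs(float(fit.predict(fit.v_max_continuous)))
    lo = fit.v_max_continuous - 250.0
    hi = fit.v_max_continuous
    f = lambda vv: abs(float(fit.predict(vv))) - target
    if f(lo) > 0:  # pragma: no cover - pathological parameter sets
        raise FitError("cannot bracket activation threshold")
    while hi - lo > tol_mv:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gv_curve(fit: IVFitResult, points: Sequence) -> list:
    """Normalized chord conductance G(V) = I*1000/(V - V_rev), max-scaled.

    Points at the fitted reversal potential are excluded with a warning.
    """
    out = []
    for v, i in points:
        if abs(v - fit.v_rev) < 1e-6:
            warnings.warn(
                f"excluding point at V={v} mV (fitted reversal potential)",
                stacklevel=2,
            )
            continue
        g = i * 1000.0 / (v - fit.v_rev)  # pA/mV*1000 -> pS, >= 0 when conducting
        out.append((float(v), float(g)))
    if not out:
        raise ValueError("no usable points for the G-V curve")
    gmax = max(g for _, g in out)
    if gmax <= 0:
        raise ValueError("non-positive maximal conductance; check current signs")
    return [(v, g / gmax) for v, g in out]


@dataclass
class ActivationKinetics:
    step_level: float  # mV
    tau_ms: float
    time_to_peak_ms: float
    model: str  # "mono" | "bi"
    tau2_ms: Optional[float] = None
    delta_aicc: float = 0.0  # AICc(mono) - AICc(bi); > 2 favors bi


def _aicc(ssr, n, k):
    ssr = max(ssr, 1e-300)
    aic = n * np.log(ssr / n) + 2 * k
    denom = n - k - 1
    return aic + (2 * k * (k + 1) / denom if denom > 0 else np.inf)


def fit_activation_kinetics(
    seg: SweepSegment, blank_ms: float = 0.2, aicc_margin: float = 2.0
) -> ActivationKinetics:
    """Fit the rising phase with I(t) = A*(1 - exp(-t/tau)) + C.

    A bi-exponential alternative is fitted as well; the mono model is
    kept unless the bi-exponential wins by more than ``aicc_margin`` of
    corrected Akaike score (such traces are flagged ``model='bi'``).
    """
    y = seg.values
    t = seg.times()
    k0 = int(round(blank_ms * seg.sample_rate_khz))
    if np.allclose(y, y[0]):
        raise FitError("flat trace: no rising phase to fit")
    k_peak = int(np.argmax(np.abs(y)))
    if k_peak <= k0 + 3:
        raise FitError("peak falls within the onset blanking window")
    tt = t[k0 : k_peak + 1] - t[k0]
    yy = y[k0 : k_peak + 1]
    n = yy.size
    a0 = yy[-1] - yy[0]
    tau0 = max(tt[-1] / 5.0, seg.dt_ms)

    def mono(tv, A, tau, C):
        return A * (1.0 - np.exp(-tv / tau)) + C

    try:
        p_mono, _ = optimize.curve_fit(
            mono, tt, yy, p0=[a0, tau0, yy[0]], maxfev=20000
        )
    except Exception as exc:
        raise FitError(f"mono-exponential fit failed: {exc}") from None
    if p_mono[1] <= 0:
        raise FitError("non-positive activation time constant")
    ssr_mono = float(np.sum((mono(tt, *p_mono) - yy) ** 2))

    def bi(tv, A1, tau1, A2, tau2, C):
        return A1 * (1.0 - np.exp(-tv / tau1)) + A2 * (1.0 - np.exp(-tv / tau2)) + C

    use_bi = False
    p_bi = None
    delta = 0.0
    if n >= 8 and ssr_mono > 1e-20 * float(np.sum(yy**2) + 1.0):
        try:
            p_bi, _ = optimize.curve_fit(
                bi, tt, yy,
                p0=[a0 / 2, max(tau0 / 3, seg.dt_ms), a0 / 2, tau0 * 3, yy[0]],
                maxfev=20000,
            )
            ssr_bi = float(np.sum((bi(tt, *p_bi) - yy) ** 2))
            delta = _aicc(ssr_mono, n, 3) - _aicc(ssr_bi, n, 5)
            use_bi = delta > aicc_margin and p_bi[1] > 0 and p_bi[3] > 0
        except Exception:
            use_bi = False
    if use_bi:
        taus = sorted((float(p_bi[1]), float(p_bi[3])))
        return ActivationKinetics(
            step_level=seg.step_level,
            tau_ms=taus[0],
            time_to_peak_ms=float(t[k_peak]),
            model="bi",
            tau2_ms=taus[1],
            delta_aicc=float(delta),
        )
    return ActivationKinetics(
        step_level=seg.step_level,
        tau_ms=float(p_mono[1]),
        time_to_peak_ms=float(t[k_peak]),
        model="mono",
        tau2_ms=None,
        delta_aicc=float(delta),
    )
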