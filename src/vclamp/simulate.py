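"""Stochastic and deterministic channel-ensemble simulator.

The generative model is an ensemble of ``N`` identical, independent
channels, each carrying two independent gates:

* an activation gate ``C <-> O`` whose steady state follows a Boltzmann
  ``p_inf(V) = p_open_max / (1 + exp((act_v05 - V)/act_k))`` with
  mono-exponential kinetics ``tau_act``;
* an inactivation gate with steady state
  ``h_inf(V) = i_ss + (1 - i_ss) / (1 + exp((V - inact_v05)/|inact_k|))``
  and time constant ``tau_inact``; ``inact_k`` is carried with the
  conventional negative sign, its magnitude enters the math.

A channel conducts when both gates are permissive; the single-channel
current is the chord ``i(V) = gamma * (V - v_rev) / 1000`` pA.  On top
of the ensemble ionic current the simulator can add linear leak,
capacitive step transients, a gating (charge-displacement) current, an
optional calcium-dependent-inactivation rate multiplier, and Gaussian
background noise of variance ``noise_sd**2``.

Stochastic mode samples per-channel transitions on the fixed sample
grid with probabilities ``1 - exp(-rate * dt)``; deterministic mode
propagates the gate-probability expectations exactly (closed form per
constant-voltage epoch) and adds no noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

from .sweeps import SweepSet, VoltageProtocol, VARIABLE

__all__ = [
    "ChannelEnsembleModel",
    "SimulationTruth",
    "StabilityError",
    "simulate",
    "simulate_iv_family",
    "simulate_ssi_family",
    "simulate_nsfa_tails",
    "simulate_long_pulse",
    "p4_subpulse_family",
    "read_model",
    "write_model",
    "E0_PC",
]

#: elementary charge in picocoulombs
E0_PC = 1.602176634e-7

#: membrane area per unit capacitance under the 1 uF/cm^2 convention
UM2_PER_PF = 100.0


class StabilityError(ValueError):
    """dt too coarse for the fastest gate rate."""


def _boltz(v, v05, k):
    return 1.0 / (1.0 + np.exp((v05 - v) / k))


@dataclass(frozen=True)
class ChannelEnsembleModel:
    """Ground-truth generative parameters of the channel ensemble."""

    n_channels: int = 1000
    gamma_ps: float = 4.5  # single-channel chord conductance
    v_rev_mv: float = 60.25
    act_v05_mv: float = 1.48
    act_k_mv: float = 8.69
    p_open_max: float = 1.0
    tau_act_ms: float = 1.0
    inact_v05_mv: float = -16.0
    inact_k_mv: float = -6.73  # negative by convention; |k| enters the math
    i_ss: float = 0.0  # non-inactivating fraction
    tau_inact_ms: float = 300.0
    cdi_rate: float = 0.0  # 1/(pA*ms); Ca carrier only
    q_gating_e0: float = 0.0  # elementary charges displaced per channel
    gating_v05_mv: float = -20.0
    gating_k_mv: float = 8.0
    tau_gating_ms: float = 0.3
    leak_conductance_ns: float = 0.0
    noise_sd_pa: float = 0.0
    cap_transient_pa_per_mv: float = 0.0
    cap_tau_ms: float = 0.1
    charge_carrier: str = "Ca"
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not 0.0 <= self.p_open_max <= 1.0:
            raise ValueError("p_open_max must lie in [0, 1]")
        if not 0.0 <= self.i_ss <= 1.0:
            raise ValueError("i_ss must lie in [0, 1]")
        if self.tau_act_ms <= 0 or self.tau_inact_ms <= 0 or self.tau_gating_ms <= 0:
            raise ValueError("time constants must be positive")
        if self.act_k_mv <= 0:
            raise ValueError("act_k_mv must be positive")
        if self.inact_k_mv >= 0:
            raise ValueError("inact_k_mv is negative by convention")
        if self.charge_carrier not in ("Ca", "Ba"):
            raise ValueError("charge_carrier must be 'Ca' or 'Ba'")
        if self.noise_sd_pa < 0 or self.cdi_rate < 0:
            raise ValueError("noise_sd_pa and cdi_rate must be non-negative")

    # --- derived quantities -------------------------------------------------
    def p_inf(self, v):
        """Steady-state open probability of the activation gate."""
        return self.p_open_max * _boltz(v, self.act_v05_mv, self.act_k_mv)

    def h_inf(self, v):
        """Steady-state availability (inactivation gate), floor ``i_ss``."""
        b = 1.0 / (1.0 + np.exp((v - self.inact_v05_mv) / abs(self.inact_k_mv)))
        return self.i_ss + (1.0 - self.i_ss) * b

    def i_single_pa(self, v):
        """Single-channel chord current in pA (pS * mV / 1000)."""
        return self.gamma_ps * (v - self.v_rev_mv) / 1000.0

    def q_inf_pc(self, v):
        """Total displaced gating charge at equilibrium, in pC."""
        return (
            self.n_channels
            * self.q_gating_e0
            * E0_PC
            * _boltz(v, self.gating_v05_mv, self.gating_k_mv)
        )

    @property
    def g_max_ns(self) -> float:
        """Whole-cell maximal conductance N*gamma*p_open_max in nS."""
        return self.n_channels * self.gamma_ps * self.p_open_max / 1000.0


@dataclass(frozen=True)
class SimulationTruth:
    """Immutable ground-truth ledger attached to every simulation."""

    model: ChannelEnsembleModel
    mode: str
    n_repeats: int
    expected_q_on_pa_ms: float  # full-range gating charge, pA*ms
    open_fraction: Optional[np.ndarray] = None  # [n_rows, n_samples]

    def i_at(self, v_mv: float) -> float:
        """Ground-truth single-channel current at a given potential."""
        return self.model.i_single_pa(v_mv)


def _check_stability(model, dt, mode):
    if mode != "stochastic":
        return
    fastest = min(model.tau_act_ms, model.tau_inact_ms)
    if dt / fastest > 0.1:
        raise StabilityError(
            f"dt={dt:.4g} ms too coarse for tau={fastest:.4g} ms "
            "(rate*dt > 0.1); use a finer sample_rate"
        )


def _epoch_plan(protocol: VoltageProtocol, sweep_index: int):
    """(level, start_sample, end_sample) for each epoch of one sweep."""
    plan = []
    for e, (b0, b1) in enumerate(protocol.epoch_bounds()):
        plan.append((protocol.epoch_level(e, sweep_index), b0, b1))
    return plan


def _deterministic_overlays(model, plan, dt, n_samples):
    """Leak + capacitive transient + gating current, closed form per epoch."""
    out = np.zeros(n_samples)
    v_prev = plan[0][0] if plan else 0.0
    # leak
    for level, b0, b1 in plan:
        out[b0:b1] += model.leak_conductance_ns * level
    # capacitive transients and gating charge relax across epoch boundaries
    cap_amp = 0.0  # running transient amplitude at epoch start
    q = model.q_inf_pc(plan[0][0])
    v_prev = plan[0][0]
    for idx, (level, b0, b1) in enumerate(plan):
        n = b1 - b0
        t = np.arange(n) * dt
        dv = level - v_prev if idx > 0 else 0.0
        cap_amp += model.cap_transient_pa_per_mv * dv
        if cap_amp != 0.0:
            out[b0:b1] += cap_amp * np.exp(-t / model.cap_tau_ms)
            cap_amp *= math.exp(-n * dt / model.cap_tau_ms)
        if model.q_gating_e0 != 0.0:
            q_target = model.q_inf_pc(level)
            # I_g = dQ/dt, pC/ms -> nA -> *1000 pA
            amp = (q_target - q) / model.tau_gating_ms * 1000.0
            out[b0:b1] += amp * np.exp(-t / model.tau_gating_ms)
            q = q_target + (q - q_target) * math.exp(-n * dt / model.tau_gating_ms)
        v_prev = level
    return out


def _simulate_deterministic_sweep(model, plan, dt, n_samples):
    """Expectation trajectory; exact per constant-voltage epoch (no CDI)."""
    p = float(model.p_inf(plan[0][0]))
    h = float(model.h_inf(plan[0][0]))
    open_frac = np.empty(n_samples)
    for level, b0, b1 in plan:
        n = b1 - b0
        t = np.arange(n) * dt
        p_inf = float(model.p_inf(level))
        h_inf = float(model.h_inf(level))
        pe = p_inf + (p - p_inf) * np.exp(-t / model.tau_act_ms)
        he = h_inf + (h - h_inf) * np.exp(-t / model.tau_inact_ms)
        open_frac[b0:b1] = pe * he
        p = p_inf + (p - p_inf) * math.exp(-n * dt / model.tau_act_ms)
        h = h_inf + (h - h_inf) * math.exp(-n * dt / model.tau_inact_ms)
    return open_frac


def _simulate_deterministic_sweep_cdi(model, plan, dt, n_samples):
    """Per-sample expectation update when CDI couples h to the current."""
    p = float(model.p_inf(plan[0][0]))
    h = float(model.h_inf(plan[0][0]))
    open_frac = np.empty(n_samples)
    flux = 0.0  # integral of |ionic current|, pA*ms
    for level, b0, b1 in plan:
        p_inf = float(model.p_inf(level))
        h_inf = float(model.h_inf(level))
        i1 = model.i_single_pa(level)
        ea = math.exp(-dt / model.tau_act_ms)
        for k in range(b0, b1):
            open_frac[k] = p * h
            ionic = model.n_channels * p * h * i1
            flux += abs(ionic) * dt
            mult = 1.0 + model.cdi_rate * flux
            r_in = (1.0 - h_inf) / model.tau_inact_ms * mult
            r_out = h_inf / model.tau_inact_ms
            rtot = r_in + r_out
            h_eq = r_out / rtot
            h = h_eq + (h - h_eq) * math.exp(-rtot * dt)
            p = p_inf + (p - p_inf) * ea
    return open_frac


def _simulate_stochastic(model, plan, dt, n_samples, n_repeats, rng):
    """Fixed-step per-channel transition sampling, vectorized over repeats.

    Channel state is tracked as counts in the four (activation x
    availability) categories; independent gate flips are drawn as nested
    binomials, which reproduces the joint multinomial split.
    """
    N = model.n_channels
    R = n_repeats
    # categories: 0 = (closed, avail), 1 = (open, avail),
    #             2 = (closed, inact), 3 = (open, inact)
    counts = np.zeros((R, 4), dtype=np.int64)
    level0 = plan[0][0]
    p0 = float(model.p_inf(level0))
    h0 = float(model.h_inf(level0))
    n_open0 = rng.binomial(N, p0 * h0, size=R)
    rest = N - n_open0
    # distribute the rest according to conditional probabilities
    pc_av = (1 - p0) * h0
    pc_in = (1 - p0) * (1 - h0)
    po_in = p0 * (1 - h0)
    denom = max(pc_av + pc_in + po_in, 1e-300)
    c_av = rng.binomial(rest, pc_av / denom)
    rem = rest - c_av
    denom2 = max(pc_in + po_in, 1e-300)
    c_in = rng.binomial(rem, pc_in / denom2) if denom2 > 0 else rem
    o_in = rem - c_in
    counts[:, 0] = c_av
    counts[:, 1] = n_open0
    counts[:, 2] = c_in
    counts[:, 3] = o_in

    open_counts = np.empty((R, n_samples), dtype=np.int32)
    use_cdi = model.cdi_rate > 0.0 and model.charge_carrier == "Ca"
    flux = np.zeros(R)

    for level, b0, b1 in plan:
        p_inf = float(model.p_inf(level))
        h_inf = float(model.h_inf(level))
        i1 = model.i_single_pa(level)
        alpha = p_inf / model.tau_act_ms  # C -> O
        beta = (1.0 - p_inf) / model.tau_act_ms  # O -> C
        p_open_step = -math.expm1(-alpha * dt)
        p_close_step = -math.expm1(-beta * dt)
        r_inact = (1.0 - h_inf) / model.tau_inact_ms
        r_recov = h_inf / model.tau_inact_ms
        p_recov_step = -math.expm1(-r_recov * dt)
        for k in range(b0, b1):
            open_counts[:, k] = counts[:, 1]
            if use_cdi:
                flux += np.abs(counts[:, 1] * i1) * dt
                mult = 1.0 + model.cdi_rate * flux
                p_inact_step = -np.expm1(-r_inact * mult * dt)
            else:
                p_inact_step = -math.expm1(-r_inact * dt)
            # activation-gate flips within each availability class
            o_from_c_av = rng.binomial(counts[:, 0], p_open_step)
            c_from_o_av = rng.binomial(counts[:, 1], p_close_step)
            o_from_c_in = rng.binomial(counts[:, 2], p_open_step)
            c_from_o_in = rng.binomial(counts[:, 3], p_close_step)
            c_av = counts[:, 0] - o_from_c_av + c_from_o_av
            o_av = counts[:, 1] - c_from_o_av + o_from_c_av
            c_in = counts[:, 2] - o_from_c_in + c_from_o_in
            o_in = counts[:, 3] - c_from_o_in + o_from_c_in
            # availability-gate flips (independent of the activation flip)
            c_drop = rng.binomial(c_av, p_inact_step)
            o_drop = rng.binomial(o_av, p_inact_step)
            c_back = rng.binomial(c_in, p_recov_step)
            o_back = rng.binomial(o_in, p_recov_step)
            counts[:, 0] = c_av - c_drop + c_back
            counts[:, 1] = o_av - o_drop + o_back
            counts[:, 2] = c_in + c_drop - c_back
            counts[:, 3] = o_in + o_drop - o_back
    return open_counts


def simulate(
    model: ChannelEnsembleModel,
    protocol: VoltageProtocol,
    mode: str = "deterministic",
    n_repeats: int = 1,
    seed: Optional[int] = None,
    record_open: Optional[bool] = None,
) -> tuple:
    """Run the ensemble under a protocol; returns ``(SweepSet, SimulationTruth)``.

    ``n_repeats`` repeats every protocol sweep; output rows are ordered
    level-major (all repeats of sweep 0, then sweep 1, ...).  The same
    ``(model, protocol, seed)`` triple always yields a bit-identical
    SweepSet.
    """
    if mode not in ("stochastic", "deterministic"):
        raise ValueError("mode must be 'stochastic' or 'deterministic'")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    dt = protocol.dt_ms
    _check_stability(model, dt, mode)
    if record_open is None:
        record_open = True
    rng = np.random.default_rng(model.seed if seed is None else seed)
    n_samples = protocol.n_samples
    n_rows = protocol.n_sweeps * n_repeats
    sweeps = np.empty((n_rows, n_samples))
    open_frac = np.empty((n_rows, n_samples)) if record_open else None

    row = 0
    for j in range(protocol.n_sweeps):
        plan = _epoch_plan(protocol, j)
        overlay = _deterministic_overlays(model, plan, dt, n_samples)
        if mode == "deterministic":
            if model.cdi_rate > 0.0 and model.charge_carrier == "Ca":
                frac = _simulate_deterministic_sweep_cdi(model, plan, dt, n_samples)
            else:
                frac = _simulate_deterministic_sweep(model, plan, dt, n_samples)
            i_v = np.empty(n_samples)
            for level, b0, b1 in plan:
                i_v[b0:b1] = model.i_single_pa(level)
            trace = model.n_channels * frac * i_v + overlay
            for _ in range(n_repeats):
                sweeps[row] = trace
                if record_open:
                    open_frac[row] = frac
                row += 1
        else:
            oc = _simulate_stochastic(model, plan, dt, n_samples, n_repeats, rng)
            i_v = np.empty(n_samples)
            for level, b0, b1 in plan:
                i_v[b0:b1] = model.i_single_pa(level)
            block = oc * i_v[None, :] + overlay[None, :]
            if model.noise_sd_pa > 0:
                block = block + rng.normal(0.0, model.noise_sd_pa, size=block.shape)
            sweeps[row : row + n_repeats] = block
            if record_open:
                open_frac[row : row + n_repeats] = oc / model.n_channels
            row += n_repeats

    out_proto = VoltageProtocol(
        name=protocol.name,
        holding_mv=protocol.holding_mv,
        epochs=protocol.epochs,
        sweep_levels=tuple(np.repeat(protocol.sweep_levels, n_repeats)),
        sample_rate_khz=protocol.sample_rate_khz,
        inter_sweep_interval_ms=protocol.inter_sweep_interval_ms,
    )
    annotations = {"simulated": "true", "sim_mode": mode}
    if (
        model.leak_conductance_ns == 0.0
        and model.cap_transient_pa_per_mv == 0.0
    ):
        annotations["leak_free"] = "true"
    sweep_set = SweepSet(
        time=np.arange(n_samples) * dt,
        sweeps=sweeps,
        sample_rate_khz=protocol.sample_rate_khz,
        protocol=out_proto,
        charge_carrier=model.charge_carrier,
        annotations=annotations,
    )
    q_full = model.n_channels * model.q_gating_e0 * E0_PC  # pC
    truth = SimulationTruth(
        model=model,
        mode=mode,
        n_repeats=n_repeats,
        expected_q_on_pa_ms=q_full * 1000.0,  # 1 pC == 1000 pA*ms
        open_fraction=open_frac,
    )
    return sweep_set, truth


# ---------------------------------------------------------------------------
# Protocol families
# ---------------------------------------------------------------------------

def iv_protocol(
    v_from=-80.0,
    v_to=70.0,
    dv=5.0,
    pulse_ms=50.0,
    holding_mv=-89.0,
    pre_ms=10.0,
    post_ms=10.0,
    sample_rate_khz=50.0,
) -> VoltageProtocol:
    """Square-pulse I-V family: hold, test step, return to hold."""
    if dv <= 0:
        raise ValueError("dv must be > 0")
    if v_to < v_from:
        raise ValueError("v_to must be >= v_from")
    n = int(round((v_to - v_from) / dv)) + 1
    levels = tuple(v_from + k * dv for k in range(n))
    return VoltageProtocol(
        name="iv",
        holding_mv=holding_mv,
        epochs=((holding_mv, pre_ms), (VARIABLE, pulse_ms), (holding_mv, post_ms)),
        sweep_levels=levels,
        sample_rate_khz=sample_rate_khz,
    )


def ssi_protocol(
    cond_levels,
    cond_ms=5000.0,
    test_level=13.0,
    test_ms=50.0,
    holding_mv=-89.0,
    pre_ms=10.0,
    gap_ms=20.0,
    tail_ms=5.0,
    sample_rate_khz=50.0,
) -> VoltageProtocol:
    """Steady-state inactivation family with an in-sweep reference pulse.

    Epochs: 0 hold, 1 reference test pulse, 2 hold gap, 3 conditioning
    (variable level), 4 test pulse, 5 tail hold.
    """
    return VoltageProtocol(
        name="ssi",
        holding_mv=holding_mv,
        epochs=(
            (holding_mv, pre_ms),
            (test_level, test_ms),
            (holding_mv, gap_ms),
            (VARIABLE, cond_ms),
            (test_level, test_ms),
            (holding_mv, tail_ms),
        ),
        sweep_levels=tuple(cond_levels),
        sample_rate_khz=sample_rate_khz,
    )


def nsfa_protocol(
    step_level=41.0,
    step_ms=10.0,
    tail_level=-49.0,
    tail_ms=10.0,
    holding_mv=-79.0,
    pre_ms=5.0,
    sample_rate_khz=50.0,
) -> VoltageProtocol:
    """Tail-current protocol: activate maximally, then step to the tail level."""
    return VoltageProtocol(
        name="nsfa",
        holding_mv=holding_mv,
        epochs=((holding_mv, pre_ms), (step_level, step_ms), (tail_level, tail_ms)),
        sweep_levels=(step_level,),
        sample_rate_khz=sample_rate_khz,
    )


def long_pulse_protocol(
    level=13.0, pulse_ms=5000.0, holding_mv=-89.0, pre_ms=50.0, sample_rate_khz=20.0
) -> VoltageProtocol:
    """Single long depolarizing pulse (5-s inactivation protocol)."""
    return VoltageProtocol(
        name="long5s",
        holding_mv=holding_mv,
        epochs=((holding_mv, pre_ms), (VARIABLE, pulse_ms), (holding_mv, pre_ms)),
        sweep_levels=(level,),
        sample_rate_khz=sample_rate_khz,
    )


def simulate_iv_family(
    model, v_from=-80.0, v_to=70.0, dv=5.0, pulse_ms=50.0, mode="deterministic", **kw
):
    """Simulate one sweep per test potential (holding -89 mV unless overridden)."""
    proto = iv_protocol(v_from=v_from, v_to=v_to, dv=dv, pulse_ms=pulse_ms, **kw)
    return simulate(model, proto, mode=mode)


def simulate_ssi_family(
    model, cond_levels, cond_ms=5000.0, test_level=13.0, test_ms=50.0,
    mode="deterministic", **kw
):
    """Simulate a steady-state inactivation family.

    Each sweep carries its own pre-conditioning reference test pulse
    (epoch 1) and post-conditioning test pulse (epoch 4).
    """
    proto = ssi_protocol(
        cond_levels, cond_ms=cond_ms, test_level=test_level, test_ms=test_ms, **kw
    )
    s, truth = simulate(model, proto, mode=mode, record_open=False)
    s.annotations.update({"pre_test_epoch": "1", "cond_epoch": "3", "test_epoch": "4"})
    return s, truth


def simulate_nsfa_tails(model, n_sweeps=400, mode="stochastic", seed=None, **kw):
    """Repeated tail-current sweeps for non-stationary fluctuation analysis."""
    proto = nsfa_protocol(**kw)
    s, truth = simulate(model, proto, mode=mode, n_repeats=n_sweeps, seed=seed)
    s.annotations["tail_epoch"] = "2"
    return s, truth


def simulate_long_pulse(model, level=13.0, pulse_ms=5000.0, mode="deterministic", **kw):
    proto = long_pulse_protocol(level=level, pulse_ms=pulse_ms, **kw)
    return simulate(model, proto, mode=mode)


def p4_subpulse_family(
    model, protocol: VoltageProtocol, mode="deterministic", seed=None,
    sub_holding_mv=None,
):
    """Simulate the 4 quarter-amplitude P/4 sub-sweeps for every test sweep.

    Sub-pulses keep the test-step shape, scale every excursion from
    holding by 1/4, and are delivered from ``sub_holding_mv`` (defaults
    to the protocol holding level).  Output rows are grouped as four
    consecutive sub-sweeps per test sweep.
    """
    hold = protocol.holding_mv
    sub_hold = hold if sub_holding_mv is None else sub_holding_mv
    scaled_epochs = tuple(
        (VARIABLE if lv is VARIABLE else sub_hold + (lv - hold) / 4.0, d)
        for lv, d in protocol.epochs
    )
    levels = tuple(sub_hold + (v - hold) / 4.0 for v in protocol.sweep_levels)
    sub_proto = VoltageProtocol(
        name=protocol.name + "_p4sub",
        holding_mv=sub_hold,
        epochs=scaled_epochs,
        sweep_levels=levels,
        sample_rate_khz=protocol.sample_rate_khz,
        inter_sweep_interval_ms=protocol.inter_sweep_interval_ms,
    )
    s, truth = simulate(model, sub_proto, mode=mode, n_repeats=4, seed=seed,
                        record_open=False)
    s.annotations["p4_subpulses"] = "true"
    return s, truth


# ---------------------------------------------------------------------------
# Flat key/value model files
# ---------------------------------------------------------------------------

def write_model(model: ChannelEnsembleModel, path) -> None:
    lines = []
    for f in fields(model):
        v = getattr(model, f.name)
        lines.append(f"{f.name}={v!r}" if isinstance(v, str) else f"{f.name}={v}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_model(path) -> ChannelEnsembleModel:
    kw = {}
    valid = {f.name: f.type for f in fields(ChannelEnsembleModel)}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            k = k.strip()
            v = v.strip().strip("'\"")
            if k not in valid:
                raise ValueError(f"unknown model field {k!r}")
            if k == "charge_carrier":
                kw[k] = v
            elif k in ("n_channels", "seed"):
                kw[k] = int(v)
            else:
                kw[k] = float(v)
    return ChannelEnsembleModel(**kw)
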