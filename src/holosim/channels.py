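"""Stochastic voltage-gated Ca2+ channels and Ca2+ influx generation.

The channel model is a two-state (closed/open) Hodgkin-Huxley-style gate.
The voltage dependence is carried by the steady-state activation ``n_inf(V)``
and the time constant ``tau_n(V)`` (both in HH mV/ms convention):

    n_inf(V) = 1 / (1 + exp(-(V - V_half)/slope))
    tau_n(V) = 0.06 + 0.7425 / (exp((V - V_half) * 0.55 / slope)
                                + exp(-(V - V_half) * 0.45 / slope))

with V_half = -15 mV and slope = 8 mV.  Opening and closing rates are
``n_inf/tau_n`` and ``(1 - n_inf)/tau_n``; per time step each channel flips
with probability ``1 - exp(-rate * dt)``.

The single-channel current is a linearized driving-force expression

    i_ca(V) = -g (V - V_s) exp(-x) / (1 - exp(-x)),   x = (V - V_s)/(RT/zF)

with conductance g = 5 pS and RT/zF = 12 mV.  The free offset potential V_s
and the number of channels N on a 1 um^2 patch are determined by a
least-squares fit of ``N * i_ca(V; V_s)`` to the Goldman-Hodgkin-Katz (GHK)
current for that patch (P = 0.241e-3 cm/s, [Ca]_o = 2 mM, [Ca]_i = 50 nM).
With those defaults the fit gives N = 16 channels and V_s = -1.91 mV.

Open channels convert current to an ion count per step as |i_ca| dt / (2 e)
with stochastic rounding, so the expected influx is exact.

Voltage inputs are plain-text two-column traces.  A synthetic theta-burst
action-potential generator is included as a stand-in for a detailed neuron
model: stereotyped biexponential spikes (resting -65 mV, peak +30 mV,
~2 ms width), 5 spikes at 100 Hz per burst, 5 bursts at 5 or 10 Hz.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .units import ELEMENTARY_CHARGE, FARADAY

__all__ = [
    "GatingParams",
    "CurrentParams",
    "VoltageTrace",
    "InfluxTrace",
    "ChannelBank",
    "n_inf",
    "tau_n",
    "gate_step",
    "single_channel_current",
    "ghk_current",
    "fit_channel_number",
    "ions_per_step",
    "generate_voltage_trace",
    "generate_influx",
    "generate_influx_ensemble",
]


@dataclass(frozen=True)
class GatingParams:
    """HH-style activation parameters (mV; tau in ms)."""

    V_half: float = -15.0
    slope: float = 8.0
    tau_base: float = 0.06
    tau_amp: float = 4.0 * 0.75 * 0.45 * 0.55  # = 0.7425
    tau_rise: float = 0.55
    tau_fall: float = 0.45

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")


@dataclass(frozen=True)
class CurrentParams:
    """Single-channel and GHK current parameters."""

    g_pS: float = 5.0
    RT_zF_mV: float = 12.0
    P_cm_s: float = 0.241e-3
    Ca_out_mM: float = 2.0
    Ca_in_nM: float = 50.0
    area_um2: float = 1.0
    z: int = 2


def n_inf(V: np.ndarray | float, params: GatingParams = GatingParams()) -> np.ndarray | float:
    """Steady-state open probability of the activation gate."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, dtype=float) - params.V_half) / params.slope))


def tau_n(V: np.ndarray | float, params: GatingParams = GatingParams()) -> np.ndarray | float:
    """Activation time constant in ms."""
    x = (np.asarray(V, dtype=float) - params.V_half) / params.slope
    return params.tau_base + params.tau_amp / (
        np.exp(x * params.tau_rise) + np.exp(-x * params.tau_fall)
    )


def gate_step(open_state: np.ndarray, V: float, dt_ms: float,
              rng: np.random.Generator,
              params: GatingParams = GatingParams()) -> np.ndarray:
    """Advance channel open/closed states one step of ``dt_ms`` milliseconds.

    Transition probabilities are exact exponentials of the instantaneous
    rates, so dt = 0 produces no transitions.
    """
    ni = n_inf(V, params)
    tn = tau_n(V, params)
    rate_open = ni / tn            # ms^-1
    rate_close = (1.0 - ni) / tn
    p_open = 1.0 - math.exp(-rate_open * dt_ms)
    p_close = 1.0 - math.exp(-rate_close * dt_ms)
    u = rng.random(open_state.shape)
    newly_open = (~open_state) & (u < p_open)
    newly_closed = open_state & (u < p_close)
    out = open_state.copy()
    out[newly_open] = True
    out[newly_closed] = False
    return out


def single_channel_current(V: np.ndarray | float, V_s: float = -1.91,
                           params: CurrentParams = CurrentParams()) -> np.ndarray | float:
    """Single-channel current in pA (negative = inward).

    The removable singularity at V = V_s is handled by its limit
    ``-g * RT/zF`` (in pA: -0.06 pA with the defaults).
    """
    V = np.asarray(V, dtype=float)
    x = (V - V_s) / params.RT_zF_mV
    # g[pS] * V[mV] = 1e-15 A = 1e-3 pA
    scale = params.g_pS * 1e-3
    with np.errstate(over="ignore", invalid="ignore"):
        core = np.where(
            np.abs(x) < 1e-9,
            params.RT_zF_mV,
            (V - V_s) * np.exp(-x) / (1.0 - np.exp(-x)),
        )
    out = -scale * core
    if np.isscalar(V) or out.ndim == 0:
        return float(out)
    return out


def ghk_current(V: np.ndarray | float,
                params: CurrentParams = CurrentParams()) -> np.ndarray | float:
    """Total GHK Ca2+ current (pA) across ``area_um2`` of membrane.

    Constant-field flux with the driving term written via RT/zF; at V = 0 the
    expression reduces to ``P z F ([Ca]_i - [Ca]_o) * area``.
    """
    V = np.asarray(V, dtype=float)
    ca_i = params.Ca_in_nM * 1e-9 / 1e3   # mol/cm^3
    ca_o = params.Ca_out_mM * 1e-3 / 1e3  # mol/cm^3
    x = V / params.RT_zF_mV
    pref = params.P_cm_s * params.z * FARADAY  # cm/s * C/mol
    with np.errstate(over="ignore", invalid="ignore"):
        density = np.where(
            np.abs(x) < 1e-9,
            pref * (ca_i - ca_o),
            pref * x * (ca_i - ca_o * np.exp(-x)) / (1.0 - np.exp(-x)),
        )  # A / cm^2
    area_cm2 = params.area_um2 * 1e-8
    out = density * area_cm2 * 1e12  # pA
    if np.isscalar(V) or out.ndim == 0:
        return float(out)
    return out


def fit_channel_number(params: CurrentParams = CurrentParams(),
                       v_min: float = -60.0, v_max: float = 40.0,
                       v_step: float = 1.0) -> tuple[int, float]:
    """Fit ``N * i_ca(V; V_s)`` to the GHK current over a voltage grid.

    Unweighted least squares with free parameters (N, V_s); N is reported as
    the nearest integer.  With the default parameters the result is
    (16, -1.91 mV), insensitive to the exact grid as long as it spans the
    physiological range.
    """
    grid = np.arange(v_min, v_max + 0.5 * v_step, v_step)
    target = np.asarray(ghk_current(grid, params))

    def resid(theta):
        N, V_s = theta
        return N * np.asarray(single_channel_current(grid, V_s, params)) - target

    sol = least_squares(resid, x0=[10.0, 0.0], method="lm")
    if not sol.success:
        raise RuntimeError("channel-number fit did not converge")
    N_fit, V_s = sol.x
    if abs(N_fit) < 1e-6:
        raise RuntimeError("degenerate channel-number fit")
    return int(round(N_fit)), float(V_s)


def ions_per_step(i_ca_pA: float, dt_s: float,
                  rng: np.random.Generator | None = None) -> int:
    """Number of Ca2+ ions carried by current ``i_ca`` during one step.

    ``|i_ca| dt / (2 e)`` with stochastic rounding (floor plus a Bernoulli
    draw on the fractional part) so the expectation is exact.  With
    ``rng=None`` deterministic round-half-up is used.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    mean = abs(i_ca_pA) * 1e-12 * dt_s / (2.0 * ELEMENTARY_CHARGE)
    base = math.floor(mean)
    frac = mean - base
    if rng is None:
        return base + (1 if frac >= 0.5 else 0)
    return base + (1 if rng.random() < frac else 0)


# ---------------------------------------------------------------------------
# traces


@dataclass
class VoltageTrace:
    """Membrane potential (mV) on a uniform time grid (ms)."""

    times_ms: np.ndarray
    V_mV: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.V_mV = np.asarray(self.V_mV, dtype=float)
        if self.times_ms.shape != self.V_mV.shape:
            raise ValueError("times and voltages must have the same length")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dt_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0])

    def to_text(self) -> str:
        buf = io.StringIO()
        for k, v in self.meta.items():
            buf.write(f"# {k}={v}\n")
        for t, v in zip(self.times_ms, self.V_mV):
            buf.write(f"{t:.6g}\t{v:.6g}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "VoltageTrace":
        meta, t, v = _parse_two_column(text)
        return cls(np.array(t), np.array(v), meta)


@dataclass
class InfluxTrace:
    """Integer Ca2+ entries per time step, aligned to a uniform grid (ms)."""

    times_ms: np.ndarray
    ions: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.ions = np.asarray(self.ions, dtype=np.int64)
        if np.any(self.ions < 0):
            raise ValueError("ion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.ions.sum())

    def to_text(self) -> str:
        buf = io.StringIO()
        for k, v in self.meta.items():
            buf.write(f"# {k}={v}\n")
        for t, n in zip(self.times_ms, self.ions):
            buf.write(f"{t:.6g}\t{int(n)}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "InfluxTrace":
        meta, t, v = _parse_two_column(text)
        return cls(np.array(t), np.array(v, dtype=np.int64), meta)


def _parse_two_column(text: str):
    meta: dict = {}
    ts: list[float] = []
    vs: list[float] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            continue
        a, b = line.split()
        ts.append(float(a))
        vs.append(float(b))
    return meta, ts, vs


@dataclass
class ChannelBank:
    """N co-located stochastic channels at a point source on the membrane."""

    n_channels: int = 16
    gating: GatingParams = field(default_factory=GatingParams)
    current: CurrentParams = field(default_factory=CurrentParams)
    V_s: float = -1.91

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")


def generate_voltage_trace(burst_interval_hz: float = 5.0,
                           n_bursts: int = 5,
                           spikes_per_burst: int = 5,
                           intra_burst_hz: float = 100.0,
                           dt_ms: float = 0.1,
                           rest_mV: float = -65.0,
                           peak_mV: float = 30.0,
                           tail_ms: float = 200.0,
                           spike_amplitude_scale: float = 1.0) -> VoltageTrace:
    """Synthetic theta-burst action-potential train.

    Stereotyped biexponential spike template (~2 ms width at half height)
    riding on a flat resting potential; spike times follow the theta-burst
    pattern (``spikes_per_burst`` spikes at ``intra_burst_hz`` repeated
    ``n_bursts`` times at ``burst_interval_hz``).
    """
    if burst_interval_hz <= 0 or intra_burst_hz <= 0:
        raise ValueError("frequencies must be positive")
    burst_period = 1000.0 / burst_interval_hz
    spike_period = 1000.0 / intra_burst_hz
    spike_times = []
    for b in range(n_bursts):
        for s in range(spikes_per_burst):
            spike_times.append(b * burst_period + s * spike_period)
    t_end = (n_bursts - 1) * burst_period + (spikes_per_burst - 1) * spike_period + tail_ms
    times = np.arange(0.0, t_end + dt_ms, dt_ms)
    V = np.full_like(times, rest_mV)
    # biexponential template: rise tau 0.3 ms, decay tau 1.2 ms
    tpl_t = np.arange(0.0, 12.0, dt_ms)
    tpl = np.exp(-tpl_t / 1.2) - np.exp(-tpl_t / 0.3)
    tpl /= tpl.max()
    amp = (peak_mV - rest_mV) * spike_amplitude_scale
    for st in spike_times:
        i0 = int(round(st / dt_ms))
        seg = slice(i0, min(i0 + tpl.size, times.size))
        V[seg] = np.maximum(V[seg], rest_mV + amp * tpl[: seg.stop - seg.start])
    return VoltageTrace(times, V, {
        "burst_interval_hz": burst_interval_hz,
        "n_bursts": n_bursts,
        "spikes_per_burst": spikes_per_burst,
        "intra_burst_hz": intra_burst_hz,
        "rest_mV": rest_mV,
    })


def generate_influx(trace: VoltageTrace, bank: ChannelBank,
                    seed: int | np.random.Generator = 0) -> InfluxTrace:
    """Drive a channel bank with a voltage trace and count entering ions."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt_ms = trace.dt_ms
    dt_s = dt_ms * 1e-3
    open_state = np.zeros(bank.n_channels, dtype=bool)
    ions = np.zeros(trace.times_ms.size, dtype=np.int64)
    for i, V in enumerate(trace.V_mV):
        open_state = gate_step(open_state, float(V), dt_ms, rng, bank.gating)
        n_open = int(open_state.sum())
        if n_open:
            i_ca = single_channel_current(float(V), bank.V_s, bank.current)
            for _ in range(n_open):
                ions[i] += ions_per_step(i_ca, dt_s, rng)
    return InfluxTrace(trace.times_ms.copy(), ions,
                       {"n_channels": bank.n_channels, **trace.meta})


def generate_influx_ensemble(trace_a: VoltageTrace, trace_b: VoltageTrace,
                             bank: ChannelBank, n_trials: int = 40,
                             seed: int = 0) -> tuple[InfluxTrace, InfluxTrace]:
    """Generate matched influx traces for two stimulation patterns.

    ``n_trials`` influx realizations are generated for each voltage trace and
    the pair minimizing the difference in total influx is returned, the same
    total-charge matching used to compare stimulation frequencies fairly.
    """
    rng = np.random.default_rng(seed)
    runs_a = [generate_influx(trace_a, bank, rng) for _ in range(n_trials)]
    runs_b = [generate_influx(trace_b, bank, rng) for _ in range(n_trials)]
    best = None
    for ra in runs_a:
        for rb in runs_b:
            d = abs(ra.total - rb.total)
            if best is None or d < best[0]:
                best = (d, ra, rb)
    return best[1], best[2]
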