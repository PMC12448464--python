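"""Adaptive exponential integrate-and-fire (aEIF) neuron dynamics.

The membrane equation, in the internal coherent unit system
(mV, ms, µF, mS, µA), is

    c_m dV/dt = g_l (E_l - V) + g_l * Delta_T * exp((V - V_th)/Delta_T)
                + I_syn - w
    tau_w dw/dt = alpha (V - V_th) - w

with the reset rule: whenever V >= V_th the neuron spikes,
V -> V_reset, w -> w + b, and a refractory period (default 5 ms)
follows during which V is held at V_reset while w keeps evolving.

Cell geometry enters through the surface area A: c_m = C_m * A and
g_l = A / R_m, where C_m is the specific capacitance (µF/cm²) and R_m
the specific membrane resistance (kΩ·cm²).

Parameters are stored in the units they are conventionally reported in
(alpha in µS, b in nA, protocol currents in pA) and converted at the
boundary: 1 µS = 1e-3 mS, 1 nA = 1e-3 µA, 1 pA = 1e-6 µA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

SUBTYPES = ("GC", "BC", "MC", "HC")

# unit conversions into the internal (mV, ms, µF, mS, µA) system
US_TO_MS = 1e-3   # µS -> mS
NA_TO_UA = 1e-3   # nA -> µA
PA_TO_UA = 1e-6   # pA -> µA

PARAM_COLUMNS = (
    "C_m", "R_m", "A", "E_l", "V_th", "Delta_T",
    "V_reset", "tau_w", "alpha", "b",
)


class InvalidParameterError(ValueError):
    """Raised when neuron parameters violate their invariants."""


@dataclass
class NeuronParameters:
    """One aEIF parameter set for one cell.

    Units: C_m µF/cm²; R_m kΩ·cm²; A cm²; E_l, V_th, Delta_T, V_reset mV;
    tau_w ms; alpha µS; b nA.
    """

    C_m: float
    R_m: float
    A: float
    E_l: float
    V_th: float
    Delta_T: float
    V_reset: float
    tau_w: float
    alpha: float
    b: float
    subtype: str = "GC"

    def __post_init__(self) -> None:
        for name in ("C_m", "R_m", "A", "Delta_T", "tau_w"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.V_reset > self.V_th:
            raise InvalidParameterError(
                f"V_reset ({self.V_reset}) must not exceed V_th ({self.V_th})"
            )

    def as_row(self) -> dict:
        d = {k: getattr(self, k) for k in PARAM_COLUMNS}
        d["subtype"] = self.subtype
        return d

    @classmethod
    def from_row(cls, row) -> "NeuronParameters":
        return cls(**{k: float(row[k]) for k in PARAM_COLUMNS}, subtype=str(row["subtype"]))


@dataclass
class NeuronState:
    """Dynamic state of one neuron: V_m (mV), w (µA), refractory time left (ms)."""

    V_m: float
    w: float = 0.0
    refractory_remaining: float = 0.0


@dataclass
class EngineConfig:
    """Integration settings shared by all simulations.

    dt: forward-Euler step (ms). refractory_period: post-spike lockout (ms).
    exp_arg_cap: ceiling on the exponential argument (V - V_th)/Delta_T so
    the spike-initiation term never overflows within a step.
    settle_ms: equilibration segment preceding stimulus onset in
    current-clamp protocols.
    """

    dt: float = 0.1
    refractory_period: float = 5.0
    exp_arg_cap: float = 20.0
    settle_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")


def derive_membrane_coefficients(params: NeuronParameters) -> tuple[float, float]:
    """Return (c_m in µF, g_l in mS) from specific quantities and area."""
    if params.A <= 0 or params.R_m <= 0:
        raise InvalidParameterError("A and R_m must be positive")
    return params.C_m * params.A, params.A / params.R_m


@dataclass
class PackedParameters:
    """Column arrays of derived parameters for vectorized integration.

    All values are in internal units (c_m µF, g_l mS, alpha mS, b µA).
    """

    c_m: np.ndarray
    g_l: np.ndarray
    E_l: np.ndarray
    V_th: np.ndarray
    Delta_T: np.ndarray
    V_reset: np.ndarray
    tau_w: np.ndarray
    alpha: np.ndarray
    b: np.ndarray

    @property
    def n(self) -> int:
        return self.c_m.size

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "PackedParameters":
        get = lambda k: np.asarray(table[k], dtype=float)
        A = get("A")
        return cls(
            c_m=get("C_m") * A,
            g_l=A / get("R_m"),
            E_l=get("E_l"),
            V_th=get("V_th"),
            Delta_T=get("Delta_T"),
            V_reset=get("V_reset"),
            tau_w=get("tau_w"),
            alpha=get("alpha") * US_TO_MS,
            b=get("b") * NA_TO_UA,
        )

    @classmethod
    def from_params(cls, params: NeuronParameters | Sequence[NeuronParameters]) -> "PackedParameters":
        if isinstance(params, NeuronParameters):
            params = [params]
        return cls.from_table(pd.DataFrame([p.as_row() for p in params]))


def step_batch(
    V: np.ndarray,
    w: np.ndarray,
    refr: np.ndarray,
    P: PackedParameters,
    I_syn: np.ndarray | float,
    config: EngineConfig,
) -> np.ndarray:
    """Advance a batch of neurons by one forward-Euler step, in place.

    ``V``, ``w``, ``refr`` are updated in place; returns the boolean spike
    mask. ``I_syn`` is the total synaptic/injected current in µA. During the
    refractory window the membrane is clamped at V_reset while w evolves.
    """
    # parameter columns broadcast over any trailing batch axis of the state
    ax = (slice(None),) + (None,) * (V.ndim - 1)
    g_l, E_l, V_th, Delta_T = P.g_l[ax], P.E_l[ax], P.V_th[ax], P.Delta_T[ax]
    V_reset, c_m, tau_w, alpha, b = (
        P.V_reset[ax], P.c_m[ax], P.tau_w[ax], P.alpha[ax], P.b[ax])

    active = refr <= 0.0
    exp_arg = np.minimum((V - V_th) / Delta_T, config.exp_arg_cap)
    dV = (
        g_l * (E_l - V)
        + g_l * Delta_T * np.exp(exp_arg)
        + I_syn
        - w
    ) * (config.dt / c_m)
    dw = (alpha * (V - V_th) - w) * (config.dt / tau_w)
    np.add(w, dw, out=w)
    V += np.where(active, dV, 0.0)
    np.copyto(V, np.broadcast_to(V_reset, V.shape), where=~active)

    spiked = active & (V >= V_th)
    np.copyto(V, np.broadcast_to(V_reset, V.shape), where=spiked)
    w += np.where(spiked, np.broadcast_to(b, V.shape), 0.0)
    np.copyto(refr, np.maximum(refr - config.dt, 0.0))
    np.copyto(refr, config.refractory_period, where=spiked)
    return spiked


def step_neuron(
    state: NeuronState,
    params: NeuronParameters,
    I_syn_total: float,
    dt: float | None = None,
    config: EngineConfig | None = None,
) -> tuple[NeuronState, bool]:
    """Single-neuron convenience wrapper around :func:`step_batch`."""
    config = config or EngineConfig()
    if dt is not None:
        config = replace(config, dt=dt)
    P = PackedParameters.from_params(params)
    V = np.array([state.V_m], dtype=float)
    w = np.array([state.w], dtype=float)
    refr = np.array([state.refractory_remaining], dtype=float)
    spiked = step_batch(V, w, refr, P, float(I_syn_total), config)
    return NeuronState(float(V[0]), float(w[0]), float(refr[0])), bool(spiked[0])


@dataclass
class CurrentClampResult:
    """Voltage trace and spikes of a current-clamp run.

    ``t`` is in ms from stimulus onset (the settling segment has t < 0);
    spike times use the same axis.
    """

    t: np.ndarray
    V: np.ndarray
    spike_times: np.ndarray
    onset_ms: float


@dataclass
class BatchClampResult:
    """Decimated traces and spikes for a batch of neurons under step currents."""

    t: np.ndarray                 # ms from stimulus onset, decimated grid
    V: np.ndarray                 # (n, len(t))
    spike_times: list             # per neuron, ms from stimulus onset
    onset_ms: float


def simulate_step_clamp(
    P: PackedParameters,
    amp_pA: np.ndarray | float,
    duration_ms: float,
    config: EngineConfig | None = None,
    record_every: int = 10,
) -> BatchClampResult:
    """Constant-current step protocol for a batch of neurons.

    A settling segment of ``config.settle_ms`` at zero current precedes the
    stimulus. Traces are recorded every ``record_every`` steps (1 ms at the
    default dt) over the full run; spike times are exact to dt.
    """
    config = config or EngineConfig()
    dt = config.dt
    n = P.n
    amp = np.broadcast_to(np.asarray(amp_pA, dtype=float), (n,)) * PA_TO_UA

    n_settle = int(round(config.settle_ms / dt))
    n_stim = int(round(duration_ms / dt))
    n_steps = n_settle + n_stim

    V = P.E_l.astype(float).copy()
    w = np.zeros(n)
    refr = np.zeros(n)

    n_rec = n_steps // record_every + 1
    traces = np.empty((n, n_rec))
    traces[:, 0] = V
    rec_i = 1

    spike_steps: list[list[int]] = [[] for _ in range(n)]
    zero = np.zeros(n)
    for k in range(n_steps):
        I = amp if k >= n_settle else zero
        spiked = step_batch(V, w, refr, P, I, config)
        if spiked.any():
            for idx in np.flatnonzero(spiked):
                spike_steps[idx].append(k)
        if (k + 1) % record_every == 0:
            traces[:, rec_i] = V
            rec_i += 1

    t = (np.arange(n_rec) * record_every) * dt - config.settle_ms
    spikes = [
        (np.asarray(s, dtype=float) + 1.0) * dt - config.settle_ms for s in spike_steps
    ]
    return BatchClampResult(t=t, V=traces[:, :rec_i], spike_times=spikes, onset_ms=config.settle_ms)


def simulate_current_clamp(
    params: NeuronParameters,
    current_waveform: Callable[[np.ndarray], np.ndarray] | np.ndarray | float,
    duration: float,
    config: EngineConfig | None = None,
) -> CurrentClampResult:
    """Simulate one neuron under an injected-current waveform (pA).

    ``current_waveform`` may be a scalar amplitude, an array sampled at dt
    over [0, duration), or a callable of time (ms from onset). A settling
    segment precedes stimulus onset; the returned time axis is relative to
    onset (settling samples have t < 0).
    """
    config = config or EngineConfig()
    dt = config.dt
    n_settle = int(round(config.settle_ms / dt))
    n_stim = int(round(duration / dt))
    t_stim = np.arange(n_stim) * dt

    if callable(current_waveform):
        I_pA = np.asarray(current_waveform(t_stim), dtype=float)
        I_pA = np.broadcast_to(I_pA, (n_stim,))
    else:
        I_pA = np.broadcast_to(np.asarray(current_waveform, dtype=float), (n_stim,))
    I_uA = I_pA * PA_TO_UA

    P = PackedParameters.from_params(params)
    V = P.E_l.copy()
    w = np.zeros(1)
    refr = np.zeros(1)

    n_steps = n_settle + n_stim
    trace = np.empty(n_steps + 1)
    trace[0] = V[0]
    spike_steps = []
    for k in range(n_steps):
        I = I_uA[k - n_settle] if k >= n_settle else 0.0
        spiked = step_batch(V, w, refr, P, I, config)
        if spiked[0]:
            spike_steps.append(k)
        trace[k + 1] = V[0]

    t = np.arange(n_steps + 1) * dt - config.settle_ms
    spike_times = (np.asarray(spike_steps, dtype=float) + 1.0) * dt - config.settle_ms
    return CurrentClampResult(t=t, V=trace, spike_times=spike_times, onset_ms=config.settle_ms)


def parameters_to_table(params: Sequence[NeuronParameters]) -> pd.DataFrame:
    """Serialize parameter sets to a table (one row per neuron)."""
    return pd.DataFrame([p.as_row() for p in params])


def table_to_parameters(table: pd.DataFrame) -> list[NeuronParameters]:
    return [NeuronParameters.from_row(row) for _, row in table.iterrows()]
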