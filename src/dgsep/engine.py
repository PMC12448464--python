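"""Time-stepped simulation of the full dentate gyrus network.

Synapses follow a difference-of-exponentials conductance kernel

    u(t) = exp(-t / tau_decay) - exp(-t / tau_rise)

normalized by its analytic maximum so the projection weight gbar is the
true peak conductance. Each projection-receptor pair keeps two state
variables per postsynaptic neuron (the rise and decay exponentials),
advanced by exact per-step decay factors; a presynaptic spike increments
both after the projection's axonal delay (rounded to the nearest step).

Excitatory projections carry colocalized AMPA and NMDA receptors (E = 0
mV); NMDA conductances are scaled by the magnesium-block sigmoid

    s(V) = 1 / (1 + eta * [Mg]_o * exp(-gamma * V))

with eta = 0.28 mM^-1, [Mg]_o = 1 mM, gamma = 0.04 mV^-1. Inhibitory
projections carry GABA_A receptors (E = -90 mV). The synaptic drive
enters the membrane equation as g * (E_syn - V), so an excitatory
conductance depolarizes a hyperpolarized cell.

Optional additive zero-mean Gaussian noise (SD in pA) is applied to the
summed synaptic current of every neuron at every step. Simulations are
batched: the same network can be integrated against many input patterns
at once, which is how the 11-pattern morph set is evaluated. All four
populations are packed into one state array, so each step costs a fixed
small number of vectorized operations regardless of population count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dgsep.config import ENGINE
from dgsep.neuron import EngineConfig, PackedParameters, step_batch, PA_TO_UA
from dgsep.network import NetworkSpec, SUBTYPE_ORDER
from dgsep.patterns import SpikePattern


class SimulationDivergedError(RuntimeError):
    """Raised when a membrane state becomes non-finite."""


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the maximum of u(t) = exp(-t/tau_d) - exp(-t/tau_r)."""
    return math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)


def kernel_peak_value(tau_rise: float, tau_decay: float) -> float:
    tp = kernel_peak_time(tau_rise, tau_decay)
    return math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)


def mg_block(V_m, eta: float = 0.28, mg_out: float = 1.0, gamma: float = 0.04):
    """NMDA magnesium-block factor s(V); V_m in mV."""
    return 1.0 / (1.0 + eta * mg_out * np.exp(-gamma * np.asarray(V_m, dtype=float)))


def synaptic_current(V_m: float, receptor_states: list[dict]) -> float:
    """Total synaptic current drive (µA) for one neuron at one instant.

    Each receptor state is a dict with keys ``gbar`` (mS), ``decay`` and
    ``rise`` (current exponential state values), ``tau_rise``/``tau_decay``
    (ms), ``E_syn`` (mV) and optionally ``nmda`` (bool) plus Mg-block
    constants. The drive is summed as gbar * u_hat * (E_syn - V_m), with
    u_hat the peak-normalized kernel and NMDA terms scaled by s(V).
    """
    total = 0.0
    for st in receptor_states:
        norm = kernel_peak_value(st["tau_rise"], st["tau_decay"])
        g = st["gbar"] * (st["decay"] - st["rise"]) / norm
        if st.get("nmda", False):
            g *= float(mg_block(V_m, st.get("eta", 0.28), st.get("mg_out", 1.0),
                                st.get("gamma", 0.04)))
        total += g * (st["E_syn"] - V_m)
    return float(total)


@dataclass
class SimulationResult:
    """Spike rasters of one network simulation for one input pattern."""

    spikes: dict                      # subtype -> DataFrame(neuron_id, time_ms)
    duration: float
    analysis_window: tuple = tuple(ENGINE["analysis_window"])
    seed: int | None = None
    sizes: dict = field(default_factory=dict)

    def rate_vector(self, population: str, window: tuple | None = None) -> np.ndarray:
        """Per-neuron average firing rate (Hz) over the analysis window."""
        lo, hi = window or self.analysis_window
        df = self.spikes[population]
        n = self.sizes[population]
        in_win = df[(df["time_ms"] >= lo) & (df["time_ms"] < hi)]
        counts = np.bincount(in_win["neuron_id"].to_numpy(), minlength=n)
        return counts / ((hi - lo) / 1000.0)

    def trains(self, population: str, window: tuple | None = None) -> list[np.ndarray]:
        """Per-neuron spike-time arrays (ms), clipped to the window."""
        lo, hi = window or self.analysis_window
        df = self.spikes[population]
        n = self.sizes[population]
        out = [np.empty(0)] * n
        in_win = df[(df["time_ms"] >= lo) & (df["time_ms"] < hi)]
        for nid, grp in in_win.groupby("neuron_id"):
            out[int(nid)] = np.sort(grp["time_ms"].to_numpy())
        return out

    def to_events(self) -> pd.DataFrame:
        rows = []
        for pop, df in self.spikes.items():
            d = df.copy()
            d.insert(0, "population", pop)
            rows.append(d)
        return pd.concat(rows, ignore_index=True)


def _bin_pattern(pattern: SpikePattern, dt: float, n_steps: int) -> np.ndarray:
    """Spike counts per (step, train), uint8."""
    counts = np.zeros((n_steps, pattern.n_trains), dtype=np.uint8)
    for i, t in enumerate(pattern.trains):
        steps = np.minimum((t / dt).astype(int), n_steps - 1)
        np.add.at(counts[:, i], steps, 1)
    return counts


class _Bank:
    """Rise/decay states of one projection-receptor pair, batched."""

    __slots__ = ("scale", "E_syn", "fr", "fd", "rise", "decay", "nmda", "sl")

    def __init__(self, gbar, E_syn, tau_rise, tau_decay, dt, sl, n_post, B, nmda):
        self.scale = gbar / kernel_peak_value(tau_rise, tau_decay)
        self.E_syn = E_syn
        self.fr = math.exp(-dt / tau_rise)
        self.fd = math.exp(-dt / tau_decay)
        self.rise = np.zeros((n_post, B))
        self.decay = np.zeros((n_post, B))
        self.nmda = nmda
        self.sl = sl                  # postsynaptic slice in the packed state


def simulate_patterns(
    net: NetworkSpec,
    patterns: list[SpikePattern],
    config: EngineConfig | None = None,
    noise_sigma: float = 0.0,
    noise_unit_pA: float = 1.0,
    seed: int | None = None,
    duration_ms: float | None = None,
    analysis_window: tuple | None = None,
) -> list[SimulationResult]:
    """Integrate the network against a batch of input patterns.

    All patterns are simulated simultaneously (one batch axis), which
    amortizes the per-step cost across the morph set. With ``noise_sigma``
    zero the result is a pure function of (network, patterns, config);
    with noise it is reproducible given ``seed``.
    """
    config = config or EngineConfig(dt=ENGINE["dt"],
                                    refractory_period=ENGINE["refractory_period"])
    dt = config.dt
    B = len(patterns)
    if B == 0:
        return []
    duration = duration_ms or min(p.duration for p in patterns)
    if any(p.duration < duration for p in patterns):
        raise ValueError("pattern duration shorter than simulation duration")
    if any(p.n_trains != net.n_pp for p in patterns):
        raise ValueError(f"patterns must have {net.n_pp} trains")
    window = analysis_window or tuple(ENGINE["analysis_window"])
    n_steps = int(round(duration / dt))

    rng = np.random.default_rng(seed)
    noise_sd_uA = noise_sigma * noise_unit_pA * PA_TO_UA

    # binned PP spikes, stacked over the batch: (n_steps, n_pp, B)
    pp = np.stack([_bin_pattern(p, dt, n_steps) for p in patterns], axis=-1)
    pp_any = pp.reshape(n_steps, -1).any(axis=1)

    # pack the four populations into one state array
    sizes = {st: len(net.populations[st]) for st in SUBTYPE_ORDER}
    offsets, off = {}, 0
    for st in SUBTYPE_ORDER:
        offsets[st] = off
        off += sizes[st]
    n_total = off
    slices = {st: slice(offsets[st], offsets[st] + sizes[st]) for st in SUBTYPE_ORDER}
    packed = PackedParameters.from_table(
        pd.concat([net.populations[st] for st in SUBTYPE_ORDER], ignore_index=True))

    V = np.tile(packed.E_l[:, None], (1, B))
    w = np.zeros((n_total, B))
    refr = np.zeros((n_total, B))

    delays = {proj: max(int(round(s.delay / dt)), 1) for proj, s in net.synapses.items()}
    ring_len = {st: 1 for st in SUBTYPE_ORDER}
    for (pre, post), d in delays.items():
        if pre != "PP":
            ring_len[pre] = max(ring_len[pre], d + 1)
    ring = {st: np.zeros((ring_len[st], sizes[st], B)) for st in SUBTYPE_ORDER}
    ring_any = {st: np.zeros(ring_len[st], dtype=bool) for st in SUBTYPE_ORDER}

    banks: list[tuple] = []           # (projection, adj_T, bank objects)
    mg = net.mg_block
    for proj, s in net.synapses.items():
        post = proj[1]
        n_post, sl = sizes[post], slices[post]
        adj_T = net.adjacency[proj].T.tocsr()
        blist = [_Bank(s.gbar, s.E_syn, s.tau_rise, s.tau_decay, dt, sl, n_post, B, False)]
        if s.excitatory and s.nmda_ratio > 0:
            blist.append(_Bank(s.gbar * s.nmda_ratio, s.E_syn, s.nmda_tau_rise,
                               s.nmda_tau_decay, dt, sl, n_post, B, True))
        banks.append((proj, adj_T, blist))

    has_nmda = any(b.nmda for _, _, bl in banks for b in bl)
    mg_scale = mg["eta"] * mg["mg_out"]
    mg_gamma = mg["gamma"]

    events = {st: [] for st in SUBTYPE_ORDER}   # (step, neuron, batch) arrays
    I = np.empty((n_total, B))
    g_by_E: dict[float, np.ndarray] = {}
    for _, _, bl in banks:
        for b in bl:
            g_by_E.setdefault(b.E_syn, np.zeros((n_total, B)))

    check_every = 200
    for t in range(n_steps):
        # deliver delayed presynaptic spikes; advance receptor states
        for proj, adj_T, blist in banks:
            pre = proj[0]
            d = delays[proj]
            inc = None
            if t >= d:
                if pre == "PP":
                    if pp_any[t - d]:
                        inc = adj_T @ pp[t - d].astype(float)
                else:
                    slot = (t - d) % ring_len[pre]
                    if ring_any[pre][slot]:
                        inc = adj_T @ ring[pre][slot]
            for b in blist:
                b.rise *= b.fr
                b.decay *= b.fd
                if inc is not None:
                    b.rise += inc
                    b.decay += inc

        # conductances grouped by reversal potential
        for g in g_by_E.values():
            g[:] = 0.0
        if has_nmda:
            s_of_V = 1.0 / (1.0 + mg_scale * np.exp(-mg_gamma * V))
        for _, _, blist in banks:
            for b in blist:
                gb = b.scale * (b.decay - b.rise)
                if b.nmda:
                    gb = gb * s_of_V[b.sl]
                g_by_E[b.E_syn][b.sl] += gb

        I[:] = 0.0
        for E, g in g_by_E.items():
            I += g * (E - V)
        if noise_sd_uA > 0:
            I += rng.normal(0.0, noise_sd_uA, size=I.shape)

        spiked = step_batch(V, w, refr, packed, I, config)
        any_spike = spiked.any()
        for st in SUBTYPE_ORDER:
            slot = t % ring_len[st]
            sub = spiked[slices[st]]
            sub_any = bool(any_spike and sub.any())
            ring[st][slot] = sub if sub_any else 0.0
            ring_any[st][slot] = sub_any
            if sub_any:
                nid, bb = np.nonzero(sub)
                events[st].append((np.full(nid.size, t), nid, bb))
        if (t % check_every == 0 or t == n_steps - 1) and not np.all(np.isfinite(V)):
            bad = np.argwhere(~np.isfinite(V))[0]
            raise SimulationDivergedError(
                f"non-finite membrane state (neuron {bad[0]}, pattern {bad[1]}) "
                f"near step {t} (t = {t * dt:.1f} ms)")

    # assemble per-pattern results
    concat = {}
    for st in SUBTYPE_ORDER:
        if events[st]:
            steps = np.concatenate([e[0] for e in events[st]])
            nid = np.concatenate([e[1] for e in events[st]])
            b = np.concatenate([e[2] for e in events[st]])
        else:
            steps = nid = b = np.empty(0, dtype=int)
        concat[st] = (steps, nid, b)
    results = []
    for k in range(B):
        spikes = {}
        for st in SUBTYPE_ORDER:
            steps, nid, b = concat[st]
            m = b == k
            spikes[st] = pd.DataFrame({
                "neuron_id": nid[m].astype(int),
                "time_ms": (steps[m] + 1.0) * dt,
            })
        results.append(SimulationResult(
            spikes=spikes, duration=duration, analysis_window=window,
            seed=seed, sizes=dict(sizes)))
    return results


def simulate_network(
    net: NetworkSpec,
    pattern: SpikePattern,
    config: EngineConfig | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    **kw,
) -> SimulationResult:
    """Simulate the network against a single input pattern."""
    return simulate_patterns(net, [pattern], config, noise_sigma=noise_sigma,
                             seed=seed, **kw)[0]


def compute_sparsity(
    result: SimulationResult,
    population: str,
    window: tuple | None = None,
) -> float:
    """1 minus the fraction of the population firing in the analysis window."""
    n = result.sizes[population]
    if n == 0:
        raise ValueError(f"population {population!r} is empty")
    lo, hi = window or result.analysis_window
    df = result.spikes[population]
    active = df.loc[(df["time_ms"] >= lo) & (df["time_ms"] < hi), "neuron_id"].nunique()
    return 1.0 - active / n
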