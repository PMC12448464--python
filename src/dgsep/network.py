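"""Dentate gyrus network construction and structural perturbations.

The microcircuit contains four populations — granule cells (GC, the
output population), basket cells (BC), mossy cells (MC) and HIPP cells
(HC) — plus the external perforant-path (PP) afferents, wired through
exactly eight projection classes:

    PP -> GC, PP -> HC          (afferent excitation)
    GC -> BC, GC -> MC          (feedback excitation onto interneurons)
    MC -> GC, MC -> BC          (hilar excitatory feedback)
    BC -> GC, HC -> GC          (perisomatic / dendritic inhibition)

Edges are realized from each projection's connection probability, either
independently per potential edge (Bernoulli) or with a fixed number of
presynaptic partners per target cell; all realized edges of a projection
share its scalar peak conductance (the projection "weight"), making the
synaptic search space eight-dimensional. Heterogeneous networks draw
non-repeating neurons from validated subtype populations; a homogeneous
counterpart replaces every neuron of a subtype with one base model while
conserving adjacency and weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from dgsep.config import (
    E_SYN,
    EXCITATORY_PRE,
    MG_BLOCK,
    PROJECTIONS,
    SYNAPSE_TABLE,
)

SUBTYPE_ORDER = ("GC", "BC", "MC", "HC")
INTERNEURONS = ("BC", "MC", "HC")


@dataclass
class SynapseSpec:
    """Kinetics, delay, probability and weight of one projection class."""

    projection: tuple
    gbar: float                       # peak conductance, mS (AMPA or GABA)
    tau_rise: float                   # ms
    tau_decay: float                  # ms
    delay: float                      # ms
    connection_probability: float
    nmda_ratio: float = 0.0           # NMDA gbar = ratio * AMPA gbar
    nmda_tau_rise: float = 5.0
    nmda_tau_decay: float = 50.0

    def __post_init__(self) -> None:
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")
        if not (0.0 <= self.connection_probability <= 1.0):
            raise ValueError("connection probability must lie in [0, 1]")

    @property
    def excitatory(self) -> bool:
        return self.projection[0] in EXCITATORY_PRE

    @property
    def E_syn(self) -> float:
        return E_SYN["AMPA"] if self.excitatory else E_SYN["GABA"]


@dataclass
class PerturbationSpec:
    """Gaussian weight jitter and/or synaptic-current noise settings.

    ``jitter_sigma``/``noise_sigma`` are the dimensionless levels (1, 3, 5
    for low/medium/high); native scales come from the config unit factors
    (mS per jitter unit, pA per noise unit).
    """

    jitter_sigma: float = 0.0
    noise_sigma: float = 0.0
    jitter_unit: float = 1e-6
    noise_unit: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be non-negative")


@dataclass
class NetworkSpec:
    """A fully wired DG network: neurons, adjacency, weights, kinetics."""

    populations: dict                 # subtype -> parameter DataFrame
    adjacency: dict                   # projection -> csr_matrix (n_pre, n_post)
    synapses: dict                    # projection -> SynapseSpec
    n_pp: int
    seed: int | None = None
    mg_block: dict = field(default_factory=lambda: dict(MG_BLOCK))

    def size(self, subtype: str) -> int:
        return len(self.populations[subtype])

    @property
    def weights(self) -> dict:
        return {proj: s.gbar for proj, s in self.synapses.items()}

    def with_weights(self, weights: dict) -> "NetworkSpec":
        syn = {proj: replace(s, gbar=float(weights.get(proj, s.gbar)))
               for proj, s in self.synapses.items()}
        return replace(self, synapses=syn)

    def edge_list(self) -> pd.DataFrame:
        """All edges as (pre_id, post_id, projection) delimited-text rows."""
        rows = []
        for (pre, post), A in self.adjacency.items():
            coo = A.tocoo()
            rows.append(pd.DataFrame({
                "pre_id": coo.row, "post_id": coo.col,
                "projection": f"{pre}->{post}"}))
        return pd.concat(rows, ignore_index=True)


class InsufficientModelsError(ValueError):
    """Raised when a valid population is too small for non-repeating draws."""


def _wire_bernoulli(rng, n_pre, n_post, p):
    if p <= 0.0:
        return sp.csr_matrix((n_pre, n_post))
    return sp.csr_matrix(rng.random((n_pre, n_post)) < p)


def _wire_fixed_in_degree(rng, n_pre, n_post, p):
    k = int(round(p * n_pre))
    if k <= 0:
        return sp.csr_matrix((n_pre, n_post))
    rows = np.concatenate([
        rng.choice(n_pre, size=k, replace=False) for _ in range(n_post)])
    cols = np.repeat(np.arange(n_post), k)
    return sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n_pre, n_post))


WIRING_MODES = {"bernoulli": _wire_bernoulli,
                "fixed_in_degree": _wire_fixed_in_degree}


def build_network(
    valid_populations: dict,
    counts: dict,
    synapse_config: dict | None = None,
    weights: dict | None = None,
    n_pp: int = 700,
    seed: int | None = None,
    wiring: str = "bernoulli",
) -> NetworkSpec:
    """Assemble a heterogeneous DG network.

    ``valid_populations`` maps subtype -> DataFrame of validated parameter
    rows; ``counts`` gives the population sizes. Neurons are drawn without
    replacement (non-repeating). Two wiring modes are available:
    ``"bernoulli"`` (default) realizes each potential edge independently
    with the projection's connection probability; ``"fixed_in_degree"``
    gives every postsynaptic cell exactly round(p * n_pre) distinct
    presynaptic partners, the fixed-divergence convention of anatomically
    grounded DG circuit models, which removes binomial in-degree spread.
    ``weights`` maps projections to peak conductances (mS).
    """
    if wiring not in WIRING_MODES:
        raise ValueError(f"unknown wiring mode {wiring!r}")
    wire = WIRING_MODES[wiring]
    rng = np.random.default_rng(seed)
    synapse_config = synapse_config or {k: dict(v) for k, v in SYNAPSE_TABLE.items()}
    weights = weights or {}

    populations = {}
    for st in SUBTYPE_ORDER:
        pool = valid_populations[st]
        need = counts[st]
        if len(pool) < need:
            raise InsufficientModelsError(
                f"{st}: need {need} non-repeating valid models, have {len(pool)}")
        idx = rng.choice(len(pool), size=need, replace=False)
        populations[st] = pool.iloc[idx].reset_index(drop=True)

    sizes = {"PP": n_pp, **{st: counts[st] for st in SUBTYPE_ORDER}}
    adjacency = {}
    synapses = {}
    for proj in PROJECTIONS:
        cfg = synapse_config[proj]
        pre, post = proj
        p = float(cfg["p"])
        adjacency[proj] = wire(rng, sizes[pre], sizes[post], p).astype(np.float64)
        synapses[proj] = SynapseSpec(
            projection=proj,
            gbar=float(weights.get(proj, 0.0)),
            tau_rise=float(cfg["tau_rise"]),
            tau_decay=float(cfg["tau_decay"]),
            delay=float(cfg["delay"]),
            connection_probability=p,
            nmda_ratio=float(cfg.get("nmda_ratio", 0.0)),
            nmda_tau_rise=float(cfg.get("nmda_tau_rise", 5.0)),
            nmda_tau_decay=float(cfg.get("nmda_tau_decay", 50.0)),
        )
    return NetworkSpec(populations=populations, adjacency=adjacency,
                       synapses=synapses, n_pp=n_pp, seed=seed)


def delete_subtype(net: NetworkSpec, subtype: str) -> NetworkSpec:
    """Silence one interneuron subtype by zeroing all its incident weights.

    Only BC, MC, or HC may be deleted; adjacency, neuron identities, and
    all other weights are untouched, so the manipulation is reversible and
    idempotent.
    """
    if subtype not in INTERNEURONS:
        raise ValueError(f"can only delete interneuron subtypes, not {subtype!r}")
    syn = {
        proj: (replace(s, gbar=0.0) if subtype in proj else s)
        for proj, s in net.synapses.items()
    }
    return replace(net, synapses=syn)


def jitter_weights(
    net: NetworkSpec,
    sigma: float,
    seed: int | None = None,
    unit: float = 1e-7,
) -> NetworkSpec:
    """Perturb each projection weight by an independent zero-mean Gaussian.

    The draw SD is ``sigma * unit`` (mS); jittered weights are floored at
    zero because a conductance cannot be negative.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    syn = {}
    for proj, s in net.synapses.items():
        delta = rng.normal(0.0, sigma * unit) if sigma > 0 else 0.0
        syn[proj] = replace(s, gbar=max(s.gbar + delta, 0.0))
    return replace(net, synapses=syn)


def make_homogeneous(net: NetworkSpec, base_models: dict) -> NetworkSpec:
    """Replace every neuron of each subtype by that subtype's base model.

    ``base_models`` maps subtype -> one parameter row (dict or Series).
    Adjacency and weights are conserved, so the homogeneous network is the
    exact structural counterpart of the heterogeneous one.
    """
    populations = {}
    for st, table in net.populations.items():
        base = base_models[st]
        row = dict(base) if not isinstance(base, dict) else base
        row = {**row, "subtype": st}
        populations[st] = pd.DataFrame([row] * len(table)).reset_index(drop=True)
    return replace(net, populations=populations)


# ---------------------------------------------------------------------------
# Persistence (hierarchical array container)
# ---------------------------------------------------------------------------

def save_network(net: NetworkSpec, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_pp"] = net.n_pp
        f.attrs["seed"] = -1 if net.seed is None else net.seed
        for st, table in net.populations.items():
            g = f.create_group(f"populations/{st}")
            for col in table.columns:
                if col == "subtype":
                    continue
                g.create_dataset(col, data=table[col].to_numpy(dtype=float))
        for proj, A in net.adjacency.items():
            name = f"{proj[0]}->{proj[1]}"
            g = f.create_group(f"adjacency/{name}")
            coo = A.tocoo()
            g.create_dataset("row", data=coo.row)
            g.create_dataset("col", data=coo.col)
            g.attrs["shape"] = A.shape
            s = net.synapses[proj]
            for k in ("gbar", "tau_rise", "tau_decay", "delay",
                      "connection_probability", "nmda_ratio",
                      "nmda_tau_rise", "nmda_tau_decay"):
                g.attrs[k] = getattr(s, k)


def load_network(path) -> NetworkSpec:
    with h5py.File(path, "r") as f:
        populations = {}
        for st in f["populations"]:
            cols = {k: f[f"populations/{st}/{k}"][...] for k in f[f"populations/{st}"]}
            table = pd.DataFrame(cols)
            table["subtype"] = st
            populations[st] = table
        adjacency = {}
        synapses = {}
        for name in f["adjacency"]:
            pre, post = name.split("->")
            g = f[f"adjacency/{name}"]
            shape = tuple(g.attrs["shape"])
            A = sp.csr_matrix(
                (np.ones(g["row"].shape[0]), (g["row"][...], g["col"][...])),
                shape=shape)
            adjacency[(pre, post)] = A
            synapses[(pre, post)] = SynapseSpec(
                projection=(pre, post),
                gbar=float(g.attrs["gbar"]),
                tau_rise=float(g.attrs["tau_rise"]),
                tau_decay=float(g.attrs["tau_decay"]),
                delay=float(g.attrs["delay"]),
                connection_probability=float(g.attrs["connection_probability"]),
                nmda_ratio=float(g.attrs["nmda_ratio"]),
                nmda_tau_rise=float(g.attrs["nmda_tau_rise"]),
                nmda_tau_decay=float(g.attrs["nmda_tau_decay"]),
            )
        seed = int(f.attrs["seed"])
        return NetworkSpec(populations=populations, adjacency=adjacency,
                           synapses=synapses, n_pp=int(f.attrs["n_pp"]),
                           seed=None if seed < 0 else seed)
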