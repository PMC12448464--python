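"""Default configuration: subtype parameters, search ranges, ephys bounds,
network architecture, synaptic kinetics, and weight-search ranges.

The quantitative entries below (base aEIF parameters per subtype, the
admissible electrophysiological ranges, connection probabilities, synaptic
kinetics/delays, NMDA:AMPA ratios, and synaptic-weight search ranges) are
implementer-chosen placeholder defaults, hand-tuned so that each subtype's
base model reproduces qualitatively realistic dentate gyrus
electrophysiology (sparse-firing granule cells, fast low-adaptation basket
cells, adapting mossy cells, excitable low-rheobase HIPP cells) and so that
the full pipeline — cell search, network construction, weight search —
functions end to end. They are editable config, not measured values: users
with access to subtype-specific experimental ranges should substitute
their own via :func:`load_config` / :func:`save_config`.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

# ---------------------------------------------------------------------------
# Base (hand-tuned) aEIF parameters per subtype.
# Units: C_m µF/cm², R_m kΩ·cm², A cm², voltages mV, tau_w ms, alpha µS, b nA.
# ---------------------------------------------------------------------------
BASE_PARAMETERS = {
    # sparse-firing principal cell: strong subthreshold adaptation (alpha
    # comparable to g_l) makes the cell a fluctuation detector whose firing
    # tracks coincidences among its afferents rather than its tonic drive
    "GC": dict(C_m=1.0, R_m=38.0, A=1.5e-4, E_l=-75.0, V_th=-45.0,
               Delta_T=2.0, V_reset=-60.0, tau_w=150.0, alpha=3e-3, b=0.03),
    # fast-spiking perisomatic interneuron: fast membrane, weak adaptation
    "BC": dict(C_m=0.9, R_m=12.0, A=0.8e-4, E_l=-65.0, V_th=-45.0,
               Delta_T=1.0, V_reset=-55.0, tau_w=50.0, alpha=2e-4, b=0.002),
    # hilar excitatory interneuron: moderate R_in, pronounced adaptation
    "MC": dict(C_m=1.0, R_m=25.0, A=1.25e-4, E_l=-68.0, V_th=-48.0,
               Delta_T=2.0, V_reset=-58.0, tau_w=150.0, alpha=1e-3, b=0.015),
    # dendritically targeting interneuron driven by the perforant path:
    # high R_in so the cell is recruited by currents just above 20 pA
    "HC": dict(C_m=0.8, R_m=45.0, A=0.7e-4, E_l=-65.0, V_th=-48.0,
               Delta_T=2.0, V_reset=-58.0, tau_w=120.0, alpha=5e-4, b=0.01),
}

# The stochastic search samples 9 of the 10 parameters; the specific
# membrane capacitance C_m is held at its subtype default (it is the
# least variable biophysical quantity of the ten).
SAMPLED_PARAMETERS = (
    "R_m", "A", "E_l", "V_th", "Delta_T", "V_reset", "tau_w", "alpha", "b",
)

# Relative half-widths of the uniform sampling ranges around the base
# value (scaled on the magnitude for voltages). Granule cells use tighter
# voltage/conductance ranges: their validation window is narrow, and the
# network-scale separation regime relies on granule-cell excitability being
# bounded by the signature measurements rather than spanning decades.
_RANGE_FRACTION = {
    "R_m": 0.30, "A": 0.30, "E_l": 0.06, "V_th": 0.06, "Delta_T": 0.50,
    "V_reset": 0.05, "tau_w": 0.40, "alpha": 0.60, "b": 0.60,
}
_RANGE_FRACTION_GC = {
    "R_m": 0.15, "A": 0.15, "E_l": 0.01, "V_th": 0.01, "Delta_T": 0.50,
    "V_reset": 0.02, "tau_w": 0.30, "alpha": 0.30, "b": 0.40,
}


def default_parameter_ranges() -> dict:
    """Uniform (min, max) sampling ranges per subtype and parameter."""
    ranges: dict = {}
    for st, base in BASE_PARAMETERS.items():
        ranges[st] = {}
        fractions = _RANGE_FRACTION_GC if st == "GC" else _RANGE_FRACTION
        for p in SAMPLED_PARAMETERS:
            v = base[p]
            half = fractions[p] * abs(v)
            lo, hi = v - half, v + half
            ranges[st][p] = (lo, hi)
        # keep the reset below the lowest admissible threshold so every
        # sampled model satisfies V_reset <= V_th
        th_lo = ranges[st]["V_th"][0]
        lo, hi = ranges[st]["V_reset"]
        ranges[st]["V_reset"] = (lo, min(hi, th_lo))
    return ranges


# ---------------------------------------------------------------------------
# Admissible electrophysiological ranges per subtype (placeholder bounds):
# tau_m ms, sag ratio, R_in MΩ, SFA ratio, f50 Hz, f150 Hz.
# ---------------------------------------------------------------------------
EPHYS_BOUNDS = {
    "GC": dict(tau_m=(5.0, 60.0), sag=(0.50, 0.80), R_in=(130.0, 190.0),
               SFA=(0.05, 1.0), f50=(0.0, 2.0), f150=(5.0, 18.0)),
    "BC": dict(tau_m=(5.0, 20.0), sag=(0.85, 1.0), R_in=(50.0, 250.0),
               SFA=(0.3, 1.05), f50=(0.0, 10.0), f150=(3.0, 120.0)),
    "MC": dict(tau_m=(10.0, 50.0), sag=(0.70, 1.0), R_in=(100.0, 350.0),
               SFA=(0.05, 0.9), f50=(0.0, 15.0), f150=(3.0, 80.0)),
    "HC": dict(tau_m=(12.0, 60.0), sag=(0.70, 1.0), R_in=(300.0, 1000.0),
               SFA=(0.05, 0.9), f50=(3.0, 60.0), f150=(10.0, 150.0)),
}

# Numbers of random models generated per subtype in the full-scale search.
FULL_SCALE_N_MODELS = {"GC": 100_000, "BC": 60_000, "MC": 10_000, "HC": 20_000}

# ---------------------------------------------------------------------------
# Network architecture. The microcircuit has exactly eight projection
# classes: the perforant path (PP) excites GC and HC; GC excites BC and MC;
# MC excites GC and BC; BC and HC inhibit GC.
# ---------------------------------------------------------------------------
POPULATION_SIZES = {"GC": 3600, "BC": 500, "MC": 180, "HC": 50}
N_PP_TRAINS = 700

PROJECTIONS = (
    ("PP", "GC"), ("PP", "HC"),
    ("GC", "BC"), ("GC", "MC"),
    ("MC", "GC"), ("MC", "BC"),
    ("BC", "GC"), ("HC", "GC"),
)
EXCITATORY_PRE = ("PP", "GC", "MC")
E_SYN = {"AMPA": 0.0, "NMDA": 0.0, "GABA": -90.0}

# Per-projection: connection probability, AMPA/GABA kinetics (ms), NMDA
# kinetics (ms) and NMDA:AMPA peak-conductance ratio, axonal delay (ms).
# The perforant-path projection onto granule cells is sparse (each GC
# samples a small subset of afferents, so its drive depends strongly on
# which trains it receives); inhibitory convergence onto granule cells is
# dense, giving every GC comparable inhibitory coverage.
SYNAPSE_TABLE = {
    ("PP", "GC"): dict(p=0.02, tau_rise=0.5, tau_decay=3.0,
                       nmda_tau_rise=5.0, nmda_tau_decay=50.0,
                       nmda_ratio=0.5, delay=3.0),
    ("PP", "HC"): dict(p=0.20, tau_rise=0.5, tau_decay=3.0,
                       nmda_tau_rise=5.0, nmda_tau_decay=50.0,
                       nmda_ratio=0.5, delay=3.0),
    ("GC", "BC"): dict(p=0.10, tau_rise=0.3, tau_decay=2.0,
                       nmda_tau_rise=5.0, nmda_tau_decay=50.0,
                       nmda_ratio=0.3, delay=1.0),
    ("GC", "MC"): dict(p=0.10, tau_rise=0.5, tau_decay=3.0,
                       nmda_tau_rise=5.0, nmda_tau_decay=50.0,
                       nmda_ratio=0.5, delay=1.5),
    ("MC", "GC"): dict(p=0.05, tau_rise=0.5, tau_decay=3.0,
                       nmda_tau_rise=5.0, nmda_tau_decay=50.0,
                       nmda_ratio=0.5, delay=2.0),
    ("MC", "BC"): dict(p=0.10, tau_rise=0.5, tau_decay=3.0,
                       nmda_tau_rise=5.0, nmda_tau_decay=50.0,
                       nmda_ratio=0.3, delay=2.0),
    ("BC", "GC"): dict(p=0.40, tau_rise=0.5, tau_decay=7.0,
                       nmda_ratio=0.0, delay=1.0),
    ("HC", "GC"): dict(p=0.40, tau_rise=1.0, tau_decay=10.0,
                       nmda_ratio=0.0, delay=2.0),
}

# How projections are realized: "fixed_in_degree" gives every postsynaptic
# cell exactly round(p * n_pre) presynaptic partners (the fixed-divergence
# convention of anatomically grounded DG models); "bernoulli" realizes each
# potential edge independently with probability p.
WIRING_MODE = "fixed_in_degree"

# Uniform sampling ranges for the 8 synaptic peak conductances (mS) used by
# the network-scale weight search; centred on a hand-tuned pattern-separating
# configuration.
WEIGHT_RANGES = {
    ("PP", "GC"): (8.0e-6, 2.2e-5),
    ("PP", "HC"): (2.0e-7, 8.0e-7),
    ("GC", "BC"): (1.0e-5, 3.0e-5),
    ("GC", "MC"): (2.0e-6, 8.0e-6),
    ("MC", "GC"): (1.0e-6, 6.0e-6),
    ("MC", "BC"): (1.0e-6, 4.0e-6),
    ("BC", "GC"): (1.0e-5, 3.0e-5),
    ("HC", "GC"): (4.0e-6, 1.2e-5),
}

# Pattern-separation validation bounds (A_PS, A_PC, T_PCPS, PS_max).
PS_BOUNDS = dict(A_PS_min=0.15, A_PC_max=0.02, T_PCPS_max=0.25, PS_max_min=0.2)

# NMDA receptor magnesium-block sigmoid constants.
MG_BLOCK = dict(eta=0.28, mg_out=1.0, gamma=0.04)   # mM⁻¹, mM, mV⁻¹

# Perturbation levels and their native-unit scale factors. Jitter SDs are
# sigma * jitter_unit (mS); noise SDs are sigma * noise_unit (pA).
PERTURBATIONS = dict(levels=dict(low=1.0, medium=3.0, high=5.0),
                     jitter_unit=1e-6, noise_unit=20.0)

ENGINE = dict(dt=0.1, refractory_period=5.0, duration_ms=2000.0,
              analysis_window=(500.0, 2000.0))

INPUTS = dict(n_trains=N_PP_TRAINS, rate_hz=8.0, duration_ms=2000.0,
              rate_distribution="poisson",
              betas=[round(0.1 * k, 1) for k in range(11)])

# Desk-scale experiment profile: a reduced network that preserves the
# population proportions and wiring statistics of the full model while
# keeping a complete weight search tractable on a single core.
DESK_SCALE = dict(
    counts={"GC": 240, "BC": 40, "MC": 16, "HC": 8},
    n_pp=200,
    n_cells={"GC": 1200, "BC": 400, "MC": 400, "HC": 400},
    n_candidates=60,
)


def default_config() -> dict:
    """Assemble the full default configuration as one plain dictionary."""
    return {
        "base_parameters": copy.deepcopy(BASE_PARAMETERS),
        "neuron_ranges": default_parameter_ranges(),
        "ephys_bounds": copy.deepcopy(EPHYS_BOUNDS),
        "network": {
            "counts": dict(POPULATION_SIZES),
            "n_pp": N_PP_TRAINS,
            "wiring": WIRING_MODE,
            "synapses": {f"{a}->{b}": dict(v) for (a, b), v in SYNAPSE_TABLE.items()},
        },
        "weight_ranges": {f"{a}->{b}": list(v) for (a, b), v in WEIGHT_RANGES.items()},
        "ps_bounds": dict(PS_BOUNDS),
        "mg_block": dict(MG_BLOCK),
        "perturbations": copy.deepcopy(PERTURBATIONS),
        "engine": dict(ENGINE),
        "inputs": copy.deepcopy(INPUTS),
    }


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dictionary (provenance tag)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def projection_key(name: str) -> tuple[str, str]:
    pre, post = name.split("->")
    return pre.strip(), post.strip()
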