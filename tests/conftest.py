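"""Shared fixtures: small validated populations and tiny networks.

Everything is generated programmatically at session start; the sizes are
deliberately small so the whole suite runs on one core in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dgsep import config as cfg
from dgsep.cell_search import run_cell_mpmoss
from dgsep.experiments import build_network_from_config
from dgsep.neuron import NeuronParameters
from dgsep.patterns import base_pattern_pair, morph_patterns

TINY_COUNTS = {"GC": 40, "BC": 8, "MC": 4, "HC": 2}
TINY_NPP = 60


@pytest.fixture(scope="session")
def base_params() -> dict:
    return {st: NeuronParameters(**p, subtype=st)
            for st, p in cfg.BASE_PARAMETERS.items()}


@pytest.fixture(scope="session")
def gc_params(base_params) -> NeuronParameters:
    return base_params["GC"]


@pytest.fixture(scope="session")
def passive_params() -> NeuronParameters:
    """A passive, non-adapting cell: closed forms apply exactly."""
    return NeuronParameters(C_m=1.0, R_m=20.0, A=1e-4, E_l=-70.0, V_th=-40.0,
                            Delta_T=0.5, V_reset=-60.0, tau_w=100.0,
                            alpha=0.0, b=0.0, subtype="GC")


@pytest.fixture(scope="session")
def valid_populations() -> dict:
    """Small validated populations of all four subtypes (seeded search)."""
    ranges = cfg.default_parameter_ranges()
    pops = {}
    for i, st in enumerate(("GC", "BC", "MC", "HC")):
        res = run_cell_mpmoss(ranges[st], cfg.EPHYS_BOUNDS, 150, 100 + i, subtype=st)
        pops[st] = res.valid_parameters()
    return pops


@pytest.fixture(scope="session")
def tiny_network(valid_populations):
    """A small wired network with mid-range weights (deterministic)."""
    weights = {proj: float(np.mean(rng)) for proj, rng in cfg.WEIGHT_RANGES.items()}
    return build_network_from_config(valid_populations, TINY_COUNTS,
                                     n_pp=TINY_NPP, seed=42, weights=weights)


@pytest.fixture(scope="session")
def tiny_patterns():
    P0, P1 = base_pattern_pair(TINY_NPP, 8.0, 2000.0, 77,
                               rate_distribution="poisson")
    return morph_patterns(P0, P1, seed=78)
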