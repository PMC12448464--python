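"""Network-scale experiments: weight search, deletions, robustness.

The network-scale stochastic search keeps the neuron assignment, the
adjacency, and the 11-pattern morph set fixed, samples the eight
projection weights uniformly within configured ranges, simulates every
candidate against all 11 patterns, quantifies separation with both
correlation metrics (average-rate r and instantaneous-rate R), and
accepts candidates whose 8 measurements satisfy the validation bounds.

On the accepted networks two perturbation studies run:

* deletion — each interneuron subtype (BC, MC, HC) is silenced in turn
  (3 x N_valid conditions), re-measuring separation, sparsity, and
  firing-rate summaries against baseline;
* robustness — Gaussian weight jitter and/or synaptic-current noise at
  low/medium/high levels (sigma = 1, 3, 5), applied to each heterogeneous
  network and its homogeneous counterpart, reporting percent changes in
  the 8 separation measurements relative to the unperturbed network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dgsep import config as cfg
from dgsep.engine import (
    SimulationDivergedError,
    compute_sparsity,
    simulate_patterns,
)
from dgsep.metrics import instantaneous_rate_correlation, rate_correlation
from dgsep.network import (
    INTERNEURONS,
    NetworkSpec,
    delete_subtype,
    jitter_weights,
    make_homogeneous,
)
from dgsep.neuron import EngineConfig
from dgsep.patterns import SpikePattern
from dgsep.psquant import PSMeasurements, ValidationBounds, quantify_curve, validate_network_ps

PS_COLUMNS = ("A_PS", "A_PC", "T_PCPS", "PS_max")


@dataclass
class NetworkSearchConfig:
    """Settings of the network-scale weight search."""

    weight_ranges: dict               # projection -> (lo, hi) in mS
    n_candidates: int = 100
    master_seed: int = 0
    ps_bounds: ValidationBounds = field(default_factory=ValidationBounds)
    analysis_window: tuple = tuple(cfg.ENGINE["analysis_window"])
    rate_dt_ms: float = 2.0           # sampling of smoothed instantaneous rates

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise ValueError("need at least one candidate")
        for proj, (lo, hi) in self.weight_ranges.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid weight range for {proj}")


def similarity_curves(
    net: NetworkSpec,
    patterns: list[SpikePattern],
    engine: EngineConfig | None = None,
    window: tuple | None = None,
    rate_dt_ms: float = 2.0,
    noise_sigma: float = 0.0,
    noise_unit_pA: float = 1.0,
    seed: int | None = None,
) -> dict:
    """Simulate the morph set and build S_out-vs-S_in curves for r and R.

    Input similarity uses the input patterns' per-train rates/trains over
    the analysis window; output similarity uses the granule cell rasters.
    Returns per-metric (s_in, s_out) arrays plus per-population sparsity
    and firing-rate summaries of the baseline (beta = 0) response.
    """
    window = window or tuple(cfg.ENGINE["analysis_window"])
    results = simulate_patterns(net, patterns, engine, noise_sigma=noise_sigma,
                                noise_unit_pA=noise_unit_pA, seed=seed,
                                analysis_window=window)
    from dgsep.patterns import pattern_rate_map

    P0 = patterns[0]
    out0_rates = results[0].rate_vector("GC")
    out0_trains = results[0].trains("GC")
    in0_rates = pattern_rate_map(P0, window)

    s_in = {"r": [], "R": []}
    s_out = {"r": [], "R": []}
    betas = []
    for P, res in zip(patterns, results):
        betas.append(P.beta)
        s_in["r"].append(rate_correlation(in0_rates, pattern_rate_map(P, window)))
        s_out["r"].append(rate_correlation(out0_rates, res.rate_vector("GC")))
        s_in["R"].append(instantaneous_rate_correlation(
            P0.trains, P.trains, window, dt_ms=rate_dt_ms))
        s_out["R"].append(instantaneous_rate_correlation(
            out0_trains, res.trains("GC"), window, dt_ms=rate_dt_ms))

    sparsity = {st: compute_sparsity(results[0], st) for st in results[0].sizes}
    rates = {st: results[0].rate_vector(st) for st in results[0].sizes}
    return {
        "betas": np.asarray(betas),
        "s_in": {k: np.asarray(v) for k, v in s_in.items()},
        "s_out": {k: np.asarray(v) for k, v in s_out.items()},
        "sparsity": sparsity,
        "rates": rates,
        "results": results,
    }


def quantify_network(
    curves: dict,
) -> tuple[PSMeasurements | None, PSMeasurements | None]:
    """Cubic-fit separation measurements for both metrics (None if undefined)."""
    out = []
    for metric in ("r", "R"):
        s_in = curves["s_in"][metric]
        s_out = curves["s_out"][metric]
        if not (np.all(np.isfinite(s_in)) and np.all(np.isfinite(s_out))):
            out.append(None)
            continue
        out.append(quantify_curve(s_in, s_out, metric_id=metric))
    return out[0], out[1]


def evaluate_network(
    net: NetworkSpec,
    patterns: list[SpikePattern],
    engine: EngineConfig | None = None,
    ps_bounds: ValidationBounds | None = None,
    rate_dt_ms: float = 2.0,
    noise_sigma: float = 0.0,
    noise_unit_pA: float = 1.0,
    seed: int | None = None,
) -> dict:
    """One candidate, end to end: simulate, quantify, validate."""
    curves = similarity_curves(net, patterns, engine, rate_dt_ms=rate_dt_ms,
                               noise_sigma=noise_sigma,
                               noise_unit_pA=noise_unit_pA, seed=seed)
    meas_r, meas_R = quantify_network(curves)
    valid, per = validate_network_ps(meas_r, meas_R, ps_bounds)
    return {
        "curves": curves, "meas_r": meas_r, "meas_R": meas_R,
        "valid": valid, "per_bound": per,
        "sparsity": curves["sparsity"],
    }


def _measurement_row(meas_r, meas_R) -> dict:
    row = {}
    for tag, m in (("r", meas_r), ("R", meas_R)):
        for k in PS_COLUMNS:
            row[f"{tag}:{k}"] = np.nan if m is None else getattr(m, k)
    return row


def run_network_mpmoss(
    base_net: NetworkSpec,
    patterns: list[SpikePattern],
    search: NetworkSearchConfig,
    engine: EngineConfig | None = None,
) -> pd.DataFrame:
    """Stochastic search over the eight projection weights.

    Every candidate shares the base network's neurons and adjacency and
    differs only in its weight vector. The returned table has one row per
    candidate: the 8 weights, the 8 separation measurements, per-population
    sparsity, a validity flag, and an error marker for candidates whose
    simulation failed (the search continues past failures).
    """
    rng = np.random.default_rng(search.master_seed)
    projections = list(search.weight_ranges)
    rows = []
    for k in range(search.n_candidates):
        weights = {proj: float(rng.uniform(*search.weight_ranges[proj]))
                   for proj in projections}
        net = base_net.with_weights(weights)
        row = {"candidate": k}
        row.update({f"w:{a}->{b}": v for (a, b), v in weights.items()})
        try:
            ev = evaluate_network(net, patterns, engine, search.ps_bounds,
                                  rate_dt_ms=search.rate_dt_ms)
            row.update(_measurement_row(ev["meas_r"], ev["meas_R"]))
            row.update({f"sparsity:{st}": v for st, v in ev["sparsity"].items()})
            row["valid"] = bool(ev["valid"])
            row["error"] = ""
        except SimulationDivergedError as exc:
            row["valid"] = False
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["master_seed"] = search.master_seed
    return table


def weights_from_row(row: pd.Series) -> dict:
    out = {}
    for col, v in row.items():
        if isinstance(col, str) and col.startswith("w:"):
            pre, post = col[2:].split("->")
            out[(pre, post)] = float(v)
    return out


def valid_networks_from_search(
    base_net: NetworkSpec,
    search_table: pd.DataFrame,
) -> list[NetworkSpec]:
    """Rebuild the accepted candidates as network objects."""
    valid = search_table[search_table["valid"].astype(bool)]
    return [base_net.with_weights(weights_from_row(row)) for _, row in valid.iterrows()]


def deletion_study(
    valid_nets: list[NetworkSpec],
    patterns: list[SpikePattern],
    engine: EngineConfig | None = None,
    rate_dt_ms: float = 2.0,
) -> pd.DataFrame:
    """Interneuron-deletion experiment over the accepted networks.

    For every network and every interneuron subtype, the subtype's synapses
    are zeroed and the full 11-pattern protocol re-run, yielding exactly
    3 x N_valid perturbed conditions plus the baselines. Reports the 8
    separation measurements, per-population sparsity, and mean firing
    rates, with percent changes relative to each network's baseline.
    """
    rows = []
    for i, net in enumerate(valid_nets):
        conditions = [("baseline", net)]
        conditions += [(f"delete_{st}", delete_subtype(net, st)) for st in INTERNEURONS]
        base_row = None
        for cond, cnet in conditions:
            ev = evaluate_network(cnet, patterns, engine, rate_dt_ms=rate_dt_ms)
            row = {"network": i, "condition": cond}
            row.update(_measurement_row(ev["meas_r"], ev["meas_R"]))
            row.update({f"sparsity:{st}": v for st, v in ev["sparsity"].items()})
            row.update({f"mean_rate:{st}": float(np.mean(v))
                        for st, v in ev["curves"]["rates"].items()})
            row["valid"] = bool(ev["valid"])
            if cond == "baseline":
                base_row = row
            else:
                for k, v in list(row.items()):
                    if isinstance(v, float) and k in base_row:
                        base = base_row[k]
                        defined = (base != 0.0 and np.isfinite(base)
                                   and np.isfinite(v))
                        row[f"pct_change:{k}"] = (
                            100.0 * (v - base) / abs(base) if defined else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def robustness_study(
    valid_nets: list[NetworkSpec],
    patterns: list[SpikePattern],
    base_models: dict,
    engine: EngineConfig | None = None,
    levels: dict | None = None,
    jitter_unit: float | None = None,
    noise_unit: float | None = None,
    master_seed: int = 0,
    rate_dt_ms: float = 2.0,
    modes: tuple = ("jitter", "noise", "both"),
) -> pd.DataFrame:
    """Jitter/noise robustness of heterogeneous vs homogeneous networks.

    Each heterogeneous network is paired with its homogeneous counterpart
    (same adjacency and weights, one base model per subtype). For every
    network, cohort, perturbation mode and level, the 8 separation
    measurements are recomputed and reported as percent change against that
    cohort's unperturbed network.
    """
    pert = cfg.PERTURBATIONS
    levels = levels or dict(pert["levels"])
    jitter_unit = pert["jitter_unit"] if jitter_unit is None else jitter_unit
    noise_unit = pert["noise_unit"] if noise_unit is None else noise_unit
    rng = np.random.default_rng(master_seed)

    rows = []
    for i, het in enumerate(valid_nets):
        hom = make_homogeneous(het, base_models)
        for cohort, net in (("heterogeneous", het), ("homogeneous", hom)):
            base_ev = evaluate_network(net, patterns, engine, rate_dt_ms=rate_dt_ms)
            base = _measurement_row(base_ev["meas_r"], base_ev["meas_R"])
            rows.append({"network": i, "cohort": cohort, "mode": "none",
                         "level": "none", "sigma": 0.0, **base})
            for mode in modes:
                for name, sigma in levels.items():
                    jit = sigma if mode in ("jitter", "both") else 0.0
                    noi = sigma if mode in ("noise", "both") else 0.0
                    seed_j = int(rng.integers(2**31 - 1))
                    pnet = jitter_weights(net, jit, seed=seed_j, unit=jitter_unit) \
                        if jit > 0 else net
                    ev = evaluate_network(pnet, patterns, engine,
                                          rate_dt_ms=rate_dt_ms,
                                          noise_sigma=noi,
                                          noise_unit_pA=noise_unit,
                                          seed=seed_j + 1)
                    row = {"network": i, "cohort": cohort, "mode": mode,
                           "level": name, "sigma": sigma}
                    meas = _measurement_row(ev["meas_r"], ev["meas_R"])
                    row.update(meas)
                    for k, v in meas.items():
                        b = base[k]
                        row[f"pct_change:{k}"] = (
                            100.0 * (v - b) / abs(b)
                            if np.isfinite(v) and np.isfinite(b) and b != 0 else np.nan)
                    rows.append(row)
    return pd.DataFrame(rows)


def desk_scale_pipeline(
    master_seed: int,
    n_candidates: int | None = None,
    counts: dict | None = None,
    n_pp: int | None = None,
    n_cells: dict | None = None,
    weight_ranges: dict | None = None,
    wiring: str | None = None,
) -> dict:
    """Run the full pipeline at the desk-scale profile.

    Cell searches for all four subtypes, heterogeneous network assembly,
    11-pattern morph set, and the weight search. Returns the populations,
    base network, patterns, and the search table. All randomness derives
    from ``master_seed``.
    """
    from dgsep.cell_search import search_all_subtypes

    prof = cfg.DESK_SCALE
    counts = counts or dict(prof["counts"])
    n_pp = n_pp or prof["n_pp"]
    n_cells = n_cells or dict(prof["n_cells"])
    n_candidates = n_candidates or prof["n_candidates"]
    weight_ranges = weight_ranges or dict(cfg.WEIGHT_RANGES)
    wiring = wiring or cfg.WIRING_MODE

    master = np.random.default_rng(master_seed)
    cell_seed, net_seed, pat_seed, search_seed = (
        int(master.integers(2**31 - 1)) for _ in range(4))

    searches = search_all_subtypes(
        n_cells, cfg.default_parameter_ranges(), cfg.EPHYS_BOUNDS, cell_seed)
    pops = {st: s.valid_parameters() for st, s in searches.items()}

    net = build_network_from_config(pops, counts, n_pp=n_pp, seed=net_seed,
                                    wiring=wiring)
    from dgsep.patterns import base_pattern_pair, morph_patterns

    ic = cfg.INPUTS
    P0, P1 = base_pattern_pair(n_pp, ic["rate_hz"], ic["duration_ms"], pat_seed,
                               rate_distribution=ic["rate_distribution"])
    patterns = morph_patterns(P0, P1, ic["betas"], seed=pat_seed + 1)

    search = NetworkSearchConfig(weight_ranges=weight_ranges,
                                 n_candidates=n_candidates,
                                 master_seed=search_seed)
    table = run_network_mpmoss(net, patterns, search)
    return {"searches": searches, "populations": pops, "network": net,
            "patterns": patterns, "search_table": table,
            "seeds": {"cells": cell_seed, "network": net_seed,
                      "patterns": pat_seed, "search": search_seed}}


def build_network_from_config(
    pops: dict,
    counts: dict,
    n_pp: int,
    seed: int,
    wiring: str | None = None,
    weights: dict | None = None,
):
    """Wire a network using the package synapse table and wiring mode."""
    from dgsep.network import build_network

    return build_network(pops, counts,
                         {k: dict(v) for k, v in cfg.SYNAPSE_TABLE.items()},
                         weights or {}, n_pp=n_pp, seed=seed,
                         wiring=wiring or cfg.WIRING_MODE)


def summarize_degeneracy(search_table: pd.DataFrame, bins: int = 20) -> dict:
    """Weight histograms and pairwise weight correlations over valid networks.

    Returns per-weight histograms, the 8 x 8 Pearson matrix with its
    defined-mask (cloned weights give undefined, not NaN-propagated,
    entries), and the list of the 28 unique off-diagonal coefficients.
    """
    from dgsep.cell_search import correlation_matrix

    valid = search_table[search_table["valid"].astype(bool)]
    wcols = [c for c in search_table.columns if isinstance(c, str) and c.startswith("w:")]
    if len(valid) < 3:
        raise ValueError("degeneracy summary needs at least 3 valid networks")
    weights = valid[wcols]
    histograms = {c: np.histogram(weights[c], bins=bins) for c in wcols}
    corr, mask = correlation_matrix(weights)
    iu = np.triu_indices(len(wcols), k=1)
    pairs = pd.DataFrame({
        "pair": [f"{wcols[a]}|{wcols[b]}" for a, b in zip(*iu)],
        "r": corr.to_numpy()[iu],
        "defined": mask.to_numpy()[iu],
    })
    return {"histograms": histograms, "correlations": corr,
            "corr_defined": mask, "unique_pairs": pairs}
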