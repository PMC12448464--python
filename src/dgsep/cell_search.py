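"""Cellular-scale stochastic search for validated heterogeneous populations.

The multi-parametric multi-objective stochastic search (MPMOSS) samples
nine aEIF parameters independently and uniformly within subtype-specific
ranges, measures all six electrophysiological signatures of every sampled
model, and declares a model valid only when every measurement falls within
the subtype's admissible range. The surviving models form the
heterogeneous population from which networks draw their neurons.

Full-scale searches (100 000 GC / 60 000 BC / 10 000 MC / 20 000 HC
candidates) are configuration defaults; desk-scale profiles use a few
hundred to a few thousand candidates per subtype. Each subtype search
runs on its own random stream derived from a master seed, so results are
reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from dgsep.config import BASE_PARAMETERS, SAMPLED_PARAMETERS, config_hash
from dgsep.ephys import MEASUREMENT_NAMES, measure_all, validate_table
from dgsep.neuron import EngineConfig, PARAM_COLUMNS


@dataclass
class SearchResult:
    """Outcome of one subtype's stochastic search."""

    subtype: str
    parameters: pd.DataFrame          # all sampled models, one row each
    measurements: pd.DataFrame        # six measurements per model
    flags: pd.DataFrame               # per-measurement booleans + 'valid'
    seed: int
    provenance: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.parameters)

    @property
    def N_valid(self) -> int:
        return int(self.flags["valid"].sum())

    def valid_parameters(self) -> pd.DataFrame:
        return self.parameters.loc[self.flags["valid"]].reset_index(drop=True)

    def summary_row(self) -> dict:
        return {"subtype": self.subtype, "N": self.N, "N_valid": self.N_valid,
                "yield": self.N_valid / self.N if self.N else np.nan,
                "seed": self.seed}


def sample_neuron_parameters(
    ranges: dict,
    n: int,
    seed: int | np.random.Generator,
    subtype: str = "GC",
    base: dict | None = None,
) -> pd.DataFrame:
    """Draw ``n`` parameter sets uniformly within the subtype's ranges.

    ``ranges`` maps parameter name -> (min, max); parameters absent from
    the map are held at the subtype's base value, so the sampled-parameter
    list is configuration-driven (nine by default, with C_m fixed).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not ranges:
        raise ValueError("empty parameter-range table")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = dict(base or BASE_PARAMETERS[subtype])
    table = {}
    for p in PARAM_COLUMNS:
        if p in ranges:
            lo, hi = ranges[p]
            if lo > hi:
                raise ValueError(f"range for {p} has min > max")
            table[p] = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, float(lo))
        else:
            table[p] = np.full(n, float(base[p]))
    df = pd.DataFrame(table)
    df["subtype"] = subtype
    return df


def run_cell_mpmoss(
    ranges: dict,
    bounds: dict,
    n: int,
    seed: int,
    subtype: str = "GC",
    config: EngineConfig | None = None,
    base: dict | None = None,
) -> SearchResult:
    """Sample, measure, and validate ``n`` candidate models of one subtype.

    Every sampled model is measured with all six protocols and validated
    against the subtype's bounds; models whose protocols fail (eg, spiking
    during a subthreshold pulse) are recorded as invalid rather than
    dropped. The result carries full provenance (seed, config hash).
    """
    params = sample_neuron_parameters(ranges, n, seed, subtype, base)
    measurements = measure_all(params, config)
    flags = validate_table(measurements, bounds, params["subtype"])
    prov = {
        "seed": seed,
        "config_hash": config_hash({"ranges": {k: list(v) for k, v in ranges.items()},
                                    "bounds": bounds[subtype]}),
        "n": n,
    }
    return SearchResult(subtype=subtype, parameters=params,
                        measurements=measurements, flags=flags,
                        seed=seed, provenance=prov)


def correlation_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with an explicit defined-mask.

    Zero-variance columns yield undefined correlations: the value matrix
    holds NaN there and the companion boolean mask is False, so undefined
    entries are flagged rather than silently propagated.
    """
    cols = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    X = table[cols].to_numpy(dtype=float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    defined = np.outer(sd > 0, sd > 0) & np.isfinite(C)
    values = pd.DataFrame(np.where(defined, C, np.nan), index=cols, columns=cols)
    mask = pd.DataFrame(defined, index=cols, columns=cols)
    return values, mask


def population_summary(result: SearchResult, bins: int = 30) -> dict:
    """Histograms and pairwise correlations of valid models.

    Returns per-parameter and per-measurement histograms plus the two
    correlation matrices (with defined-masks) over the valid population.
    """
    valid = result.flags["valid"]
    if int(valid.sum()) < 3:
        raise ValueError("population summary needs at least 3 valid models")
    params = result.parameters.loc[valid, list(SAMPLED_PARAMETERS)]
    meas = result.measurements.loc[valid, list(MEASUREMENT_NAMES)]
    histograms = {
        c: np.histogram(params[c].dropna(), bins=bins) for c in params.columns
    }
    histograms.update({
        c: np.histogram(meas[c].dropna(), bins=bins) for c in meas.columns
    })
    p_corr, p_mask = correlation_matrix(params)
    m_corr, m_mask = correlation_matrix(meas.dropna(axis=0))
    return {
        "histograms": histograms,
        "parameter_correlations": p_corr, "parameter_corr_defined": p_mask,
        "measurement_correlations": m_corr, "measurement_corr_defined": m_mask,
        "N": result.N, "N_valid": result.N_valid,
    }


def save_search_result(result: SearchResult, path) -> None:
    """Persist a search result as a hierarchical array container."""
    with h5py.File(path, "w") as f:
        f.attrs["subtype"] = result.subtype
        f.attrs["seed"] = result.seed
        f.attrs["config_hash"] = result.provenance.get("config_hash", "")
        for name, df in (("parameters", result.parameters),
                         ("measurements", result.measurements),
                         ("flags", result.flags)):
            g = f.create_group(name)
            for col in df.columns:
                if df[col].dtype == object:
                    continue
                g.create_dataset(col, data=df[col].to_numpy(dtype=float))


def load_search_result(path) -> SearchResult:
    with h5py.File(path, "r") as f:
        subtype = f.attrs["subtype"]
        tables = {}
        for name in ("parameters", "measurements", "flags"):
            cols = {k: f[f"{name}/{k}"][...] for k in f[name]}
            tables[name] = pd.DataFrame(cols)
        tables["parameters"]["subtype"] = subtype
        flags = tables["flags"].astype(bool)
        return SearchResult(subtype=str(subtype), parameters=tables["parameters"],
                            measurements=tables["measurements"], flags=flags,
                            seed=int(f.attrs["seed"]),
                            provenance={"config_hash": str(f.attrs["config_hash"])})


def search_all_subtypes(
    n_per_subtype: dict,
    ranges: dict,
    bounds: dict,
    master_seed: int,
    config: EngineConfig | None = None,
) -> dict:
    """Run the four independent subtype searches from one master seed."""
    master = np.random.default_rng(master_seed)
    out = {}
    for st in ("GC", "BC", "MC", "HC"):
        sub_seed = int(master.integers(2**31 - 1))
        out[st] = run_cell_mpmoss(ranges[st], bounds, n_per_subtype[st],
                                  sub_seed, subtype=st, config=config)
    return out
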