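"""Subtype-specific electrophysiological measurement protocols.

Six measurements characterize every model neuron:

* ``tau_m`` — membrane time constant from a single-exponential fit,
  V(t) = V_inf (1 - exp(-t/tau_m)) + V_0, to the charging response to a
  20 pA / 1500 ms pulse;
* ``sag`` — ratio of steady-state to peak voltage deflection for a
  -50 pA / 1 s pulse;
* ``R_in`` — slope of the steady-state deflection vs. injected current
  over a family of 1-s pulses (-40..40 pA step 10; HIPP cells use
  -20..20 pA step 5 because they fire above 20 pA);
* ``f50``, ``f150`` — spike counts for 1-s pulses of 50 and 150 pA;
* ``SFA`` — first over last inter-spike interval at 150 pA (defined
  only when the pulse elicits at least 3 spikes).

All protocols include a 500 ms settling segment before pulse onset;
baselines are averaged over the 100 ms preceding onset and steady states
over the last 10% of the pulse window. A model is valid only if all six
measurements fall within the subtype's admissible range; an undefined
measurement counts as a failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from dgsep.neuron import (
    EngineConfig,
    NeuronParameters,
    PackedParameters,
    simulate_step_clamp,
)

MEASUREMENT_NAMES = ("tau_m", "sag", "R_in", "SFA", "f50", "f150")

# R_in pulse families (pA): standard and low-rheobase (HC) variants
RIN_CURRENTS = {"default": np.arange(-40.0, 41.0, 10.0),
                "HC": np.arange(-20.0, 21.0, 5.0)}


@dataclass
class EphysMeasurements:
    """The six measurements for one neuron; NaN marks an undefined value."""

    tau_m: float
    sag: float
    R_in: float
    SFA: float
    f50: float
    f150: float
    V_inf: float = np.nan
    V_0: float = np.nan
    V_SS: float = np.nan
    V_peak: float = np.nan


def _baseline(res, n_baseline_ms: float = 100.0) -> np.ndarray:
    """Mean membrane potential over the window preceding pulse onset."""
    mask = (res.t >= -n_baseline_ms) & (res.t < 0.0)
    return res.V[:, mask].mean(axis=1)


def _steady_state(res, duration_ms: float, fraction: float = 0.1) -> np.ndarray:
    mask = (res.t >= duration_ms * (1.0 - fraction)) & (res.t <= duration_ms)
    return res.V[:, mask].mean(axis=1)


def _spike_counts(res, duration_ms: float) -> np.ndarray:
    return np.array([
        int(np.count_nonzero((s >= 0.0) & (s < duration_ms))) for s in res.spike_times
    ])


def _fit_single_exponential(t: np.ndarray, v: np.ndarray) -> tuple[float, float, float, float]:
    """Fit V = V_inf (1 - exp(-t/tau)) + V_0; return (tau, V_inf, V_0, rms)."""
    v0 = v[0]
    v_inf = v[-1] - v0
    # log-linear seed for tau from the normalized residual decay
    resid = 1.0 - (v - v0) / v_inf if v_inf != 0 else np.full_like(v, np.nan)
    ok = (resid > 1e-3) & (t > 0)
    if ok.sum() >= 3 and v_inf != 0:
        tau0 = -1.0 / np.polyfit(t[ok], np.log(resid[ok]), 1)[0]
        tau0 = float(np.clip(tau0, 0.1, 1e4))
    else:
        tau0 = max(t[-1] / 5.0, 1.0)

    def model(t, v_inf, tau, v0):
        # clip the argument: optimizer trial steps may visit tau <= 0
        return v_inf * (1.0 - np.exp(np.clip(-t / tau, -700.0, 50.0))) + v0

    try:
        with np.errstate(over="ignore", invalid="ignore"):
            popt, _ = curve_fit(model, t, v, p0=[v_inf, tau0, v0], maxfev=2000)
    except RuntimeError:
        return np.nan, np.nan, np.nan, np.nan
    rms = float(np.sqrt(np.mean((model(t, *popt) - v) ** 2)))
    return float(popt[1]), float(popt[0]), float(popt[2]), rms


def measure_all(
    table: pd.DataFrame,
    config: EngineConfig | None = None,
) -> pd.DataFrame:
    """Run all six protocols for every row of a parameter table.

    Returns a DataFrame aligned with ``table`` holding the six measurements
    (NaN where undefined) plus the sag/tau intermediates. Protocols are
    vectorized across models, so measuring a whole searched population costs
    a handful of batch simulations.
    """
    config = config or EngineConfig()
    P = PackedParameters.from_table(table)
    n = P.n
    subtypes = np.asarray(table["subtype"]) if "subtype" in table else np.array(["GC"] * n)
    out = pd.DataFrame(index=table.index, columns=list(MEASUREMENT_NAMES) +
                       ["V_inf", "V_0", "V_SS", "V_peak"], dtype=float)

    # --- tau_m: 20 pA, 1500 ms ------------------------------------------
    res = simulate_step_clamp(P, 20.0, 1500.0, config)
    base = _baseline(res)
    fit_mask = (res.t >= 0.0) & (res.t <= 1500.0)
    t_fit = res.t[fit_mask]
    counts = _spike_counts(res, 1500.0)
    for i in range(n):
        if counts[i] > 0:
            continue  # spiking during the pulse invalidates the fit
        tau, v_inf, v0, _ = _fit_single_exponential(t_fit, res.V[i, fit_mask])
        out.iloc[i, out.columns.get_loc("tau_m")] = tau
        out.iloc[i, out.columns.get_loc("V_inf")] = v_inf
        out.iloc[i, out.columns.get_loc("V_0")] = v0

    # --- sag: -50 pA, 1000 ms -------------------------------------------
    res = simulate_step_clamp(P, -50.0, 1000.0, config)
    base = _baseline(res)
    pulse = (res.t >= 0.0) & (res.t <= 1000.0)
    v_min = res.V[:, pulse].min(axis=1)
    peak_defl = base - v_min              # positive for hyperpolarization
    ss_defl = base - _steady_state(res, 1000.0)
    counts = _spike_counts(res, 1000.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sag = np.where((peak_defl > 1e-9) & (counts == 0), ss_defl / peak_defl, np.nan)
    out["sag"] = sag
    out["V_SS"] = ss_defl
    out["V_peak"] = peak_defl

    # --- R_in: pulse family ---------------------------------------------
    rin = np.full(n, np.nan)
    groups = {"HC": np.flatnonzero(subtypes == "HC"),
              "default": np.flatnonzero(subtypes != "HC")}
    for key, idx in groups.items():
        if idx.size == 0:
            continue
        amps = RIN_CURRENTS[key]
        deflections = np.full((idx.size, amps.size), np.nan)
        Pg = PackedParameters.from_table(table.iloc[idx])
        for j, amp in enumerate(amps):
            r = simulate_step_clamp(Pg, amp, 1000.0, config)
            c = _spike_counts(r, 1000.0)
            d = _steady_state(r, 1000.0) - _baseline(r)
            d[c > 0] = np.nan             # spiking points are excluded
            deflections[:, j] = d
        for row, gi in enumerate(idx):
            ok = np.isfinite(deflections[row])
            if ok.sum() < 3:
                continue
            slope = np.polyfit(amps[ok], deflections[row, ok], 1)[0]  # mV/pA = GΩ
            rin[gi] = slope * 1000.0       # MΩ
    out["R_in"] = rin

    # --- f50, f150, SFA ---------------------------------------------------
    res50 = simulate_step_clamp(P, 50.0, 1000.0, config)
    res150 = simulate_step_clamp(P, 150.0, 1000.0, config)
    out["f50"] = _spike_counts(res50, 1000.0).astype(float)
    f150 = _spike_counts(res150, 1000.0).astype(float)
    out["f150"] = f150
    sfa = np.full(n, np.nan)
    for i in range(n):
        s = res150.spike_times[i]
        s = s[(s >= 0.0) & (s < 1000.0)]
        if s.size >= 3:
            isi = np.diff(s)
            sfa[i] = isi[0] / isi[-1]
    out["SFA"] = sfa
    return out


def _measure_one(params: NeuronParameters, config: EngineConfig | None = None) -> pd.Series:
    table = pd.DataFrame([params.as_row()])
    return measure_all(table, config).iloc[0]


def measure_tau_m(params: NeuronParameters, config: EngineConfig | None = None) -> float:
    """Membrane time constant (ms) from the 20 pA charging-curve fit."""
    return float(_measure_one(params, config)["tau_m"])


def measure_sag(params: NeuronParameters, config: EngineConfig | None = None) -> float:
    """Sag ratio V_SS / V_peak for a -50 pA, 1 s pulse."""
    return float(_measure_one(params, config)["sag"])


def measure_input_resistance(params: NeuronParameters, config: EngineConfig | None = None) -> float:
    """Input resistance (MΩ) from the steady-state V-I slope."""
    return float(_measure_one(params, config)["R_in"])


def measure_firing_and_sfa(
    params: NeuronParameters, config: EngineConfig | None = None
) -> tuple[float, float, float]:
    """(f50, f150, SFA); SFA is NaN when the 150 pA pulse gives < 3 spikes."""
    m = _measure_one(params, config)
    return float(m["f50"]), float(m["f150"]), float(m["SFA"])


def validate_neuron(
    measurements: pd.Series | dict | EphysMeasurements,
    bounds: dict,
    subtype: str,
) -> tuple[bool, dict]:
    """Check all six measurements against the subtype's bounds.

    Returns ``(valid, per_measurement)`` where validity is the strict
    conjunction over the six measurements; NaN (undefined) fails.
    """
    if isinstance(measurements, EphysMeasurements):
        measurements = measurements.__dict__
    b = bounds[subtype]
    per = {}
    for name in MEASUREMENT_NAMES:
        lo, hi = b[name]
        v = float(measurements[name])
        per[name] = bool(np.isfinite(v) and lo <= v <= hi)
    return all(per.values()), per


def validate_table(measurements: pd.DataFrame, bounds: dict, subtypes) -> pd.DataFrame:
    """Vectorized validation; returns per-measurement booleans plus 'valid'."""
    subtypes = np.asarray(subtypes)
    flags = pd.DataFrame(index=measurements.index)
    for name in MEASUREMENT_NAMES:
        lo = np.array([bounds[st][name][0] for st in subtypes])
        hi = np.array([bounds[st][name][1] for st in subtypes])
        v = measurements[name].to_numpy(dtype=float)
        flags[name] = np.isfinite(v) & (v >= lo) & (v <= hi)
    flags["valid"] = flags[list(MEASUREMENT_NAMES)].all(axis=1)
    return flags
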