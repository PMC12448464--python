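"""Similarity metrics between spike patterns.

Six metrics compare a reference pattern P0 with a morphed pattern P_beta,
all computed on per-neuron firing rates over an analysis window:

* Hamming distance          HD   = sum_i |F0_i - Fb_i|
* normalized Euclidean      nED  = sqrt(sum_i (F0_i - Fb_i)^2 / N)
* cosine similarity         cos  = F0·Fb / (||F0|| ||Fb||)
* mutual information        MI   = sum p(f0,fb) log2 p(f0,fb)/(p(f0)p(fb))
* average-rate correlation  r    = Pearson(F0, Fb)
* instantaneous-rate corr.  R    = Pearson between the upper triangles of
  the two within-pattern N x N correlation matrices of Gaussian-smoothed
  instantaneous rates (kernel SD = 1/(10 f) seconds, f the train's own
  average rate).

HD and nED use rates normalized by the maximum rate over the two compared
patterns; the correlation metrics are scale-free and use raw rates. The
distance metrics are sensitive to population size and mean rate, whereas
r and R are invariant to both — the property probed by
:func:`invariance_harness`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from dgsep.patterns import SpikePattern, base_pattern_pair, morph_patterns, pattern_rate_map

METRIC_IDS = ("HD", "nED", "cosine", "MI", "r", "R")

#: value reported when a metric is undefined for the given inputs
UNDEFINED = np.nan


def _check_lengths(F0: np.ndarray, Fb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    F0 = np.asarray(F0, dtype=float)
    Fb = np.asarray(Fb, dtype=float)
    if F0.shape != Fb.shape:
        raise ValueError(f"length mismatch: {F0.shape} vs {Fb.shape}")
    return F0, Fb


def normalize_rates(F0: np.ndarray, Fb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize both rate vectors by their joint maximum (if nonzero)."""
    F0, Fb = _check_lengths(F0, Fb)
    m = max(F0.max(initial=0.0), Fb.max(initial=0.0))
    if m > 0:
        return F0 / m, Fb / m
    return F0, Fb


def hamming_distance(F0, Fb, normalize: bool = True) -> float:
    F0, Fb = _check_lengths(F0, Fb)
    if normalize:
        F0, Fb = normalize_rates(F0, Fb)
    return float(np.abs(F0 - Fb).sum())


def normalized_euclidean(F0, Fb, normalize: bool = True) -> float:
    F0, Fb = _check_lengths(F0, Fb)
    if normalize:
        F0, Fb = normalize_rates(F0, Fb)
    return float(np.sqrt(np.mean((F0 - Fb) ** 2)))


def cosine_similarity(F0, Fb) -> float:
    F0, Fb = _check_lengths(F0, Fb)
    n0, nb = np.linalg.norm(F0), np.linalg.norm(Fb)
    if n0 == 0 or nb == 0:
        return UNDEFINED
    return float(F0 @ Fb / (n0 * nb))


def mutual_information(F0, Fb, bins: int = 10) -> float:
    """Plug-in MI estimate (bits) from the joint histogram of binned rates.

    Bins are equal-width over the pooled range of the two vectors.
    """
    F0, Fb = _check_lengths(F0, Fb)
    lo = min(F0.min(), Fb.min())
    hi = max(F0.max(), Fb.max())
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    joint, _, _ = np.histogram2d(F0, Fb, bins=[edges, edges])
    p = joint / joint.sum()
    p0 = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (p0 @ pb)[nz])).sum())


def rate_correlation(F0, Fb) -> float:
    """Pearson correlation between average-rate vectors."""
    F0, Fb = _check_lengths(F0, Fb)
    if F0.std() == 0 or Fb.std() == 0:
        return UNDEFINED
    return float(np.corrcoef(F0, Fb)[0, 1])


# ---------------------------------------------------------------------------
# Instantaneous-rate correlation R
# ---------------------------------------------------------------------------

def smoothed_rates(
    trains: Sequence[np.ndarray],
    window: tuple[float, float],
    dt_ms: float = 2.0,
    truncate_sd: float = 4.0,
) -> np.ndarray:
    """Gaussian-smoothed instantaneous rate series for each train.

    The kernel SD is 1/(10 f) seconds where f is that train's average rate
    over the window; silent trains give the zero series. Series are sampled
    on a ``dt_ms`` grid and the kernel is truncated at ±``truncate_sd`` SDs.
    """
    lo, hi = window
    n_bins = int(round((hi - lo) / dt_ms))
    span_s = (hi - lo) / 1000.0
    out = np.zeros((len(trains), n_bins))
    for i, t in enumerate(trains):
        t = t[(t >= lo) & (t < hi)]
        if t.size == 0:
            continue
        f = t.size / span_s                      # Hz
        sigma_ms = 1000.0 / (10.0 * f)
        counts = np.bincount(((t - lo) / dt_ms).astype(int), minlength=n_bins)[:n_bins]
        half = max(int(np.ceil(truncate_sd * sigma_ms / dt_ms)), 1)
        x = np.arange(-half, half + 1) * dt_ms
        kernel = np.exp(-0.5 * (x / sigma_ms) ** 2)
        kernel /= kernel.sum() * (dt_ms / 1000.0)  # unit-area rate kernel (Hz)
        out[i] = np.convolve(counts.astype(float), kernel, mode="same")
    return out


def _corr_matrix(X: np.ndarray) -> np.ndarray:
    """Row-pairwise Pearson matrix; constant rows correlate 0 with everything."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    good = sd > 0
    Xn = np.zeros_like(Xc)
    Xn[good] = Xc[good] / (sd[good, None] * np.sqrt(X.shape[1]))
    C = Xn @ Xn.T
    np.fill_diagonal(C, 1.0)
    return C


def instantaneous_rate_correlation(
    trains0: Sequence[np.ndarray],
    trainsb: Sequence[np.ndarray],
    window: tuple[float, float],
    dt_ms: float = 2.0,
) -> float:
    """R: Pearson correlation between the two within-pattern correlation
    matrices (upper triangles, diagonal excluded)."""
    if len(trains0) != len(trainsb):
        raise ValueError("patterns must have equal numbers of trains")
    n = len(trains0)
    if n < 3:
        return UNDEFINED
    C0 = _corr_matrix(smoothed_rates(trains0, window, dt_ms))
    Cb = _corr_matrix(smoothed_rates(trainsb, window, dt_ms))
    iu = np.triu_indices(n, k=1)
    a, b = C0[iu], Cb[iu]
    if a.std() == 0 or b.std() == 0:
        return UNDEFINED
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Curves and the invariance harness
# ---------------------------------------------------------------------------

def compute_metric(
    metric: str,
    P0: SpikePattern,
    Pb: SpikePattern,
    window: tuple[float, float] | None = None,
    **kw,
) -> float:
    """Evaluate one metric between two patterns over a window (default: full)."""
    window = window or (0.0, P0.duration)
    if metric == "R":
        return instantaneous_rate_correlation(P0.trains, Pb.trains, window, **kw)
    F0 = pattern_rate_map(P0, window)
    Fb = pattern_rate_map(Pb, window)
    if metric == "HD":
        return hamming_distance(F0, Fb)
    if metric == "nED":
        return normalized_euclidean(F0, Fb)
    if metric == "cosine":
        return cosine_similarity(F0, Fb)
    if metric == "MI":
        return mutual_information(F0, Fb, **kw)
    if metric == "r":
        return rate_correlation(F0, Fb)
    raise ValueError(f"unknown metric {metric!r}")


def metric_curve(
    metric: str,
    patterns: Sequence[SpikePattern],
    window: tuple[float, float] | None = None,
    **kw,
) -> pd.DataFrame:
    """Metric of each pattern against the first (beta=0) pattern."""
    P0 = patterns[0]
    rows = [{"beta": P.beta, "metric_id": metric,
             "value": compute_metric(metric, P0, P, window, **kw)} for P in patterns]
    return pd.DataFrame(rows)


INVARIANCE_SETTINGS = {
    "size": {"factor_values": (1000, 2000, 3000)},
    "rate": {"factor_values": (5.0, 15.0, 25.0)},
    "distribution": {"factor_values": ("poisson", "exponential")},
}


def invariance_harness(
    metrics: Sequence[str],
    factor: str,
    n_sets: int = 10,
    seed: int = 0,
    n_trains: int = 700,
    rate_hz: float = 8.0,
    duration_ms: float = 2000.0,
    betas: Sequence[float] | None = None,
    dt_ms: float = 2.5,
) -> pd.DataFrame:
    """Mean metric-vs-beta curves across settings of one generation factor.

    ``factor`` is one of ``"size"`` (population sizes 1000/2000/3000),
    ``"rate"`` (mean rates 5/15/25 Hz), or ``"distribution"`` (Poisson vs
    exponential firing-rate distributions at 8 Hz). For each setting,
    ``n_sets`` independent P0-P1 pairs are generated, morphed, and measured;
    the returned tidy table has one row per (setting, set, beta, metric).
    """
    if factor not in INVARIANCE_SETTINGS:
        raise ValueError(f"unknown factor {factor!r}")
    values = INVARIANCE_SETTINGS[factor]["factor_values"]
    rows = []
    master = np.random.default_rng(seed)
    for setting in values:
        n = int(setting) if factor == "size" else n_trains
        rate = float(setting) if factor == "rate" else rate_hz
        dist = str(setting) if factor == "distribution" else "constant"
        for s in range(n_sets):
            pair_seed = int(master.integers(2**31 - 1))
            P0, P1 = base_pattern_pair(n, rate, duration_ms, pair_seed,
                                       rate_distribution=dist)
            fam = morph_patterns(P0, P1, betas, seed=pair_seed + 1)
            for metric in metrics:
                kw = {"dt_ms": dt_ms} if metric == "R" else {}
                for P in fam:
                    rows.append({
                        "factor": factor, "setting": setting, "set": s,
                        "beta": P.beta, "metric_id": metric,
                        "value": compute_metric(metric, P0, P, None, **kw),
                    })
    return pd.DataFrame(rows)


def mean_curves(harness_table: pd.DataFrame) -> pd.DataFrame:
    """Average the harness output over sets: one curve per (setting, metric)."""
    return (harness_table
            .groupby(["factor", "setting", "metric_id", "beta"], sort=True)["value"]
            .mean().reset_index())
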