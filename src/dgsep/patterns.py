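"""Perforant-path input patterns: Poisson spike trains and morphing.

One input pattern is a set of independent spike trains (700 by default),
each a homogeneous Poisson process: inter-spike intervals are drawn from
an exponential distribution with mean 1/rate (125 ms at the default
8 Hz) and accumulated until the pattern duration is exceeded.

Two independent base patterns P0 and P1 are bridged by *morphing*: the
pattern P_beta takes a beta fraction of its trains from P1 and the rest
from P0. Morphing is nested by default — one random permutation of train
indices is drawn and P_beta replaces the first round(beta * n) entries —
so the replaced-train sets grow monotonically with beta and the morph is
progressive. Independent per-beta selection is available via
``nested=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class SpikePattern:
    """A set of spike-time sequences (ms) forming one input pattern."""

    trains: list                      # list of float ndarrays, strictly increasing
    duration: float                   # ms
    rate_hz: float = np.nan           # nominal mean rate
    beta: float = 0.0                 # morph parameter in [0, 1]
    seed: int | None = None

    @property
    def n_trains(self) -> int:
        return len(self.trains)

    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))

    def to_events(self) -> pd.DataFrame:
        """Serialize as an event list (train_id, spike_time_ms)."""
        ids = np.concatenate([np.full(t.size, i) for i, t in enumerate(self.trains)]) \
            if self.n_spikes() else np.empty(0, dtype=int)
        times = np.concatenate(self.trains) if self.n_spikes() else np.empty(0)
        return pd.DataFrame({"train_id": ids.astype(int), "spike_time_ms": times})

    @classmethod
    def from_events(cls, events: pd.DataFrame, n_trains: int, duration: float,
                    **kw) -> "SpikePattern":
        trains = [np.sort(events.loc[events["train_id"] == i, "spike_time_ms"].to_numpy())
                  for i in range(n_trains)]
        return cls(trains=trains, duration=duration, **kw)


def _poisson_train(rng: np.random.Generator, rate_hz: float, duration_ms: float) -> np.ndarray:
    """Draw one homogeneous Poisson train by accumulating exponential ISIs."""
    if rate_hz <= 0 or duration_ms <= 0:
        return np.empty(0)
    mean_isi = 1000.0 / rate_hz
    # draw in blocks until the accumulated time exceeds the duration
    expected = max(int(duration_ms / mean_isi * 1.5) + 10, 16)
    times = np.cumsum(rng.exponential(mean_isi, size=expected))
    while times.size and times[-1] < duration_ms:
        more = np.cumsum(rng.exponential(mean_isi, size=expected)) + times[-1]
        times = np.concatenate([times, more])
    return times[times < duration_ms]


def generate_base_pattern(
    n_trains: int,
    rate_hz: float,
    duration_ms: float,
    seed: int | np.random.Generator | None = None,
    rate_distribution: str = "constant",
) -> SpikePattern:
    """Generate one base input pattern of independent Poisson spike trains.

    ``rate_distribution`` controls the per-train rate:

    * ``"constant"`` (default): every train fires at ``rate_hz``, so ISIs
      are exponential with mean 1000/rate ms and per-train counts are
      Poisson with mean rate*duration;
    * ``"poisson"``: per-train rates are drawn from a Poisson distribution
      with mean ``rate_hz``;
    * ``"exponential"``: per-train rates from an exponential distribution
      with mean ``rate_hz``.

    The two non-constant forms are used to probe metric invariance to the
    shape of the firing-rate distribution.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if duration_ms < 0:
        raise ValueError("duration_ms must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if rate_distribution == "constant":
        rates = np.full(n_trains, float(rate_hz))
    elif rate_distribution == "poisson":
        rates = rng.poisson(rate_hz, size=n_trains).astype(float)
    elif rate_distribution == "exponential":
        rates = rng.exponential(rate_hz, size=n_trains)
    else:
        raise ValueError(f"unknown rate_distribution {rate_distribution!r}")

    trains = [_poisson_train(rng, r, duration_ms) for r in rates]
    return SpikePattern(trains=trains, duration=duration_ms, rate_hz=rate_hz,
                        beta=0.0, seed=seed if isinstance(seed, int) else None)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def morph_patterns(
    P0: SpikePattern,
    P1: SpikePattern,
    betas: Sequence[float] | None = None,
    seed: int | np.random.Generator | None = None,
    nested: bool = True,
) -> list[SpikePattern]:
    """Build the morph family P_beta between two base patterns.

    For each beta, round(beta * n_trains) train indices are taken from P1
    and the rest from P0 (round half away from zero). beta=0 reproduces P0
    exactly and beta=1 reproduces P1. The default grid is beta = 0, 0.1,
    ..., 1.0 — eleven patterns.
    """
    if P0.n_trains != P1.n_trains or P0.duration != P1.duration:
        raise ValueError("P0 and P1 must share n_trains and duration")
    if betas is None:
        betas = [round(0.1 * k, 1) for k in range(11)]
    betas = list(betas)
    if any(b < 0 or b > 1 for b in betas):
        raise ValueError("betas must lie in [0, 1]")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = P0.n_trains
    perm = rng.permutation(n)
    out = []
    for beta in betas:
        k = _round_half_away(beta * n)
        if nested:
            replaced = perm[:k]
        else:
            replaced = rng.permutation(n)[:k]
        take = np.zeros(n, dtype=bool)
        take[replaced] = True
        trains = [P1.trains[i] if take[i] else P0.trains[i] for i in range(n)]
        out.append(SpikePattern(trains=trains, duration=P0.duration,
                                rate_hz=P0.rate_hz, beta=float(beta)))
    return out


def pattern_rate_map(P: SpikePattern, window: tuple[float, float]) -> np.ndarray:
    """Per-train average firing rate (Hz) over a time window (ms)."""
    lo, hi = window
    if not (0.0 <= lo < hi <= P.duration):
        raise ValueError(f"window {window} must be a nonempty subinterval of [0, {P.duration}]")
    span_s = (hi - lo) / 1000.0
    return np.array([np.count_nonzero((t >= lo) & (t < hi)) for t in P.trains]) / span_s


def base_pattern_pair(
    n_trains: int,
    rate_hz: float,
    duration_ms: float,
    seed: int,
    rate_distribution: str = "constant",
    max_abs_corr: float = 0.1,
    max_tries: int = 20,
) -> tuple[SpikePattern, SpikePattern]:
    """Two independent base patterns verified to be distinct.

    Distinctness is enforced as |Pearson r| < ``max_abs_corr`` between the
    per-train rate vectors of the two patterns; on failure a fresh seed
    stream is used (constant-rate patterns have degenerate rate variance
    only in pathological cases, which also trigger a redraw).
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        P0 = generate_base_pattern(n_trains, rate_hz, duration_ms, rng, rate_distribution)
        P1 = generate_base_pattern(n_trains, rate_hz, duration_ms, rng, rate_distribution)
        f0 = pattern_rate_map(P0, (0.0, duration_ms))
        f1 = pattern_rate_map(P1, (0.0, duration_ms))
        if f0.std() == 0 or f1.std() == 0:
            continue
        r = float(np.corrcoef(f0, f1)[0, 1])
        if abs(r) < max_abs_corr:
            P0.seed = P1.seed = seed
            return P0, P1
    raise RuntimeError("could not generate two sufficiently uncorrelated base patterns")


def save_pattern(P: SpikePattern, path: str | Path) -> None:
    """Write a pattern as a delimited event list with a header comment."""
    path = Path(path)
    header = (f"# n_trains={P.n_trains} duration_ms={P.duration} "
              f"rate_hz={P.rate_hz} beta={P.beta} seed={P.seed}\n")
    with open(path, "w") as fh:
        fh.write(header)
        P.to_events().to_csv(fh, sep="\t", index=False)


def load_pattern(path: str | Path) -> SpikePattern:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        events = pd.read_csv(fh, sep="\t")
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return SpikePattern.from_events(
        events, n_trains=int(meta["n_trains"]), duration=float(meta["duration_ms"]),
        rate_hz=float(meta["rate_hz"]), beta=float(meta["beta"]), seed=seed)
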