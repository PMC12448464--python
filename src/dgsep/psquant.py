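"""Pattern-separation quantification from output-vs-input similarity.

The network's output similarity S_out (between granule-cell responses to
P0 and P_beta) is plotted against the input similarity S_in (between the
corresponding input patterns) for the eleven morph levels. The points are
rotated clockwise by 45 degrees so the equality line S_out = S_in becomes
the new x axis:

    x' = (S_in + S_out) / sqrt(2),   y' = (S_out - S_in) / sqrt(2)

Points below zero (S_out < S_in) indicate pattern separation; points
above indicate pattern completion. A cubic polynomial p(x') is fitted to
the rotated points and four measurements are taken over the observed x'
range:

* A_PS    — area under the negative-rectified cubic, ∫ max(-p, 0) dx
* A_PC    — area under the positive-rectified cubic, ∫ max(p, 0) dx
* T_PCPS  — the completion-to-separation transition: the smallest x' at
  which p crosses from >= 0 to < 0 (the range start if p starts negative,
  the range end if p is never negative)
* PS_max  — the peak separation depth, max over the range of max(-p, 0)

A network separates patterns effectively when, for both correlation
metrics, A_PS > 0.15, A_PC < 0.02, T_PCPS < 0.25 and PS_max > 0.2.

Areas are computed by analytic integration of the cubic between its real
roots (no quadrature); PS_max is evaluated at the range endpoints and the
real critical points of p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SQRT2 = np.sqrt(2.0)

#: tolerance band within which a polynomial value is treated as zero
ZERO_TOL = 1e-12


@dataclass
class ValidationBounds:
    A_PS_min: float = 0.15
    A_PC_max: float = 0.02
    T_PCPS_max: float = 0.25
    PS_max_min: float = 0.2


@dataclass
class PSMeasurements:
    """The four pattern-separation quantities for one similarity metric."""

    A_PS: float
    A_PC: float
    T_PCPS: float
    PS_max: float
    coeffs: np.ndarray = field(default_factory=lambda: np.zeros(4))
    x_range: tuple = (0.0, 0.0)
    metric_id: str = ""

    def as_dict(self) -> dict:
        return {"A_PS": self.A_PS, "A_PC": self.A_PC,
                "T_PCPS": self.T_PCPS, "PS_max": self.PS_max}


def rotate_points(points: np.ndarray) -> np.ndarray:
    """Rotate (S_in, S_out) points clockwise by 45 degrees.

    Returns an array of (x', y') with x' = (S_in + S_out)/sqrt(2) and
    y' = (S_out - S_in)/sqrt(2); y' < 0 means separation.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    s_in, s_out = pts[:, 0], pts[:, 1]
    return np.column_stack([(s_in + s_out) / SQRT2, (s_out - s_in) / SQRT2])


def fit_cubic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares cubic fit; degenerate x falls back to a lower degree.

    Returns coefficients in descending powers (length 4, zero-padded when a
    lower degree was used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points for a cubic fit")
    degree = min(3, len(np.unique(x)) - 1)
    if degree < 0:
        raise ValueError("all x values identical")
    coeffs = np.polyfit(x, y, degree)
    return np.concatenate([np.zeros(3 - degree), coeffs])


def _real_roots_in(coeffs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    c = np.trim_zeros(np.asarray(coeffs, dtype=float), "f")
    if c.size <= 1:
        return np.empty(0)
    roots = np.roots(c)
    real = roots[np.abs(roots.imag) < 1e-9].real
    real = real[(real > lo + ZERO_TOL) & (real < hi - ZERO_TOL)]
    return np.unique(np.sort(real))


def _poly_integral(coeffs: np.ndarray, a: float, b: float) -> float:
    anti = np.polyint(coeffs)
    return float(np.polyval(anti, b) - np.polyval(anti, a))


def ps_measurements(
    coeffs: np.ndarray,
    x_range: tuple[float, float],
    metric_id: str = "",
) -> PSMeasurements:
    """The four separation measurements for a fitted cubic over a range."""
    lo, hi = float(x_range[0]), float(x_range[1])
    if hi < lo:
        raise ValueError("x_range must be ordered")
    coeffs = np.asarray(coeffs, dtype=float)
    roots = _real_roots_in(coeffs, lo, hi)
    edges = np.concatenate([[lo], roots, [hi]])

    a_ps = a_pc = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a <= ZERO_TOL:
            continue
        mid = np.polyval(coeffs, 0.5 * (a + b))
        seg = _poly_integral(coeffs, a, b)
        if mid < 0:
            a_ps += -seg
        else:
            a_pc += seg
    a_ps, a_pc = max(a_ps, 0.0), max(a_pc, 0.0)

    # transition point: scan x' upward for a (>=0) -> (<0) sign change
    p_lo = np.polyval(coeffs, lo)
    if p_lo < -ZERO_TOL:
        t_pcps = lo
    else:
        t_pcps = hi
        sign_prev = 1.0
        for rt in roots:
            after = np.polyval(coeffs, min(rt + max(1e-9, (hi - lo) * 1e-9), hi))
            # crossing from non-negative into negative territory
            if sign_prev >= 0 and after < 0:
                t_pcps = float(rt)
                break
            sign_prev = 1.0 if after >= 0 else -1.0

    # peak separation depth at endpoints and interior critical points
    deriv = np.polyder(coeffs)
    crit = _real_roots_in(np.concatenate([np.zeros(4 - deriv.size), deriv]), lo, hi) \
        if deriv.size > 1 else np.empty(0)
    xs = np.concatenate([[lo, hi], crit])
    ps_max = float(max(np.max(-np.polyval(coeffs, xs)), 0.0))

    return PSMeasurements(A_PS=a_ps, A_PC=a_pc, T_PCPS=float(t_pcps),
                          PS_max=ps_max, coeffs=coeffs, x_range=(lo, hi),
                          metric_id=metric_id)


def quantify_curve(
    s_in: np.ndarray,
    s_out: np.ndarray,
    metric_id: str = "",
) -> PSMeasurements:
    """Rotate, fit, and measure one S_out-vs-S_in similarity curve."""
    pts = np.column_stack([np.asarray(s_in, float), np.asarray(s_out, float)])
    if not np.all(np.isfinite(pts)):
        raise ValueError("similarity curve contains undefined values")
    rot = rotate_points(pts)
    coeffs = fit_cubic(rot[:, 0], rot[:, 1])
    x_range = (float(rot[:, 0].min()), float(rot[:, 0].max()))
    return ps_measurements(coeffs, x_range, metric_id=metric_id)


def validate_network_ps(
    meas_r: PSMeasurements | None,
    meas_R: PSMeasurements | None,
    bounds: ValidationBounds | dict | None = None,
) -> tuple[bool, dict]:
    """Strict conjunction of the 8 measurement bounds (4 per metric).

    An undefined metric (``None`` or non-finite measurements) is invalid.
    """
    if bounds is None:
        bounds = ValidationBounds()
    elif isinstance(bounds, dict):
        bounds = ValidationBounds(**bounds)
    per: dict = {}
    for tag, m in (("r", meas_r), ("R", meas_R)):
        if m is None or not all(np.isfinite(v) for v in m.as_dict().values()):
            per.update({f"{tag}:{k}": False for k in ("A_PS", "A_PC", "T_PCPS", "PS_max")})
            continue
        per[f"{tag}:A_PS"] = m.A_PS > bounds.A_PS_min
        per[f"{tag}:A_PC"] = m.A_PC < bounds.A_PC_max
        per[f"{tag}:T_PCPS"] = m.T_PCPS < bounds.T_PCPS_max
        per[f"{tag}:PS_max"] = m.PS_max > bounds.PS_max_min
    return all(per.values()), per
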