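"""Bounded nonlinear least-squares EPG fitting.

Voxel signals are fitted by trust-region reflective least squares over the
nonlinear parameters, with the signal amplitude(s) eliminated in closed form
at every iterate (variable projection): because the two-pool model is linear
in the pool amplitudes, the optimal nonnegative amplitudes given (T2s, B1)
are a 2x2 least-squares solve.  This minimizes exactly the same objective

    sum_n (signal_n - scale * model_n)^2

as an explicit-amplitude formulation, but with fewer nonlinear parameters
and exact scale equivariance: scaling the input by c > 0 scales only the
returned amplitude.

Fat calibration mode fits (T2f, T2w, B1) with FF fixed at 0.9; muscle mode
fits (FF, T2w, B1) with T2f fixed at the calibrated value.  Bounds mirror
the dictionary/training ranges.  Voxels where the optimizer fails or the
signal is identically zero are flagged and filled with NaN rather than
raising, so a whole-slice fit never aborts.  Muscle voxels with FF > 0.95
carry a quality flag: the water pool is then too weak for a reliable T2w.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .epg_core import (
    T1_FAT_MS,
    T1_WATER_MS,
    SequenceConfig,
    mese_single_component_batch,
)

__all__ = [
    "FitBounds",
    "FatFitResult",
    "MuscleFitResult",
    "fit_fat_voxel",
    "fit_muscle_voxel",
    "fit_fat_voxels",
    "fit_muscle_voxels",
    "HIGH_FF_FLAG_THRESHOLD",
]

HIGH_FF_FLAG_THRESHOLD = 0.95


@dataclass(frozen=True)
class FitBounds:
    """Per-parameter (lower, upper) boxes for the two fitting modes."""

    t2f: tuple = (50.0, 250.0)
    t2w_fat: tuple = (10.0, 110.0)
    t2w_muscle: tuple = (10.0, 80.0)
    b1: tuple = (0.4, 1.2)
    ff: tuple = (0.0, 1.0)

    def __post_init__(self):
        for name in ("t2f", "t2w_fat", "t2w_muscle", "b1", "ff"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound")


DEFAULT_BOUNDS = FitBounds()

#: Multi-start T2w initializations for muscle voxels (ms).
_T2W_STARTS = (15.0, 35.0, 60.0)


@dataclass
class FatFitResult:
    t2f: float
    t2w: float
    b1: float
    scale: float
    residual: float
    valid: bool


@dataclass
class MuscleFitResult:
    ff: float
    t2w: float
    b1: float
    scale: float
    residual: float
    valid: bool
    high_ff: bool = False


def _pool_signals(t2_fat, t2_wat, b1, seq):
    s_fat = mese_single_component_batch(
        np.array([t2_fat]), np.array([b1]), T1_FAT_MS, seq
    )[0]
    s_wat = mese_single_component_batch(
        np.array([t2_wat]), np.array([b1]), T1_WATER_MS, seq
    )[0]
    return s_fat, s_wat


def _nnls2(signal, s_fat, s_wat):
    """Nonnegative LS amplitudes of a two-column design, closed form."""
    gff = s_fat @ s_fat
    gww = s_wat @ s_wat
    gfw = s_fat @ s_wat
    rf = signal @ s_fat
    rw = signal @ s_wat
    det = gff * gww - gfw * gfw
    if det > 1e-30:
        c1 = (gww * rf - gfw * rw) / det
        c2 = (gff * rw - gfw * rf) / det
        if c1 >= 0 and c2 >= 0:
            return c1, c2
    # boundary solutions
    c2_only = max(rw / gww, 0.0) if gww > 0 else 0.0
    c1_only = max(rf / gff, 0.0) if gff > 0 else 0.0
    r1 = signal - c1_only * s_fat
    r2 = signal - c2_only * s_wat
    if r1 @ r1 <= r2 @ r2:
        return c1_only, 0.0
    return 0.0, c2_only


def fit_fat_voxel(
    signal,
    seq: SequenceConfig,
    bounds: FitBounds = DEFAULT_BOUNDS,
    ff_fixed: float = 0.9,
) -> FatFitResult:
    """Fit a subcutaneous-fat voxel: (T2f, T2w, B1) with FF fixed at 0.9."""
    signal = np.asarray(signal, dtype=float)
    if signal.size != seq.etl:
        raise ValueError("signal length must equal the echo-train length")
    if not np.all(np.isfinite(signal)) or np.all(signal == 0):
        return FatFitResult(np.nan, np.nan, np.nan, np.nan, np.nan, False)

    def residual(x):
        s_fat, s_wat = _pool_signals(x[0], x[1], x[2], seq)
        model = ff_fixed * s_fat + (1.0 - ff_fixed) * s_wat
        mm = model @ model
        scale = max((signal @ model) / mm, 0.0) if mm > 0 else 0.0
        return signal - scale * model

    lo = [bounds.t2f[0], bounds.t2w_fat[0], bounds.b1[0]]
    hi = [bounds.t2f[1], bounds.t2w_fat[1], bounds.b1[1]]
    x0 = 0.5 * (np.array(lo) + np.array(hi))
    try:
        sol = least_squares(
            residual, x0, bounds=(lo, hi), method="trf", ftol=1e-8, xtol=1e-8
        )
    except Exception:
        return FatFitResult(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    t2f, t2w, b1 = sol.x
    s_fat, s_wat = _pool_signals(t2f, t2w, b1, seq)
    model = ff_fixed * s_fat + (1.0 - ff_fixed) * s_wat
    scale = max((signal @ model) / (model @ model), 0.0)
    return FatFitResult(t2f, t2w, b1, scale, float(2 * sol.cost), True)


def fit_muscle_voxel(
    signal,
    t2f_ms: float,
    seq: SequenceConfig,
    bounds: FitBounds = DEFAULT_BOUNDS,
) -> MuscleFitResult:
    """Fit a muscle voxel: (FF, T2w, B1) with T2f fixed to the calibrated value.

    Both pool amplitudes are free nonnegative linear coefficients; FF is
    their normalized ratio and the overall scale their sum.  A three-point
    multi-start over T2w guards against local minima; the best-residual
    solution is kept.
    """
    if not (bounds.t2f[0] <= t2f_ms <= bounds.t2f[1]):
        raise ValueError(f"t2f_ms must lie within {bounds.t2f}")
    signal = np.asarray(signal, dtype=float)
    if signal.size != seq.etl:
        raise ValueError("signal length must equal the echo-train length")
    if not np.all(np.isfinite(signal)) or np.all(signal == 0):
        return MuscleFitResult(np.nan, np.nan, np.nan, np.nan, np.nan, False)

    def residual(x):
        s_fat, s_wat = _pool_signals(t2f_ms, x[0], x[1], seq)
        c1, c2 = _nnls2(signal, s_fat, s_wat)
        return signal - c1 * s_fat - c2 * s_wat

    lo = [bounds.t2w_muscle[0], bounds.b1[0]]
    hi = [bounds.t2w_muscle[1], bounds.b1[1]]
    b1_mid = 0.5 * (bounds.b1[0] + bounds.b1[1])
    best = None
    for t2w0 in _T2W_STARTS:
        try:
            sol = least_squares(
                residual,
                [t2w0, b1_mid],
                bounds=(lo, hi),
                method="trf",
                ftol=1e-8,
                xtol=1e-8,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return MuscleFitResult(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    t2w, b1 = best.x
    s_fat, s_wat = _pool_signals(t2f_ms, t2w, b1, seq)
    c1, c2 = _nnls2(signal, s_fat, s_wat)
    scale = c1 + c2
    ff = c1 / scale if scale > 0 else np.nan
    return MuscleFitResult(
        ff,
        t2w,
        b1,
        scale,
        float(2 * best.cost),
        True,
        high_ff=bool(ff > HIGH_FF_FLAG_THRESHOLD) if np.isfinite(ff) else True,
    )


def fit_fat_voxels(signals, seq, bounds=DEFAULT_BOUNDS) -> dict:
    """Fit many fat voxels; returns a dict of per-voxel arrays."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    res = [fit_fat_voxel(s, seq, bounds) for s in signals]
    return {
        "t2f": np.array([r.t2f for r in res]),
        "t2w": np.array([r.t2w for r in res]),
        "b1": np.array([r.b1 for r in res]),
        "scale": np.array([r.scale for r in res]),
        "residual": np.array([r.residual for r in res]),
        "valid": np.array([r.valid for r in res]),
    }


def fit_muscle_voxels(signals, t2f_ms, seq, bounds=DEFAULT_BOUNDS) -> dict:
    """Fit many muscle voxels; returns a dict of per-voxel arrays."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    res = [fit_muscle_voxel(s, t2f_ms, seq, bounds) for s in signals]
    return {
        "ff": np.array([r.ff for r in res]),
        "t2w": np.array([r.t2w for r in res]),
        "b1": np.array([r.b1 for r in res]),
        "scale": np.array([r.scale for r in res]),
        "residual": np.array([r.residual for r in res]),
        "valid": np.array([r.valid for r in res]),
        "high_ff": np.array([r.high_ff for r in res]),
    }
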