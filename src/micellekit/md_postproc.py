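"""Aggregation propensity and equilibration checks on MD observable traces.

The aggregation propensity (AP) of a self-assembling peptide amphiphile is
the ratio of the initial to the final solvent-accessible surface area over
a simulation: compaction of the molecules into aggregates buries surface,
so AP > 1 indicates aggregation.  Both ends are window-averaged for noise
robustness, with window standard errors propagated in quadrature.  A
plateau check on the trailing window guards the "final" value against an
unequilibrated trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OBSERVABLES",
    "TimeSeriesTrace",
    "APResult",
    "aggregation_propensity",
    "plateau_check",
]

OBSERVABLES = ("sasa", "rg", "rmsd")

_MIN_WINDOW_SAMPLES = 5


@dataclass
class TimeSeriesTrace:
    """An MD observable vs time (SASA nm^2, R_g nm or RMSD nm; t in ns)."""

    t: np.ndarray
    value: np.ndarray
    observable: str = "sasa"

    def __post_init__(self) -> None:
        if self.observable not in OBSERVABLES:
            raise ValueError(
                f"unknown observable {self.observable!r}; expected one of {OBSERVABLES}"
            )
        t = np.asarray(self.t, float)
        v = np.asarray(self.value, float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("t and value must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("observable values must be finite and non-negative")
        self.t, self.value = t, v

    def __len__(self) -> int:
        return self.t.size

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Values with lo <= t <= hi."""
        return self.value[(self.t >= lo) & (self.t <= hi)]


@dataclass
class APResult:
    """Aggregation propensity with propagated uncertainty."""

    ap: float
    ap_err: float
    init_mean: float
    final_mean: float
    init_window: tuple[float, float]
    final_window: tuple[float, float]
    plateau_ok: bool

    def to_dict(self) -> dict:
        return {
            "ap": self.ap,
            "ap_err": self.ap_err,
            "init_mean": self.init_mean,
            "final_mean": self.final_mean,
            "init_window": list(self.init_window),
            "final_window": list(self.final_window),
            "plateau_ok": self.plateau_ok,
        }


def _check_window(trace: TimeSeriesTrace, window: tuple[float, float], name: str):
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"{name} window is empty: {window}")
    vals = trace.window(lo, hi)
    if vals.size == 0:
        raise ValueError(f"{name} window {window} contains no samples")
    if vals.size < _MIN_WINDOW_SAMPLES:
        raise ValueError(
            f"{name} window {window} has {vals.size} samples; "
            f"need at least {_MIN_WINDOW_SAMPLES}"
        )
    return vals


def aggregation_propensity(
    trace: TimeSeriesTrace,
    init_window: tuple[float, float] | None = None,
    final_window: tuple[float, float] | None = None,
    plateau_slope_tol: float = 0.01,
) -> APResult:
    """AP = mean(initial window) / mean(final window) of an MD trace.

    Defaults: initial window = first 2% of the trace span, final window =
    last 25%.  Uncertainty combines the two window standard errors of the
    mean in quadrature (samples treated as independent; correlated MD
    frames make this a lower bound).  The AP is defined on SASA; other
    observables are accepted with a warning.
    """
    if trace.observable != "sasa":
        warnings.warn(
            f"AP is defined on SASA traces; got {trace.observable!r}", stacklevel=2
        )
    t0, t1 = trace.t[0], trace.t[-1]
    span = t1 - t0
    if init_window is None:
        # first 2% of the span, widened if needed to hold 5 samples
        hi = max(t0 + 0.02 * span, trace.t[min(_MIN_WINDOW_SAMPLES - 1, len(trace) - 1)])
        init_window = (float(t0), float(hi))
    if final_window is None:
        final_window = (float(t1 - 0.25 * span), float(t1))
    if init_window[1] > final_window[0]:
        raise ValueError(
            f"init window {init_window} overlaps final window {final_window}"
        )
    vi = _check_window(trace, init_window, "init")
    vf = _check_window(trace, final_window, "final")
    mi, mf = float(vi.mean()), float(vf.mean())
    if mf == 0:
        raise ValueError("final window mean is zero; AP undefined")
    se_i = float(vi.std(ddof=1) / np.sqrt(vi.size))
    se_f = float(vf.std(ddof=1) / np.sqrt(vf.size))
    ap = mi / mf
    ap_err = abs(ap) * float(np.hypot(se_i / mi if mi else 0.0, se_f / mf))
    plateau_ok = plateau_check(trace, final_window, slope_tol=plateau_slope_tol)
    return APResult(
        ap=ap,
        ap_err=ap_err,
        init_mean=mi,
        final_mean=mf,
        init_window=init_window,
        final_window=final_window,
        plateau_ok=plateau_ok,
    )


def plateau_check(
    trace: TimeSeriesTrace,
    window: tuple[float, float],
    slope_tol: float = 0.01,
) -> bool:
    """True iff the trace is flat over ``window``.

    Flat means |least-squares slope| / window mean < slope_tol, with
    slope_tol in fractional change per ns (default 1%/ns).
    """
    lo, hi = window
    mask = (trace.t >= lo) & (trace.t <= hi)
    if mask.sum() < _MIN_WINDOW_SAMPLES:
        raise ValueError(
            f"window {window} has {int(mask.sum())} samples; "
            f"need at least {_MIN_WINDOW_SAMPLES}"
        )
    tw, vw = trace.t[mask], trace.value[mask]
    res = stats.linregress(tw, vw)
    mean = vw.mean()
    if mean == 0:
        return abs(res.slope) < slope_tol
    return abs(res.slope / mean) < slope_tol
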