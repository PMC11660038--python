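"""Critical micelle concentration estimation from titration series.

A titration series is a concentration–response curve from one technique
(surface tensiometry, conductometry, fluorescence probe ratios or shifts,
UV/vis peak position).  Micellization shows up as a kink: below the CMC the
response varies with one slope, above it with another (for surface tension,
a plateau).  The CMC is estimated as the breakpoint of a continuous
two-segment linear fit, on a per-technique abscissa transform, with a
residual-resampling bootstrap for the confidence interval and an F-test
guard against declaring a breakpoint in featureless data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TECHNIQUES",
    "DEFAULT_TRANSFORMS",
    "TitrationSeries",
    "BreakpointEstimate",
    "SegmentedCMCRegression",
    "fit_two_segment",
    "bootstrap_breakpoint_ci",
    "consensus_cmc",
]

TECHNIQUES = (
    "surface_tension",
    "conductivity",
    "fluor_intensity_ratio",
    "fluor_wavelength_shift",
    "uvvis_peak_wavelength",
)

#: Conventional abscissa for each technique: surface tension and fluorescence
#: data are plotted against log10(c); conductivity and UV/vis peak position
#: against c itself.
DEFAULT_TRANSFORMS = {
    "surface_tension": "log10",
    "conductivity": "linear",
    "fluor_intensity_ratio": "log10",
    "fluor_wavelength_shift": "log10",
    "uvvis_peak_wavelength": "linear",
}

_TRANSFORM_FWD = {
    "linear": lambda c: np.asarray(c, float),
    "log10": np.log10,
    "ln": np.log,
}
_TRANSFORM_INV = {
    "linear": lambda x: x,
    "log10": lambda x: 10.0**x,
    "ln": np.exp,
}

MIN_POINTS = 5
_MIN_SIDE = 3  # points required on each side of a candidate breakpoint


@dataclass
class TitrationSeries:
    """One technique's concentration–response curve.

    Concentrations are canonically sorted ascending on construction and must
    be strictly positive (log transforms must stay defined) and strictly
    increasing after the sort (tied concentrations are rejected rather than
    silently averaged).
    """

    technique: str
    conc: np.ndarray
    response: np.ndarray
    conc_unit: str = "wt%"
    response_unit: str = ""
    temperature: float = 293.0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(
                f"unknown technique {self.technique!r}; expected one of {TECHNIQUES}"
            )
        conc = np.asarray(self.conc, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        if conc.ndim != 1 or resp.ndim != 1 or conc.size != resp.size:
            raise ValueError("conc and response must be 1-D arrays of equal length")
        order = np.argsort(conc)
        conc, resp = conc[order], resp[order]
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing (no ties)")
        if not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite")
        self.conc, self.response = conc, resp

    def __len__(self) -> int:
        return self.conc.size


@dataclass
class BreakpointEstimate:
    """Two-segment fit summary: CMC, CI, segment slopes/intercepts.

    Slopes and intercepts are on the transformed abscissa (``abscissa_transform``);
    the CMC and its CI are back-transformed to the concentration unit of the
    input.  ``detected`` is False when the F-test cannot reject a single
    straight line at alpha.
    """

    cmc: float
    ci95: tuple[float, float] | None
    slopes: tuple[float, float]
    intercepts: tuple[float, float]
    abscissa_transform: str
    rss: float
    detected: bool
    technique: str | None = None
    conc_unit: str = "wt%"
    f_pvalue: float | None = None

    def to_dict(self) -> dict:
        return {
            "cmc": self.cmc,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
            "slopes": list(self.slopes),
            "intercepts": list(self.intercepts),
            "abscissa_transform": self.abscissa_transform,
            "rss": self.rss,
            "detected": self.detected,
            "technique": self.technique,
            "conc_unit": self.conc_unit,
            "f_pvalue": self.f_pvalue,
        }


def _segment_design(x: np.ndarray, xb: float, constrained: bool) -> np.ndarray:
    # continuity is built in: y = a + b1*min(x-xb,0) + b2*max(x-xb,0);
    # both segments pass through (xb, a).
    dx = x - xb
    left = np.minimum(dx, 0.0)
    if constrained:
        return np.column_stack([np.ones_like(x), left])
    right = np.maximum(dx, 0.0)
    return np.column_stack([np.ones_like(x), left, right])


def _rss_at(x: np.ndarray, y: np.ndarray, xb: float, constrained: bool):
    X = _segment_design(x, xb, constrained)
    # small dense problem: normal equations are faster than lstsq and
    # adequately conditioned for centred two-segment designs
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


class SegmentedCMCRegression(RegressorMixin, BaseEstimator):
    """Continuous two-segment linear regression with a free breakpoint.

    Parameters
    ----------
    abscissa_transform : {"linear", "log10", "ln"}
        Transform applied to concentration before fitting.
    constrain_post_slope_zero : bool
        Force the second segment horizontal (the surface-tension plateau
        convention, where gamma is constant above the CMC).
    alpha : float
        Significance level of the one- vs two-segment F-test; if a single
        line is not rejected, ``detected_`` is False.

    Attributes
    ----------
    cmc_ : float
        Breakpoint on the original concentration scale.
    breakpoint_x_ : float
        Breakpoint on the transformed abscissa.
    slopes_ : tuple of float
        (pre, post) segment slopes per transformed-abscissa unit.
    intercepts_ : tuple of float
        (pre, post) intercepts of the two segment lines, transformed axis.
    rss_ : float
        Residual sum of squares of the two-segment fit.
    detected_ : bool
        Whether the breakpoint is statistically supported.
    f_pvalue_ : float
        P-value of the one- vs two-segment F-test.
    """

    def __init__(
        self,
        abscissa_transform: str = "log10",
        constrain_post_slope_zero: bool = False,
        alpha: float = 0.05,
    ):
        self.abscissa_transform = abscissa_transform
        self.constrain_post_slope_zero = constrain_post_slope_zero
        self.alpha = alpha

    # ------------------------------------------------------------------
    def _transform(self, conc: np.ndarray) -> np.ndarray:
        try:
            fwd = _TRANSFORM_FWD[self.abscissa_transform]
        except KeyError:
            raise ValueError(
                f"unknown abscissa_transform {self.abscissa_transform!r}"
            ) from None
        return fwd(np.asarray(conc, dtype=float))

    def _inverse(self, x: float) -> float:
        return float(_TRANSFORM_INV[self.abscissa_transform](x))

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be a 1-D concentration array (or column vector)")
        y = np.asarray(y, dtype=float)
        if y.shape != X.shape:
            raise ValueError("X and y must have the same length")
        if X.size < MIN_POINTS:
            raise ValueError(f"need at least {MIN_POINTS} points, got {X.size}")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite responses")
        if np.any(X <= 0) and self.abscissa_transform in ("log10", "ln"):
            raise ValueError("concentrations must be positive for log transforms")
        order = np.argsort(X)
        return X[order], y[order]

    def fit(self, X, y):
        """Fit the two-segment model to concentrations ``X``, responses ``y``."""
        conc, resp = self._validate(X, y)
        x = self._transform(conc)
        n = x.size
        constrained = self.constrain_post_slope_zero

        # coarse grid: candidate breakpoints at interior data abscissae with
        # >= 3 points strictly on each side allowed to include the candidate
        lo_i, hi_i = _MIN_SIDE - 1, n - _MIN_SIDE  # inclusive candidate indices
        cand = x[lo_i:hi_i]
        if cand.size == 0:
            raise ValueError("too few points for any breakpoint candidate")
        grid = [( *_rss_at(x, resp, xb, constrained), xb) for xb in cand]
        rss_grid = np.array([g[0] for g in grid])
        best = int(np.argmin(rss_grid))
        xb_best, rss_best, beta_best = grid[best][2], grid[best][0], grid[best][1]

        # golden-section refinement between the grid neighbours of the best
        # candidate (breakpoint may fall between observed abscissae)
        j = lo_i + best
        lo_x = x[max(j - 1, 0)]
        hi_x = x[min(j + 1, n - 1)]
        if hi_x > lo_x:
            res = optimize.minimize_scalar(
                lambda xb: _rss_at(x, resp, xb, constrained)[0],
                bounds=(lo_x, hi_x),
                method="bounded",
                options={"xatol": 1e-10 * (x[-1] - x[0])},
            )
            if res.fun < rss_best:
                xb_best = float(res.x)
                rss_best, beta_best = _rss_at(x, resp, xb_best, constrained)

        a = beta_best[0]
        b_pre = beta_best[1]
        b_post = 0.0 if constrained else beta_best[2]

        # one- vs two-segment F-test
        X1 = np.column_stack([np.ones(n), x])
        beta1, *_ = np.linalg.lstsq(X1, resp, rcond=None)
        r1 = resp - X1 @ beta1
        rss1 = float(r1 @ r1)
        k2 = 3 if constrained else 4  # intercept, slope(s), breakpoint
        k1 = 2
        yscale = max(np.ptp(resp), 1e-300)
        tiny = (1e-9 * yscale) ** 2 * n
        pval: float
        if rss1 <= tiny:
            detected, pval = False, 1.0  # collinear: one line already exact
        elif rss_best <= tiny:
            detected, pval = True, 0.0  # two segments exact, one line is not
        elif n <= k2:
            detected, pval = False, 1.0
        else:
            F = ((rss1 - rss_best) / (k2 - k1)) / (rss_best / (n - k2))
            pval = float(stats.f.sf(F, k2 - k1, n - k2))
            detected = pval < self.alpha

        self.n_features_in_ = 1
        self.x_ = x
        self.y_ = resp
        self.conc_ = conc
        self.breakpoint_x_ = float(xb_best)
        self.cmc_ = self._inverse(xb_best)
        self.slopes_ = (float(b_pre), float(b_post))
        self.intercepts_ = (
            float(a - b_pre * xb_best),
            float(a - b_post * xb_best),
        )
        self.value_at_break_ = float(a)
        self.rss_ = float(rss_best)
        self.detected_ = bool(detected)
        self.f_pvalue_ = pval
        return self

    def predict(self, X):
        """Predict responses at concentrations ``X`` from the fitted segments."""
        x = self._transform(np.asarray(X, dtype=float).ravel())
        dx = x - self.breakpoint_x_
        return (
            self.value_at_break_
            + self.slopes_[0] * np.minimum(dx, 0.0)
            + self.slopes_[1] * np.maximum(dx, 0.0)
        )

    # ------------------------------------------------------------------
    def bootstrap_ci(
        self, n_boot: int = 1000, seed: int | None = None, level: float = 0.95
    ) -> tuple[float, float]:
        """Residual-resampling bootstrap percentile CI for the CMC.

        Residuals of the fitted two-segment model are resampled with
        replacement, added back to the fitted values, and the model refitted;
        the interval is the percentile range of the refitted breakpoints on
        the original concentration scale.
        """
        if not hasattr(self, "cmc_"):
            raise RuntimeError("fit before bootstrap_ci")
        if seed is None:
            raise ValueError("an explicit seed is required for the bootstrap")
        if n_boot < 100:
            warnings.warn(
                f"n_boot={n_boot} < 100 gives unstable percentile intervals",
                stacklevel=2,
            )
        rng = np.random.default_rng(seed)
        fitted = self.predict(self.conc_)
        resid = self.y_ - fitted
        # OLS residuals have deflated variance (k parameters absorbed);
        # inflate by sqrt(n/(n-k)) so resampled noise matches the data noise
        k = 3 if self.constrain_post_slope_zero else 4
        n = resid.size
        if n > k:
            resid = resid * math.sqrt(n / (n - k))
        clone = SegmentedCMCRegression(
            abscissa_transform=self.abscissa_transform,
            constrain_post_slope_zero=self.constrain_post_slope_zero,
            alpha=self.alpha,
        )
        cmcs = []
        failures = 0
        for _ in range(n_boot):
            yb = fitted + rng.choice(resid, size=resid.size, replace=True)
            try:
                clone.fit(self.conc_, yb)
            except (ValueError, np.linalg.LinAlgError):
                failures += 1
                continue
            cmcs.append(clone.cmc_)
        if failures > 0.2 * n_boot:
            raise RuntimeError(
                f"breakpoint fit failed in {failures}/{n_boot} bootstrap replicates"
            )
        q = (1.0 - level) / 2.0
        lo, hi = np.quantile(cmcs, [q, 1.0 - q])
        return float(lo), float(hi)


# ----------------------------------------------------------------------
# functional interface


def fit_two_segment(
    series: TitrationSeries,
    abscissa_transform: str | None = None,
    constrain_post_slope_zero: bool = False,
    alpha: float = 0.05,
) -> BreakpointEstimate:
    """Estimate the CMC of a titration series as a two-segment breakpoint.

    The abscissa transform defaults to the technique's convention
    (log10 for surface tension and fluorescence, linear for conductivity
    and UV/vis peak position).
    """
    transform = abscissa_transform or DEFAULT_TRANSFORMS[series.technique]
    est = SegmentedCMCRegression(
        abscissa_transform=transform,
        constrain_post_slope_zero=constrain_post_slope_zero,
        alpha=alpha,
    ).fit(series.conc, series.response)
    return BreakpointEstimate(
        cmc=est.cmc_,
        ci95=None,
        slopes=est.slopes_,
        intercepts=est.intercepts_,
        abscissa_transform=transform,
        rss=est.rss_,
        detected=est.detected_,
        technique=series.technique,
        conc_unit=series.conc_unit,
        f_pvalue=est.f_pvalue_,
    )


def bootstrap_breakpoint_ci(
    series: TitrationSeries,
    n_boot: int = 1000,
    seed: int | None = None,
    abscissa_transform: str | None = None,
    constrain_post_slope_zero: bool = False,
) -> tuple[float, float]:
    """95% bootstrap CI for the CMC of ``series`` (residual resampling)."""
    transform = abscissa_transform or DEFAULT_TRANSFORMS[series.technique]
    est = SegmentedCMCRegression(
        abscissa_transform=transform,
        constrain_post_slope_zero=constrain_post_slope_zero,
    ).fit(series.conc, series.response)
    return est.bootstrap_ci(n_boot=n_boot, seed=seed)


def consensus_cmc(estimates: Sequence[BreakpointEstimate]) -> dict:
    """Cross-technique CMC summary with a >10x discrepancy flag.

    Fluorescent-probe assays can report apparent CMCs orders of magnitude
    below colligative-property techniques (probe binding to monomers);
    the flag trips when any pair of detected CMCs differs by more than 10x.
    """
    detected = [e for e in estimates if e.detected]
    if not detected:
        raise ValueError("no detected breakpoint estimates to summarize")
    cmcs = np.array([e.cmc for e in detected])
    ratio = float(cmcs.max() / cmcs.min())
    return {
        "cmc_by_technique": {
            (e.technique or f"series{i}"): e.cmc for i, e in enumerate(detected)
        },
        "max_ratio": ratio,
        "agreement": ratio <= 10.0,
    }
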