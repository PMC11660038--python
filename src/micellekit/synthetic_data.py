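"""Synthetic-data generators with planted ground truth.

Every generator is deterministic under its mandatory seed and returns a
``(data, truth)`` pair, where ``truth`` is a JSON-serializable sidecar of
the planted parameters.  The three generators emulate the three input
classes of the analysis pipeline:

* ``gen_titration`` — two-segment concentration–response curves (CMC kink)
  with additive Gaussian noise (instrument-limited techniques);
* ``gen_saxs`` — absolute-scale micelle SAXS curves with multiplicative
  Gaussian noise (signal-proportional counting statistics);
* ``gen_sasa`` — exponentially equilibrating SASA traces with
  multiplicative Gaussian noise.

The SAXS generator deliberately re-implements the full intensity model by
direct transcription of the formulas (adaptive quadrature for the
polydispersity average, no helpers shared with :mod:`micellekit.saxs_model`)
so that it can serve as an independent correctness oracle for the analysis
model: the two implementations are required to agree to better than 1e-8
relative on noiseless curves.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, special

from .md_postproc import TimeSeriesTrace
from .saxs_model import MicelleModelParams, SAXSCurve
from .titration import DEFAULT_TRANSFORMS, TitrationSeries

__all__ = ["gen_titration", "gen_saxs", "gen_sasa", "reference_saxs_intensity"]

#: per-technique generator defaults: (response at the CMC, pre-CMC slope,
#: post-CMC slope) on the technique's conventional abscissa
_TITRATION_DEFAULTS = {
    # gamma falls to the limiting ~51 mN/m plateau; -10.8 mN/m per ln c
    # corresponds to about -24.9 per decade
    "surface_tension": (51.0, -24.9, 0.0),
    # mS/cm vs wt%: micellar charge screening lowers the slope above the CMC
    "conductivity": (0.30, 0.60, 0.35),
    # pyrene-like I1/I0 drops as the probe partitions into micelle cores
    "fluor_intensity_ratio": (1.2, -0.5, -0.1),
    # emission maximum blue-shifts then saturates above the CMC
    "fluor_wavelength_shift": (15.0, 12.0, 0.0),
    # backbone peak position vs wt%: turbidity shifts the apparent maximum
    "uvvis_peak_wavelength": (205.0, 2.0, 14.0),
}


def gen_titration(
    technique: str,
    cmc: float,
    pre_slope: float | None = None,
    post_slope: float | None = None,
    noise_sigma: float = 0.0,
    n: int = 15,
    conc_range: tuple[float, float] = (0.01, 2.0),
    seed: int | None = None,
    response_at_cmc: float | None = None,
) -> tuple[TitrationSeries, dict]:
    """Two-segment titration curve with a kink planted at ``cmc``.

    The response is continuous and piecewise linear on the technique's
    conventional abscissa (log10 or linear concentration), with i.i.d.
    additive Gaussian noise of standard deviation ``noise_sigma``.  For
    ``fluor_wavelength_shift`` the post-CMC branch is forced flat
    (saturating shift).  Concentration grids are geometric for log-abscissa
    techniques and uniform otherwise.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    if n < 8:
        raise ValueError("need n >= 8 points")
    lo, hi = conc_range
    if not (lo < cmc < hi):
        raise ValueError(f"cmc={cmc} outside conc_range={conc_range}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    y0_d, pre_d, post_d = _TITRATION_DEFAULTS[technique]
    y0 = y0_d if response_at_cmc is None else response_at_cmc
    b_pre = pre_d if pre_slope is None else pre_slope
    b_post = post_d if post_slope is None else post_slope
    if technique == "fluor_wavelength_shift":
        b_post = 0.0

    transform = DEFAULT_TRANSFORMS[technique]
    if transform in ("log10", "ln"):
        conc = np.geomspace(lo, hi, n)
        x = np.log10(conc) if transform == "log10" else np.log(conc)
        xb = math.log10(cmc) if transform == "log10" else math.log(cmc)
    else:
        conc = np.linspace(lo, hi, n)
        x, xb = conc, cmc
    dx = x - xb
    resp = y0 + b_pre * np.minimum(dx, 0.0) + b_post * np.maximum(dx, 0.0)
    rng = np.random.default_rng(seed)
    resp = resp + rng.normal(0.0, noise_sigma, size=n) if noise_sigma else resp

    series = TitrationSeries(technique=technique, conc=conc, response=resp)
    truth = {
        "generator": "gen_titration",
        "technique": technique,
        "cmc": cmc,
        "response_at_cmc": y0,
        "pre_slope": b_pre,
        "post_slope": b_post,
        "abscissa_transform": transform,
        "noise_sigma": noise_sigma,
        "n": n,
        "conc_range": list(conc_range),
        "seed": seed,
    }
    return series, truth


# ----------------------------------------------------------------------
# independent SAXS intensity transcription (oracle for saxs_model)


def _ref_sphere_amp(q, R, drho):
    # F(q) = (4/3) pi R^3 drho * 3 (sin qR - qR cos qR)/(qR)^3
    qR = q * R
    vol = 4.0 / 3.0 * math.pi * R**3
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 3.0 * (np.sin(qR) - qR * np.cos(qR)) / qR**3
    return vol * drho * np.where(qR < 1e-8, 1.0, f)


def _ref_core_shell_int(q, R_i, R_o, rc, rs, rsolv):
    amp = _ref_sphere_amp(q, R_o, rs - rsolv) + _ref_sphere_amp(q, R_i, rc - rs)
    return amp**2


def _ref_coil(q, Rg, nu):
    q = np.atleast_1d(np.asarray(q, float))
    U = (2 * nu + 1) * (2 * nu + 2) / 6.0 * (q * Rg) ** 2
    out = np.ones_like(U)
    m = U > 1e-12
    Um = U[m]
    a1, a2 = 1.0 / (2 * nu), 1.0 / nu
    g1 = special.gammainc(a1, Um) * special.gamma(a1)
    g2 = special.gammainc(a2, Um) * special.gamma(a2)
    out[m] = g1 / (nu * Um**a1) - g2 / (nu * Um**a2)
    return out


def _ref_py_structure_factor(q, R_hs, phi):
    if phi == 0:
        return np.ones_like(np.asarray(q, float))
    A = 2.0 * R_hs * np.asarray(q, float)
    a = (1 + 2 * phi) ** 2 / (1 - phi) ** 4
    b = -6 * phi * (1 + phi / 2) ** 2 / (1 - phi) ** 4
    g = phi * a / 2.0
    sinA, cosA = np.sin(A), np.cos(A)
    G = (
        a * (sinA - A * cosA) / A**2
        + b * (2 * A * sinA + (2 - A**2) * cosA - 2) / A**3
        + g
        * (-(A**4) * cosA + 4 * ((3 * A**2 - 6) * cosA + (A**3 - 6 * A) * sinA + 6))
        / A**5
    )
    return 1.0 / (1.0 + 24.0 * phi * G / A)


def reference_saxs_intensity(q, params: MicelleModelParams) -> np.ndarray:
    """Noiseless model intensity by direct formula transcription.

    Polydispersity on the core radius (shell thickness fixed) is evaluated
    with adaptive Gauss-Kronrod quadrature over the +-3 sigma truncated
    Gaussian; independent of the analysis implementation by construction.
    """
    params.validate()
    q = np.asarray(q, float)
    p = params
    if p.poly_sigma == 0:
        I_mic = _ref_core_shell_int(q, p.R_i, p.R_o, p.rho_core, p.rho_shell, p.rho_solv)
    else:
        t = p.R_o - p.R_i
        lo = max(p.R_i - 3 * p.poly_sigma, 1e-6)
        hi = p.R_i + 3 * p.poly_sigma
        norm = integrate.quad(
            lambda r: math.exp(-0.5 * ((r - p.R_i) / p.poly_sigma) ** 2),
            lo, hi, epsabs=0.0, epsrel=1e-12,
        )[0]
        I_mic = np.empty_like(q)
        for k, qk in enumerate(q):
            num = integrate.quad(
                lambda r: math.exp(-0.5 * ((r - p.R_i) / p.poly_sigma) ** 2)
                * float(
                    _ref_core_shell_int(
                        np.array([qk]), r, r + t, p.rho_core, p.rho_shell, p.rho_solv
                    )[0]
                ),
                lo, hi, epsabs=0.0, epsrel=1e-11, limit=200,
            )[0]
            I_mic[k] = num / norm
    if p.phi_hs > 0:
        I_mic = I_mic * _ref_py_structure_factor(q, p.R_hs, p.phi_hs)
    I = p.scale_mic * I_mic
    if p.f_mono > 0:
        I = I + p.f_mono * _ref_coil(q, p.Rg_coil, p.nu)
    return I + p.background


def gen_saxs(
    params: MicelleModelParams,
    q_grid: np.ndarray | None = None,
    noise_frac: float = 0.02,
    seed: int | None = None,
) -> tuple[SAXSCurve, dict]:
    """Synthetic absolute-scale SAXS curve from planted model parameters.

    The noiseless intensity comes from the independent reference
    transcription; multiplicative Gaussian noise sigma = noise_frac * I is
    added and emitted as the uncertainty column.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    if noise_frac < 0:
        raise ValueError("noise_frac must be non-negative")
    if q_grid is None:
        q_grid = np.geomspace(0.005, 0.48, 200)
    q = np.asarray(q_grid, float)
    I_true = reference_saxs_intensity(q, params)
    sigma = noise_frac * I_true
    rng = np.random.default_rng(seed)
    I = I_true + rng.normal(0.0, 1.0, size=q.size) * sigma if noise_frac else I_true
    curve = SAXSCurve(q=q, I=I, sigma=sigma if noise_frac else None)
    truth = {
        "generator": "gen_saxs",
        "params": params.to_dict(),
        "noise_frac": noise_frac,
        "n": int(q.size),
        "q_range": [float(q[0]), float(q[-1])],
        "seed": seed,
    }
    return curve, truth


def gen_sasa(
    S0: float,
    S_inf: float,
    tau: float,
    noise_frac: float = 0.01,
    t_max: float = 10.0,
    dt: float = 0.01,
    seed: int | None = None,
) -> tuple[TimeSeriesTrace, dict]:
    """Exponentially equilibrating SASA trace.

    S(t) = S_inf + (S0 - S_inf) exp(-t/tau) with multiplicative Gaussian
    noise of fractional width ``noise_frac``; t in ns, SASA in nm^2.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    if min(S0, S_inf, tau) <= 0:
        raise ValueError("S0, S_inf and tau must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if noise_frac < 0:
        raise ValueError("noise_frac must be non-negative")
    t = np.arange(0.0, t_max + 0.5 * dt, dt)
    S_true = S_inf + (S0 - S_inf) * np.exp(-t / tau)
    rng = np.random.default_rng(seed)
    S = S_true * (1.0 + rng.normal(0.0, noise_frac, size=t.size)) if noise_frac else S_true
    trace = TimeSeriesTrace(t=t, value=np.clip(S, 0.0, None), observable="sasa")
    truth = {
        "generator": "gen_sasa",
        "S0": S0,
        "S_inf": S_inf,
        "plateau_ratio": S0 / S_inf,
        "tau": tau,
        "noise_frac": noise_frac,
        "t_max": t_max,
        "dt": dt,
        "seed": seed,
    }
    return trace, truth
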