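"""Absolute-intensity SAXS model for lipopeptide micelles.

The micelle is modelled as a core-shell sphere (hydrophobic alkyl core,
peptide shell) with Gaussian polydispersity on the core radius at fixed
shell thickness.  Interparticle interference at higher concentration is
captured by the Percus-Yevick hard-sphere structure factor (two parameters:
effective radius and volume fraction).  Unaggregated monomers, when present,
contribute a generalized Gaussian-coil term whose Flory exponent allows
chain expansion or contraction relative to a theta-solvent Gaussian coil.

    I(q) = scale_mic * <|F_cs(q)|^2>_poly * S_PY(q)
           + f_mono * P_coil(q) + background

All q in A^-1, intensities in cm^-1 (the prefactors carry the absolute
units).  Fitting is weighted least squares on (I_obs - I_model)/sigma via
bounded trust-region optimization, exposed both as a sklearn-style
estimator (`MicelleSAXSModel`) and a functional wrapper (`fit_saxs`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import optimize
from scipy.special import gammainc, gamma as gamma_fn
from sklearn.base import BaseEstimator

__all__ = [
    "SAXSCurve",
    "MicelleModelParams",
    "SAXSFitResult",
    "core_shell_sphere_intensity",
    "generalized_gaussian_coil",
    "hard_sphere_structure_factor",
    "model_intensity",
    "forward_intensity",
    "fit_saxs",
    "MicelleSAXSModel",
]

MAX_PACKING = 0.64  # random close packing; PY is unphysical beyond this


@dataclass
class SAXSCurve:
    """Background-subtracted absolute-scale SAXS curve (q, I, sigma)."""

    q: np.ndarray  # A^-1, strictly increasing, > 0
    I: np.ndarray  # cm^-1
    sigma: np.ndarray | None = None  # cm^-1, 1-sigma errors

    def __post_init__(self) -> None:
        q = np.asarray(self.q, float)
        I = np.asarray(self.I, float)
        if q.ndim != 1 or I.shape != q.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly positive and strictly increasing")
        sig = self.sigma
        if sig is not None:
            sig = np.asarray(sig, float)
            if sig.shape != q.shape:
                raise ValueError("sigma length mismatch")
            if np.any(sig <= 0):
                raise ValueError("sigma must be positive where provided")
        self.q, self.I, self.sigma = q, I, sig

    def __len__(self) -> int:
        return self.q.size


@dataclass
class MicelleModelParams:
    """Parameters of the micelle + monomer intensity model.

    Radii in A, densities relative (e A^-3 or any common scale — only
    differences enter), prefactors and background in cm^-1-bearing units.
    """

    R_i: float = 14.0  # core radius
    R_o: float = 30.0  # outer radius (core + shell)
    rho_core: float = 0.299
    rho_shell: float = 0.38
    rho_solv: float = 0.333
    poly_sigma: float = 0.0  # Gaussian width on R_i, shell thickness fixed
    scale_mic: float = 1e-8
    f_mono: float = 0.0
    Rg_coil: float = 15.0
    nu: float = 0.5  # Flory exponent
    R_hs: float = 35.0  # hard-sphere radius
    phi_hs: float = 0.0  # hard-sphere volume fraction
    background: float = 0.0

    def validate(self) -> None:
        if not (0 < self.R_i < self.R_o):
            raise ValueError("need 0 < R_i < R_o")
        if not (0 <= self.poly_sigma < self.R_i / 3):
            raise ValueError("poly_sigma must lie in [0, R_i/3)")
        if not (0 <= self.phi_hs < MAX_PACKING):
            raise ValueError(f"phi_hs must lie in [0, {MAX_PACKING})")
        if not (0.3 <= self.nu <= 1.0):
            raise ValueError("Flory exponent nu must lie in [0.3, 1.0]")
        if self.Rg_coil <= 0 or self.R_hs <= 0:
            raise ValueError("Rg_coil and R_hs must be positive")
        if min(self.scale_mic, self.f_mono, self.background) < 0:
            raise ValueError("prefactors and background must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "MicelleModelParams":
        return replace(self, **kw)


# ----------------------------------------------------------------------
# form and structure factors


def _sphere_ff(x: np.ndarray) -> np.ndarray:
    """3(sin x - x cos x)/x^3 with a series branch for small x (f(0) = 1)."""
    x = np.asarray(x, float)
    out = np.empty_like(x)
    small = np.abs(x) < 0.05
    xs = x[small]
    x2 = xs * xs
    out[small] = 1.0 - x2 / 10.0 + x2 * x2 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def core_shell_amplitude(q, R_i, R_o, rho_core, rho_shell, rho_solv):
    """Scattering amplitude F(q) of a core-shell sphere, electron units."""
    q = np.asarray(q, float)
    V_o = 4.0 / 3.0 * math.pi * R_o**3
    V_i = 4.0 / 3.0 * math.pi * R_i**3
    return V_o * (rho_shell - rho_solv) * _sphere_ff(q * R_o) + V_i * (
        rho_core - rho_shell
    ) * _sphere_ff(q * R_i)


def core_shell_sphere_intensity(q, R_i, R_o, rho_core, rho_shell, rho_solv):
    """Per-particle intensity |F(q)|^2 of a core-shell sphere.

    R_i = R_o is tolerated as the degenerate zero-thickness shell (a
    homogeneous sphere of core contrast).
    """
    if R_i > R_o:
        raise ValueError("core radius cannot exceed outer radius")
    if R_i <= 0:
        raise ValueError("core radius must be positive")
    return core_shell_amplitude(q, R_i, R_o, rho_core, rho_shell, rho_solv) ** 2


def generalized_gaussian_coil(q, Rg, nu=0.5):
    """Generalized Gaussian-coil form factor, normalized to P(0) = 1.

    Uses the excluded-volume chain expression built from lower incomplete
    gamma functions with U = (2nu+1)(2nu+2) (q Rg)^2 / 6; at nu = 1/2 it
    reduces exactly to the Debye function 2(exp(-x) + x - 1)/x^2 with
    x = q^2 Rg^2.
    """
    if Rg <= 0:
        raise ValueError("Rg must be positive")
    if not (0.3 <= nu <= 1.0):
        raise ValueError("nu must lie in [0.3, 1.0]")
    q = np.asarray(q, float)
    x2 = (q * Rg) ** 2
    U = (2 * nu + 1) * (2 * nu + 2) / 6.0 * x2
    out = np.ones_like(U)
    big = U > 1e-10
    Ub = U[big]
    a1 = 1.0 / (2.0 * nu)
    a2 = 1.0 / nu
    g1 = gammainc(a1, Ub) * gamma_fn(a1)  # lower incomplete gamma
    g2 = gammainc(a2, Ub) * gamma_fn(a2)
    out[big] = g1 / (nu * Ub**a1) - g2 / (nu * Ub**a2)
    out[~big] = 1.0 - x2[~big] / 3.0
    return out


def hard_sphere_structure_factor(q, R_hs, phi):
    """Percus-Yevick hard-sphere structure factor S(q).

    Analytic solution via the direct correlation function; S(0) equals the
    compressibility limit (1-phi)^4/(1+2phi)^2 and S -> 1 at large q.
    """
    if phi < 0 or phi >= MAX_PACKING:
        raise ValueError(f"phi must lie in [0, {MAX_PACKING}) for a physical packing")
    if R_hs <= 0:
        raise ValueError("hard-sphere radius must be positive")
    q = np.asarray(q, float)
    if phi == 0:
        return np.ones_like(q)
    om = (1.0 - phi) ** 4
    alpha = (1.0 + 2.0 * phi) ** 2 / om
    beta = -6.0 * phi * (1.0 + phi / 2.0) ** 2 / om
    gam = 0.5 * phi * alpha
    A = 2.0 * R_hs * q
    GoverA = np.empty_like(A)
    small = A < 0.1
    As = A[small]
    A2 = As * As
    # series of G(A)/A about A = 0 (keeps the q -> 0 limit exact)
    GoverA[small] = (
        alpha * (1.0 / 3.0 - A2 / 30.0)
        + beta * (0.25 - A2 / 36.0)
        + gam * (1.0 / 6.0 - A2 / 48.0)
    )
    Al = A[~small]
    sinA, cosA = np.sin(Al), np.cos(Al)
    t1 = alpha * (sinA - Al * cosA) / Al**2
    t2 = beta * (2.0 * Al * sinA + (2.0 - Al**2) * cosA - 2.0) / Al**3
    t3 = gam * (
        -(Al**4) * cosA
        + 4.0 * ((3.0 * Al**2 - 6.0) * cosA + (Al**3 - 6.0 * Al) * sinA + 6.0)
    ) / Al**5
    GoverA[~small] = (t1 + t2 + t3) / Al
    return 1.0 / (1.0 + 24.0 * phi * GoverA)


# ----------------------------------------------------------------------
# polydispersity and composite model

_POLY_NODES = 41  # Gauss-Legendre nodes over +-3 sigma


def _poly_average_intensity(q, p: MicelleModelParams) -> np.ndarray:
    """<|F_cs|^2> over a Gaussian distribution of R_i, shell thickness fixed.

    Truncated at +-3 sigma (and at R_i > 0), Gauss-Legendre quadrature with
    renormalized truncated-normal weights.
    """
    if p.poly_sigma == 0:
        return core_shell_sphere_intensity(
            q, p.R_i, p.R_o, p.rho_core, p.rho_shell, p.rho_solv
        )
    thickness = p.R_o - p.R_i
    lo = max(p.R_i - 3.0 * p.poly_sigma, 1e-6)
    hi = p.R_i + 3.0 * p.poly_sigma
    xg, wg = leggauss(_POLY_NODES)
    nodes = 0.5 * (hi - lo) * xg + 0.5 * (hi + lo)
    wq = 0.5 * (hi - lo) * wg
    gauss = np.exp(-0.5 * ((nodes - p.R_i) / p.poly_sigma) ** 2)
    weights = wq * gauss
    weights /= weights.sum()
    q = np.asarray(q, float)
    acc = np.zeros_like(q)
    for Ri_k, w_k in zip(nodes, weights):
        acc += w_k * core_shell_sphere_intensity(
            q, Ri_k, Ri_k + thickness, p.rho_core, p.rho_shell, p.rho_solv
        )
    return acc


def model_intensity(q, params: MicelleModelParams) -> np.ndarray:
    """Total model intensity I(q) in cm^-1.

    scale_mic * <|F_cs|^2>_poly * S_PY(q) + f_mono * P_coil(q) + background.
    The structure factor multiplies the polydispersity-averaged micelle
    intensity (monodisperse S(q) approximation, no decoupling correction).
    """
    params.validate()
    q = np.asarray(q, float)
    I_mic = _poly_average_intensity(q, params)
    if params.phi_hs > 0:
        I_mic = I_mic * hard_sphere_structure_factor(q, params.R_hs, params.phi_hs)
    I = params.scale_mic * I_mic
    if params.f_mono > 0:
        I = I + params.f_mono * generalized_gaussian_coil(q, params.Rg_coil, params.nu)
    return I + params.background


def forward_intensity(params: MicelleModelParams) -> float:
    """Micelle-term forward scattering I(0) in cm^-1.

    Dilute extrapolation: excludes the hard-sphere S(0), the monomer coil
    term and the background, so the value feeds the absolute-intensity
    molar-mass analysis directly.
    """
    params.validate()
    if params.scale_mic == 0:
        return 0.0
    I0 = _poly_average_intensity(np.array([1e-8]), params)[0]
    return float(params.scale_mic * I0)


# ----------------------------------------------------------------------
# fitting

#: parameters optimized on an internal vector where R_o is carried as the
#: shell thickness t = R_o - R_i so the bound t > 0 preserves R_i < R_o
_FIT_NAMES = (
    "R_i", "shell_t", "rho_core", "rho_shell", "rho_solv", "poly_sigma",
    "scale_mic", "f_mono", "Rg_coil", "nu", "R_hs", "phi_hs", "background",
)

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "R_i": (2.0, 200.0),
    "shell_t": (0.5, 200.0),
    "rho_core": (0.0, 1.0),
    "rho_shell": (0.0, 1.0),
    "rho_solv": (0.0, 1.0),
    "poly_sigma": (0.0, 30.0),
    "scale_mic": (0.0, np.inf),
    "f_mono": (0.0, np.inf),
    "Rg_coil": (1.0, 200.0),
    "nu": (0.3, 1.0),
    "R_hs": (2.0, 500.0),
    "phi_hs": (0.0, MAX_PACKING - 1e-6),
    "background": (0.0, np.inf),
}


def _params_to_internal(p: MicelleModelParams) -> dict[str, float]:
    d = p.to_dict()
    d["shell_t"] = d.pop("R_o") - d["R_i"]
    return d


def _internal_to_params(d: dict[str, float]) -> MicelleModelParams:
    d = dict(d)
    d["R_o"] = d["R_i"] + d.pop("shell_t")
    return MicelleModelParams(**d)


@dataclass
class SAXSFitResult:
    """Weighted least-squares fit outcome."""

    params: MicelleModelParams
    chi2_red: float
    cov: np.ndarray | None  # covariance of the free parameters
    stderr: dict[str, float]  # 1-sigma uncertainties, internal names
    free_names: tuple[str, ...]
    success: bool
    message: str
    nfev: int


def fit_saxs(
    curve: SAXSCurve,
    init: MicelleModelParams,
    bounds: dict[str, tuple[float, float]] | None = None,
    fixed: tuple[str, ...] = (),
    multi_start: int = 1,
    seed: int | None = None,
) -> SAXSFitResult:
    """Fit the micelle model to an absolute-scale SAXS curve.

    Parameters may be held fixed by name (``R_o`` may be given as ``shell_t``
    to fix the shell thickness instead).  ``multi_start > 1`` jitters the
    free initial values by +-10% (seeded) and keeps the best fit.

    Raises if the number of data points does not exceed the number of free
    parameters; non-convergence is reported in the result, never silent.
    """
    init.validate()
    fixed = tuple("shell_t" if f == "R_o" else f for f in fixed)
    for f in fixed:
        if f not in _FIT_NAMES:
            raise ValueError(f"unknown parameter {f!r}")
    free = [n for n in _FIT_NAMES if n not in fixed]
    n_data = len(curve)
    if n_data <= len(free):
        raise ValueError(
            f"{n_data} points cannot constrain {len(free)} free parameters"
        )

    sigma = curve.sigma
    if sigma is None:
        sigma = np.maximum(0.02 * np.abs(curve.I), 1e-4 * np.abs(curve.I).max())

    d0 = _params_to_internal(init)
    bmap = dict(DEFAULT_BOUNDS)
    if bounds:
        for k, v in bounds.items():
            bmap["shell_t" if k == "R_o" else k] = v
    lo = np.array([bmap[n][0] for n in free])
    hi = np.array([bmap[n][1] for n in free])
    x0 = np.clip(np.array([d0[n] for n in free]), lo, hi)

    def residuals(x):
        d = dict(d0)
        d.update(zip(free, x))
        try:
            p = _internal_to_params(d)
            I = model_intensity(curve.q, p)
        except ValueError:
            return np.full(n_data, 1e12)
        return (curve.I - I) / sigma

    starts = [x0]
    if multi_start > 1:
        rng = np.random.default_rng(seed)
        for _ in range(multi_start - 1):
            jit = x0 * (1.0 + 0.1 * rng.standard_normal(x0.size))
            starts.append(np.clip(jit, lo, hi))

    best = None
    for s in starts:
        res = optimize.least_squares(
            residuals, s, bounds=(lo, hi), method="trf", x_scale="jac",
            max_nfev=4000,
        )
        if best is None or res.cost < best.cost:
            best = res

    dof = max(n_data - len(free), 1)
    chi2_red = float(2.0 * best.cost / dof)
    d = dict(d0)
    d.update(zip(free, best.x))
    fitted = _internal_to_params(d)

    cov = None
    stderr: dict[str, float] = {}
    try:
        JTJ = best.jac.T @ best.jac
        cov = np.linalg.inv(JTJ) * chi2_red
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        stderr = dict(zip(free, se))
    except np.linalg.LinAlgError:
        pass

    return SAXSFitResult(
        params=fitted,
        chi2_red=chi2_red,
        cov=cov,
        stderr=stderr,
        free_names=tuple(free),
        success=bool(best.success),
        message=str(best.message),
        nfev=int(best.nfev),
    )


class MicelleSAXSModel(BaseEstimator):
    """sklearn-style estimator wrapping the micelle SAXS model fit.

    Init parameters are the model's starting values plus ``fixed`` (names
    held constant) and ``bounds`` overrides; ``fit(q, I, sigma=...)`` runs
    the weighted least squares and exposes ``params_``, ``chi2_red_``,
    ``stderr_``, ``success_``; ``predict(q)`` evaluates the fitted model.
    """

    def __init__(
        self,
        R_i: float = 14.0,
        R_o: float = 30.0,
        rho_core: float = 0.299,
        rho_shell: float = 0.38,
        rho_solv: float = 0.333,
        poly_sigma: float = 0.0,
        scale_mic: float = 1e-8,
        f_mono: float = 0.0,
        Rg_coil: float = 15.0,
        nu: float = 0.5,
        R_hs: float = 35.0,
        phi_hs: float = 0.0,
        background: float = 0.0,
        fixed: tuple[str, ...] = (),
        bounds: dict | None = None,
        multi_start: int = 1,
        seed: int | None = None,
    ):
        self.R_i = R_i
        self.R_o = R_o
        self.rho_core = rho_core
        self.rho_shell = rho_shell
        self.rho_solv = rho_solv
        self.poly_sigma = poly_sigma
        self.scale_mic = scale_mic
        self.f_mono = f_mono
        self.Rg_coil = Rg_coil
        self.nu = nu
        self.R_hs = R_hs
        self.phi_hs = phi_hs
        self.background = background
        self.fixed = fixed
        self.bounds = bounds
        self.multi_start = multi_start
        self.seed = seed

    def _init_params(self) -> MicelleModelParams:
        keys = MicelleModelParams().to_dict().keys()
        return MicelleModelParams(**{k: getattr(self, k) for k in keys})

    def fit(self, X, y, sigma=None):
        curve = SAXSCurve(np.asarray(X, float).ravel(), np.asarray(y, float), sigma)
        result = fit_saxs(
            curve,
            self._init_params(),
            bounds=self.bounds,
            fixed=tuple(self.fixed),
            multi_start=self.multi_start,
            seed=self.seed,
        )
        self.result_ = result
        self.params_ = result.params
        self.chi2_red_ = result.chi2_red
        self.stderr_ = result.stderr
        self.success_ = result.success
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return model_intensity(np.asarray(X, float).ravel(), self.params_)

    def forward_intensity(self) -> float:
        """Fitted dilute-limit micelle I(0), cm^-1."""
        return forward_intensity(self.params_)
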