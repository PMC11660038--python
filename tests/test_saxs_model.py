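"""Core-shell form factor, coil, Percus-Yevick structure factor, model fit."""

import numpy as np
import pytest
from scipy import integrate

import micellekit as mk
from micellekit.saxs_model import (
    DEFAULT_BOUNDS,
    MicelleModelParams,
    MicelleSAXSModel,
    core_shell_sphere_intensity,
    fit_saxs,
)
from micellekit.synthetic_data import gen_saxs


def realspace_amplitude(q, R_i, R_o, rc, rs, rsolv):
    """Radial Fourier transform of the excess-density profile (oracle)."""

    def integrand(r):
        drho = (rc - rsolv) if r < R_i else (rs - rsolv)
        x = q * r
        sinc = np.sinc(x / np.pi)  # sin(x)/x, handles q*r = 0
        return 4.0 * np.pi * drho * r**2 * sinc

    val, _ = integrate.quad(integrand, 0.0, R_o, points=[R_i], epsrel=1e-12, epsabs=0)
    return val


class TestCoreShellSphere:
    def test_contrast_match_is_identically_zero(self):
        q = np.geomspace(0.005, 0.48, 50)
        I = core_shell_sphere_intensity(q, 14, 30, 0.3, 0.3, 0.3)
        assert np.all(I == 0.0)

    def test_degenerate_shell_is_homogeneous_sphere(self):
        q = np.geomspace(0.01, 0.4, 30)
        I = core_shell_sphere_intensity(q, 20, 20, 0.29, 0.5, 0.333)
        V = 4 / 3 * np.pi * 20**3
        x = q * 20.0
        f = 3 * (np.sin(x) - x * np.cos(x)) / x**3
        expected = (V * (0.29 - 0.333) * f) ** 2
        assert np.allclose(I, expected, rtol=1e-12)
        # forward value = [V (rho_core - rho_solv)]^2
        I0 = core_shell_sphere_intensity(np.array([1e-9]), 20, 20, 0.29, 0.5, 0.333)[0]
        assert I0 == pytest.approx((V * (0.29 - 0.333)) ** 2, rel=1e-9)

    @pytest.mark.parametrize("q", [0.005, 0.02, 0.1, 0.3])
    def test_against_realspace_fourier_oracle(self, q):
        amp = realspace_amplitude(q, 14, 30, 0.299, 0.38, 0.333)
        I = core_shell_sphere_intensity(np.array([q]), 14, 30, 0.299, 0.38, 0.333)[0]
        assert I == pytest.approx(amp**2, rel=1e-9)

    def test_forward_limit_closed_form(self):
        Vo = 4 / 3 * np.pi * 30**3
        Vi = 4 / 3 * np.pi * 14**3
        expect = (Vo * (0.38 - 0.333) + Vi * (0.299 - 0.38)) ** 2
        I0 = core_shell_sphere_intensity(np.array([1e-10]), 14, 30, 0.299, 0.38, 0.333)[0]
        assert I0 == pytest.approx(expect, rel=1e-10)

    def test_vanishing_core_continuity(self):
        """R_i -> 0 approaches the homogeneous sphere of shell contrast."""
        q = np.geomspace(0.01, 0.4, 20)
        I_small = core_shell_sphere_intensity(q, 1e-5, 30, 0.9, 0.38, 0.333)
        I_shell = core_shell_sphere_intensity(q, 30, 30, 0.38, 0.38, 0.333)
        assert np.allclose(I_small, I_shell, rtol=1e-9)

    def test_inverted_radii_rejected(self):
        with pytest.raises(ValueError):
            core_shell_sphere_intensity(np.array([0.1]), 31, 30, 0.3, 0.4, 0.33)

    def test_nonnegative(self):
        q = np.geomspace(0.005, 0.48, 200)
        assert np.all(core_shell_sphere_intensity(q, 14, 30, 0.299, 0.38, 0.333) >= 0)


class TestGeneralizedCoil:
    def test_normalization_at_zero_q(self):
        assert mk.generalized_gaussian_coil(np.array([0.0]), 20.0, 0.6)[0] == 1.0

    def test_debye_value_at_unit_argument(self):
        # q Rg = 1, nu = 1/2: Debye P = 2(exp(-1) + 1 - 1)/1 = 2/e
        val = mk.generalized_gaussian_coil(np.array([0.05]), 20.0, 0.5)[0]
        assert val == pytest.approx(2 / np.e, abs=1e-6)
        assert val == pytest.approx(0.7358, abs=1e-4)

    def test_reduces_to_debye_at_half(self):
        q = np.geomspace(1e-3, 0.5, 80)
        Rg = 18.0
        x = (q * Rg) ** 2
        debye = 2 * (np.exp(-x) + x - 1) / x**2
        P = mk.generalized_gaussian_coil(q, Rg, 0.5)
        assert np.max(np.abs(P - debye)) < 1e-6

    def test_expanded_chain_decays_more_slowly_at_high_q(self):
        # high-q power law is q^(-1/nu): nu = 0.6 falls off slower than nu = 0.5
        q = np.array([0.2])
        P_theta = mk.generalized_gaussian_coil(q, 18.0, 0.5)[0]
        P_good = mk.generalized_gaussian_coil(q, 18.0, 0.6)[0]
        assert 0 < P_theta < P_good < 1

    def test_invalid_nu_rejected(self):
        with pytest.raises(ValueError):
            mk.generalized_gaussian_coil(np.array([0.1]), 18.0, 0.2)


class TestHardSphereStructureFactor:
    def test_ideal_gas_limit(self):
        q = np.geomspace(0.005, 0.5, 50)
        assert np.all(mk.hard_sphere_structure_factor(q, 30, 0.0) == 1.0)

    @pytest.mark.parametrize("phi", [0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.49])
    def test_compressibility_limit(self, phi):
        S0 = mk.hard_sphere_structure_factor(np.array([0.0]), 30.0, phi)[0]
        assert S0 == pytest.approx((1 - phi) ** 4 / (1 + 2 * phi) ** 2, abs=1e-10)

    def test_phi_010_value(self):
        S0 = mk.hard_sphere_structure_factor(np.array([1e-9]), 30.0, 0.1)[0]
        assert S0 == pytest.approx(0.4556, abs=1e-4)

    def test_large_q_limit(self):
        # q R_hs = 50
        S = mk.hard_sphere_structure_factor(np.array([50 / 30.0]), 30.0, 0.3)[0]
        assert abs(S - 1) < 0.01

    def test_positive_and_continuous_at_series_switch(self):
        R = 30.0
        q = np.linspace(0.09 / (2 * R), 0.11 / (2 * R), 201)  # spans A = 0.1
        S = mk.hard_sphere_structure_factor(q, R, 0.35)
        assert np.all(S > 0)
        assert np.max(np.abs(np.diff(S))) < 1e-5

    def test_unphysical_packing_rejected(self):
        with pytest.raises(ValueError):
            mk.hard_sphere_structure_factor(np.array([0.1]), 30.0, 0.64)


class TestModelIntensity:
    def test_reduces_to_bare_core_shell(self):
        p = MicelleModelParams(
            poly_sigma=0.0, phi_hs=0.0, f_mono=0.0, scale_mic=3e-9, background=2e-3
        )
        q = np.geomspace(0.005, 0.48, 60)
        expected = 3e-9 * core_shell_sphere_intensity(
            q, p.R_i, p.R_o, p.rho_core, p.rho_shell, p.rho_solv
        ) + 2e-3
        assert np.allclose(mk.model_intensity(q, p), expected, rtol=1e-12)

    def test_forward_value_consistency(self):
        p = MicelleModelParams(
            poly_sigma=2.0, phi_hs=0.12, f_mono=0.04, scale_mic=5e-9, background=1e-3
        )
        S0 = mk.hard_sphere_structure_factor(np.array([1e-8]), p.R_hs, p.phi_hs)[0]
        I_low = mk.model_intensity(np.array([1e-6]), p)[0]
        expected = mk.forward_intensity(p) * S0 + p.f_mono + p.background
        assert I_low == pytest.approx(expected, rel=1e-6)

    def test_forward_intensity_scaling(self):
        p = MicelleModelParams(scale_mic=4e-9)
        assert mk.forward_intensity(p.replace(scale_mic=0.0)) == 0.0
        half = p.replace(
            rho_core=0.333 + (p.rho_core - 0.333) / 2,
            rho_shell=0.333 + (p.rho_shell - 0.333) / 2,
        )
        assert mk.forward_intensity(half) == pytest.approx(
            mk.forward_intensity(p) / 4, rel=1e-9
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            mk.model_intensity(np.array([0.1]), MicelleModelParams(R_i=31, R_o=30))
        with pytest.raises(ValueError):
            mk.model_intensity(np.array([0.1]), MicelleModelParams(poly_sigma=8.0))


class TestFit:
    TRUTH = MicelleModelParams(
        R_i=14.0, R_o=30.0, poly_sigma=2.0, scale_mic=5e-9,
        phi_hs=0.10, R_hs=35.0, background=1e-3,
    )
    FIXED = ("rho_core", "rho_shell", "rho_solv", "f_mono", "Rg_coil", "nu")

    def test_noiseless_fit_from_truth_is_exact(self):
        curve, _ = gen_saxs(self.TRUTH, noise_frac=0.0, seed=1)
        curve.sigma = 0.02 * curve.I
        res = fit_saxs(curve, self.TRUTH, fixed=self.FIXED)
        assert res.success
        assert res.chi2_red < 1e-12
        assert res.params.R_i == pytest.approx(14.0, rel=1e-4)

    def test_recovery_from_perturbed_init(self):
        curve, truth = gen_saxs(self.TRUTH, noise_frac=0.02, seed=3)
        init = self.TRUTH.replace(
            R_i=14.0 * 1.2, R_o=30.0 * 0.85, scale_mic=5e-9 * 1.2,
            phi_hs=0.12, poly_sigma=2.4, background=1.2e-3,
        )
        res = fit_saxs(curve, init, fixed=self.FIXED)
        assert res.success
        assert res.params.R_i == pytest.approx(14.0, rel=0.05)
        assert res.params.R_o == pytest.approx(30.0, rel=0.05)

    def test_missing_monomer_term_degrades_fit(self):
        truth = self.TRUTH.replace(f_mono=0.05, Rg_coil=16.0, phi_hs=0.0)
        curve, _ = gen_saxs(truth, noise_frac=0.02, seed=9)
        fixed_nomono = self.FIXED + ("phi_hs", "R_hs")
        full = fit_saxs(curve, truth, fixed=tuple(f for f in fixed_nomono if f != "f_mono"))
        reduced = fit_saxs(curve, truth.replace(f_mono=0.0), fixed=fixed_nomono)
        assert reduced.chi2_red > 2 * full.chi2_red

    def test_chi2_consistent_with_injected_noise(self):
        vals = []
        for seed in (11, 12, 13):
            curve, _ = gen_saxs(self.TRUTH, noise_frac=0.02, seed=seed)
            res = fit_saxs(curve, self.TRUTH, fixed=self.FIXED)
            vals.append(res.chi2_red)
        assert all(0.7 < v < 1.3 for v in vals)

    def test_too_few_points_rejected(self):
        q = np.geomspace(0.01, 0.4, 6)
        curve = mk.SAXSCurve(q, np.ones(6), np.ones(6))
        with pytest.raises(ValueError, match="free parameters"):
            fit_saxs(curve, self.TRUTH)

    def test_estimator_contract(self):
        from sklearn.base import clone

        curve, _ = gen_saxs(self.TRUTH, noise_frac=0.02, seed=21)
        est = MicelleSAXSModel(
            R_i=15.0, R_o=28.0, poly_sigma=2.0, scale_mic=5e-9,
            phi_hs=0.1, R_hs=35.0, background=1e-3, fixed=self.FIXED,
        )
        est = clone(est)  # init params survive cloning
        est.fit(curve.q, curve.I, sigma=curve.sigma)
        assert est.success_
        assert est.params_.R_i == pytest.approx(14.0, rel=0.05)
        pred = est.predict(curve.q)
        assert pred.shape == curve.q.shape
        assert est.forward_intensity() > 0

    def test_bounds_table_covers_all_fit_names(self):
        from micellekit.saxs_model import _FIT_NAMES

        assert set(DEFAULT_BOUNDS) == set(_FIT_NAMES)
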