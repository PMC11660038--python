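"""Breakpoint (CMC) estimation on titration series."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import micellekit as mk
from micellekit.titration import SegmentedCMCRegression


def vshape(xb=0.5, n=12, b_pre=-20.0, b_post=2.0, y0=50.0, transform="linear"):
    """Exact two-segment data with a kink planted at xb (transformed axis)."""
    x = np.linspace(-2.0, 1.0, n) if transform != "linear" else np.linspace(0.05, 2.0, n)
    if transform == "log10":
        conc = 10.0**x
    elif transform == "ln":
        conc = np.exp(x)
    else:
        conc = x
    dx = x - xb
    y = y0 + b_pre * np.minimum(dx, 0) + b_post * np.maximum(dx, 0)
    return conc, y, x


class TestExactRecovery:
    @pytest.mark.parametrize("transform", ["linear", "log10", "ln"])
    def test_noiseless_kink_recovered_exactly(self, transform):
        xb = 0.5 if transform == "linear" else -0.3
        conc, y, x = vshape(xb=xb, transform=transform)
        est = SegmentedCMCRegression(abscissa_transform=transform).fit(conc, y)
        yscale = np.ptp(y)
        assert est.rss_ < (1e-9 * yscale) ** 2 * len(y)
        assert abs(est.breakpoint_x_ - xb) < 1e-6 * np.ptp(x)
        assert est.detected_

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        xb=st.floats(0.4, 1.6),
        b_pre=st.floats(-50.0, -5.0),
        b_post=st.floats(-2.0, 5.0),
    )
    def test_random_planted_kinks(self, xb, b_pre, b_post):
        """Any noiseless piecewise-linear input is recovered with rss ~ 0."""
        if abs(b_pre - b_post) < 1.0:
            return  # no resolvable kink
        conc, y, x = vshape(xb=xb, n=15, b_pre=b_pre, b_post=b_post)
        est = SegmentedCMCRegression(abscissa_transform="linear").fit(conc, y)
        assert est.rss_ < (1e-9 * np.abs(y).max()) ** 2 * len(y)
        assert abs(est.cmc_ - xb) < np.diff(x).max()

    def test_continuity_at_breakpoint(self):
        conc, y, _ = vshape()
        est = SegmentedCMCRegression(abscissa_transform="linear").fit(conc, y)
        pre, post = est.slopes_
        i_pre, i_post = est.intercepts_
        v_pre = i_pre + pre * est.breakpoint_x_
        v_post = i_post + post * est.breakpoint_x_
        assert abs(v_pre - v_post) < 1e-9 * np.ptp(y)

    def test_affine_response_invariance(self):
        """Rescaling/shifting the response axis leaves the breakpoint unchanged."""
        conc, y, _ = vshape(xb=0.8)
        rng = np.random.default_rng(11)
        y = y + rng.normal(0, 0.8, y.size)
        est0 = SegmentedCMCRegression(abscissa_transform="linear").fit(conc, y)
        for a, b in [(3.7, -12.0), (0.01, 5.0), (-2.0, 0.0)]:
            est = SegmentedCMCRegression(abscissa_transform="linear").fit(conc, a * y + b)
            assert est.cmc_ == pytest.approx(est0.cmc_, abs=1e-6)


class TestDetection:
    def test_collinear_not_detected(self):
        conc = np.linspace(0.1, 2.0, 10)
        y = 3.0 - 1.5 * conc
        est = SegmentedCMCRegression(abscissa_transform="linear").fit(conc, y)
        assert not est.detected_

    def test_pure_noise_rarely_detected(self):
        """F-test at alpha=0.05 keeps false detections near the nominal rate."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            conc = np.linspace(0.1, 2.0, 15)
            y = 5.0 + 2.0 * conc + rng.normal(0, 0.3, 15)
            est = SegmentedCMCRegression(abscissa_transform="linear").fit(conc, y)
            hits += est.detected_
        assert hits <= 5  # P(>5 | p=0.05, n=20) < 1e-3

    def test_plateau_constraint_forces_flat_post_segment(self):
        s, _ = mk.gen_titration("surface_tension", cmc=0.5, noise_sigma=0.3, n=15, seed=3)
        est = mk.fit_two_segment(s, constrain_post_slope_zero=True)
        assert est.slopes[1] == 0.0
        assert 0.3 < est.cmc < 0.8


class TestInputValidation:
    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least"):
            SegmentedCMCRegression().fit([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])

    def test_non_finite_response(self):
        with pytest.raises(ValueError):
            SegmentedCMCRegression(abscissa_transform="linear").fit(
                np.linspace(0.1, 1, 8), [1, 2, np.nan, 4, 5, 6, 7, 8]
            )

    def test_series_rejects_ties_and_nonpositive_conc(self):
        with pytest.raises(ValueError):
            mk.TitrationSeries("conductivity", [0.1, 0.1, 0.3, 0.4, 0.5], [1, 2, 3, 4, 5])
        with pytest.raises(ValueError):
            mk.TitrationSeries("conductivity", [-0.1, 0.2, 0.3, 0.4, 0.5], [1, 2, 3, 4, 5])


class TestBootstrap:
    def test_noiseless_interval_collapses_to_kink(self):
        conc, y, _ = vshape(xb=0.9, n=14)
        est = SegmentedCMCRegression(abscissa_transform="linear").fit(conc, y)
        lo, hi = est.bootstrap_ci(n_boot=200, seed=0)
        assert hi - lo < 1e-6
        assert lo == pytest.approx(0.9, abs=1e-6)

    def test_same_seed_is_deterministic(self):
        s, _ = mk.gen_titration("surface_tension", cmc=0.3, noise_sigma=0.5, n=15, seed=7)
        ci1 = mk.bootstrap_breakpoint_ci(s, n_boot=300, seed=42)
        ci2 = mk.bootstrap_breakpoint_ci(s, n_boot=300, seed=42)
        assert ci1 == ci2

    def test_small_n_boot_warns(self):
        conc, y, _ = vshape()
        est = SegmentedCMCRegression(abscissa_transform="linear").fit(conc, y)
        with pytest.warns(UserWarning, match="n_boot"):
            est.bootstrap_ci(n_boot=50, seed=1)

    def test_seed_required(self):
        conc, y, _ = vshape()
        est = SegmentedCMCRegression(abscissa_transform="linear").fit(conc, y)
        with pytest.raises(ValueError, match="seed"):
            est.bootstrap_ci(n_boot=200)

    def test_ci_width_grows_with_noise_on_average(self):
        """More response noise never shrinks the mean bootstrap CI width."""
        widths = []
        for sigma in (0.2, 0.8, 2.0):
            ws = []
            for seed in range(6):
                s, _ = mk.gen_titration(
                    "surface_tension", cmc=0.3, noise_sigma=sigma, n=15, seed=100 + seed
                )
                lo, hi = mk.bootstrap_breakpoint_ci(s, n_boot=200, seed=seed)
                ws.append(hi - lo)
            widths.append(np.mean(ws))
        assert widths[0] <= widths[1] <= widths[2]


class TestConsensus:
    def _est(self, cmc, technique="surface_tension", detected=True):
        return mk.BreakpointEstimate(
            cmc=cmc, ci95=None, slopes=(-1.0, 0.0), intercepts=(0.0, 0.0),
            abscissa_transform="log10", rss=0.0, detected=detected,
            technique=technique,
        )

    def test_agreeing_techniques(self):
        ests = [
            self._est(0.54, "surface_tension"),
            self._est(0.45, "conductivity"),
            self._est(0.3, "uvvis_peak_wavelength"),
        ]
        out = mk.consensus_cmc(ests)
        assert out["agreement"]
        assert out["max_ratio"] == pytest.approx(0.54 / 0.3)

    def test_probe_discrepancy_flagged(self):
        out = mk.consensus_cmc(
            [self._est(0.0016, "fluor_intensity_ratio"), self._est(0.54)]
        )
        assert not out["agreement"]
        assert out["max_ratio"] == pytest.approx(337.5, rel=1e-6)

    def test_single_estimate_passes(self):
        out = mk.consensus_cmc([self._est(0.3)])
        assert out["agreement"]
        assert out["cmc_by_technique"]["surface_tension"] == 0.3

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mk.consensus_cmc([])
        with pytest.raises(ValueError):
            mk.consensus_cmc([self._est(0.3, detected=False)])


def test_sklearn_estimator_contract():
    from sklearn.base import clone

    est = SegmentedCMCRegression(abscissa_transform="linear", alpha=0.01)
    est2 = clone(est)
    assert est2.get_params()["alpha"] == 0.01
    conc, y, _ = vshape()
    est2.fit(conc, y)
    pred = est2.predict(conc)
    assert np.allclose(pred, y, atol=1e-8)
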