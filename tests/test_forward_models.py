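"""Signal generators, the Watson convolution, the sphere restriction
coefficient, constrained prior samplers, and the Rician noise model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import spherical_jn
from scipy.stats import chi2_contingency

from dmipost.forward_models import (
    BallStickParams,
    SandiParams,
    StandardModelParams,
    add_rician_noise,
    ball_attenuation,
    ball_stick_signal,
    get_model,
    odi_to_kappa,
    powder_average_stick,
    sample_orientations,
    sample_simplex_fractions,
    sample_sm_diffusivities,
    sandi_signal,
    sphere_Cs,
    sphere_bessel_roots,
    standard_model_signal,
    stick_attenuation,
    watson_convolved_stick,
    zeppelin_attenuation,
)


def _watson_mc_average(g, mean_dir, D, odi, b_smm2, rng, n=200_000):
    """Brute-force oracle: sample Watson orientations by rejection and
    average the stick attenuation."""
    kappa = odi_to_kappa(odi)
    dirs = sample_orientations(4 * n, rng)
    t = dirs @ mean_dir
    keep = rng.uniform(0, 1, dirs.shape[0]) < np.exp(kappa * (t**2 - 1.0))
    dirs = dirs[keep][:n]
    proj2 = (dirs @ g) ** 2
    return np.exp(-b_smm2 * 1e-3 * D * proj2).mean()


class TestElementaryAttenuations:
    def test_stick_limits(self):
        g = np.array([0.6, 0.8, 0.0])
        n = np.array([0.0, 0.0, 1.0])
        assert stick_attenuation(0.0, g, g, 2.0) == pytest.approx(1.0)
        assert stick_attenuation(5000.0, g, n, 2.5) == pytest.approx(1.0)  # g ⟂ n
        # b = 1 ms/µm² (=1000 s·mm⁻²), g ∥ n, D = 2 → exp(−2)
        assert stick_attenuation(1000.0, g, g, 2.0) == pytest.approx(
            np.exp(-2.0), rel=1e-12
        )

    def test_ball_values_and_monotonicity(self):
        assert ball_attenuation(0.0, 1.7) == pytest.approx(1.0)
        assert ball_attenuation(6000.0, 0.1) == pytest.approx(np.exp(-0.6))
        b = np.linspace(0, 6000, 13)
        vals = ball_attenuation(b, 1.2)
        assert np.all(np.diff(vals) < 0)

    def test_zeppelin_limits(self):
        g = np.array([1.0, 0.0, 0.0])
        u = np.array([0.0, 0.0, 1.0])
        # isotropy limit equals the ball
        assert zeppelin_attenuation(3000.0, g, u, 1.5, 1.5) == pytest.approx(
            ball_attenuation(3000.0, 1.5)
        )
        # D_perp = 0 reduces to the stick
        v = np.array([0.6, 0.8, 0.0])
        assert zeppelin_attenuation(2000.0, v, u, 2.0, 0.0) == pytest.approx(
            stick_attenuation(2000.0, v, u, 2.0)
        )
        # perpendicular gradient sees exp(−b·D_perp)
        assert zeppelin_attenuation(2000.0, g, u, 2.0, 0.4) == pytest.approx(
            np.exp(-2.0 * 0.4)
        )
        with pytest.raises(ValueError):
            zeppelin_attenuation(1000.0, g, u, 1.0, 2.0)


class TestWatsonConvolution:
    def test_matches_monte_carlo_oracle(self, rng):
        u = np.array([0.0, 0.0, 1.0])
        g = np.array([np.sin(1.1), 0.0, np.cos(1.1)])
        for odi, b in [(0.1, 2400.0), (0.5, 6000.0), (0.9, 1200.0)]:
            mc = _watson_mc_average(g, u, 2.0, odi, b, rng)
            spectral = watson_convolved_stick(b, g, u, 2.0, odi)
            assert spectral == pytest.approx(mc, abs=5e-3)

    def test_high_dispersion_is_isotropic_average(self, rng):
        """κ→0: the convolved value approaches the isotropic orientation
        average of the stick for any gradient direction."""
        u = np.array([0.0, 0.0, 1.0])
        dirs = sample_orientations(100_000, rng)
        for g in (np.array([1.0, 0, 0]), np.array([0, 0.6, 0.8])):
            iso = np.exp(-6.0 * 2.0 * (dirs @ g) ** 2).mean()
            val = watson_convolved_stick(6000.0, g, u, 2.0, 0.95)
            assert val == pytest.approx(iso, abs=1e-2)

    def test_powder_average_independent_of_mean_dir(self, scheme, rng):
        shell = scheme.shell_index == 6
        g = scheme.directions[shell]
        vals = []
        for _ in range(2):
            u = sample_orientations(1, rng)[0]
            vals.append(
                np.mean([watson_convolved_stick(6000.0, gi, u, 1.5, 0.2)
                         for gi in g])
            )
        assert vals[0] == pytest.approx(vals[1], abs=1e-3)

    def test_quadrature_order_floor(self):
        with pytest.raises(ValueError, match="quadrature"):
            watson_convolved_stick(
                1000.0, np.array([1.0, 0, 0]), np.array([0, 0, 1.0]),
                2.0, 0.2, quadrature_order=4,
            )


class TestSphereRestriction:
    def test_first_root_from_independent_bisection(self):
        """Oracle: the eigencondition is the stationarity of the l=1
        spherical Bessel function, j₁'(x) = 0; bisect it directly."""
        lo, hi = 1.5, 3.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if spherical_jn(1, mid, derivative=True) > 0:
                lo = mid
            else:
                hi = mid
        assert sphere_bessel_roots(10)[0] == pytest.approx(lo, abs=1e-6)
        assert sphere_bessel_roots(10)[0] == pytest.approx(2.0816, abs=1e-4)

    def test_monotone_in_radius(self):
        radii = np.linspace(1, 15, 8)
        cs = [sphere_Cs(r, 3.0, 7.0, 24.0) for r in radii]
        assert np.all(np.diff(cs) > 0)

    def test_root_count_stability(self):
        a = sphere_Cs(8.0, 3.0, 7.0, 24.0, n_roots=50)
        b = sphere_Cs(8.0, 3.0, 7.0, 24.0, n_roots=100)
        assert abs(a / b - 1) < 1e-3

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            sphere_Cs(-1.0, 3.0, 7.0, 24.0)
        with pytest.raises(ValueError):
            sphere_Cs(5.0, 3.0, 24.0, 7.0)
        with pytest.raises(ValueError):
            sphere_Cs(5.0, 3.0, 7.0, 24.0, n_roots=3)


class TestModelSignals:
    def test_ball_stick_limits(self, scheme):
        n = np.array([0.0, 0.0, 1.0])
        pure_ball = BallStickParams(0.0, 1.0, 0.8, n)
        sig = ball_stick_signal(pure_ball, scheme)
        np.testing.assert_allclose(
            sig, ball_attenuation(scheme.b_values, 0.8), atol=1e-12
        )
        any_params = BallStickParams(0.37, 2.1, 0.9, n)
        sig = ball_stick_signal(any_params, scheme)
        np.testing.assert_allclose(sig[scheme.b0_mask], 1.0)
        assert np.all((sig > 0) & (sig <= 1))

    def test_pure_stick_powder_average_closed_form(self, scheme):
        """Direction average of a stick on the 61-direction shells matches
        √(π/(4bD))·erf(√(bD)) within 2%."""
        n = np.array([0.0, 0.0, 1.0])
        sig = ball_stick_signal(BallStickParams(1.0, 2.0, 1.0, n), scheme)
        for lab in (4, 5, 6):
            mask = scheme.shell_index == lab
            b = scheme.b_values[mask].mean()
            da = sig[mask].mean()
            assert da == pytest.approx(powder_average_stick(b, 2.0), rel=0.02)

    def test_standard_model_against_watson_oracle(self, scheme, rng):
        """f=1 reduces to the Watson-dispersed stick; check a few
        measurements against the brute-force Monte-Carlo average."""
        u = sample_orientations(1, rng)[0]
        p = StandardModelParams(1.0, 1.8, 0.3, 2.0, 0.5, u)
        sig = standard_model_signal(p, scheme)
        for i in (40, 120, 250):
            if scheme.shell_index[i] == 0:
                continue
            mc = _watson_mc_average(
                scheme.directions[i], u, 1.8, 0.3, scheme.b_values[i], rng
            )
            assert sig[i] == pytest.approx(mc, abs=7e-3)

    def test_standard_model_isotropic_extra_limit(self, scheme):
        """f=0 with D_e∥=D_e⊥ collapses to the isotropic ball whatever the
        dispersion."""
        u = np.array([0.0, 0.0, 1.0])
        p = StandardModelParams(0.0, 1.0, 0.5, 1.2, 1.2, u)
        sig = standard_model_signal(p, scheme)
        np.testing.assert_allclose(
            sig, ball_attenuation(scheme.b_values, 1.2), atol=1e-6
        )

    def test_joint_rotation_invariance(self, scheme, rng):
        """Rotating gradients and tissue orientation together leaves the
        signal unchanged."""
        from scipy.spatial.transform import Rotation

        import dataclasses as dc

        R = Rotation.random(random_state=7).as_matrix()
        rot = dc.replace  # keep the frozen dataclass immutable
        scheme_rot = type(scheme)(
            scheme.b_values, scheme.directions @ R.T,
            scheme.delta_small, scheme.delta_big, scheme.shell_index,
        )
        u = sample_orientations(1, rng)[0]
        p = StandardModelParams(0.6, 1.8, 0.25, 2.2, 0.7, u)
        p_rot = StandardModelParams(0.6, 1.8, 0.25, 2.2, 0.7, R @ u)
        sig = standard_model_signal(p, scheme)
        sig_rot = standard_model_signal(p_rot, scheme_rot)
        np.testing.assert_allclose(sig, sig_rot, atol=1e-6)

    def test_sandi_limits(self, scheme):
        u = np.array([0.0, 0.0, 1.0])
        sticks_only = SandiParams(1.0, 0.0, 0.0, 1.5, 0.3, 1.0, 100.0, u)
        spheres_only = SandiParams(0.0, 1.0, 0.0, 1.5, 0.3, 1.0, 100.0, u)
        s1 = sandi_signal(sticks_only, scheme)
        np.testing.assert_allclose(s1[scheme.b0_mask], 1.0, atol=1e-9)
        # sphere attenuation decreases with C_s at fixed b
        lows = sandi_signal(
            SandiParams(0.0, 1.0, 0.0, 1.5, 0.3, 1.0, 10.0, u), scheme
        )
        highs = sandi_signal(
            SandiParams(0.0, 1.0, 0.0, 1.5, 0.3, 1.0, 800.0, u), scheme
        )
        dw = scheme.dw_mask
        assert np.all(highs[dw] < lows[dw])
        s2 = sandi_signal(spheres_only, scheme)
        assert np.all((s2 > 0) & (s2 <= 1))

    def test_noise_free_signals_in_unit_interval(self, scheme, rng):
        for name in ("ball_stick", "standard_model", "extended_sandi"):
            model = get_model(name)
            theta = model.sample_prior(50, rng)
            dirs = sample_orientations(50, rng)
            sig = model.signal(theta, dirs, scheme)
            assert np.all(sig > 0) and np.all(sig <= 1 + 1e-9)
            np.testing.assert_allclose(sig[:, scheme.b0_mask], 1.0, atol=1e-7)


class TestConstrainedSamplers:
    def test_sm_diffusivity_corners(self):
        assert sample_sm_diffusivities(1.0, 1.0) == pytest.approx((3.0, 3.0))
        dpar, dperp = sample_sm_diffusivities(0.0, 0.7)
        assert (dpar, dperp) == pytest.approx((0.1, 0.1))

    def test_sm_diffusivities_uniform_on_triangle(self, rng):
        """χ² against a rejection-sampling oracle that draws uniformly on
        the bounding square and keeps the triangle D_e⊥ ≤ D_e∥."""
        n = 100_000
        dpar, dperp = sample_sm_diffusivities(
            rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        )
        a = rng.uniform(0.1, 3.0, 3 * n)
        b = rng.uniform(0.1, 3.0, 3 * n)
        keep = b <= a
        ref_par, ref_perp = a[keep][:n], b[keep][:n]
        bins = np.linspace(0.1, 3.0, 11)
        h1, *_ = np.histogram2d(dpar, dperp, bins=(bins, bins))
        h2, *_ = np.histogram2d(ref_par, ref_perp, bins=(bins, bins))
        cells = (h1 + h2) > 10
        table = np.stack([h1[cells], h2[cells]])
        _, pvalue, *_ = chi2_contingency(table)
        assert pvalue > 0.01
        assert np.all(dperp <= dpar + 1e-12)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_simplex_fractions_sum_to_one(self, k1, k2):
        fn, fs, fe = sample_simplex_fractions(k1, k2)
        assert fn + fs + fe == pytest.approx(1.0, abs=1e-12)
        assert min(fn, fs, fe) >= 0

    def test_simplex_corners(self):
        assert sample_simplex_fractions(1.0, 1.0) == pytest.approx((1.0, 0.0, 0.0))
        assert sample_simplex_fractions(0.0, 0.3)[2] == pytest.approx(1.0)

    def test_prior_draws_within_bounds_and_deterministic(self):
        for name in ("ball_stick", "standard_model", "extended_sandi"):
            model = get_model(name)
            t1 = model.sample_prior(10_000, np.random.default_rng(4))
            t2 = model.sample_prior(10_000, np.random.default_rng(4))
            np.testing.assert_array_equal(t1, t2)
            assert model.satisfies_constraints(t1).all()

    def test_unconstrained_prior_means(self, rng):
        model = get_model("ball_stick")
        t = model.sample_prior(10_000, rng)
        for j in range(3):
            lo, hi = model.prior.lower[j], model.prior.upper[j]
            se = (hi - lo) / np.sqrt(12 * t.shape[0])
            assert abs(t[:, j].mean() - (lo + hi) / 2) < 3 * se


class TestRicianNoise:
    def test_infinite_snr_identity(self, rng):
        s = rng.uniform(0, 1, 100)
        np.testing.assert_array_equal(add_rician_noise(s, np.inf, rng), s)

    def test_second_moment_analytic(self, rng):
        """E[x²] = s² + 2σ² for the Rician magnitude."""
        s, snr = 0.5, 50.0
        n = 100_000
        x = add_rician_noise(np.full(n, s), snr, rng)
        m2 = (x**2).mean()
        expected = s**2 + 2 / snr**2
        se = (x**2).std() / np.sqrt(n)
        assert abs(m2 - expected) < 3 * se
        assert np.all(x > 0)

    def test_invalid_snr(self, rng):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), 0.0, rng)
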