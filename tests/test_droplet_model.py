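"""Reduced single-droplet model: profiles, radius ODE, fixed points,
critical switching ratio, passive growth."""

import numpy as np
import pytest

from pyrecond.droplet_model import (
    DropletParams,
    critical_ratio,
    fixed_points,
    flux_scaling_exponents,
    interface_fluxes,
    k_drop_from_k_tilde,
    k_tilde_from_k_drop,
    passive_growth,
    passive_growth_ode,
    profiles,
    radius_rate,
)

P = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=0.3)


class TestProfiles:
    @pytest.mark.parametrize("geometry", ["3d", "2d"])
    def test_interface_values_imposed(self, geometry):
        p = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=0.3,
                          geometry=geometry)
        phi_in, phi_out = profiles(2.0, p)
        assert phi_in(2.0) == pytest.approx(0.9, rel=1e-12)
        assert phi_out(2.0) == pytest.approx(0.01, rel=1e-12)

    def test_far_field_is_switching_balance(self):
        phi_in, phi_out = profiles(2.0, P)
        assert phi_out(1e4) == pytest.approx(0.3 / 1.3, rel=1e-6)

    def test_regular_at_origin(self):
        phi_in, _ = profiles(2.0, P)
        assert np.isfinite(phi_in(0.0))
        # even function: flat at r=0
        assert phi_in(1e-6) == pytest.approx(float(phi_in(0.0)), rel=1e-9)

    @pytest.mark.parametrize("geometry", ["3d", "2d"])
    def test_screened_diffusion_residual(self, geometry):
        # plug-back oracle: lap(phi) - phi + k(1-phi) = 0 along the profile
        p = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=0.3,
                          geometry=geometry)
        R = 1.7
        phi_in, phi_out = profiles(R, p)
        d = 1e-4
        dim = 2.0 if geometry == "3d" else 1.0
        for phi, rr in ((phi_in, np.linspace(0.2, R, 12)),
                        (phi_out, np.linspace(R, 6 * R, 12))):
            f0, fp_, fm = phi(rr), phi(rr + d), phi(rr - d)
            lap = (fp_ - 2 * f0 + fm) / d**2 + dim / rr * (fp_ - fm) / (2 * d)
            residual = lap - f0 + p.k_drop * (1 - f0)
            assert np.abs(residual).max() < 1e-5

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            profiles(-1.0, P)


class TestRadiusRate:
    def test_degenerate_phases_raise(self):
        p = DropletParams(phi_plus=0.5, phi_minus=0.0, k_drop=0.1)
        object.__setattr__(p, "phi_minus", 0.5)  # bypass ctor check
        with pytest.raises(ZeroDivisionError):
            radius_rate(1.0, p)

    @pytest.mark.parametrize("geometry", ["3d", "2d"])
    @pytest.mark.parametrize("R", [0.3, 1.0, 4.0])
    def test_matches_numerical_profile_derivatives(self, geometry, R):
        # independent oracle: differentiate the profiles numerically at R
        p = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=0.3,
                          geometry=geometry)
        phi_in, phi_out = profiles(R, p)
        d = 1e-5
        slope_in = (phi_in(R + d) - phi_in(R - d)) / (2 * d)
        slope_out = (phi_out(R + d) - phi_out(R - d)) / (2 * d)
        expected = (slope_out - slope_in) / (p.phi_plus - p.phi_minus)
        assert radius_rate(R, p) == pytest.approx(float(expected), rel=1e-6)

    def test_large_droplet_growth_above_critical(self):
        # above k_c the rate tends to a positive constant at large R
        kc = critical_ratio(0.9, 0.01)
        p = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=2.0 * kc)
        r1, r2 = radius_rate(1e5, p), radius_rate(1e6, p)
        assert r1 > 0 and r2 > 0
        assert r1 == pytest.approx(r2, rel=1e-3)


class TestFixedPoints:
    def test_below_critical_has_one_stable_point(self):
        kc = critical_ratio(0.9, 0.01)
        p = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=0.1 * kc)
        fp = fixed_points(p)
        stable = [r for r, s in fp.fixed_points if s == "stable"]
        assert len(stable) == 1
        assert fp.regime == "size_controlled"
        # root property
        assert abs(radius_rate(stable[0], p)) < 1e-8

    def test_above_critical_grows_unbounded(self):
        kc = critical_ratio(0.9, 0.01)
        p = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=1.5 * kc)
        fp = fixed_points(p)
        assert fp.stable_radius is None
        assert fp.regime == "unbounded_growth"

    def test_flux_balance_at_fixed_point(self):
        # J_in = J_out at the equilibrium radius, from the profiles
        p = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=0.3)
        req = fixed_points(p).stable_radius
        jin, jout = interface_fluxes(req, p)
        assert jin == pytest.approx(jout, abs=1e-8 * max(1.0, abs(jout)))


class TestCriticalRatio:
    def test_closed_form_value(self):
        assert critical_ratio(0.9, 0.01) == pytest.approx(0.91 / 1.09, rel=1e-12)

    def test_dense_limit_diverges(self):
        assert critical_ratio(0.999, 0.999) > 1e2

    def test_numeric_agrees_with_closed_form(self):
        cf = critical_ratio(0.9, 0.01, method="closed_form")
        num = critical_ratio(0.9, 0.01, method="numeric")
        assert abs(cf - num) / num < 0.10

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            critical_ratio(0.9, 0.01, method="magic")


class TestFluxScaling:
    def test_inner_flux_scales_as_volume_at_small_radius(self):
        # conversion inside the droplet is a volume term: exponent ~ 3
        p = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=0.3)
        e_in, _ = flux_scaling_exponents(p, r_window=(0.05, 0.3))
        assert 2.7 <= e_in <= 3.3

    def test_outer_flux_scales_as_surface_when_screened(self):
        # the outer supply flux ~ beta R^2 + R: surface scaling holds for
        # beta*R >> 1
        p = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=0.5)
        _, e_out = flux_scaling_exponents(p, r_window=(2.0, 20.0))
        assert 1.7 <= e_out <= 2.3


class TestPassiveGrowth:
    PASSIVE = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=0.0,
                            phi_inf=0.05)

    def test_zero_supersaturation_is_static(self):
        p = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=0.0,
                          phi_inf=0.01)
        t = np.linspace(0, 10, 5)
        assert np.allclose(passive_growth(2.0, p, t), 2.0)

    def test_growth_law_slope_linear_in_supersaturation(self):
        t = np.array([0.0, 5.0, 10.0])
        r1 = passive_growth(2.0, self.PASSIVE, t)
        p2 = DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=0.0,
                           phi_inf=0.09)
        r2 = passive_growth(2.0, p2, t)
        s1 = (r1[-1] ** 2 - 4.0) / 10.0
        s2 = (r2[-1] ** 2 - 4.0) / 10.0
        ratio = (0.09 - 0.01) / (0.05 - 0.01)
        assert s2 / s1 == pytest.approx(ratio, rel=1e-9)

    def test_matches_ode_integration(self):
        t = np.linspace(0.1, 20.0, 30)
        closed = passive_growth(1.5, self.PASSIVE, t)
        ode = passive_growth_ode(1.5, self.PASSIVE, t)
        assert np.max(np.abs(closed - ode) / closed) < 1e-2

    def test_undersaturated_droplet_shrinks_to_zero(self):
        p = DropletParams(phi_plus=0.9, phi_minus=0.05, k_drop=0.0,
                          phi_inf=0.01)
        r = passive_growth(1.0, p, np.linspace(0, 100, 20))
        assert r[-1] == 0.0
        assert np.all(np.diff(r) <= 0)

    def test_requires_passive_parameters(self):
        with pytest.raises(ValueError):
            passive_growth(1.0, P, 1.0)


class TestConventions:
    def test_switching_ratio_converters_are_reciprocal(self):
        assert k_drop_from_k_tilde(0.14) == pytest.approx(1 / 0.14)
        assert k_tilde_from_k_drop(k_drop_from_k_tilde(0.37)) == pytest.approx(0.37)
        with pytest.raises(ValueError):
            k_drop_from_k_tilde(0.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            DropletParams(phi_plus=0.1, phi_minus=0.5, k_drop=0.1)
        with pytest.raises(ValueError):
            DropletParams(phi_plus=0.9, phi_minus=0.01, k_drop=-1.0)


class TestCrossModelConsistency:
    """The reduced model and the full phase-field simulation agree on the
    existence of a finite preferred size; quantitatively the reduced model
    underestimates the equilibrium radius (it converts the whole bath at
    the phosphatase rate and ignores the phosphorylated pool accumulating
    inside the condensate), so only order-of-magnitude agreement holds."""

    def test_pde_equilibrium_radius_vs_reduced_model(self):
        import numpy as np

        from pyrecond import KinaseProtocol, PRESETS, make_periodic_square, run
        from pyrecond import quantify
        from pyrecond.simulator import StepperOptions
        from pyrecond.synthetic_data import DropletSpec, place_droplets

        p = PRESETS["default"]
        geo = make_periodic_square(48.0, 96)
        spec = DropletSpec(droplets=[((0.0, 0.0), 6.0)], phi_plus=0.99,
                           phi_minus=0.006, interface_width=1.0)
        st = place_droplets(spec, geo, p)
        traj = run(st, p, geo, KinaseProtocol.constant(0.14), t_end=300.0,
                   cadence=100.0, options=StepperOptions(dphi_target=4e-3))
        f = traj.final
        total = f.phi_s + f.phi_ns
        tab = quantify.detect(total, threshold=0.5, periodic=True,
                              grid_spacing=geo.h)
        assert len(tab) == 1
        r_pde = float(tab["equivalent_radius"].iloc[0])
        dilute = total < 0.1
        phi_plus = float(f.phi_s.max())
        phi_minus = float(f.phi_s[dilute].min())
        phi_ns_far = float(np.median(f.phi_ns[dilute]))
        k_drop = phi_ns_far / p.k_tilde
        dp = DropletParams(phi_plus=phi_plus, phi_minus=phi_minus,
                           k_drop=k_drop, geometry="2d")
        fp = fixed_points(dp, (1e-3, 1e3))
        assert fp.regime == "size_controlled"
        ell = np.sqrt(p.D_tilde / p.k_tilde)   # reduced-model length unit
        r_model = fp.stable_radius * ell
        assert 0.2 < r_model / r_pde < 5.0
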