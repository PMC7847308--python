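"""Dipole-emission physics: reflection coefficients and power integrals."""

import numpy as np
import pytest

from gietkit import (
    OpticalLayer,
    OpticalStack,
    default_stack,
    relative_emission_power,
    stack_reflection,
)

WATER, GLASS, LIPID = 1.33, 1.52, 1.44
GRAPHENE_520 = 2.68 + 1.21j


def water_glass_stack():
    return OpticalStack(
        (OpticalLayer("glass", GLASS), OpticalLayer("water", WATER)), 518.0
    )


def homogeneous_stack(wavelength=518.0):
    return OpticalStack(
        (
            OpticalLayer("w1", WATER),
            OpticalLayer("w2", WATER, 2.5),
            OpticalLayer("w3", WATER),
        ),
        wavelength,
    )


# --------------------------------------------------------------------------
# independent oracle: direct recursion over interfaces, written separately
# from the package implementation (top-down continued-fraction form)

def oracle_reflection(indices, thicknesses, wavelength, u, pol):
    """indices/thicknesses ordered from the emitter's medium downward."""
    k0 = 2 * np.pi / wavelength
    kpar = u * indices[0].real * k0

    def kz(n):
        return np.sqrt(complex(n * n * k0 * k0 - kpar * kpar))

    def r_single(n1, n2):
        k1, k2 = kz(n1), kz(n2)
        if pol == "s":
            return (k1 - k2) / (k1 + k2)
        return (n2 * n2 * k1 - n1 * n1 * k2) / (n2 * n2 * k1 + n1 * n1 * k2)

    r = r_single(indices[-2], indices[-1])
    for i in range(len(indices) - 3, -1, -1):
        phase = np.exp(2j * kz(indices[i + 1]) * thicknesses[i + 1])
        rij = r_single(indices[i], indices[i + 1])
        r = (rij + r * phase) / (1 + rij * r * phase)
    return r


class TestStackReflection:
    def test_no_index_contrast_reflects_nothing(self):
        stack = homogeneous_stack()
        for pol in ("s", "p"):
            for u in (0.0, 0.5, 1.3, 4.0):
                assert stack_reflection(stack, pol, u) == pytest.approx(0.0, abs=1e-12)

    def test_normal_incidence_matches_fresnel(self):
        # water -> glass at u = 0: r_s = (n1 - n2) / (n1 + n2)
        r = stack_reflection(water_glass_stack(), "s", 0.0)
        assert r.real == pytest.approx((WATER - GLASS) / (WATER + GLASS), abs=1e-12)
        assert r.imag == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("pol", ["s", "p"])
    @pytest.mark.parametrize("u", [0.0, 0.5, 0.99, 1.05, 1.2, 3.0])
    def test_full_stack_matches_independent_recursion(self, pol, u):
        stack = default_stack("FAM")
        expected = oracle_reflection(
            [WATER, LIPID, GRAPHENE_520, GLASS], [None, 2.5, 0.34, None], 518.0, u, pol
        )
        got = stack_reflection(stack, pol, u)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_rejects_negative_u_and_bad_polarization(self):
        stack = water_glass_stack()
        with pytest.raises(ValueError):
            stack_reflection(stack, "s", -0.1)
        with pytest.raises(ValueError):
            stack_reflection(stack, "x", 0.5)

    def test_vectorized_over_u(self):
        stack = default_stack("FAM")
        u = np.array([0.0, 0.5, 1.5])
        r = stack_reflection(stack, "p", u)
        assert r.shape == (3,)
        assert r[1] == pytest.approx(stack_reflection(stack, "p", 0.5), abs=1e-14)


class TestRelativeEmissionPower:
    def test_homogeneous_medium_identity(self):
        stack = homogeneous_stack()
        for orientation in ("perpendicular", "parallel", "isotropic_average"):
            for z in (3.0, 10.0, 50.0):
                s = relative_emission_power(stack, z, orientation)
                assert s == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("fluor", ["FAM", "EGFP", "mNeonGreen", "Dy647P1"])
    def test_far_field_limit(self, fluor):
        s = relative_emission_power(default_stack(fluor), 1000.0)
        assert abs(s - 1.0) < 0.02

    def test_isotropic_is_orientation_average(self):
        stack = default_stack("FAM")
        sp = relative_emission_power(stack, 5.0, "perpendicular")
        sl = relative_emission_power(stack, 5.0, "parallel")
        si = relative_emission_power(stack, 5.0, "isotropic_average")
        assert si == pytest.approx((sp + 2 * sl) / 3, rel=1e-12)

    @pytest.mark.parametrize("z", [3.0, 5.0, 10.0, 20.0])
    def test_matches_brute_force_quadrature(self, z):
        """Adaptive scheme vs fixed 1e6-node trapezoid on the u-grid."""
        stack = default_stack("FAM")
        k1 = WATER * stack.k0
        # u_max chosen so the integrand tail is < 1e-10: the absorber sits
        # below z + 2.84 nm of transparent material, giving exp damping
        depth = z + stack.finite_thickness_nm
        x_max = 30.0 / (2 * k1 * depth)
        n_nodes = 1_000_000

        # propagating: u in [0, 1) via sin substitution on a uniform grid
        th = np.linspace(0.0, np.pi / 2, n_nodes)
        s, c = np.sin(th), np.cos(th)
        rp = stack_reflection(stack, "p", s)
        rs = stack_reflection(stack, "s", s)
        ph = np.exp(2j * k1 * z * c)
        perp_prop = np.trapezoid(s**3 * np.real(rp * ph), th)
        par_prop = np.trapezoid(s * np.real((rs - c * c * rp) * ph), th)

        # evanescent: x = sqrt(u^2 - 1) substitution on a uniform grid
        x = np.linspace(0.0, x_max, n_nodes)
        u = np.sqrt(1 + x * x)
        rp = stack_reflection(stack, "p", u)
        rs = stack_reflection(stack, "s", u)
        damp = np.exp(-2 * k1 * z * x)
        perp_evan = np.trapezoid((1 + x * x) * np.imag(rp) * damp, x)
        par_evan = np.trapezoid(np.imag(rs + x * x * rp) * damp, x)

        s_perp = 1 + 1.5 * (perp_prop + perp_evan)
        s_par = 1 + 0.75 * (par_prop + par_evan)
        brute = (s_perp + 2 * s_par) / 3

        adaptive = relative_emission_power(stack, z)
        assert adaptive == pytest.approx(brute, rel=1e-5)

    def test_rejects_nonpositive_height(self):
        stack = default_stack("FAM")
        with pytest.raises(ValueError):
            relative_emission_power(stack, 0.0)
        with pytest.raises(ValueError):
            relative_emission_power(stack, -1.0)


class TestStackValidation:
    def test_interior_layers_need_thickness(self):
        with pytest.raises(ValueError):
            OpticalStack(
                (
                    OpticalLayer("glass", GLASS),
                    OpticalLayer("film", 1.4),  # missing thickness
                    OpticalLayer("water", WATER),
                ),
                518.0,
            )

    def test_halfspaces_required_at_both_ends(self):
        with pytest.raises(ValueError):
            OpticalStack(
                (OpticalLayer("glass", GLASS, 10.0), OpticalLayer("water", WATER)),
                518.0,
            )

    def test_absorbing_index_must_have_nonnegative_imag(self):
        with pytest.raises(ValueError):
            OpticalLayer("bad", 1.5 - 0.2j, 1.0)
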