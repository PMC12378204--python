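"""Thermodynamic core: compositions, free energy, potentials, kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ladkit.model import (CompositionField, ModelParams,
                          bulk_free_energy_density, chemical_potentials,
                          composite_rate, composition_from_state,
                          lamina_energy_density, reaction_rate,
                          total_free_energy)
from ladkit.model import CompositionDomainError, GeometryError


class TestComposition:
    @pytest.mark.parametrize("phi_n,phi_d,expected", [
        (1.0, 0.0, (0.0, 0.0)),      # pure nucleoplasm
        (0.4, 0.2, (0.4, 0.2)),      # direct substitution
        (0.0, 1.0, (1.0, 0.0)),      # pure heterochromatin
        (0.0, -1.0, (0.0, 1.0)),     # pure euchromatin
    ])
    def test_examples(self, phi_n, phi_d, expected):
        phi_h, phi_e = composition_from_state(phi_n, phi_d)
        assert phi_h == pytest.approx(expected[0])
        assert phi_e == pytest.approx(expected[1])
        assert phi_h + phi_e + phi_n == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(CompositionDomainError):
            composition_from_state(0.5, 0.8)

    @given(phi_n=st.floats(0, 1), frac=st.floats(-1, 1))
    @settings(max_examples=50, deadline=None)
    def test_simplex_closure(self, phi_n, frac):
        phi_d = frac * (1 - phi_n)
        phi_h, phi_e = composition_from_state(phi_n, phi_d)
        assert phi_h >= -1e-12 and phi_e >= -1e-12
        assert phi_h + phi_e + phi_n == pytest.approx(1.0)


class TestBulkEnergy:
    def test_wells_are_zero(self, params):
        assert bulk_free_energy_density(0.0, 0.0, params) == 0.0
        assert bulk_free_energy_density(params.phi_h0, 0.0, params) == 0.0

    def test_midpoint_value(self):
        p = ModelParams(c=2.0, phi_h0=1.0)
        # (c/2) * phi_h^2 (1 - phi_h)^2 = 1 * 0.25 * 0.25
        assert bulk_free_energy_density(0.5, 0.0, p) == pytest.approx(0.0625)

    def test_exactly_two_zeros_on_simplex(self, params):
        """Grid search at 1e-3 resolution: zeros only at the two wells."""
        phi_h = np.arange(0, 1.0001, 1e-3)
        f = bulk_free_energy_density(phi_h, 0.0, params)
        zero_h = phi_h[f < 1e-15]
        assert np.all((np.abs(zero_h) < 2e-3)
                      | (np.abs(zero_h - params.phi_h0) < 2e-3))
        # nonzero euchromatin is never a well
        f2 = bulk_free_energy_density(phi_h[None, :],
                                      np.arange(1e-3, 0.2, 1e-3)[:, None],
                                      params)
        assert np.all(f2 > 0)


class TestLaminaEnergy:
    def test_decay_limit(self, params):
        p = params.with_(V_HC=1.0)
        val = lamina_energy_density(p.phi_h0, 1e5, p)
        assert abs(val) < 1e-12

    def test_contact_value(self):
        p = ModelParams(V_HC=1.0, d0=2.5)
        assert lamina_energy_density(p.phi_h0, 0.0, p) == pytest.approx(-0.4)

    def test_zero_euchromatin_affinity(self):
        p = ModelParams(V_EC=0.0, V_HC=1.0, d0=2.5)
        assert lamina_energy_density(0.0, 0.0, p) == pytest.approx(0.0)

    def test_monotone_in_distance(self, params):
        p = params.with_(V_HC=2.0)
        d = np.linspace(0, 100, 50)
        mag = np.abs(lamina_energy_density(p.phi_h0, d, p))
        assert np.all(np.diff(mag) <= 0)

    def test_negative_distance_rejected(self, params):
        with pytest.raises(GeometryError):
            lamina_energy_density(0.5, -1.0, params)


def brute_force_energy(fieldc, geom, params):
    """Independent term-by-term re-implementation of the energy integral."""
    h = fieldc.h
    m = fieldc.mask
    phi_h, phi_e = fieldc.phi_h, fieldc.phi_e
    total = 0.0
    ny, nx = m.shape
    for i in range(ny):
        for j in range(nx):
            if not m[i, j]:
                continue
            fh, fe = phi_h[i, j], phi_e[i, j]
            e = 0.5 * params.c * (fe ** 2 + fh ** 2 * (params.phi_h0 - fh) ** 2)
            for arr in (fieldc.phi_n, fieldc.phi_d):
                for (di, dj) in ((1, 0), (0, 1)):
                    ip, jp = i + di, j + dj
                    up = arr[ip, jp] if (0 <= ip < ny and 0 <= jp < nx
                                         and m[ip, jp]) else arr[i, j]
                    e += 0.5 * params.kappa * ((up - arr[i, j]) / h) ** 2
            e += -(params.V(fh) / params.d0) * np.exp(
                -geom.distance[i, j] / params.d0)
            total += e * h * h
    return total


class TestTotalEnergy:
    def test_uniform_field_is_bulk_times_area(self, small_geom, params):
        phi_n = np.full(small_geom.mask.shape, 0.4)
        phi_d = np.full(small_geom.mask.shape, 0.1)
        f = CompositionField(10.0, phi_n, phi_d, small_geom.mask)
        e = total_free_energy(f, small_geom, params)
        expected = bulk_free_energy_density(0.35, 0.25, params) * \
            small_geom.area
        # no lamina (V=0 default) and no gradients
        assert e == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force(self, small_geom, random_field):
        p = ModelParams(c=8e-3, kappa=0.8, phi_h0=0.8, V_HC=0.05, d0=25.0)
        e = total_free_energy(random_field, small_geom, p)
        e_ref = brute_force_energy(random_field, small_geom, p)
        assert e == pytest.approx(e_ref, rel=1e-10)

    def test_gradient_energy_nonnegative(self, small_geom, random_field,
                                         params):
        e_full = total_free_energy(random_field, small_geom, params)
        flat = CompositionField(
            random_field.h,
            np.full_like(random_field.phi_n,
                         random_field.phi_n[small_geom.mask].mean()),
            np.full_like(random_field.phi_d,
                         random_field.phi_d[small_geom.mask].mean()),
            small_geom.mask)
        # removing all gradients at matched mean composition can only help
        # the interfacial term; check the interfacial part directly instead
        p0 = params
        e_grad = e_full - brute_force_energy(flat, small_geom, p0) \
            if False else None
        # direct check: kappa term is a sum of squares
        from ladkit.model import _masked_gradient_sq
        g = _masked_gradient_sq(random_field.phi_d, small_geom.mask, 10.0)
        assert np.all(g >= 0)


class TestChemicalPotentials:
    def test_uniform_field_matches_analytic(self, small_geom):
        """Spatially constant mu equal to the analytic bulk partials."""
        p = ModelParams(c=8e-3, kappa=0.8, phi_h0=0.8)
        phi_n0, phi_d0 = 0.4, 0.1
        f = CompositionField(10.0, np.full((16, 16), phi_n0),
                             np.full((16, 16), phi_d0), small_geom.mask)
        pot = chemical_potentials(f, small_geom, p)
        # symbolic partials of (c/2)[phi_e^2 + phi_h^2(phi_h0-phi_h)^2]
        # with phi_h=(1-n+d)/2, phi_e=(1-n-d)/2
        import sympy as sp
        n, d = sp.symbols("n d")
        ph = (1 - n + d) / 2
        pe = (1 - n - d) / 2
        fb = sp.Rational(1, 2) * p.c * (pe ** 2 + ph ** 2 *
                                        (p.phi_h0 - ph) ** 2)
        mun = float(sp.diff(fb, n).subs({n: phi_n0, d: phi_d0}))
        mud = float(sp.diff(fb, d).subs({n: phi_n0, d: phi_d0}))
        inner = small_geom.mask.copy()
        assert pot.mu_n[inner] == pytest.approx(mun, rel=1e-9)
        assert pot.mu_d[inner] == pytest.approx(mud, rel=1e-9)

    def test_variational_consistency(self, small_geom, random_field):
        """Perturbing one site changes the energy by mu * delta * h^2."""
        p = ModelParams(c=8e-3, kappa=0.8, phi_h0=0.8, V_HC=0.05, d0=25.0)
        pot = chemical_potentials(random_field, small_geom, p)
        rng = np.random.default_rng(0)
        delta = 1e-6
        h2 = random_field.h ** 2
        for _ in range(6):
            i, j = rng.integers(1, 15, 2)
            for name, arr, mu in (("phi_n", random_field.phi_n, pot.mu_n),
                                  ("phi_d", random_field.phi_d, pot.mu_d)):
                up = random_field.copy()
                dn = random_field.copy()
                getattr(up, name)[i, j] += delta
                getattr(dn, name)[i, j] -= delta
                de = (total_free_energy(up, small_geom, p)
                      - total_free_energy(dn, small_geom, p)) / (2 * delta)
                assert de == pytest.approx(mu[i, j] * h2, rel=1e-4, abs=1e-12)

    def test_bulk_stationary_at_well(self, small_geom):
        p = ModelParams(c=8e-3, kappa=0.8, phi_h0=0.8)
        # heterochromatic well: phi_h = phi_h0, phi_e = 0
        phi_n0 = 1 - p.phi_h0
        phi_d0 = p.phi_h0
        f = CompositionField(10.0, np.full((16, 16), phi_n0),
                             np.full((16, 16), phi_d0), small_geom.mask)
        pot = chemical_potentials(f, small_geom, p)
        assert np.allclose(pot.mu_d[small_geom.mask], 0.0, atol=1e-15)


class TestReactionRate:
    @pytest.mark.parametrize("phi_h,phi_e,gme,gac,expected", [
        (0.3, 0.3, 1.0, 1.0, 0.0),
        (0.0, 0.3, 1.0, 5.0, 0.6),
        (0.2, 0.0, 7.0, 1.0, -0.4),
    ])
    def test_examples(self, phi_h, phi_e, gme, gac, expected):
        assert reaction_rate(phi_h, phi_e, gme, gac) == pytest.approx(expected)

    def test_zero_iff_ratio_matches(self):
        assert reaction_rate(0.6, 0.2, 3.0, 1.0) == pytest.approx(0.0)
        assert reaction_rate(0.6, 0.2, 2.9, 1.0) != 0.0


class TestCompositeRate:
    @pytest.mark.parametrize("a,b,expected", [
        (1.0, 1.0, 0.5), (2.0, 2.0, 1.0), (np.inf, 3.0, 3.0)])
    def test_examples(self, a, b, expected):
        assert composite_rate(a, b) == pytest.approx(expected)

    @given(a=st.floats(1e-6, 1e6), b=st.floats(1e-6, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        r = composite_rate(a, b)
        assert r == pytest.approx(composite_rate(b, a))
        assert r <= min(a, b) + 1e-12

    @given(a=st.floats(1e-3, 1e3), b=st.floats(1e-3, 1e3),
           da=st.floats(1e-3, 1e2))
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, a, b, da):
        assert composite_rate(a + da, b) >= composite_rate(a, b) - 1e-12

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            composite_rate(0.0, 0.0)


class TestModelParams:
    def test_derived_quantities(self):
        p = ModelParams(c=8e-3, kappa=0.8, V_EC=0.1, V_HC=0.5)
        assert p.l_int == pytest.approx(10.0)
        assert p.V_LAD == pytest.approx(0.4)

    def test_composite_rates_from_components(self):
        p = ModelParams(Gamma_HDAC=2.0, Gamma_HMT=2.0)
        assert p.Gamma_me == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [dict(c=0), dict(kappa=-1),
                                     dict(phi_h0=0), dict(phi_h0=1.5),
                                     dict(d0=0)])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)
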