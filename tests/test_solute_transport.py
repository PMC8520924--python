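"""Finite-volume transport vs. analytic steady states and conservation."""

import numpy as np
import pytest

from lymphchip.device_model import PorousLayer, ValidationError, default_config
from lymphchip.solute_transport import (
    BoundaryCondition,
    advection_diffusion_profile,
    build_domain,
    extract_line_profile,
    secretion_under_flow,
    simulate,
    steady_state,
    steady_two_layer_analytic,
)

D_GEL = 6.5e-11
L_GEL = 2e-3
GEL = PorousLayer("COL1", L_GEL, 1.04e-13, {"default": D_GEL})


@pytest.fixture(scope="module")
def gel_domain():
    return build_domain(layers=[GEL], n_cells=400)


@pytest.fixture(scope="module")
def two_layer_domain():
    cfg = default_config()
    return build_domain(cfg.geometry, cfg.layers, cfg.solutes[0], n_cells=400)


class TestBuildDomain:
    def test_default_domain_spans_gel_with_membrane(self, two_layer_domain):
        assert two_layer_domain.length == pytest.approx(L_GEL)
        assert len(two_layer_domain.membrane_faces) == 1
        face, pm = two_layer_domain.membrane_faces[0]
        assert face == two_layer_domain.n_cells  # endothelium at the sink face
        assert pm == 1e-8

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValidationError):
            build_domain(layers=[GEL], n_cells=5)

    def test_refining_grid_keeps_interfaces(self):
        cfg = default_config()
        d1 = build_domain(cfg.geometry, cfg.layers, cfg.solutes[0], n_cells=100)
        d2 = build_domain(cfg.geometry, cfg.layers, cfg.solutes[0], n_cells=200)
        assert d1.interfaces == d2.interfaces

    def test_membrane_first_rejected(self):
        memb = PorousLayer("m", 10e-6, 1e-16, solute_permeability=1e-8)
        with pytest.raises(ValidationError, match="membrane"):
            build_domain(layers=[memb, GEL], n_cells=50)


class TestSteadyOracles:
    def test_pure_diffusion_linear_midpoint(self, gel_domain):
        ss = steady_state(gel_domain, velocity=0.0)
        mid = np.interp(L_GEL / 2, ss.x, ss.concentration[0])
        assert mid == pytest.approx(0.5, abs=1e-10)

    @pytest.mark.parametrize("pe", [1.0, 3.0, 15.0])
    def test_exponential_profile(self, gel_domain, pe):
        v = pe * D_GEL / L_GEL
        ss = steady_state(gel_domain, velocity=v)
        analytic = advection_diffusion_profile(gel_domain.x, L_GEL, pe)
        assert np.max(np.abs(ss.concentration[0] - analytic)) <= 5e-3

    def test_convective_flat_gradient_at_pe15(self, gel_domain):
        v = 15.0 * D_GEL / L_GEL
        ss = steady_state(gel_domain, velocity=v)
        mid = np.interp(L_GEL / 2, ss.x, ss.concentration[0])
        assert mid == pytest.approx(0.9994, abs=5e-4)
        assert mid > 0.99

    def test_two_layer_profile_and_drop_fraction(self, two_layer_domain):
        ss = steady_state(two_layer_domain, velocity=0.0)
        x, analytic, frac = steady_two_layer_analytic(
            D_GEL, L_GEL, 1e-8, x=two_layer_domain.x)
        assert np.max(np.abs(ss.concentration[0] - analytic)) <= 5e-3
        assert frac == pytest.approx(0.765, abs=5e-3)
        assert frac > 0.5  # steep decrease over the endothelium

    def test_drop_fraction_limits(self):
        _, _, f_inf = steady_two_layer_analytic(D_GEL, L_GEL, 1e2)
        assert f_inf == pytest.approx(0.0, abs=1e-6)
        _, _, f1 = steady_two_layer_analytic(D_GEL, L_GEL, 1e-8)
        _, _, f2 = steady_two_layer_analytic(D_GEL, 2 * L_GEL, 1e-8)
        assert f2 < f1

    def test_grid_convergence_diffusion_dominated(self):
        # membrane face makes the 2-layer solve non-trivial; error halves with h
        cfg = default_config()
        errs = []
        for n in (50, 100, 200):
            dom = build_domain(cfg.geometry, cfg.layers, cfg.solutes[0], n_cells=n)
            ss = steady_state(dom, velocity=0.5 * D_GEL / L_GEL)
            # reference: fine-grid solution interpolated
            ref_dom = build_domain(cfg.geometry, cfg.layers, cfg.solutes[0], n_cells=1600)
            ref = steady_state(ref_dom, velocity=0.5 * D_GEL / L_GEL)
            errs.append(np.max(np.abs(
                ss.concentration[0] - np.interp(dom.x, ref_dom.x, ref.concentration[0]))))
        assert errs[1] <= 0.55 * errs[0] or errs[1] < 1e-8
        assert errs[2] <= 0.55 * errs[1] or errs[2] < 1e-8


class TestTransient:
    def test_closed_mass_conservation(self):
        dom = build_domain(layers=[GEL], n_cells=60,
                           bc_left=BoundaryCondition("closed"),
                           bc_right=BoundaryCondition("closed"))
        ic = np.exp(-(((dom.x - 5e-4) / 2e-4) ** 2))
        field = simulate(dom, 0.0, t_end=6 * 3600, dt=60, initial=ic)
        mass = field.total_mass(dom.dx)
        assert np.max(np.abs(mass - mass[0])) / mass[0] <= 1e-10

    def test_maximum_principle_source_free(self):
        dom = build_domain(layers=[GEL], n_cells=80)
        field = simulate(dom, 2 * D_GEL / L_GEL, t_end=12 * 3600, dt=120)
        assert field.concentration.min() >= -1e-12
        assert field.concentration.max() <= 1.0 + 1e-12

    def test_snapshot_cadence_three_hourly(self, gel_domain):
        field = simulate(gel_domain, 0.0, t_end=24 * 3600, dt=600)
        assert len(field.times) == 9  # t = 0, 3, ..., 24 h
        assert field.times[1] == pytest.approx(3 * 3600)

    def test_implicit_matches_explicit(self):
        dom = build_domain(layers=[GEL], n_cells=40)
        dt_exp = 10.0  # under the explicit stability bound at this resolution
        imp = simulate(dom, 0.0, t_end=3600, dt=dt_exp, method="implicit")
        exp = simulate(dom, 0.0, t_end=3600, dt=dt_exp, method="explicit")
        assert np.max(np.abs(imp.concentration[-1] - exp.concentration[-1])) < 5e-3

    def test_unstable_explicit_raises_with_advice(self):
        dom = build_domain(layers=[GEL], n_cells=400)
        with pytest.raises(ValidationError, match="implicit"):
            simulate(dom, 0.0, t_end=3600, dt=600, method="explicit")

    def test_upwind_scheme_converges_to_exponential_profile(self):
        # upwind cross-check: first-order accurate, so compare loosely at high n
        dom = build_domain(layers=[GEL], n_cells=800)
        v = 3.0 * D_GEL / L_GEL
        ss = steady_state(dom, velocity=v, scheme="upwind")
        analytic = advection_diffusion_profile(dom.x, L_GEL, 3.0)
        assert np.max(np.abs(ss.concentration[0] - analytic)) < 2e-3

    def test_two_solute_independence(self):
        # joint simulation is per-solute independent: fields superpose trivially
        cfg = default_config()
        doms = [build_domain(cfg.geometry, cfg.layers, s, n_cells=60)
                for s in cfg.solutes]
        f1 = simulate(doms[0], 0.0, t_end=6 * 3600, dt=300)
        f1_again = simulate(doms[0], 0.0, t_end=6 * 3600, dt=300)
        assert np.array_equal(f1.concentration, f1_again.concentration)


class TestSecretion:
    def test_symmetric_source_no_flow(self, gel_domain):
        _, up = secretion_under_flow(gel_domain, 0.0, source_position=L_GEL / 2)
        assert up == pytest.approx(0.5, abs=0.01)

    def test_upstream_fraction_decreases_with_pe(self, gel_domain):
        ups = []
        for pe in (0.0, 1.0, 3.0, 15.0):
            _, up = secretion_under_flow(gel_domain, pe * D_GEL / L_GEL,
                                         source_position=L_GEL / 2)
            ups.append(up)
        assert all(b < a for a, b in zip(ups, ups[1:]))

    def test_source_rate_invariance(self, gel_domain):
        _, u1 = secretion_under_flow(gel_domain, 2 * D_GEL / L_GEL, L_GEL / 2, 1.0)
        _, u2 = secretion_under_flow(gel_domain, 2 * D_GEL / L_GEL, L_GEL / 2, 7.3)
        assert u1 == pytest.approx(u2, rel=1e-12)

    def test_source_outside_rejected(self, gel_domain):
        with pytest.raises(ValidationError):
            secretion_under_flow(gel_domain, 0.0, source_position=2 * L_GEL)


class TestLineProfile:
    def test_linear_image_round_trip(self):
        profile = np.linspace(1.0, 0.0, 120)
        img = np.tile(profile, (40, 1))
        pos, rec = extract_line_profile(img)
        assert np.allclose(rec, profile)

    def test_single_row_roi_equals_raw_row(self, rng):
        img = rng.random((30, 50))
        _, rec = extract_line_profile(img, roi=(7, 8, 0, 50))
        assert np.array_equal(rec, img[7])

    def test_positions_in_physical_units(self):
        img = np.ones((10, 20))
        pos, _ = extract_line_profile(img, pixel_size=2.5)
        assert pos[1] - pos[0] == pytest.approx(2.5)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValidationError):
            extract_line_profile(np.ones((10, 10)), roi=(5, 5, 0, 10))
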