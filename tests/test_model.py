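import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ooperm import (
    BathSolution,
    KKParameters,
    OocyteState,
    PhysicalConstants,
    VolumeTrajectory,
    bvh_equilibrium,
    kk_derivatives,
    make_geometry,
    pf_from_lp,
    simulate,
)
from ooperm.model import lp_from_pf


class TestMakeGeometry:
    def test_sphere_formulas(self):
        # frozen oracle: pi/6*d^3, pi*d^2, 9x folding at d = 0.12 cm
        g = make_geometry(0.12)
        assert g.V0 == pytest.approx(9.0478e-4, rel=1e-4)
        assert g.A_apparent == pytest.approx(4.5239e-2, rel=1e-4)
        assert g.S == pytest.approx(0.40715, rel=1e-4)
        assert g.S / g.V0 == pytest.approx(450.0, rel=1e-12)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            make_geometry(0.0)
        with pytest.raises(ValueError):
            make_geometry(-0.1)

    def test_unit_fold_factor_gives_apparent_area(self):
        g = make_geometry(0.12, PhysicalConstants(area_fold_factor=1.0))
        assert g.S == g.A_apparent

    @given(d=st.floats(0.01, 1.0))
    def test_area_ratio_invariant(self, d):
        g = make_geometry(d)
        assert g.S == pytest.approx(9 * g.A_apparent)
        assert g.V0 == pytest.approx(np.pi / 6 * d**3)


class TestConstants:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            PhysicalConstants(Vw=-1.0)
        with pytest.raises(ValueError):
            PhysicalConstants(area_fold_factor=0.5)


class TestKKDerivatives:
    def make_state(self, geom, vb_fraction=0.75, ns=0.0, osm_iso=200.0):
        vb = vb_fraction * geom.V0
        return OocyteState(
            V=geom.V0,
            Ns=ns,
            N_imp_osm=osm_iso * 1e-6 * (geom.V0 - vb),
            Vb=vb,
        )

    def test_impermeable_membrane(self, geom, sucrose_bath):
        state = self.make_state(geom)
        dv, dns = kk_derivatives(
            state, sucrose_bath, KKParameters(Lp=0.0, Ps=0.0, sigma=1.0), geom
        )
        assert dv == 0.0
        assert dns == 0.0

    def test_equilibrium_is_stationary(self, geom):
        # internal and external concentrations identical -> zero flux
        state = self.make_state(geom, osm_iso=200.0)
        bath = BathSolution(osm_impermeant=200.0)
        dv, dns = kk_derivatives(
            state, bath, KKParameters(Lp=2.0, Ps=0.01, sigma=0.8), geom
        )
        assert dv == pytest.approx(0.0, abs=1e-18)
        assert dns == pytest.approx(0.0, abs=1e-18)

    def test_hypertonic_shrink_sign(self, geom, sucrose_bath):
        state = self.make_state(geom)
        dv, dns = kk_derivatives(
            state, sucrose_bath, KKParameters(Lp=2.0, Ps=0.0, sigma=1.0), geom
        )
        assert dv < 0
        assert dns == 0.0

    def test_invalid_state_rejected(self, geom, sucrose_bath):
        state = self.make_state(geom)
        state.V = state.Vb * 0.5
        with pytest.raises(ValueError):
            kk_derivatives(
                state, sucrose_bath, KKParameters(Lp=1.0), geom
            )


class TestSimulate:
    def test_zero_lp_constant_volume(self, geom, sucrose_bath):
        traj = simulate(
            KKParameters(Lp=0.0), geom, sucrose_bath, duration=5.0
        )
        np.testing.assert_allclose(traj.rel_volumes, 1.0, atol=1e-12)

    def test_impermeant_equilibrium_matches_bvh(self, geom, sucrose_bath):
        traj = simulate(
            KKParameters(Lp=2.57, Ps=0.0, sigma=1.0),
            geom,
            sucrose_bath,
            duration=120.0,
            sample_interval=2.0,
        )
        assert traj.rel_volumes[-1] == pytest.approx(
            bvh_equilibrium(0.75, 200.0, 1460.0), abs=1e-6
        )

    def test_impermeant_shrink_is_monotone(self, geom, sucrose_bath):
        traj = simulate(
            KKParameters(Lp=2.0, Ps=0.0, sigma=1.0), geom, sucrose_bath
        )
        assert np.all(np.diff(traj.rel_volumes) < 1e-9)
        assert traj.rel_volumes[-1] < 0.8

    def test_volume_floor(self, geom):
        # even an extreme impermeant step cannot push below the inactive volume
        traj = simulate(
            KKParameters(Lp=10.0, Ps=0.0, sigma=1.0),
            geom,
            BathSolution(osm_impermeant=10000.0),
            duration=60.0,
            sample_interval=1.0,
        )
        assert traj.rel_volumes.min() >= 0.75 - 1e-9

    def test_shrink_then_swell_with_permeant(self, t85a_eg_traj):
        rv = t85a_eg_traj.rel_volumes
        imin = int(rv.argmin())
        assert 0 < imin < len(rv) - 1  # interior minimum
        assert rv[imin] < 1.0
        assert rv[-1] > rv[imin]

    def test_permeant_concentration_equilibrates(self, geom, eg_bath):
        traj = simulate(
            KKParameters(Lp=2.64, Ps=25.49e-3, sigma=0.8),
            geom,
            eg_bath,
            duration=300.0,
            sample_interval=5.0,
        )
        vb = 0.75 * geom.V0
        v = traj.rel_volumes[-1] * traj.V0
        ns = traj.permeant_mol[-1]
        cs_in = ns / (v - vb - ns * 54.0)
        assert cs_in == pytest.approx(1.3e-3, rel=1e-6)

    def test_solver_tolerance_convergence(self, geom, eg_bath, t85a_eg_params):
        a = simulate(t85a_eg_params, geom, eg_bath, rtol=1e-9)
        b = simulate(t85a_eg_params, geom, eg_bath, rtol=5e-10)
        assert np.max(np.abs(a.rel_volumes - b.rel_volumes)) < 1e-6

    def test_folded_area_is_faster(self, geom, sucrose_bath):
        slow = simulate(
            KKParameters(Lp=2.0), geom, sucrose_bath, area_basis="apparent"
        )
        fast = simulate(
            KKParameters(Lp=2.0), geom, sucrose_bath, area_basis="folded"
        )
        assert fast.rel_volumes[1] < slow.rel_volumes[1]

    def test_invalid_inputs(self, geom, sucrose_bath):
        with pytest.raises(ValueError):
            simulate(KKParameters(Lp=1.0), geom, sucrose_bath, vb_fraction=1.0)
        with pytest.raises(ValueError):
            simulate(KKParameters(Lp=1.0), geom, sucrose_bath, duration=-1.0)


class TestBvhEquilibrium:
    def test_sucrose_value(self):
        assert bvh_equilibrium(0.75, 200.0, 1460.0) == pytest.approx(
            0.78425, abs=1e-5
        )

    def test_isotonic_identity(self):
        assert bvh_equilibrium(0.75, 200.0, 200.0) == 1.0

    def test_infinite_osmolarity_limit(self):
        # maximum loss is the free water content (25%)
        assert bvh_equilibrium(0.75, 200.0, 1e12) == pytest.approx(0.75, abs=1e-9)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bvh_equilibrium(0.75, 200.0, 100.0)
        with pytest.raises(ValueError):
            bvh_equilibrium(1.5, 200.0, 400.0)

    @given(
        vb=st.floats(0.0, 0.99),
        iso=st.floats(1.0, 500.0),
        ratio=st.floats(1.0, 100.0),
    )
    def test_bounds_property(self, vb, iso, ratio):
        v = bvh_equilibrium(vb, iso, iso * ratio)
        assert vb - 1e-12 <= v <= 1.0 + 1e-12


class TestPfFromLp:
    def test_zero(self):
        assert pf_from_lp(0.0) == 0.0

    def test_reference_value(self):
        # frozen: 2.57e-4 * 82.3 * 293.15 / 18
        assert pf_from_lp(2.57) == pytest.approx(0.34447, rel=1e-4)

    def test_linearity(self):
        assert pf_from_lp(2.0) == pytest.approx(2 * pf_from_lp(1.0), rel=1e-12)

    def test_round_trip(self):
        assert lp_from_pf(pf_from_lp(1.7)) == pytest.approx(1.7, rel=1e-12)


class TestVolumeTrajectory:
    def test_validation(self):
        with pytest.raises(ValueError):
            VolumeTrajectory(times=[0.0, 1.0], rel_volumes=[1.0], V0=1e-3)
        with pytest.raises(ValueError):
            VolumeTrajectory(times=[0.5, 1.0], rel_volumes=[1.0, 0.9], V0=1e-3)
        with pytest.raises(ValueError):
            VolumeTrajectory(times=[0.0, 1.0], rel_volumes=[1.0, -0.5], V0=1e-3)

    def test_restrict(self, t85a_eg_traj):
        sub = t85a_eg_traj.restrict(2.0)
        assert sub.times[-1] <= 2.0 + 1e-9
        assert len(sub) == 13  # 10-s sampling over [0, 2 min]
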