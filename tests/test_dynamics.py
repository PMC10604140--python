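"""Forward dynamics: inverse-dynamics oracle cases, penalty contact,
Kutta-Merson integration and the passive drawer harness."""

import numpy as np
import pytest

import kneesim as ks
from kneesim.dynamics import (KneeModel, contact_force, integrate_step,
                              inverse_dynamics_knee, kutta_merson_step,
                              passive_drawer_test)
from kneesim.errors import ParameterError
from kneesim.gait import GaitCycle
from kneesim.geometry import KneeState, segment_properties
from kneesim.ligaments import default_ligament_set, scale_pcl_stiffness


def _still_gait(n=100, hip=0.0, knee=0.0):
    """A motionless 'gait' record (bypasses waveform validation on
    purpose: inverse dynamics accepts any kinematic record)."""
    t = np.arange(n) / n
    z = np.zeros(n)
    return GaitCycle(t=t, hip_flexion=np.full(n, hip),
                     knee_flexion=np.full(n, knee), ankle_flexion=z,
                     grf_vertical=z, grf_anteroposterior=z,
                     toe_off_fraction=0.6)


class TestInverseDynamics:
    def test_no_gravity_no_motion_no_grf_gives_zero_moment(self):
        body = ks.BodyParams(gravity=0.0)
        demand = inverse_dynamics_knee(_still_gait(), body)
        assert np.allclose(demand.moment, 0.0, atol=1e-12)

    def test_static_tilted_shank_balances_gravity(self, body):
        # shank held 20 deg forward: extensor demand m*g*d*sin(20)
        demand = inverse_dynamics_knee(_still_gait(hip=20.0), body)
        seg = segment_properties(body)
        expected = -seg.total_mass * body.gravity * seg.com_distance * np.sin(np.radians(20))
        assert np.allclose(demand.moment, expected, rtol=1e-9)

    def test_free_pendulum_swing_needs_no_muscle_moment(self, body):
        from scipy.integrate import solve_ivp

        seg = segment_properties(body)
        mgd = seg.total_mass * body.gravity * seg.com_distance

        def rhs(t, y):
            return [y[1], -mgd * np.sin(y[0]) / seg.inertia_about_knee]

        n = 400
        t = np.arange(n) / n
        sol = solve_ivp(rhs, (0.0, 1.0), [np.radians(20.0), 0.0],
                        t_eval=t, rtol=1e-10, atol=1e-12)
        phi = np.degrees(sol.y[0])
        gait = _still_gait(n)
        gait.knee_flexion = -phi  # phi = hip - knee with hip = 0
        demand = inverse_dynamics_knee(gait, body)
        interior = demand.moment[5:-5]
        assert np.max(np.abs(interior)) < 0.02 * mgd


class TestContact:
    def test_separated_surfaces_carry_no_force(self, geometry, contact):
        n, f = contact_force(KneeState(comp=-0.5), geometry, contact)
        assert n == 0.0 and f == 0.0

    def test_penalty_force_proportional_to_penetration(self, geometry, contact):
        n, _ = contact_force(KneeState(comp=0.05), geometry, contact)
        assert n == pytest.approx(contact.contact_stiffness * 0.05, rel=1e-6)

    def test_friction_bounded_by_coulomb_cone(self, geometry, contact):
        for apv in (-300.0, -5.0, 0.3, 40.0, 800.0):
            n, f = contact_force(
                KneeState(comp=0.05, ap_velocity=apv), geometry, contact)
            assert abs(f) <= contact.friction_mu * n + 1e-12
            if abs(apv) > 10.0:  # well beyond the regularization scale
                assert abs(f) > 0.9 * contact.friction_mu * n
                assert np.sign(f) == -np.sign(apv)

    def test_dish_offset_produces_centering_force(self, geometry, contact):
        from kneesim.dynamics import _contact_force_vector

        vec, info = _contact_force_vector(-6.0, 0.2, 0.0, 0.0, geometry,
                                          contact, 0.00427)
        assert info["normal"] > 0
        assert vec[0] > 0  # posteriorly displaced tibia is pushed anteriorly

    def test_restitution_must_stay_zero(self):
        with pytest.raises(ParameterError):
            ks.ContactParams(restitution=0.3)


class TestIntegrator:
    def test_ballistic_closed_form(self):
        # constant 10 N on 2 kg from rest for 0.5 s: x = F t^2 / (2 m)
        state = integrate_step(KneeState(), lambda st: (10.0, 0.0), 0.5,
                               effective_mass_kg=2.0)
        expected = 0.5 * (10.0 / 0.002) * 0.5 ** 2  # mm
        assert state.ap == pytest.approx(expected, rel=1e-8)
        assert state.comp == pytest.approx(0.0, abs=1e-12)

    def test_embedded_error_estimate_tracks_true_error(self):
        # y' = -y, exact solution known; one coarse step
        f = lambda t, y: -y  # noqa: E731
        y0 = np.array([1.0])
        h = 0.4
        y1, err = kutta_merson_step(f, 0.0, y0, h)
        true_err = abs(y1[0] - np.exp(-h))
        assert true_err < 10 * max(abs(err[0]), 1e-16)
        # fourth order: halving the step shrinks the error ~16x
        ya, _ = kutta_merson_step(f, 0.0, y0, h / 2)
        yb, _ = kutta_merson_step(f, h / 2, ya, h / 2)
        assert abs(yb[0] - np.exp(-h)) < true_err / 8.0

    def test_equilibrium_state_is_fixed_point(self):
        state = integrate_step(KneeState(ap=1.0, comp=-0.5),
                               lambda st: (0.0, 0.0), 0.1,
                               effective_mass_kg=4.0)
        assert state.ap == pytest.approx(1.0, abs=1e-12)
        assert state.comp == pytest.approx(-0.5, abs=1e-12)
        assert state.time == pytest.approx(0.1)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ParameterError):
            integrate_step(KneeState(), lambda st: (0.0, 0.0), -0.1, 4.0)


class TestSimulateGait:
    def test_unloaded_standing_knee_stays_put(self, geometry, ligaments,
                                              muscles, body, contact):
        gait = _still_gait()
        forces = np.zeros((gait.n_samples, 10))
        result = ks.simulate_gait(geometry, ligaments, muscles, gait,
                                  ks.BodyParams(gravity=0.0), contact,
                                  muscle_forces=forces)
        assert np.max(np.abs(result.ap)) < contact.config_tolerance_translation
        assert np.max(np.abs(result.comp)) < contact.config_tolerance_translation

    def test_ligament_action_reaction_bookkeeping(self, geometry, ligaments,
                                                  muscles, gait_clean, body,
                                                  contact):
        model = KneeModel(geometry, ligaments, muscles, gait_clean, body,
                          contact, muscle_forces=np.zeros((100, 10)))
        theta, ap, comp = 20.0, -9.0, -0.4
        f_tibia, tensions = model.ligament_forces(theta, ap, comp)
        # recompute the force on the femur bundle by bundle
        rot = ks.geometry.flexion_rotation(theta)
        f_femur = np.zeros(2)
        for j, name in enumerate(ks.BUNDLE_NAMES):
            b = ligaments.bundles[name]
            fem = rot @ np.asarray(geometry.site(b.femur_site).xy)
            tib = np.asarray(geometry.site(b.tibia_site).xy) + [ap, comp]
            v = tib - fem
            length = np.linalg.norm(v)
            f_femur += tensions[j] * v / length
        assert np.allclose(f_femur, -f_tibia, atol=1e-9)

    def test_metadata_records_condition(self, intact_result):
        md = intact_result.metadata
        assert md["pcl_factor"] == 1.0
        assert md["hamstring_factor"] == 1.0
        assert md["n_cycles"] == 2

    def test_result_on_driving_grid_with_physical_signs(self, intact_result):
        r = intact_result
        assert len(r.t) == 100
        assert np.all(r.contact_normal >= 0.0)
        assert np.all(r.bundle_tensions >= 0.0)
        assert r.contact_bw.max() > 2.0  # stance peaks are multi-BW


class TestDrawer:
    def test_zero_force_zero_displacement(self, geometry, ligaments, contact):
        assert passive_drawer_test(geometry, ligaments, contact, 30.0, 0.0) == 0.0

    def test_pcl_rupture_increases_posterior_laxity(self, geometry, ligaments,
                                                    contact):
        cut = scale_pcl_stiffness(ligaments, 0.0)
        intact = passive_drawer_test(geometry, ligaments, contact, 30.0, -90.0)
        ruptured = passive_drawer_test(geometry, cut, contact, 30.0, -90.0)
        assert ruptured < intact < 0.0

    def test_displacement_monotone_in_force(self, geometry, ligaments, contact):
        disp = [passive_drawer_test(geometry, ligaments, contact, 20.0, -f)
                for f in (30.0, 90.0, 150.0, 250.0)]
        assert np.all(np.diff(disp) < 0.0)

    def test_excessive_force_rejected(self, geometry, ligaments, contact):
        with pytest.raises(ParameterError):
            passive_drawer_test(geometry, ligaments, contact, 30.0, -900.0)

    def test_equilibrium_invariant_under_joint_load_scaling(self, geometry,
                                                            contact):
        # scaling every structural stiffness and every load by the same
        # factor leaves the quasi-static displacement unchanged
        factor = 3.0
        lig1 = default_ligament_set(geometry)
        table = {k: v * factor for k, v in
                 ks.ligaments.DEFAULT_LIGAMENT_STIFFNESS.items()}
        lig3 = default_ligament_set(geometry, stiffness_table=table)
        con3 = ks.ContactParams(
            contact_stiffness=contact.contact_stiffness * factor)
        d1 = passive_drawer_test(geometry, lig1, contact, 30.0, -120.0,
                                 preload=100.0)
        d3 = passive_drawer_test(geometry, lig3, con3, 30.0, -360.0,
                                 preload=300.0)
        assert d3 == pytest.approx(d1, abs=0.02)
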