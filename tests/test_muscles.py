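"""Muscle actuators: lever-arm probing, Min/Max force sharing, group
scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kneesim as ks
from kneesim.errors import GeometryError, InfeasibleError, LookupError_, ParameterError
from kneesim.geometry import KneeGeometry, KneeState, Site
from kneesim.muscles import (MUSCLE_GROUPS, MomentDemand, MuscleActuator,
                             lever_arm, minmax_forces, scale_group,
                             solve_muscle_forces_cycle)
from conftest import brute_force_minmax_stress


def _toy_geometry(sites):
    table = {name: Site(name, body, tuple(xy)) for name, (body, xy) in sites.items()}
    return KneeGeometry(sites=table)


def _muscle(origin, insertion, pcsa=1000.0):
    return MuscleActuator(name="toy", group="hamstrings",
                          origin_site=origin, insertion_site=insertion,
                          pcsa=pcsa)


class TestLeverArm:
    def test_line_through_joint_center_has_zero_arm(self):
        geo = _toy_geometry({
            "o": ("femur", (0.0, 50.0)), "i": ("tibia", (0.0, -50.0))})
        r = lever_arm(_muscle("o", "i"), geo, KneeState())
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_anterior_force_forty_mm_below_knee(self):
        # force along +x applied 40 mm distal on the tibia: |r| = 40 mm
        geo = _toy_geometry({
            "o": ("femur", (1000.0, -40.0)), "i": ("tibia", (0.0, -40.0))})
        r = lever_arm(_muscle("o", "i"), geo, KneeState())
        assert abs(r) == pytest.approx(40.0, rel=1e-6)

    def test_independent_of_probe_force(self, geometry, muscles):
        m = muscles.muscle("Semimembranosus")
        state = KneeState(flexion=20.0, hip_flexion=25.0)
        r100 = lever_arm(m, geometry, state, probe_force=100.0)
        r500 = lever_arm(m, geometry, state, probe_force=500.0)
        assert r100 == pytest.approx(r500, rel=1e-12)

    def test_hamstrings_flex_quadriceps_extend(self, geometry, muscles):
        state = KneeState(flexion=15.0, hip_flexion=20.0)
        for name in MUSCLE_GROUPS["hamstrings"] + MUSCLE_GROUPS["gastrocnemius"]:
            assert lever_arm(muscles.muscle(name), geometry, state) > 0
        for name in MUSCLE_GROUPS["quadriceps"]:
            assert lever_arm(muscles.muscle(name), geometry, state) < 0

    def test_degenerate_path_raises(self):
        geo = _toy_geometry({
            "o": ("femur", (5.0, -5.0)), "i": ("tibia", (5.0, -5.0))})
        with pytest.raises(GeometryError):
            lever_arm(_muscle("o", "i"), geo, KneeState())

    def test_invalid_probe_force_rejected(self, geometry, muscles):
        with pytest.raises(ParameterError):
            lever_arm(muscles.muscle("Semitendinosus"), geometry, KneeState(),
                      probe_force=0.0)


class TestMinMax:
    def test_zero_demand_gives_zero_forces(self):
        muscles = [_muscle("o", "i", pcsa=p) for p in (500.0, 1500.0)]
        forces = minmax_forces(0.0, muscles, np.array([0.03, 0.04]))
        assert np.all(forces == 0.0)

    def test_single_muscle_unique_solution(self):
        forces = minmax_forces(20.0, [_muscle("o", "i")], np.array([0.04]))
        assert forces[0] == pytest.approx(500.0, rel=1e-9)

    def test_two_flexors_share_common_stress(self):
        muscles = [_muscle("o", "i", pcsa=2000.0), _muscle("o", "i", pcsa=1000.0)]
        forces = minmax_forces(24.0, muscles, np.array([0.04, 0.04]))
        assert forces[0] == pytest.approx(400.0, rel=1e-8)
        assert forces[1] == pytest.approx(200.0, rel=1e-8)
        stresses = forces / np.array([2000.0, 1000.0])
        assert stresses[0] == pytest.approx(stresses[1], rel=1e-8)

    def test_antagonists_stay_silent(self):
        muscles = [_muscle("o", "i", pcsa=1000.0), _muscle("o", "i", pcsa=1000.0)]
        forces = minmax_forces(10.0, muscles, np.array([0.03, -0.04]))
        assert forces[1] == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_sign_raises(self):
        with pytest.raises(InfeasibleError):
            minmax_forces(10.0, [_muscle("o", "i")], np.array([-0.03]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_oracle_on_random_problems(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 4))
        levers = rng.uniform(0.01, 0.06, n) * rng.choice([-1.0, 1.0], n)
        pcsas = rng.uniform(300.0, 3000.0, n)
        demand = float(rng.uniform(-60.0, 60.0))
        muscles = [_muscle("o", "i", pcsa=p) for p in pcsas]
        agonists = levers * np.sign(demand) > 0
        if demand != 0 and not np.any(agonists):
            return
        forces = minmax_forces(demand, muscles, levers)
        assert float(levers @ forces) == pytest.approx(demand, rel=1e-8, abs=1e-8)
        sigma = np.max(forces / pcsas) if n else 0.0
        oracle = brute_force_minmax_stress(demand, levers, pcsas)
        assert sigma == pytest.approx(oracle, rel=1e-3, abs=1e-9)

    def test_optimal_stress_shrinks_when_a_muscle_is_added(self):
        pcsas = [1000.0, 800.0]
        levers = np.array([0.03, 0.025])
        f2 = minmax_forces(30.0, [_muscle("o", "i", pcsa=p) for p in pcsas], levers)
        s2 = np.max(f2 / np.array(pcsas))
        pcsas3 = pcsas + [1200.0]
        levers3 = np.append(levers, 0.035)
        f3 = minmax_forces(30.0, [_muscle("o", "i", pcsa=p) for p in pcsas3], levers3)
        s3 = np.max(f3 / np.array(pcsas3))
        assert s3 < s2
        # and stress grows with demand magnitude
        f_big = minmax_forces(60.0, [_muscle("o", "i", pcsa=p) for p in pcsas], levers)
        assert np.max(f_big / np.array(pcsas)) > s2


class TestCycleSolve:
    def test_zero_demand_everywhere_gives_zero_forces(self, geometry, muscles, gait_clean):
        demand = MomentDemand(t=gait_clean.t, moment=np.zeros(gait_clean.n_samples))
        states = [KneeState(flexion=th, hip_flexion=h)
                  for th, h in zip(gait_clean.knee_flexion, gait_clean.hip_flexion)]
        forces = solve_muscle_forces_cycle(demand, muscles, geometry, states)
        assert np.all(forces == 0.0)

    def test_flexor_demand_recruits_only_flexors(self, geometry, muscles, gait_clean):
        moment = np.where((gait_clean.t > 0.8) & (gait_clean.t < 0.95), 20.0, 0.0)
        demand = MomentDemand(t=gait_clean.t, moment=moment)
        states = [KneeState(flexion=th, hip_flexion=h)
                  for th, h in zip(gait_clean.knee_flexion, gait_clean.hip_flexion)]
        forces = solve_muscle_forces_cycle(demand, muscles, geometry, states)
        names = list(ks.MUSCLE_NAMES)
        ham_idx = [names.index(n) for n in MUSCLE_GROUPS["hamstrings"]]
        quad_idx = [names.index(n) for n in MUSCLE_GROUPS["quadriceps"]]
        active = moment > 0
        assert np.all(forces[active][:, ham_idx].sum(axis=1) > 0)
        assert np.allclose(forces[:, quad_idx], 0.0)
        assert np.allclose(forces[~active], 0.0)
        assert np.all(forces >= 0.0)

    def test_moment_balance_holds_at_every_sample(self, geometry, muscles, gait_clean, body):
        demand = ks.inverse_dynamics_knee(gait_clean, body)
        states = [KneeState(flexion=th, hip_flexion=h)
                  for th, h in zip(gait_clean.knee_flexion, gait_clean.hip_flexion)]
        forces = solve_muscle_forces_cycle(demand, muscles, geometry, states)
        mus = list(muscles)
        for j in range(0, gait_clean.n_samples, 7):
            levers = np.array([lever_arm(m, geometry, states[j]) for m in mus]) * 1e-3
            assert float(levers @ forces[j]) == pytest.approx(
                demand.moment[j], rel=1e-6, abs=1e-6)


class TestScaleGroup:
    def test_identity_factor(self, muscles):
        out = scale_group(muscles, "hamstrings", 1.0)
        assert out.scales() == pytest.approx(muscles.scales())

    def test_hamstring_scaling_touches_only_the_group(self, muscles):
        out = scale_group(muscles, "hamstrings", 0.6)
        for name in ks.MUSCLE_NAMES:
            expected = 0.6 if name in MUSCLE_GROUPS["hamstrings"] else 1.0
            assert out.muscle(name).scale == pytest.approx(expected)

    def test_repeated_scaling_composes(self, muscles):
        out = scale_group(scale_group(muscles, "hamstrings", 0.9), "hamstrings", 0.9)
        assert out.muscle("Semimembranosus").scale == pytest.approx(0.81)

    def test_unknown_group_raises(self, muscles):
        with pytest.raises(LookupError_):
            scale_group(muscles, "rotator_cuff", 0.5)

    def test_out_of_range_factor_rejected(self, muscles):
        with pytest.raises(ParameterError):
            scale_group(muscles, "hamstrings", 1.5)
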