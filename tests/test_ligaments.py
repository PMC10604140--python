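"""Ligament bundle set and the quadratic-toe/linear force-strain law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kneesim as ks
from kneesim.errors import ParameterError
from kneesim.geometry import KneeState
from kneesim.ligaments import (BUNDLE_NAMES, LIGAMENT_GROUPS, bundle_strain,
                               bundle_tension, scale_pcl_stiffness,
                               split_stiffness, total_ligament_tension)


class TestForceStrainLaw:
    def test_slack_carries_no_load(self):
        assert bundle_tension(-0.01, 100.0, 0.03) == 0.0
        assert bundle_tension(0.0, 100.0, 0.03) == 0.0

    def test_closed_form_at_strain_limit(self):
        # k*eps_l/2 at the toe/linear junction
        assert bundle_tension(0.03, 100.0, 0.03) == pytest.approx(1.5)

    def test_closed_form_in_linear_region(self):
        # k*(eps - eps_l/2)
        assert bundle_tension(0.10, 100.0, 0.03) == pytest.approx(8.5)

    def test_value_and_slope_continuous_at_limit(self):
        k, el, h = 5000.0, 0.03, 1e-7
        below = bundle_tension(el - h, k, el)
        above = bundle_tension(el + h, k, el)
        assert above - below == pytest.approx(0.0, abs=k * h * 2)
        slope_below = (bundle_tension(el, k, el) - bundle_tension(el - h, k, el)) / h
        slope_above = (bundle_tension(el + h, k, el) - bundle_tension(el, k, el)) / h
        assert slope_above == pytest.approx(slope_below, rel=1e-4)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(eps=st.floats(-0.05, 0.3), k=st.floats(0.0, 2e4),
           el=st.floats(1e-3, 0.1))
    def test_nonnegative_and_linear_in_stiffness(self, eps, k, el):
        t = bundle_tension(eps, k, el)
        assert t >= 0.0
        assert bundle_tension(eps, 2 * k, el) == pytest.approx(2 * t, rel=1e-12, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(el=st.floats(5e-3, 0.08), k=st.floats(10.0, 2e4))
    def test_monotone_nondecreasing_in_strain(self, el, k):
        eps = np.linspace(-0.02, 0.3, 300)
        t = bundle_tension(eps, k, el)
        assert np.all(np.diff(t) >= -1e-12)

    def test_double_limit_variant_values_and_continuity(self):
        # quadratic k*eps^2/(4 eps_l) up to 2*eps_l, then k*(eps - eps_l)
        assert bundle_tension(0.06, 100.0, 0.03, "double_limit") == pytest.approx(3.0)
        assert bundle_tension(0.10, 100.0, 0.03, "double_limit") == pytest.approx(7.0)
        h = 1e-7
        lo = bundle_tension(0.06 - h, 100.0, 0.03, "double_limit")
        hi = bundle_tension(0.06 + h, 100.0, 0.03, "double_limit")
        assert hi - lo == pytest.approx(0.0, abs=1e-4)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            bundle_tension(0.05, 100.0, 0.0)
        with pytest.raises(ParameterError):
            bundle_tension(0.05, -1.0, 0.03)
        with pytest.raises(ParameterError):
            bundle_tension(0.05, 100.0, 0.03, "bogus")


class TestSplitStiffness:
    def test_divides_reported_value_by_bundle_count(self):
        assert split_stiffness(6000.0, 3) == pytest.approx(2000.0)

    def test_single_bundle_identity(self):
        assert split_stiffness(1234.5, 1) == 1234.5

    def test_split_conserves_total(self):
        for n in (1, 2, 3, 5):
            assert n * split_stiffness(8250.0, n) == pytest.approx(8250.0)

    def test_invalid_count_rejected(self):
        with pytest.raises(ParameterError):
            split_stiffness(1000.0, 0)


class TestStrain:
    def test_zero_at_calibrated_neutral_state(self, geometry, ligaments):
        for b in ligaments:
            assert bundle_strain(geometry, b, KneeState()) == pytest.approx(0.0, abs=1e-12)

    def test_three_percent_elongation_reads_003(self, geometry, ligaments):
        b = ligaments.bundle("PCL-al")
        stretched = type(b)(name=b.name, femur_site=b.femur_site,
                            tibia_site=b.tibia_site,
                            rest_length=b.rest_length / 1.03,
                            stiffness=b.stiffness, strain_limit=b.strain_limit)
        assert bundle_strain(geometry, stretched, KneeState()) == pytest.approx(0.03, rel=1e-9)

    def test_translated_state_matches_hand_computation(self, geometry, ligaments):
        b = ligaments.bundle("PCL-al")
        state = KneeState(ap=-8.0, comp=-1.0)
        fem = np.asarray(geometry.site(b.femur_site).xy)
        tib = np.asarray(geometry.site(b.tibia_site).xy) + np.array([-8.0, -1.0])
        expected = (np.linalg.norm(fem - tib) - b.rest_length) / b.rest_length
        assert bundle_strain(geometry, b, state) == pytest.approx(expected, rel=1e-12)


class TestPclScaling:
    def test_factor_one_is_identity(self, ligaments):
        scaled = scale_pcl_stiffness(ligaments, 1.0)
        assert scaled.scales == ligaments.scales

    def test_residual_fifteen_percent_touches_only_pcl(self, ligaments):
        scaled = scale_pcl_stiffness(ligaments, 0.15)
        for name in BUNDLE_NAMES:
            if name in LIGAMENT_GROUPS["PCL"]:
                assert scaled.effective_stiffness(name) == pytest.approx(
                    0.15 * ligaments.effective_stiffness(name))
            else:
                assert scaled.effective_stiffness(name) == ligaments.effective_stiffness(name)
                assert scaled.bundles[name] is ligaments.bundles[name]

    def test_scaling_composes_multiplicatively(self, ligaments):
        twice = scale_pcl_stiffness(scale_pcl_stiffness(ligaments, 0.5), 0.3)
        assert twice.scales["PCL-al"] == pytest.approx(0.15)

    def test_out_of_range_factor_rejected(self, ligaments):
        with pytest.raises(ParameterError):
            scale_pcl_stiffness(ligaments, 1.2)
        with pytest.raises(ParameterError):
            scale_pcl_stiffness(ligaments, -0.1)

    def test_zero_factor_silences_pcl_at_any_state(self, geometry, ligaments):
        dead = scale_pcl_stiffness(ligaments, 0.0)
        for state in (KneeState(ap=-15.0), KneeState(flexion=60, ap=-20.0)):
            per_lig, _ = total_ligament_tension(dead, geometry, state)
            assert per_lig["PCL"] == 0.0


class TestTotalTension:
    def test_all_slack_gives_zero_everywhere(self, geometry, ligaments):
        per_lig, per_bundle = total_ligament_tension(ligaments, geometry, KneeState())
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in per_lig.values())
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in per_bundle.values())

    def test_ligament_totals_are_bundle_sums(self, geometry, ligaments):
        state = KneeState(flexion=20.0, ap=-10.0, comp=-0.5)
        per_lig, per_bundle = total_ligament_tension(ligaments, geometry, state)
        for lig, members in LIGAMENT_GROUPS.items():
            assert per_lig[lig] == pytest.approx(sum(per_bundle[m] for m in members))
        assert any(v > 0 for v in per_bundle.values())

    def test_missing_bundle_rejected_at_construction(self, ligaments):
        bundles = dict(ligaments.bundles)
        bundles.pop("PCL-al")
        with pytest.raises(ParameterError):
            ks.LigamentSet(bundles=bundles)
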