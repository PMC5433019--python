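import math

import numpy as np
import pytest

from iacflow.peripheral import (DEFAULT_GROUPS, MMHG_PA, PeripheralTreeSpec,
                                build_tree_resistance, group_for_diameter,
                                outlet_pressure, resistance_si_to_mmhg_per_kg_s,
                                segment_resistance, update_terminal_state)
from iacflow.rheology import blood_viscosity_0d

from _oracles import brute_force_tree_resistance


class TestGroupTable:
    @pytest.mark.parametrize("name, lam", [
        ("large arteries", 61.5385),
        ("main artery branches", 83.3333),
        ("terminal artery branches", 16.6667),
        ("capillaries", 250.0),
    ])
    def test_lambda_consistent_with_geometry(self, name, lam):
        """λ recomputed as length/radius reproduces the tabulated values."""
        g = next(g for g in DEFAULT_GROUPS if g.name == name)
        assert g.lam == pytest.approx(lam, abs=1e-4)
        assert g.lam_from_geometry() == pytest.approx(lam, abs=1e-4)

    def test_groups_ordered_by_diameter(self):
        means = [g.mean_diameter_mm for g in DEFAULT_GROUPS[1:]]
        assert means == sorted(means, reverse=True)

    @pytest.mark.parametrize("d_mm, name", [
        (6.0, "large arteries"),
        (5.0, "ICA"),
        (2.0, "main artery branches"),
        (0.5, "terminal artery branches"),
        (0.05, "arterioles"),
        (0.024, "arterioles"),  # the 12 um terminal radius
        (0.006, "capillaries"),
        (10.0, "large arteries"),  # clamped above the table range
    ])
    def test_group_assignment(self, d_mm, name):
        assert group_for_diameter(d_mm * 1e-3).name == name


class TestSegmentResistance:
    def test_closed_form(self):
        # r = 1 mm, lambda = 10 (l = 10 mm), mu = 0.0046
        expected = 8 * 0.0046 * 0.01 / (math.pi * (1e-3) ** 4)
        assert segment_resistance(1e-3, 10.0, 0.0046) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(1.171e8, rel=1e-3)

    def test_zero_length_limit(self):
        assert segment_resistance(1e-3, 0.0, 0.0046) == 0.0

    def test_linearity_in_viscosity(self):
        r1 = segment_resistance(1e-3, 10.0, 0.0023)
        r2 = segment_resistance(1e-3, 10.0, 0.0046)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            segment_resistance(0.0, 1.0, 1e-3)
        with pytest.raises(ValueError):
            segment_resistance(1e-3, 1.0, 0.0)


class TestTreeRecursion:
    @pytest.mark.parametrize("n_gen", [1, 2, 3, 6, 10])
    def test_matches_brute_force_network_reduction(self, n_gen):
        """The generation recursion equals a dense solve of the explicit
        binary tree (up to 2^10 terminals) to machine precision."""
        ratio = 2.0 ** (-1.0 / 3.0)
        root_r = 1.0e-3
        spec = PeripheralTreeSpec(root_radius=root_r,
                                  terminal_radius=root_r * ratio ** n_gen * 1.0001,
                                  radius_ratio=ratio)
        radii = spec.generation_radii()
        assert len(radii) - 1 == n_gen
        lams = [group_for_diameter(2 * r, spec.groups).lam for r in radii]
        mus = [blood_viscosity_0d(2 * r * 1e6, 0.0, spec.rheology) for r in radii]
        q_root = 1e-6
        r_ours = build_tree_resistance(spec, 0.0, q_root)
        r_ref, terminals = brute_force_tree_resistance(
            radii, lams, mus, spec.p_terminal_mmhg * MMHG_PA, q_root)
        assert r_ours == pytest.approx(r_ref, rel=1e-12)

    def test_terminals_sit_at_terminal_pressure(self):
        """In the explicit network solved with the recursion's resistance,
        every terminal node is at exactly 30 mmHg."""
        ratio = 2.0 ** (-1.0 / 3.0)
        spec = PeripheralTreeSpec(root_radius=0.6e-3,
                                  terminal_radius=0.6e-3 * ratio ** 8 * 1.0001,
                                  radius_ratio=ratio)
        radii = spec.generation_radii()
        lams = [group_for_diameter(2 * r, spec.groups).lam for r in radii]
        mus = [blood_viscosity_0d(2 * r * 1e6, 0.0, spec.rheology) for r in radii]
        _, terminals = brute_force_tree_resistance(
            radii, lams, mus, spec.p_terminal_mmhg * MMHG_PA, 1e-6)
        assert np.allclose(terminals, 30.0 * MMHG_PA, rtol=1e-10)

    def test_single_generation_closed_form(self):
        """Base case: root + one bifurcation into terminal daughters."""
        ratio = 0.8
        spec = PeripheralTreeSpec(root_radius=1e-3, terminal_radius=0.81e-3,
                                  radius_ratio=ratio)
        radii = spec.generation_radii()
        assert len(radii) == 2
        q = 2e-6
        mu0 = blood_viscosity_0d(2e3, 0.0, spec.rheology)
        mu1 = blood_viscosity_0d(1.6e3, 0.0, spec.rheology)
        lam0 = group_for_diameter(2e-3).lam
        lam1 = group_for_diameter(1.6e-3).lam
        expected = (segment_resistance(1e-3, lam0, mu0)
                    + 0.5 * (segment_resistance(0.8e-3, lam1, mu1)
                             + 30.0 * MMHG_PA / (q / 2)))
        assert build_tree_resistance(spec, 0.0, q) == pytest.approx(expected, rel=1e-12)

    def test_terminal_pressure_contribution_is_p_over_q(self):
        """The terminal load contributes exactly P_terminal/Q_root to the
        root resistance, independent of tree depth."""
        spec = PeripheralTreeSpec(root_radius=1e-3)
        for q in (1e-7, 1e-6, 5e-6):
            r_visc = build_tree_resistance(spec, 0.0, q) - 30.0 * MMHG_PA / q
            r_visc2 = build_tree_resistance(spec, 0.0, 2 * q) - 30.0 * MMHG_PA / (2 * q)
            assert r_visc == pytest.approx(r_visc2, rel=1e-12)

    def test_monotone_in_root_radius_and_terminal_pressure(self):
        q = 1e-6
        r_small = build_tree_resistance(PeripheralTreeSpec(root_radius=0.8e-3), 0.0, q)
        r_large = build_tree_resistance(PeripheralTreeSpec(root_radius=1.2e-3), 0.0, q)
        assert r_small > r_large
        lo = build_tree_resistance(PeripheralTreeSpec(root_radius=1e-3,
                                                      p_terminal_mmhg=20.0), 0.0, q)
        hi = build_tree_resistance(PeripheralTreeSpec(root_radius=1e-3,
                                                      p_terminal_mmhg=40.0), 0.0, q)
        assert hi > lo

    def test_reported_resistance_in_clinical_range(self):
        """Branch-scale outlets give resistances of the tabulated order
        (1e4-1e6 mmHg/(kg/s)) at flows scaling with r^3."""
        for r in np.linspace(0.5e-3, 2.0e-3, 7):
            q = 1.26e-5 * (r / 3.25e-3) ** 3
            r_si = build_tree_resistance(PeripheralTreeSpec(root_radius=float(r)),
                                         0.0, float(q))
            r_rep = resistance_si_to_mmhg_per_kg_s(r_si, 1050.0)
            assert 1e4 <= r_rep <= 1e6

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            PeripheralTreeSpec(root_radius=10e-6)  # below terminal radius
        with pytest.raises(ValueError):
            PeripheralTreeSpec(root_radius=1e-3, radius_ratio=1.1)
        with pytest.raises(ValueError):
            build_tree_resistance(PeripheralTreeSpec(root_radius=1e-3), 0.0, 0.0)


class TestOutletPressure:
    def test_ica_fixture_product(self):
        assert outlet_pressure(17790.0, 5e-3) == pytest.approx(88.95)

    def test_zero_flow_zero_pressure(self):
        assert outlet_pressure(1e5, 0.0) == 0.0

    def test_linearity(self):
        assert outlet_pressure(1e5, 2e-3) == pytest.approx(
            2 * outlet_pressure(1e5, 1e-3))

    def test_reverse_flow_floored_with_warning(self):
        with pytest.warns(UserWarning, match="reverse flow"):
            assert outlet_pressure(1e5, -1e-3) == 30.0


class TestTerminalUpdate:
    def test_fixed_point_matches_closed_form(self):
        """Single tube feeding a single peripheral tree from a pressure
        source: the update iteration converges to the closed-form flow
        Q* = (P_src − P_terminal) / (R_tube + R_viscous)."""
        spec = PeripheralTreeSpec(root_radius=1e-3)
        p_src = 100.0 * MMHG_PA
        r_tube = 5e9  # Pa s/m3
        q = 1e-6  # initial guess
        r_visc = build_tree_resistance(spec, 0.0, q) - 30.0 * MMHG_PA / q
        q_star = (p_src - 30.0 * MMHG_PA) / (r_tube + r_visc)
        for _ in range(200):
            state = update_terminal_state({"X": spec}, {"X": q})
            r_si = state.resistance_si("X")
            q = p_src / (r_tube + r_si)
        assert q == pytest.approx(q_star, rel=1e-9)

    def test_pressures_are_r_times_mass_flow(self):
        spec = PeripheralTreeSpec(root_radius=1e-3)
        state = update_terminal_state({"X": spec}, {"X": 1e-6})
        rho = 1050.0
        assert state.pressure_mmhg["X"] == pytest.approx(
            state.resistance_mmhg_per_kg_s["X"] * rho * 1e-6, rel=1e-9)

    def test_non_positive_flow_rejected(self):
        spec = PeripheralTreeSpec(root_radius=1e-3)
        with pytest.raises(ValueError):
            update_terminal_state({"X": spec}, {"X": 0.0})
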