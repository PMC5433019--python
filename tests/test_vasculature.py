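import math

import pytest

from iacflow.vasculature import (KNOWN_BRANCH_ORDERS, NetworkVariantConfig,
                                 enumerate_model_grid, generate_network,
                                 place_catheter, read_network, relative_label,
                                 write_network)


class TestGeneration:
    def test_deterministic_for_fixed_seed(self):
        cfg = NetworkVariantConfig(case="B", seed=7)
        assert generate_network(cfg) == generate_network(cfg)

    def test_different_seed_changes_geometry(self):
        a = generate_network(NetworkVariantConfig(seed=1))
        b = generate_network(NetworkVariantConfig(seed=2))
        assert a != b

    def test_full_branch_set_with_ligated_sta(self, network_b):
        assert set(network_b.outlet_ids()) == {
            "ICA", "SThA", "LA", "OA", "FA", "PAA", "MA", "MMA"}
        assert "STA" in network_b.ligated_outlets
        assert network_b["STA"].id == "STA"  # present in the tree, but a wall

    def test_reduced_branch_set(self, network_a):
        assert set(network_a.outlet_ids()) == {
            "ICA", "SThA", "LA", "OA", "FA", "MA"}

    def test_outlet_stubs_cut_at_five_diameters(self, network_b):
        for leaf in network_b.leaves():
            assert leaf.length >= 5 * leaf.diameter - 1e-12

    def test_trunk_radii_monotone_non_increasing(self, network_b):
        trunk = [s for s in network_b.segments if s.name == "ECA trunk"]
        radii = [s.radius for s in trunk]
        assert radii == sorted(radii, reverse=True)

    def test_every_outlet_has_unique_path_to_root(self, network_b):
        for leaf in network_b.leaves():
            seen = set()
            cur = leaf
            while cur.parent is not None:
                assert cur.id not in seen
                seen.add(cur.id)
                cur = network_b[cur.parent]
            assert cur.id == "CCA"

    def test_branch_order_variants(self):
        for order in KNOWN_BRANCH_ORDERS:
            net = generate_network(NetworkVariantConfig(branch_order=order))
            carriers = [b.id for b in net.trunk_branches()
                        if b.id in ("LA", "OA", "FA", "LFT", "TLT")]
            assert carriers == list(order)

    def test_common_trunk_children(self):
        net = generate_network(NetworkVariantConfig(branch_order=("LFT", "OA")))
        kids = {s.id for s in net.children("LFT")}
        assert kids == {"LA", "FA"}
        assert net.carrier_of("LA").id == "LFT"

    @pytest.mark.parametrize("order", [("LA", "LA", "OA", "FA"), ("LA", "XX", "FA"),
                                       ("LA", "OA")])
    def test_invalid_branch_order_rejected(self, order):
        with pytest.raises(ValueError):
            NetworkVariantConfig(branch_order=order)


class TestCatheterPlacement:
    def test_vertical_class_positions(self, network_b):
        la_x = network_b["LA"].ostium_axial_position
        fa_x = network_b["FA"].ostium_axial_position
        assert place_catheter(network_b, 1, "C").tip_axial_position == pytest.approx(la_x / 2)
        assert place_catheter(network_b, 2, "C").tip_axial_position == pytest.approx(la_x)
        assert place_catheter(network_b, 3, "C").tip_axial_position == pytest.approx(
            (la_x + fa_x) / 2)
        p4 = place_catheter(network_b, 4, "C")
        assert p4.inside_branch == "LA"

    def test_center_has_zero_offset(self, network_b):
        assert place_catheter(network_b, 1, "C").tip_offset == 0.0

    def test_quarter_diameter_shift(self, network_b):
        """|offset| is a quarter of the local trunk diameter, and the catheter
        wall stays inside the lumen."""
        for p in enumerate_model_grid(network_b):
            if p.vertical_class == 4:
                continue
            r_local = network_b.trunk_radius_at(p.tip_axial_position)
            if p.horizontal_class == "C":
                assert p.tip_offset == 0.0
            else:
                assert p.tip_offset == pytest.approx(2 * r_local / 4)
            assert abs(p.tip_offset) + p.catheter_radius < r_local

    def test_shift_direction_follows_target_ostium(self, network_b):
        theta_la = network_b["LA"].ostium_angle
        f = place_catheter(network_b, 2, "F", "LA")
        b = place_catheter(network_b, 2, "B", "LA")
        assert f.tip_angle == pytest.approx(theta_la)
        assert math.cos(b.tip_angle - theta_la) == pytest.approx(-1.0)

    def test_class4_infeasible_catheter(self, network_a):
        with pytest.raises(ValueError):
            place_catheter(network_a, 4, "C", "LA",
                           catheter_radius=network_a["LA"].radius)

    def test_invalid_classes(self, network_a):
        with pytest.raises(ValueError):
            place_catheter(network_a, 5, "C")
        with pytest.raises(ValueError):
            place_catheter(network_a, 1, "X")
        with pytest.raises(ValueError):
            place_catheter(network_a, 1, "C", "MA")


class TestModelGrid:
    def test_sixteen_distinct_models_per_network(self, network_a, network_b):
        for net in (network_a, network_b):
            grid = enumerate_model_grid(net)
            assert len(grid) == 16
            keys = {(p.vertical_class, p.horizontal_class, p.inside_branch)
                    for p in grid}
            assert len(keys) == 16
        assert len(enumerate_model_grid(network_a)) + len(
            enumerate_model_grid(network_b)) == 32

    def test_exactly_one_superselective_model(self, network_b):
        grid = enumerate_model_grid(network_b)
        assert sum(1 for p in grid if p.vertical_class == 4) == 1

    def test_shared_column_label_cycles(self, network_a, network_b):
        """The same physical shift names different relative labels per branch,
        matching the two cases' column conventions."""
        def cycle(net):
            out = {}
            for p in enumerate_model_grid(net):
                if p.vertical_class == 1 and p.horizontal_class != "C":
                    out[p.relative_labels["LA"]] = (
                        p.relative_labels["OA"], p.relative_labels["FA"])
            return out

        assert cycle(network_a) == {
            "F": ("R", "L"), "L": ("F", "B"), "R": ("B", "F"), "B": ("L", "R")}
        assert cycle(network_b) == {
            "F": ("L", "B"), "L": ("B", "R"), "R": ("F", "L"), "B": ("R", "F")}

    def test_relative_label_function(self):
        assert relative_label(0.0, 0.0) == "F"
        assert relative_label(math.pi, 0.0) == "B"
        assert relative_label(math.pi / 2, 0.0) == "L"
        assert relative_label(-math.pi / 2, 0.0) == "R"


class TestNetworkFiles:
    def test_round_trip_identity(self, tmp_path, network_b):
        path = tmp_path / "net.json"
        write_network(network_b, path)
        assert read_network(path) == network_b

    def test_missing_radius_is_a_parse_error(self, tmp_path, network_a):
        import json

        path = tmp_path / "net.json"
        write_network(network_a, path)
        doc = json.loads(path.read_text())
        del doc["segments"][3]["radius"]
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="radius"):
            read_network(path)

    def test_unknown_keys_accepted_with_warning(self, tmp_path, network_a):
        import json

        path = tmp_path / "net.json"
        write_network(network_a, path)
        doc = json.loads(path.read_text())
        doc["future_extension"] = {"x": 1}
        doc["segments"][0]["note"] = "legacy"
        path.write_text(json.dumps(doc))
        with pytest.warns(UserWarning, match="unknown keys"):
            net = read_network(path)
        assert net == network_a

    def test_malformed_json_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            read_network(path)
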