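import math

import numpy as np
import pytest

from needlefield.electrodes import (
    StimulationProtocol,
    charge_density,
    make_electrode,
    montage_source_terms,
    place_montage,
    project_to_surface,
    total_current,
)
from needlefield.head import make_nested_head
from needlefield.surfaces import edge_lengths, triangle_areas

PROTOCOL = StimulationProtocol(current_density=43.0, duration=1200.0, ramp=30.0)


class TestElectrodeGeometry:
    def test_flat_disc_area_is_disc_area(self):
        e = make_electrode("flat_disc", radius=0.5)
        assert e.total_contact_area == pytest.approx(0.785, abs=5e-4)
        assert e.needle_area_fraction == 0.0

    def test_needle_conjugated_area_fraction(self):
        e = make_electrode("needle_conjugated", radius=0.5, total_contact_area=1.0)
        assert e.total_contact_area == 1.0
        assert e.needle_area_fraction == pytest.approx(0.215, abs=5e-4)

    def test_needle_area_must_exceed_disc_area(self):
        with pytest.raises(ValueError, match="exceed"):
            make_electrode("needle_conjugated", radius=0.5, total_contact_area=0.5)

    @pytest.mark.parametrize(
        "kwargs", [{"radius": 0.0}, {"radius": -1.0}, {"polarity": "ground"}]
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            make_electrode("flat_disc", **{"radius": 0.5, **kwargs})

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            make_electrode("sponge", radius=0.5)


class TestDose:
    def test_reference_protocol_charge_density(self):
        assert charge_density(PROTOCOL) == pytest.approx(51.6)

    def test_zero_dose(self):
        assert charge_density(StimulationProtocol(0.0, 100.0)) == 0.0

    def test_unit_identity_one_ampere_per_m2_second(self):
        # 1 uA/mm^2 == 1 A/m^2, so 1 second gives 1 C/m^2 = 1e-3 kC/m^2
        assert charge_density(StimulationProtocol(1.0, 1.0)) == pytest.approx(1e-3)

    def test_total_current_scales_with_contact_area(self):
        disc = make_electrode("flat_disc", radius=0.5)
        needle = make_electrode("needle_conjugated", radius=0.5, total_contact_area=1.0)
        assert total_current(disc, PROTOCOL) == pytest.approx(33.77, abs=0.01)
        assert total_current(needle, PROTOCOL) == pytest.approx(43.0)
        assert total_current(disc, StimulationProtocol(0.0, 1.0)) == 0.0

    def test_invalid_protocols(self):
        with pytest.raises(ValueError):
            StimulationProtocol(current_density=-1.0)
        with pytest.raises(ValueError):
            StimulationProtocol(duration=0.0)


class TestMontagePlacement:
    def test_ca_preset_currents_balance(self, small_head):
        m = place_montage(small_head, "cA", "flat_disc", PROTOCOL)
        currents = [p.current for p in m.electrodes]
        assert currents[0] == pytest.approx(43.0 * math.pi * 0.25, abs=1e-9)
        assert sum(currents) == pytest.approx(0.0, abs=1e-9)
        polarities = [p.electrode.polarity for p in m.electrodes]
        assert polarities == ["anode", "cathode"]

    def test_bihemispheric_preset_symmetric_currents(self, small_head):
        m = place_montage(small_head, "iC-cA", "needle_conjugated", PROTOCOL)
        currents = [p.current for p in m.electrodes]
        assert currents == pytest.approx([43.0, -43.0])

    def test_unknown_preset(self, small_head):
        with pytest.raises(ValueError, match="preset"):
            place_montage(small_head, "tripolar", "flat_disc", PROTOCOL)

    def test_mirrored_placements_are_symmetric(self, small_head):
        a = place_montage(small_head, "cA", "flat_disc", PROTOCOL, contralesional_ml=+1.25)
        b = place_montage(small_head, "cA", "flat_disc", PROTOCOL, contralesional_ml=-1.25)
        pa = a.electrodes[0].contact_point
        pb = b.electrodes[0].contact_point
        edge = edge_lengths(small_head.scalp).max()
        assert np.linalg.norm(pa - pb * np.array([-1, 1, 1])) < edge

    def test_contact_patch_area_converges_to_disc_area(self):
        target = math.pi * 0.5**2
        errors = {}
        for sub in (4, 6):
            head = make_nested_head(subdivisions=sub)
            scalp = head.scalp
            q, _ = project_to_surface(scalp, head.bregma.to_world(1.2, 1.25))
            cents = scalp.vertices[scalp.triangles].mean(axis=1)
            idx = np.flatnonzero(np.linalg.norm(cents - q, axis=1) <= 0.5)
            area = triangle_areas(scalp)[idx].sum()
            errors[sub] = abs(area - target) / target
        assert errors[4] < 0.10
        assert errors[6] < errors[4]


class TestSourceTerms:
    def test_needle_current_split_by_area_fraction(self, small_head):
        m = place_montage(small_head, "cA", "needle_conjugated", PROTOCOL)
        terms = montage_source_terms(m, small_head)
        assert len(terms.monopoles) == 1
        tip = terms.monopoles[0]
        assert tip.current == pytest.approx(43.0 * 0.215, abs=0.05)
        anode_patch = terms.patches[0]
        assert anode_patch.total == pytest.approx(43.0 * 0.785, abs=0.05)
        assert terms.net_current == pytest.approx(0.0, abs=1e-9)

    def test_needle_tip_stays_inside_the_scalp(self, small_head):
        m = place_montage(small_head, "cA", "needle_conjugated", PROTOCOL)
        terms = montage_source_terms(m, small_head)
        tip = terms.monopoles[0].position
        placed = m.electrodes[0]
        depth = np.linalg.norm(tip - placed.contact_point)
        assert 0 < depth < placed.scalp_thickness

    def test_excessive_tip_depth_rejected(self, small_head):
        m = place_montage(
            small_head,
            "cA",
            "needle_conjugated",
            PROTOCOL,
            electrode_kwargs={"needle_tip_depth": 5.0},
        )
        with pytest.raises(ValueError, match="scalp thickness"):
            montage_source_terms(m, small_head)

    def test_flat_disc_has_no_monopole(self, small_head):
        m = place_montage(small_head, "cA", "flat_disc", PROTOCOL)
        terms = montage_source_terms(m, small_head)
        assert terms.monopoles == []
        assert len(terms.patches) == 2  # anode + reference

    def test_zero_dose_montage_gives_zero_source_terms(self, small_head):
        zero = StimulationProtocol(0.0, 1200.0)
        m = place_montage(small_head, "cA", "flat_disc", zero)
        terms = montage_source_terms(m, small_head)
        _, currents = terms.point_sources()
        assert np.all(currents == 0.0)

    def test_kirchhoff_closure_over_presets(self, small_head):
        for preset in ("cA", "iC-cA"):
            for kind in ("flat_disc", "needle_conjugated"):
                m = place_montage(small_head, preset, kind, PROTOCOL)
                terms = montage_source_terms(m, small_head)
                assert abs(sum(p.current for p in m.electrodes)) < 1e-9
                assert abs(terms.net_current) < 1e-9
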