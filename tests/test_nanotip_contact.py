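"""Bead-stick dynamics, contact classification and contact statistics."""

import math

import numpy as np
import pytest

from nanotear.constants import PhysicalConstants
from nanotear.nanotip_contact import (
    BeadStickCell,
    CellParameters,
    ContactEvent,
    classify_contact,
    contact_statistics,
    simulate_contacts,
    step_cell,
)
from nanotear.synthetic_data import generate_tip_array
from nanotear.flow_field import TIP_MARGIN_PITCH

ROOM = PhysicalConstants()
COLD = PhysicalConstants(temperature=1e-18)
TIPS = generate_tip_array()  # 5x5, d=200 nm, L=5 um, 1-um gaps


def _cell(center, axis, params=None):
    params = params or CellParameters()
    center = np.asarray(center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = params.rest_length / 2.0
    return BeadStickCell(center - half * axis, center + half * axis, params)


def _first_tip_center():
    margin = TIP_MARGIN_PITCH * TIPS.pitch
    return margin + TIPS.tip_diameter / 2.0


class TestStepCell:
    def test_stationary_without_flow_or_noise(self):
        cell = _cell([3e-6, 3e-6, 8e-6], [1, 0, 0])
        rng = np.random.default_rng(0)
        out = step_cell(cell, None, COLD, 1e-6, rng)
        assert np.allclose(out.r1, cell.r1, atol=1e-18)
        assert np.allclose(out.r2, cell.r2, atol=1e-18)

    def test_rigid_advection_in_uniform_flow(self):
        u = np.array([2e-4, 0.0, -1e-4])
        flow = lambda pts: np.tile(u, (len(pts), 1))
        cell = _cell([3e-6, 3e-6, 8e-6], [0, 1, 1])
        rng = np.random.default_rng(0)
        dt = 1e-6
        out = cell
        for _ in range(100):
            out = step_cell(out, flow, COLD, dt, rng)
        assert np.allclose(out.center, cell.center + u * 100 * dt, rtol=1e-9)
        assert out.bond_length == pytest.approx(cell.bond_length, rel=1e-9)

    def test_bond_length_rms_below_one_percent(self):
        params = CellParameters()
        cell = _cell([3e-6, 3e-6, 8e-6], [1, 1, 0], params)
        rng = np.random.default_rng(42)
        lengths = np.empty(10_000)
        out = cell
        for i in range(10_000):
            out = step_cell(out, None, ROOM, 1e-6, rng)
            lengths[i] = out.bond_length
        rms = math.sqrt(np.mean((lengths - params.rest_length) ** 2))
        assert rms < 0.01 * params.rest_length

    def test_unstable_dt_rejected(self):
        cell = _cell([3e-6, 3e-6, 8e-6], [1, 0, 0])
        with pytest.raises(ValueError, match="unstable"):
            step_cell(cell, None, ROOM, 1e-3, np.random.default_rng(0))


class TestClassifyContact:
    def test_bead_on_tip_apex_is_end(self):
        x0 = _first_tip_center()
        a = CellParameters().bead_radius
        # vertical cell standing on the tip top: lower cap tangent to the apex
        center = [x0, x0, TIPS.tip_length + a + CellParameters().rest_length / 2 + 2e-9]
        cell = _cell(center, [0, 0, 1])
        cls, sub = classify_contact(cell, TIPS)
        assert cls == "end"
        assert 1 <= sub <= 6

    def test_stick_across_tip_apex_is_middle(self):
        x0 = _first_tip_center()
        a = CellParameters().bead_radius
        # horizontal cell resting across the apex, beads clear of the tip
        center = [x0, x0, TIPS.tip_length + a + 2e-9]
        cell = _cell(center, [1, 0, 0])
        cls, sub = classify_contact(cell, TIPS)
        assert cls == "middle"
        assert sub in (7, 8)

    def test_far_cell_is_none(self):
        cell = _cell([3e-6, 3e-6, TIPS.tip_length + 10e-6], [1, 0, 0])
        assert classify_contact(cell, TIPS) == ("none", 0)

    def test_bead_on_tip_side_is_end(self):
        x0 = _first_tip_center()
        r_tip = TIPS.tip_diameter / 2
        a = CellParameters().bead_radius
        half = CellParameters().rest_length / 2
        # horizontal cell pointing at the tip shaft midway up
        center = [x0 - r_tip - a - half - 2e-9, x0, TIPS.tip_length / 2]
        cell = _cell(center, [1, 0, 0])
        cls, sub = classify_contact(cell, TIPS)
        assert cls == "end"

    def test_invalid_threshold(self):
        cell = _cell([3e-6, 3e-6, 8e-6], [1, 0, 0])
        with pytest.raises(ValueError):
            classify_contact(cell, TIPS, threshold=0.0)


class TestSimulation:
    def _uniform_flow(self, speed=5.5e-4, angle=45.0):
        th = math.radians(angle)
        u = np.array([speed * math.cos(th), 0.0, -speed * math.sin(th)])
        return lambda pts: np.tile(u, (len(pts), 1))

    def test_deterministic_event_list_for_fixed_seed(self):
        flow = self._uniform_flow()
        a = simulate_contacts(flow, TIPS, n_cells=12, seed=5, max_time=0.01)
        b = simulate_contacts(flow, TIPS, n_cells=12, seed=5, max_time=0.01)
        assert a == b

    def test_every_cell_yields_one_event(self):
        flow = self._uniform_flow()
        events = simulate_contacts(flow, TIPS, n_cells=25, seed=1, max_time=0.01)
        assert len(events) == 25
        assert sorted(e.cell_id for e in events) == list(range(25))

    def test_no_tips_in_reach_means_no_contacts(self):
        """Cells released far above short tips in a lofted domain never touch."""
        flow = lambda pts: np.tile([5.5e-4, 0.0, 0.0], (len(pts), 1))
        events = simulate_contacts(
            flow, TIPS, n_cells=10, seed=2, max_time=2e-3,
            domain_extent=(7e-6, 7e-6, 40e-6), release_height=30e-6,
        )
        assert all(e.contact_class == "none" for e in events)
        with pytest.raises(ValueError, match="no tip contacts"):
            contact_statistics(events)

    @pytest.mark.parametrize("rest_length_um", [0.5, 0.625, 0.75])
    def test_end_exceeds_middle_for_elongated_cells(self, rest_length_um):
        """Geometric capture favours the polar caps for moderately elongated
        rods (aspect ratios around the 0.5 x 1 um bench cell); at much higher
        aspect the growing lateral surface takes over."""
        params = CellParameters(rest_length=rest_length_um * 1e-6)
        flow = self._uniform_flow()
        events = simulate_contacts(
            flow, TIPS, n_cells=120, seed=3, params=params, max_time=0.02
        )
        stats = contact_statistics(events)
        assert stats["end_fraction"] > stats["middle_fraction"]

    def test_zero_temperature_reproducible(self):
        flow = self._uniform_flow()
        a = simulate_contacts(flow, TIPS, n_cells=8, seed=1, constants=COLD, max_time=5e-3)
        b = simulate_contacts(flow, TIPS, n_cells=8, seed=1, constants=COLD, max_time=5e-3)
        assert a == b


class TestStatistics:
    def _event(self, i, cls, sub):
        return ContactEvent(i, 1e-3, 0, cls, sub, (0.0, 0.0, 0.0), "tip")

    def test_all_end_gives_unit_fraction(self):
        events = [self._event(i, "end", 1) for i in range(10)]
        stats = contact_statistics(events)
        assert stats["end_fraction"] == 1.0
        assert stats["middle_fraction"] == 0.0

    def test_57_43_split(self):
        events = [self._event(i, "end", 1) for i in range(57)]
        events += [self._event(100 + i, "middle", 7) for i in range(43)]
        stats = contact_statistics(events)
        assert stats["end_fraction"] == pytest.approx(0.57)
        assert stats["middle_fraction"] == pytest.approx(0.43)

    def test_fractions_always_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_end = int(rng.integers(0, 30))
            n_mid = int(rng.integers(0, 30))
            if n_end + n_mid == 0:
                continue
            events = [self._event(i, "end", 1) for i in range(n_end)]
            events += [self._event(50 + i, "middle", 7) for i in range(n_mid)]
            stats = contact_statistics(events)
            assert stats["end_fraction"] + stats["middle_fraction"] == pytest.approx(1.0)

    def test_subtype_maps_to_class(self):
        for e in [self._event(0, "end", s) for s in range(1, 7)]:
            assert e.subtype <= 6
        for e in [self._event(0, "middle", s) for s in (7, 8)]:
            assert e.subtype >= 7
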