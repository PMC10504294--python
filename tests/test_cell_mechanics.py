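"""Indentation models, modulus fitting, puncture detection and rupture stresses."""

import math

import numpy as np
import pytest
from scipy.integrate import simpson

from nanotear.cell_mechanics import (
    CRITICAL_STRESS,
    ForceCurve,
    IndentationModel,
    collision_stress,
    detect_puncture,
    fit_modulus,
    indentation_force,
    kinetic_energy,
    rupture_verdict,
    spherocylinder_volume,
    stokes_drag_force,
    tearing_stress,
)
from nanotear.synthetic_data import generate_force_curve

SNEDDON = IndentationModel("sneddon_cone", half_opening_angle=30.0)
HERTZ = IndentationModel("hertz_sphere", tip_radius=40e-9)


class TestIndentationForce:
    def test_zero_indentation_zero_force(self):
        assert indentation_force(SNEDDON, 0.5e6, 0.0) == 0.0
        assert indentation_force(HERTZ, 0.5e6, 0.0) == 0.0

    def test_sneddon_power_law(self):
        f1 = indentation_force(SNEDDON, 0.5e6, 40e-9)
        f2 = indentation_force(SNEDDON, 0.5e6, 80e-9)
        assert f2 == pytest.approx(4.0 * f1, rel=1e-12)

    def test_closed_form_matches_quadrature(self):
        """F(delta) equals the integral of its own stiffness dF/d(delta)."""
        e, d_max = 0.5e6, 85e-9
        for model in (SNEDDON, HERTZ):
            deltas = np.linspace(0.0, d_max, 4001)
            eps = d_max * 1e-7
            dfd = (
                indentation_force(model, e, deltas + eps)
                - indentation_force(model, e, np.maximum(deltas - eps, 0.0))
            ) / (eps + np.minimum(deltas, eps))
            integral = simpson(dfd, x=deltas)
            assert integral == pytest.approx(
                indentation_force(model, e, d_max), rel=1e-3
            )

    def test_negative_indentation_rejected(self):
        with pytest.raises(ValueError):
            indentation_force(SNEDDON, 0.5e6, -1e-9)

    def test_model_parameter_validation(self):
        with pytest.raises(ValueError):
            IndentationModel("sneddon_cone")  # missing angle
        with pytest.raises(ValueError):
            IndentationModel("hertz_sphere", tip_radius=-1.0)
        with pytest.raises(ValueError):
            IndentationModel("sneddon_cone", half_opening_angle=30, poisson_ratio=0.7)


class TestFitModulus:
    @pytest.mark.parametrize("model", [SNEDDON, HERTZ], ids=["sneddon", "hertz"])
    @pytest.mark.parametrize("modulus", [0.1e6, 0.5e6, 3.0e6])
    def test_zero_noise_round_trip(self, model, modulus):
        curve = generate_force_curve(model, modulus, 100e-9, noise_sd=0.0)
        fit = fit_modulus(curve, model)
        assert fit.youngs_modulus == pytest.approx(modulus, rel=1e-6)

    def test_noisy_recovery_median_within_10_percent(self):
        modulus = 0.5e6
        f_max = indentation_force(SNEDDON, modulus, 100e-9)
        recovered = []
        for seed in range(100):
            curve = generate_force_curve(
                SNEDDON, modulus, 100e-9, noise_sd=0.05 * f_max, seed=seed
            )
            recovered.append(fit_modulus(curve, SNEDDON).youngs_modulus)
        assert abs(np.median(recovered) / modulus - 1.0) < 0.10

    def test_model_mismatch_inflates_residual(self):
        curve = generate_force_curve(HERTZ, 0.5e6, 100e-9, noise_sd=0.0)
        good = fit_modulus(curve, HERTZ)
        bad = fit_modulus(curve, SNEDDON)
        assert bad.rms_residual > 10.0 * max(good.rms_residual, 1e-30)

    def test_retract_branch_rejected(self):
        d = np.linspace(0, 1e-7, 10)
        curve = ForceCurve(d, d * 1e-2, branch="retract")
        with pytest.raises(ValueError):
            fit_modulus(curve, SNEDDON)


class TestDetectPuncture:
    def test_monotone_curve_has_no_puncture(self):
        curve = generate_force_curve(SNEDDON, 0.5e6, 120e-9, noise_sd=0.0)
        assert detect_puncture(curve) is None

    def test_drop_located_within_one_sample(self):
        curve = generate_force_curve(
            SNEDDON, 0.5e6, 120e-9, puncture_depth=85e-9, noise_sd=0.0
        )
        spacing = curve.displacement[1] - curve.displacement[0]
        found = detect_puncture(curve, drop_threshold=0.1)
        assert found == pytest.approx(85e-9, abs=spacing)

    def test_zero_threshold_degenerates_to_first_decrease(self):
        d = np.linspace(0, 1e-7, 5)
        f = np.array([0.0, 2.0, 1.9, 2.5, 3.0])
        found = detect_puncture(ForceCurve(d, f), drop_threshold=0.0)
        assert found == pytest.approx(d[1])


class TestKineticEnergy:
    def test_zero_speed(self):
        assert kinetic_energy(0.5e-6, 1e-6, 1000.0, 0.0) == 0.0

    def test_near_wall_value_to_one_significant_figure(self):
        e_k = kinetic_energy(0.5e-6, 1e-6, 1000.0, 5e-5)
        assert 1.5e-25 <= e_k < 2.5e-25  # prints as 2e-25

    def test_sphere_limit(self):
        d = 0.8e-6
        e_k = kinetic_energy(d, d, 1200.0, 3e-5)
        m = 1200.0 * (4.0 / 3.0) * math.pi * (d / 2) ** 3
        assert e_k == pytest.approx(0.5 * m * (3e-5) ** 2, rel=1e-12)

    def test_volume_additivity(self):
        assert spherocylinder_volume(0.5e-6, 1e-6) == pytest.approx(
            math.pi * 0.25e-6**2 * 0.5e-6 + (4 / 3) * math.pi * 0.25e-6**3
        )


class TestStokesDrag:
    def test_paper_operating_point(self):
        assert stokes_drag_force(1e-6, 1e-3, 5e-5) == pytest.approx(4.7e-13, rel=0.01)

    def test_half_micron_cell(self):
        assert stokes_drag_force(0.5e-6, 1e-3, 5e-5) == pytest.approx(2.36e-13, rel=0.01)

    def test_zero_speed(self):
        assert stokes_drag_force(1e-6, 1e-3, 0.0) == 0.0


class TestStressAssessment:
    def test_zero_energy_collision_is_intact(self):
        a = collision_stress(0.0, 0.5e6)
        assert a.max_stress == 0.0 and a.verdict == "intact"

    def test_collision_stress_monotone_in_energy(self):
        energies = np.logspace(-27, -22, 30)
        for form in ("end", "middle"):
            stresses = [
                collision_stress(e, 0.5e6, contact_form=form).max_stress
                for e in energies
            ]
            assert np.all(np.diff(stresses) >= 0)

    def test_collision_at_flow_energies_cannot_rupture(self):
        e_k = kinetic_energy(0.5e-6, 1e-6, 1000.0, 5e-5)
        for form in ("end", "middle"):
            a = collision_stress(e_k, 0.5e6, contact_form=form)
            assert a.verdict == "intact"
            assert a.max_stress < 0.1 * CRITICAL_STRESS

    def test_tearing_linear_in_drag(self):
        s1 = tearing_stress(2e-13).max_stress
        s2 = tearing_stress(4e-13).max_stress
        assert s2 == pytest.approx(2.0 * s1, rel=1e-12)
        assert tearing_stress(0.0).max_stress == 0.0

    def test_tearing_at_flow_drag_ruptures(self):
        drag = stokes_drag_force(1e-6, 1e-3, 5e-5)
        for form in ("end", "middle"):
            a = tearing_stress(drag, contact_form=form)
            assert a.verdict == "ruptured"
            assert a.max_stress >= CRITICAL_STRESS

    def test_verdict_tie_rule_is_inclusive(self):
        a = tearing_stress(1e-13)
        boundary = a.__class__(
            mode="tearing", contact_form="end", max_stress=CRITICAL_STRESS,
            critical_stress=CRITICAL_STRESS, verdict="ruptured",
        )
        assert rupture_verdict(boundary) == "ruptured"

    def test_mechanism_gap_spans_two_orders(self):
        e_k = kinetic_energy(0.5e-6, 1e-6, 1000.0, 5e-5)
        drag = stokes_drag_force(1e-6, 1e-3, 5e-5)
        worst_collision = max(
            collision_stress(e_k, 0.5e6, contact_form=f).max_stress
            for f in ("end", "middle")
        )
        best_tearing = min(
            tearing_stress(drag, contact_form=f).max_stress for f in ("end", "middle")
        )
        assert best_tearing / worst_collision >= 100.0
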