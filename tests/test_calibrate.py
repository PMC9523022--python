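"""Calibration chain: sensitivity, baseline, contact point, subtraction."""

import numpy as np
import pytest

from cellmech.calibrate import (
    DegenerateCurveError,
    correct_baseline,
    detect_contact_point,
    fit_sensitivity,
    prepare_curve,
    to_force_indentation,
)
from cellmech.synthetic import (
    AcquisitionProtocol,
    MechanicalGroundTruth,
    simulate_force_curve,
    simulate_reference_curve,
)


def _spacing(protocol):
    return (protocol.z_end - protocol.z_start) / (protocol.n_samples - 1)


class TestSensitivity:
    def test_meter_unit_reference(self, rigid_reference):
        cal = fit_sensitivity(rigid_reference)
        assert cal.sensitivity == 1.0
        assert cal.residual_rms < 1e-12

    def test_volt_unit_reference_recovers_sensitivity(self, protocol_volts):
        ref = simulate_reference_curve(protocol_volts, contact_point=5e-6)
        cal = fit_sensitivity(ref)
        assert cal.sensitivity == pytest.approx(40e-9, rel=1e-9)

    def test_flat_curve_raises(self, protocol):
        ref = simulate_reference_curve(protocol, contact_point=5e-6)
        flat = ref.with_deflection(np.zeros(len(ref)))
        with pytest.raises(DegenerateCurveError):
            fit_sensitivity(flat)


class TestBaseline:
    def test_known_tilt_recovered(self, protocol):
        truth = MechanicalGroundTruth(
            modulus_shallow=2400.0, baseline_offset=25e-9, baseline_slope=3e-4
        )
        curve = simulate_force_curve(truth, protocol)
        corrected = correct_baseline(curve)
        offset, slope = corrected.baseline
        assert slope == pytest.approx(3e-4, rel=1e-9)
        assert offset == pytest.approx(25e-9, rel=1e-9)
        pre = corrected.z < truth.contact_point - 0.5e-6
        assert np.max(np.abs(corrected.deflection[pre])) < 1e-12

    def test_idempotent_on_flat_curve(self, clean_curve):
        once = correct_baseline(clean_curve)
        twice = correct_baseline(once)
        np.testing.assert_allclose(
            once.deflection, twice.deflection, atol=1e-12 * 1e-6
        )

    def test_short_precontact_rejected(self, protocol):
        truth = MechanicalGroundTruth(modulus_shallow=2400.0, contact_point=1e-6)
        curve = simulate_force_curve(truth, protocol)
        with pytest.raises(ValueError, match="pre-contact region too short"):
            correct_baseline(curve)


class TestContactPoint:
    def test_noise_free_within_one_sample(self, protocol):
        for e in (500.0, 1000.0, 2400.0, 5000.0):
            truth = MechanicalGroundTruth(modulus_shallow=e)
            curve = correct_baseline(simulate_force_curve(truth, protocol))
            z0 = detect_contact_point(curve)
            assert abs(z0 - truth.contact_point) < _spacing(protocol)

    def test_flat_curve_degenerate(self, protocol):
        z = protocol.z_grid()
        from cellmech.curves import ForceCurve

        flat = ForceCurve(z=z, deflection=np.zeros_like(z))
        with pytest.raises(DegenerateCurveError):
            detect_contact_point(flat)

    def test_order_invariance_noise_free(self, protocol):
        """Baseline-then-detect equals detect on pre-corrected data."""
        truth = MechanicalGroundTruth(
            modulus_shallow=2400.0, baseline_offset=10e-9, baseline_slope=2e-4
        )
        tilted = simulate_force_curve(truth, protocol)
        pristine = simulate_force_curve(
            MechanicalGroundTruth(modulus_shallow=2400.0), protocol
        )
        z0_a = detect_contact_point(correct_baseline(tilted))
        pristine.baseline = (0.0, 0.0)
        z0_b = detect_contact_point(pristine)
        assert z0_a == pytest.approx(z0_b, abs=1e-12)

    def test_rigid_kink_exact_with_linear_model(self, protocol):
        ref = simulate_reference_curve(protocol, contact_point=5e-6)
        ref.baseline = (0.0, 0.0)
        z0 = detect_contact_point(ref, exponent=1)
        assert z0 == ref.z[ref.deflection == 0].max()  # bit-exact on the grid


class TestForceIndentation:
    def test_rigid_substrate_identity(self, rigid_reference):
        """Calibration subtraction of the reference yields zero indentation."""
        cal = fit_sensitivity(rigid_reference)
        curve = correct_baseline(rigid_reference, min_pre_fraction=0.05)
        ic = to_force_indentation(
            curve, cal=cal, contact_point=cal.reference_contact_point
        )
        past = ic.delta[1:]  # strictly past the kink sample
        assert np.max(np.abs(past)) < 1e-12

    def test_delta_plus_deflection_identity(self, clean_curve, homogeneous_truth):
        """delta + d = z - z0 holds exactly at every retained sample."""
        curve = correct_baseline(clean_curve)
        z0 = homogeneous_truth.contact_point
        ic = to_force_indentation(curve, contact_point=z0)
        d = ic.force / ic.spring_constant
        z_past = curve.z[curve.z >= z0]
        np.testing.assert_allclose(ic.delta + d, z_past - z0, rtol=0, atol=1e-20)

    def test_noise_free_pairs_satisfy_contact_law(
        self, clean_curve, homogeneous_truth, protocol
    ):
        import math

        curve = correct_baseline(clean_curve)
        ic = to_force_indentation(curve, contact_point=homogeneous_truth.contact_point)
        sel = ic.delta > 1e-10
        e = ic.force[sel] * math.pi * (1 - 0.25) / (
            2 * math.tan(protocol.half_angle) * ic.delta[sel] ** 2
        )
        np.testing.assert_allclose(e, 2400.0, rtol=1e-9)

    def test_volt_curve_requires_sensitivity(self, protocol_volts):
        truth = MechanicalGroundTruth(modulus_shallow=2400.0)
        curve = simulate_force_curve(truth, protocol_volts)
        curve = curve.with_deflection(curve.deflection, sensitivity=None)
        curve.baseline = (0.0, 0.0)
        with pytest.raises(ValueError, match="sensitivity"):
            to_force_indentation(curve, contact_point=truth.contact_point)

    def test_volt_curve_with_calibration(self, protocol_volts):
        """Volt curve + measured sensitivity reproduces the meter-curve fit."""
        truth = MechanicalGroundTruth(modulus_shallow=2400.0)
        ref = simulate_reference_curve(protocol_volts, contact_point=5e-6)
        cal = fit_sensitivity(ref)
        curve = correct_baseline(simulate_force_curve(truth, protocol_volts))
        ic = to_force_indentation(curve, cal=cal, contact_point=truth.contact_point)
        from cellmech.hertz import fit_modulus

        est = fit_modulus(ic, 400e-9)
        assert est.modulus == pytest.approx(2400.0, rel=1e-6)


def test_prepare_curve_noisy_contact_recovery(protocol):
    """Median contact error stays below one sample spacing at 2 nm noise."""
    errs = []
    for i in range(25):
        truth = MechanicalGroundTruth(
            modulus_shallow=1000.0,
            noise_sd=2e-9,
            seed=100 + i,
            baseline_offset=5e-9,
            baseline_slope=1e-4,
        )
        _, z0 = prepare_curve(simulate_force_curve(truth, protocol))
        errs.append(abs(z0 - truth.contact_point))
    assert np.median(errs) < _spacing(protocol)
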