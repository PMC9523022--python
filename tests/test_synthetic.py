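"""Generator correctness: the synthetic curves must *be* their own oracle."""

import math

import numpy as np
import pytest

from cellmech.synthetic import (
    AcquisitionProtocol,
    GroupSpec,
    MechanicalGroundTruth,
    cone_prefactor,
    draw_cell_moduli,
    effective_modulus,
    hertz_force,
    simulate_cell_population,
    simulate_force_curve,
    simulate_mask_pair,
    simulate_plate,
    simulate_reference_curve,
)

# hand-substitution of the cone contact law: E=2400 Pa, alpha=36 deg, mu=0.5
# F(400 nm) = (2*tan 36 / pi) * 2400/0.75 * (4e-7)^2 = 2.368160454626e-10 N
F_ORACLE_400NM = 2.368160454626e-10


def test_cone_law_matches_hand_substitution():
    truth = MechanicalGroundTruth(modulus_shallow=2400.0)
    f = hertz_force(400e-9, truth, math.radians(36.0), 0.5)
    assert f == pytest.approx(F_ORACLE_400NM, rel=1e-11)


def test_force_zero_at_contact():
    truth = MechanicalGroundTruth(modulus_shallow=2400.0)
    assert hertz_force(0.0, truth, math.radians(36.0), 0.5) == 0.0


def test_generated_curve_satisfies_contact_law(clean_curve, homogeneous_truth, protocol):
    """At every sampled point past contact, k*d equals F(delta) exactly."""
    z0 = homogeneous_truth.contact_point
    past = clean_curve.z > z0
    d = clean_curve.deflection[past]
    delta = (clean_curve.z[past] - z0) - d
    f_expected = hertz_force(delta, homogeneous_truth, protocol.half_angle, protocol.poisson)
    np.testing.assert_allclose(protocol.spring_constant * d, f_expected, rtol=1e-12)


@pytest.mark.parametrize("e_shallow,e_deep", [(2400.0, 1200.0), (1200.0, 2400.0)])
def test_compliance_coupling_consistency_two_layer(e_shallow, e_deep, protocol):
    """Re-solving the contact law per point reproduces the secant modulus.

    For noise-free curves, E from the closed-form quadratic at each sample
    must match effective_modulus(delta) to 1e-9 relative.
    """
    truth = MechanicalGroundTruth(
        modulus_shallow=e_shallow, modulus_deep=e_deep, transition_depth=600e-9
    )
    curve = simulate_force_curve(truth, protocol)
    z0 = truth.contact_point
    past = curve.z > z0
    d = curve.deflection[past]
    delta = (curve.z[past] - z0) - d
    ok = delta > 1e-12
    f = protocol.spring_constant * d[ok]
    # invert F = (2 tan a/pi) * E_sec/(1-mu^2) * delta^2 per point
    e_solved = f * math.pi * (1 - protocol.poisson**2) / (
        2 * math.tan(protocol.half_angle) * delta[ok] ** 2
    )
    e_expected = np.array([effective_modulus(truth, dd) for dd in delta[ok]])
    np.testing.assert_allclose(e_solved, e_expected, rtol=1e-9)


def test_deflection_monotonic_past_contact(protocol):
    for truth in (
        MechanicalGroundTruth(modulus_shallow=500.0),
        MechanicalGroundTruth(modulus_shallow=5000.0, modulus_deep=500.0),
        MechanicalGroundTruth(modulus_shallow=500.0, modulus_deep=5000.0),
    ):
        curve = simulate_force_curve(truth, protocol)
        past = curve.z > truth.contact_point
        assert np.all(np.diff(curve.deflection[past]) >= 0)


def test_sampling_density_independence(homogeneous_truth):
    """Doubling n_samples must not change noise-free deflection at shared z."""
    p1 = AcquisitionProtocol(n_samples=256)
    p2 = AcquisitionProtocol(n_samples=511)  # shares every other grid point
    c1 = simulate_force_curve(homogeneous_truth, p1)
    c2 = simulate_force_curve(homogeneous_truth, p2)
    np.testing.assert_allclose(c1.deflection, c2.deflection[::2], rtol=1e-12, atol=0)


def test_seed_determinism(protocol):
    truth = MechanicalGroundTruth(modulus_shallow=1000.0, noise_sd=2e-9, seed=7)
    c1 = simulate_force_curve(truth, protocol)
    c2 = simulate_force_curve(truth, protocol)
    np.testing.assert_array_equal(c1.deflection, c2.deflection)


def test_no_contact_region_rejected(protocol):
    truth = MechanicalGroundTruth(modulus_shallow=1000.0, contact_point=20e-6)
    with pytest.raises(ValueError, match="no contact region"):
        simulate_force_curve(truth, protocol)
    with pytest.raises(ValueError, match="no contact region"):
        simulate_reference_curve(protocol, contact_point=20e-6)


def test_baseline_and_volts(protocol_volts):
    truth = MechanicalGroundTruth(
        modulus_shallow=1000.0, baseline_offset=10e-9, baseline_slope=1e-4
    )
    curve = simulate_force_curve(truth, protocol_volts)
    assert curve.unit == "V"
    # pre-contact deflection in volts = baseline(z)/sensitivity, noise-free
    pre = curve.z < truth.contact_point - 1e-7
    expected = (10e-9 + 1e-4 * curve.z[pre]) / 40e-9
    np.testing.assert_allclose(curve.deflection[pre], expected, rtol=1e-12)


class TestReferenceCurve:
    def test_unit_slope_in_meters(self, rigid_reference):
        z0 = 5e-6
        past = rigid_reference.z > z0 + 1e-9
        slope = np.polyfit(rigid_reference.z[past], rigid_reference.deflection[past], 1)[0]
        assert slope == pytest.approx(1.0, rel=1e-12)

    def test_slope_is_inverse_sensitivity_in_volts(self, protocol_volts):
        ref = simulate_reference_curve(protocol_volts, contact_point=5e-6)
        past = ref.z > 5e-6 + 1e-9
        slope = np.polyfit(ref.z[past], ref.deflection[past], 1)[0]
        assert slope == pytest.approx(1.0 / 40e-9, rel=1e-12)

    def test_contact_point_snaps_to_grid(self, protocol):
        requested = 5.0001e-6
        ref = simulate_reference_curve(protocol, contact_point=requested)
        z0 = ref.z[ref.deflection == 0].max()  # recorded kink position
        spacing = (protocol.z_end - protocol.z_start) / (protocol.n_samples - 1)
        assert abs(z0 - requested) <= spacing / 2
        np.testing.assert_array_equal(ref.deflection, np.clip(ref.z - z0, 0, None))


class TestCellPopulation:
    def test_population_shape_and_truth_table(self, protocol):
        spec = GroupSpec(label="ctrl", mean_modulus=2400.0, sd_modulus=1310.0)
        cs, truth = simulate_cell_population(spec, n_cells=3, protocol=protocol, seed=5)
        assert len(cs.curves) == 3 * 36
        assert cs.reference is not None
        assert set(truth["cell_id"]) == {f"ctrl_cell{i:03d}" for i in range(3)}
        # zero within-cell variation: all 36 curves share the cell modulus
        for _, sub in truth.groupby("cell_id"):
            assert sub["point_modulus_pa"].nunique() == 1
            assert len(sub) == 36

    def test_seed_extensibility(self, protocol):
        """Adding cells never reshuffles previously generated ones."""
        spec = GroupSpec(label="g", mean_modulus=2000.0, sd_modulus=500.0)
        _, t3 = simulate_cell_population(spec, n_cells=3, protocol=protocol, seed=9)
        _, t5 = simulate_cell_population(spec, n_cells=5, protocol=protocol, seed=9)
        m3 = t3.groupby("cell_id")["cell_modulus_pa"].first()
        m5 = t5.groupby("cell_id")["cell_modulus_pa"].first()
        for cid in m3.index:
            assert m5[cid] == m3[cid]

    def test_lognormal_moments(self, rng):
        x = draw_cell_moduli(2400.0, 1310.0, 200_000, rng)
        assert np.all(x > 0)
        assert np.mean(x) == pytest.approx(2400.0, rel=0.02)
        assert np.std(x) == pytest.approx(1310.0, rel=0.03)


class TestMaskPair:
    def test_exact_areas_and_count(self):
        cell, nuc, truth = simulate_mask_pair(n_cells=4, cell_radius_px=15, seed=3)
        assert truth.n_cells == 4
        assert int(cell.sum()) == truth.total_cell_area_px
        assert int(nuc.sum()) == truth.total_nucleus_area_px
        # identical disks: every per-cell area equal
        assert len(set(truth.cell_areas_px)) == 1

    def test_nucleus_ratio_near_radius_squared(self):
        _, _, truth = simulate_mask_pair(
            n_cells=5, cell_radius_px=25, nucleus_fraction=0.5, seed=4
        )
        ratio = truth.total_nucleus_area_px / truth.total_cell_area_px
        assert ratio == pytest.approx(0.25, abs=0.01)  # rasterization tolerance

    def test_empty(self):
        cell, nuc, truth = simulate_mask_pair(n_cells=0)
        assert truth.n_cells == 0 and cell.sum() == 0 and nuc.sum() == 0

    def test_overcrowded_raises(self):
        with pytest.raises(RuntimeError, match="could not place"):
            simulate_mask_pair(n_cells=50, cell_radius_px=60, image_shape=(256, 256))


class TestPlate:
    def test_noise_free_equals_means(self):
        plate = simulate_plate({"control": 1.0, "ogd": 0.7}, noise_sd=0.0, replicates=12)
        assert len(plate) == 24
        for cond, mean in (("control", 1.0), ("ogd", 0.7)):
            assert (plate.loc[plate.condition == cond, "od"] == mean).all()

    def test_seed_determinism(self):
        p1 = simulate_plate({"a": 1.0}, noise_sd=0.1, seed=2)
        p2 = simulate_plate({"a": 1.0}, noise_sd=0.1, seed=2)
        assert (p1["od"] == p2["od"]).all()

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_plate({"a": 1.0}, noise_sd=-0.1)
        with pytest.raises(ValueError):
            simulate_plate({"a": -1.0})
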