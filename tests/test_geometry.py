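"""Superposition, symmetry-axis detection and blade-geometry parameters."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bladekit.geometry import (
    AsymmetryError,
    BladeSet,
    ReferencePoints,
    assign_reference_points,
    blade_rmsd_matrix,
    chord_from_radius,
    compute_blade_geometry,
    detect_symmetry_frame,
    kabsch_superpose,
    regress_vs_blade_number,
    rotation_axis_angle,
    signed_dihedral,
)
from bladekit.reference import (
    PROPELLER_GEOMETRY,
    RADIUS_REGRESSION_SET,
    geometry_series,
)
from bladekit.simulate import (
    PropellerSimParams,
    gen_ideal_propeller,
    marker_offsets,
    random_rotation,
)


def pipeline_geometry(params: PropellerSimParams):
    model, blades, _, truth = gen_ideal_propeller(params)
    frame = detect_symmetry_frame(model, blades)
    refs = assign_reference_points(model, blades, marker_offsets(params))
    return compute_blade_geometry(refs, frame), frame, truth


class TestKabsch:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0, atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_rotation(self, rng):
        pts = rng.normal(size=(12, 3))
        R0 = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        t0 = np.array([1.0, -2.0, 3.0])
        R, t, rmsd = kabsch_superpose(pts, pts @ R0.T + t0)
        assert np.allclose(R, R0, atol=1e-9)
        assert np.allclose(t, t0, atol=1e-9)
        assert rmsd < 1e-9

    def test_mirror_gives_proper_rotation_with_residual(self):
        tetra = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        mirrored = tetra * np.array([1, 1, -1.0])
        R, _, rmsd = kabsch_superpose(tetra, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert rmsd > 0.1

    def test_agrees_with_scipy_align_vectors(self, rng):
        # independent oracle for the optimal proper rotation
        a = rng.normal(size=(8, 3))
        b = a @ Rotation.random(random_state=7).as_matrix().T + rng.normal(size=3)
        b += rng.normal(scale=0.05, size=b.shape)
        R, _, rmsd = kabsch_superpose(a, b)
        rot, _ = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert np.allclose(R, rot.as_matrix(), atol=1e-6)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(np.linalg.LinAlgError):
            kabsch_superpose(line, line + [0, 1, 0])


class TestSymmetryFrame:
    def test_ideal_sevenfold_axis_and_angle(self):
        _, frame, _ = pipeline_geometry(PropellerSimParams(n=7))
        assert abs(frame.axis_dir @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert frame.alpha_per_blade == pytest.approx(360 / 7, abs=1e-9)

    def test_fourfold_square(self):
        _, frame, _ = pipeline_geometry(PropellerSimParams(n=4))
        assert frame.alpha_per_blade == pytest.approx(90.0, abs=1e-9)

    def test_axis_equivariant_under_rigid_motion(self, rng):
        R0 = random_rotation(rng)
        t0 = rng.normal(scale=20, size=3)
        base = PropellerSimParams(n=7)
        posed = PropellerSimParams(n=7, rotation=R0, translation=t0)
        _, f0, _ = pipeline_geometry(base)
        _, f1, _ = pipeline_geometry(posed)
        assert abs(f1.axis_dir @ (R0 @ f0.axis_dir)) == pytest.approx(1.0, abs=1e-9)
        # axis point transforms onto the same line
        d = (R0 @ f0.axis_point + t0) - f1.axis_point
        d -= (d @ f1.axis_dir) * f1.axis_dir
        assert np.linalg.norm(d) == pytest.approx(0.0, abs=1e-6)

    def test_asymmetric_structure_rejected(self, rng):
        model, blades, _, _ = gen_ideal_propeller(
            PropellerSimParams(n=4, noise_sd=3.0, seed=5))
        with pytest.raises(AsymmetryError):
            detect_symmetry_frame(model, blades, max_axis_spread_deg=5.0)

    def test_rotation_axis_angle_roundtrip(self):
        R = Rotation.from_rotvec(np.radians(40) * np.array([0, 0, 1.0])).as_matrix()
        axis, angle = rotation_axis_angle(R)
        assert angle == pytest.approx(40.0)
        assert np.allclose(axis, [0, 0, 1])


class TestReferencePoints:
    def test_offsets_select_expected_residues(self):
        params = PropellerSimParams(n=5, points_per_strand=6)
        model, blades, truth_refs, _ = gen_ideal_propeller(params)
        refs = assign_reference_points(model, blades, marker_offsets(params))
        for key in ("p1", "p2", "q1", "q2"):
            assert np.allclose(getattr(refs, key), getattr(truth_refs, key), atol=1e-12)

    def test_out_of_range_offset(self):
        model, blades, _, _ = gen_ideal_propeller(PropellerSimParams(n=5))
        with pytest.raises(ValueError, match="offset"):
            assign_reference_points(model, blades, (1, 2, 3, 99))


class TestBladeGeometry:
    def test_heptagonal_closed_form(self):
        """p1 on a radius-5 circle, p2 straight above: a=b=5, chords
        2*5*sin(pi/7), delta=beta=0, alpha=360/7."""
        params = PropellerSimParams(n=7, a=5.0, b=5.0, rise=3.0,
                                    rq1=12.0, rq2=12.0, q1_z=0.0, q2_z=3.0)
        g, frame, _ = pipeline_geometry(params)
        assert g.mean["a"] == pytest.approx(5.0, abs=1e-9)
        assert g.mean["b"] == pytest.approx(5.0, abs=1e-9)
        assert g.mean["c"] == pytest.approx(2 * 5 * math.sin(math.pi / 7), abs=1e-9)
        assert g.mean["c"] == pytest.approx(4.3388, abs=1e-4)
        assert g.mean["delta"] == pytest.approx(0.0, abs=1e-9)
        assert g.mean["beta"] == pytest.approx(0.0, abs=1e-9)
        assert g.mean["alpha"] == pytest.approx(51.4286, abs=1e-3)

    @pytest.mark.parametrize("params", [
        PropellerSimParams(n=9, a=8.34, b=12.96),
        PropellerSimParams(n=7, a=5.82, b=8.51, p2_azimuth_deg=10.0,
                           q1_azimuth_deg=-8.0, q2_azimuth_deg=6.0),
        PropellerSimParams(n=5, a=7.0, b=6.28, rise=4.0, q2_z=8.0),
    ])
    def test_generator_round_trip_recovers_truth(self, params):
        g, frame, truth = pipeline_geometry(params)
        for key in g.PARAMS:
            assert g.mean[key] == pytest.approx(truth.mean[key], abs=1e-6), key
        # chord identities on the recovered values
        assert g.mean["c"] == pytest.approx(chord_from_radius(g.mean["a"], params.n), abs=1e-9)
        assert g.mean["d"] == pytest.approx(chord_from_radius(g.mean["b"], params.n), abs=1e-9)

    def test_round_trip_invariant_under_pose(self, rng):
        base = PropellerSimParams(n=8, a=6.63, b=10.85)
        posed = PropellerSimParams(n=8, a=6.63, b=10.85,
                                   rotation=random_rotation(rng),
                                   translation=rng.normal(scale=30, size=3))
        g0, _, _ = pipeline_geometry(base)
        g1, _, _ = pipeline_geometry(posed)
        for key in g0.PARAMS:
            assert g1.mean[key] == pytest.approx(g0.mean[key], abs=1e-8), key

    def test_outer_chords_exceed_inner_for_larger_radii(self):
        g, _, _ = pipeline_geometry(PropellerSimParams(n=7))
        assert g.mean["e"] > g.mean["c"]
        assert g.mean["f"] > g.mean["d"]

    def test_degenerate_strand_vector_raises(self):
        pts = np.tile([[1.0, 0, 0]], (3, 1))
        refs = ReferencePoints(p1=pts, p2=pts.copy(), q1=pts + [1, 0, 0], q2=pts + [2, 0, 0])
        from bladekit.geometry import SymmetryFrame
        frame = SymmetryFrame(axis_point=np.zeros(3), axis_dir=np.array([0, 0, 1.0]),
                              alpha_per_blade=120.0, step_angles=np.full(3, 120.0))
        with pytest.raises(ValueError, match="degenerate"):
            compute_blade_geometry(refs, frame)


class TestBladeRmsd:
    def test_symmetric_blades_superpose_exactly(self):
        model, blades, _, _ = gen_ideal_propeller(PropellerSimParams(n=6))
        assert blade_rmsd_matrix(model, blades).max() == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_grows_monotonically_with_noise(self):
        means = []
        for sd in (0.05, 0.2, 0.5):
            model, blades, _, _ = gen_ideal_propeller(
                PropellerSimParams(n=6, noise_sd=sd, seed=42))
            m = blade_rmsd_matrix(model, blades)
            means.append(m[np.triu_indices_from(m, 1)].mean())
        assert means[0] < means[1] < means[2]


class TestChord:
    def test_square(self):
        assert chord_from_radius(1.0, 4) == pytest.approx(math.sqrt(2))

    def test_hexagon_radius_equals_chord(self):
        # consistent with the reported Pizza6 inner radius/chord pair
        assert chord_from_radius(4.6, 6) == pytest.approx(4.6)

    def test_heptagon(self):
        assert chord_from_radius(5.0, 7) == pytest.approx(4.3388, abs=1e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            chord_from_radius(1.0, 2)


class TestRegression:
    def test_collinear_points(self):
        res = regress_vs_blade_number([1.0, 2.0, 3.0], [5, 6, 7])
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_channel_radius_vs_blade_number(self):
        """Inner radius a against n over the 6- to 9-bladed designer
        propellers correlates strongly (the published claim r^2 > 0.95)."""
        vals, ns, labels = geometry_series("a", RADIUS_REGRESSION_SET)
        res = regress_vs_blade_number(vals, ns, labels)
        assert res.r_squared == pytest.approx(0.9691, abs=1e-4)
        assert res.r_squared > 0.95

    def test_beta_twist_vs_blade_number_excluding_tako(self):
        vals, ns, labels = geometry_series("beta")
        res = regress_vs_blade_number(vals, ns, labels, exclude=("Tako8",))
        assert res.r_squared == pytest.approx(0.9623, abs=1e-4)
        assert res.r_squared > 0.95

    def test_beta_with_tako_is_weak(self):
        vals, ns, labels = geometry_series("beta")
        res = regress_vs_blade_number(vals, ns, labels)
        assert res.r_squared < 0.6

    def test_identical_n_rejected(self):
        with pytest.raises(ValueError, match="undefined slope"):
            regress_vs_blade_number([1.0, 2.0, 3.0], [7, 7, 7])

    def test_too_few_points_after_exclusion(self):
        with pytest.raises(ValueError, match=">= 3"):
            regress_vs_blade_number([1.0, 2.0, 3.0], [5, 6, 7],
                                    labels=["x", "y", "z"], exclude=("x",))


class TestDihedral:
    def test_right_handed_sign(self):
        # +60 degree twist about the x axis
        p0, p1, p2 = [0, 1, 0], [0, 0, 0], [1, 0, 0]
        p3 = [1, math.cos(math.radians(60)), math.sin(math.radians(60))]
        assert signed_dihedral(p0, p1, p2, p3) == pytest.approx(60.0)
        p3m = [1, math.cos(math.radians(60)), -math.sin(math.radians(60))]
        assert signed_dihedral(p0, p1, p2, p3m) == pytest.approx(-60.0)
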