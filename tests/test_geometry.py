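"""COM distances, Kabsch superposition (with a brute-force rotation-grid
oracle), and the complex-reference FMN–heme distance prediction."""

import numpy as np
import pytest

from cpranalysis.exceptions import DegenerateGeometryError, PairingError, ValidationError
from cpranalysis.geometry import (
    ComplexReference,
    RigidTransform,
    interdomain_distance,
    intercofactor_distance,
    kabsch_superpose,
    predict_fmn_heme_distance,
)
from cpranalysis.model_io import Structure, center_of_mass, resolve_selection
from cpranalysis.synthetic import (
    BeadModelSpec,
    REDUCED,
    bead_selections,
    build_bead_trajectory,
    build_complex_reference,
)


@pytest.fixture(scope="module")
def bead_frame():
    spec = BeadModelSpec(n_frames=2, jitter_sd=0.0, seed=9, random_pose=False)
    traj, _ = build_bead_trajectory(spec)
    return spec, traj


@pytest.fixture(scope="module")
def complex_ref():
    return build_complex_reference(BeadModelSpec(n_frames=2, seed=9))


class TestRigidTransform:
    def test_validates_orthogonality_and_handedness(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(ValidationError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # reflection

    def test_inverse_and_compose(self, random_rigid_transform, rng):
        rot, t = random_rigid_transform()
        tr = RigidTransform(rot, t)
        pts = rng.normal(size=(7, 3))
        np.testing.assert_allclose(tr.inverse().apply(tr.apply(pts)), pts, atol=1e-10)
        np.testing.assert_allclose(
            tr.compose(tr.inverse()).apply(pts), pts, atol=1e-10
        )


class TestDistances:
    def test_three_four_five_triangle(self, bead_frame):
        spec, traj = bead_frame
        # point selections: one atom per "domain"
        frame = Structure(
            traj.topology,
            np.vstack([np.zeros(3), [3.0, 4.0, 0.0]] * (traj.topology.n_atoms // 2))[
                : traj.topology.n_atoms
            ],
        )
        d = interdomain_distance(frame, np.array([0]), np.array([1]))
        assert d == pytest.approx(5.0)

    def test_identical_selection_gives_zero(self, bead_frame):
        _, traj = bead_frame
        f = traj.frame(0)
        sel = np.arange(5)
        assert interdomain_distance(f, sel, sel) == 0.0

    def test_rigid_transform_invariance(self, bead_frame, random_rigid_transform):
        spec, traj = bead_frame
        sels = bead_selections(spec)
        f = traj.frame(0)
        a = resolve_selection(f, sels["fad_domain"])
        b = resolve_selection(f, sels["fmn_domain"])
        d0 = interdomain_distance(f, a, b)
        for _ in range(3):
            rot, t = random_rigid_transform()
            assert interdomain_distance(f.transformed(rot, t), a, b) == pytest.approx(
                d0, abs=1e-9
            )

    def test_ring_distance_constructed_and_permutation_invariant(self, bead_frame):
        spec, traj = bead_frame
        sels = bead_selections(spec)
        f = traj.frame(0)
        fad = resolve_selection(f, sels["fad_ring"])
        fmn = resolve_selection(f, sels["fmn_ring"])
        assert intercofactor_distance(f, fad, fad) == 0.0
        d = intercofactor_distance(f, fad, fmn)
        # fixed-separation bead model: ring centers sit on the domain centers
        assert d == pytest.approx(spec.closed_separation, abs=1e-9)
        perm = np.random.default_rng(1).permutation(fmn)
        assert intercofactor_distance(f, fad, perm) == pytest.approx(d, abs=1e-12)
        assert intercofactor_distance(f, fmn, fad) == pytest.approx(d, abs=1e-12)

    def test_com_triangle_inequality(self, bead_frame):
        spec, traj = bead_frame
        sels = bead_selections(spec)
        f = traj.frame(0)
        a = resolve_selection(f, sels["fad_domain"])
        b = resolve_selection(f, sels["fmn_domain"])
        c = resolve_selection(f, sels["fmn_ring"])
        dab = interdomain_distance(f, a, b)
        dac = interdomain_distance(f, a, c)
        dbc = interdomain_distance(f, b, c)
        assert abs(dac - dbc) <= dab + 1e-12


class TestKabsch:
    def test_identical_sets_give_identity_and_zero_rmsd(self, rng):
        pts = rng.normal(size=(6, 3))
        tr, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(tr.translation, np.zeros(3), atol=1e-10)
        assert rmsd < 1e-10

    def test_recovers_known_rigid_transform(self, rng, random_rigid_transform):
        pts = rng.normal(size=(8, 3))
        rot, t = random_rigid_transform()
        tr, rmsd = kabsch_superpose(pts, pts @ rot.T + t)
        assert rmsd < 1e-8
        np.testing.assert_allclose(tr.rotation, rot, atol=1e-8)
        np.testing.assert_allclose(tr.translation, t, atol=1e-8)

    def test_agrees_with_scipy_align_vectors(self, rng):
        # independent library route as a cross-check of the SVD path
        from scipy.spatial.transform import Rotation

        mob = rng.normal(size=(10, 3))
        ref = rng.normal(size=(10, 3))
        tr, rmsd = kabsch_superpose(mob, ref)
        rot_sp, rssd = Rotation.align_vectors(ref - ref.mean(0), mob - mob.mean(0))
        np.testing.assert_allclose(tr.rotation, rot_sp.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(mob)), rel=1e-6)

    def test_mirror_image_keeps_proper_rotation_and_beats_grid(
        self, rng, rotation_grid_rmsd
    ):
        pts = rng.normal(size=(4, 3))
        mirror = pts * np.array([1.0, 1.0, -1.0])
        tr, rmsd = kabsch_superpose(pts, mirror)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-10)
        assert rmsd > 0.0
        assert rmsd <= rotation_grid_rmsd(pts, mirror, 5.0) + 1e-9

    def test_matches_brute_force_rotation_grid_on_random_sets(
        self, rotation_grid_rmsd
    ):
        gen = np.random.default_rng(17)
        for _ in range(3):
            mob = gen.normal(size=(5, 3))
            ref = gen.normal(size=(5, 3))
            _, rmsd = kabsch_superpose(mob, ref)
            grid = rotation_grid_rmsd(mob, ref, 5.0)
            assert rmsd <= grid + 1e-9
            # grid minimum within the angular discretization of the optimum
            r_max = np.linalg.norm(mob - mob.mean(0), axis=1).max()
            assert grid - rmsd <= np.deg2rad(5.0) * r_max

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestFMNHemePrediction:
    def _cpr_only_frame(self, ref: ComplexReference) -> Structure:
        keep = np.flatnonzero(ref.structure.topology.res_name != "HEM")
        return Structure(ref.structure.topology.subset(keep), ref.structure.coord[keep])

    def test_self_consistency_with_the_reference(self, complex_ref):
        frame = self._cpr_only_frame(complex_ref)
        d = predict_fmn_heme_distance(
            frame, complex_ref.fad_domain, complex_ref.fmn_ring, complex_ref
        )
        ref_fmn = center_of_mass(
            complex_ref.structure,
            resolve_selection(complex_ref.structure, complex_ref.fmn_ring),
        )
        expected = float(np.linalg.norm(ref_fmn - complex_ref.heme_com()))
        assert d == pytest.approx(expected, abs=1e-8)

    def test_invariance_under_rigid_transform_of_the_frame(
        self, complex_ref, random_rigid_transform
    ):
        frame = self._cpr_only_frame(complex_ref)
        d0 = predict_fmn_heme_distance(
            frame, complex_ref.fad_domain, complex_ref.fmn_ring, complex_ref
        )
        for _ in range(4):
            rot, t = random_rigid_transform()
            d = predict_fmn_heme_distance(
                frame.transformed(rot, t),
                complex_ref.fad_domain,
                complex_ref.fmn_ring,
                complex_ref,
            )
            assert d == pytest.approx(d0, abs=1e-8)

    def test_two_angstrom_shift_toward_heme_shortens_prediction_by_two(
        self, complex_ref
    ):
        frame = self._cpr_only_frame(complex_ref)
        top = frame.topology
        fmn_unit = np.flatnonzero((top.res_id >= 101) & (top.res_id <= 901) & (top.res_id != 900))
        fmn_ring_idx = resolve_selection(frame, complex_ref.fmn_ring)
        ring_com = center_of_mass(frame, fmn_ring_idx)
        axis = complex_ref.heme_com() - ring_com
        axis /= np.linalg.norm(axis)
        coords = frame.coord.copy()
        coords[fmn_unit] += 2.0 * axis
        shifted = Structure(top, coords)
        d_ref = predict_fmn_heme_distance(
            frame, complex_ref.fad_domain, complex_ref.fmn_ring, complex_ref
        )
        d_shift = predict_fmn_heme_distance(
            shifted, complex_ref.fad_domain, complex_ref.fmn_ring, complex_ref
        )
        assert d_shift == pytest.approx(d_ref - 2.0, abs=1e-8)

    def test_unmatched_pairing_raises_listing_missing_atoms(self, complex_ref):
        frame = self._cpr_only_frame(complex_ref)
        # truncate the FAD domain to 2 beads: pairing must fail
        keep = np.r_[np.arange(2), np.flatnonzero(frame.topology.res_id > 100)]
        broken = Structure(frame.topology.subset(keep), frame.coord[keep])
        with pytest.raises(PairingError, match="unmatched"):
            predict_fmn_heme_distance(
                broken, complex_ref.fad_domain, complex_ref.fmn_ring, complex_ref
            )

    def test_heme_must_sit_on_partner_chain(self, complex_ref):
        from dataclasses import replace
        from cpranalysis.model_io import SelectionSpec

        with pytest.raises(ValidationError, match="partner"):
            ComplexReference(
                complex_ref.structure,
                complex_ref.fad_domain,
                complex_ref.fmn_ring,
                SelectionSpec("heme", residue_names=frozenset({"FMN"})),  # same chain
            )
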