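"""Structure/trajectory IO, selections, masses, ΔV logs."""

import numpy as np
import pytest

from cpranalysis.exceptions import (
    PDBParseError,
    SelectionError,
    TopologyError,
    ValidationError,
)
from cpranalysis.model_io import (
    ALLOXAZINE_RING_ATOMS,
    SelectionSpec,
    Structure,
    Topology,
    Trajectory,
    center_of_mass,
    read_amd_log,
    read_deltav_log,
    read_pdb,
    resolve_selection,
    write_deltav_log,
    write_pdb,
)

SINGLE_MODEL = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       3.000   0.000   0.000  1.00  0.00           C
HETATM    4  N5  FMN A 901       0.000   2.000   0.000  1.00  0.00           N
HETATM    5 FE   HEM B   1       5.000   5.000   5.000  1.00  0.00          FE
"""

MULTI_MODEL = (
    "MODEL        1\n" + SINGLE_MODEL + "ENDMDL\n"
    "MODEL        2\n" + SINGLE_MODEL.replace("0.000   0.000   0.000", "0.000   0.000   1.000")
    + "ENDMDL\n"
    "MODEL        3\n" + SINGLE_MODEL + "ENDMDL\n"
)


@pytest.fixture
def single_pdb(tmp_path):
    p = tmp_path / "single.pdb"
    p.write_text(SINGLE_MODEL)
    return p


@pytest.fixture
def multi_pdb(tmp_path):
    p = tmp_path / "multi.pdb"
    p.write_text(MULTI_MODEL)
    return p


class TestReadPDB:
    def test_single_model_preserves_atom_count_and_heteros(self, single_pdb):
        s = read_pdb(single_pdb)
        assert isinstance(s, Structure)
        assert s.n_atoms == 5
        assert set(s.topology.res_name) == {"ALA", "FMN", "HEM"}
        # masses come from the element: Fe heavier than N heavier than C
        m = dict(zip(s.topology.atom_name, s.topology.mass))
        assert m["FE"] > m["N5"] > m["CA"]

    def test_multi_model_becomes_trajectory_with_shared_topology(self, multi_pdb):
        t = read_pdb(multi_pdb)
        assert isinstance(t, Trajectory)
        assert t.n_frames == 3 and t.topology.n_atoms == 5
        assert np.all(np.diff(t.times) > 0)
        assert t.coords[1, 0, 2] == pytest.approx(1.0)

    def test_model_missing_an_atom_is_a_topology_error(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        lines = SINGLE_MODEL.splitlines(keepends=True)
        bad.write_text(
            "MODEL        1\n" + SINGLE_MODEL + "ENDMDL\n"
            "MODEL        2\n" + "".join(lines[:-1]) + "ENDMDL\n"
        )
        with pytest.raises(TopologyError):
            read_pdb(bad)

    def test_malformed_record_raises_parse_error_naming_line(self, tmp_path):
        bad = tmp_path / "mal.pdb"
        bad.write_text(SINGLE_MODEL.replace("3.000", "x.000"))
        with pytest.raises(PDBParseError, match="line"):
            read_pdb(bad)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_pdb(tmp_path / "nope.pdb")


class TestRoundTrip:
    def test_write_read_preserves_names_ids_and_coords_to_3_decimals(self, tmp_path, rng):
        from cpranalysis.synthetic import BeadModelSpec, build_bead_trajectory

        traj, _ = build_bead_trajectory(BeadModelSpec(n_frames=3, seed=5))
        out = tmp_path / "traj.pdb"
        write_pdb(out, traj)
        back = read_pdb(out)
        assert isinstance(back, Trajectory)
        assert back.n_frames == traj.n_frames
        assert np.array_equal(back.topology.atom_name, traj.topology.atom_name)
        assert np.array_equal(back.topology.res_id, traj.topology.res_id)
        assert np.array_equal(back.topology.chain_id, traj.topology.chain_id)
        np.testing.assert_allclose(back.coords, traj.coords, atol=5.1e-4)

    def test_single_structure_roundtrip(self, tmp_path, single_pdb):
        s = read_pdb(single_pdb)
        out = tmp_path / "copy.pdb"
        write_pdb(out, s)
        s2 = read_pdb(out)
        np.testing.assert_allclose(s2.coord, s.coord, atol=5.1e-4)
        assert np.array_equal(s2.topology.res_name, s.topology.res_name)


class TestSelections:
    def test_match_all_is_identity(self, single_pdb):
        s = read_pdb(single_pdb)
        idx = resolve_selection(s, SelectionSpec("all"))
        assert np.array_equal(idx, np.arange(s.n_atoms))

    def test_residue_and_atom_name_filters_compose(self, single_pdb):
        s = read_pdb(single_pdb)
        idx = resolve_selection(
            s,
            SelectionSpec(
                "ring",
                residue_names=frozenset({"FMN"}),
                atom_names=frozenset(ALLOXAZINE_RING_ATOMS),
            ),
        )
        assert list(s.topology.atom_name[idx]) == ["N5"]

    def test_empty_selection_raises_naming_spec(self, single_pdb):
        s = read_pdb(single_pdb)
        with pytest.raises(SelectionError, match="nothing_here"):
            resolve_selection(s, SelectionSpec("nothing_here", residue_names=frozenset({"XYZ"})))

    def test_resolution_is_idempotent_and_field_order_free(self, single_pdb):
        s = read_pdb(single_pdb)
        a = SelectionSpec("d", residue_ranges=((1, 2),), atom_names=frozenset({"CA"}))
        b = SelectionSpec("d", atom_names=frozenset({"CA"}), residue_ranges=((1, 2),))
        ia = resolve_selection(s, a)
        assert np.array_equal(ia, resolve_selection(s, a))
        assert np.array_equal(ia, resolve_selection(s, b))

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(SelectionError, match="overlap"):
            SelectionSpec("bad", residue_ranges=((1, 10), (5, 20)))


class TestCenterOfMass:
    def _structure(self, coords, elements):
        n = len(coords)
        import biotite.structure.info as info

        top = Topology(
            atom_name=np.array([f"A{i}" for i in range(n)]),
            res_name=np.array(["ALA"] * n),
            res_id=np.arange(1, n + 1),
            chain_id=np.array(["A"] * n),
            element=np.array(elements),
            mass=np.array([info.mass(e) for e in elements]),
        )
        return Structure(top, np.asarray(coords, dtype=float))

    def test_equal_masses_give_midpoint(self):
        s = self._structure([[0, 0, 0], [2, 0, 0]], ["C", "C"])
        np.testing.assert_allclose(center_of_mass(s), [1, 0, 0])

    def test_weighted_mean_with_mass_ratio(self):
        # masses 12 and 3*12 at x=0 and x=4 -> COM at x=3
        s = self._structure([[0, 0, 0], [4, 0, 0]], ["C", "C"])
        object.__setattr__(s.topology, "mass", np.array([12.0, 36.0]))
        np.testing.assert_allclose(center_of_mass(s), [3, 0, 0])

    def test_single_atom_is_identity(self):
        s = self._structure([[1.0, 2.0, 3.0]], ["N"])
        np.testing.assert_allclose(center_of_mass(s), [1, 2, 3])

    def test_rigid_transform_equivariance(self, random_rigid_transform):
        s = self._structure(
            [[0, 0, 0], [2, 1, 0], [1, 3, 2], [-1, 0, 4]], ["C", "N", "O", "S"]
        )
        com = center_of_mass(s)
        for _ in range(5):
            rot, t = random_rigid_transform()
            moved = s.transformed(rot, t)
            np.testing.assert_allclose(center_of_mass(moved), rot @ com + t, atol=1e-10)


class TestDeltaVLog:
    def test_basic_series(self, tmp_path):
        p = tmp_path / "dv.log"
        p.write_text("# comment\n0 0.0\n1 1.5\n2 0.7\n")
        s = read_deltav_log(p)
        np.testing.assert_allclose(s.to_numpy(), [0.0, 1.5, 0.7])
        assert list(s.index) == [0, 1, 2]

    def test_dual_boost_columns_sum(self, tmp_path):
        p = tmp_path / "dv.log"
        p.write_text("0 1.0 0.5\n1 2.0 0.25\n")
        np.testing.assert_allclose(read_deltav_log(p).to_numpy(), [1.5, 2.25])

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "dv.log"
        p.write_text("0 -1.0\n")
        with pytest.raises(ValidationError, match="negative"):
            read_deltav_log(p)

    def test_duplicate_frame_rejected(self, tmp_path):
        p = tmp_path / "dv.log"
        p.write_text("0 1.0\n0 2.0\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_deltav_log(p)

    def test_write_read_roundtrip(self, tmp_path):
        p = tmp_path / "dv.log"
        dv = np.array([0.0, 0.123456789, 7.5])
        write_deltav_log(p, dv)
        np.testing.assert_allclose(read_deltav_log(p).to_numpy(), dv)

    def test_amd_log_shim_extracts_and_sums_boost_columns(self, tmp_path):
        p = tmp_path / "amd.log"
        p.write_text(
            "# ntwx steps epot edih boost_tot boost_dih\n"
            "500 500 -32220.0 9100.0 2.0 1.5\n"
            "500 1000 -32215.0 9105.0 1.0 0.5\n"
        )
        s = read_amd_log(p)
        np.testing.assert_allclose(s.to_numpy(), [3.5, 1.5])


class TestDataModelInvariants:
    def test_trajectory_rejects_mismatched_delta_v(self, multi_pdb):
        t = read_pdb(multi_pdb)
        with pytest.raises(ValidationError):
            t.with_delta_v(np.zeros(t.n_frames + 1))
        with pytest.raises(ValidationError):
            t.with_delta_v(-np.ones(t.n_frames))

    def test_duplicate_atom_key_rejected(self):
        with pytest.raises(ValidationError, match="unique"):
            Topology(
                atom_name=np.array(["CA", "CA"]),
                res_name=np.array(["ALA", "ALA"]),
                res_id=np.array([1, 1]),
                chain_id=np.array(["A", "A"]),
                element=np.array(["C", "C"]),
                mass=np.array([12.0, 12.0]),
            )
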