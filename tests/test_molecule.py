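"""Molecule loading, plane normals and rigid-body pose transforms."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nanocap as nc

poses = st.builds(
    nc.Pose,
    x=st.floats(-16, 16), y=st.floats(-16, 16), z=st.floats(-16, 16),
    theta_x=st.floats(-math.pi, math.pi), theta_y=st.floats(-math.pi, math.pi),
)


class TestLoading:
    def test_xyz_single_atom_recentered(self, tmp_path, ff):
        p = tmp_path / "one.xyz"
        p.write_text("1\ncomment\nC 1.0 2.0 3.0\n")
        mol = nc.load_molecule(p, forcefield=ff)
        assert mol.n_atoms == 1
        assert mol.coords_body == pytest.approx(np.zeros((1, 3)), abs=1e-12)

    def test_hexagon_com_at_origin(self, hexagon):
        assert np.linalg.norm(hexagon.center_of_mass()) < 1e-9
        assert hexagon.n_atoms == 6

    def test_sdf_v2000(self, tmp_path, ff):
        # minimal V2000 block: one carbon
        sdf = (
            "probe\n  test\n\n"
            "  1  0  0  0  0  0  0  0  0  0999 V2000\n"
            "    1.0000    2.0000    3.0000 C   0  0\n"
            "M  END\n$$$$\n"
        )
        p = tmp_path / "probe.sdf"
        p.write_text(sdf)
        mol = nc.load_molecule(p, forcefield=ff)
        assert mol.elements == ["C"]
        assert mol.coords_body == pytest.approx(np.zeros((1, 3)), abs=1e-12)

    def test_unknown_element_rejected(self, ff):
        with pytest.raises(nc.MissingParameterError):
            nc.Molecule("bad", ["Zz"], [[0, 0, 0]], forcefield=ff)

    def test_empty_molecule_rejected(self, ff):
        with pytest.raises(ValueError):
            nc.Molecule("empty", [], np.zeros((0, 3)), forcefield=ff)


class TestNormalVector:
    def test_planar_hexagon_normal_is_z(self, hexagon):
        n = nc.normal_vector(hexagon)
        assert abs(n @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_rotated_hexagon_equivariance(self, hexagon, ff):
        # rotate 90 deg about x: plane z=0 -> plane y=0, normal -> y
        rot = nc.rotation_matrix(math.pi / 2, 0.0)
        mol = nc.Molecule("rot", hexagon.elements, hexagon.coords_body @ rot.T,
                          forcefield=ff)
        n = nc.normal_vector(mol)
        assert abs(n @ [0, 1, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_svd_oracle_on_drug(self, fluorouracil):
        mol = fluorouracil
        w = np.sqrt(mol.masses)[:, None]
        _, s, vt = np.linalg.svd(mol.coords_body * w, full_matrices=False)
        oracle = vt[-1]  # right singular vector of the smallest singular value
        n = nc.normal_vector(mol)
        assert abs(n @ oracle) == pytest.approx(1.0, abs=1e-9)
        # out-of-plane spread along the normal is the smallest principal spread
        spread = np.linalg.norm((mol.coords_body * w) @ n)
        assert spread == pytest.approx(s[-1], rel=1e-9)
        assert spread < np.linalg.norm((mol.coords_body * w) @ vt[0])

    def test_collinear_is_degenerate(self, ff):
        with pytest.raises(nc.DegenerateGeometryError):
            nc.normal_vector(nc.Molecule("line", ["C"] * 3,
                                         [[0, 0, 0], [0, 0, 1], [0, 0, 2]],
                                         forcefield=ff))

    def test_fewer_than_three_atoms_degenerate(self, ff):
        dimer = nc.make_fixture("dimer", forcefield=ff)
        with pytest.raises(nc.DegenerateGeometryError):
            nc.normal_vector(dimer)


class TestApplyPose:
    def test_identity(self, hexagon):
        out = nc.apply_pose(hexagon, nc.Pose())
        assert out == pytest.approx(hexagon.coords_body)

    def test_pure_translation(self, hexagon):
        out = nc.apply_pose(hexagon, nc.Pose(1, 2, 3))
        assert out == pytest.approx(hexagon.coords_body + [1, 2, 3])

    def test_half_turn_maps_plane_to_itself(self, hexagon):
        out = nc.apply_pose(hexagon, nc.Pose(theta_x=math.pi))
        assert np.allclose(out[:, 2], 0.0, atol=1e-12)

    def test_com_lands_on_translation(self, fluorouracil):
        pose = nc.Pose(2.0, -3.0, 1.5, 0.7, -1.1)
        out = nc.apply_pose(fluorouracil, pose)
        com = fluorouracil.masses @ out / fluorouracil.total_mass
        assert com == pytest.approx([2.0, -3.0, 1.5], abs=1e-9)

    @given(pose=poses)
    def test_distance_matrix_invariant(self, pose):
        mol = nc.make_fixture("tetrahedron", length=1.54)
        ref = mol.distance_matrix()
        out = nc.apply_pose(mol, pose)
        d = out[:, None, :] - out[None, :, :]
        assert np.abs(np.sqrt((d**2).sum(-1)) - ref).max() < 1e-9

    @given(pose=poses)
    def test_normal_equivariance(self, pose):
        mol = nc.make_fixture("hexagon_ring")
        n0 = nc.normal_vector(mol)
        R = nc.rotation_matrix(pose.theta_x, pose.theta_y)
        world = nc.apply_pose(mol, pose)
        n1 = nc.normal_vector(world - np.mean(world, axis=0), np.ones(6))
        assert abs(n1 @ (R @ n0)) == pytest.approx(1.0, abs=1e-9)

    def test_out_of_bounds_pose_rejected(self, hexagon):
        with pytest.raises(ValueError):
            nc.apply_pose(hexagon, nc.Pose(x=17.0))
        with pytest.raises(ValueError):
            nc.apply_pose(hexagon, nc.Pose(theta_x=4.0))


class TestXyzBundle:
    def test_roundtrip(self, tmp_path, hexagon, fluorouracil):
        poses_ = [nc.Pose(1, 0, -2, 0.3, 0.1), nc.Pose(-1, 2, 3, -0.5, 1.0)]
        path = tmp_path / "bundle.xyz"
        nc.write_xyz_bundle(path, [hexagon, fluorouracil], poses_,
                            comments=["E_total=-1.5", ""])
        blocks = nc.read_xyz_bundle(path)
        assert len(blocks) == 2
        for (name, els, world, pose), mol, p in zip(blocks, [hexagon, fluorouracil], poses_):
            assert els == mol.elements
            assert world == pytest.approx(nc.apply_pose(mol, p), abs=1e-9)
            assert pose.as_array() == pytest.approx(p.as_array())
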