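"""Geometry substrate: PDB round trips, superposition, RMSD, dihedrals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ffval import (
    ConformationalEnsemble,
    DegenerateGeometryError,
    MissingAtomError,
    ResidueRange,
    backbone_dihedral,
    ca_rmsd_series,
    kabsch_superpose,
    read_ensemble,
    write_ensemble,
)
from ffval.ensemble import _rotation_from_axis_angle
from ffval.synthetic import build_ideal_peptide

from oracles import dihedral_oracle, quaternion_rmsd


# -- PDB I/O ----------------------------------------------------------------

class TestPdbRoundTrip:
    def test_multi_model_round_trip(self, tmp_path, helix_peptide, rng):
        frames = np.stack(
            [helix_peptide.frames[0] + 0.5 * rng.standard_normal((helix_peptide.n_atoms, 3))
             for _ in range(3)]
        )
        ens = ConformationalEnsemble(atoms=helix_peptide.atoms, frames=frames)
        path = tmp_path / "ens.pdb"
        write_ensemble(ens, path)
        back = read_ensemble(path)
        assert back.n_frames == 3
        assert back.atoms == ens.atoms
        assert np.abs(back.frames - ens.frames).max() < 1e-3  # PDB precision

    def test_single_model_gives_one_frame(self, tmp_path, helix_peptide):
        path = tmp_path / "single.pdb"
        write_ensemble(helix_peptide, path)
        assert read_ensemble(path).n_frames == 1

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            read_ensemble(tmp_path / "absent.pdb")


def test_ensemble_validation_rejects_bad_shapes(helix_peptide):
    with pytest.raises(ValueError, match="finite"):
        bad = helix_peptide.frames.copy()
        bad[0, 0, 0] = np.nan
        ConformationalEnsemble(atoms=helix_peptide.atoms, frames=bad)
    with pytest.raises(ValueError):
        ConformationalEnsemble(atoms=helix_peptide.atoms, frames=np.zeros((0, 3, 3)))


# -- Kabsch superposition ---------------------------------------------------

class TestKabsch:
    def test_identity(self, rng):
        x = rng.standard_normal((6, 3))
        rot, trans, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, np.eye(3), atol=1e-8)

    def test_rigid_motion_removed(self, rng):
        x = rng.standard_normal((6, 3))
        rot90 = _rotation_from_axis_angle([0, 0, 1], np.pi / 2)
        moved = x @ rot90.T + np.array([5.0, 0.0, 0.0])
        _, _, rmsd = kabsch_superpose(moved, x)
        assert rmsd < 1e-6
        rot, trans, _ = kabsch_superpose(moved, x)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 10))
            a, b = rng.standard_normal((2, n, 3))
            _, _, rmsd = kabsch_superpose(a, b)
            assert rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-8)

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.standard_normal((2, 7, 3))
        assert kabsch_superpose(a, b)[2] == pytest.approx(kabsch_superpose(b, a)[2], abs=1e-10)

    @pytest.mark.parametrize(
        "coords",
        [np.zeros((2, 3)), np.outer(np.arange(5.0), [1.0, 0.0, 0.0])],
        ids=["too-few", "collinear"],
    )
    def test_degenerate_selection_rejected(self, coords):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(coords, coords + 1.0)

    def test_saddle_displacement_hand_value(self):
        """Square corners pushed alternately +/-h out of plane: RMSD = h exactly.

        By symmetry the cross-covariance has no off-plane coupling, so the
        optimal rotation is the identity and the residual is purely the
        out-of-plane displacement.
        """
        ref = np.array([[1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0]], dtype=float)
        h = 0.5
        mob = ref.copy()
        mob[:, 2] = [h, -h, h, -h]
        _, _, rmsd = kabsch_superpose(mob, ref)
        assert rmsd == pytest.approx(h, abs=1e-10)


# -- Calpha RMSD series -----------------------------------------------------

class TestCaRmsdSeries:
    def test_reference_frames_give_zero(self, helix_peptide):
        ens = ConformationalEnsemble(
            atoms=helix_peptide.atoms,
            frames=np.repeat(helix_peptide.frames, 4, axis=0),
        )
        series = ca_rmsd_series(ens, helix_peptide, ResidueRange(1, 6))
        assert np.abs(series).max() < 1e-10

    def test_translation_removed(self, helix_peptide):
        ens = ConformationalEnsemble(
            atoms=helix_peptide.atoms,
            frames=helix_peptide.frames + np.array([3.0, -2.0, 7.0]),
        )
        series = ca_rmsd_series(ens, helix_peptide, ResidueRange(2, 5))
        assert np.abs(series).max() < 1e-10

    def test_two_frame_toy_matches_oracle(self, helix_peptide):
        frames = np.repeat(helix_peptide.frames, 2, axis=0)
        ca4 = helix_peptide.atom_index(4, "CA")
        frames[1, ca4] += [0.0, 0.0, 1.0]  # stretch one Calpha by 1 A
        ens = ConformationalEnsemble(atoms=helix_peptide.atoms, frames=frames)
        series = ca_rmsd_series(ens, helix_peptide, ResidueRange(1, 6))
        ca_idx = [helix_peptide.atom_index(r, "CA") for r in range(1, 7)]
        expected = quaternion_rmsd(frames[1][ca_idx], helix_peptide.frames[0][ca_idx])
        assert series[0] == pytest.approx(0.0, abs=1e-10)
        assert series[1] == pytest.approx(expected, abs=1e-8)

    def test_missing_ca_listed(self, helix_peptide):
        with pytest.raises(MissingAtomError, match=r"\[7, 8\]"):
            ca_rmsd_series(helix_peptide, helix_peptide, ResidueRange(5, 8))


# -- Dihedrals --------------------------------------------------------------

def _four_atom_ensemble(points):
    """Minimal 2-residue topology exposing one psi built from raw points."""
    from ffval import AtomRecord

    atoms = [
        AtomRecord("N", 1),
        AtomRecord("CA", 1),
        AtomRecord("C", 1),
        AtomRecord("N", 2),
    ]
    return ConformationalEnsemble(atoms=atoms, frames=np.asarray(points, float)[None])


class TestDihedrals:
    def test_trans_is_180(self):
        ens = _four_atom_ensemble([[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]])
        assert backbone_dihedral(ens, 1, "psi")[0] == pytest.approx(180.0)

    def test_cis_is_0(self):
        ens = _four_atom_ensemble([[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]])
        assert backbone_dihedral(ens, 1, "psi")[0] == pytest.approx(0.0, abs=1e-10)

    def test_helix_build_measure_round_trip(self):
        ens = build_ideal_peptide(5, phi_deg=-57.0, psi_deg=-47.0)
        for r in range(2, 5):
            assert backbone_dihedral(ens, r, "phi")[0] == pytest.approx(-57.0, abs=1e-6)
            assert backbone_dihedral(ens, r, "psi")[0] == pytest.approx(-47.0, abs=1e-6)

    def test_matches_vector_algebra_oracle(self, rng):
        for _ in range(50):
            pts = rng.standard_normal((4, 3)) * 3.0
            ens = _four_atom_ensemble(pts)
            got = backbone_dihedral(ens, 1, "psi")[0]
            assert got == pytest.approx(dihedral_oracle(*pts), abs=1e-6)

    def test_terminal_residue_raises(self, helix_peptide):
        with pytest.raises(MissingAtomError):
            backbone_dihedral(helix_peptide, 1, "phi")
        with pytest.raises(MissingAtomError):
            backbone_dihedral(helix_peptide, 6, "psi")

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 2**31 - 1),
        angle=st.floats(-np.pi, np.pi),
    )
    def test_rigid_motion_invariance_and_mirror_antisymmetry(self, seed, angle):
        r = np.random.default_rng(seed)
        pts = r.standard_normal((4, 3)) * 2.0 + 1.0
        base = backbone_dihedral(_four_atom_ensemble(pts), 1, "psi")[0]
        rot = _rotation_from_axis_angle(r.standard_normal(3) + 0.1, angle)
        moved = pts @ rot.T + r.standard_normal(3) * 5.0
        assert backbone_dihedral(_four_atom_ensemble(moved), 1, "psi")[0] == pytest.approx(
            base, abs=1e-6
        )
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        flipped = backbone_dihedral(_four_atom_ensemble(mirrored), 1, "psi")[0]
        if abs(abs(base) - 180.0) > 1e-6:  # +/-180 are the same angle
            assert flipped == pytest.approx(-base, abs=1e-6)


def test_reconstructed_hydrogens_are_flagged(helix_peptide):
    # session fixture was built with hydrogens reconstructed from heavy atoms
    assert helix_peptide.metadata["reconstructed_H"] == [2, 3, 4, 5, 6]
    nh = helix_peptide.coords(3, "H") - helix_peptide.coords(3, "N")
    assert np.linalg.norm(nh) == pytest.approx(1.01, abs=1e-9)
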