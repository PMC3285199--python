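"""Coordinate data model, ensemble I/O, superposition, RMSD and dihedrals.

The central container is :class:`ConformationalEnsemble`: an ordered atom
list (PDB naming, author residue numbering) plus a ``(n_frames, n_atoms, 3)``
coordinate array in Angstrom.  Everything downstream — scalar couplings,
RDCs, order parameters, folding-state assignment — is computed from this
geometric substrate.

Angles are degrees externally and radians internally; dihedrals follow the
IUPAC convention (trans = 180, cis = 0) with range (-180, 180].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .exceptions import (
    DegenerateGeometryError,
    FormatError,
    MissingAtomError,
)

__all__ = [
    "AtomRecord",
    "ConformationalEnsemble",
    "ResidueRange",
    "read_ensemble",
    "write_ensemble",
    "kabsch_superpose",
    "superpose_frames",
    "ca_rmsd_series",
    "backbone_dihedral",
    "reconstruct_amide_hydrogens",
]

BACKBONE_HEAVY = ("N", "CA", "C")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology, identified by PDB name and author numbering."""

    atom_name: str
    residue_index: int
    residue_name: str = "ALA"
    element: str = ""

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive residue range in author (1-based) numbering, e.g. 3-31."""

    first: int
    last: int

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError(f"first ({self.first}) > last ({self.last})")

    def __contains__(self, residue_index: int) -> bool:
        return self.first <= residue_index <= self.last

    def indices(self) -> range:
        return range(self.first, self.last + 1)


@dataclass
class ConformationalEnsemble:
    """Ordered frames of labeled atomic coordinates for one molecule.

    Parameters
    ----------
    atoms
        Topology shared by all frames; ``(residue_index, atom_name)`` must be
        unique.
    frames
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    frame_interval_ns
        Time between consecutive frames, if the ensemble is a time series.
    temperature_K
        Temperature label of the ensemble (e.g. one rung of a tempering
        ladder); purely a label, no reweighting is applied.
    metadata
        Free-form provenance, e.g. ground-truth order parameters attached by
        the synthetic generators.
    """

    atoms: list[AtomRecord]
    frames: np.ndarray
    frame_interval_ns: float | None = None
    temperature_K: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must have shape (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"frame has {self.frames.shape[1]} coordinates for {len(self.atoms)} atoms"
            )
        if not np.isfinite(self.frames).all():
            raise ValueError("coordinates must be finite")
        self._index: dict[tuple[int, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.residue_index, a.atom_name)
            if key in self._index:
                raise ValueError(f"duplicate atom {key} in topology")
            self._index[key] = i

    # -- lookups ---------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_indices(self) -> list[int]:
        return sorted({a.residue_index for a in self.atoms})

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        return (residue_index, atom_name) in self._index

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        try:
            return self._index[(residue_index, atom_name)]
        except KeyError:
            raise MissingAtomError(
                f"atom {atom_name!r} of residue {residue_index} not in topology"
            ) from None

    def select(
        self,
        atom_names: Iterable[str] | None = None,
        residue_range: ResidueRange | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching name set and residue range (both optional)."""
        names = set(atom_names) if atom_names is not None else None
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if (names is None or a.atom_name in names)
            and (residue_range is None or a.residue_index in residue_range)
        ]
        return np.asarray(idx, dtype=int)

    def coords(self, residue_index: int, atom_name: str) -> np.ndarray:
        """Per-frame coordinates of one atom, shape ``(n_frames, 3)``."""
        return self.frames[:, self.atom_index(residue_index, atom_name), :]


# ---------------------------------------------------------------------------
# PDB I/O (multi-model PDB is the baseline interchange format)
# ---------------------------------------------------------------------------

def read_ensemble(
    path: str | Path,
    fmt: Literal["pdb", "traj"] = "pdb",
    topology: str | Path | None = None,
    frame_interval_ns: float | None = None,
    temperature_K: float | None = None,
) -> ConformationalEnsemble:
    """Read a conformational ensemble.

    ``fmt="pdb"`` reads a (multi-model) PDB file, one frame per MODEL, via
    Bio.PDB.  ``fmt="traj"`` reads a binary trajectory (DCD/XTC/...) plus a
    PDB topology via mdtraj, if mdtraj is installed.

    Alternate locations keep altloc ' ' or 'A'; insertion codes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"ensemble file not found: {path}")
    if fmt == "pdb":
        return _read_pdb(path, frame_interval_ns, temperature_K)
    if fmt == "traj":
        return _read_traj(path, topology, frame_interval_ns, temperature_K)
    raise ValueError(f"unknown format {fmt!r}")


def _read_pdb(path: Path, frame_interval_ns, temperature_K) -> ConformationalEnsemble:
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Bio.PDB is chatty about minor issues
        structure = PDBParser(QUIET=True).get_structure("ens", str(path))
    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no models found")

    atoms_per_model: list[list[AtomRecord]] = []
    coords_per_model: list[np.ndarray] = []
    for model in models:
        chains = list(model)
        if len(chains) != 1:
            raise FormatError(
                f"{path}: model {model.id} has {len(chains)} chains; expected a single chain"
            )
        records, coords = [], []
        for residue in chains[0]:
            het, resseq, icode = residue.id
            if het.strip():
                continue  # skip waters/heteroatoms
            if icode.strip():
                raise FormatError(
                    f"{path}: residue {resseq}{icode} carries an insertion code; not supported"
                )
            for atom in residue:
                altloc = atom.get_altloc()
                if altloc not in (" ", "A"):
                    continue
                records.append(
                    AtomRecord(
                        atom_name=atom.get_name(),
                        residue_index=int(resseq),
                        residue_name=residue.get_resname(),
                        element=(atom.element or "").strip(),
                    )
                )
                coords.append(atom.get_coord())
        atoms_per_model.append(records)
        coords_per_model.append(np.asarray(coords, dtype=float))

    ref_atoms = atoms_per_model[0]
    for m, recs in enumerate(atoms_per_model[1:], start=2):
        if recs != ref_atoms:
            raise FormatError(
                f"{path}: model {m} atom list differs from model 1 "
                f"({len(recs)} vs {len(ref_atoms)} atoms)"
            )
    return ConformationalEnsemble(
        atoms=ref_atoms,
        frames=np.stack(coords_per_model),
        frame_interval_ns=frame_interval_ns,
        temperature_K=temperature_K,
    )


def _read_traj(path: Path, topology, frame_interval_ns, temperature_K) -> ConformationalEnsemble:
    try:
        import mdtraj
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError("binary trajectory support requires the 'mdtraj' extra") from exc
    if topology is None:
        raise ValueError("fmt='traj' requires a PDB topology file")
    traj = mdtraj.load(str(path), top=str(topology))
    records = [
        AtomRecord(
            atom_name=a.name,
            residue_index=a.residue.resSeq,
            residue_name=a.residue.name,
            element=a.element.symbol if a.element is not None else "",
        )
        for a in traj.topology.atoms
    ]
    return ConformationalEnsemble(
        atoms=records,
        frames=np.asarray(traj.xyz, dtype=float) * 10.0,  # nm -> Angstrom
        frame_interval_ns=frame_interval_ns,
        temperature_K=temperature_K,
    )


def write_ensemble(ensemble: ConformationalEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB (one MODEL per frame)."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("ens")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # residue revisits for ungrouped topologies
        _build_models(builder, ensemble)
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def _build_models(builder, ensemble: ConformationalEnsemble) -> None:
    for f in range(ensemble.n_frames):
        builder.init_model(f)
        builder.init_chain("A")
        builder.init_seg("    ")
        current_res = None
        serial = 1
        for i, a in enumerate(ensemble.atoms):
            if a.residue_index != current_res:
                builder.init_residue(a.residue_name, " ", a.residue_index, " ")
                current_res = a.residue_index
            name = a.atom_name
            fullname = name.rjust(4) if len(name) == 4 else f" {name}".ljust(4)
            builder.init_atom(
                name,
                np.asarray(ensemble.frames[f, i], dtype=float),
                0.0,
                1.0,
                " ",
                fullname,
                serial,
                element=a.element or name[0],
            )
            serial += 1


# ---------------------------------------------------------------------------
# Optimal superposition (Kabsch) and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: Sequence[int] | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD over the
    selection.  The rotation is proper (det = +1); reflections are excluded.

    Raises
    ------
    DegenerateGeometryError
        Fewer than three selected atoms, or a collinear selection (the
        rotation about the line would be undetermined).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        sel_m, sel_r = mobile, reference
    else:
        selection = np.asarray(selection, dtype=int)
        sel_m, sel_r = mobile[selection], reference[selection]
    if sel_m.shape != sel_r.shape:
        raise ValueError("mobile and reference selections differ in shape")
    n = sel_m.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"superposition needs >= 3 atoms, got {n}")

    cm, cr = sel_m.mean(axis=0), sel_r.mean(axis=0)
    xm, xr = sel_m - cm, sel_r - cr
    scale = max(np.linalg.norm(xm), np.linalg.norm(xr), 1.0)
    for x in (xm, xr):
        if np.linalg.svd(x, compute_uv=False)[1] < 1e-8 * scale:
            raise DegenerateGeometryError("selection is collinear; rotation undetermined")

    h = xm.T @ xr
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cr - rotation @ cm
    moved = xm @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - xr) ** 2, axis=1))))
    return rotation, translation, rmsd


def superpose_frames(
    ensemble: ConformationalEnsemble,
    reference: np.ndarray,
    selection: Sequence[int] | np.ndarray | None = None,
) -> np.ndarray:
    """All frames rigid-body fitted onto ``reference`` coordinates.

    The fit is computed on ``selection`` (atom indices; default all atoms)
    and applied to every atom.  Used to remove overall tumbling before
    extracting internal bond-vector dynamics.
    """
    out = np.empty_like(ensemble.frames)
    for f in range(ensemble.n_frames):
        rot, trans, _ = kabsch_superpose(ensemble.frames[f], reference, selection)
        out[f] = ensemble.frames[f] @ rot.T + trans
    return out


def ca_rmsd_series(
    ensemble: ConformationalEnsemble,
    reference: ConformationalEnsemble | np.ndarray,
    residue_range: ResidueRange,
    ref_ensemble_for_coords: ConformationalEnsemble | None = None,
) -> np.ndarray:
    """Per-frame Calpha RMSD (after optimal superposition) over a residue range.

    ``reference`` is either an ensemble (its first frame is used) sharing the
    Calpha topology, or a raw coordinate array aligned with the ensemble's
    selected Calpha atoms.
    """
    wanted = list(residue_range.indices())
    missing = [r for r in wanted if not ensemble.has_atom(r, "CA")]
    if missing:
        raise MissingAtomError(f"ensemble lacks CA for residues {missing}")
    mob_idx = np.asarray([ensemble.atom_index(r, "CA") for r in wanted])

    if isinstance(reference, ConformationalEnsemble):
        missing = [r for r in wanted if not reference.has_atom(r, "CA")]
        if missing:
            raise MissingAtomError(f"reference lacks CA for residues {missing}")
        ref_idx = np.asarray([reference.atom_index(r, "CA") for r in wanted])
        ref_coords = reference.frames[0][ref_idx]
    else:
        ref_coords = np.asarray(reference, dtype=float)
        if ref_coords.shape != (len(wanted), 3):
            raise ValueError(
                f"reference coordinates must have shape ({len(wanted)}, 3), got {ref_coords.shape}"
            )

    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        _, _, out[f] = kabsch_superpose(ensemble.frames[f][mob_idx], ref_coords)
    return out


# ---------------------------------------------------------------------------
# Backbone dihedrals
# ---------------------------------------------------------------------------

def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral (degrees, IUPAC, range (-180, 180]) for frame-stacked points."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # close the range at +180 rather than -180
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def backbone_dihedral(
    ensemble: ConformationalEnsemble,
    residue_index: int,
    angle: Literal["phi", "psi"],
) -> np.ndarray:
    """Per-frame phi or psi of one residue, degrees in (-180, 180].

    phi(i) is defined by C(i-1), N(i), CA(i), C(i); psi(i) by N(i), CA(i),
    C(i), N(i+1).  Terminal residues lacking a defining atom raise
    :class:`MissingAtomError`.
    """
    if angle == "phi":
        quad = [(residue_index - 1, "C"), (residue_index, "N"),
                (residue_index, "CA"), (residue_index, "C")]
    elif angle == "psi":
        quad = [(residue_index, "N"), (residue_index, "CA"),
                (residue_index, "C"), (residue_index + 1, "N")]
    else:
        raise ValueError(f"angle must be 'phi' or 'psi', got {angle!r}")
    missing = [(r, a) for r, a in quad if not ensemble.has_atom(r, a)]
    if missing:
        raise MissingAtomError(
            f"{angle} of residue {residue_index} undefined: missing atoms {missing}"
        )
    pts = [ensemble.frames[:, ensemble.atom_index(r, a), :] for r, a in quad]
    return _dihedral(*pts)


def reconstruct_amide_hydrogens(ensemble: ConformationalEnsemble, nh_bond: float = 1.01) -> ConformationalEnsemble:
    """Add missing backbone amide H atoms from ideal amide geometry.

    Experimental structures often lack protons; the H of residue i is placed
    along the external bisector of C(i-1)-N(i)-CA(i) at ``nh_bond`` Angstrom,
    i.e. trans to both heavy-atom bonds in the peptide plane.  Reconstructed
    atoms are flagged in ``metadata["reconstructed_H"]``.
    """
    new_atoms = list(ensemble.atoms)
    cols = [ensemble.frames]
    added: list[int] = []
    for r in ensemble.residue_indices:
        if ensemble.has_atom(r, "H") or not (
            ensemble.has_atom(r, "N")
            and ensemble.has_atom(r, "CA")
            and ensemble.has_atom(r - 1, "C")
        ):
            continue
        n = ensemble.coords(r, "N")
        u = n - ensemble.coords(r - 1, "C")
        v = n - ensemble.coords(r, "CA")
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        h_dir = u + v
        h_dir /= np.linalg.norm(h_dir, axis=1, keepdims=True)
        resname = next(a.residue_name for a in ensemble.atoms if a.residue_index == r)
        new_atoms.append(AtomRecord("H", r, resname, "H"))
        cols.append((n + nh_bond * h_dir)[:, None, :])
        added.append(r)
    frames = np.concatenate(cols, axis=1)
    # keep the topology grouped by residue (stable within a residue) so the
    # atom ordering survives a PDB round trip
    order = sorted(range(len(new_atoms)), key=lambda i: new_atoms[i].residue_index)
    out = ConformationalEnsemble(
        atoms=[new_atoms[i] for i in order],
        frames=frames[:, order, :],
        frame_interval_ns=ensemble.frame_interval_ns,
        temperature_K=ensemble.temperature_K,
        metadata=dict(ensemble.metadata),
    )
    out.metadata["reconstructed_H"] = added
    return out


def _rotation_from_axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)
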