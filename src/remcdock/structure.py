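"""Structures, atom parameters, side-chain topology and PDB I/O.

A docking system is a :class:`ComplexPose`: a fixed receptor, a mobile ligand
whose rigid placement is a :class:`~remcdock.geometry.RigidTransform` applied
about the ligand's centroid, and continuous side-chain χ angles on both
partners.  Atom parameters (hard-sphere radius, Lennard-Jones well depth,
polarity flag) live in a tab-separated table shared with the energy module.

Only heavy atoms are kept: hydrogens are dropped at parse time, matching the
extended-atom (CHARMM19-style) parameterization the scoring function assumes.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .geometry import (
    RigidTransform,
    quat_from_axis_angle,
    quat_to_matrix,
)

__all__ = [
    "AtomRecord",
    "AtomParams",
    "ChiDef",
    "PartnerStructure",
    "ComplexPose",
    "read_complex",
    "realized_coordinates",
    "write_snapshots",
    "read_snapshots",
    "measure_dihedral",
    "STANDARD_CHI_TABLE",
]


@dataclass
class AtomRecord:
    """One heavy atom with its scoring parameters."""

    atom_name: str
    element: str
    residue_index: int
    residue_type: str
    partner_id: str  # "receptor" | "ligand"
    position: np.ndarray  # (3,) Å
    radius_hard: float  # Å
    well_depth: float  # score units
    nonpolar: bool
    charge: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")
        if self.radius_hard <= 0:
            raise ValueError(f"radius must be positive for atom {self.atom_name}")
        if self.well_depth < 0:
            raise ValueError(f"well depth must be >= 0 for atom {self.atom_name}")


class AtomParams:
    """Lookup table (residue_type, atom_name) -> (radius, well depth, polarity).

    Rows with ``*`` in either key column act as wildcard defaults; an exact
    match wins over a wildcard.  File format: tab-separated columns
    ``residue_type  atom_name  radius_hard  well_depth  nonpolar`` with an
    optional ``charge`` column.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"residue_type", "atom_name", "radius_hard", "well_depth", "nonpolar"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"atom parameter table lacks columns: {sorted(missing)}")
        self.table = table.copy()
        if "charge" not in self.table.columns:
            self.table["charge"] = 0.0
        self._index: dict[tuple[str, str], tuple[float, float, bool, float]] = {}
        for row in self.table.itertuples(index=False):
            key = (str(row.residue_type), str(row.atom_name))
            self._index[key] = (
                float(row.radius_hard),
                float(row.well_depth),
                bool(row.nonpolar),
                float(row.charge),
            )

    @classmethod
    def from_tsv(cls, source) -> "AtomParams":
        return cls(pd.read_csv(source, sep="\t", comment="#"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def lookup(self, residue_type: str, atom_name: str):
        for key in (
            (residue_type, atom_name),
            (residue_type, "*"),
            ("*", atom_name),
            ("*", "*"),
        ):
            if key in self._index:
                return self._index[key]
        raise KeyError(
            f"no parameters for atom {atom_name!r} in residue {residue_type!r} "
            "and no wildcard default declared"
        )


@dataclass
class ChiDef:
    """One χ degree of freedom: dihedral quadruple + the atoms it rotates."""

    atom_quadruple: tuple[str, str, str, str]
    moved_atoms: tuple[str, ...]


def _chis(*entries) -> list[ChiDef]:
    return [ChiDef(tuple(q.split("-")), tuple(m)) for q, m in entries]


#: χ dihedral definitions (heavy atoms) for the standard amino acids.
#: GLY/ALA/PRO carry no sampled χ (proline is excluded from side-chain moves).
STANDARD_CHI_TABLE: dict[str, list[ChiDef]] = {
    "ARG": _chis(
        ("N-CA-CB-CG", ["CG", "CD", "NE", "CZ", "NH1", "NH2"]),
        ("CA-CB-CG-CD", ["CD", "NE", "CZ", "NH1", "NH2"]),
        ("CB-CG-CD-NE", ["NE", "CZ", "NH1", "NH2"]),
        ("CG-CD-NE-CZ", ["CZ", "NH1", "NH2"]),
    ),
    "ASN": _chis(("N-CA-CB-CG", ["CG", "OD1", "ND2"]), ("CA-CB-CG-OD1", ["OD1", "ND2"])),
    "ASP": _chis(("N-CA-CB-CG", ["CG", "OD1", "OD2"]), ("CA-CB-CG-OD1", ["OD1", "OD2"])),
    "CYS": _chis(("N-CA-CB-SG", ["SG"])),
    "GLN": _chis(
        ("N-CA-CB-CG", ["CG", "CD", "OE1", "NE2"]),
        ("CA-CB-CG-CD", ["CD", "OE1", "NE2"]),
        ("CB-CG-CD-OE1", ["OE1", "NE2"]),
    ),
    "GLU": _chis(
        ("N-CA-CB-CG", ["CG", "CD", "OE1", "OE2"]),
        ("CA-CB-CG-CD", ["CD", "OE1", "OE2"]),
        ("CB-CG-CD-OE1", ["OE1", "OE2"]),
    ),
    "HIS": _chis(
        ("N-CA-CB-CG", ["CG", "ND1", "CD2", "CE1", "NE2"]),
        ("CA-CB-CG-ND1", ["ND1", "CD2", "CE1", "NE2"]),
    ),
    "ILE": _chis(("N-CA-CB-CG1", ["CG1", "CG2", "CD1"]), ("CA-CB-CG1-CD1", ["CD1"])),
    "LEU": _chis(("N-CA-CB-CG", ["CG", "CD1", "CD2"]), ("CA-CB-CG-CD1", ["CD1", "CD2"])),
    "LYS": _chis(
        ("N-CA-CB-CG", ["CG", "CD", "CE", "NZ"]),
        ("CA-CB-CG-CD", ["CD", "CE", "NZ"]),
        ("CB-CG-CD-CE", ["CE", "NZ"]),
        ("CG-CD-CE-NZ", ["NZ"]),
    ),
    "MET": _chis(
        ("N-CA-CB-CG", ["CG", "SD", "CE"]),
        ("CA-CB-CG-SD", ["SD", "CE"]),
        ("CB-CG-SD-CE", ["CE"]),
    ),
    "PHE": _chis(
        ("N-CA-CB-CG", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]),
        ("CA-CB-CG-CD1", ["CD1", "CD2", "CE1", "CE2", "CZ"]),
    ),
    "SER": _chis(("N-CA-CB-OG", ["OG"])),
    "THR": _chis(("N-CA-CB-OG1", ["OG1", "CG2"])),
    "TRP": _chis(
        ("N-CA-CB-CG", ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"]),
        ("CA-CB-CG-CD1", ["CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"]),
    ),
    "TYR": _chis(
        ("N-CA-CB-CG", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"]),
        ("CA-CB-CG-CD1", ["CD1", "CD2", "CE1", "CE2", "CZ", "OH"]),
    ),
    "VAL": _chis(("N-CA-CB-CG1", ["CG1", "CG2"])),
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    # scalar math: this sits in the sampler's side-chain hot loop
    b0x, b0y, b0z = p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2]
    b1x, b1y, b1z = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    b2x, b2y, b2z = p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2]
    n1x, n1y, n1z = b0y * b1z - b0z * b1y, b0z * b1x - b0x * b1z, b0x * b1y - b0y * b1x
    n2x, n2y, n2z = b1y * b2z - b1z * b2y, b1z * b2x - b1x * b2z, b1x * b2y - b1y * b2x
    nb = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    m1x = (n1y * b1z - n1z * b1y) / nb
    m1y = (n1z * b1x - n1x * b1z) / nb
    m1z = (n1x * b1y - n1y * b1x) / nb
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = m1x * n2x + m1y * n2y + m1z * n2z
    return wrap_angle(math.degrees(math.atan2(y, x)))


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    if a == -180.0:
        a = 180.0
    return a


@dataclass
class _ResidueChi:
    """Index-resolved χ topology of one residue."""

    quadruples: list[np.ndarray]  # each (4,) atom indices into the partner
    moved: list[np.ndarray]  # each: atom indices rotated by that χ
    sidechain: np.ndarray  # all side-chain atom indices (union of moved)


class PartnerStructure:
    """One binding partner: ordered heavy atoms plus per-residue χ topology.

    Coordinates are the partner's *base* geometry; rigid placement and χ
    changes are applied on top (see :class:`ComplexPose`).
    """

    def __init__(self, atoms: list[AtomRecord], chi_table: dict[str, list[ChiDef]] | None = None):
        if not atoms:
            raise ValueError("empty partner: a partner needs at least one atom")
        pid = atoms[0].partner_id
        if any(a.partner_id != pid for a in atoms):
            raise ValueError("all atoms of a partner must share one partner_id")
        self.partner_id = pid
        self.atom_names = np.array([a.atom_name for a in atoms])
        self.elements = np.array([a.element for a in atoms])
        self.residue_index = np.array([a.residue_index for a in atoms], dtype=int)
        self.residue_types = np.array([a.residue_type for a in atoms])
        self.coords = np.array([a.position for a in atoms], dtype=float)
        self.radius_hard = np.array([a.radius_hard for a in atoms], dtype=float)
        self.well_depth = np.array([a.well_depth for a in atoms], dtype=float)
        self.nonpolar = np.array([a.nonpolar for a in atoms], dtype=bool)
        self.charge = np.array([a.charge for a in atoms], dtype=float)
        self._build_residue_table()
        self._build_chi(chi_table or STANDARD_CHI_TABLE)

    # -- construction helpers ------------------------------------------------
    def _build_residue_table(self) -> None:
        self.residue_table: dict[int, tuple[str, np.ndarray]] = {}
        for ri in np.unique(self.residue_index):
            mask = np.flatnonzero(self.residue_index == ri)
            self.residue_table[int(ri)] = (str(self.residue_types[mask[0]]), mask)

    def _build_chi(self, chi_table: dict[str, list[ChiDef]]) -> None:
        self.chi_topology: dict[int, _ResidueChi] = {}
        for ri, (rtype, span) in self.residue_table.items():
            defs = chi_table.get(rtype)
            if not defs:
                continue
            names = {str(self.atom_names[i]): i for i in span}
            quadruples, moved = [], []
            for cd in defs:
                if not all(n in names for n in cd.atom_quadruple):
                    continue  # incomplete side chain: skip this and deeper χ
                quadruples.append(np.array([names[n] for n in cd.atom_quadruple], dtype=int))
                moved.append(np.array(sorted(names[n] for n in cd.moved_atoms if n in names), dtype=int))
            if quadruples:
                side = np.unique(np.concatenate(moved))
                self.chi_topology[ri] = _ResidueChi(quadruples, moved, side)

    # -- queries -------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def backbone_indices(self) -> np.ndarray:
        mask = np.isin(self.atom_names, BACKBONE_ATOMS)
        return np.flatnonzero(mask)

    def measure_chi(self, coords: np.ndarray, residue_index: int) -> np.ndarray:
        """χ angles (deg) of one residue as realized in ``coords``."""
        topo = self.chi_topology[residue_index]
        return np.array(
            [measure_dihedral(*(coords[q] for q in quad)) for quad in topo.quadruples]
        )

    def chi_residues(self) -> list[int]:
        return sorted(self.chi_topology)

    def apply_chi(self, coords: np.ndarray, residue_index: int, chi_target: np.ndarray) -> np.ndarray:
        """Return a copy of ``coords`` with one residue's χ set to ``chi_target``.

        Each χ is set in order by rotating its moved-atom set about the
        dihedral's central bond by the difference to the current value.
        """
        out = coords.copy()
        topo = self.chi_topology[residue_index]
        for k, quad in enumerate(topo.quadruples):
            current = measure_dihedral(*(out[q] for q in quad))
            delta = chi_target[k] - current
            if abs(delta) < 1e-12:
                continue
            b, c = out[quad[1]], out[quad[2]]
            # rotating the distal set by -delta about the b->c axis raises the
            # signed dihedral by +delta under the IUPAC sign convention
            axis = c - b
            rot = quat_to_matrix(quat_from_axis_angle(axis, -delta))
            idx = topo.moved[k]
            out[idx] = (out[idx] - c) @ rot.T + c
        return out


class ComplexPose:
    """Receptor + mobile ligand under a rigid transform, plus χ angles.

    The ligand transform rotates about the *base* ligand centroid and then
    translates, so the translation component is exactly the displacement of
    the ligand's centre — which keeps the 20 Å / 90° restriction accounting
    decoupled.  ``start_transform`` is the immutable reference the restriction
    is measured against.
    """

    def __init__(
        self,
        receptor: PartnerStructure,
        ligand_base: PartnerStructure,
        ligand_transform: RigidTransform | None = None,
        chi_angles: dict[tuple[str, int], np.ndarray] | None = None,
        start_transform: RigidTransform | None = None,
    ):
        self.receptor = receptor
        self.ligand_base = ligand_base
        self.ligand_transform = (ligand_transform or RigidTransform.identity()).copy()
        self.start_transform = (start_transform or self.ligand_transform).copy()
        if chi_angles is None:
            chi_angles = {}
            for pid, partner in (("receptor", receptor), ("ligand", ligand_base)):
                for ri in partner.chi_residues():
                    chi_angles[(pid, ri)] = partner.measure_chi(partner.coords, ri)
        self.chi_angles = {k: np.asarray(v, float) for k, v in chi_angles.items()}
        self._ligand_centroid = ligand_base.centroid.copy()

    # -- copies --------------------------------------------------------------
    def copy(self) -> "ComplexPose":
        new = object.__new__(ComplexPose)  # hot path: skip validation
        new.receptor = self.receptor
        new.ligand_base = self.ligand_base
        new.ligand_transform = self.ligand_transform.copy()
        new.start_transform = self.start_transform.copy()
        new.chi_angles = {k: v.copy() for k, v in self.chi_angles.items()}
        new._ligand_centroid = self._ligand_centroid
        return new

    def with_transform(self, transform: RigidTransform) -> "ComplexPose":
        new = self.copy()
        new.ligand_transform = transform.copy()
        return new

    def with_chi(self, partner_id: str, residue_index: int, chi: np.ndarray) -> "ComplexPose":
        new = self.copy()
        new.chi_angles[(partner_id, residue_index)] = np.array(
            [wrap_angle(float(c)) for c in chi]
        )
        return new

    # -- realization ---------------------------------------------------------
    def receptor_coordinates(self) -> np.ndarray:
        """Receptor coordinates with current χ applied (never rigidly moved)."""
        coords = self.receptor.coords
        out = None
        for (pid, ri), chi in self.chi_angles.items():
            if pid != "receptor":
                continue
            base = self.receptor.measure_chi(coords if out is None else out, ri)
            if np.allclose(base, chi, atol=1e-9):
                continue
            out = self.receptor.apply_chi(coords if out is None else out, ri, chi)
        return coords if out is None else out

    def ligand_base_coordinates(self) -> np.ndarray:
        """Ligand base-frame coordinates with current χ applied."""
        coords = self.ligand_base.coords
        out = None
        for (pid, ri), chi in self.chi_angles.items():
            if pid != "ligand":
                continue
            base = self.ligand_base.measure_chi(coords if out is None else out, ri)
            if np.allclose(base, chi, atol=1e-9):
                continue
            out = self.ligand_base.apply_chi(coords if out is None else out, ri, chi)
        return coords if out is None else out

    def ligand_coordinates(self) -> np.ndarray:
        """Realized ligand coordinates: R·(x − c) + c + t about the base centroid."""
        x = self.ligand_base_coordinates()
        c = self._ligand_centroid
        r = self.ligand_transform.matrix
        return (x - c) @ r.T + c + self.ligand_transform.translation

    def com_separation(self) -> float:
        """Distance between the partners' (unweighted) centres, Å."""
        return float(
            np.linalg.norm(self.receptor_coordinates().mean(0) - self.ligand_coordinates().mean(0))
        )


def realized_coordinates(pose: ComplexPose) -> np.ndarray:
    """Realized ligand coordinates of a pose (module-level convenience)."""
    return pose.ligand_coordinates()


# -- PDB I/O -----------------------------------------------------------------

def _atoms_from_array(
    array: bst.AtomArray,
    chains: tuple[str, ...],
    partner_id: str,
    params: AtomParams,
) -> list[AtomRecord]:
    mask = np.isin(array.chain_id, list(chains))
    sub = array[mask]
    # drop hydrogens (extended-atom parameterization)
    heavy = ~np.isin(np.char.upper(sub.element.astype(str)), ["H", "D"])
    sub = sub[heavy]
    records = []
    for at in sub:
        try:
            radius, eps, nonpolar, charge = params.lookup(str(at.res_name), str(at.atom_name))
        except KeyError as exc:
            raise KeyError(
                f"{exc.args[0]} (residue {at.res_name} {at.res_id}, partner {partner_id})"
            ) from None
        records.append(
            AtomRecord(
                atom_name=str(at.atom_name),
                element=str(at.element),
                residue_index=int(at.res_id),
                residue_type=str(at.res_name),
                partner_id=partner_id,
                position=np.array(at.coord, dtype=float),
                radius_hard=radius,
                well_depth=eps,
                nonpolar=nonpolar,
                charge=charge,
            )
        )
    return records


def read_complex(
    pdb_source,
    receptor_chains,
    ligand_chains,
    atom_params: AtomParams,
    chi_table: dict[str, list[ChiDef]] | None = None,
) -> ComplexPose:
    """Read a two-partner complex from a PDB file (path, handle or text).

    Chains listed in ``receptor_chains`` form the fixed partner, those in
    ``ligand_chains`` the mobile one; hydrogens are discarded.  Every heavy
    atom must resolve in ``atom_params`` (wildcard rows act as defaults).
    The returned pose carries an identity ligand transform.
    """
    if isinstance(pdb_source, str) and "\n" in pdb_source:
        pdb_file = PDBFile.read(io.StringIO(pdb_source))
    else:
        pdb_file = PDBFile.read(pdb_source)
    array = pdb_file.get_structure(model=1)
    receptor_chains = tuple(receptor_chains)
    ligand_chains = tuple(ligand_chains)
    present = set(np.unique(array.chain_id))
    unknown = (set(receptor_chains) | set(ligand_chains)) - present
    if unknown:
        raise ValueError(f"unknown chain id(s): {sorted(unknown)}; file has {sorted(present)}")
    rec_atoms = _atoms_from_array(array, receptor_chains, "receptor", atom_params)
    lig_atoms = _atoms_from_array(array, ligand_chains, "ligand", atom_params)
    if not rec_atoms:
        raise ValueError("empty partner: no heavy atoms in receptor chains")
    if not lig_atoms:
        raise ValueError("empty partner: no heavy atoms in ligand chains")
    receptor = PartnerStructure(rec_atoms, chi_table)
    ligand = PartnerStructure(lig_atoms, chi_table)
    return ComplexPose(receptor, ligand)


def _pose_template(pose: ComplexPose) -> bst.AtomArray:
    n = pose.receptor.n_atoms + pose.ligand_base.n_atoms
    arr = bst.AtomArray(n)
    names = np.concatenate([pose.receptor.atom_names, pose.ligand_base.atom_names])
    elements = np.concatenate([pose.receptor.elements, pose.ligand_base.elements])
    res_ids = np.concatenate([pose.receptor.residue_index, pose.ligand_base.residue_index])
    res_names = np.concatenate([pose.receptor.residue_types, pose.ligand_base.residue_types])
    chains = np.array(["R"] * pose.receptor.n_atoms + ["L"] * pose.ligand_base.n_atoms)
    arr.atom_name = names
    arr.element = elements
    arr.res_id = res_ids
    arr.res_name = res_names
    arr.chain_id = chains
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_snapshots(poses, score_table: pd.DataFrame, path) -> None:
    """Write poses as a multi-MODEL PDB plus a tab-separated score table.

    The score table is written next to the PDB with suffix ``.scores.tsv``.
    All poses must share one topology.  An empty pose list produces a valid
    empty PDB and a header-only table.
    """
    path = Path(path)
    poses = list(poses)
    pdb_file = PDBFile()
    if poses:
        template = _pose_template(poses[0])
        coords = np.stack(
            [
                np.concatenate([p.receptor_coordinates(), p.ligand_coordinates()])
                for p in poses
            ]
        )
        stack = bst.from_template(template, coords.astype(np.float32))
        pdb_file.set_structure(stack)
    pdb_file.write(path)
    score_path = path.with_suffix(path.suffix + ".scores.tsv")
    score_table.to_csv(score_path, sep="\t", index=False)


def read_snapshots(path, template_pose: ComplexPose) -> list[ComplexPose]:
    """Read a multi-MODEL snapshot PDB back into poses.

    Coordinates are taken verbatim (identity ligand transform); the template
    pose supplies topology and parameters.  Intended for decoy analysis, not
    for resuming a run.
    """
    pdb_file = PDBFile.read(path)
    stack = pdb_file.get_structure()
    n_rec = template_pose.receptor.n_atoms
    poses = []
    for model in stack:
        rec = _partner_with_coords(template_pose.receptor, model.coord[:n_rec])
        lig = _partner_with_coords(template_pose.ligand_base, model.coord[n_rec:])
        poses.append(ComplexPose(rec, lig))
    return poses


def _partner_with_coords(partner: PartnerStructure, coords: np.ndarray) -> PartnerStructure:
    import copy as _copy

    new = _copy.copy(partner)
    new.coords = np.asarray(coords, dtype=float)
    return new
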