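"""Synthetic toy complexes for end-to-end testing of the docking protocols.

A toy complex is a miniature two-partner system engineered so that the bound
("native") arrangement is the global minimum of the package's own docking
score, by construction: a planar receptor "pocket" of beads and a ligand
whose anchor beads sit exactly at the pair-potential minimum distance
``r = sigma_ij`` above them.  Options add a *decoy trap* — a laterally
displaced, shallower binding patch that creates a competing local minimum —
and both partners carry one 4-bead side-chain residue with a single χ angle
so all three side-chain movers are exercised.

The module also generates starting geometries the way docking refinement
benchmarks do — the mobile partner displaced by exactly 15 Å in a random
direction and rotated by exactly 60° about a random axis through its
centroid, rejection-sampled until sterically clash-free — and bundles the
matching atom-parameter table, a miniature rotamer library and ready-to-run
configurations of the four protocols.

Toy geometries make no attempt at realistic protein topology; they exist so
the samplers, the score and the analysis can be certified quickly against
closed-form and brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import EnergyParams, PairTables, lj_pair, make_level
from .geometry import RigidTransform, quat_from_axis_angle, quat_multiply, random_unit_vector
from .movers import MoverSchedule, Rotamer, RotamerLibrary
from .sampling import ProtocolConfig
from .structure import AtomRecord, AtomParams, ChiDef, ComplexPose, PartnerStructure

__all__ = [
    "ToyComplexSpec",
    "TOY_CHI_TABLE",
    "make_toy_complex",
    "generate_start",
    "trap_pose",
    "default_params",
]

_BEAD_RADIUS = 2.0  # Å -> pair contact distance sigma_ij = 4.0 Å
_SUPPORT_EPS = 0.05
_CONTACT_Z = 2 * _BEAD_RADIUS

TOY_CHI_TABLE = {
    "LSC": [ChiDef(("N", "CA", "CB", "CG"), ("CG",))],
    "RSC": [ChiDef(("N", "CA", "CB", "CG"), ("CG",))],
}


@dataclass
class ToyComplexSpec:
    """Size, funnel depth and optional decoy trap of a toy complex.

    ``funnel_depth`` is the Lennard-Jones well depth (score units) of the
    native contact beads; the trap, if any, is ``(lateral offset Å, well
    depth)`` of a competing shallower patch.
    """

    receptor_atom_count: int = 16
    ligand_atom_count: int = 8
    funnel_depth: float = 2.0
    decoy_trap: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.receptor_atom_count < 1 or self.ligand_atom_count < 1:
            raise ValueError("atom counts must be >= 1")
        if self.funnel_depth <= 0:
            raise ValueError("funnel depth must be positive")
        if self.decoy_trap is not None:
            offset, depth = self.decoy_trap
            if offset <= 0:
                raise ValueError("trap offset must be positive")
            if depth >= self.funnel_depth:
                raise ValueError("infeasible spec: trap deeper than funnel")
            if depth <= 0:
                raise ValueError("trap depth must be positive")


_SPACING = 4.0  # lattice constant = sigma_ij: hollow-seated beads touch at the LJ minimum
_A1 = np.array([_SPACING, 0.0])
_A2 = np.array([_SPACING / 2, _SPACING * np.sqrt(3) / 2])
#: height above the pocket plane at which a bead in an up-triangle hollow is
#: exactly sigma = 4 A from all three vertices: sqrt(sigma^2 - (s/sqrt(3))^2)
_HOLLOW_Z = float(np.sqrt(_SPACING**2 - (_SPACING / np.sqrt(3)) ** 2))


def _hex_sites(n: int, spacing: float = _SPACING) -> np.ndarray:
    """First ``n`` points of a triangular lattice, sorted by radius."""
    pts = []
    r = int(np.ceil(np.sqrt(n))) + 2
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            pts.append((spacing * (i + 0.5 * j), spacing * (np.sqrt(3) / 2) * j))
    pts.sort(key=lambda p: (p[0] ** 2 + p[1] ** 2, p))
    return np.array(pts[:n])


def _toy_layout(spec: ToyComplexSpec) -> dict:
    """Deterministic geometry plan of a toy complex.

    The bound ligand seats each anchor bead in an "up-triangle" hollow of the
    receptor pocket lattice, touching its three vertex beads at exactly
    sigma.  The hollow is the single-bead optimum of the pair potential on a
    triangular patch (an on-top placement reaches only one contact), so the
    bound arrangement maximizes contacts by construction.  Tiny receptors
    (< 3 pocket beads) fall back to a single on-top contact per anchor.
    """
    n_l, n_r = spec.ligand_atom_count, spec.receptor_atom_count
    n_sc_l = 1 if n_l >= 5 else 0
    n_anchor = (n_l - 4 * n_sc_l) + n_sc_l
    reserve = (3 if spec.decoy_trap is not None else 0) + (4 if n_r >= 12 else 0)
    pocket_budget = max(n_r - reserve, min(n_r, 3))

    # greedy hollow selection by radius under the pocket vertex budget
    cand = []
    for i in range(-3, 4):
        for j in range(-3, 4):
            centre = i * _A1 + j * _A2 + (_A1 + _A2) / 3
            verts = [tuple(np.round(v, 6)) for v in (i * _A1 + j * _A2, (i + 1) * _A1 + j * _A2, i * _A1 + (j + 1) * _A2)]
            cand.append((float(centre @ centre), tuple(centre), verts))
    cand.sort()
    hollows: list[tuple[float, float]] = []
    verts: list[tuple[float, float]] = []
    if pocket_budget >= 3:
        for _, centre, vs in cand:
            new = [v for v in vs if v not in verts]
            if len(verts) + len(new) > pocket_budget:
                continue
            verts.extend(new)
            hollows.append(centre)
            if len(hollows) == n_anchor:
                break
    if len(hollows) == n_anchor:
        anchor_xy = np.array(hollows)
        anchor_z = _HOLLOW_Z
        pocket = np.array(verts)
    else:  # tiny receptor: one on-top contact per anchor
        anchor_xy = _hex_sites(max(n_anchor, 1))[:n_anchor]
        anchor_z = _SPACING
        pocket = _hex_sites(max(min(n_r, n_anchor), 1))[: min(n_r, n_anchor)]
    trap = None
    if spec.decoy_trap is not None:
        base = np.array([spec.decoy_trap[0], 0.0])
        trap = {
            "vertices": np.array([base, base + _A1, base + _A2]),
            "translation": np.array(
                [*(base + (_A1 + _A2) / 3 - anchor_xy[0]), 0.0]
            ),
        }
    return {
        "anchor_xy": anchor_xy,
        "anchor_z": anchor_z,
        "pocket": pocket,
        "n_anchor": n_anchor,
        "n_sc_l": n_sc_l,
        "trap": trap,
    }


def _atom(name, res_idx, res_type, partner, xyz, eps):
    return AtomRecord(
        atom_name=name,
        element="C",
        residue_index=res_idx,
        residue_type=res_type,
        partner_id=partner,
        position=np.asarray(xyz, float),
        radius_hard=_BEAD_RADIUS,
        well_depth=eps,
        nonpolar=True,
    )


def _sidechain_residue(partner, res_idx, res_type, anchor_xyz, anchor_eps, up=1.0):
    """4-bead residue N-CA-CB-CG with one χ about the CA-CB bond.

    The N/CB/CG beads point away from the interface (``up`` sign of z) so
    the side chain decorates the residue without blocking the anchor contact.
    """
    x, y, z = anchor_xyz
    return [
        _atom("N", res_idx, res_type, partner, (x - 1.5, y, z + up * 1.0), _SUPPORT_EPS),
        _atom("CA", res_idx, res_type, partner, (x, y, z), anchor_eps),
        _atom("CB", res_idx, res_type, partner, (x, y, z + up * 1.5), _SUPPORT_EPS),
        _atom("CG", res_idx, res_type, partner, (x + 1.5, y, z + up * 1.5), _SUPPORT_EPS),
    ]


def make_toy_complex(
    spec: ToyComplexSpec | None = None,
) -> tuple[ComplexPose, AtomParams, RotamerLibrary]:
    """Build a toy complex in its bound pose plus its parameter tables.

    Deterministic for a given spec/seed.  Ligand anchor beads sit at exactly
    ``sigma_ij`` above receptor pocket beads, so the bound pose realizes every
    contact at the pair-potential minimum; support beads below the pocket
    plane (small well depth, seeded sub-Å jitter) give the receptor bulk.
    """
    spec = spec or ToyComplexSpec()
    rng = np.random.default_rng(spec.seed)
    layout = _toy_layout(spec)
    anchor_xy, z = layout["anchor_xy"], layout["anchor_z"]

    # --- ligand: anchors (+ one side-chain residue if it fits) -------------
    n_l = spec.ligand_atom_count
    lig_atoms: list[AtomRecord] = []
    res = 1
    for i in range(n_l - 4 * layout["n_sc_l"]):
        x, y = anchor_xy[i]
        lig_atoms.append(_atom("CA", res, "LAN", "ligand", (x, y, z), spec.funnel_depth))
        res += 1
    if layout["n_sc_l"]:
        x, y = anchor_xy[layout["n_anchor"] - 1]
        lig_atoms.extend(
            _sidechain_residue("ligand", res, "LSC", (x, y, z), spec.funnel_depth, up=+1.0)
        )
        res += 1

    # --- receptor: pocket, optional trap, side-chain residue, supports -----
    n_r = spec.receptor_atom_count
    rec_atoms: list[AtomRecord] = []
    res = 1
    for x, y in layout["pocket"]:
        rec_atoms.append(_atom("CA", res, "PKT", "receptor", (x, y, 0.0), spec.funnel_depth))
        res += 1
    remaining = n_r - len(layout["pocket"])
    if layout["trap"] is not None and remaining >= 3:
        depth = spec.decoy_trap[1]
        for x, y in layout["trap"]["vertices"]:
            rec_atoms.append(_atom("CA", res, "TRQ", "receptor", (x, y, 0.0), depth))
            res += 1
        remaining -= 3
    if remaining >= 4:
        edge_x = float(layout["pocket"][:, 0].min()) - _SPACING
        rec_atoms.extend(
            _sidechain_residue("receptor", res, "RSC", (edge_x, 0.0, 0.0), _SUPPORT_EPS, up=-1.0)
        )
        res += 1
        remaining -= 4
    support_sites = _hex_sites(max(remaining, 1))
    for i in range(remaining):
        x, y = support_sites[i] + rng.uniform(-0.3, 0.3, 2)
        rec_atoms.append(
            _atom("CA", res, "SUP", "receptor", (x, y, -3.0 + rng.uniform(-0.2, 0.2)), _SUPPORT_EPS)
        )
        res += 1

    receptor = PartnerStructure(rec_atoms, TOY_CHI_TABLE)
    ligand = PartnerStructure(lig_atoms, TOY_CHI_TABLE)
    native = ComplexPose(receptor, ligand)

    params = _toy_params(spec)
    library = _toy_library()
    return native, params, library


def _toy_params(spec: ToyComplexSpec) -> AtomParams:
    rows = [
        ("PKT", "CA", _BEAD_RADIUS, spec.funnel_depth, 1),
        ("LAN", "CA", _BEAD_RADIUS, spec.funnel_depth, 1),
        ("SUP", "CA", _BEAD_RADIUS, _SUPPORT_EPS, 1),
    ]
    if spec.decoy_trap is not None:
        rows.append(("TRQ", "CA", _BEAD_RADIUS, spec.decoy_trap[1], 1))
    for rtype, anchor_eps in (("LSC", spec.funnel_depth), ("RSC", _SUPPORT_EPS)):
        rows.extend(
            [
                (rtype, "N", _BEAD_RADIUS, _SUPPORT_EPS, 1),
                (rtype, "CA", _BEAD_RADIUS, anchor_eps, 1),
                (rtype, "CB", _BEAD_RADIUS, _SUPPORT_EPS, 1),
                (rtype, "CG", _BEAD_RADIUS, _SUPPORT_EPS, 1),
            ]
        )
    table = pd.DataFrame(
        rows, columns=["residue_type", "atom_name", "radius_hard", "well_depth", "nonpolar"]
    )
    return AtomParams(table)


def _toy_library() -> RotamerLibrary:
    rots = [
        Rotamer(0.5, np.array([60.0]), np.array([20.0])),
        Rotamer(0.3, np.array([-60.0]), np.array([20.0])),
        Rotamer(0.2, np.array([180.0]), np.array([20.0])),
    ]
    return RotamerLibrary({"LSC": list(rots), "RSC": list(rots)})


def trap_pose(native: ComplexPose, spec: ToyComplexSpec) -> ComplexPose:
    """The decoy-trap arrangement: the first anchor seated in the trap hollow."""
    if spec.decoy_trap is None:
        raise ValueError("spec has no decoy trap")
    layout = _toy_layout(spec)
    return native.with_transform(RigidTransform(translation=layout["trap"]["translation"]))


CLASH_ENERGY_THRESHOLD = 10.0  # score units on a single hard-rep pair


def _max_pair_rep(pose: ComplexPose, params: EnergyParams) -> float:
    tables = PairTables(pose, make_level(0.0, "hard_rep"), params)
    rec, lig = pose.receptor_coordinates(), pose.ligand_coordinates()
    d = rec[:, None, :] - lig[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    np.maximum(r, 1e-6, out=r)
    _, rep = lj_pair(r, tables.sigma, tables.eps, tables.switch_fraction)
    return float(np.max(rep))


def generate_start(
    native: ComplexPose,
    translation_magnitude: float = 15.0,
    rotation_magnitude: float = 60.0,
    rng: np.random.Generator | None = None,
    params: EnergyParams | None = None,
    max_attempts: int = 10_000,
) -> ComplexPose:
    """Generate a docking start: exact 15 Å / 60° displacement, clash-free.

    The ligand is translated by exactly ``translation_magnitude`` in a
    uniform random direction and rotated by exactly ``rotation_magnitude``
    about a uniform random axis through its centroid, re-sampled until no
    inter-partner pair exceeds the hard-repulsion clash threshold.  The
    resulting transform is recorded as the pose's ``start_transform``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    params = params or EnergyParams()
    base = native.ligand_transform
    for _ in range(max_attempts):
        direction = random_unit_vector(rng)
        if rotation_magnitude > 0:
            axis = random_unit_vector(rng)
            quat = quat_multiply(quat_from_axis_angle(axis, rotation_magnitude), base.quat)
        else:
            quat = base.quat.copy()
        transform = RigidTransform(quat, base.translation + translation_magnitude * direction)
        candidate = ComplexPose(
            native.receptor,
            native.ligand_base,
            transform,
            {k: v.copy() for k, v in native.chi_angles.items()},
            start_transform=transform,
        )
        if _max_pair_rep(candidate, params) < CLASH_ENERGY_THRESHOLD:
            return candidate
    raise RuntimeError(f"no clash-free start geometry found in {max_attempts} attempts")


def default_params(
    spec: ToyComplexSpec | None = None,
) -> tuple[AtomParams, MoverSchedule, dict[str, ProtocolConfig]]:
    """Bundle the published defaults: parameter table, reference mover
    schedule (weights 0.5/4/6/10, steps 0.1 Å/1°) and the four ready-to-run
    protocol configurations (MC at T=0.15; REMC 13 temperatures 0.15-0.31;
    WTE-REMC 5 temperatures with γ=5, bin width 2; WTE-H-REMC 5 temperatures
    0.15-0.3 x 5 repulsive-softness levels = 25 replicas)."""
    spec = spec or ToyComplexSpec()
    params = _toy_params(spec)
    schedule = MoverSchedule.reference()
    configs = {name: ProtocolConfig(protocol=name) for name in ("MC", "REMC", "WTE-REMC", "WTE-H-REMC")}
    return params, schedule, configs
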