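"""Proposal kernels for Metropolis-Hastings docking moves.

Four movers drive the search: one rigid-body kernel (Gaussian translations
along all three axes plus a Gaussian-angle rotation about a uniform random
axis, composed with the current rotation) and three side-chain kernels
operating on the χ angles of one randomly chosen residue:

* ``jump_rotamer`` — draw a rotamer by library probability, then each χ from
  a Gaussian around that rotamer's means.  Forward/reverse densities are the
  full rotamer-marginalized mixtures, so the Hastings ratio is exact.
* ``perturb_rotamer`` — pick the rotamer most likely to have produced the
  *current* χ (argmax of probability × Gaussian likelihood, ties broken by
  lowest index) and redraw χ around its means; single-component densities in
  both directions.
* ``perturb_chi`` — symmetric Gaussian (or uniform) increments on every χ of
  the residue, wrapped to (-180, 180].

Gaussian χ densities include the ±360° wrap images, so the kernels are
proper densities on the circle and a flat-energy chain is stationary on the
uniform law — the property the detailed-balance tests check.

The sampling-space restriction (default 20 Å translation / 90° rotation
relative to the start transform) is enforced by rejecting violating rigid
proposals; with a symmetric kernel this preserves detailed balance on the
truncated space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import quat_from_axis_angle, quat_multiply, random_unit_vector, relative_transform
from .structure import ComplexPose, wrap_angle

__all__ = [
    "MOVER_LABELS",
    "MoverSchedule",
    "Rotamer",
    "RotamerLibrary",
    "Proposal",
    "select_mover",
    "propose_rigid_body",
    "propose_jump_rotamer",
    "propose_perturb_rotamer",
    "propose_perturb_chi",
    "within_restriction",
    "eligible_residues",
    "interpolate_schedule",
]

MOVER_LABELS = ("rigid_body", "jump_rotamer", "perturb_rotamer", "perturb_chi")

#: Reference sampling weights for (rigid body, jump rotamer, perturb rotamer,
#: perturb chi) and the reference rigid-body step sigmas.
REFERENCE_WEIGHTS = {"rigid_body": 0.5, "jump_rotamer": 4.0, "perturb_rotamer": 6.0, "perturb_chi": 10.0}
HOT_WEIGHTS = {"rigid_body": 4.0, "jump_rotamer": 2.0, "perturb_rotamer": 3.0, "perturb_chi": 5.0}


@dataclass
class MoverSchedule:
    """Mover weights and step magnitudes of one replica."""

    weights: dict = field(default_factory=lambda: dict(REFERENCE_WEIGHTS))
    trans_sigma: float = 0.1  # Å
    rot_sigma: float = 1.0  # degrees
    chi_sigma: float = 10.0  # degrees, perturb_chi magnitude
    chi_uniform: bool = False

    def __post_init__(self) -> None:
        if all(w <= 0 for w in self.weights.values()):
            raise ValueError("at least one mover weight must be positive")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("mover weights must be non-negative")
        if self.trans_sigma < 0 or self.rot_sigma < 0 or self.chi_sigma < 0:
            raise ValueError("step magnitudes must be >= 0")

    @classmethod
    def reference(cls) -> "MoverSchedule":
        return cls()

    @classmethod
    def hot(cls) -> "MoverSchedule":
        return cls(weights=dict(HOT_WEIGHTS), trans_sigma=1.0, rot_sigma=10.0)


def interpolate_schedule(
    reference: MoverSchedule, hot: MoverSchedule, fraction: float
) -> MoverSchedule:
    """Linear blend between the reference (fraction 0) and hot-end (1) schedules.

    Used to give colder/harder replicas more frequent small side-chain moves
    and hotter/softer replicas fewer but larger rigid-body moves.
    """
    f = float(np.clip(fraction, 0.0, 1.0))
    weights = {
        k: (1 - f) * reference.weights.get(k, 0.0) + f * hot.weights.get(k, 0.0)
        for k in MOVER_LABELS
    }
    return MoverSchedule(
        weights=weights,
        trans_sigma=(1 - f) * reference.trans_sigma + f * hot.trans_sigma,
        rot_sigma=(1 - f) * reference.rot_sigma + f * hot.rot_sigma,
        chi_sigma=(1 - f) * reference.chi_sigma + f * hot.chi_sigma,
        chi_uniform=reference.chi_uniform,
    )


@dataclass(frozen=True)
class Rotamer:
    """One canonical side-chain conformation: weight + Gaussian χ parameters."""

    probability: float
    chi_means: np.ndarray  # degrees
    chi_sigmas: np.ndarray  # degrees


class RotamerLibrary:
    """Residue type -> probability-weighted rotamers with Gaussian χ spread.

    File format (tab-separated): ``residue_type  rotamer_index  probability
    chi_means  chi_sigmas`` with the per-χ values comma-joined.
    """

    def __init__(self, rotamers: dict[str, list[Rotamer]]):
        self.rotamers = {}
        for rtype, rots in rotamers.items():
            rots = [
                Rotamer(float(r.probability), np.asarray(r.chi_means, float), np.asarray(r.chi_sigmas, float))
                for r in rots
            ]
            total = sum(r.probability for r in rots)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"rotamer probabilities of {rtype} sum to {total}, not 1")
            if any(np.any(r.chi_sigmas <= 0) for r in rots):
                raise ValueError(f"rotamer sigmas of {rtype} must be positive")
            self.rotamers[rtype] = rots

    def __contains__(self, rtype: str) -> bool:
        return rtype in self.rotamers

    def __getitem__(self, rtype: str) -> list[Rotamer]:
        return self.rotamers[rtype]

    @classmethod
    def from_tsv(cls, source) -> "RotamerLibrary":
        import pandas as pd

        table = pd.read_csv(source, sep="\t", comment="#")
        rotamers: dict[str, list[tuple[int, Rotamer]]] = {}
        for row in table.itertuples(index=False):
            means = np.array([float(x) for x in str(row.chi_means).split(",")])
            sigmas = np.array([float(x) for x in str(row.chi_sigmas).split(",")])
            rotamers.setdefault(str(row.residue_type), []).append(
                (int(row.rotamer_index), Rotamer(float(row.probability), means, sigmas))
            )
        return cls({k: [r for _, r in sorted(v)] for k, v in rotamers.items()})

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for rtype, rots in self.rotamers.items():
            for i, r in enumerate(rots):
                rows.append(
                    {
                        "residue_type": rtype,
                        "rotamer_index": i,
                        "probability": r.probability,
                        "chi_means": ",".join(f"{m:g}" for m in r.chi_means),
                        "chi_sigmas": ",".join(f"{s:g}" for s in r.chi_sigmas),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class Proposal:
    """A proposed pose with its forward/reverse log proposal densities."""

    new_pose: ComplexPose
    log_forward_density: float
    log_reverse_density: float
    mover_label: str
    residue: tuple[str, int] | None = None  # (partner_id, residue_index) if side-chain


def select_mover(schedule: MoverSchedule, rng: np.random.Generator) -> str:
    """Draw a mover label with probability proportional to its weight."""
    labels = [l for l in MOVER_LABELS if schedule.weights.get(l, 0.0) > 0]
    w = np.array([schedule.weights[l] for l in labels])
    return labels[rng.choice(len(labels), p=w / w.sum())]


def propose_rigid_body(
    pose: ComplexPose, schedule: MoverSchedule, rng: np.random.Generator
) -> Proposal:
    """Symmetric rigid-body kernel: Gaussian translation + axis-angle rotation."""
    dt = rng.standard_normal(3) * schedule.trans_sigma if schedule.trans_sigma > 0 else np.zeros(3)
    quat = pose.ligand_transform.quat
    if schedule.rot_sigma > 0:
        axis = random_unit_vector(rng)
        angle = rng.standard_normal() * schedule.rot_sigma
        quat = quat_multiply(quat_from_axis_angle(axis, angle), quat)
    new = pose.with_transform(
        replace_transform(pose, quat, pose.ligand_transform.translation + dt)
    )
    return Proposal(new, 0.0, 0.0, "rigid_body")


def replace_transform(pose: ComplexPose, quat, translation):
    from .geometry import RigidTransform

    return RigidTransform(np.asarray(quat, float), np.asarray(translation, float))


def within_restriction(pose: ComplexPose, limits: tuple[float, float] = (20.0, 90.0)) -> bool:
    """True iff the pose lies inside the closed translation/rotation ball."""
    dt, da = relative_transform(pose.ligand_transform, pose.start_transform)
    return dt <= limits[0] and da <= limits[1]


def eligible_residues(pose: ComplexPose, library: RotamerLibrary | None = None):
    """Residues open to side-chain moves: χ-bearing, non-proline, on either partner.

    With a library given, only residue types present in it qualify (the
    rotamer movers need the Gaussian parameters).
    """
    out = []
    for pid, partner in (("receptor", pose.receptor), ("ligand", pose.ligand_base)):
        for ri in partner.chi_residues():
            rtype = partner.residue_table[ri][0]
            if rtype == "PRO":
                continue
            if library is not None and rtype not in library:
                continue
            out.append((pid, ri, rtype))
    return out


def _pick_residue(pose, library, rng):
    cands = eligible_residues(pose, library)
    if not cands:
        raise ValueError("no residue eligible for side-chain moves")
    return cands[rng.integers(len(cands))]


_LOG_2PI = float(np.log(2.0 * np.pi))


def _log_gauss_wrapped(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """log wrapped-Gaussian density on (-180, 180], per χ (±360° images)."""
    x = np.asarray(x, float)
    acc = np.zeros_like(x)
    for k in (-360.0, 0.0, 360.0):
        z = (x + k - mu) / sigma
        acc = acc + np.exp(-0.5 * z * z)
    with np.errstate(divide="ignore"):  # -inf is a legitimate log density
        return np.log(acc / (sigma * np.sqrt(2.0 * np.pi)))


def _log_mixture_density(chi: np.ndarray, rotamers: list[Rotamer]) -> float:
    """log Σ_rot p(rot)·Π_χ N_wrapped(χ; mean, σ)."""
    log_terms = [
        np.log(r.probability) + float(np.sum(_log_gauss_wrapped(chi, r.chi_means, r.chi_sigmas)))
        for r in rotamers
    ]
    m = max(log_terms)
    if not np.isfinite(m):
        return -np.inf
    return m + float(np.log(sum(np.exp(t - m) for t in log_terms)))


def _draw_chi(rotamer: Rotamer, rng: np.random.Generator) -> np.ndarray:
    raw = rotamer.chi_means + rng.standard_normal(rotamer.chi_means.shape) * rotamer.chi_sigmas
    return np.array([wrap_angle(float(v)) for v in raw])


def propose_jump_rotamer(
    pose: ComplexPose, library: RotamerLibrary, rng: np.random.Generator
) -> Proposal:
    """Independence-type χ resampling from the rotamer mixture of one residue."""
    pid, ri, rtype = _pick_residue(pose, library, rng)
    rotamers = library[rtype]
    probs = np.array([r.probability for r in rotamers])
    rot = rotamers[rng.choice(len(rotamers), p=probs)]
    chi_old = pose.chi_angles[(pid, ri)][: rot.chi_means.shape[0]]
    chi_new = _draw_chi(rot, rng)
    log_fwd = _log_mixture_density(chi_new, rotamers)
    log_rev = _log_mixture_density(chi_old, rotamers)
    return Proposal(pose.with_chi(pid, ri, chi_new), log_fwd, log_rev, "jump_rotamer", (pid, ri))


def argmax_rotamer(chi: np.ndarray, rotamers: list[Rotamer]) -> int:
    """Index of the rotamer most likely to have proposed ``chi``; ties -> lowest."""
    best, best_val = 0, -np.inf
    for i, r in enumerate(rotamers):
        val = np.log(r.probability) + float(np.sum(_log_gauss_wrapped(chi, r.chi_means, r.chi_sigmas)))
        if val > best_val + 1e-12:
            best, best_val = i, val
    return best


def propose_perturb_rotamer(
    pose: ComplexPose, library: RotamerLibrary, rng: np.random.Generator
) -> Proposal:
    """Redraw χ around the rotamer that best explains the current angles."""
    pid, ri, rtype = _pick_residue(pose, library, rng)
    rotamers = library[rtype]
    chi_old = pose.chi_angles[(pid, ri)][: rotamers[0].chi_means.shape[0]]
    rot_fwd = rotamers[argmax_rotamer(chi_old, rotamers)]
    chi_new = _draw_chi(rot_fwd, rng)
    rot_rev = rotamers[argmax_rotamer(chi_new, rotamers)]
    log_fwd = float(np.sum(_log_gauss_wrapped(chi_new, rot_fwd.chi_means, rot_fwd.chi_sigmas)))
    log_rev = float(np.sum(_log_gauss_wrapped(chi_old, rot_rev.chi_means, rot_rev.chi_sigmas)))
    return Proposal(pose.with_chi(pid, ri, chi_new), log_fwd, log_rev, "perturb_rotamer", (pid, ri))


def propose_perturb_chi(
    pose: ComplexPose, schedule: MoverSchedule, rng: np.random.Generator
) -> Proposal:
    """Symmetric increment on every χ of one residue, wrapped to (-180, 180]."""
    pid, ri, _ = _pick_residue(pose, None, rng)
    chi_old = pose.chi_angles[(pid, ri)]
    if schedule.chi_sigma == 0:
        return Proposal(pose.copy(), 0.0, 0.0, "perturb_chi", (pid, ri))
    if schedule.chi_uniform:
        delta = rng.uniform(-schedule.chi_sigma, schedule.chi_sigma, chi_old.shape)
    else:
        delta = rng.standard_normal(chi_old.shape) * schedule.chi_sigma
    chi_new = np.array([wrap_angle(float(v)) for v in chi_old + delta])
    return Proposal(pose.with_chi(pid, ri, chi_new), 0.0, 0.0, "perturb_chi", (pid, ri))
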