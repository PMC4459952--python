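"""Simplified docking score: split Lennard-Jones ladder + encounter constraint.

The score keeps the two ingredients the sampling protocols actually exploit:

* a 6-12 Lennard-Jones potential split into an attractive and a repulsive
  component, where the repulsive branch is replaced below a switch distance
  ``f_switch * sigma_ij`` by its tangent line (value- and slope-continuous
  linear extrapolation), and
* a ladder of progressively softened repulsive parameterizations
  ("hard_rep" -> "soft") obtained by linearly interpolating atomic radii
  (nonpolar radii inflated by 1.07 at the fully soft end) and the switch
  point, indexed by a coefficient lambda in [0, 1].

A flat-bottom harmonic encounter restraint on the centre-of-centre distance
prevents the partners from dissociating, and an optional distance-dependent
dielectric Coulomb term is available when charges are supplied.  Solvation,
hydrogen bonding and statistical terms of full docking force fields are
deliberately out of scope: the sampling machinery, not the force field, is
what this package is about.

Convention for the attractive/repulsive split: for r >= sigma the pair energy
is purely attractive; inside the minimum the attractive part is clamped at
-eps and the excess is repulsive.  All pair energies are smoothly tapered to
zero at ``sigma_ij + cutoff_offset``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import ComplexPose, PartnerStructure

__all__ = [
    "EnergyParams",
    "HamiltonianLevel",
    "ScoreBreakdown",
    "make_level",
    "effective_radii",
    "lj_pair",
    "score_pose",
    "interaction_score",
    "encounter_penalty",
    "PairTables",
    "DEFAULT_LEVELS",
]

COULOMB_CONSTANT = 332.0637  # kcal·Å/(mol·e²), used with eps(r) = r


@dataclass
class EnergyParams:
    """Weights and shape parameters of the docking score.

    ``soft_scale`` is the radius inflation of nonpolar atoms at the fully
    soft end of the Hamiltonian ladder; ``*_switch_fraction`` locate the
    linear-extrapolation switch as a fraction of sigma_ij for the hard and
    soft parameterizations.  The soft switch sits higher (0.8 vs. 0.6) so
    that every softer rung of the ladder penalizes a given clash distance no
    more than a harder one — radius inflation alone would do the opposite,
    since at fixed r it pushes pairs deeper into the steep linear branch.  ``encounter_d_max`` of ``None`` means the
    restraint is resolved at run start from the initial pose (its centre
    separation + 5 Å).
    """

    soft_scale: float = 1.07
    hard_switch_fraction: float = 0.6
    soft_switch_fraction: float = 0.8
    weights: dict = field(
        default_factory=lambda: {"atr": 1.0, "rep": 1.0, "coulomb": 1.0, "encounter": 1.0}
    )
    coulomb_enabled: bool = False
    encounter_d_max: float | None = None
    encounter_k: float = 1.0  # score units / Å^2
    cutoff_offset: float = 6.0  # outer cutoff = sigma_ij + offset, Å
    taper_width: float = 1.0  # cosine taper width, Å

    def __post_init__(self) -> None:
        if self.soft_scale < 1.0:
            raise ValueError("soft_scale must be >= 1")
        for f in (self.hard_switch_fraction, self.soft_switch_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("switch fractions must lie in (0, 1)")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")

    def resolved(self, pose: ComplexPose) -> "EnergyParams":
        """Copy with the encounter distance fixed from ``pose`` if unset."""
        if self.encounter_d_max is not None:
            return self
        import copy

        out = copy.copy(self)
        out.weights = dict(self.weights)
        out.encounter_d_max = pose.com_separation() + 5.0
        return out


@dataclass(frozen=True)
class HamiltonianLevel:
    """One rung of the hard->soft repulsive ladder: lambda in [0, 1]."""

    lam: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")


def make_level(lam: float, label: str | None = None) -> HamiltonianLevel:
    if label is None:
        label = "hard_rep" if lam == 0.0 else f"soft {round(lam * 100)}%"
    return HamiltonianLevel(float(lam), label)


#: Ladder used by the 2-D Hamiltonian replica exchange protocol.
DEFAULT_LEVELS = tuple(
    make_level(lam, lab)
    for lam, lab in [
        (0.0, "hard_rep"),
        (0.50, "soft 50%"),
        (0.55, "soft 55%"),
        (0.60, "soft 60%"),
        (0.65, "soft 65%"),
    ]
)


def effective_radii(
    radius_hard: np.ndarray, nonpolar: np.ndarray, level: HamiltonianLevel, params: EnergyParams
) -> np.ndarray:
    """Per-atom radii at a ladder level: (1-λ)·r_hard + λ·r_soft.

    r_soft inflates only atoms flagged nonpolar, by ``soft_scale``.
    """
    r_soft = np.where(nonpolar, params.soft_scale * radius_hard, radius_hard)
    return (1.0 - level.lam) * radius_hard + level.lam * r_soft


def effective_switch_fraction(level: HamiltonianLevel, params: EnergyParams) -> float:
    return (1.0 - level.lam) * params.hard_switch_fraction + level.lam * params.soft_switch_fraction


def lj_pair(
    r,
    sigma_ij,
    eps_ij,
    switch_fraction: float = 0.6,
    cutoff_offset: float = 6.0,
    taper_width: float = 1.0,
):
    """Split Lennard-Jones pair energy -> (attractive, repulsive) components.

    Base potential E(r) = eps·[(σ/r)^12 − 2(σ/r)^6] with minimum −eps at
    r = σ.  For r >= σ: atr = E, rep = 0.  For f·σ <= r < σ: atr = −eps,
    rep = E + eps.  Below the switch f·σ the repulsion continues as the
    tangent line at the switch.  atr is tapered smoothly to 0 at
    σ + cutoff_offset.  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sigma = np.asarray(sigma_ij, dtype=float)
    eps = np.asarray(eps_ij, dtype=float)
    s6 = (sigma / r) ** 6
    energy = eps * (s6 * s6 - 2.0 * s6)
    r_cut = sigma + cutoff_offset
    x = np.clip((r - (r_cut - taper_width)) / taper_width, 0.0, 1.0)
    taper = 0.5 * (1.0 + np.cos(np.pi * x))  # C1 at both ends
    outside = r >= sigma
    atr = np.where(outside, energy * taper, -eps)
    r_sw = switch_fraction * sigma
    rep_mid = energy + eps
    s6_sw = switch_fraction ** -6
    e_sw = eps * (s6_sw * s6_sw - 2.0 * s6_sw) + eps
    slope_sw = 12.0 * eps / (switch_fraction * sigma) * (s6_sw - s6_sw * s6_sw)
    rep_lin = e_sw + slope_sw * (r - r_sw)
    rep = np.where(outside, 0.0, np.where(r >= r_sw, rep_mid, rep_lin))
    if atr.ndim == 0:
        return float(atr), float(rep)
    return atr, rep


@dataclass
class ScoreBreakdown:
    """Per-term energies plus force-field and grand totals (score units)."""

    terms: dict
    forcefield_total: float
    bias: float

    @property
    def grand_total(self) -> float:
        return self.forcefield_total + self.bias


class PairTables:
    """Precomputed pair parameters of one pose topology at one ladder level.

    Holds the inter-partner sigma/eps matrices, the intra-partner clash pair
    lists (side-chain atoms of χ-bearing residues vs. atoms of other residues
    of the same partner, each unordered pair once), the switch fraction and
    optional charge products.  Built once per (topology, level); evaluation is
    then a handful of vectorized operations, which is what keeps the samplers'
    inner loop fast.
    """

    def __init__(self, pose: ComplexPose, level: HamiltonianLevel, params: EnergyParams):
        self.level = level
        self.params = params
        rec, lig = pose.receptor, pose.ligand_base
        r_rec = effective_radii(rec.radius_hard, rec.nonpolar, level, params)
        r_lig = effective_radii(lig.radius_hard, lig.nonpolar, level, params)
        self.sigma = r_rec[:, None] + r_lig[None, :]
        self.eps = np.sqrt(rec.well_depth[:, None] * lig.well_depth[None, :])
        self.switch_fraction = effective_switch_fraction(level, params)
        self.qq = (
            COULOMB_CONSTANT * rec.charge[:, None] * lig.charge[None, :]
            if params.coulomb_enabled
            else None
        )
        self.intra = [
            self._intra_pairs(rec, r_rec),
            self._intra_pairs(lig, r_lig),
        ]
        self._inter_consts = self._split_constants(self.sigma, self.eps)
        # merged intra pair list indexing the stacked [receptor; ligand] array
        merged_i, merged_j, merged_sig, merged_eps = [], [], [], []
        for offset, pairs in zip((0, rec.n_atoms), self.intra):
            if pairs is None:
                continue
            i, j, sig, eps = pairs
            merged_i.append(i + offset)
            merged_j.append(j + offset)
            merged_sig.append(sig)
            merged_eps.append(eps)
        if merged_i:
            self._intra_i = np.concatenate(merged_i)
            self._intra_j = np.concatenate(merged_j)
            sig = np.concatenate(merged_sig)
            eps = np.concatenate(merged_eps)
            self._intra_sig = sig
            self._intra_eps = eps
            self._intra_consts_merged = self._split_constants(sig, eps)
        else:
            self._intra_i = None

    def _split_constants(self, sigma, eps):
        """Per-pair constants of the split potential, hoisted out of the hot loop."""
        f = self.switch_fraction
        s6f = f ** -6
        r_sw = f * sigma
        e_sw_plus = eps * (s6f * s6f - 2.0 * s6f) + eps
        slope_sw = 12.0 * eps / r_sw * (s6f - s6f * s6f)
        t_start = sigma + self.params.cutoff_offset - self.params.taper_width
        return r_sw, e_sw_plus, slope_sw, t_start

    def _split_eval(self, r, sigma, eps, consts):
        """(atr_sum, rep_sum) of the split LJ on a distance array."""
        r_sw, e_sw_plus, slope_sw, t_start = consts
        t = sigma / r
        t = t * t
        s6 = t * t * t
        e = eps * (s6 * s6 - 2.0 * s6)
        x = np.clip((r - t_start) / self.params.taper_width, 0.0, 1.0)
        taper = 0.5 * (1.0 + np.cos(np.pi * x))
        outside = r >= sigma
        atr = np.where(outside, e * taper, -eps)
        rep = np.where(
            outside, 0.0, np.where(r >= r_sw, e + eps, e_sw_plus + slope_sw * (r - r_sw))
        )
        return float(atr.sum()), float(rep.sum())

    @staticmethod
    def _intra_pairs(partner: PartnerStructure, radii: np.ndarray):
        pairs = set()
        for ri, topo in partner.chi_topology.items():
            others = np.flatnonzero(partner.residue_index != ri)
            for s in topo.sidechain:
                for o in others:
                    pairs.add((min(int(s), int(o)), max(int(s), int(o))))
        if not pairs:
            return None
        idx = np.array(sorted(pairs), dtype=int)
        i, j = idx[:, 0], idx[:, 1]
        return i, j, radii[i] + radii[j], np.sqrt(partner.well_depth[i] * partner.well_depth[j])

    # -- evaluation ----------------------------------------------------------
    def inter_terms(self, rec_coords: np.ndarray, lig_coords: np.ndarray):
        d = rec_coords[:, None, :] - lig_coords[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        np.maximum(r, 1e-6, out=r)
        atr, rep = self._split_eval(r, self.sigma, self.eps, self._inter_consts)
        coulomb = 0.0
        if self.qq is not None:
            x = np.clip(
                (r - self._inter_consts[3]) / self.params.taper_width, 0.0, 1.0
            )
            taper = 0.5 * (1.0 + np.cos(np.pi * x))
            coulomb = float(np.sum(self.qq / (r * r) * taper))
        return atr, rep, coulomb

    def intra_rep(self, rec_coords: np.ndarray, lig_coords: np.ndarray) -> float:
        if self._intra_i is None:
            return 0.0
        stacked = np.concatenate((rec_coords, lig_coords))
        d = stacked[self._intra_i] - stacked[self._intra_j]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        np.maximum(r, 1e-6, out=r)
        _, rep = self._split_eval(r, self._intra_sig, self._intra_eps, self._intra_consts_merged)
        return rep

    def total(
        self,
        rec_coords: np.ndarray,
        lig_coords: np.ndarray,
        include_encounter: bool = True,
    ) -> float:
        """Weighted force-field total only — the samplers' hot path."""
        atr, rep, coulomb = self.inter_terms(rec_coords, lig_coords)
        intra = self.intra_rep(rec_coords, lig_coords)
        w = self.params.weights
        total = (
            w.get("atr", 1.0) * atr
            + w.get("rep", 1.0) * (rep + intra)
            + w.get("coulomb", 1.0) * coulomb
        )
        if include_encounter and self.params.encounter_d_max is not None:
            d = float(np.linalg.norm(rec_coords.mean(0) - lig_coords.mean(0)))
            if d > self.params.encounter_d_max:
                total += (
                    w.get("encounter", 1.0)
                    * self.params.encounter_k
                    * (d - self.params.encounter_d_max) ** 2
                )
        return total

    def forcefield(
        self,
        rec_coords: np.ndarray,
        lig_coords: np.ndarray,
        include_encounter: bool = True,
    ) -> tuple[dict, float]:
        atr, rep, coulomb = self.inter_terms(rec_coords, lig_coords)
        intra = self.intra_rep(rec_coords, lig_coords)
        enc = 0.0
        if include_encounter and self.params.encounter_d_max is not None:
            d = float(np.linalg.norm(rec_coords.mean(0) - lig_coords.mean(0)))
            if d > self.params.encounter_d_max:
                enc = self.params.encounter_k * (d - self.params.encounter_d_max) ** 2
        terms = {"atr": atr, "rep": rep, "intra_rep": intra, "coulomb": coulomb, "encounter": enc}
        w = self.params.weights
        total = (
            w.get("atr", 1.0) * atr
            + w.get("rep", 1.0) * (rep + intra)
            + w.get("coulomb", 1.0) * coulomb
            + w.get("encounter", 1.0) * enc
        )
        return terms, total


def score_pose(
    pose: ComplexPose,
    level: HamiltonianLevel,
    params: EnergyParams,
    bias_value: float = 0.0,
) -> ScoreBreakdown:
    """Score a pose at one ladder level.

    Sums the weighted inter-partner split-LJ terms over all receptor-ligand
    heavy-atom pairs, the intra-partner side-chain clash term of χ-bearing
    residues, the optional Coulomb term, and the encounter restraint; the
    supplied metadynamics ``bias_value`` enters only the grand total.
    """
    tables = PairTables(pose, level, params)
    terms, total = tables.forcefield(pose.receptor_coordinates(), pose.ligand_coordinates())
    return ScoreBreakdown(terms=terms, forcefield_total=total, bias=float(bias_value))


def encounter_penalty(pose: ComplexPose, params: EnergyParams) -> float:
    """Flat-bottom restraint: 0 inside d_max, k·(d − d_max)² beyond."""
    if params.encounter_d_max is None:
        return 0.0
    d = pose.com_separation()
    if d <= params.encounter_d_max:
        return 0.0
    return params.encounter_k * (d - params.encounter_d_max) ** 2


SEPARATION_DISTANCE = 500.0  # Å; any displacement beyond the cutoff is equivalent


def interaction_score(
    pose: ComplexPose, level: HamiltonianLevel, params: EnergyParams
) -> float:
    """Interaction score I_sc = E(complex) − E(separated partners).

    The separated reference displaces the ligand rigidly by 500 Å with all
    internal degrees of freedom fixed; the encounter restraint is excluded
    from both evaluations, so I_sc isolates the inter-partner energy.
    """
    tables = PairTables(pose, level, params)
    rec = pose.receptor_coordinates()
    lig = pose.ligand_coordinates()
    _, bound = tables.forcefield(rec, lig, include_encounter=False)
    shift = np.array([SEPARATION_DISTANCE, 0.0, 0.0])
    _, free = tables.forcefield(rec, lig + shift, include_encounter=False)
    return bound - free
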