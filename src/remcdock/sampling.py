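"""Metropolis-Hastings driver, replica exchange and the well-tempered bias.

Four protocols are provided, all built from the same step kernel:

* ``MC`` — a single chain at temperature 0.15 (score units).
* ``REMC`` — parallel tempering over a 13-level geometric temperature ladder
  0.15-0.31 with neighbour exchanges every 1,000 steps.
* ``WTE-REMC`` — 5 temperature levels over the same range, each replica
  additionally accumulating a well-tempered-ensemble (WTE) metadynamics bias
  on its force-field energy, which broadens the energy fluctuations and keeps
  exchange rates high with far fewer replicas.
* ``WTE-H-REMC`` — a 2-D grid: 5 temperatures (0.15-0.3) x 5 repulsive
  softness levels (hard_rep, soft 50/55/60/65 %), 25 replicas, WTE per
  replica, exchanges alternating between the two dimensions.

Moves are accepted on the *total* energy (force field + bias) with the exact
Hastings correction supplied by the movers; snapshots of the reference
replica (coldest temperature, hard_rep) store force-field-only scores.

The original asynchronous exchange scheme lets fast replicas run ahead
instead of waiting at the exchange barrier; executed serially here, replicas
advance round-robin one step per round, a pair exchanges once both have
crossed their next stride multiple, and the run ends when the slowest
replica exhausts the step budget — the same semantics without concurrency.

On the deposition temperature offset: the well-tempered deposition height is
W = ω·τ·exp(−V/ΔT).  We use ΔT = (γ−1)·T (the convention under which the
heights decay geometrically and the bias converges); ``delta_t_sign=-1``
selects the opposite sign for fidelity experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .energy import (
    DEFAULT_LEVELS,
    EnergyParams,
    HamiltonianLevel,
    PairTables,
    ScoreBreakdown,
    make_level,
)
from .geometry import quat_from_axis_angle, quat_multiply, random_unit_vector, relative_transform
from .movers import (
    MoverSchedule,
    RotamerLibrary,
    interpolate_schedule,
    propose_jump_rotamer,
    propose_perturb_chi,
    propose_perturb_rotamer,
)
from .structure import ComplexPose

__all__ = [
    "WTEBias",
    "ReplicaState",
    "ExchangeTopology",
    "Trajectory",
    "ProtocolConfig",
    "metropolis_accept",
    "build_temperature_ladder",
    "attempt_exchange",
    "replica_total_energy",
    "run_protocol",
    "PROTOCOLS",
]

PROTOCOLS = ("MC", "REMC", "WTE-REMC", "WTE-H-REMC")


class WTEBias:
    """History-dependent metadynamics bias over the energy axis.

    Gaussian heights are deposited into ``bin_width``-wide energy bins with
    height ``W = omega * stride * exp(-V_old / dT)`` where ``dT = (gamma-1)*T``:
    repeated visits to a bin shrink the deposit geometrically, so the
    accumulated bias converges while energy fluctuations are boosted by a
    factor of roughly ``gamma``.  Bins are keyed by ``floor(E / bin_width)``
    and extend dynamically; unvisited bins carry zero bias.
    """

    def __init__(
        self,
        temperature: float,
        bin_width: float = 2.0,
        gamma: float = 5.0,
        omega: float = 1.0,
        stride: int = 1,
        delta_t_sign: int = +1,
    ):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if gamma <= 1:
            raise ValueError("gamma must exceed 1")
        self.temperature = float(temperature)
        self.bin_width = float(bin_width)
        self.gamma = float(gamma)
        self.omega = float(omega)
        self.stride = int(stride)
        self.delta_t_sign = int(delta_t_sign)
        self.bins: dict[int, float] = {}

    @property
    def delta_t(self) -> float:
        return self.delta_t_sign * (self.gamma - 1.0) * self.temperature

    def _index(self, energy: float) -> int:
        return math.floor(energy / self.bin_width)

    def value(self, energy: float) -> float:
        """Accumulated bias V at the bin containing ``energy`` (0 if unvisited)."""
        return self.bins.get(self._index(energy), 0.0)

    def deposit(self, energy: float) -> float:
        """Deposit one Gaussian at ``energy``; returns the height added."""
        idx = self._index(energy)
        v_old = self.bins.get(idx, 0.0)
        w = self.omega * self.stride * math.exp(-v_old / self.delta_t)
        self.bins[idx] = v_old + w
        return w

    def as_table(self) -> pd.DataFrame:
        rows = [
            {"bin_index": i, "energy_low": i * self.bin_width, "bias": v}
            for i, v in sorted(self.bins.items())
        ]
        return pd.DataFrame(rows, columns=["bin_index", "energy_low", "bias"])


def metropolis_accept(
    delta_total_energy: float,
    temperature: float,
    log_hastings_ratio: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis-Hastings test: accept w.p. min(1, exp(-Δ/T + log q-ratio)).

    ``log_hastings_ratio`` is log q(old|new) − log q(new|old); zero for
    symmetric kernels.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    log_p = -delta_total_energy / temperature + log_hastings_ratio
    if log_p >= 0:
        return True
    return float(rng.random()) < math.exp(log_p)


def build_temperature_ladder(t_min: float, t_max: float, n_levels: int) -> np.ndarray:
    """Geometric temperature progression from ``t_min`` to ``t_max``."""
    if not 0 < t_min <= t_max:
        raise ValueError("need 0 < t_min <= t_max")
    if n_levels < 1:
        raise ValueError("need at least one level")
    if n_levels == 1:
        if t_min != t_max:
            raise ValueError("a single level requires t_min == t_max")
        return np.array([t_min])
    return np.geomspace(t_min, t_max, n_levels)


@dataclass
class ReplicaState:
    """One replica: temperature, Hamiltonian level, pose, optional WTE bias.

    ``energy_fn(pose)`` must return the force-field energy of a pose under
    *this replica's* Hamiltonian; the WTE bias (if any) is evaluated at that
    energy.  The pose can be any object ``energy_fn`` understands, which lets
    the exchange machinery run on analytic toy systems as well as docking
    poses.
    """

    replica_id: tuple[int, int]
    temperature: float
    energy_fn: Callable
    level: HamiltonianLevel | None = None
    schedule: MoverSchedule | None = None
    pose: object = None
    bias: WTEBias | None = None
    step_count: int = 0
    is_reference: bool = False


def replica_total_energy(replica: ReplicaState, pose) -> float:
    """U_k(x): force-field energy at the replica's Hamiltonian + its bias."""
    e = replica.energy_fn(pose)
    if replica.bias is not None:
        e = e + replica.bias.value(e)
    return e


def attempt_exchange(
    replica_i: ReplicaState, replica_j: ReplicaState, rng: np.random.Generator
) -> bool:
    """Attempt a configuration swap between two neighbouring replicas.

    Acceptance: min(1, exp(−Δ)) with
    Δ = [U_i(x_j) − U_i(x_i)]/T_i + [U_j(x_i) − U_j(x_j)]/T_j,
    each U evaluated under that replica's Hamiltonian plus its own bias.
    On acceptance the *poses* swap; temperatures, Hamiltonians, biases and
    mover schedules stay with the replica.
    """
    xi, xj = replica_i.pose, replica_j.pose
    u_ii = replica_total_energy(replica_i, xi)
    u_ij = replica_total_energy(replica_i, xj)
    u_jj = replica_total_energy(replica_j, xj)
    u_ji = replica_total_energy(replica_j, xi)
    delta = (u_ij - u_ii) / replica_i.temperature + (u_ji - u_jj) / replica_j.temperature
    accept = delta <= 0 or float(rng.random()) < math.exp(-delta)
    if accept:
        replica_i.pose, replica_j.pose = xj, xi
    return accept


@dataclass
class ExchangeTopology:
    """Replica layout and neighbour pairs of a run."""

    layout: str  # "single" | "chain" | "grid"
    temperature_ladder: np.ndarray
    level_ladder: tuple[HamiltonianLevel, ...]
    stride: int
    pairs_by_dimension: list[list[tuple[int, int]]]  # indices into the replica list


@dataclass
class Trajectory:
    """Output of one protocol run (reference-replica snapshots + bookkeeping)."""

    snapshots: list  # (step, ComplexPose, ScoreBreakdown, replica_label)
    table: pd.DataFrame  # step, forcefield_total, i_sc, replica
    propose_counts: dict
    accept_counts: dict
    restriction_rejects: int
    exchange_attempts: dict
    exchange_accepts: dict
    max_translation: float
    max_rotation: float
    first_hit_step: int | None
    topology: ExchangeTopology
    biases: list  # per-replica WTEBias or None

    @property
    def i_sc_series(self) -> np.ndarray:
        return self.table["i_sc"].to_numpy()

    def exchange_rates(self) -> dict:
        return {
            pair: self.exchange_accepts[pair] / att
            for pair, att in self.exchange_attempts.items()
            if att > 0
        }


@dataclass
class ProtocolConfig:
    """Run configuration for :func:`run_protocol`.

    Temperature range, ladder sizes, WTE parameters and strides default to
    the published protocol settings; ``steps`` is the per-replica step
    budget.  ``restriction`` is the (translation Å, rotation deg) ball around
    the start transform.
    """

    protocol: str = "MC"
    steps: int = 100_000
    seed: int = 0
    t_min: float = 0.15
    t_max: float | None = None  # protocol-dependent default
    n_temperatures: int | None = None
    levels: tuple[HamiltonianLevel, ...] | None = None
    exchange_stride: int = 1000
    snapshot_stride: int = 1000
    gamma: float = 5.0
    omega: float = 1.0
    bin_width: float = 2.0
    wte_stride: int = 1
    delta_t_sign: int = +1
    restriction: tuple[float, float] = (20.0, 90.0)
    schedule_reference: MoverSchedule = field(default_factory=MoverSchedule.reference)
    schedule_hot: MoverSchedule = field(default_factory=MoverSchedule.hot)
    hit_threshold: float = 2.0  # Å, L_rmsd for first-hit tracking
    hit_check_stride: int = 10
    stop_on_hit: bool = False  # end the run once the threshold is reached

    def resolve(self):
        """Temperature ladder, level ladder and WTE flag for the protocol."""
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}; choose from {PROTOCOLS}")
        hard = (make_level(0.0, "hard_rep"),)
        if self.protocol == "MC":
            temps = build_temperature_ladder(self.t_min, self.t_min, 1)
            return temps, self.levels or hard, False
        if self.protocol == "REMC":
            temps = build_temperature_ladder(
                self.t_min, self.t_max or 0.31, self.n_temperatures or 13
            )
            return temps, self.levels or hard, False
        if self.protocol == "WTE-REMC":
            temps = build_temperature_ladder(
                self.t_min, self.t_max or 0.31, self.n_temperatures or 5
            )
            return temps, self.levels or hard, True
        temps = build_temperature_ladder(
            self.t_min, self.t_max or 0.30, self.n_temperatures or 5
        )
        return temps, self.levels or DEFAULT_LEVELS, True


# ---------------------------------------------------------------------------
# engine


class _Engine:
    """Serial multi-replica Metropolis-Hastings engine on one pose topology."""

    def __init__(
        self,
        config: ProtocolConfig,
        pose: ComplexPose,
        params: EnergyParams,
        library: RotamerLibrary,
        native: ComplexPose | None,
    ):
        self.config = config
        self.params = params.resolved(pose)
        self.library = library
        temps, levels, use_wte = config.resolve()
        self.temperatures = temps
        self.levels = tuple(levels)
        self.tables = [PairTables(pose, lvl, self.params) for lvl in self.levels]
        n_t, n_l = len(temps), len(self.levels)
        seq = np.random.SeedSequence(config.seed)
        streams = seq.spawn(n_t * n_l + 1)
        self.exchange_rng = np.random.default_rng(streams[-1])
        self.replicas: list[dict] = []
        for li in range(n_l):
            for ti in range(n_t):
                frac_t = ti / (n_t - 1) if n_t > 1 else 0.0
                frac_l = li / (n_l - 1) if n_l > 1 else 0.0
                frac = (frac_t + frac_l) / 2.0 if (n_t > 1 and n_l > 1) else max(frac_t, frac_l)
                schedule = (
                    config.schedule_reference
                    if frac == 0.0
                    else interpolate_schedule(config.schedule_reference, config.schedule_hot, frac)
                )
                bias = None
                if use_wte:
                    bias = WTEBias(
                        temperature=temps[ti],
                        bin_width=config.bin_width,
                        gamma=config.gamma,
                        omega=config.omega,
                        stride=config.wte_stride,
                        delta_t_sign=config.delta_t_sign,
                    )
                p = pose.copy()
                rec = p.receptor_coordinates()
                ligb = p.ligand_base_coordinates()
                rep = {
                    "id": (ti, li),
                    "temperature": float(temps[ti]),
                    "level_idx": li,
                    "schedule": schedule,
                    "bias": bias,
                    "rng": np.random.default_rng(streams[li * n_t + ti]),
                    "pose": p,
                    "rec": rec,
                    "lig_base": ligb,
                    "lig": self._realize(p, ligb),
                    "ff": None,
                    "is_reference": (ti == 0 and li == 0),
                }
                rep["ff"] = self.tables[li].total(rep["rec"], rep["lig"])
                labels = [l for l in ("rigid_body", "jump_rotamer", "perturb_rotamer", "perturb_chi") if schedule.weights.get(l, 0.0) > 0]
                w = np.array([schedule.weights[l] for l in labels])
                rep["mv_labels"] = labels
                rep["mv_cum"] = np.cumsum(w / w.sum())
                self.replicas.append(rep)
        self.reference = self.replicas[0]
        # exchange neighbour pairs, one list per dimension
        index = {(ti, li): k for k, r in enumerate(self.replicas) for (ti, li) in [r["id"]]}
        temp_pairs = [
            (index[(ti, li)], index[(ti + 1, li)])
            for li in range(n_l)
            for ti in range(n_t - 1)
        ]
        level_pairs = [
            (index[(ti, li)], index[(ti, li + 1)])
            for ti in range(n_t)
            for li in range(n_l - 1)
        ]
        dims = [p for p in (temp_pairs, level_pairs) if p]
        layout = "single" if len(self.replicas) == 1 else ("grid" if n_t > 1 and n_l > 1 else "chain")
        self.topology = ExchangeTopology(layout, temps, self.levels, config.exchange_stride, dims)
        # bookkeeping
        self.propose_counts = {l: 0 for l in ("rigid_body", "jump_rotamer", "perturb_rotamer", "perturb_chi")}
        self.accept_counts = dict(self.propose_counts)
        self.restriction_rejects = 0
        self.exchange_attempts: dict = {}
        self.exchange_accepts: dict = {}
        self.max_translation = 0.0
        self.max_rotation = 0.0
        self.snapshots: list = []
        self.rows: list = []
        self.first_hit_step: int | None = None
        self._setup_hit_tracking(native)

    # -- helpers -------------------------------------------------------------
    def _realize(self, pose: ComplexPose, lig_base: np.ndarray) -> np.ndarray:
        c = pose._ligand_centroid
        t = pose.ligand_transform
        return (lig_base - c) @ t.matrix.T + c + t.translation

    def _setup_hit_tracking(self, native: ComplexPose | None) -> None:
        self.native = native
        if native is None:
            return
        bb = native.ligand_base.backbone_indices()
        self._lig_bb = bb if bb.size else np.arange(native.ligand_base.n_atoms)
        self._native_lig_bb = native.ligand_coordinates()[self._lig_bb]
        # When the run shares the native receptor frame (always the case for
        # poses built from the same structure: χ moves leave the backbone
        # fixed), the receptor superposition is the identity and L_rmsd
        # reduces to a direct ligand-backbone RMSD.
        rb = native.receptor.backbone_indices()
        rb = rb if rb.size else np.arange(native.receptor.n_atoms)
        run_rb = self.replicas[0]["pose"].receptor.coords[rb]
        nat_rb = native.receptor_coordinates()[rb]
        if not np.allclose(run_rb, nat_rb, atol=1e-6):
            raise ValueError(
                "first-hit tracking requires the run and native poses to share "
                "the receptor frame; superpose the native first"
            )

    def _check_hit(self, rep: dict, step: int) -> None:
        if self.native is None or self.first_hit_step is not None:
            return
        d = rep["lig"][self._lig_bb] - self._native_lig_bb
        rmsd = math.sqrt(float(np.einsum("ij,ij->", d, d)) / d.shape[0])
        if rmsd <= self.config.hit_threshold:
            self.first_hit_step = step

    def _grand(self, rep: dict, ff: float) -> float:
        if rep["bias"] is None:
            return ff
        return ff + rep["bias"].value(ff)

    # -- one MC step on one replica ------------------------------------------
    def _step(self, rep: dict, step: int) -> None:
        rng = rep["rng"]
        schedule = rep["schedule"]
        # weighted mover choice (cached cumulative weights; cf. select_mover)
        u = rng.random()
        cum = rep["mv_cum"]
        k = 0
        while cum[k] < u:
            k += 1
        label = rep["mv_labels"][k]
        self.propose_counts[label] += 1
        tables = self.tables[rep["level_idx"]]
        pose = rep["pose"]
        if label == "rigid_body":
            dt = rng.standard_normal(3) * schedule.trans_sigma
            quat = pose.ligand_transform.quat
            if schedule.rot_sigma > 0:
                axis = random_unit_vector(rng)
                angle = rng.standard_normal() * schedule.rot_sigma
                quat = quat_multiply(quat_from_axis_angle(axis, angle), quat)
            new_t = pose.ligand_transform.translation + dt
            from .geometry import RigidTransform

            cand = RigidTransform(quat, new_t)
            off_t, off_r = relative_transform(cand, pose.start_transform)
            if off_t > self.config.restriction[0] or off_r > self.config.restriction[1]:
                self.restriction_rejects += 1
                return  # rejected without evaluation: outside the sampling ball
            c = pose._ligand_centroid
            lig_new = (rep["lig_base"] - c) @ cand.matrix.T + c + cand.translation
            ff_new = tables.total(rep["rec"], lig_new)
            delta = self._grand(rep, ff_new) - self._grand(rep, rep["ff"])
            if metropolis_accept(delta, rep["temperature"], 0.0, rng):
                pose.ligand_transform = cand
                rep["lig"] = lig_new
                rep["ff"] = ff_new
                self.accept_counts[label] += 1
        else:
            if label == "jump_rotamer":
                prop = propose_jump_rotamer(pose, self.library, rng)
            elif label == "perturb_rotamer":
                prop = propose_perturb_rotamer(pose, self.library, rng)
            else:
                prop = propose_perturb_chi(pose, schedule, rng)
            pid, ri = prop.residue
            chi_new = prop.new_pose.chi_angles[(pid, ri)]
            if pid == "receptor":
                rec_new = pose.receptor.apply_chi(rep["rec"], ri, chi_new)
                lig_new = rep["lig"]
                ff_new = tables.total(rec_new, lig_new)
            else:
                lig_base_new = pose.ligand_base.apply_chi(rep["lig_base"], ri, chi_new)
                lig_new = self._realize(prop.new_pose, lig_base_new)
                ff_new = tables.total(rep["rec"], lig_new)
            delta = self._grand(rep, ff_new) - self._grand(rep, rep["ff"])
            log_ratio = prop.log_reverse_density - prop.log_forward_density
            if metropolis_accept(delta, rep["temperature"], log_ratio, rng):
                rep["pose"] = prop.new_pose
                if pid == "receptor":
                    rep["rec"] = rec_new
                else:
                    rep["lig_base"] = lig_base_new
                    rep["lig"] = lig_new
                rep["ff"] = ff_new
                self.accept_counts[label] += 1
        # WTE deposition at the current (post-decision) energy
        bias = rep["bias"]
        if bias is not None and step % bias.stride == 0:
            bias.deposit(rep["ff"])

    # -- exchange ------------------------------------------------------------
    def _exchange_epoch(self, epoch: int) -> None:
        dims = self.topology.pairs_by_dimension
        if not dims:
            return
        if len(dims) == 1:
            pairs, offset = dims[0], epoch % 2
        else:
            pairs, offset = dims[epoch % 2], (epoch // 2) % 2
        for k, (a, b) in enumerate(pairs):
            if k % 2 != offset:
                continue
            ra, rb = self.replicas[a], self.replicas[b]
            key = (ra["id"], rb["id"])
            self.exchange_attempts[key] = self.exchange_attempts.get(key, 0) + 1
            # energies of both configurations under both Hamiltonians+biases
            ta, tb = self.tables[ra["level_idx"]], self.tables[rb["level_idx"]]
            e_aa, e_bb = ra["ff"], rb["ff"]
            if ra["level_idx"] == rb["level_idx"]:
                e_ab, e_ba = e_bb, e_aa
            else:
                e_ab = ta.total(rb["rec"], rb["lig"])
                e_ba = tb.total(ra["rec"], ra["lig"])
            u_aa = self._grand(ra, e_aa)
            u_ab = self._grand(ra, e_ab)
            u_bb = self._grand(rb, e_bb)
            u_ba = self._grand(rb, e_ba)
            delta = (u_ab - u_aa) / ra["temperature"] + (u_ba - u_bb) / rb["temperature"]
            if delta <= 0 or float(self.exchange_rng.random()) < math.exp(-delta):
                for fld in ("pose", "rec", "lig_base", "lig"):
                    ra[fld], rb[fld] = rb[fld], ra[fld]
                ra["ff"], rb["ff"] = e_ab, e_ba
                self.exchange_accepts[key] = self.exchange_accepts.get(key, 0) + 1
            else:
                self.exchange_accepts.setdefault(key, 0)

    # -- snapshots -----------------------------------------------------------
    def _snapshot(self, step: int) -> None:
        rep = self.reference
        tables = self.tables[rep["level_idx"]]
        terms, total = tables.forcefield(rep["rec"], rep["lig"])
        _, bound = tables.forcefield(rep["rec"], rep["lig"], include_encounter=False)
        shift = np.array([500.0, 0.0, 0.0])
        _, free = tables.forcefield(rep["rec"], rep["lig"] + shift, include_encounter=False)
        i_sc = bound - free
        breakdown = ScoreBreakdown(terms=terms, forcefield_total=total, bias=0.0)
        self.snapshots.append((step, rep["pose"].copy(), breakdown, rep["id"]))
        self.rows.append(
            {"step": step, "forcefield_total": total, "i_sc": i_sc, "replica": str(rep["id"])}
        )

    # -- main loop -----------------------------------------------------------
    def run(self) -> Trajectory:
        cfg = self.config
        epoch = 0
        for step in range(1, cfg.steps + 1):
            for rep in self.replicas:
                self._step(rep, step)
                if cfg.hit_check_stride and step % cfg.hit_check_stride == 0:
                    self._check_hit(rep, step)
            # restriction invariant + offset tracking on the reference chain
            for rep in self.replicas:
                off_t, off_r = relative_transform(
                    rep["pose"].ligand_transform, rep["pose"].start_transform
                )
                if off_t > cfg.restriction[0] + 1e-9 or off_r > cfg.restriction[1] + 1e-9:
                    raise RuntimeError("restriction invariant violated")
                if off_t > self.max_translation:
                    self.max_translation = off_t
                if off_r > self.max_rotation:
                    self.max_rotation = off_r
            if len(self.replicas) > 1 and step % cfg.exchange_stride == 0:
                self._exchange_epoch(epoch)
                epoch += 1
            if step % cfg.snapshot_stride == 0:
                self._snapshot(step)
            if cfg.stop_on_hit and self.first_hit_step is not None:
                break
        table = pd.DataFrame(self.rows, columns=["step", "forcefield_total", "i_sc", "replica"])
        return Trajectory(
            snapshots=self.snapshots,
            table=table,
            propose_counts=self.propose_counts,
            accept_counts=self.accept_counts,
            restriction_rejects=self.restriction_rejects,
            exchange_attempts=self.exchange_attempts,
            exchange_accepts=self.exchange_accepts,
            max_translation=self.max_translation,
            max_rotation=self.max_rotation,
            first_hit_step=self.first_hit_step,
            topology=self.topology,
            biases=[r["bias"] for r in self.replicas],
        )


def run_protocol(
    config: ProtocolConfig,
    pose: ComplexPose,
    params: EnergyParams,
    library: RotamerLibrary,
    native: ComplexPose | None = None,
) -> Trajectory:
    """Run one docking protocol from ``pose`` and return its trajectory.

    ``native``, if given, enables first-hit tracking: the earliest per-replica
    step at which any replica's pose comes within ``config.hit_threshold`` Å
    ligand-RMSD of the native.  Fixed ``config.seed`` makes runs bit-identical.
    """
    return _Engine(config, pose, params, library, native).run()
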