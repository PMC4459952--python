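"""Metropolis test, ladders, WTE bias, exchange and the protocol driver."""

import math

import numpy as np
import pytest
from scipy import stats

from remcdock.sampling import (
    ProtocolConfig,
    ReplicaState,
    WTEBias,
    attempt_exchange,
    build_temperature_ladder,
    metropolis_accept,
    run_protocol,
)


class _FixedRng:
    """Deterministic uniform source for pinning acceptance thresholds."""

    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-0.5, 0.15, 0.0, rng) for _ in range(100))
        assert metropolis_accept(0.0, 0.15, 0.0, rng)

    def test_acceptance_frequency_matches_closed_form(self, rng):
        """Δ = T gives acceptance probability e^-1."""
        n = 100_000
        acc = sum(metropolis_accept(0.15, 0.15, 0.0, rng) for _ in range(n))
        p = math.exp(-1)
        assert abs(acc / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_infinite_temperature_always_accepts(self, rng):
        assert all(metropolis_accept(50.0, 1e12, 0.0, rng) for _ in range(50))

    def test_hastings_ratio_shifts_threshold(self):
        # exp(-Δ/T + log_ratio) = exp(-1): just below accepts, just above rejects
        assert metropolis_accept(0.3, 0.15, 1.0, _FixedRng(math.exp(-1) - 1e-9))
        assert not metropolis_accept(0.3, 0.15, 1.0, _FixedRng(math.exp(-1) + 1e-9))

    def test_nonpositive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, 0.0, rng)


class TestTemperatureLadder:
    def test_published_13_level_ladder(self):
        temps = build_temperature_ladder(0.15, 0.31, 13)
        assert len(temps) == 13
        assert temps[0] == pytest.approx(0.15)
        assert temps[-1] == pytest.approx(0.31)
        ratios = temps[1:] / temps[:-1]
        np.testing.assert_allclose(ratios, ratios[0], atol=1e-12)

    def test_single_level(self):
        np.testing.assert_allclose(build_temperature_ladder(0.15, 0.15, 1), [0.15])
        with pytest.raises(ValueError):
            build_temperature_ladder(0.15, 0.31, 1)

    def test_five_level_second_value(self):
        temps = build_temperature_ladder(0.15, 0.30, 5)
        assert temps[1] == pytest.approx(0.15 * 2 ** 0.25)  # ~0.17838


class TestWTEBias:
    def test_fresh_bias_zero_everywhere(self):
        bias = WTEBias(temperature=0.15)
        assert all(bias.value(e) == 0.0 for e in (-10.0, 0.0, 3.7, 100.0))

    def test_first_deposit_is_omega_stride(self):
        bias = WTEBias(temperature=0.15, omega=0.7, stride=3)
        assert bias.deposit(1.0) == pytest.approx(0.7 * 3)

    def test_tempered_height_closed_form(self):
        """ω=1, γ=5, T=0.15 (ΔT=0.6), V_old=1.2 -> W = e^-2."""
        bias = WTEBias(temperature=0.15, gamma=5.0, omega=1.0, bin_width=2.0)
        bias.bins[bias._index(3.0)] = 1.2
        assert bias.deposit(3.0) == pytest.approx(math.exp(-2.0), abs=1e-9)

    def test_untempered_limit(self):
        bias = WTEBias(temperature=0.15, gamma=1e12, omega=1.0)
        bias.bins[0] = 50.0
        assert bias.deposit(0.5) == pytest.approx(1.0)

    def test_floor_binning(self):
        bias = WTEBias(temperature=0.15, bin_width=2.0, omega=1.0)
        bias.deposit(3.1)
        assert bias.value(3.9) == pytest.approx(1.0)
        assert bias.value(2.1) == pytest.approx(1.0)
        assert bias.value(1.9) == 0.0

    def test_deposition_heights_strictly_decreasing(self):
        """W_k = ω exp(-V_{k-1}/ΔT): heights decay with closed-form ratio."""
        bias = WTEBias(temperature=0.15, gamma=5.0, omega=1.0)
        heights = [bias.deposit(1.0) for _ in range(20)]
        assert all(b < a for a, b in zip(heights, heights[1:]))
        v = 0.0
        for w in heights:
            assert w == pytest.approx(math.exp(-v / bias.delta_t), abs=1e-12)
            v += w


E_TWO_STATE = {0: 0.0, 1: 1.0}


def _two_state_replicas(temps=(0.5, 2.0)):
    return [
        ReplicaState(replica_id=(i, 0), temperature=t, energy_fn=lambda s: E_TWO_STATE[s], pose=0)
        for i, t in enumerate(temps)
    ]


class TestExchange:
    def test_identical_conditions_always_swap(self, rng):
        reps = _two_state_replicas((1.0, 1.0))
        reps[0].pose, reps[1].pose = 0, 1
        assert attempt_exchange(reps[0], reps[1], rng)
        assert (reps[0].pose, reps[1].pose) == (1, 0)

    def test_delta_matches_temperature_only_closed_form(self):
        """Δ = (1/T_i − 1/T_j)(E_j − E_i) for a pure temperature pair."""
        t_i, t_j, e_i, e_j = 0.15, 0.31, -3.0, -1.0
        energies = {"a": e_i, "b": e_j}
        ri = ReplicaState(replica_id=(0, 0), temperature=t_i, energy_fn=energies.get, pose="a")
        rj = ReplicaState(replica_id=(1, 0), temperature=t_j, energy_fn=energies.get, pose="b")
        delta = (1 / t_i - 1 / t_j) * (e_j - e_i)
        assert attempt_exchange(ri, rj, _FixedRng(math.exp(-delta) - 1e-12))
        ri.pose, rj.pose = "a", "b"
        assert not attempt_exchange(ri, rj, _FixedRng(math.exp(-delta) + 1e-12))

    def test_bias_enters_exchange_energies(self):
        bias = WTEBias(temperature=0.5, bin_width=1.0)
        bias.bins[0] = 2.0  # bin [0,1): only state 0 is biased
        ri = ReplicaState(
            replica_id=(0, 0), temperature=0.5, energy_fn=lambda s: E_TWO_STATE[s], pose=0, bias=bias
        )
        rj = ReplicaState(
            replica_id=(1, 0), temperature=2.0, energy_fn=lambda s: E_TWO_STATE[s], pose=1
        )
        # U_i(0)=0+2, U_i(1)=1+0; U_j as unbiased
        delta = ((1.0 - 2.0) / 0.5) + ((2.0 - 1.0) / 2.0)
        assert attempt_exchange(ri, rj, _FixedRng(math.exp(-delta) - 1e-12))

    def _run_two_state(self, exchange, seed, n=30_000):
        rng = np.random.default_rng(seed)
        reps = _two_state_replicas()
        counts = [np.zeros(2), np.zeros(2)]
        for step in range(n):
            for r in reps:
                new = 1 - r.pose
                if metropolis_accept(
                    E_TWO_STATE[new] - E_TWO_STATE[r.pose], r.temperature, 0.0, rng
                ):
                    r.pose = new
            if exchange and step % 10 == 0:
                attempt_exchange(reps[0], reps[1], rng)
            for i, r in enumerate(reps):
                counts[i][r.pose] += 1
        return counts

    @pytest.mark.parametrize("exchange", [False, True])
    def test_two_state_boltzmann_occupancies(self, exchange):
        """Per-replica occupancies match the exact Boltzmann weights, with or
        without exchanges (exchange leaves the marginals invariant)."""
        counts = self._run_two_state(exchange, seed=5)
        for i, t in enumerate((0.5, 2.0)):
            z = 1 + math.exp(-1.0 / t)
            expected = np.array([1 / z, math.exp(-1.0 / t) / z]) * counts[i].sum()
            _, p = stats.chisquare(counts[i], expected)
            assert p > 0.01


class TestRunProtocol:
    def test_snapshot_counting(self, start_pose, native, energy_params, library):
        cfg = ProtocolConfig(protocol="MC", steps=3000, snapshot_stride=1000, seed=3)
        traj = run_protocol(cfg, start_pose, energy_params, library)
        assert len(traj.snapshots) == 3
        assert [s[0] for s in traj.snapshots] == [1000, 2000, 3000]

    def test_step_accounting(self, start_pose, energy_params, library):
        cfg = ProtocolConfig(protocol="MC", steps=2000, seed=4)
        traj = run_protocol(cfg, start_pose, energy_params, library)
        assert sum(traj.propose_counts.values()) == 2000
        for label in traj.propose_counts:
            assert 0 <= traj.accept_counts[label] <= traj.propose_counts[label]
        assert traj.restriction_rejects <= traj.propose_counts["rigid_body"]

    def test_wte_h_remc_has_25_replicas(self, start_pose, energy_params, library):
        cfg = ProtocolConfig(protocol="WTE-H-REMC", steps=10, snapshot_stride=10, seed=1)
        traj = run_protocol(cfg, start_pose, energy_params, library)
        assert len(traj.biases) == 25
        assert all(b is not None for b in traj.biases)
        assert traj.topology.layout == "grid"
        labels = [lvl.label for lvl in traj.topology.level_ladder]
        assert labels == ["hard_rep", "soft 50%", "soft 55%", "soft 60%", "soft 65%"]

    def test_remc_ladder_sizes(self, start_pose, energy_params, library):
        cfg = ProtocolConfig(protocol="REMC", steps=10, snapshot_stride=10, seed=1)
        traj = run_protocol(cfg, start_pose, energy_params, library)
        assert len(traj.topology.temperature_ladder) == 13
        assert all(b is None for b in traj.biases)
        cfg = ProtocolConfig(protocol="WTE-REMC", steps=10, snapshot_stride=10, seed=1)
        traj = run_protocol(cfg, start_pose, energy_params, library)
        assert len(traj.topology.temperature_ladder) == 5

    def test_fixed_seed_bit_identical(self, start_pose, energy_params, library):
        cfg = ProtocolConfig(protocol="REMC", steps=1200, exchange_stride=400, seed=7)
        t1 = run_protocol(cfg, start_pose, energy_params, library)
        t2 = run_protocol(cfg, start_pose, energy_params, library)
        assert t1.table.equals(t2.table)
        np.testing.assert_array_equal(
            t1.snapshots[-1][1].ligand_coordinates(), t2.snapshots[-1][1].ligand_coordinates()
        )
        assert t1.accept_counts == t2.accept_counts

    def test_restricted_chain_never_leaves_ball(self, start_pose, energy_params, library):
        cfg = ProtocolConfig(
            protocol="MC", steps=2000, seed=11, restriction=(2.0, 10.0), snapshot_stride=500
        )
        traj = run_protocol(cfg, start_pose, energy_params, library)
        assert traj.max_translation <= 2.0
        assert traj.max_rotation <= 10.0
        assert traj.restriction_rejects > 0  # tight ball: violations proposed and rejected

    def test_unknown_protocol_rejected(self, start_pose, energy_params, library):
        with pytest.raises(ValueError, match="unknown protocol"):
            run_protocol(
                ProtocolConfig(protocol="SA"), start_pose, energy_params, library
            )

    def test_snapshots_store_forcefield_only_scores(self, start_pose, energy_params, library):
        cfg = ProtocolConfig(protocol="WTE-REMC", steps=1000, seed=2)
        traj = run_protocol(cfg, start_pose, energy_params, library)
        _, pose, breakdown, _ = traj.snapshots[0]
        assert breakdown.bias == 0.0
        assert breakdown.grand_total == breakdown.forcefield_total
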