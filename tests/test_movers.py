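"""Proposal kernels: symmetry, proposal densities, restriction, selection."""

import numpy as np
import pytest

from remcdock.geometry import RigidTransform
from remcdock.movers import (
    MoverSchedule,
    Rotamer,
    RotamerLibrary,
    argmax_rotamer,
    eligible_residues,
    interpolate_schedule,
    propose_jump_rotamer,
    propose_perturb_chi,
    propose_perturb_rotamer,
    propose_rigid_body,
    select_mover,
    within_restriction,
)
from remcdock.movers import _log_gauss_wrapped, _log_mixture_density
from remcdock.structure import ChiDef
from remcdock.toys import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="module")
def two_rotamer_library():
    return RotamerLibrary(
        {
            "LSC": [
                Rotamer(0.7, np.array([60.0]), np.array([15.0])),
                Rotamer(0.3, np.array([-60.0]), np.array([20.0])),
            ],
            "RSC": [Rotamer(1.0, np.array([0.0]), np.array([25.0]))],
        }
    )


class TestRigidBody:
    def test_zero_steps_identity(self, native, rng):
        schedule = MoverSchedule(trans_sigma=0.0, rot_sigma=0.0)
        prop = propose_rigid_body(native, schedule, rng)
        np.testing.assert_allclose(
            prop.new_pose.ligand_transform.translation, native.ligand_transform.translation
        )
        np.testing.assert_allclose(
            prop.new_pose.ligand_transform.quat, native.ligand_transform.quat
        )
        assert prop.log_forward_density == prop.log_reverse_density == 0.0

    def test_translation_statistics_match_stated_sigma(self, native, rng):
        """Per-axis Gaussian with the reference sigma = 0.1 Å."""
        schedule = MoverSchedule()
        n = 100_000
        deltas = np.empty((n, 3))
        for i in range(n):
            prop = propose_rigid_body(native, schedule, rng)
            deltas[i] = (
                prop.new_pose.ligand_transform.translation - native.ligand_transform.translation
            )
        se_mean = 0.1 / np.sqrt(n)
        for ax in range(3):
            assert abs(deltas[:, ax].mean()) < 3 * se_mean
            se_sd = 0.1 / np.sqrt(2 * (n - 1))
            assert abs(deltas[:, ax].std(ddof=1) - 0.1) < 3 * se_sd

    def test_symmetric_densities_every_draw(self, native, rng):
        schedule = MoverSchedule()
        for _ in range(50):
            prop = propose_rigid_body(native, schedule, rng)
            assert prop.log_forward_density == prop.log_reverse_density


class TestRestriction:
    def test_start_pose_inside(self, start_pose):
        assert within_restriction(start_pose)

    def test_translation_boundary_closed(self, native):
        inside = native.with_transform(RigidTransform(translation=np.array([20.0, 0, 0])))
        outside = native.with_transform(RigidTransform(translation=np.array([20.001, 0, 0])))
        assert within_restriction(inside)
        assert not within_restriction(outside)

    def test_rotation_boundary_closed_at_90(self, native):
        at_limit = native.with_transform(RigidTransform.from_axis_angle([0, 0, 1], 90.0))
        beyond = native.with_transform(RigidTransform.from_axis_angle([0, 0, 1], 90.6))
        assert within_restriction(at_limit)
        assert not within_restriction(beyond)


class TestJumpRotamer:
    def test_degenerate_sigma_snaps_to_means(self, one_residue_pose, rng):
        lib = RotamerLibrary({"LSC": [Rotamer(1.0, np.array([42.0]), np.array([1e-9]))]})
        prop = propose_jump_rotamer(one_residue_pose, lib, rng)
        key = prop.residue
        assert prop.new_pose.chi_angles[key][0] == pytest.approx(42.0, abs=1e-6)

    def test_forward_density_matches_hand_mixture(self, one_residue_pose, two_rotamer_library, rng):
        prop = propose_jump_rotamer(one_residue_pose, two_rotamer_library, rng)
        chi = prop.new_pose.chi_angles[prop.residue]
        hand = np.log(
            sum(
                r.probability
                * sum(
                    np.exp(-0.5 * ((chi[0] + k - r.chi_means[0]) / r.chi_sigmas[0]) ** 2)
                    / (r.chi_sigmas[0] * np.sqrt(2 * np.pi))
                    for k in (-360.0, 0.0, 360.0)
                )
                for r in two_rotamer_library["LSC"]
            )
        )
        assert prop.log_forward_density == pytest.approx(hand, abs=1e-12)

    def test_density_integrates_to_one(self, two_rotamer_library):
        xs = np.linspace(-180, 180, 10001)
        dens = np.exp(
            [_log_mixture_density(np.array([x]), two_rotamer_library["LSC"]) for x in xs]
        )
        assert np.trapezoid(dens, xs) == pytest.approx(1.0, abs=1e-4)


class TestPerturbRotamer:
    def test_argmax_selects_component_at_its_mean(self):
        rots = [
            Rotamer(0.6, np.array([60.0]), np.array([15.0])),
            Rotamer(0.4, np.array([-60.0]), np.array([15.0])),
        ]
        assert argmax_rotamer(np.array([60.0]), rots) == 0
        assert argmax_rotamer(np.array([-60.0]), rots) == 1

    def test_tie_breaks_to_lowest_index(self):
        rots = [
            Rotamer(0.5, np.array([30.0]), np.array([10.0])),
            Rotamer(0.5, np.array([30.0]), np.array([10.0])),
        ]
        assert argmax_rotamer(np.array([10.0]), rots) == 0

    def test_matches_enumeration_oracle(self, rng):
        rots = [
            Rotamer(0.45, np.array([70.0]), np.array([12.0])),
            Rotamer(0.35, np.array([-65.0]), np.array([18.0])),
            Rotamer(0.20, np.array([175.0]), np.array([22.0])),
        ]
        for _ in range(50):
            chi = np.array([rng.uniform(-180, 180)])
            vals = [
                np.log(r.probability) + float(_log_gauss_wrapped(chi, r.chi_means, r.chi_sigmas)[0])
                for r in rots
            ]
            assert argmax_rotamer(chi, rots) == int(np.argmax(vals))


class TestPerturbChi:
    def test_zero_magnitude_identity(self, one_residue_pose, rng):
        schedule = MoverSchedule(chi_sigma=0.0)
        prop = propose_perturb_chi(one_residue_pose, schedule, rng)
        key = prop.residue
        np.testing.assert_allclose(
            prop.new_pose.chi_angles[key], one_residue_pose.chi_angles[key]
        )

    def test_wraps_into_range(self, one_residue_pose):
        """χ = 179° plus a +5° increment lands at −176°."""

        class _FixedNormal:
            def standard_normal(self, shape):
                return np.full(shape, 1.0)

            def integers(self, n):
                return 0

        pose = one_residue_pose.with_chi("ligand", one_residue_pose.ligand_base.chi_residues()[0], np.array([179.0]))
        schedule = MoverSchedule(chi_sigma=5.0)
        prop = propose_perturb_chi(pose, schedule, _FixedNormal())
        assert prop.new_pose.chi_angles[prop.residue][0] == pytest.approx(-176.0)

    def test_increment_statistics(self, one_residue_pose, rng):
        schedule = MoverSchedule(chi_sigma=10.0)
        key = ("ligand", one_residue_pose.ligand_base.chi_residues()[0])
        n = 20_000
        incs = np.empty(n)
        for i in range(n):
            prop = propose_perturb_chi(one_residue_pose, schedule, rng)
            d = prop.new_pose.chi_angles[key][0] - one_residue_pose.chi_angles[key][0]
            incs[i] = (d + 180) % 360 - 180
        assert abs(incs.std(ddof=1) - 10.0) < 3 * 10.0 / np.sqrt(2 * (n - 1))
        assert abs(incs.mean()) < 3 * 10.0 / np.sqrt(n)


class TestSelection:
    def test_reference_weight_frequencies(self, rng):
        """Rigid-body share of draws ~ 0.5/20.5 under the reference weights."""
        schedule = MoverSchedule()
        n = 100_000
        labels = [select_mover(schedule, rng) for _ in range(n)]
        p = 0.5 / 20.5
        freq = labels.count("rigid_body") / n
        assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_single_nonzero_weight(self, rng):
        schedule = MoverSchedule(weights={"rigid_body": 0.0, "perturb_chi": 2.0})
        assert all(select_mover(schedule, rng) == "perturb_chi" for _ in range(100))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            MoverSchedule(weights={"rigid_body": 0.0})

    def test_schedule_interpolation_endpoints(self):
        ref, hot = MoverSchedule.reference(), MoverSchedule.hot()
        mid = interpolate_schedule(ref, hot, 0.5)
        assert interpolate_schedule(ref, hot, 0.0).weights == ref.weights
        assert interpolate_schedule(ref, hot, 1.0).trans_sigma == hot.trans_sigma
        assert mid.weights["rigid_body"] == pytest.approx((0.5 + 4.0) / 2)
        assert mid.trans_sigma == pytest.approx(0.55)


class TestEligibility:
    def test_proline_and_chiless_excluded(self):
        """Proline never moves; residues without χ topology are skipped."""
        from remcdock.structure import AtomRecord, ComplexPose, PartnerStructure

        chi_table = {
            "PRO": [ChiDef(("N", "CA", "CB", "CG"), ("CG",))],
            "LSC": [ChiDef(("N", "CA", "CB", "CG"), ("CG",))],
        }

        def residue(res_idx, rtype, z):
            return [
                AtomRecord("N", "N", res_idx, rtype, "ligand", [-1.5, 0, z], 2.0, 0.1, True),
                AtomRecord("CA", "C", res_idx, rtype, "ligand", [0, 0, z], 2.0, 0.1, True),
                AtomRecord("CB", "C", res_idx, rtype, "ligand", [0, 0, z + 1.5], 2.0, 0.1, True),
                AtomRecord("CG", "C", res_idx, rtype, "ligand", [1.5, 0, z + 1.5], 2.0, 0.1, True),
            ]

        rec = [AtomRecord("CA", "C", 1, "PKT", "receptor", [0, 0, -4], 2.0, 1.0, True)]
        lig = residue(1, "PRO", 4.0) + residue(2, "LSC", 8.0) + [
            AtomRecord("CA", "C", 3, "GLY", "ligand", [4, 0, 4], 2.0, 0.1, True)
        ]
        pose = ComplexPose(
            PartnerStructure(rec, chi_table), PartnerStructure(lig, chi_table)
        )
        eligible = eligible_residues(pose)
        assert [(pid, ri) for pid, ri, _ in eligible] == [("ligand", 2)]

    def test_no_eligible_residue_raises(self, rng, two_rotamer_library):
        pose, _, _ = make_toy_complex(ToyComplexSpec(receptor_atom_count=2, ligand_atom_count=2))
        with pytest.raises(ValueError, match="eligible"):
            propose_jump_rotamer(pose, two_rotamer_library, rng)
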