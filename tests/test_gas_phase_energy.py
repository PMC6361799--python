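"""Pairwise Coulomb/LJ energies against brute-force and hand oracles."""

import dataclasses

import numpy as np
import pytest

from bindscope import (
    AtomRecord,
    Topology,
    Trajectory,
    group_interaction_energy,
    interaction_energy_series,
    pair_energy,
    per_residue_interaction_series,
)
from bindscope.constants import COULOMB_KCAL

from conftest import make_random_system


def _atom(index, charge=0.0, rmin_half=0.0, epsilon=0.0):
    return AtomRecord(
        atom_index=index, atom_name=f"X{index}", element="C",
        residue_number=1, residue_name="RES", chain_id="A",
        charge=charge, lj_rmin_half=rmin_half, lj_epsilon=epsilon,
    )


class TestPairEnergy:
    def test_unit_charges_at_scaled_distance(self):
        # r chosen so 332.0637·(+1)(−1)/r = −100 exactly
        a = _atom(0, charge=1.0)
        b = _atom(1, charge=-1.0)
        components = pair_energy(a, b, 3.320637)
        assert components.ele == -100.0
        assert components.vdw == 0.0

    def test_lj_minimum_is_minus_epsilon(self):
        a = _atom(0, rmin_half=1.75, epsilon=0.2)
        b = _atom(1, rmin_half=1.75, epsilon=0.2)
        components = pair_energy(a, b, 3.5)
        assert components.vdw == pytest.approx(-0.2, abs=1e-12)

    def test_repulsive_branch_hand_value(self):
        # ε_ij=0.1, R_min,ij=3.5, r=3.0 → 0.1·[(3.5/3)^12 − 2(3.5/3)^6]
        a = _atom(0, rmin_half=1.75, epsilon=0.1)
        b = _atom(1, rmin_half=1.75, epsilon=0.1)
        expected = 0.1 * ((3.5 / 3.0) ** 12 - 2 * (3.5 / 3.0) ** 6)
        assert pair_energy(a, b, 3.0).vdw == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1315, abs=5e-5)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            pair_energy(_atom(0), _atom(1), 0.0)


def _brute_force(frame, topology):
    """Independent oracle: explicit python double loop over partner pairs."""
    ele = vdw = 0.0
    for i in sorted(topology.partner1):
        for j in sorted(topology.partner2):
            a, b = topology.atoms[i], topology.atoms[j]
            r = float(np.linalg.norm(frame[i] - frame[j]))
            ele += COULOMB_KCAL * a.charge * b.charge / r
            rmin = a.lj_rmin_half + b.lj_rmin_half
            eps = (a.lj_epsilon * b.lj_epsilon) ** 0.5
            vdw += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
    return ele, vdw


class TestGroupEnergy:
    def test_all_zero_parameters_give_zero(self):
        atoms = tuple(
            dataclasses.replace(_atom(i), chain_id="A" if i < 2 else "B",
                                residue_number=1 if i < 2 else 2)
            for i in range(4)
        )
        topology = Topology(atoms=atoms, partner1=frozenset({0, 1}),
                            partner2=frozenset({2, 3}))
        frame = np.arange(12, dtype=float).reshape(4, 3)
        components = group_interaction_energy(frame, topology)
        assert components.ele == components.vdw == components.total == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        topology, frame = make_random_system(rng, n1=5, n2=5)
        components = group_interaction_energy(frame, topology)
        ele, vdw = _brute_force(frame, topology)
        assert components.ele == pytest.approx(ele, abs=1e-8)
        assert components.vdw == pytest.approx(vdw, abs=1e-8)
        assert components.total == components.ele + components.vdw

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(5)
        topology, frame = make_random_system(rng)
        base = group_interaction_energy(frame, topology)
        moved = group_interaction_energy(frame + np.array([3.1, -7.2, 11.5]),
                                         topology)
        assert moved.ele == pytest.approx(base.ele, abs=1e-10)
        assert moved.vdw == pytest.approx(base.vdw, abs=1e-10)

    def test_partner_swap_symmetry(self):
        rng = np.random.default_rng(6)
        topology, frame = make_random_system(rng)
        base = group_interaction_energy(frame, topology)
        swapped = group_interaction_energy(frame, topology.swapped())
        assert swapped.ele == pytest.approx(base.ele, abs=1e-8)
        assert swapped.vdw == pytest.approx(base.vdw, abs=1e-8)

    @pytest.mark.parametrize("scale", [2.0, 3.0])
    def test_charge_scaling_is_quadratic_in_ele(self, scale):
        rng = np.random.default_rng(7)
        topology, frame = make_random_system(rng)
        scaled = dataclasses.replace(
            topology,
            atoms=tuple(
                dataclasses.replace(a, charge=scale * a.charge)
                for a in topology.atoms
            ),
        )
        base = group_interaction_energy(frame, topology)
        big = group_interaction_energy(frame, scaled)
        assert big.ele == pytest.approx(scale**2 * base.ele, rel=1e-10)
        assert big.vdw == pytest.approx(base.vdw, abs=1e-12)

    def test_coincident_atoms_name_the_pair(self):
        rng = np.random.default_rng(8)
        topology, frame = make_random_system(rng)
        frame[next(iter(topology.partner2))] = frame[next(iter(topology.partner1))]
        with pytest.raises(ValueError, match="coincident"):
            group_interaction_energy(frame, topology)


class TestSeries:
    def test_single_frame_series(self, dimer):
        topology, reference = dimer
        trajectory = Trajectory(topology=topology, frames=reference[None])
        table = interaction_energy_series(trajectory)
        single = group_interaction_energy(reference, topology)
        assert len(table["total"]) == 1
        assert table["ele"].values[0] == single.ele
        assert table["total"].values[0] == single.total

    def test_frozen_trajectory_is_constant(self, frozen_trajectory):
        table = interaction_energy_series(frozen_trajectory)
        assert np.ptp(table["total"].values) == 0.0

    def test_frame_self_consistency(self, sampled_trajectory):
        table = interaction_energy_series(sampled_trajectory)
        frame7 = group_interaction_energy(
            sampled_trajectory.frames[7], sampled_trajectory.topology
        )
        assert table["total"].values[7] == frame7.total


class TestPerResidue:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_decomposition_conserves_frame_totals(self, seed):
        rng = np.random.default_rng(seed)
        topology, frame = make_random_system(rng, n1=6, n2=6, n_res1=3, n_res2=3)
        frames = frame[None] + 0.1 * rng.standard_normal((4,) + frame.shape)
        trajectory = Trajectory(topology=topology, frames=frames)
        table = interaction_energy_series(trajectory)
        for side in (1, 2):
            per_res = per_residue_interaction_series(trajectory, side=side)
            total = sum(
                ele.values + vdw.values for ele, vdw in per_res.values()
            )
            assert np.max(np.abs(total - table["total"].values)) < 1e-8

    def test_single_residue_partner_equals_total(self):
        rng = np.random.default_rng(3)
        topology, frame = make_random_system(rng, n1=4, n2=4, n_res1=1, n_res2=2)
        trajectory = Trajectory(topology=topology, frames=frame[None])
        table = interaction_energy_series(trajectory)
        per_res = per_residue_interaction_series(trajectory, side=1)
        assert len(per_res) == 1
        ele, vdw = next(iter(per_res.values()))
        assert ele.values[0] + vdw.values[0] == pytest.approx(
            table["total"].values[0], abs=1e-10
        )

    def test_inert_residue_contributes_zero(self, sampled_trajectory):
        per_res = per_residue_interaction_series(sampled_trajectory, side=1)
        inert = [
            key for key in per_res if key.residue_name == "ALA"
        ]  # filler beads carry zero charge; LJ tail is tiny but nonzero
        assert inert
        for key in inert:
            ele, _ = per_res[key]
            assert np.all(ele.values == 0.0)
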