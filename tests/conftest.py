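import numpy as np
import pytest

from bindscope import (
    AtomRecord,
    DimerSpec,
    Topology,
    Trajectory,
    build_toy_dimer,
    sample_trajectory,
)


def make_random_system(rng, n1=5, n2=5, n_res1=2, n_res2=2, spread=3.0):
    """Random two-partner system with nonzero charges and LJ parameters.

    Chains are offset by 10 Å along x so atoms never coincide.
    """
    atoms = []
    coords = []
    for chain, n_atoms, n_res, x0 in (("A", n1, n_res1, 0.0), ("B", n2, n_res2, 10.0)):
        bounds = np.linspace(0, n_atoms, n_res + 1).astype(int)
        res_of = np.searchsorted(bounds, np.arange(n_atoms), side="right")
        for i in range(n_atoms):
            atoms.append(
                AtomRecord(
                    atom_index=len(atoms),
                    atom_name=f"X{i}",
                    element="C",
                    residue_number=int(res_of[i]),
                    residue_name="RES",
                    chain_id=chain,
                    charge=float(rng.uniform(-1, 1)),
                    lj_rmin_half=float(rng.uniform(1.0, 2.0)),
                    lj_epsilon=float(rng.uniform(0.0, 0.3)),
                )
            )
            coords.append([x0, 0.0, 0.0] + rng.uniform(-spread, spread, 3))
    partner1 = frozenset(a.atom_index for a in atoms if a.chain_id == "A")
    partner2 = frozenset(a.atom_index for a in atoms if a.chain_id == "B")
    topology = Topology(atoms=tuple(atoms), partner1=partner1, partner2=partner2)
    return topology, np.array(coords)


@pytest.fixture(scope="session")
def dimer():
    """Standard toy dimer: 2 designed H-bonds, 1 salt bridge, filler beads."""
    spec = DimerSpec(
        n_residues_partner1=4,
        n_residues_partner2=4,
        n_designed_hbonds=2,
        n_salt_bridges=1,
        seed=0,
    )
    return build_toy_dimer(spec)


@pytest.fixture(scope="session")
def frozen_trajectory(dimer):
    topology, reference = dimer
    frames = np.repeat(reference[None, :, :], 3, axis=0)
    return Trajectory(topology=topology, frames=frames)


@pytest.fixture(scope="session")
def sampled_trajectory(dimer):
    topology, reference = dimer
    return sample_trajectory(
        topology, reference, n_frames=300, temperature=300.0, seed=7,
        tether_force_constant=10.0,
    )
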