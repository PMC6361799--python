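"""Synthetic two-chain systems with known ground truth.

Real binding studies sample complexes with restrained MD; every
downstream stage here (energies, interaction entropy, solvation,
hydrogen bonds, reports) only consumes equilibrium-like snapshot
ensembles, so this module provides:

* :func:`gen_energy_series` — parametric interaction-energy series
  (Gaussian, two-state mixture, AR(1)) for testing the entropy
  estimator against closed forms;
* :func:`build_toy_dimer` — a coarse two-chain complex with designed
  inter-chain hydrogen bonds and salt bridges that satisfy the default
  geometric criteria in the reference pose;
* :func:`sample_trajectory` — Metropolis Monte-Carlo sampling of
  per-atom Gaussian displacement moves under inter-chain Coulomb + LJ
  plus harmonic tethers ½k|x−x_ref|² to the reference pose.

Everything is strictly reproducible given its seed; each call owns one
:class:`numpy.random.Generator` and no hidden global state is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .constants import BOLTZMANN_KCAL, COULOMB_KCAL, DEFAULT_TEMPERATURE
from .model_io import AtomRecord, EnergySeries, Topology, Trajectory

__all__ = [
    "SeriesSpec",
    "DimerSpec",
    "gen_energy_series",
    "build_toy_dimer",
    "sample_trajectory",
]

_SERIES_MODELS = ("gaussian", "two_state_mixture", "ar1")


@dataclass(frozen=True)
class SeriesSpec:
    """Parameters of a synthetic interaction-energy series.

    ``mixture_weight``/``mixture_delta`` apply to the two-state model
    (a fraction of frames shifted by ``mixture_delta`` kcal/mol);
    ``ar1_coeff`` is the lag-1 autocorrelation of the AR(1) model, whose
    stationary standard deviation equals ``sigma``.
    """

    n_frames: int
    model: str = "gaussian"
    mean: float = -100.0
    sigma: float = 1.0
    mixture_weight: float = 0.2
    mixture_delta: float = 2.0
    ar1_coeff: float = 0.0
    seed: int = 0
    frame_interval: float = 10.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.model not in _SERIES_MODELS:
            raise ValueError(
                f"unknown series model {self.model!r}; "
                f"allowed models: {', '.join(_SERIES_MODELS)}"
            )
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ValueError("ar1_coeff must lie in [0, 1)")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError("mixture_weight must lie in [0, 1]")


def gen_energy_series(spec: SeriesSpec) -> EnergySeries:
    """Draw a reproducible synthetic energy series from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    if spec.model == "gaussian":
        values = spec.mean + spec.sigma * rng.standard_normal(n)
    elif spec.model == "two_state_mixture":
        shifted = rng.random(n) < spec.mixture_weight
        values = (
            spec.mean
            + spec.mixture_delta * shifted
            + spec.sigma * rng.standard_normal(n)
        )
    else:  # ar1
        phi = spec.ar1_coeff
        innovations = rng.standard_normal(n)
        values = np.empty(n)
        # innovation scale chosen so the stationary std equals sigma
        scale = spec.sigma * math.sqrt(1.0 - phi * phi)
        x = spec.sigma * innovations[0]
        values[0] = spec.mean + x
        for t in range(1, n):
            x = phi * x + scale * innovations[t]
            values[t] = spec.mean + x
    return EnergySeries(
        values=values,
        component="total",
        frame_interval=spec.frame_interval,
        temperature=spec.temperature,
    )


# ---------------------------------------------------------------------------
# Toy dimer construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DimerSpec:
    """Layout of a coarse two-chain complex.

    Designed contacts (hydrogen bonds, then salt bridges) occupy the
    first residues of both chains; remaining residues are inert filler
    beads kept well apart across the interface.
    """

    n_residues_partner1: int = 4
    n_residues_partner2: int = 4
    n_designed_hbonds: int = 1
    n_salt_bridges: int = 1
    tether_force_constant: float = 10.0  # kcal mol^-1 Å^-2
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.n_residues_partner1 < 1 or self.n_residues_partner2 < 1:
            raise ValueError("each partner needs at least one residue")
        if self.n_designed_hbonds < 0 or self.n_salt_bridges < 0:
            raise ValueError("contact counts must be non-negative")
        if self.tether_force_constant <= 0:
            raise ValueError("tether_force_constant must be positive")
        n_contacts = self.n_designed_hbonds + self.n_salt_bridges
        if n_contacts > min(self.n_residues_partner1, self.n_residues_partner2):
            raise ValueError(
                "designed contacts exceed the residue count of a partner"
            )


# Coarse bead parameters (AMBER-like R_min/2, ε).
_BEAD = {
    "CA": dict(element="C", rmin_half=1.908, epsilon=0.1094),
    "N": dict(element="N", rmin_half=1.824, epsilon=0.17),
    "H": dict(element="H", rmin_half=0.6, epsilon=0.0157),
    "O": dict(element="O", rmin_half=1.6612, epsilon=0.21),
    "NZ": dict(element="N", rmin_half=1.824, epsilon=0.17),
    "OD": dict(element="O", rmin_half=1.6612, epsilon=0.21),
}

_ROW_SPACING = 6.0  # Å between residue rows along the interface


def _toy_atoms(spec: DimerSpec, jitter: np.ndarray):
    """Atom records + coordinates for one placement attempt."""
    atoms: list[AtomRecord] = []
    coords: list[list[float]] = []

    def add(chain, resnum, resname, name, xyz, charge, roles=(), bonded_heavy=None):
        bead = _BEAD[name]
        atoms.append(
            AtomRecord(
                atom_index=len(atoms),
                atom_name=name,
                element=bead["element"],
                residue_number=resnum,
                residue_name=resname,
                chain_id=chain,
                charge=charge,
                lj_rmin_half=bead["rmin_half"],
                lj_epsilon=bead["epsilon"],
                role_flags=frozenset(roles),
                bonded_heavy=bonded_heavy,
            )
        )
        coords.append(list(xyz))
        return len(atoms) - 1

    n_hb, n_sb = spec.n_designed_hbonds, spec.n_salt_bridges
    jit = iter(jitter)

    row = 0
    res_a = res_b = 0
    for _ in range(n_hb):
        y = _ROW_SPACING * row
        res_a += 1
        add("A", res_a, "DON", "CA", (-2.4, y, 0.0), 0.0)
        n_idx = add("A", res_a, "DON", "N", (-1.0, y, 0.0), -0.4, ("donor_heavy",))
        h_idx = add(
            "A", res_a, "DON", "H", (0.0, y, 0.0), 0.4, ("polar_hydrogen",),
            bonded_heavy=n_idx,
        )
        atoms[n_idx] = replace(atoms[n_idx], bonded_hydrogens=(h_idx,))
        res_b += 1
        add("B", res_b, "ACC", "O", (1.9, y, 0.0), -0.4, ("acceptor",))
        add("B", res_b, "ACC", "CA", (3.3, y, 0.0), 0.4)
        row += 1
    for _ in range(n_sb):
        y = _ROW_SPACING * row
        res_a += 1
        add("A", res_a, "POS", "CA", (-2.2, y, 0.0), 0.0)
        add("A", res_a, "POS", "NZ", (0.0, y, 0.0), 1.0)
        res_b += 1
        add("B", res_b, "NEG", "OD", (3.5, y, 0.0), -1.0)
        add("B", res_b, "NEG", "CA", (5.7, y, 0.0), 0.0)
        row += 1

    filler_row_a = filler_row_b = row
    while res_a < spec.n_residues_partner1:
        res_a += 1
        dx, dy, dz = next(jit), next(jit), next(jit)
        add("A", res_a, "ALA", "CA", (-6.0 + dx, _ROW_SPACING * filler_row_a + dy, dz), 0.0)
        filler_row_a += 1
    while res_b < spec.n_residues_partner2:
        res_b += 1
        dx, dy, dz = next(jit), next(jit), next(jit)
        add("B", res_b, "ALA", "CA", (6.0 + dx, _ROW_SPACING * filler_row_b + dy, dz), 0.0)
        filler_row_b += 1

    partner1 = frozenset(a.atom_index for a in atoms if a.chain_id == "A")
    partner2 = frozenset(a.atom_index for a in atoms if a.chain_id == "B")
    topology = Topology(
        atoms=tuple(atoms),
        partner1=partner1,
        partner2=partner2,
        temperature_default=spec.temperature,
    )
    return topology, np.array(coords)


def _placement_ok(spec: DimerSpec, topology: Topology, frame: np.ndarray) -> bool:
    """Check designed-contact exclusivity of one placement attempt."""
    from .hbond_analysis import HBondCriteria, detect_hbonds

    traj = Trajectory(topology=topology, frames=frame[None, :, :])
    records = detect_hbonds(traj, HBondCriteria())
    if len(records) != spec.n_designed_hbonds:
        return False
    # charged inter-chain pairs within 4 Å must be exactly the designed
    # salt bridges
    p1 = topology.partner_indices(1)
    p2 = topology.partner_indices(2)
    q = topology.charges()
    close_charged = 0
    for i in p1:
        for j in p2:
            if abs(q[i] * q[j]) > 0.5:  # only the ±1 salt beads qualify
                r = float(np.linalg.norm(frame[i] - frame[j]))
                if r <= 4.0:
                    close_charged += 1
    return close_charged == spec.n_salt_bridges


def build_toy_dimer(spec: DimerSpec):
    """Build a toy dimer; returns ``(topology, reference_frame)``.

    The designed contacts are deterministic; the seed only jitters the
    filler beads.  Placement is re-attempted with fresh jitter if a
    filler bead accidentally interferes with a designed contact.
    """
    rng = np.random.default_rng(spec.seed)
    n_filler = max(spec.n_residues_partner1, 0) + max(spec.n_residues_partner2, 0)
    for _ in range(20):
        jitter = 0.3 * rng.standard_normal(3 * n_filler + 3)
        topology, frame = _toy_atoms(spec, jitter)
        if _placement_ok(spec, topology, frame):
            return topology, frame
    raise RuntimeError(
        "geometric placement failed after 20 attempts; relax the dimer spec"
    )


# ---------------------------------------------------------------------------
# Metropolis Monte-Carlo sampler
# ---------------------------------------------------------------------------


def _atom_tables(topology: Topology):
    """Per-atom interaction tables against the opposite partner."""
    p1 = topology.partner_indices(1)
    p2 = topology.partner_indices(2)
    q = topology.charges()
    rh = topology.rmin_half()
    eps = topology.epsilon()
    tables = []
    for i in range(topology.n_atoms):
        other = p2 if i in topology.partner1 else p1
        tables.append(
            dict(
                other=other,
                qq=COULOMB_KCAL * q[i] * q[other],
                rmin=rh[i] + rh[other],
                eps=np.sqrt(eps[i] * eps[other]),
            )
        )
    return tables


def _atom_energy(pos: np.ndarray, coords: np.ndarray, table: dict) -> float:
    other = table["other"]
    if other.size == 0:
        return 0.0
    diff = coords[other] - pos
    r = np.sqrt(np.sum(diff * diff, axis=1))
    s6 = (table["rmin"] / r) ** 6
    return float(np.sum(table["qq"] / r) + np.sum(table["eps"] * (s6 * s6 - 2.0 * s6)))


def sample_trajectory(
    topology: Topology,
    reference: np.ndarray,
    n_frames: int,
    temperature: float = DEFAULT_TEMPERATURE,
    step_size: float = 0.15,
    seed: int = 0,
    tether_force_constant: float = 10.0,
    record_every: int = 2,
    n_tune_sweeps: int = 50,
    auto_tune: bool = True,
    frame_interval: float = 10.0,
) -> Trajectory:
    """Sample snapshots around a reference pose by Metropolis MC.

    The potential is U = E_inter(Coulomb + LJ, inter-partner only) +
    Σ_i ½k|x_i − x_ref,i|².  One sweep attempts one Gaussian
    displacement move per atom (acceptance min(1, e^{−ΔU/KT})); a frame
    is recorded every ``record_every`` sweeps after an auto-tuning
    burn-in that adjusts the step size toward a mid-range acceptance
    rate.  A final acceptance rate outside [0.05, 0.95] triggers a
    warning, not an error.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (topology.n_atoms, 3):
        raise ValueError("reference does not match topology")
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")

    rng = np.random.default_rng(seed)
    kt = BOLTZMANN_KCAL * temperature
    k = tether_force_constant
    tables = _atom_tables(topology)
    coords = reference.copy()
    n_atoms = topology.n_atoms

    def sweep(step: float) -> int:
        accepted = 0
        for i in range(n_atoms):
            old = coords[i].copy()
            new = old + step * rng.standard_normal(3)
            d_tether = 0.5 * k * (
                float(np.sum((new - reference[i]) ** 2))
                - float(np.sum((old - reference[i]) ** 2))
            )
            d_inter = _atom_energy(new, coords, tables[i]) - _atom_energy(
                old, coords, tables[i]
            )
            du = d_tether + d_inter
            if du <= 0 or rng.random() < math.exp(-du / kt):
                coords[i] = new
                accepted += 1
        return accepted

    step = step_size
    if auto_tune:
        acc = 0
        for s in range(n_tune_sweeps):
            acc += sweep(step)
            if (s + 1) % 10 == 0:
                rate = acc / (10 * n_atoms)
                if rate > 0.6:
                    step *= 1.4
                elif rate < 0.2:
                    step *= 0.7
                acc = 0

    frames = np.empty((n_frames, n_atoms, 3))
    accepted = attempted = 0
    for f in range(n_frames):
        for _ in range(record_every):
            accepted += sweep(step)
            attempted += n_atoms
        frames[f] = coords

    rate = accepted / attempted if attempted else 0.0
    if not 0.05 <= rate <= 0.95:
        warnings.warn(
            f"MC acceptance rate {rate:.3f} outside [0.05, 0.95] after tuning",
            RuntimeWarning,
            stacklevel=2,
        )
    return Trajectory(topology=topology, frames=frames, frame_interval=frame_interval)
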