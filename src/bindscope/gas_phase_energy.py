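"""Inter-partner molecular-mechanics energies.

The gas-phase interaction energy between the two partners of a complex
is the sum over all inter-partner atom pairs of a Coulomb term,
332.0637·q_i·q_j/r, and a Lennard-Jones term in the AMBER R_min
convention, ε_ij·[(R_min,ij/r)^12 − 2(R_min,ij/r)^6].  No distance
cutoff and no periodic images are applied: the observable is the single
interaction energy between two proteins, and desk-scale systems make
exact all-pairs summation cheap.  Under the single-trajectory protocol
the per-frame total E^int = E_ele + E_vdW is also the fluctuating
quantity the interaction-entropy estimator consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_KCAL
from .model_io import AtomRecord, EnergySeries, ResidueKey, Topology, Trajectory

__all__ = [
    "EnergyComponents",
    "pair_energy",
    "group_interaction_energy",
    "interaction_energy_series",
    "per_residue_interaction_series",
]

_MIN_SEPARATION = 1e-9  # Å; below this two atoms are coincident


@dataclass(frozen=True)
class EnergyComponents:
    """Electrostatic + van der Waals energies, kcal/mol."""

    ele: float
    vdw: float

    @property
    def total(self) -> float:
        return self.ele + self.vdw


def pair_energy(atom_i: AtomRecord, atom_j: AtomRecord, r: float) -> EnergyComponents:
    """Coulomb and LJ energy of one atom pair at separation ``r`` (Å).

    Pair LJ parameters use Lorentz–Berthelot-style combination:
    R_min,ij = rmin_half_i + rmin_half_j, ε_ij = sqrt(ε_i ε_j).
    """
    if r <= 0:
        raise ValueError("pair separation must be positive")
    ele = COULOMB_KCAL * atom_i.charge * atom_j.charge / r
    rmin = atom_i.lj_rmin_half + atom_j.lj_rmin_half
    eps = np.sqrt(atom_i.lj_epsilon * atom_j.lj_epsilon)
    s6 = (rmin / r) ** 6
    vdw = eps * (s6 * s6 - 2.0 * s6)
    return EnergyComponents(ele=float(ele), vdw=float(vdw))


def _partner_params(topology: Topology):
    p1 = topology.partner_indices(1)
    p2 = topology.partner_indices(2)
    q = topology.charges()
    rh = topology.rmin_half()
    eps = topology.epsilon()
    return p1, p2, q, rh, eps


def _pair_matrices(frame: np.ndarray, topology: Topology):
    """Per-pair ele and vdw matrices (partner1 rows × partner2 columns)."""
    p1, p2, q, rh, eps = _partner_params(topology)
    frame = np.asarray(frame, dtype=float)
    diff = frame[p1][:, None, :] - frame[None, p2, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    if np.any(r < _MIN_SEPARATION):
        i, j = np.argwhere(r < _MIN_SEPARATION)[0]
        a, b = topology.atoms[p1[i]], topology.atoms[p2[j]]
        raise ValueError(
            f"coincident inter-partner atoms {a.qualified_name()} and "
            f"{b.qualified_name()}"
        )
    ele = COULOMB_KCAL * np.outer(q[p1], q[p2]) / r
    rmin = rh[p1][:, None] + rh[None, p2]
    eps_ij = np.sqrt(np.outer(eps[p1], eps[p2]))
    s6 = (rmin / r) ** 6
    vdw = eps_ij * (s6 * s6 - 2.0 * s6)
    return ele, vdw, p1, p2


def group_interaction_energy(frame: np.ndarray, topology: Topology) -> EnergyComponents:
    """Total inter-partner interaction energy of one frame."""
    ele, vdw, _, _ = _pair_matrices(frame, topology)
    return EnergyComponents(ele=float(ele.sum()), vdw=float(vdw.sum()))


def interaction_energy_series(trajectory: Trajectory):
    """Per-frame (ele, vdw, total) series for a trajectory.

    Returns a dict with keys ``"ele"``, ``"vdw"``, ``"total"``; the mean
    of the total series is the reported ⟨E^int⟩.
    """
    n = trajectory.n_frames
    if n == 0:
        raise ValueError("empty trajectory")
    ele = np.empty(n)
    vdw = np.empty(n)
    for f in range(n):
        comp = group_interaction_energy(trajectory.frames[f], trajectory.topology)
        ele[f], vdw[f] = comp.ele, comp.vdw
    meta = dict(
        frame_interval=trajectory.frame_interval,
        temperature=trajectory.topology.temperature_default,
    )
    return {
        "ele": EnergySeries(values=ele, component="ele", **meta),
        "vdw": EnergySeries(values=vdw, component="vdw", **meta),
        "total": EnergySeries(values=ele + vdw, component="total", **meta),
    }


def per_residue_interaction_series(trajectory: Trajectory, side: int = 2) -> dict:
    """Decompose the interaction energy over the residues of one partner.

    For every residue R of partner ``side``, the per-frame sum of pair
    energies between R's atoms and all atoms of the other partner.
    Returns {ResidueKey: (ele EnergySeries, vdw EnergySeries)}.  The
    per-frame sum over residues equals the total series (pair terms are
    merely regrouped).
    """
    topology = trajectory.topology
    residues = topology.residues(side=side)
    if not residues:
        raise ValueError(f"partner {side} has no residues")
    if side == 2:
        sel_axis = 1  # columns of the pair matrices
    elif side == 1:
        sel_axis = 0
    else:
        raise ValueError("side must be 1 or 2")

    partner = topology.partner_indices(side)
    pos_in_partner = {atom: k for k, atom in enumerate(partner)}
    res_slices = {
        key: np.array([pos_in_partner[i] for i in idxs])
        for key, idxs in residues.items()
    }

    n = trajectory.n_frames
    ele_out = {key: np.empty(n) for key in residues}
    vdw_out = {key: np.empty(n) for key in residues}
    for f in range(n):
        ele, vdw, _, _ = _pair_matrices(trajectory.frames[f], topology)
        if sel_axis == 0:
            ele_rows, vdw_rows = ele.sum(axis=1), vdw.sum(axis=1)
        else:
            ele_rows, vdw_rows = ele.sum(axis=0), vdw.sum(axis=0)
        for key, sel in res_slices.items():
            ele_out[key][f] = ele_rows[sel].sum()
            vdw_out[key][f] = vdw_rows[sel].sum()

    meta = dict(
        frame_interval=trajectory.frame_interval,
        temperature=topology.temperature_default,
    )
    return {
        key: (
            EnergySeries(values=ele_out[key], component=f"ele[{key}]", **meta),
            EnergySeries(values=vdw_out[key], component=f"vdw[{key}]", **meta),
        )
        for key in residues
    }
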