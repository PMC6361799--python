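"""Inter-partner hydrogen-bond detection, occupancy and 12-10 energetics.

A candidate hydrogen bond is a (donor heavy atom, bonded polar
hydrogen, acceptor) triple with donor and acceptor on opposite
partners.  A frame satisfies the geometric criteria when the
donor–acceptor distance is at most ``max_da_distance`` and the
donor–H···acceptor angle is at least ``min_dha_angle`` (defaults
3.5 Å / 120°).  Occupancy is the percentage of frames satisfying the
criteria; a triple is reported once its occupancy reaches a floor
(default 10 %).

The hydrogen-bond energy uses the 12-10 potential

    E(R) = α/R¹² − β/R¹⁰,   α = 5.571, β = 668.580,

with R the hydrogen–acceptor distance, evaluated per frame and averaged
over the frames that satisfy the criteria.  With these coefficients the
repulsive 12-term is negligible at physical distances: the turning
point sqrt(12α/(10β)) ≈ 0.1 Å lies far below any real H···A contact,
so the potential is strictly negative and monotonically rising toward
zero over the physical range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HBOND_ALPHA, HBOND_BETA
from .model_io import Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "detect_hbonds",
    "hbond_energy",
    "geometry_profiles",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance criteria for a hydrogen bond."""

    max_da_distance: float = 3.5  # Å, donor heavy to acceptor
    min_dha_angle: float = 120.0  # degrees, donor–H···acceptor

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not 0.0 < self.min_dha_angle <= 180.0:
            raise ValueError("min_dha_angle must lie in (0, 180]")


@dataclass(frozen=True)
class HBondRecord:
    """One detected inter-partner hydrogen bond with per-frame geometry.

    ``mean_da_distance`` and ``mean_energy`` are averaged over the
    frames satisfying the criteria only; the full per-frame series are
    kept for distribution plots.
    """

    donor: str
    hydrogen: str
    acceptor: str
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    ha_distance_series: np.ndarray
    da_distance_series: np.ndarray
    angle_series: np.ndarray
    satisfied: np.ndarray
    occupancy: float
    mean_da_distance: float
    mean_energy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 100.0:
            raise ValueError("occupancy must lie in [0, 100]")


def hbond_energy(r_ha):
    """12-10 hydrogen-bond energy at H···A distance ``r_ha`` (Å)."""
    r = np.asarray(r_ha, dtype=float)
    if np.any(r <= 0):
        raise ValueError("H-acceptor distance must be positive")
    out = HBOND_ALPHA / r**12 - HBOND_BETA / r**10
    return float(out) if np.isscalar(r_ha) else out


def _candidate_triples(topology: Topology):
    donors = [
        a
        for a in topology.atoms
        if "donor_heavy" in a.role_flags and a.bonded_hydrogens
    ]
    acceptors = [a for a in topology.atoms if "acceptor" in a.role_flags]
    if not donors or not acceptors:
        raise ValueError("topology annotates no donor/acceptor pairs")
    triples = []
    for d in donors:
        d_side = 1 if d.atom_index in topology.partner1 else 2
        for h_index in d.bonded_hydrogens:
            for a in acceptors:
                a_side = 1 if a.atom_index in topology.partner1 else 2
                if a_side != d_side:
                    triples.append((d.atom_index, h_index, a.atom_index))
    return triples


def detect_hbonds(
    trajectory: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    occupancy_floor: float = 10.0,
) -> list:
    """Detect inter-partner hydrogen bonds over a trajectory.

    Returns the records whose occupancy reaches ``occupancy_floor``
    percent, sorted by descending occupancy then mean energy.
    """
    topology = trajectory.topology
    frames = trajectory.frames
    n = trajectory.n_frames
    records = []
    for d_idx, h_idx, a_idx in _candidate_triples(topology):
        d = frames[:, d_idx, :]
        h = frames[:, h_idx, :]
        a = frames[:, a_idx, :]
        da = np.linalg.norm(a - d, axis=1)
        ha = np.linalg.norm(a - h, axis=1)
        v1 = d - h
        v2 = a - h
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        satisfied = (da <= criteria.max_da_distance) & (
            angle >= criteria.min_dha_angle
        )
        occupancy = 100.0 * satisfied.sum() / n
        if occupancy < occupancy_floor or not satisfied.any():
            continue
        records.append(
            HBondRecord(
                donor=topology.atoms[d_idx].qualified_name(),
                hydrogen=topology.atoms[h_idx].qualified_name(),
                acceptor=topology.atoms[a_idx].qualified_name(),
                donor_index=d_idx,
                hydrogen_index=h_idx,
                acceptor_index=a_idx,
                ha_distance_series=ha,
                da_distance_series=da,
                angle_series=angle,
                satisfied=satisfied,
                occupancy=float(occupancy),
                mean_da_distance=float(da[satisfied].mean()),
                mean_energy=float(hbond_energy(ha[satisfied]).mean()),
            )
        )
    records.sort(key=lambda r: (-r.occupancy, r.mean_energy))
    return records


def geometry_profiles(record: HBondRecord, bin_width: float = 0.05):
    """Distance histogram and angle-vs-frame trace for one bond.

    Returns ``(bin_edges, frequencies, angle_trace)``: a normalized
    frequency histogram of the H···A distance over all frames (the
    frequencies sum to 1) and the ordered per-frame angle series.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    distances = record.ha_distance_series
    if distances.size == 0:
        raise ValueError("empty distance series")
    lo = np.floor(distances.min() / bin_width) * bin_width
    hi = np.ceil(distances.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(distances, bins=edges)
    frequencies = counts / distances.size
    return edges, frequencies, record.angle_series.copy()
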