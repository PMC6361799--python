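"""Implicit-solvent terms: SASA, nonpolar surface energy, Generalized Born.

The solvation free energy of binding splits into a polar part,
ΔG_pol, and a nonpolar part, ΔG_np = γ·SASA + β (γ = 0.00542
kcal mol⁻¹ Å⁻², β = 0.92 kcal/mol).  The polar part is computed with a
Still-style Generalized Born model (interior dielectric 1, exterior 80)
whose effective Born radii come from Hawkins–Cramer–Truhlar-style
pairwise descreening; per-frame polar energies computed externally
(e.g. by a Poisson–Boltzmann solver) can be supplied instead through
:func:`binding_solvation`'s ``external_polar`` argument.

Surface areas use the Shrake–Rupley point-counting construction with a
deterministic golden-spiral point set, a 1.4 Å water probe and
Bondi-style per-element radii (overridable).

Under the single-trajectory protocol, the solvation contribution to
binding for each frame is term(complex) − term(p1) − term(p2), with the
partner coordinates extracted from the complex frame.  Note the
constant offsets β of the nonpolar term do not cancel in this
difference: applied per species, binding ΔG_np = γ·ΔSASA − β.  The
literal per-species convention is the default; ``include_offset=False``
drops β entirely, the convention of several MM/PBSA codes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import (
    BONDI_RADII,
    COULOMB_KCAL,
    DEFAULT_ELEMENT_RADIUS,
    DEFAULT_EPS_IN,
    DEFAULT_EPS_OUT,
    DEFAULT_PROBE_RADIUS,
    NONPOLAR_BETA,
    NONPOLAR_GAMMA,
)
from .model_io import EnergySeries, Topology, Trajectory

__all__ = [
    "SolvationResult",
    "SolvationSummary",
    "element_radii",
    "shrake_rupley_sasa",
    "nonpolar_term",
    "born_radii",
    "gb_polar",
    "binding_solvation",
    "read_polar_series",
]

logger = logging.getLogger(__name__)


def element_radii(topology: Topology, table: dict | None = None) -> np.ndarray:
    """Per-atom radii (Å) looked up by element from a Bondi-style table."""
    table = BONDI_RADII if table is None else table
    return np.array(
        [
            table.get(element.upper(), DEFAULT_ELEMENT_RADIUS)
            for element in topology.elements()
        ]
    )


def _golden_spiral(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    k = np.arange(n_points)
    z = 1.0 - (2.0 * k + 1.0) / n_points
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley_sasa(
    frame: np.ndarray,
    radii: Sequence[float],
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å².

    Each atom's accessible sphere (radius r_i + probe) carries
    ``n_points`` golden-spiral test points; a point is accessible if it
    lies outside every neighbour's accessible sphere, and the per-atom
    area is 4π(r_i+probe)² × (accessible points / n_points).
    """
    if n_points < 16:
        raise ValueError("n_points must be at least 16")
    frame = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    expanded = radii + probe
    n_atoms = frame.shape[0]
    sphere = _golden_spiral(n_points)
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        diff = frame - frame[i]
        dist = np.sqrt(np.sum(diff * diff, axis=1))
        neighbors = np.where(
            (dist < expanded[i] + expanded) & (np.arange(n_atoms) != i)
        )[0]
        points = frame[i] + expanded[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = points - frame[j]
            accessible &= np.sum(d * d, axis=1) > expanded[j] ** 2
            if not accessible.any():
                break
        areas[i] = (
            4.0 * math.pi * expanded[i] ** 2 * accessible.sum() / n_points
        )
    return areas


def nonpolar_term(
    sasa_total: float,
    gamma: float = NONPOLAR_GAMMA,
    offset: float = NONPOLAR_BETA,
) -> float:
    """Nonpolar solvation energy γ·SASA + β of one species, kcal/mol."""
    if sasa_total < 0:
        raise ValueError("SASA must be non-negative")
    return gamma * sasa_total + offset


def born_radii(frame: np.ndarray, radii: Sequence[float]) -> np.ndarray:
    """Effective Born radii via pairwise descreening (HCT-style).

    The inverse Born radius of atom i starts at 1/ρ_i (intrinsic
    radius) and is reduced by the analytic integral of every
    neighbour's descreening sphere (no scaling factors).  A
    non-positive inverse radius is clamped back to the intrinsic
    radius and logged.
    """
    frame = np.asarray(frame, dtype=float)
    rho = np.asarray(radii, dtype=float)
    n = frame.shape[0]
    inv = 1.0 / rho.copy()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = float(np.linalg.norm(frame[i] - frame[j]))
            rj = rho[j]
            if r + rj <= rho[i]:
                continue  # j entirely inside i
            u = r + rj
            l = max(rho[i], abs(r - rj))
            term = 0.5 * (
                (1.0 / l - 1.0 / u)
                + (r / 4.0) * (1.0 / u**2 - 1.0 / l**2)
                + (1.0 / (2.0 * r)) * math.log(l / u)
                + (rj**2 / (4.0 * r)) * (1.0 / l**2 - 1.0 / u**2)
            )
            inv[i] -= term
    clamped = inv <= 0
    if np.any(clamped):
        logger.info(
            "clamped %d non-positive Born radii to intrinsic radii",
            int(clamped.sum()),
        )
        inv[clamped] = 1.0 / rho[clamped]
    return 1.0 / inv


def gb_polar(
    frame: np.ndarray,
    topology: Topology,
    selection: Sequence[int] | None = None,
    eps_in: float = DEFAULT_EPS_IN,
    eps_out: float = DEFAULT_EPS_OUT,
    radii: Sequence[float] | None = None,
) -> float:
    """Still-style Generalized Born polar solvation energy, kcal/mol.

    E = −½·332.0637·(1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB(r_ij) with
    f_GB = sqrt(r² + a_i a_j e^{−r²/(4 a_i a_j)}), the double sum
    including i = j (Born self terms, f_GB(0) = a_i).  ``selection``
    restricts the computation to a subset of atoms (with only those
    atoms present, as the single-trajectory protocol requires).
    """
    frame = np.asarray(frame, dtype=float)
    if selection is None:
        selection = np.arange(topology.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("selection must not be empty")
    all_radii = element_radii(topology) if radii is None else np.asarray(radii, float)
    sub_frame = frame[selection]
    sub_radii = all_radii[selection]
    q = topology.charges()[selection]

    a = born_radii(sub_frame, sub_radii)
    diff = sub_frame[:, None, :] - sub_frame[None, :, :]
    r2 = np.sum(diff * diff, axis=2)
    aa = np.outer(a, a)
    f_gb = np.sqrt(r2 + aa * np.exp(-r2 / (4.0 * aa)))
    prefactor = -0.5 * COULOMB_KCAL * (1.0 / eps_in - 1.0 / eps_out)
    return float(prefactor * np.sum(np.outer(q, q) / f_gb))


@dataclass(frozen=True)
class SolvationResult:
    """Solvation terms of one frame under the single-trajectory protocol."""

    polar: float
    nonpolar: float
    sasa_complex: float
    sasa_p1: float
    sasa_p2: float
    source: str  # "gb_internal" or "external_file"


@dataclass(frozen=True)
class SolvationSummary:
    """Per-frame binding solvation series and their means."""

    results: tuple
    pol_series: EnergySeries
    np_series: EnergySeries
    frame_indices: tuple

    @property
    def mean_pol(self) -> float:
        return self.pol_series.mean()

    @property
    def mean_np(self) -> float:
        return self.np_series.mean()

    @property
    def mean_sol(self) -> float:
        return self.mean_pol + self.mean_np


def read_polar_series(path: str | Path, n_expected: int) -> np.ndarray:
    """Read external per-frame polar binding energies from CSV.

    Accepts either ``frame,dg_pol`` rows (the binding difference) or
    ``frame,pol_complex,pol_p1,pol_p2`` rows; returns the per-frame
    ΔG_pol array, which must have one value per selected frame.
    """
    import csv

    values = []
    with open(path) as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if lineno == 1 and not _is_number(row[1] if len(row) > 1 else ""):
                continue  # header
            if len(row) == 2:
                values.append(float(row[1]))
            elif len(row) == 4:
                values.append(float(row[1]) - float(row[2]) - float(row[3]))
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 4 columns, got {len(row)}"
                )
    if len(values) != n_expected:
        raise ValueError(
            f"external polar file has {len(values)} values, expected "
            f"{n_expected} (one per selected frame)"
        )
    return np.array(values)


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def binding_solvation(
    trajectory: Trajectory,
    stride: int | None = None,
    polar_source: str = "gb_internal",
    external_polar: str | Path | Sequence[float] | None = None,
    include_offset: bool = True,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
    eps_in: float = DEFAULT_EPS_IN,
    eps_out: float = DEFAULT_EPS_OUT,
    radii_table: dict | None = None,
) -> SolvationSummary:
    """Per-frame ΔG_pol and ΔG_np of binding for selected frames.

    Frames are taken every ``stride`` snapshots; by default the stride
    is chosen so roughly 100 snapshots enter the solvation average (the
    gas-phase and entropy terms use all frames).  With
    ``polar_source="external"``, per-frame polar energies are read from
    ``external_polar`` instead of the internal GB model.
    """
    if stride is None:
        stride = max(1, trajectory.n_frames // 100)
    if stride < 1:
        raise ValueError("stride must be at least 1")
    frame_indices = np.arange(0, trajectory.n_frames, stride)
    topology = trajectory.topology
    p1 = topology.partner_indices(1)
    p2 = topology.partner_indices(2)
    radii = element_radii(topology, radii_table)
    offset = NONPOLAR_BETA if include_offset else 0.0

    if polar_source not in ("gb_internal", "external"):
        raise ValueError("polar_source must be 'gb_internal' or 'external'")
    external = None
    if polar_source == "external":
        if external_polar is None:
            raise ValueError("external polar source requires external_polar")
        if isinstance(external_polar, (str, Path)):
            external = read_polar_series(external_polar, frame_indices.size)
        else:
            external = np.asarray(external_polar, dtype=float)
            if external.size != frame_indices.size:
                raise ValueError(
                    f"external polar series has {external.size} values, "
                    f"expected {frame_indices.size}"
                )

    results = []
    for pos, f in enumerate(frame_indices):
        frame = trajectory.frames[f]
        sasa_c = float(shrake_rupley_sasa(frame, radii, probe, n_points).sum())
        sasa_1 = float(
            shrake_rupley_sasa(frame[p1], radii[p1], probe, n_points).sum()
        )
        sasa_2 = float(
            shrake_rupley_sasa(frame[p2], radii[p2], probe, n_points).sum()
        )
        d_np = (
            nonpolar_term(sasa_c, offset=offset)
            - nonpolar_term(sasa_1, offset=offset)
            - nonpolar_term(sasa_2, offset=offset)
        )
        if external is not None:
            d_pol = float(external[pos])
            source = "external_file"
        else:
            d_pol = (
                gb_polar(frame, topology, eps_in=eps_in, eps_out=eps_out,
                         radii=radii)
                - gb_polar(frame, topology, selection=p1, eps_in=eps_in,
                           eps_out=eps_out, radii=radii)
                - gb_polar(frame, topology, selection=p2, eps_in=eps_in,
                           eps_out=eps_out, radii=radii)
            )
            source = "gb_internal"
        results.append(
            SolvationResult(
                polar=d_pol,
                nonpolar=d_np,
                sasa_complex=sasa_c,
                sasa_p1=sasa_1,
                sasa_p2=sasa_2,
                source=source,
            )
        )

    meta = dict(
        frame_interval=trajectory.frame_interval * stride,
        temperature=topology.temperature_default,
    )
    return SolvationSummary(
        results=tuple(results),
        pol_series=EnergySeries(
            values=np.array([r.polar for r in results]), component="polar", **meta
        ),
        np_series=EnergySeries(
            values=np.array([r.nonpolar for r in results]),
            component="nonpolar",
            **meta,
        ),
        frame_indices=tuple(int(i) for i in frame_indices),
    )
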