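"""Domain types and file I/O for two-chain molecular systems.

The on-disk formats are deliberately plain text:

* structures and trajectories: PDB (multi-model PDB for trajectories,
  ``MODEL``/``ENDMDL`` records, coordinates at 3 decimals), read and
  written through :mod:`biotite`;
* per-atom parameters (partial charges, Lennard-Jones parameters,
  hydrogen-bond roles): a JSON "sidecar" keyed by
  chain → residue number → atom name;
* per-frame energy series: CSV with a leading comment block for
  metadata, values written at 17 significant digits so that round-trips
  are bit-exact.

Insertion codes and alternate locations are rejected with a clear error;
this package targets clean single-conformer inputs.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .constants import DEFAULT_TEMPERATURE

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "EnergySeries",
    "ResidueKey",
    "ModelIOError",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "read_energy_series",
    "write_energy_series",
    "read_energy_table",
    "write_energy_table",
]

#: Recognised hydrogen-bond role flags.
ROLE_FLAGS = frozenset({"donor_heavy", "acceptor", "polar_hydrogen"})

_FRAME_INTERVAL_REMARK = "REMARK 250 FRAME_INTERVAL_FS"


class ModelIOError(ValueError):
    """Raised for malformed structures, sidecars or series files."""


@dataclass(frozen=True)
class ResidueKey:
    """Identity of one residue: chain, author residue number, name."""

    chain_id: str
    residue_number: int
    residue_name: str

    def __str__(self) -> str:  # e.g. "A:GLY1"
        return f"{self.chain_id}:{self.residue_name}{self.residue_number}"


@dataclass(frozen=True)
class AtomRecord:
    """One atom with force-field parameters and hydrogen-bond roles.

    ``lj_rmin_half`` and ``lj_epsilon`` follow the AMBER R_min/2 + ε
    convention; pair parameters are combined as
    R_min,ij = rmin_half_i + rmin_half_j and ε_ij = sqrt(ε_i ε_j).
    """

    atom_index: int
    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    charge: float
    lj_rmin_half: float
    lj_epsilon: float
    role_flags: frozenset = frozenset()
    bonded_hydrogens: tuple = ()
    bonded_heavy: int | None = None  # set on polar hydrogens

    def __post_init__(self) -> None:
        if self.lj_rmin_half < 0 or self.lj_epsilon < 0:
            raise ModelIOError(
                f"negative LJ parameter on atom {self.qualified_name()}"
            )
        unknown = set(self.role_flags) - ROLE_FLAGS
        if unknown:
            raise ModelIOError(
                f"unknown role flags {sorted(unknown)} on atom "
                f"{self.qualified_name()}"
            )
        if "polar_hydrogen" in self.role_flags and self.bonded_heavy is None:
            raise ModelIOError(
                f"polar hydrogen {self.qualified_name()} lacks a bonded "
                "heavy atom"
            )

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.residue_number, self.residue_name)

    def qualified_name(self) -> str:
        return (
            f"(chain {self.chain_id}, residue {self.residue_number} "
            f"{self.residue_name}, atom {self.atom_name})"
        )


@dataclass(frozen=True)
class Topology:
    """An ordered atom list with a two-partner partition.

    ``partner1`` / ``partner2`` are disjoint frozensets of 0-based atom
    indices whose union covers all atoms; every residue lies entirely
    within one partner.
    """

    atoms: tuple
    partner1: frozenset
    partner2: frozenset
    temperature_default: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        indices = [a.atom_index for a in self.atoms]
        if indices != list(range(len(self.atoms))):
            raise ModelIOError("atom indices must be dense and 0-based")
        if self.partner1 & self.partner2:
            raise ModelIOError("partner sets overlap")
        if self.partner1 | self.partner2 != set(indices):
            raise ModelIOError("partner sets do not cover all atoms")
        for key, idxs in self.residues().items():
            sides = {i in self.partner1 for i in idxs}
            if len(sides) > 1:
                raise ModelIOError(f"residue {key} spans both partners")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def partner_indices(self, side: int) -> np.ndarray:
        """Sorted atom indices of partner 1 or 2."""
        if side not in (1, 2):
            raise ValueError("side must be 1 or 2")
        members = self.partner1 if side == 1 else self.partner2
        return np.array(sorted(members), dtype=int)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def rmin_half(self) -> np.ndarray:
        return np.array([a.lj_rmin_half for a in self.atoms])

    def epsilon(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms])

    def elements(self) -> list:
        return [a.element for a in self.atoms]

    def residues(self, side: int | None = None) -> dict:
        """Ordered map ResidueKey -> list of atom indices (file order)."""
        keep = None
        if side is not None:
            keep = self.partner1 if side == 1 else self.partner2
        out: dict = {}
        for atom in self.atoms:
            if keep is not None and atom.atom_index not in keep:
                continue
            out.setdefault(atom.residue_key, []).append(atom.atom_index)
        return out

    def swapped(self) -> "Topology":
        """The same system with partner labels exchanged."""
        return replace(self, partner1=self.partner2, partner2=self.partner1)


@dataclass(frozen=True)
class Trajectory:
    """Ordered coordinate snapshots tied to a topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``frame_interval``
    is the time between stored frames in fs.
    """

    topology: Topology
    frames: np.ndarray
    frame_interval: float = 10.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ModelIOError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[1] != self.topology.n_atoms:
            raise ModelIOError(
                f"frames carry {frames.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if self.frame_interval <= 0:
            raise ModelIOError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times_fs(self) -> np.ndarray:
        return np.arange(1, self.n_frames + 1) * self.frame_interval


@dataclass(frozen=True)
class EnergySeries:
    """Per-frame scalar energies (kcal/mol) with a component label."""

    values: np.ndarray
    component: str = "total"
    frame_interval: float = 10.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise ModelIOError("series must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise ModelIOError("series contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    def mean(self) -> float:
        return float(np.mean(self.values))

    def times_fs(self) -> np.ndarray:
        return np.arange(1, len(self) + 1) * self.frame_interval


# ---------------------------------------------------------------------------
# PDB structures and trajectories
# ---------------------------------------------------------------------------


def _check_clean(atoms: struc.AtomArray, context: str) -> None:
    if hasattr(atoms, "ins_code") and np.any(atoms.ins_code != ""):
        raise ModelIOError(f"{context}: insertion codes are not supported")
    if hasattr(atoms, "altloc_id") and np.any(~np.isin(atoms.altloc_id, ["", " ", "."])):
        raise ModelIOError(f"{context}: alternate locations are not supported")


def _atom_array(topology: Topology, frame: np.ndarray) -> struc.AtomArray:
    arr = struc.AtomArray(topology.n_atoms)
    arr.coord = np.asarray(frame, dtype=float)
    arr.chain_id = np.array([a.chain_id for a in topology.atoms])
    arr.res_id = np.array([a.residue_number for a in topology.atoms])
    arr.res_name = np.array([a.residue_name for a in topology.atoms])
    arr.atom_name = np.array([a.atom_name for a in topology.atoms])
    arr.element = np.array([a.element for a in topology.atoms])
    return arr


def write_topology(
    topology: Topology,
    frame: np.ndarray,
    structure_path: str | Path,
    params_path: str | Path,
) -> None:
    """Write a single-frame PDB plus the JSON parameter sidecar."""
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_atom_array(topology, frame))
    pdb_file.write(str(structure_path))

    atoms_blob: dict = {}
    for atom in topology.atoms:
        entry: dict = {
            "charge": atom.charge,
            "rmin_half": atom.lj_rmin_half,
            "epsilon": atom.lj_epsilon,
            "roles": sorted(atom.role_flags),
            "element": atom.element,
        }
        if atom.bonded_heavy is not None:
            entry["bonded_to"] = topology.atoms[atom.bonded_heavy].atom_name
        atoms_blob.setdefault(atom.chain_id, {}).setdefault(
            str(atom.residue_number), {}
        )[atom.atom_name] = entry

    p1_chains = sorted({topology.atoms[i].chain_id for i in topology.partner1})
    p2_chains = sorted({topology.atoms[i].chain_id for i in topology.partner2})
    sidecar = {
        "partner1_chains": p1_chains,
        "partner2_chains": p2_chains,
        "temperature": topology.temperature_default,
        "atoms": atoms_blob,
    }
    Path(params_path).write_text(json.dumps(sidecar, indent=1))


def read_topology(structure_path: str | Path, params_path: str | Path) -> Topology:
    """Read a PDB structure plus its parameter sidecar into a Topology.

    The partner partition is inferred from the ``partner1_chains`` /
    ``partner2_chains`` lists of the sidecar.  A missing parameter entry
    for any structure atom is a hard error naming the atom.
    """
    pdb_file = pdb.PDBFile.read(str(structure_path))
    arr = pdb_file.get_structure(model=1)
    _check_clean(arr, str(structure_path))

    sidecar = json.loads(Path(params_path).read_text())
    p1_chains = set(sidecar["partner1_chains"])
    p2_chains = set(sidecar["partner2_chains"])
    if p1_chains & p2_chains:
        raise ModelIOError(
            f"partner chain lists overlap: {sorted(p1_chains & p2_chains)}"
        )
    blob = sidecar.get("atoms", {})

    records: list[AtomRecord] = []
    seen: set = set()
    pending_bonds: list[tuple[int, str]] = []  # (H index, heavy atom name)
    for i in range(arr.array_length()):
        chain = str(arr.chain_id[i])
        resnum = int(arr.res_id[i])
        name = str(arr.atom_name[i])
        ident = (chain, resnum, name)
        if ident in seen:
            raise ModelIOError(
                f"duplicate atom (chain {chain}, residue {resnum}, atom {name})"
            )
        seen.add(ident)
        try:
            entry = blob[chain][str(resnum)][name]
        except KeyError:
            raise ModelIOError(
                "missing sidecar parameters for atom "
                f"(chain {chain}, residue {resnum}, atom {name})"
            ) from None
        roles = frozenset(entry.get("roles", []))
        bonded_heavy = None
        if "polar_hydrogen" in roles:
            if "bonded_to" not in entry:
                raise ModelIOError(
                    f"polar hydrogen (chain {chain}, residue {resnum}, atom "
                    f"{name}) lacks a 'bonded_to' heavy atom in the sidecar"
                )
            pending_bonds.append((i, entry["bonded_to"]))
        records.append(
            AtomRecord(
                atom_index=i,
                atom_name=name,
                element=str(entry.get("element", arr.element[i])),
                residue_number=resnum,
                residue_name=str(arr.res_name[i]),
                chain_id=chain,
                charge=float(entry["charge"]),
                lj_rmin_half=float(entry.get("rmin_half", 0.0)),
                lj_epsilon=float(entry.get("epsilon", 0.0)),
                role_flags=roles,
                bonded_heavy=-1 if "polar_hydrogen" in roles else None,
            )
        )

    # Resolve donor-hydrogen bonds within each residue.
    by_ident = {
        (r.chain_id, r.residue_number, r.atom_name): r.atom_index for r in records
    }
    hydrogens_of: dict[int, list[int]] = {}
    for h_index, heavy_name in pending_bonds:
        h = records[h_index]
        heavy = by_ident.get((h.chain_id, h.residue_number, heavy_name))
        if heavy is None:
            raise ModelIOError(
                f"polar hydrogen {h.qualified_name()} is bonded to unknown "
                f"atom {heavy_name!r}"
            )
        records[h_index] = replace(h, bonded_heavy=heavy)
        hydrogens_of.setdefault(heavy, []).append(h_index)
    for heavy, hs in hydrogens_of.items():
        records[heavy] = replace(records[heavy], bonded_hydrogens=tuple(hs))

    partner1, partner2 = set(), set()
    for r in records:
        if r.chain_id in p1_chains:
            partner1.add(r.atom_index)
        elif r.chain_id in p2_chains:
            partner2.add(r.atom_index)
        else:
            raise ModelIOError(
                f"chain {r.chain_id!r} belongs to neither partner chain list"
            )
    return Topology(
        atoms=tuple(records),
        partner1=frozenset(partner1),
        partner2=frozenset(partner2),
        temperature_default=float(sidecar.get("temperature", DEFAULT_TEMPERATURE)),
    )


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB; the frame interval goes into a REMARK."""
    stack = struc.stack(
        [_atom_array(trajectory.topology, f) for f in trajectory.frames]
    )
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.lines = [
        f"{_FRAME_INTERVAL_REMARK} {trajectory.frame_interval!r}"
    ] + pdb_file.lines
    pdb_file.write(str(path))


def read_trajectory(
    path: str | Path,
    topology: Topology,
    frame_interval: float | None = None,
) -> Trajectory:
    """Read a multi-model PDB whose atom order matches ``topology``.

    ``frame_interval`` falls back to the REMARK written by
    :func:`write_trajectory`, then to 10 fs.  An atom-count mismatch in
    any model is an error naming the model index (1-based, as in the
    file).
    """
    pdb_file = pdb.PDBFile.read(str(path))
    if frame_interval is None:
        for line in pdb_file.lines:
            if line.startswith(_FRAME_INTERVAL_REMARK):
                frame_interval = float(line.split()[-1])
                break
        else:
            frame_interval = 10.0

    n_models = pdb_file.get_model_count()
    frames = np.empty((n_models, topology.n_atoms, 3))
    for m in range(1, n_models + 1):
        arr = pdb_file.get_structure(model=m)
        _check_clean(arr, f"{path} model {m}")
        if arr.array_length() != topology.n_atoms:
            raise ModelIOError(
                f"model {m} has {arr.array_length()} atoms, topology has "
                f"{topology.n_atoms}"
            )
        for i, atom in enumerate(topology.atoms):
            if (
                str(arr.chain_id[i]) != atom.chain_id
                or int(arr.res_id[i]) != atom.residue_number
                or str(arr.atom_name[i]) != atom.atom_name
            ):
                raise ModelIOError(
                    f"model {m}: atom {i} is "
                    f"(chain {arr.chain_id[i]}, residue {arr.res_id[i]}, atom "
                    f"{arr.atom_name[i]}), expected {atom.qualified_name()}"
                )
        frames[m - 1] = arr.coord
    return Trajectory(topology=topology, frames=frames, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# Energy-series CSV
# ---------------------------------------------------------------------------


def write_energy_series(series: EnergySeries, path: str | Path) -> None:
    """Write one series as CSV; exact round-trip at 17 significant digits."""
    write_energy_table({series.component: series}, path)


def write_energy_table(table: Mapping[str, EnergySeries], path: str | Path) -> None:
    """Write several component series (equal metadata) into one CSV."""
    first = next(iter(table.values()))
    with open(path, "w", newline="") as fh:
        fh.write(f"# temperature_k={first.temperature!r}\n")
        fh.write(f"# frame_interval_fs={first.frame_interval!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["frame", "time_fs", "value", "component"])
        for component, series in table.items():
            times = series.times_fs()
            for i, v in enumerate(series.values):
                writer.writerow([i, f"{times[i]:.6f}", f"{v:.17g}", component])


def read_energy_table(path: str | Path) -> dict:
    """Read an energy CSV into {component: EnergySeries}."""
    temperature = DEFAULT_TEMPERATURE
    frame_interval = 10.0
    columns: dict[str, list[float]] = {}
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    key = key.strip()
                    if key == "temperature_k":
                        temperature = float(value)
                    elif key == "frame_interval_fs":
                        frame_interval = float(value)
                continue
            fields = next(csv.reader([line]))
            if not header_seen:
                if [f.strip() for f in fields[:4]] != [
                    "frame",
                    "time_fs",
                    "value",
                    "component",
                ]:
                    raise ModelIOError(
                        f"{path}:{lineno}: expected header "
                        "'frame,time_fs,value,component'"
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise ModelIOError(
                    f"{path}:{lineno}: expected 4 fields, found {len(fields)}"
                )
            try:
                value = float(fields[2])
            except ValueError:
                raise ModelIOError(
                    f"{path}:{lineno}: malformed value {fields[2]!r}"
                ) from None
            if not math.isfinite(value):
                raise ModelIOError(f"{path}:{lineno}: non-finite value")
            columns.setdefault(fields[3], []).append(value)
    if not columns:
        raise ModelIOError(f"{path}: no data rows")
    return {
        component: EnergySeries(
            values=np.array(values),
            component=component,
            frame_interval=frame_interval,
            temperature=temperature,
        )
        for component, values in columns.items()
    }


def read_energy_series(path: str | Path, component: str | None = None) -> EnergySeries:
    """Read one series; ``component`` selects among several in the file."""
    table = read_energy_table(path)
    if component is None:
        if len(table) != 1:
            raise ModelIOError(
                f"{path} holds components {sorted(table)}; pass component="
            )
        return next(iter(table.values()))
    if component not in table:
        raise ModelIOError(f"{path} has no component {component!r}")
    return table[component]
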