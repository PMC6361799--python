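"""Assembly of binding free-energy reports and structural stability checks.

The end-state decomposition of the binding free energy is

    ΔG_bind = ΔG_gas + ΔG_sol
    ΔG_gas  = ΔE_ele + ΔE_vdW + (−TΔS)
    ΔG_sol  = ΔG_pol + ΔG_np

with ΔE_ele/ΔE_vdW the mean inter-partner gas-phase terms, −TΔS from
the interaction-entropy estimator and the solvation terms from the
implicit-solvent model.  These identities hold exactly for the stored
values of every assembled :class:`BindingReport`; printing rounds to
two decimals.  ΔΔG comparisons are computed second-minus-first.

Also provided: the per-residue contribution table with the −2 kcal/mol
hot-spot threshold, and backbone RMSD relative to a reference pose via
Kabsch superposition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .interaction_entropy import IEResult
from .model_io import EnergySeries, ResidueKey, Trajectory
from .solvation import SolvationSummary

__all__ = [
    "BindingReport",
    "ResidueContribution",
    "assemble_binding_report",
    "delta_delta_g",
    "residue_contributions",
    "hotspot_residues",
    "backbone_rmsd",
]

_DD_TERMS = (
    "mean_gas_interaction",
    "mean_ele",
    "mean_vdw",
    "minus_t_delta_s",
    "dg_pol",
    "dg_np",
    "dg_sol",
    "dg_gas",
    "dg_bind",
)


@dataclass(frozen=True)
class BindingReport:
    """All energy terms of one complex, kcal/mol.

    ``mean_ele``/``mean_vdw`` (and ``dg_pol``/``dg_np``) may be None
    when only their sums are known, e.g. when assembling from published
    summary rows; every identity among the populated values is enforced
    exactly.
    """

    system_label: str
    force_field_label: str
    mean_gas_interaction: float
    minus_t_delta_s: float
    dg_sol: float
    mean_ele: float | None = None
    mean_vdw: float | None = None
    dg_pol: float | None = None
    dg_np: float | None = None
    uncertainties: Mapping[str, float] = field(default_factory=dict)
    temperature: float = 300.0
    n_frames: int | None = None

    def __post_init__(self) -> None:
        if self.mean_ele is not None and self.mean_vdw is not None:
            if self.mean_ele + self.mean_vdw != self.mean_gas_interaction:
                raise ValueError(
                    "mean_gas_interaction must equal mean_ele + mean_vdw"
                )
        if self.dg_pol is not None and self.dg_np is not None:
            if self.dg_pol + self.dg_np != self.dg_sol:
                raise ValueError("dg_sol must equal dg_pol + dg_np")

    @property
    def dg_gas(self) -> float:
        return self.mean_gas_interaction + self.minus_t_delta_s

    @property
    def dg_bind(self) -> float:
        return self.dg_gas + self.dg_sol

    @property
    def dg_ele_pol(self) -> float | None:
        """Combined electrostatics: ΔE_ele + ΔG_pol, when both known."""
        if self.mean_ele is None or self.dg_pol is None:
            return None
        return self.mean_ele + self.dg_pol

    @classmethod
    def from_components(
        cls,
        system_label: str,
        force_field_label: str,
        mean_ele: float | None = None,
        mean_vdw: float | None = None,
        mean_gas_interaction: float | None = None,
        minus_t_delta_s: float = 0.0,
        dg_pol: float | None = None,
        dg_np: float | None = None,
        dg_sol: float | None = None,
        **kwargs,
    ) -> "BindingReport":
        """Build a report from whichever component breakdown is known."""
        if mean_gas_interaction is None:
            if mean_ele is None or mean_vdw is None:
                raise ValueError(
                    "need mean_gas_interaction or both mean_ele and mean_vdw"
                )
            mean_gas_interaction = mean_ele + mean_vdw
        if dg_sol is None:
            if dg_pol is None or dg_np is None:
                raise ValueError("need dg_sol or both dg_pol and dg_np")
            dg_sol = dg_pol + dg_np
        return cls(
            system_label=system_label,
            force_field_label=force_field_label,
            mean_gas_interaction=mean_gas_interaction,
            mean_ele=mean_ele,
            mean_vdw=mean_vdw,
            minus_t_delta_s=minus_t_delta_s,
            dg_pol=dg_pol,
            dg_np=dg_np,
            dg_sol=dg_sol,
            **kwargs,
        )

    def as_dict(self, rounded: bool = False) -> dict:
        out = {
            "system_label": self.system_label,
            "force_field_label": self.force_field_label,
            "temperature": self.temperature,
            "n_frames": self.n_frames,
            "uncertainties": dict(self.uncertainties),
        }
        for term in _DD_TERMS + ("dg_ele_pol",):
            value = getattr(self, term)
            if value is not None and rounded:
                value = round(value, 2)
            out[term] = value
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BindingReport":
        blob = json.loads(Path(path).read_text())
        return cls(
            system_label=blob["system_label"],
            force_field_label=blob["force_field_label"],
            mean_gas_interaction=blob["mean_gas_interaction"],
            minus_t_delta_s=blob["minus_t_delta_s"],
            dg_sol=blob["dg_sol"],
            mean_ele=blob.get("mean_ele"),
            mean_vdw=blob.get("mean_vdw"),
            dg_pol=blob.get("dg_pol"),
            dg_np=blob.get("dg_np"),
            uncertainties=blob.get("uncertainties", {}),
            temperature=blob.get("temperature", 300.0),
            n_frames=blob.get("n_frames"),
        )

    def format_table(self) -> str:
        """Two-decimal table of the populated terms."""
        lines = [f"{self.system_label} ({self.force_field_label})"]
        for term in _DD_TERMS + ("dg_ele_pol",):
            value = getattr(self, term)
            if value is None:
                continue
            std = self.uncertainties.get(term)
            suffix = f"  (STD {std:.2f})" if std is not None else ""
            lines.append(f"  {term:22s} {value:10.2f}{suffix}")
        return "\n".join(lines)


def assemble_binding_report(
    gas_series: Mapping[str, EnergySeries],
    ie_result: IEResult,
    solvation: SolvationSummary,
    system_label: str = "synthetic dimer",
    force_field_label: str = "toy",
) -> BindingReport:
    """Combine gas-phase series, IE result and solvation means.

    ``gas_series`` is the {"ele", "vdw", "total"} mapping from the
    gas-phase engine; frame counts and temperatures must be mutually
    consistent.
    """
    for name in ("ele", "vdw"):
        if name not in gas_series:
            raise ValueError(f"missing gas-phase term {name!r}")
    ele, vdw = gas_series["ele"], gas_series["vdw"]
    if len(ele) != len(vdw):
        raise ValueError("ele/vdw series lengths differ")
    if ie_result.n_frames != len(ele):
        raise ValueError(
            f"IE used {ie_result.n_frames} frames, gas series has {len(ele)}"
        )
    if not math.isclose(ie_result.temperature, ele.temperature, rel_tol=1e-9):
        raise ValueError("IE and gas-phase temperatures differ")
    mean_ele, mean_vdw = ele.mean(), vdw.mean()

    from .interaction_entropy import block_uncertainty

    uncertainties = {}
    if len(ele) >= 20:
        uncertainties["mean_ele"] = block_uncertainty(ele, statistic="mean")
        uncertainties["mean_vdw"] = block_uncertainty(vdw, statistic="mean")
        uncertainties["mean_gas_interaction"] = block_uncertainty(
            gas_series["total"], statistic="mean"
        )
    if ie_result.block_std is not None:
        uncertainties["minus_t_delta_s"] = ie_result.block_std
    if len(solvation.pol_series) >= 20:
        uncertainties["dg_pol"] = block_uncertainty(
            solvation.pol_series, statistic="mean"
        )
        uncertainties["dg_np"] = block_uncertainty(
            solvation.np_series, statistic="mean"
        )

    return BindingReport(
        system_label=system_label,
        force_field_label=force_field_label,
        mean_gas_interaction=mean_ele + mean_vdw,
        mean_ele=mean_ele,
        mean_vdw=mean_vdw,
        minus_t_delta_s=ie_result.minus_t_delta_s,
        dg_pol=solvation.mean_pol,
        dg_np=solvation.mean_np,
        dg_sol=solvation.mean_pol + solvation.mean_np,
        uncertainties=uncertainties,
        temperature=ie_result.temperature,
        n_frames=ie_result.n_frames,
    )


def delta_delta_g(report_a: BindingReport, report_b: BindingReport) -> dict:
    """Per-term differences b − a (second argument minus first)."""
    if not math.isclose(report_a.temperature, report_b.temperature, rel_tol=1e-9):
        raise ValueError("reports have different temperatures")
    out = {}
    for term in _DD_TERMS + ("dg_ele_pol",):
        a, b = getattr(report_a, term), getattr(report_b, term)
        out[term] = None if a is None or b is None else b - a
    return out


@dataclass(frozen=True)
class ResidueContribution:
    """Decomposed binding contribution of one residue, kcal/mol."""

    residue: ResidueKey
    ele: float
    vdw: float
    pol: float
    nonpol: float
    minus_t_delta_s: float

    @property
    def total(self) -> float:
        return self.ele + self.vdw + self.pol + self.nonpol + self.minus_t_delta_s


def residue_contributions(
    per_residue_series: Mapping,
    per_residue_entropy: Mapping,
    pol: Mapping | None = None,
    nonpol: Mapping | None = None,
) -> list:
    """Assemble per-residue contribution records.

    ``per_residue_series`` maps residue → (ele series, vdw series) from
    the gas-phase decomposition; ``per_residue_entropy`` maps residue →
    −TΔS_res.  Optional ``pol``/``nonpol`` maps supply per-residue
    solvation terms (default 0, since the implicit-solvent terms are
    not decomposed by residue in this package).
    """
    out = []
    for key, (ele_series, vdw_series) in per_residue_series.items():
        if key not in per_residue_entropy:
            raise ValueError(f"missing per-residue entropy for {key}")
        out.append(
            ResidueContribution(
                residue=key,
                ele=ele_series.mean(),
                vdw=vdw_series.mean(),
                pol=float(pol.get(key, 0.0)) if pol else 0.0,
                nonpol=float(nonpol.get(key, 0.0)) if nonpol else 0.0,
                minus_t_delta_s=float(per_residue_entropy[key]),
            )
        )
    return out


def hotspot_residues(
    contributions: Sequence[ResidueContribution], threshold: float = -2.0
) -> list:
    """Residues whose total contribution is at or below ``threshold``.

    Sorted ascending by total (strongest contributors first).
    """
    hits = [c for c in contributions if c.total <= threshold]
    hits.sort(key=lambda c: c.total)
    return hits


def _kabsch_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centred ``moving`` onto ``target``."""
    h = moving.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    return u @ correction @ vt


def backbone_rmsd(
    trajectory: Trajectory,
    reference: np.ndarray,
    selection: frozenset | set = frozenset({"N", "CA", "C"}),
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD of selected atoms relative to a reference pose, Å.

    Each frame's selected atoms are optimally superposed onto the
    reference (Kabsch least squares) before the deviation is measured;
    ``superpose=False`` skips the fit and measures raw deviations.
    """
    topology = trajectory.topology
    idx = np.array(
        [a.atom_index for a in topology.atoms if a.atom_name in selection]
    )
    if idx.size < 3:
        raise ValueError(
            f"selection {sorted(selection)} matches fewer than 3 atoms"
        )
    reference = np.asarray(reference, dtype=float)
    ref = reference[idx]
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        mob = trajectory.frames[f][idx]
        if superpose:
            mob_c = mob - mob.mean(axis=0)
            ref_c = ref - ref.mean(axis=0)
            rot = _kabsch_rotation(mob_c, ref_c)
            diff = mob_c @ rot - ref_c
        else:
            diff = mob - ref
        out[f] = math.sqrt(float(np.mean(np.sum(diff * diff, axis=1))))
    return out
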