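"""Report assembly identities, ΔΔG bookkeeping, hot spots and RMSD."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from bindscope import (
    BindingReport,
    ResidueContribution,
    ResidueKey,
    Trajectory,
    assemble_binding_report,
    backbone_rmsd,
    binding_solvation,
    delta_delta_g,
    hotspot_residues,
    interaction_energy_series,
    interaction_entropy,
    per_residue_entropy,
    per_residue_interaction_series,
    residue_contributions,
    sample_trajectory,
)

finite = st.floats(-600.0, 600.0, allow_nan=False)


class TestAssembly:
    @pytest.mark.parametrize(
        "gas, ts, sol, expected",
        [
            (-336.96, 18.87, 290.65, -27.44),
            (-372.41, 14.47, 320.47, -37.47),
            (0.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_published_summary_rows(self, gas, ts, sol, expected):
        report = BindingReport.from_components(
            "case", "ff", mean_gas_interaction=gas, minus_t_delta_s=ts,
            dg_sol=sol,
        )
        assert round(report.dg_bind, 2) == expected

    def test_missing_term_is_named(self):
        with pytest.raises(ValueError, match="dg_sol"):
            BindingReport.from_components(
                "case", "ff", mean_gas_interaction=-10.0, minus_t_delta_s=1.0
            )
        with pytest.raises(ValueError, match="mean_gas_interaction"):
            BindingReport.from_components("case", "ff", dg_sol=5.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(ele=finite, vdw=finite, ts=st.floats(0.0, 50.0), pol=finite,
           np_=finite)
    def test_identities_hold_exactly(self, ele, vdw, ts, pol, np_):
        report = BindingReport.from_components(
            "prop", "ff", mean_ele=ele, mean_vdw=vdw, minus_t_delta_s=ts,
            dg_pol=pol, dg_np=np_,
        )
        assert report.dg_sol == report.dg_pol + report.dg_np
        assert report.dg_gas == report.mean_gas_interaction + report.minus_t_delta_s
        assert report.dg_bind == report.dg_gas + report.dg_sol
        assert report.mean_gas_interaction == ele + vdw
        assert report.dg_ele_pol == ele + pol

    def test_inconsistent_components_rejected(self):
        with pytest.raises(ValueError, match="mean_ele"):
            BindingReport(
                system_label="bad", force_field_label="ff",
                mean_gas_interaction=-10.0, minus_t_delta_s=1.0, dg_sol=5.0,
                mean_ele=-3.0, mean_vdw=-3.0,
            )

    def test_json_roundtrip(self, tmp_path):
        report = BindingReport.from_components(
            "sys", "ff", mean_ele=-5.0, mean_vdw=-2.0, minus_t_delta_s=1.5,
            dg_pol=4.0, dg_np=-1.0, uncertainties={"dg_pol": 0.3},
        )
        path = tmp_path / "report.json"
        report.to_json(path)
        rebuilt = BindingReport.from_json(path)
        assert rebuilt == report


class TestDeltaDeltaG:
    def test_published_peptide_pair(self):
        from bindscope.literature import literature_report

        a = literature_report("pDIQ-MDMX", "PPC")
        b = literature_report("pDIQ-MDM2", "PPC")
        assert round(delta_delta_g(a, b)["dg_bind"], 2) == -2.90

    def test_published_receptor_component_deltas(self):
        from bindscope.literature import literature_report

        a = literature_report("p53-MDMX", "PPC")
        b = literature_report("p53-MDM2", "PPC")
        deltas = delta_delta_g(a, b)
        assert round(deltas["mean_vdw"], 2) == -19.35
        assert round(deltas["dg_pol"], 2) == 192.87
        assert round(deltas["mean_ele"], 2) == -180.38
        assert round(deltas["minus_t_delta_s"], 2) == 7.01

    def test_identical_reports_give_zero(self):
        report = BindingReport.from_components(
            "x", "ff", mean_gas_interaction=-20.0, minus_t_delta_s=2.0,
            dg_sol=10.0,
        )
        assert all(
            v == 0.0 for v in delta_delta_g(report, report).values()
            if v is not None
        )

    def test_antisymmetry(self):
        a = BindingReport.from_components(
            "a", "ff", mean_gas_interaction=-20.0, minus_t_delta_s=2.0,
            dg_sol=10.0,
        )
        b = BindingReport.from_components(
            "b", "ff", mean_gas_interaction=-30.0, minus_t_delta_s=3.0,
            dg_sol=12.0,
        )
        forward = delta_delta_g(a, b)
        backward = delta_delta_g(b, a)
        for term, value in forward.items():
            if value is not None:
                assert backward[term] == -value


def _contribution(total):
    return ResidueContribution(
        residue=ResidueKey("A", 1, "RES"), ele=total, vdw=0.0, pol=0.0,
        nonpol=0.0, minus_t_delta_s=0.0,
    )


class TestHotspots:
    def test_filter_and_order(self):
        contribs = [_contribution(t) for t in (-2.5, -1.0, -3.0)]
        hits = hotspot_residues(contribs)
        assert [h.total for h in hits] == [-3.0, -2.5]

    def test_all_above_threshold_is_empty(self):
        assert hotspot_residues([_contribution(-1.0)]) == []

    def test_salt_bridge_residue_is_hot(self, sampled_trajectory):
        per_res = per_residue_interaction_series(sampled_trajectory, side=1)
        entropy = per_residue_entropy(per_res, 300.0)
        contribs = residue_contributions(per_res, entropy)
        hot_names = {c.residue.residue_name for c in hotspot_residues(contribs)}
        assert "POS" in hot_names


class TestEndToEnd:
    def test_pipeline_report_identities(self, sampled_trajectory):
        gas = interaction_energy_series(sampled_trajectory)
        ie = interaction_entropy(gas["total"])
        solv = binding_solvation(sampled_trajectory, stride=30)
        report = assemble_binding_report(gas, ie, solv, "toy dimer", "toy")
        assert report.dg_bind == report.dg_gas + report.dg_sol
        assert report.dg_sol == report.dg_pol + report.dg_np
        assert report.mean_gas_interaction == report.mean_ele + report.mean_vdw
        assert report.minus_t_delta_s >= 0.0
        assert set(report.uncertainties) >= {
            "mean_ele", "mean_vdw", "minus_t_delta_s"
        }

    def test_stronger_contacts_bind_more_tightly(self, dimer):
        # scaling all charges strengthens electrostatics monotonically
        topology, reference = dimer
        means = []
        for scale in (1.0, 2.0, 3.0):
            scaled = dataclasses.replace(
                topology,
                atoms=tuple(
                    dataclasses.replace(a, charge=scale * a.charge)
                    for a in topology.atoms
                ),
            )
            trajectory = sample_trajectory(
                scaled, reference, n_frames=150, seed=19,
                tether_force_constant=10.0,
            )
            means.append(interaction_energy_series(trajectory)["ele"].mean())
        assert means[0] > means[1] > means[2]

    def test_frame_count_mismatch_rejected(self, sampled_trajectory):
        gas = interaction_energy_series(sampled_trajectory)
        ie = interaction_entropy(gas["total"].values[:-5], temperature=300.0)
        solv = binding_solvation(sampled_trajectory, stride=100)
        with pytest.raises(ValueError, match="frames"):
            assemble_binding_report(gas, ie, solv)


class TestBackboneRMSD:
    def test_identical_frame_is_zero(self, dimer):
        topology, reference = dimer
        trajectory = Trajectory(topology=topology, frames=reference[None])
        assert backbone_rmsd(trajectory, reference, selection={"CA"})[0] < 1e-12
        assert backbone_rmsd(
            trajectory, reference, selection={"CA"}, superpose=False
        )[0] == 0.0

    def test_rigid_motion_removed_by_superposition(self, dimer):
        topology, reference = dimer
        rotation = Rotation.from_euler("zyx", [1.0, 0.4, -0.7]).as_matrix()
        moved = reference @ rotation.T + np.array([2.0, -8.0, 3.0])
        trajectory = Trajectory(topology=topology, frames=moved[None])
        assert backbone_rmsd(trajectory, reference, selection={"CA"})[0] < 1e-8

    def test_single_displacement_without_fit(self, dimer):
        topology, reference = dimer
        idx = [a.atom_index for a in topology.atoms if a.atom_name == "CA"]
        n = len(idx)
        moved = reference.copy()
        moved[idx[0]] += np.array([1.0, 0.0, 0.0])
        trajectory = Trajectory(topology=topology, frames=moved[None])
        value = backbone_rmsd(trajectory, reference, selection={"CA"},
                              superpose=False)[0]
        assert value == pytest.approx(np.sqrt(1.0 / n), rel=1e-12)

    def test_small_selection_rejected(self, dimer):
        topology, reference = dimer
        trajectory = Trajectory(topology=topology, frames=reference[None])
        with pytest.raises(ValueError, match="fewer than 3"):
            backbone_rmsd(trajectory, reference, selection={"NZ"})

    def test_tethered_sampling_stays_near_reference(self, sampled_trajectory, dimer):
        _, reference = dimer
        values = backbone_rmsd(sampled_trajectory, reference, selection={"CA"})
        assert np.all(values >= 0.0)
        assert values.mean() < 1.0  # tether keeps the complex near the pose
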