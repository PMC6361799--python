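# bindscope

End-state binding free energies for two-chain protein complexes:
MM/PB(GB)SA term assembly with the **interaction-entropy (IE)** estimator for
the entropic term, hydrogen-bond occupancy and 12-10 energetics, per-residue
hot-spot decomposition, and a synthetic dimer sampler so the full pipeline is
testable without molecular-dynamics software.

It is written for computational structural biologists who analyse
protein–protein (receptor–peptide) trajectories — the motivating systems are
the p53 and pDIQ peptides bound to the oncoproteins MDMX and MDM2 — but every
stage operates on plain coordinate snapshots plus a per-atom parameter file,
so any two-chain ensemble can be analysed.

## The model

The binding free energy of a complex is assembled from end-state terms
averaged over trajectory snapshots:

```
ΔG_bind = ΔG_gas + ΔG_sol
ΔG_gas  = ΔE_ele + ΔE_vdW + (−TΔS)
ΔG_sol  = ΔG_pol + ΔG_np,    ΔG_np = γ·SASA + β   (γ = 0.00542, β = 0.92)
```

Under the single-trajectory protocol the gas-phase terms are the mean
inter-partner Coulomb (332.0637·q_iq_j/r) and Lennard-Jones
(ε_ij[(R_min,ij/r)¹² − 2(R_min,ij/r)⁶]) energies, with no cutoff.  The
entropic penalty comes from the fluctuations of the same interaction energy
E^int along the trajectory:

```
−TΔS = KT · ln ⟨ e^{β ΔE^int} ⟩,   ΔE^int = E^int − ⟨E^int⟩,   β = 1/KT
```

evaluated in numerically stable log-sum-exp form.  The polar solvation term
uses a Still-type Generalized Born model with Hawkins–Cramer–Truhlar
descreening (dielectrics 1/80); externally computed Poisson–Boltzmann
energies can be imported per frame instead.  Hydrogen bonds are detected
geometrically (D···A ≤ 3.5 Å, D–H···A ≥ 120°) and scored with the 12-10
potential E(R) = 5.571/R¹² − 668.580/R¹⁰ over the H···A distance R.
Residues whose decomposed contribution is ≤ −2 kcal/mol are flagged as hot
spots.

## Worked example

Generate a toy dimer (one designed hydrogen bond, one salt bridge), sample
500 Monte-Carlo snapshots around the reference pose, and run the pipeline:

```sh
bindscope simulate --out-prefix toy --n-frames 500 --seed 1
bindscope energy    --traj toy_traj.pdb --top toy_top.pdb --params toy_params.json --out gas.csv
bindscope ie        --series gas.csv --component total --out ie.json
bindscope solvation --traj toy_traj.pdb --top toy_top.pdb --params toy_params.json --stride 5 --out solv.csv
bindscope report    --gas gas.csv --ie ie.json --solv solv.csv --labels "toy dimer,synthetic" --out report.json
```

which prints

```
toy dimer (synthetic)
  mean_gas_interaction      -144.32  (STD 0.70)
  mean_ele                  -154.16  (STD 0.84)
  mean_vdw                     9.84  (STD 0.58)
  minus_t_delta_s              4.02  (STD 1.03)
  dg_pol                     144.59  (STD 1.34)
  dg_np                       -1.64  (STD 0.01)
  dg_sol                     142.96
  dg_gas                    -140.30
  dg_bind                      2.65
  dg_ele_pol                  -9.57
```

All values are kcal/mol.  The designed salt bridge gives a strongly
favourable electrostatic interaction (`mean_ele`), most of which is offset by
the polar desolvation penalty (`dg_pol`) — the same compensation seen in real
charged interfaces; `minus_t_delta_s` is the entropic penalty estimated from
the energy fluctuations; the identities above (ΔG_bind = ΔG_gas + ΔG_sol,
etc.) hold exactly for the stored values, while printing rounds to two
decimals.  The STD columns are 10-block standard deviations.
`bindscope hbond` tabulates the detected hydrogen bonds (mean D···A distance,
occupancy, mean 12-10 energy), and `bindscope rmsd` reports backbone RMSD
against the reference pose (here 0.43 Å on average — the tethered sampler
stays near the pose).

The same assembly applied to published component tables for the
p53/pDIQ–MDMX/MDM2 complexes ships in `bindscope.literature`; e.g.
`literature_report("p53-MDMX", "PPC").dg_bind` evaluates to −27.44 kcal/mol
from its components.

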