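# Methods

This note documents the models, numerical choices and limitations of
bindscope in one place.  Units throughout: Å, kcal/mol, elementary charges
e, K, fs.  Constants: K (Boltzmann) = 0.0019872041 kcal mol⁻¹ K⁻¹, Coulomb
factor 332.0637 kcal Å mol⁻¹ e⁻², default temperature 300 K.

## Energy model and the single-trajectory protocol

The gas-phase interaction energy between the two partners of a complex is
the exact all-pairs sum of Coulomb and Lennard-Jones terms over inter-partner
atom pairs.  LJ parameters follow the AMBER R_min/2 + ε per-atom convention
with Lorentz–Berthelot-style combination (R_min,ij = rmin_half_i +
rmin_half_j, ε_ij = √(ε_iε_j)).  No nonbonded cutoff and no periodic images
are applied: the observable is a single interaction energy between two
molecules, and at the system sizes this package targets the exact sum is
cheap.  Intra-partner terms never enter — under the single-trajectory
protocol the partner conformations are extracted from the complex frames, so
intramolecular energies cancel identically in the binding difference and
only the inter-partner interaction remains.  Conformational reorganization
energy is therefore outside the model.

Per-residue decomposition regroups exactly the same pair terms by the
residue owning one of the pair's atoms, so the per-frame sum over residues
reproduces the frame total to float associativity (tested at 10⁻⁸ kcal/mol).

## Interaction entropy

The entropic penalty is estimated from the fluctuations of the inter-partner
interaction energy:

−TΔS = KT·ln⟨e^{βΔE}⟩ with ΔE = E − ⟨E⟩ and β = 1/KT.

Numerics: the exponential average is evaluated in max-shifted log-sum-exp
form, KT·(max βΔE + ln[(1/N)Σe^{βΔE−max}]).  The naive average overflows
double precision once βΔE ≳ 700, i.e. for fluctuations of a few hundred
kcal/mol·β⁻¹ — easily reached by tail frames of real series.  The stable
form agrees with the naive form to 10⁻¹⁰ relative where the latter is
representable and stays finite far beyond.  Jensen's inequality guarantees a
non-negative estimate; float rounding can produce −10⁻¹⁶, which is clipped
to zero.  A length-1 series returns 0 by convention.

Convergence traces re-centre the mean on each prefix, so every trace point
is a valid standalone estimate of the prefix; the final point equals the
full-series value bit-for-bit.  (Using the global mean for all prefixes is
the other defensible convention; per-prefix was chosen because it makes each
point independently meaningful.)

For Gaussian fluctuations of standard deviation σ the estimator converges to
σ²/(2KT); the tests use this closed form at σ = 0.5 kcal/mol (0.2097
kcal/mol at 300 K) and check the error shrinks with sample size.  Note the
estimator's sampling error grows quickly with βσ; the synthetic series used
in tests keep βσ ≲ 1, where 10⁶ frames give ~1 % accuracy.

Per-residue entropies apply the same estimator to each residue's own
interaction series (ele + vdW).  Because the functional is nonlinear, the
per-residue values do not sum to the whole-system −TΔS; they are reported
without rescaling.

Uncertainty ("STD") columns are 10-block statistics: the series is cut into
equal contiguous blocks (remainder truncated) and the sample standard
deviation (ddof = 1) of the per-block estimate — the IE value for the
entropy term, the plain mean for energy terms — is reported.  This is a
package convention; published tables rarely define their STD columns, and no
claim is made of reproducing any particular one.

## Implicit solvation

**Nonpolar.**  ΔG_np = γ·SASA + β with γ = 0.00542 kcal mol⁻¹ Å⁻² and
β = 0.92 kcal/mol.  The offset is applied per species (complex, partner 1,
partner 2), so the binding difference carries a constant −0.92 kcal/mol:
ΔG_np(bind) = γ·ΔSASA − β.  This is the literal reading of the linear
relation; several MM/PBSA codes drop the offset instead, so
`include_offset=False` is provided.

**SASA.**  Shrake–Rupley point counting with a deterministic golden-spiral
set of 960 points per atom (configurable, minimum 16), probe 1.4 Å, and
Bondi-style per-element radii (H 1.20, C 1.70, N 1.55, O 1.52, S 1.80 …;
unknown elements 1.50), overridable per call.  At 960 points the two-sphere
benchmark against the spherical-cap closed form is accurate to ~0.1 %.

**Polar.**  A Still-type Generalized Born energy,
E = −½·332.0637·(1/ε_in − 1/ε_out)·Σ_ij q_iq_j/f_GB with
f_GB = √(r² + a_ia_j·e^{−r²/(4a_ia_j)}) and the i = j self terms included,
ε_in = 1, ε_out = 80.  Effective Born radii come from
Hawkins–Cramer–Truhlar-style pairwise descreening of the intrinsic (element)
radii, with no scaling factors (S_j = 1); a non-positive inverse radius is
clamped back to the intrinsic radius and logged.  GB stands in for a
finite-difference Poisson–Boltzmann solver, which is deliberately out of
scope; per-frame PB energies computed externally can be supplied as a CSV
(`frame,dg_pol` or `frame,pol_complex,pol_p1,pol_p2`) and are passed through
unchanged.  GB and PB polar energies differ systematically at charged
interfaces, so absolute toy ΔG_bind values are not comparable to
PB-based published numbers; the assembly identities and differences are.

Solvation terms default to a stride giving ≈100 snapshots per trajectory —
the customary end-state sample size — while the gas-phase and entropy terms
use every frame.

## Hydrogen bonds

Candidate triples are (donor heavy, bonded polar hydrogen, acceptor) with
donor and acceptor on opposite partners, taken from role annotations in the
parameter sidecar.  A frame satisfies the bond when D···A ≤ 3.5 Å and the
D–H···A angle ≥ 120°; both thresholds are configurable.  Occupancy is the
percentage of satisfying frames, and a triple is reported above a 10 %
occupancy floor.  The reported distance is the mean D···A separation over
satisfying frames; the 12-10 energy E(R) = 5.571/R¹² − 668.580/R¹⁰ is
evaluated per frame on the H···A distance and averaged over satisfying
frames only (evaluating it once at a mean distance is not equivalent and is
not done).  With these coefficients the potential's turning point lies near
0.1 Å, far below physical contact, so it is strictly negative and
monotonically rising toward zero over 1–10 Å — asserted analytically in the
tests.

## Synthetic systems

The generator emulates what the analysis consumes from a restrained MD run:
approximately stationary interaction-energy fluctuations and an ensemble of
poses near a reference structure.

* **Energy series** — Gaussian, two-state mixture, or AR(1) with prescribed
  stationary σ and lag-1 autocorrelation; all reproducible from a seed.
* **Toy dimer** — two chains of 1–3-atom coarse residues: filler beads
  (uncharged, LJ only), designed hydrogen-bond triples (N–H···O collinear,
  D···A 2.9 Å, H···A 1.9 Å) and salt bridges (±1 beads 3.5 Å apart, each
  pair net neutral).  Designed geometry is deterministic; the seed only
  jitters filler beads, and a construction check re-detects exactly the
  designed contacts (retrying the jitter a bounded number of times).
* **Sampler** — Metropolis Monte Carlo over per-atom Gaussian displacement
  moves under U = E_inter + Σ½k|x − x_ref|², with the tether k defaulting to
  10 kcal mol⁻¹ Å⁻² (a free synthetic parameter chosen to keep backbone RMSD
  near 0.5 Å, the stability regime of a restrained run).  One sweep attempts
  one move per atom; a burn-in of 50 sweeps auto-tunes the step size toward
  mid-range acceptance, then frames are recorded every 2 sweeps.  With the
  ½k convention the per-coordinate variance of a lone tethered atom is KT/k,
  which the detailed-balance test verifies to 5 %.  A final acceptance rate
  outside [0.05, 0.95] (e.g. under an extremely stiff tether) is reported as
  a warning, not an error, since the frozen limit is sometimes exactly what
  a test wants.

What the synthetic systems do **not** emulate: bonded force-field terms,
realistic protein geometry and packing, explicit water, long-range
electrostatics of a periodic box, and the slow conformational relaxation of
real interfaces.  Passing tests therefore demonstrate the correctness of the
estimators and bookkeeping on controlled ensembles, not force-field accuracy
on real complexes.

## Published-table inputs

`bindscope.literature` ships the published end-state components (⟨E_pp⟩,
−TΔS, ΔG_sol, and the polarized-charge component breakdowns) for
p53/pDIQ–MDMX/MDM2 under two charge models.  The package re-derives ΔG_bind,
ΔG_ele+pol and all ΔΔG values from the components; only components are
stored.  Two rows are internally inconsistent at the printed precision
(component sums give −28.92 and −29.13 where the source prints −28.93 and
−29.12 — rounding from unrounded internals); the recomputed sums are
reported as-is.  The same source prints a ΔG_ele+pol of 24.85 for one system
whose own components sum to 34.54; ele+pol is always recomputed here, never
stored.

## Problem sizes

Default test and reproduction runs use desk-scale problems chosen to
exercise every code path: toy dimers of 4+4 residues (~16 atoms), 2000-frame
Monte-Carlo ensembles, 10⁶-point synthetic series for the closed-form
entropy checks, and ~100-snapshot solvation averages.  The full acceptance
reproduction completes in seconds on one CPU.

## Known limitations

* GB with S = 1 descreening overestimates screening in tightly packed
  interfaces; no salt dependence, no molecular-surface (SEV) definition.
* Per-residue solvation terms are not decomposed (the per-residue
  contribution table carries zeros for pol/nonpol unless supplied).
* PDB insertion codes and altlocs are rejected rather than handled.
* The trajectory format is multi-model PDB only — human-inspectable and
  dependency-light, but bulky for long trajectories.
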