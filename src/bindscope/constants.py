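"""Physical constants and force-field defaults.

Units are fixed globally across the package: lengths in Å, energies in
kcal/mol, charges in elementary-charge units e, temperatures in K and
times in fs.
"""

#: Boltzmann constant, kcal mol^-1 K^-1.
BOLTZMANN_KCAL = 0.0019872041

#: Coulomb conversion factor, kcal Å mol^-1 e^-2 (electrostatic energy
#: = COULOMB_KCAL * q_i * q_j / r for charges in e and r in Å).
COULOMB_KCAL = 332.0637

#: Default simulation/analysis temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Surface-tension coefficient γ of the nonpolar solvation term
#: ΔG_np = γ·SASA + β, kcal mol^-1 Å^-2.
NONPOLAR_GAMMA = 0.00542

#: Constant offset β of the nonpolar solvation term, kcal/mol.
NONPOLAR_BETA = 0.92

#: Repulsive (R^-12) coefficient of the 12-10 hydrogen-bond potential,
#: kcal Å^12 / mol.
HBOND_ALPHA = 5.571

#: Attractive (R^-10) coefficient of the 12-10 hydrogen-bond potential,
#: kcal Å^10 / mol.
HBOND_BETA = 668.580

#: Water-probe radius used for solvent-accessible surface areas, Å.
DEFAULT_PROBE_RADIUS = 1.4

#: Bondi-style van der Waals radii per element, Å.  Used for SASA and as
#: intrinsic radii for the Generalized Born term; overridable in every
#: public function that consumes radii.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Fallback radius for elements absent from :data:`BONDI_RADII`, Å.
DEFAULT_ELEMENT_RADIUS = 1.50

#: Interior dielectric constant of the solute.
DEFAULT_EPS_IN = 1.0

#: Exterior (water) dielectric constant.
DEFAULT_EPS_OUT = 80.0
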