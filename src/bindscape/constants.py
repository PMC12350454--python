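"""Physical constants and the package's fixed unit system.

Units everywhere: lengths in Å, times in ps, energies in kcal/mol,
charges in elementary charges, masses in amu. Conversions happen only at
I/O edges.
"""

#: Boltzmann constant, kcal/(mol K)
KB_KCAL = 0.0019872041

#: Coulomb prefactor so that q_i q_j / r with q in e and r in Å is kcal/mol
COULOMB_KCAL = 332.0716

#: Generalized-Born prefactor (half the Coulomb constant)
GB_KCAL = 166.0358

#: Default simulation/analysis temperature (K); matches a 310 K thermostat
DEFAULT_TEMPERATURE_K = 310.0

#: HCT intrinsic-radius offset (Å): reduced radius = gb_radius - GB_OFFSET
GB_OFFSET = 0.09

#: Default water probe radius for SASA (Å)
DEFAULT_PROBE_RADIUS = 1.4

#: Default nonpolar surface coefficient gamma, kcal/(mol Å^2), and offset beta
DEFAULT_SURF_GAMMA = 0.0072
DEFAULT_SURF_BETA = 0.0

#: Default interior / exterior dielectric constants
DEFAULT_EPS_IN = 1.0
DEFAULT_EPS_OUT = 78.5
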