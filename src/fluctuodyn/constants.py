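"""Physical constants and unit conversions used throughout the package.

Internal conventions: lengths in Å, wavevectors in Å⁻¹, temperatures in K,
compressibilities in Pa⁻¹ (SI). The display conversion to the field's
customary 10⁻⁶ bar⁻¹ is ``kappa / BAR_INV_MICRO``.
"""

K_B = 1.380649e-23  # Boltzmann constant, J/K (exact, SI 2019)
N_A = 6.02214076e23  # Avogadro constant, 1/mol (exact)
R_GAS = K_B * N_A  # molar gas constant, J/(mol K)

M_WATER = 18.015  # g/mol
M_GLYCEROL = 92.094  # g/mol

A3_TO_M3 = 1e-30  # Å³ → m³
INV_A3_TO_INV_M3 = 1e30  # Å⁻³ → m⁻³
BAR_INV_MICRO = 1e-11  # 1 × 10⁻⁶ bar⁻¹ expressed in Pa⁻¹

# Hard-sphere radius of the water-like normal-liquid component, Å.
# Temperature-independent by convention in the SAXS decomposition.
DEFAULT_HARD_SPHERE_RADIUS = 1.78

# Local structure index conventions (Å², Å)
LSI_THRESHOLD = 0.114
LSI_CUTOFF = 3.7
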