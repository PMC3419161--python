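"""Physical constants in the unit system used throughout the package.

Energies are kcal/mol, lengths Å, times ps, temperatures K, charges in
elementary charge units.
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL: float = 1.9872e-3

#: Boltzmann constant per mole — identical to R in molar energy units.
KB_KCAL: float = R_KCAL

#: Standard-state reference concentration for binding free energies, mol/L.
C_STANDARD: float = 1.0
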