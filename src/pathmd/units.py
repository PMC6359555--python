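"""Package-wide unit conventions.

All quantities are in GROMACS-style units: energies kJ/mol, lengths nm,
times ps, masses amu, angles radians.  Momenta are amu·nm/ps, gradients
kJ/mol/nm, temperatures K.
"""

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083144621

#: Gas constant for Arrhenius fits, kJ/mol/K (numerically identical to KB).
R_GAS = 8.314e-3
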