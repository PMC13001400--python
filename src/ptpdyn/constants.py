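"""Physical constants, kcal/mol and Kelvin conventions."""

# Boltzmann constant in kcal mol^-1 K^-1 (so kT = KCAL_PER_MOL_K * T)
KCAL_PER_MOL_K = 0.0019872041

# SI constants for transition-state-theory prefactors
BOLTZMANN_SI = 1.380649e-23   # J/K
PLANCK_SI = 6.62607015e-34    # J s
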