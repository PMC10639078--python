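"""Physical constants shared across the package."""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL_PER_MOL_K: float = 1.987e-3

#: Standard analysis temperature (20 degC) in kelvin. All docking free
#: energies are reported at this temperature unless stated otherwise.
T_STANDARD_K: float = 293.15

#: RT at the standard temperature, kcal mol^-1.
RT_KCAL_PER_MOL: float = R_KCAL_PER_MOL_K * T_STANDARD_K
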