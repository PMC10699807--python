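"""Physical constants shared across the package."""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL: float = 1.987e-3

#: Reference labeling temperature (K) for free-energy arithmetic: 25 degC.
T_REF: float = 298.15

#: Glass-electrode correction for D2O solutions: pD = pD_read + 0.4.
PD_OFFSET: float = 0.4
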