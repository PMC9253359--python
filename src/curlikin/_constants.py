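"""Physical constants shared across modules.

All masses are average (not monoisotopic) masses in daltons: at protein
scale (>10 kDa) isotopic fine structure is unresolved and centroided peak
positions follow the average mass.
"""

#: Mass of the charge carrier (proton), Da. Positive-mode nESI.
PROTON_MASS_DA: float = 1.00728

#: Average atomic mass of helium, Da (IM drift gas for CCS calibration).
HELIUM_MASS_DA: float = 4.002602
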