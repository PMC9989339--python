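"""Physical constants used by the reduction and the session generator.

Atomic masses are in unified atomic mass units; the "reference" ratios are
natural-abundance isotope ratios of calcium, used only to compute instrumental
mass-bias factors for quality control (never to correct the data — bracketing
does that).
"""
import numpy as np

#: Atomic masses of the measured calcium isotopes (u).
MASS_42 = 41.9586
MASS_43 = 42.9588
MASS_44 = 43.9555

#: Natural-abundance reference ratios used as the "true" values in the
#: exponential mass-bias law.
R44_42_REFERENCE = 3.224
R43_42_REFERENCE = 0.2087

#: Exponential-law slope linking the 43/42 and 44/42 delta scales:
#: ln(m43/m42)/ln(m44/m42) ≈ 0.50669.  Mass-dependently fractionated material
#: satisfies δ43/42 ≈ slope × δ44/42.
EXPONENTIAL_LAW_SLOPE = float(np.log(MASS_43 / MASS_42) / np.log(MASS_44 / MASS_42))

#: Conventional rounded slope used by the mass-dependence QC statistic.
MASS_DEPENDENCE_COEF = 0.50667
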