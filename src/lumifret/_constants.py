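"""Physical constants and unit-conversion factors used across the package.

Internal unit conventions:

* wavelengths         nm
* distances           nm
* molar extinction    M^-1 cm^-1
* overlap integral J  M^-1 cm^-1 nm^4
* donor lifetimes     ms  (lanthanide emission decays on the ms scale)
* transfer rates      ms^-1
* decay/gate times    us (microseconds; time-gated detection operates here)
"""

import math

AVOGADRO = 6.02214076e23  # mol^-1 (exact, SI 2019)

# Bracketed constant of the Forster rate expression,
#   9000 ln(10) / (128 pi^5 N_A),
# i.e. everything in k_T(r) except kappa^2, Q_D, n^-4, tau_D, r^-6 and J.
# The leading 9000 = 9 x 1000 absorbs the litre -> cm^3 conversion of the
# molar extinction, so with J in M^-1 cm^-1 nm^4 the product carries
# cm^2 nm^4 per molecule.
FORSTER_NUMERIC = 9000.0 * math.log(10.0) / (128.0 * math.pi**5 * AVOGADRO)

CM2_TO_NM2 = 1.0e14  # (1 cm = 1e7 nm)^2

# R0^6 [nm^6] = FORSTER_PREFACTOR_NM6 * kappa^2 * n^-4 * Q_D * J[M^-1 cm^-1 nm^4]
# Rounded to three digits this is the textbook 8.79e-5 A^6 coefficient
# (1 nm^6 = 1e6 A^6).
FORSTER_PREFACTOR_NM6 = FORSTER_NUMERIC * CM2_TO_NM2

NM_TO_CM = 1.0e-7
NM4_TO_CM4 = 1.0e-28
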