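"""Independent brute-force evaluation of the three impedance models.

Written with scalar `cmath` arithmetic, straight from the closed-form
expressions and deliberately separate from the library implementation
(which vectorizes and algebraically rearranges the formulas). Used as
the reference in oracle-equivalence tests.
"""

import cmath
import math


def ri_of(r0: float, rinf: float) -> float:
    return rinf * r0 / (r0 - rinf)


def zc_brute(r0, rinf, cm, alpha, f) -> complex:
    re_plus_ri = r0 + ri_of(r0, rinf)
    jwt = 1j * 2 * math.pi * f * re_plus_ri * cm
    return rinf + (r0 - rinf) / (1 + jwt**alpha)


def z0_brute(r0, rinf, cm, alpha, td, f) -> complex:
    return zc_brute(r0, rinf, cm, alpha, f) * cmath.exp(-1j * 2 * math.pi * f * td)


def z1_brute(r0, rinf, cm, alpha, td, cp, f) -> complex:
    zc = zc_brute(r0, rinf, cm, alpha, f)
    if cp == 0.0 or f == 0.0:
        z = zc  # shunt absent / open at DC
    else:
        zp = 1 / (1j * 2 * math.pi * f * cp)
        z = zc * zp / (zc + zp)
    return z * cmath.exp(-1j * 2 * math.pi * f * td)


def z2_brute(r0, rinf, cm_lf, a, alpha, td, f) -> complex:
    re_plus_ri = r0 + ri_of(r0, rinf)
    jwt = 1j * 2 * math.pi * f * re_plus_ri * (a * f + cm_lf)
    zm = rinf + (r0 - rinf) / (1 + jwt**alpha)
    return zm * cmath.exp(-1j * 2 * math.pi * f * td)
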