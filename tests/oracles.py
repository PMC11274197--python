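"""Independent oracles used by the mechanics and acceptance suites."""

import numpy as np
from scipy import optimize

from apexfree.mechanics import MMHG_TO_MPA


def shell_oracle_volume(p_mmhg, R_i, R_o, passive, base_frac,
                        n_r=40, n_c=6):
    """Independent 1-D quadrature oracle for the inflation of an
    isotropic, nearly incompressible thick spherical shell.

    Spherically symmetric map r(R) = R (1 + sum c_k T_k(s)), s the
    normalized wall coordinate; the total potential (strain energy via
    Gauss quadrature in R, minus pressure work on the truncated cavity)
    is minimized over the coefficients.  Truncation enters only through
    the solid-angle fraction of the wall and the cavity-volume fraction
    of the basal cap.
    """
    gauss_x, gauss_w = np.polynomial.legendre.leggauss(n_r)
    R = 0.5 * (R_o - R_i) * gauss_x + 0.5 * (R_o + R_i)
    wR = 0.5 * (R_o - R_i) * gauss_w
    s = (R - R_i) / (R_o - R_i)
    basis = np.stack([s ** k for k in range(n_c)])
    ds = 1.0 / (R_o - R_i)
    dbasis = np.stack([np.zeros_like(s) if k == 0 else k * s ** (k - 1) * ds
                       for k in range(n_c)])
    omega = 4 * np.pi * (1 + base_frac) / 2.0          # wall solid angle
    u = base_frac
    cav_frac = ((u + 1) - (u ** 3 + 1) / 3.0) / (4.0 / 3.0)
    p_mpa = p_mmhg * MMHG_TO_MPA

    def potential(c):
        f = 1.0 + basis.T @ c
        fp = dbasis.T @ c
        lam_t = f
        lam_r = f + R * fp
        if np.any(lam_r <= 0):
            return 1e12
        J = lam_r * lam_t ** 2
        I1 = lam_r ** 2 + 2 * lam_t ** 2
        I1b = J ** (-2.0 / 3.0) * I1
        psi = (passive.a / (2 * passive.b)
               * np.exp(passive.b * (I1b - 3.0))
               + 0.5 * passive.kappa * (J - 1.0) ** 2)
        W = omega * np.sum(psi * R ** 2 * wR)
        r_i = R_i * (1.0 + c[0] * 0.0 + float(basis.T[0] @ c) * 0 + f[0])
        # inner radius from the map evaluated at R_i (s = 0 -> c[0] term)
        r_i = R_i * (1.0 + c[0])
        V_cav = (4.0 / 3.0) * np.pi * r_i ** 3 * cav_frac
        return W - p_mpa * V_cav

    res = optimize.minimize(potential, np.zeros(n_c), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-14,
                                     "maxiter": 4000})
    c = res.x
    r_i = R_i * (1.0 + c[0])
    return (4.0 / 3.0) * np.pi * r_i ** 3 * cav_frac / 1000.0  # mL
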