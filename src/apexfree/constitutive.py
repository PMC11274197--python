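"""Myocardial constitutive laws.

Passive behaviour follows the orthotropic Holzapfel–Ogden strain-energy
function with an isotropic term, tension-only fiber and sheet terms, and a
fiber–sheet shear coupling term.  Near-incompressibility is enforced with a
quadratic volumetric penalty ``kappa/2 (J-1)^2`` on top of the deviatoric
energy.  Active contraction is a time-varying-elastance fiber stress: a
cosine twitch scaled by a calcium-sensitivity factor whose half-activation
level ECa50 depends on the effective sarcomere length, which gives the model
its Frank–Starling (length-dependent activation) behaviour.

Units: lengths in mm, stresses in MPa (= N/mm^2), times in s, calcium
concentrations in mM.  Sarcomere lengths follow the same mm convention as
the parameter tables (l_0 = 0.00158 mm is 1.58 um).

A single-beat Klotz-style end-diastolic pressure-volume relation (EDPVR)
estimator is included as a calibration check for passive inflation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MaterialError

__all__ = [
    "PassiveParams",
    "ActiveParams",
    "KinematicsState",
    "kinematics_from_F",
    "psi_dev",
    "psi_vol",
    "passive_stress",
    "eff_sarcomere_length",
    "eca50",
    "active_fiber_stress",
    "klotz_edpvr",
    "KLOTZ_DEFAULTS",
]


@dataclass(frozen=True)
class PassiveParams:
    """Holzapfel–Ogden passive parameters plus volumetric penalty.

    Defaults are the ventricular values used throughout: a = 3.9e-4 MPa,
    b = 3.7, a_f = 1.9e-3 MPa, b_f = 14, a_s = 1.1e-3 MPa, b_s = 11,
    a_fs = 3.6e-7 MPa, b_fs = 7e-4, kappa = 1 MPa.
    """

    a: float = 3.9e-4
    b: float = 3.7
    a_f: float = 1.9e-3
    b_f: float = 14.0
    a_s: float = 1.1e-3
    b_s: float = 11.0
    a_fs: float = 3.6e-7
    b_fs: float = 7e-4
    kappa: float = 1.0

    def __post_init__(self):
        for name in ("a", "a_f", "a_s", "a_fs"):
            if getattr(self, name) < 0:
                raise MaterialError(f"stress-like parameter {name} must be >= 0")
        for name in ("b", "b_f", "b_s", "b_fs"):
            if getattr(self, name) <= 0:
                raise MaterialError(f"exponent {name} must be > 0")
        if self.kappa < 10.0 * max(self.a, self.a_f):
            raise MaterialError(
                "volumetric modulus kappa must dominate the deviatoric "
                "stiffness (kappa >= 10 * max(a, a_f)) for near-incompressibility"
            )

    @classmethod
    def atrium(cls) -> "PassiveParams":
        return cls(a=1.0e-3, b=3.1, a_f=4.7e-3, b_f=12.0,
                   a_s=2.7e-3, b_s=9.1, a_fs=9.0e-7, b_fs=6.7e-4)


@dataclass(frozen=True)
class ActiveParams:
    """Time-varying-elastance active-stress parameters (ventricular defaults).

    ``b_relax`` is the relaxation-duration intercept (the active-law "b",
    in s); the linear relaxation duration is ``tr(l) = m*l + b_relax``.
    """

    T_max: float = 0.2
    Ca_0: float = 4.35
    Ca_0max: float = 4.35
    B: float = 4750.0
    l_0: float = 0.00158
    l_r: float = 0.00185
    t_0: float = 0.35
    m: float = 950.0
    b_relax: float = -1.5

    def __post_init__(self):
        if self.T_max < 0:
            raise MaterialError("T_max must be >= 0")
        if not (self.l_r > self.l_0 > 0):
            raise MaterialError("require l_r > l_0 > 0")
        if self.m * self.l_r + self.b_relax <= 0:
            raise MaterialError("relaxation duration tr(l_r) must be positive")

    @classmethod
    def atrium(cls) -> "ActiveParams":
        return cls(T_max=0.1, t_0=0.05, m=1048.9)

    def tr(self, l_eff):
        """Linear relaxation duration tr(l) = m*l + b_relax (s)."""
        return self.m * np.asarray(l_eff) + self.b_relax


@dataclass
class KinematicsState:
    """Deformation invariants at one or more evaluation points.

    All arrays share a leading point dimension.  ``F`` is optional (needed
    only for push-forward of stresses to the deformed configuration).
    """

    I1: np.ndarray
    I4f: np.ndarray
    I4s: np.ndarray
    I8fs: np.ndarray
    J: np.ndarray
    E_ff: np.ndarray = field(default=None)
    F: np.ndarray = None
    f0: np.ndarray = None
    s0: np.ndarray = None

    def __post_init__(self):
        self.I1 = np.atleast_1d(np.asarray(self.I1, dtype=float))
        self.I4f = np.atleast_1d(np.asarray(self.I4f, dtype=float))
        self.I4s = np.atleast_1d(np.asarray(self.I4s, dtype=float))
        self.I8fs = np.atleast_1d(np.asarray(self.I8fs, dtype=float))
        self.J = np.atleast_1d(np.asarray(self.J, dtype=float))
        if self.E_ff is None:
            self.E_ff = 0.5 * (self.I4f - 1.0)
        self.E_ff = np.atleast_1d(np.asarray(self.E_ff, dtype=float))
        for arr in (self.I1, self.I4f, self.I4s, self.I8fs, self.J):
            if not np.all(np.isfinite(arr)):
                raise MaterialError("non-finite deformation invariants")
        if np.any(self.J <= 0):
            raise MaterialError("det(F) must be positive (element inversion)")

    @classmethod
    def identity(cls, n: int = 1) -> "KinematicsState":
        one = np.ones(n)
        return cls(I1=3 * one, I4f=one, I4s=one, I8fs=0 * one, J=one)


def kinematics_from_F(F, f0, s0) -> KinematicsState:
    """Build a :class:`KinematicsState` from deformation gradients and a
    reference fiber/sheet frame.  ``F`` is (..., 3, 3); ``f0``/``s0`` (..., 3).
    """
    F = np.asarray(F, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    C = np.einsum("...ki,...kj->...ij", F, F)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I4f = np.einsum("...i,...ij,...j->...", f0, C, f0)
    I4s = np.einsum("...i,...ij,...j->...", s0, C, s0)
    I8 = np.einsum("...i,...ij,...j->...", f0, C, s0)
    J = np.linalg.det(F)
    return KinematicsState(I1=I1, I4f=I4f, I4s=I4s, I8fs=I8,
                           J=J, E_ff=0.5 * (I4f - 1.0), F=F, f0=f0, s0=s0)


def psi_dev(state: KinematicsState, p: PassiveParams):
    """Deviatoric Holzapfel–Ogden strain-energy density (MPa).

    psi = a/(2b) exp[b(I1-3)]
        + sum_{i=f,s} a_i/(2 b_i) {exp[b_i (I4i-1)^2] - 1}   (tension only)
        + a_fs/(2 b_fs) {exp[b_fs I8fs^2] - 1}

    evaluated on the isochoric (volume-preserving) invariants
    ``J^{-2/3} I`` so the energy is purely deviatoric; volume change is
    penalized separately by :func:`psi_vol`.  For isochoric deformations
    (J = 1) the invariants coincide with the full ones.  The fiber and
    sheet terms contribute only in tension.
    """
    J23 = state.J ** (-2.0 / 3.0)
    I1, I4f, I4s, I8 = (J23 * state.I1, J23 * state.I4f,
                        J23 * state.I4s, J23 * state.I8fs)
    e4f = np.where(I4f > 1.0, I4f - 1.0, 0.0)
    e4s = np.where(I4s > 1.0, I4s - 1.0, 0.0)
    psi = p.a / (2 * p.b) * np.exp(p.b * (I1 - 3.0))
    psi = psi + p.a_f / (2 * p.b_f) * (np.exp(p.b_f * e4f ** 2) - 1.0)
    psi = psi + p.a_s / (2 * p.b_s) * (np.exp(p.b_s * e4s ** 2) - 1.0)
    psi = psi + p.a_fs / (2 * p.b_fs) * (np.exp(p.b_fs * I8 ** 2) - 1.0)
    return psi


def psi_vol(state: KinematicsState, p: PassiveParams):
    """Quadratic volumetric penalty kappa/2 (J-1)^2 (MPa)."""
    return 0.5 * p.kappa * (state.J - 1.0) ** 2


def passive_stress(state: KinematicsState, p: PassiveParams, cauchy: bool = False):
    """Passive second Piola–Kirchhoff stress (MPa), analytic.

    S = 2 dPsi/dC with Psi = psi_dev + psi_vol.  Requires ``state.F``,
    ``state.f0`` and ``state.s0``.  With ``cauchy=True`` the push-forward
    sigma = J^-1 F S F^T is returned instead.
    """
    if state.F is None or state.f0 is None or state.s0 is None:
        raise MaterialError("passive_stress requires F, f0 and s0 in the state")
    F = state.F
    f0, s0 = state.f0, state.s0
    C = np.einsum("...ki,...kj->...ij", F, F)
    J = state.J
    eye = np.broadcast_to(np.eye(3), C.shape)

    # fictitious stress 2 dPsi/dCbar on the isochoric invariants
    J23 = J ** (-2.0 / 3.0)
    I1b, I4fb = J23 * state.I1, J23 * state.I4f
    I4sb, I8b = J23 * state.I4s, J23 * state.I8fs
    dpsi1 = 0.5 * p.a * np.exp(p.b * (I1b - 3.0))
    e4f = np.where(I4fb > 1.0, I4fb - 1.0, 0.0)
    e4s = np.where(I4sb > 1.0, I4sb - 1.0, 0.0)
    dpsi4f = p.a_f * e4f * np.exp(p.b_f * e4f ** 2)
    dpsi4s = p.a_s * e4s * np.exp(p.b_s * e4s ** 2)
    dpsi8 = 0.5 * p.a_fs * I8b * np.exp(p.b_fs * I8b ** 2)

    ff = np.einsum("...i,...j->...ij", f0, f0)
    ss = np.einsum("...i,...j->...ij", s0, s0)
    fs = np.einsum("...i,...j->...ij", f0, s0)
    fs_sym = fs + np.swapaxes(fs, -1, -2)

    Sbar = (2.0 * dpsi1[..., None, None] * eye
            + 2.0 * dpsi4f[..., None, None] * ff
            + 2.0 * dpsi4s[..., None, None] * ss
            + 2.0 * dpsi8[..., None, None] * fs_sym)
    # deviatoric projection: S_dev = J^{-2/3} [Sbar - (Sbar:C)/3 C^{-1}]
    Cinv = np.linalg.inv(C)
    trSC = np.einsum("...ij,...ij->...", Sbar, C)
    S = J23[..., None, None] * (Sbar - (trSC / 3.0)[..., None, None] * Cinv)
    # volumetric: dPsi_vol/dJ * J * C^{-1}
    S = S + (p.kappa * (J - 1.0) * J)[..., None, None] * Cinv
    if cauchy:
        sig = np.einsum("...ij,...jk,...lk->...il", F, S, F) / J[..., None, None]
        return sig
    return S


def eff_sarcomere_length(E_ff, p: ActiveParams):
    """Effective sarcomere length l_eff = l_r sqrt(2 E_ff + 1) (mm)."""
    E_ff = np.asarray(E_ff, dtype=float)
    arg = 2.0 * E_ff + 1.0
    if np.any(arg <= 0):
        raise MaterialError("2*E_ff + 1 must be positive (non-physical compression)")
    return p.l_r * np.sqrt(arg)


def eca50(l_eff, p: ActiveParams):
    """Length-dependent calcium sensitivity ECa50 (mM).

    ECa50 = Ca_0max / sqrt(exp[B (l_eff - l_0)] - 1); below l_0 no active
    force develops, which is represented by an infinite ECa50.
    """
    l_eff = np.asarray(l_eff, dtype=float)
    denom_sq = np.expm1(p.B * (l_eff - p.l_0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom_sq > 0.0, p.Ca_0max / np.sqrt(np.abs(denom_sq)), np.inf)
    return out


def active_fiber_stress(t, E_ff, p: ActiveParams, tr_floor: float | None = None,
                        E_phase=None):
    """Active fiber stress sigma_a(t, E_ff) (MPa).

    sigma_a = T_max/2 * Ca_0^2/(Ca_0^2 + ECa50^2) * (1 - cos w) with the
    cosine phase w rising over [0, t_0], relaxing over [t_0, t_0 + tr(l_eff)]
    and zero afterwards; tr(l) = m*l + b_relax.

    For fibers compressed to l_eff near or below l_0 the linear tr(l)
    becomes non-positive while the stress is already zero through the
    diverging ECa50; ``tr_floor`` (s) clips tr there to keep the expression
    defined (None raises instead, the strict parameter-checking behaviour).

    ``E_phase``: optional fiber strain used for the twitch *timing*
    (tr and the cosine phase) while the amplitude keeps the instantaneous
    length dependence.  The equilibrium solver passes the strain of the
    previous coupled step here, reflecting that relaxation duration is set
    by the sarcomere-length history rather than the instantaneous length
    and keeping the residual smooth within one solve.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise MaterialError("activation time must be >= 0")
    l_eff = eff_sarcomere_length(E_ff, p)
    l_ph = l_eff if E_phase is None else eff_sarcomere_length(E_phase, p)
    tr = p.tr(l_ph)
    if np.any(tr <= 0):
        if tr_floor is None:
            raise MaterialError("relaxation duration tr(l_eff) must be positive")
        tr = np.maximum(tr, tr_floor)
    elif tr_floor is not None:
        tr = np.maximum(tr, tr_floor)
    t, l_eff, tr = np.broadcast_arrays(t, l_eff, tr)
    w = np.where(
        t <= p.t_0,
        np.pi * t / p.t_0,
        np.where(t < p.t_0 + tr, np.pi * (t - p.t_0 + tr) / tr, 0.0),
    )
    ec = eca50(l_eff, p)
    with np.errstate(over="ignore"):
        ca_frac = np.where(np.isinf(ec), 0.0,
                           p.Ca_0 ** 2 / (p.Ca_0 ** 2 + ec ** 2))
    return 0.5 * p.T_max * ca_frac * (1.0 - np.cos(w))


#: Empirical constants of the normalized single-beat EDPVR (configuration,
#: overridable): P_n = An * V_n^Bn with V_n the volume normalized between
#: the zero-pressure volume V0 and the 30 mmHg volume V30.
KLOTZ_DEFAULTS = {"An": 28.2, "Bn": 2.79}


def klotz_edpvr(volume_samples, measured_pv, constants: dict | None = None):
    """Predicted single-beat EDPVR (mmHg) at ``volume_samples`` (mL).

    ``measured_pv`` is one measured (P, V) anchor pair (mmHg, mL).  The
    empirical normalized curve P = An*V_n^Bn is rescaled so it passes
    through the anchor:  V0 = Vm (0.6 - 0.006 Pm),
    V30 = V0 + (Vm - V0) / (Pm/An)^(1/Bn).  Pressure is 0 below V0.
    """
    cst = dict(KLOTZ_DEFAULTS)
    if constants:
        cst.update(constants)
    An, Bn = cst["An"], cst["Bn"]
    Pm, Vm = measured_pv
    if Pm <= 0 or Vm <= 0:
        raise MaterialError("measured (P, V) anchor must be positive")
    V = np.asarray(volume_samples, dtype=float)
    V0 = Vm * (0.6 - 0.006 * Pm)
    V30 = V0 + (Vm - V0) / (Pm / An) ** (1.0 / Bn)
    vn = (V - V0) / (V30 - V0)
    P = np.where(vn > 0.0, An * np.abs(vn) ** Bn, 0.0)
    return P
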