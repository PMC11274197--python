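"""Quasi-static LV wall mechanics.

The wall deformation is represented by a global reduced-kinematics basis:
smooth polynomial displacement modes over the parametric truncated-ellipsoid
wall (radial scaling, axial shortening/translation, apex bulge, torsion and
a septally biased axial family), with the constitutive laws evaluated at a
tensor-product Gauss grid (default 4 transmural x 8 longitudinal x 8
circumferential sample regions).  Equilibrium is the stationarity of the
total potential

    Pi(q) = int (Psi_dev + Psi_vol) dV0 + sum springs 1/2 k e^2
            - p (V(q) - V0)  +  (active-stress virtual work),

solved as a root problem in the mode coefficients q (scipy hybrid Powell
with load stepping).  The cavity couples to the circulation through a
hydrostatic fluid cavity: a single uniform pressure acting on the deformed
endocardial surface, whose volume is computed by the divergence theorem.

Internal units: mm, N, MPa, s; pressures enter in mmHg
(1 mmHg = 1.33322e-4 MPa) and volumes in mL (1 mL = 1000 mm^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constitutive import (ActiveParams, PassiveParams, active_fiber_stress,
                           kinematics_from_F, passive_stress)
from .errors import ConvergenceError, GeometryError, MaterialError
from .geometry import (GeometryParams, LVGeometry, SpringBC, enclosed_volume,
                       fiber_frame, parametric_position, parametric_tangents)

__all__ = ["WallModel", "MechanicalState", "MMHG_TO_MPA", "ML_TO_MM3"]

MMHG_TO_MPA = 1.33322e-4
ML_TO_MM3 = 1000.0

MODE_FAMILIES = ("radial", "axial", "bulge", "torsion", "septal")
ALL_MODE_FAMILIES = MODE_FAMILIES + ("spherical",)


@dataclass
class MechanicalState:
    """Converged equilibrium state of the wall."""

    q: np.ndarray                 # mode coefficients
    pressure: float               # cavity pressure (mmHg)
    cavity_volume: float          # mL
    activation_time: float        # s
    residual_norm: float
    spring_forces: dict           # cluster_id -> force vector (N)


class WallModel:
    """Reduced-kinematics continuum model of the LV wall.

    Parameters
    ----------
    geometry : LVGeometry
    passive, active : constitutive parameter sets
    springs : pericardial SpringBC list (inactive ones carry no force)
    aortic_spring : SpringBC or None
    endo_angle, epi_angle : fiber helix angles (degrees)
    n_gauss : (transmural, longitudinal, circumferential) sample counts
    mode_families : subset of the displacement-mode families to enable
    sheet_active_fraction : fraction of the active fiber stress also applied
        along the sheet direction (default 0: fiber only)
    """

    def __init__(self, geometry: LVGeometry,
                 passive: PassiveParams | None = None,
                 active: ActiveParams | None = None,
                 springs: list[SpringBC] | None = None,
                 aortic_spring: SpringBC | None = None,
                 endo_angle: float = 60.0, epi_angle: float = -60.0,
                 n_gauss: tuple = (4, 8, 8),
                 mode_families: tuple = MODE_FAMILIES,
                 sheet_active_fraction: float = 0.0,
                 newton_tol: float = 1e-8, max_iter: int = 50,
                 mode_regularization: float = 0.05):
        self.geometry = geometry
        self.passive = passive if passive is not None else PassiveParams()
        self.active = active if active is not None else ActiveParams()
        self.springs = list(springs) if springs else []
        self.aortic_spring = aortic_spring
        self.endo_angle = endo_angle
        self.epi_angle = epi_angle
        self.mode_families = tuple(mode_families)
        self.sheet_active_fraction = sheet_active_fraction
        self.newton_tol = newton_tol
        self.max_iter = max_iter
        # tiny quadratic penalty on the mode coefficients: bounds the
        # conditioning of the tangent system in the nearly unconstrained
        # tangential directions; orders of magnitude below physical forces
        self.mode_regularization = mode_regularization
        # small artificial step viscosity (N mm per unit mode-coefficient
        # change per coupled step): regularizes quasi-static snap-throughs
        # during rapid filling; bias on converged beat metrics is
        # negligible against the O(100 N mm) physical generalized forces
        self.step_viscosity = 2.0
        if any(n < m for n, m in zip(n_gauss, (3, 3, 4))):
            raise GeometryError("need >= 3 transmural, >= 3 longitudinal and "
                                ">= 4 circumferential sample regions")
        self._build_gauss(n_gauss)
        self._build_surface()
        self._build_springs()
        self._build_landmarks()
        self.n_modes = self._n_modes

    # ------------------------------------------------------------------
    # displacement modes
    # ------------------------------------------------------------------
    def _mode_list(self, xi, eta, phi):
        """Mode displacement fields evaluated at parametric points.

        Returns a list of arrays of shape broadcast(xi,...) + (3,).
        """
        p = self.geometry.params
        X = parametric_position(p, xi, eta, phi)
        x, y = X[..., 0], X[..., 1]
        xi, eta, phi = np.broadcast_arrays(np.asarray(xi, float),
                                           np.asarray(eta, float),
                                           np.asarray(phi, float))
        zero = np.zeros_like(x)
        one = np.ones_like(x)
        L = p.axial_length
        a_o = p.scale * p.a_epi

        def radial(f):
            return np.stack([f * x, f * y, zero], axis=-1)

        def axial(g):
            return np.stack([zero, zero, L * g], axis=-1)

        modes = []
        if "radial" in self.mode_families:
            for f in (one, xi, xi ** 2, xi ** 3, eta, eta ** 2, xi * eta):
                modes.append(radial(f))
        if "axial" in self.mode_families:
            for g in (one, eta, eta ** 2, eta ** 3, xi, xi * eta):
                modes.append(axial(g))
        if "bulge" in self.mode_families:
            r2 = (x ** 2 + y ** 2) / a_o ** 2
            for g in (r2, r2 * eta):
                modes.append(np.stack([zero, zero, L * g], axis=-1))
        if "spherical" in self.mode_families:
            # position-proportional (true radial) modes: exact for
            # spherically symmetric inflation fields
            for f in (one, xi, xi ** 2, xi ** 3):
                modes.append(f[..., None] * X)
        if "torsion" in self.mode_families:
            modes.append(np.stack([-eta * y, eta * x, zero], axis=-1))
        if "septal" in self.mode_families:
            c = np.cos(phi - p.septal_azimuth)
            for g in (c * eta, c * eta ** 2):
                modes.append(np.stack([zero, zero, L * g], axis=-1))
        return modes

    def mode_displacements(self, xi, eta, phi) -> np.ndarray:
        """Stacked mode displacements, shape (n_modes, ..., 3)."""
        return np.stack(self._mode_list(xi, eta, phi), axis=0)

    def displacement(self, q, xi, eta, phi) -> np.ndarray:
        """Displacement field u(X; q) at parametric points (mm)."""
        U = self.mode_displacements(xi, eta, phi)
        return np.tensordot(np.asarray(q, float), U, axes=(0, 0))

    def _mode_param_derivs(self, xi, eta, phi, h=1e-5):
        """d(modes)/d(xi, eta, phi), shape (n_modes, ..., 3, 3par)."""
        cols = []
        base = [np.asarray(xi, float), np.asarray(eta, float),
                np.asarray(phi, float)]
        for d in range(3):
            plus = [c.copy() for c in base]
            minus = [c.copy() for c in base]
            plus[d] = plus[d] + h
            minus[d] = minus[d] - h
            cols.append((self.mode_displacements(*plus)
                         - self.mode_displacements(*minus)) / (2 * h))
        return np.stack(cols, axis=-1)

    def mode_gradients(self, xi, eta, phi) -> np.ndarray:
        """Material mode gradients G_k = du_k/dX, shape (n_modes, ..., 3, 3)."""
        dU = self._mode_param_derivs(xi, eta, phi)
        T = parametric_tangents(self.geometry.params, xi, eta, phi)
        Tinv = np.linalg.inv(T)
        return np.einsum("k...id,...dj->k...ij", dU, Tinv)

    # ------------------------------------------------------------------
    # precomputation
    # ------------------------------------------------------------------
    def _build_gauss(self, n_gauss):
        nt, nl, nc = n_gauss
        gx, wx = np.polynomial.legendre.leggauss(nt)
        ge, we = np.polynomial.legendre.leggauss(nl)
        xi = 0.5 * (gx + 1.0)
        eta = 0.5 * (ge + 1.0)
        phi = 2 * np.pi * np.arange(nc) / nc
        XI, ETA, PHI = np.meshgrid(xi, eta, phi, indexing="ij")
        W = (np.einsum("i,j->ij", 0.25 * wx, we)[:, :, None]
             * np.full(nc, 2 * np.pi / nc))
        self._gp = (XI.ravel(), ETA.ravel(), PHI.ravel())
        T = parametric_tangents(self.geometry.params, *self._gp)
        detJ = np.abs(np.linalg.det(T))
        self._w = W.ravel() * detJ                       # volume weights (mm^3)
        f0, s0, n0 = fiber_frame(self.geometry.params, *self._gp,
                                 self.endo_angle, self.epi_angle)
        self._f0, self._s0, self._n0 = f0, s0, n0
        G = self.mode_gradients(*self._gp)
        self._G = G
        self._n_modes = G.shape[0]
        self._eye = np.broadcast_to(np.eye(3), (len(self._w), 3, 3))

    def _build_surface(self, n_eta=12, n_phi=24):
        g, w = np.polynomial.legendre.leggauss(n_eta)
        eta = 0.5 * (g + 1.0)
        w_eta = 0.5 * w
        phi = 2 * np.pi * np.arange(n_phi) / n_phi
        E, P = np.meshgrid(eta, phi, indexing="ij")
        Z = np.zeros_like(E)
        p = self.geometry.params
        self._surf_w = (w_eta, 2 * np.pi / n_phi)
        self._Xs = parametric_position(p, Z, E, P)
        h = 1e-5
        self._Teta0 = (parametric_position(p, Z, E + h, P)
                       - parametric_position(p, Z, E - h, P)) / (2 * h)
        self._Tphi0 = (parametric_position(p, Z, E, P + h)
                       - parametric_position(p, Z, E, P - h)) / (2 * h)
        self._Us = self.mode_displacements(Z, E, P)
        self._dUse = (self.mode_displacements(Z, E + h, P)
                      - self.mode_displacements(Z, E - h, P)) / (2 * h)
        self._dUsp = (self.mode_displacements(Z, E, P + h)
                      - self.mode_displacements(Z, E, P - h)) / (2 * h)
        ring_eta = np.ones_like(phi)
        self._Xr = parametric_position(p, np.zeros_like(phi), ring_eta, phi)
        self._Ur = self.mode_displacements(np.zeros_like(phi), ring_eta, phi)
        self._Ur_mean = self._Ur.mean(axis=1)            # (nm, 3)
        self.volume_unloaded = self.cavity_volume(np.zeros(self._Us.shape[0]))

    def _build_springs(self):
        entries = []
        for s in self.springs:
            if s.attach_param is None:
                raise GeometryError("spring lacks an attachment material point")
            Phi = self.mode_displacements(*s.attach_param)  # (nm, 3)
            d = None if s.direction is None else np.asarray(s.direction, float)
            entries.append((s, Phi, d))
        if self.aortic_spring is not None:
            s = self.aortic_spring
            Phi = self.mode_displacements(*s.attach_param)
            entries.append((s, Phi, np.asarray(s.direction, float)))
        self._spring_entries = entries
        # vectorized assembly arrays (active springs only)
        rows_dir, k_dir = [], []
        iso = []
        for s, Phi, d in entries:
            if not s.active or s.stiffness == 0.0:
                continue
            if d is None:
                iso.append((s.stiffness, Phi))
            else:
                rows_dir.append(Phi @ d)
                k_dir.append(s.stiffness)
        self._spring_C = (np.asarray(rows_dir) if rows_dir
                          else np.zeros((0, self._n_modes)))
        self._spring_k = np.asarray(k_dir)
        self._spring_iso = iso

    def _build_landmarks(self):
        self._Phi_apex = self.mode_displacements(1.0, 0.0, 0.0)
        phi = 2 * np.pi * np.arange(16) / 16
        Phi_ring = self.mode_displacements(np.zeros(16), np.ones(16), phi)
        self._Phi_annulus = Phi_ring.mean(axis=1)
        if self.aortic_spring is not None:
            self._Phi_root = self.mode_displacements(
                *self.aortic_spring.attach_param)
        else:
            p = self.geometry.params
            self._Phi_root = self.mode_displacements(0.5, 1.0, p.septal_azimuth)

    # ------------------------------------------------------------------
    # kinematics / volume
    # ------------------------------------------------------------------
    def deformation_gradients(self, q, xi=None, eta=None, phi=None):
        """F at the Gauss grid (default) or at supplied parametric points."""
        q = np.asarray(q, float)
        if xi is None:
            G = self._G
            eye = self._eye
        else:
            G = self.mode_gradients(xi, eta, phi)
            eye = np.broadcast_to(np.eye(3), G.shape[1:])
        return eye + np.tensordot(q, G, axes=(0, 0))

    def cavity_volume(self, q) -> float:
        """Deformed hydrostatic-cavity volume (mL)."""
        q = np.asarray(q, float)
        x = self._Xs + np.tensordot(q, self._Us, axes=(0, 0))
        te = self._Teta0 + np.tensordot(q, self._dUse, axes=(0, 0))
        tp = self._Tphi0 + np.tensordot(q, self._dUsp, axes=(0, 0))
        ring = self._Xr + np.tensordot(q, self._Ur, axes=(0, 0))
        w_eta, d_phi = self._surf_w
        return enclosed_volume(x, te, tp, ring, w_eta, d_phi) / ML_TO_MM3

    def cavity_volume_gradient(self, q) -> np.ndarray:
        """dV/dq (mm^3 per unit mode coefficient), analytic."""
        q = np.asarray(q, float)
        x = self._Xs + np.tensordot(q, self._Us, axes=(0, 0))
        te = self._Teta0 + np.tensordot(q, self._dUse, axes=(0, 0))
        tp = self._Tphi0 + np.tensordot(q, self._dUsp, axes=(0, 0))
        ring = self._Xr + np.tensordot(q, self._Ur, axes=(0, 0))
        x_ref = ring.mean(axis=0)
        n = np.cross(te, tp)
        w_eta, d_phi = self._surf_w
        W = w_eta[:, None] * d_phi
        xc = x - x_ref
        dU = self._Us - self._Ur_mean[:, None, None, :]
        t1 = np.einsum("kabi,abi,ab->k", dU, n, W)
        t2 = np.einsum("abi,kabi,ab->k", xc, np.cross(self._dUse, tp), W)
        t3 = np.einsum("abi,kabi,ab->k", xc, np.cross(te, self._dUsp), W)
        grad = (t1 + t2 + t3) / 3.0
        # orientation: make gradient consistent with the positive volume
        V = np.einsum("abi,abi,ab->", xc, n, W) / 3.0
        return grad if V >= 0 else -grad

    def material_volume(self, q) -> float:
        """Total deformed wall material volume (mL) = int J dV0."""
        F = self.deformation_gradients(q)
        J = np.linalg.det(F)
        return float((J * self._w).sum() / ML_TO_MM3)

    # ------------------------------------------------------------------
    # residual
    # ------------------------------------------------------------------
    def _second_pk(self, q, t_act, t_scale=1.0):
        F = self.deformation_gradients(q)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            bad = int(np.argmin(J))
            raise MaterialError(f"element inversion at Gauss point {bad} "
                                f"(det F = {J[bad]:.3g})")
        state = kinematics_from_F(F, self._f0, self._s0)
        S = passive_stress(state, self.passive)
        if t_scale > 0 and self.active.T_max > 0:
            # the solvers stagger the activation: a frozen active-stress
            # field (from the previous outer iteration) makes the inner
            # equilibrium solve a smooth constant-load problem; the outer
            # Aitken-relaxed fixed point restores self-consistency of the
            # length-dependent activation
            sig_frozen = getattr(self, "_sig_frozen", None)
            if sig_frozen is not None:
                sig_a = t_scale * sig_frozen
            else:
                E_ff = np.maximum(state.E_ff, -0.495)
                sig_a = t_scale * active_fiber_stress(
                    t_act, E_ff, self.active, tr_floor=0.02,
                    E_phase=getattr(self, "_E_timing", None))
            ff = np.einsum("pi,pj->pij", self._f0, self._f0)
            S = S + sig_a[:, None, None] * ff
            if self.sheet_active_fraction:
                ss = np.einsum("pi,pj->pij", self._s0, self._s0)
                S = S + (self.sheet_active_fraction
                         * sig_a[:, None, None]) * ss
        return F, S

    def _fiber_strain(self, q):
        """Per-Gauss-point fiber Lagrangian strain E_ff at state ``q``."""
        F = self.deformation_gradients(q)
        C = np.einsum("pki,pkj->pij", F, F)
        I4f = np.einsum("pi,pij,pj->p", self._f0, C, self._f0)
        return np.maximum(0.5 * (I4f - 1.0), -0.495)

    def active_stress_at(self, q, t_act):
        """Instantaneous active fiber-stress field sigma_a (MPa) at ``q``
        (twitch timing uses the frozen strain when one is set)."""
        return active_fiber_stress(t_act, self._fiber_strain(q),
                                   self.active, tr_floor=0.02,
                                   E_phase=getattr(self, "_E_timing", None))

    def _spring_residual(self, q):
        # directional springs: R = C^T (k * (C q))
        R = self._spring_C.T @ (self._spring_k * (self._spring_C @ q))
        for k, Phi in self._spring_iso:
            u = Phi.T @ q                       # attachment displacement (mm)
            R += k * (Phi @ u)
        return R

    def _residual_batch(self, Qb, pressure_mmhg, t_act, t_scale=1.0):
        """Equilibrium residual for a batch of mode-coefficient vectors
        (B, n_modes) at one pressure/activation; returns (B, n_modes).
        Raises MaterialError if any batch state is inverted."""
        Qb = np.asarray(Qb, float)
        F = np.tensordot(Qb, self._G, axes=(1, 0)) + np.eye(3)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise MaterialError("element inversion in batch evaluation")
        state = kinematics_from_F(F, self._f0, self._s0)
        S = passive_stress(state, self.passive)
        if t_scale > 0 and self.active.T_max > 0:
            sig_frozen = getattr(self, "_sig_frozen", None)
            if sig_frozen is not None:
                sig_a = t_scale * np.broadcast_to(sig_frozen, state.J.shape)
            else:
                E_ff = np.maximum(state.E_ff, -0.495)
                sig_a = t_scale * active_fiber_stress(
                    t_act, E_ff, self.active, tr_floor=0.02,
                    E_phase=getattr(self, "_E_timing", None))
            ff = np.einsum("pi,pj->pij", self._f0, self._f0)
            S = S + sig_a[..., None, None] * ff
            if self.sheet_active_fraction:
                ss = np.einsum("pi,pj->pij", self._s0, self._s0)
                S = S + (self.sheet_active_fraction
                         * sig_a[..., None, None]) * ss
        M = np.einsum("kpji,bpjl->bkpil", self._G, F)
        dE = 0.5 * (M + np.swapaxes(M, -1, -2))
        R = np.einsum("bpil,bkpil,p->bk", S, dE, self._w)
        R += (self._spring_C.T @ (self._spring_k[:, None]
                                  * (self._spring_C @ Qb.T))).T
        for k, Phi in self._spring_iso:
            R += k * (Qb @ Phi) @ Phi.T
        R += self.mode_regularization * Qb
        p_mpa = pressure_mmhg * MMHG_TO_MPA
        if p_mpa != 0.0:
            R -= p_mpa * self._cavity_volume_gradient_batch(Qb)
        return R

    def _cavity_volume_batch(self, Qb):
        """Cavity volumes (mL) for a batch of coefficient vectors."""
        Qb = np.asarray(Qb, float)
        x = np.tensordot(Qb, self._Us, axes=(1, 0)) + self._Xs
        te = np.tensordot(Qb, self._dUse, axes=(1, 0)) + self._Teta0
        tp = np.tensordot(Qb, self._dUsp, axes=(1, 0)) + self._Tphi0
        ring = np.tensordot(Qb, self._Ur, axes=(1, 0)) + self._Xr
        x_ref = ring.mean(axis=1)
        n = np.cross(te, tp)
        w_eta, d_phi = self._surf_w
        W = w_eta[:, None] * d_phi
        V = np.einsum("xaci,xaci,ac->x",
                      x - x_ref[:, None, None, :], n, W) / 3.0
        return np.abs(V) / ML_TO_MM3

    def _cavity_volume_gradient_batch(self, Qb):
        """dV/dq (mm^3) for a batch, shape (B, n_modes)."""
        Qb = np.asarray(Qb, float)
        x = np.tensordot(Qb, self._Us, axes=(1, 0)) + self._Xs
        te = np.tensordot(Qb, self._dUse, axes=(1, 0)) + self._Teta0
        tp = np.tensordot(Qb, self._dUsp, axes=(1, 0)) + self._Tphi0
        ring = np.tensordot(Qb, self._Ur, axes=(1, 0)) + self._Xr
        x_ref = ring.mean(axis=1)
        n = np.cross(te, tp)
        w_eta, d_phi = self._surf_w
        W = w_eta[:, None] * d_phi
        xc = x - x_ref[:, None, None, :]
        dU = self._Us - self._Ur_mean[:, None, None, :]
        t1 = np.einsum("kaci,baci,ac->bk", dU, n, W)
        cr2 = np.cross(self._dUse[None], tp[:, None])    # (B, k, a, c, 3)
        t2 = np.einsum("baci,bkaci,ac->bk", xc, cr2, W)
        cr3 = np.cross(te[:, None], self._dUsp[None])
        t3 = np.einsum("baci,bkaci,ac->bk", xc, cr3, W)
        grad = (t1 + t2 + t3) / 3.0
        v_signed = np.einsum("baci,baci,ac->b", xc, n, W)
        return grad * np.sign(v_signed)[:, None]

    def residual(self, q, pressure_mmhg, t_act, t_scale=1.0) -> np.ndarray:
        """Equilibrium residual dPi/dq (N mm per unit mode coefficient)."""
        q = np.asarray(q, float)
        with np.errstate(over="ignore", invalid="ignore"):
            return self._residual_impl(q, pressure_mmhg, t_act, t_scale)

    def _residual_impl(self, q, pressure_mmhg, t_act, t_scale):
        F, S = self._second_pk(q, t_act, t_scale)
        # dE/dq_k = sym(G_k^T F)
        M = np.einsum("kpji,pjl->kpil", self._G, F)
        dE = 0.5 * (M + np.swapaxes(M, -1, -2))
        R = np.einsum("pil,kpil,p->k", S, dE, self._w)
        R += self._spring_residual(q)
        R += self.mode_regularization * q
        p_mpa = pressure_mmhg * MMHG_TO_MPA
        if p_mpa != 0.0:
            R -= p_mpa * self.cavity_volume_gradient(q)
        return R

    def _force_scale(self, q, pressure_mmhg, t_act, t_scale=1.0) -> float:
        q = np.asarray(q, float)
        F, S = self._second_pk(q, t_act, t_scale)
        M = np.einsum("kpji,pjl->kpil", self._G, F)
        dE = 0.5 * (M + np.swapaxes(M, -1, -2))
        internal = np.einsum("pil,kpil,p->k", np.abs(S), np.abs(dE), self._w)
        pres = abs(pressure_mmhg) * MMHG_TO_MPA * np.abs(
            self.cavity_volume_gradient(q))
        return float(np.linalg.norm(internal) + np.linalg.norm(pres)) + 1.0

    # ------------------------------------------------------------------
    # solvers
    # ------------------------------------------------------------------
    def solve_equilibrium(self, pressure_mmhg: float, t_act: float = 0.0,
                          q0=None, t_scale: float = 1.0) -> MechanicalState:
        """Solve mechanical equilibrium at a prescribed cavity pressure.

        Uses the hybrid Powell root finder with automatic load-step halving
        from the last converged state on divergence.
        """
        def attempt(p_try, s_try, start):
            sol = optimize.root(
                lambda z: self.residual(z, p_try, t_act, s_try),
                start, method="hybr",
                options={"maxfev": 150 * (self.n_modes + 1)})
            ok = sol.success or np.linalg.norm(sol.fun) < 1e-6 * \
                self._force_scale(sol.x, p_try, t_act, s_try)
            return ok, sol

        self._sig_frozen = None
        self._E_timing = None
        if q0 is not None:
            ok, sol = attempt(pressure_mmhg, t_scale, np.asarray(q0, float))
            if ok:
                q = sol.x
            else:
                q = None
        else:
            q = None
        if q is None:
            # ramped continuation from the unloaded configuration with
            # automatic step halving on divergence
            q_good, lam_good = np.zeros(self.n_modes), 0.0
            dlam = 1.0
            last = None
            while lam_good < 1.0:
                lam = min(1.0, lam_good + dlam)
                ok, sol = attempt(pressure_mmhg * lam, t_scale * lam, q_good)
                last = sol
                if ok:
                    q_good, lam_good = sol.x, lam
                    dlam = min(1.0, 2 * dlam)
                else:
                    dlam *= 0.5
                    if dlam < 1e-4:
                        raise ConvergenceError(
                            "load stepping stalled",
                            residual=float(np.linalg.norm(last.fun)))
            q = q_good
        if t_scale > 0 and self.active.T_max > 0:
            # Aitken-relaxed fixed point on the active-stress field
            sig = self.active_stress_at(q, t_act)
            r_prev, beta = None, 0.5
            for _ in range(30):
                self._sig_frozen = sig
                ok, sol = attempt(pressure_mmhg, t_scale, q)
                if not ok:
                    break
                q = sol.x
                r = self.active_stress_at(q, t_act) - sig
                if np.max(np.abs(r)) < 2e-4:
                    break
                if r_prev is not None:
                    dr = r - r_prev
                    denom = float(dr @ dr)
                    if denom > 0:
                        beta = float(np.clip(-beta * (r_prev @ dr) / denom,
                                             0.05, 1.0))
                sig = sig + beta * r
                r_prev = r
        # residual of the (possibly staggered) system actually solved
        rnorm = float(np.linalg.norm(
            self.residual(q, pressure_mmhg, t_act, t_scale)))
        bad = rnorm > 1e-6 * self._force_scale(q, pressure_mmhg, t_act,
                                               t_scale)
        self._sig_frozen = None
        if bad:
            raise ConvergenceError("equilibrium residual too large",
                                   residual=rnorm)
        return self._make_state(q, pressure_mmhg, t_act, rnorm)

    def _fd_jacobian(self, fun, z, f0=None, h: float = 1e-6):
        f0 = fun(z) if f0 is None else f0
        n = len(z)
        J = np.empty((len(f0), n))
        for j in range(n):
            col = None
            for hj in (h * max(1.0, abs(z[j])), 1e-8 * max(1.0, abs(z[j]))):
                zp = z.copy()
                zp[j] += hj
                try:
                    col = (fun(zp) - f0) / hj
                except MaterialError:
                    continue
                if np.all(np.isfinite(col)):
                    break
                col = None
            if col is None:
                col = np.zeros(len(f0))
                col[min(j, len(f0) - 1)] = 1.0
            J[:, j] = col
        return J

    def _newton_cached(self, fun, z0, nm, target_volume_ml, t_act, vol_tol,
                       v_scale=None, always_refresh=False, jac=None):
        """Quasi-Newton on the augmented (q, p) system reusing the
        LU-factorized Jacobian across coupled time steps; the Jacobian is
        refreshed only when the iteration slows down.  ``jac(z, f0)`` is an
        optional fast (batched) Jacobian builder; None falls back to
        column-by-column finite differences."""
        from scipy.linalg import lu_factor, lu_solve

        def build_lu(z, f0):
            with np.errstate(over="ignore", invalid="ignore"), \
                    warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if jac is not None:
                    J = jac(z, f0)
                    if J is None or not np.all(np.isfinite(J)):
                        J = self._fd_jacobian(fun, z, f0)
                else:
                    J = self._fd_jacobian(fun, z, f0)
                return lu_factor(J)

        z = np.asarray(z0, float).copy()
        try:
            f = fun(z)
            fscale = self._force_scale(z[:nm], z[nm] * 100.0, t_act)
        except MaterialError:
            return z0[:nm], z0[nm] * 100.0, False

        def converged(f):
            dv_ml = abs(f[nm]) * v_scale * 10.0 / ML_TO_MM3
            return (dv_ml <= vol_tol
                    and np.linalg.norm(f[:nm]) <= 1e-6 * fscale)

        stale = True
        if getattr(self, "_J_lu", None) is None or always_refresh:
            try:
                self._J_lu = build_lu(z, f)
            except (MaterialError, ValueError):
                return z0[:nm], z0[nm] * 100.0, False
            stale = False
        n_refresh = 0
        max_refresh = 25 if always_refresh else 3
        for _ in range(25 if always_refresh else 20):
            if converged(f):
                return z[:nm], z[nm] * 100.0, True
            if always_refresh and stale:
                try:
                    self._J_lu = build_lu(z, f)
                    stale = False
                except (MaterialError, ValueError):
                    return z[:nm], z[nm] * 100.0, False
            try:
                dz = -lu_solve(self._J_lu, f)
            except Exception:
                return z[:nm], z[nm] * 100.0, False
            if not np.all(np.isfinite(dz)):
                return z[:nm], z[nm] * 100.0, False
            # evaluate the step, halving only on non-physical trial states
            step, f_new = 1.0, None
            for _ in range(4):
                try:
                    f_try = fun(z + step * dz)
                except MaterialError:
                    step *= 0.5
                    continue
                if np.all(np.isfinite(f_try)):
                    f_new = f_try
                    break
                step *= 0.5
            if f_new is None:
                if stale and n_refresh < max_refresh:
                    self._J_lu = build_lu(z, f)
                    stale, n_refresh = False, n_refresh + 1
                    continue
                return z[:nm], z[nm] * 100.0, False
            if (np.linalg.norm(f_new) > 0.9 * np.linalg.norm(f)
                    and stale and n_refresh < max_refresh):
                # poor progress with a stale Jacobian: refresh and retry
                # from the current point (Newton steps need not reduce the
                # residual monotonically, so growth with a fresh Jacobian
                # is accepted)
                self._J_lu = build_lu(z, f)
                stale, n_refresh = False, n_refresh + 1
                continue
            z = z + step * dz
            f = f_new
            stale = True
        return z[:nm], z[nm] * 100.0, converged(f)

    def pressure_for_volume(self, target_volume_ml: float, t_act: float = 0.0,
                            q0=None, p0: float = 1.0,
                            vol_tol: float = 0.05) -> MechanicalState:
        """Find the cavity pressure at which the equilibrium volume equals
        ``target_volume_ml`` (within ``vol_tol`` mL); returns the state.

        Solves the augmented system [residual(q, p); V(q) - V*] for (q, p).
        """
        nm = self.n_modes
        q = np.zeros(nm) if q0 is None else np.asarray(q0, float)
        v_scale = max(1.0, 0.02 * target_volume_ml) * ML_TO_MM3
        self.solve_stats = getattr(
            self, "solve_stats", {"newton": 0, "hybr": 0, "continuation": 0})

        q_ref = q.copy()
        eta_holder = {"v": self.step_viscosity if q0 is not None else 0.0}

        def make_fun(tgt):
            def fun(z):
                qz, p = z[:nm], z[nm] * 100.0
                try:
                    R = (self.residual(qz, p, t_act)
                         + eta_holder["v"] * (qz - q_ref))
                except MaterialError:
                    # inverted trial state: huge finite residual so the
                    # root finders retreat instead of crashing
                    return 1e10 * np.ones(nm + 1)
                dv = (self.cavity_volume(qz) - tgt) * ML_TO_MM3
                return np.concatenate([R, [dv / v_scale * 1e-1]])
            return fun

        def make_jac(tgt):
            def jac(z, f0):
                """Batched FD columns for q plus analytic pressure column."""
                try:
                    qz, p = z[:nm], z[nm] * 100.0
                    hs = 1e-6 * np.maximum(1.0, np.abs(qz))
                    Qb = qz[None, :] + np.diag(hs)
                    Rb = (self._residual_batch(Qb, p, t_act)
                          + eta_holder["v"] * (Qb - q_ref))
                    Vb = self._cavity_volume_batch(Qb)
                    Fb = np.concatenate(
                        [Rb, ((Vb - tgt) * ML_TO_MM3 / v_scale
                              * 1e-1)[:, None]], axis=1)
                    J = np.empty((nm + 1, nm + 1))
                    J[:, :nm] = ((Fb - f0[None, :]) / hs[:, None]).T
                    J[:nm, nm] = (-100.0 * MMHG_TO_MPA
                                  * self.cavity_volume_gradient(qz))
                    J[nm, nm] = 0.0
                    return J
                except (MaterialError, ValueError):
                    return None
            return jac

        def solve_newton(qa, pa, tgt):
            """Light augmented solve: cached then refreshed quasi-Newton."""
            z0 = np.concatenate([qa, [pa / 100.0]])
            fun = make_fun(tgt)
            jacb = make_jac(tgt)
            qs, ps, ok = self._newton_cached(fun, z0, nm, tgt, t_act,
                                             vol_tol, v_scale=v_scale,
                                             jac=jacb)
            if ok:
                self.solve_stats["newton"] += 1
                return qs, ps, True
            qs, ps, ok = self._newton_cached(fun, z0, nm, tgt, t_act,
                                             vol_tol, v_scale=v_scale,
                                             always_refresh=True, jac=jacb)
            if ok:
                self.solve_stats["newton_refresh"] = \
                    self.solve_stats.get("newton_refresh", 0) + 1
            return qs, ps, ok

        def solve_once(qa, pa, tgt):
            """Full augmented solve chain at the current frozen activation."""
            qs, ps, ok = solve_newton(qa, pa, tgt)
            if ok:
                return qs, ps, True
            z0 = np.concatenate([qa, [pa / 100.0]])
            fun = make_fun(tgt)
            self.solve_stats["hybr"] += 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = optimize.root(fun, z0, method="hybr",
                                    options={"maxfev": 60 * (nm + 2)})
            self._J_lu = None

            def check(x):
                try:
                    fend = fun(x)
                    verr = abs(self.cavity_volume(x[:nm]) - tgt)
                    return (verr <= vol_tol and np.all(np.isfinite(fend))
                            and np.linalg.norm(fend[:nm])
                            <= 1e-6 * self._force_scale(
                                x[:nm], x[nm] * 100.0, t_act))
                except MaterialError:
                    return False

            if check(sol.x):
                return sol.x[:nm], sol.x[nm] * 100.0, True
            # trust-region fallback: steps are radius-bounded, so the
            # strongly nonlinear states cannot make it blow up
            self.solve_stats["trf"] = self.solve_stats.get("trf", 0) + 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = optimize.least_squares(
                    fun, z0, method="trf", max_nfev=40 * (nm + 2),
                    x_scale=np.r_[np.full(nm, 0.05), 0.2])
            ok = check(sol.x)
            return sol.x[:nm], sol.x[nm] * 100.0, bool(ok)

        def make_ramp(solver):
            def solve_with_ramp(qa, pa, tgt):
                """``solver``, falling back to ramping the target volume
                from the warm state's volume on failure."""
                qs, ps, ok = solver(qa, pa, tgt)
                if ok:
                    return qs, ps, True
                self.solve_stats["continuation"] += 1
                v_from = self.cavity_volume(qa)
                qs, ps = qa.copy(), pa
                lam_good, dlam = 0.0, 0.5
                while lam_good < 1.0:
                    lam = min(1.0, lam_good + dlam)
                    vt = v_from + lam * (tgt - v_from)
                    qn, pn, ok = solver(qs, ps, vt)
                    if ok:
                        qs, ps, lam_good = qn, pn, lam
                        dlam = min(0.5, 2 * dlam)
                    else:
                        dlam *= 0.5
                        if dlam < 1e-3:
                            return qs, ps, False
                return qs, ps, True
            return solve_with_ramp

        solve_with_ramp = make_ramp(solve_once)
        solve_with_ramp_light = make_ramp(solve_newton)

        if q0 is None:
            # cold start: passive inflate, then volume-ramp to the target
            self._sig_frozen = None
            self._E_timing = None
            st = self.solve_equilibrium(p0, t_act=t_act, t_scale=0.0)
            q, p_run = st.q, st.pressure
        else:
            p_run = p0

        qs, ps = np.asarray(q, float), p_run
        self._sig_frozen = None
        self._E_timing = None
        try:
            if self.active.T_max == 0:
                qs, ps, ok = solve_with_ramp(qs, ps, target_volume_ml)
                if not ok:
                    raise ConvergenceError(
                        "volume targeting failed (passive)")
            else:
                # primary: monolithic solve with instantaneous
                # length-dependent activation; on failure, staggered
                # activation, escalating the step viscosity as a last
                # resort (a heavily damped step lags slightly and is
                # corrected over the following steps)
                eta0 = eta_holder["v"]
                q_in, p_in = qs.copy(), ps
                # start at the damping level the previous step needed
                # (hysteresis avoids re-climbing the failure ladder during
                # a difficult phase); relax it one level after a success
                hint = getattr(self, "_eta_hint", 1.0)
                ladder = [m for m in (1.0, 10.0, 100.0, 1000.0) if m >= hint]
                for mult in ladder:
                    eta_holder["v"] = eta0 * mult
                    qs, ps = q_in.copy(), p_in
                    # cheap first: quasi-Newton, then Newton with a ramped
                    # volume target
                    qn, pn, ok = solve_with_ramp_light(qs, ps,
                                                       target_volume_ml)
                    if ok:
                        qs, ps = qn, pn
                        break
                    try:
                        qs, ps = self._aitken_staggered(
                            solve_with_ramp_light, qs, ps, target_volume_ml,
                            t_act)
                        break
                    except ConvergenceError:
                        pass
                    # expensive globalized root finders as the last direct
                    # attempt at this damping level
                    qn, pn, ok = solve_once(qs, ps, target_volume_ml)
                    if ok:
                        qs, ps = qn, pn
                        break
                    if eta0 == 0.0:
                        raise ConvergenceError(
                            "volume targeting failed (undamped)")
                else:
                    raise ConvergenceError(
                        "volume targeting failed at all damping levels")
                # sticky hysteresis: hold an escalated damping level for a
                # few steps before relaxing it
                hint_prev = getattr(self, "_eta_hint", 1.0)
                if mult > hint_prev:
                    self._eta_hint = mult
                    self._eta_cool = 5
                else:
                    self._eta_cool = getattr(self, "_eta_cool", 0) - 1
                    if self._eta_cool <= 0:
                        self._eta_hint = max(1.0, hint_prev / 10.0)
                        self._eta_cool = 3
                eta_holder["v"] = eta0
            verr = abs(self.cavity_volume(qs) - target_volume_ml)
            if verr > vol_tol:
                raise ConvergenceError(
                    f"volume targeting failed (|dV| = {verr:.3g} mL)")
            rnorm = float(np.linalg.norm(self.residual(qs, ps, t_act)))
            return self._make_state(qs, ps, t_act, rnorm)
        finally:
            self._sig_frozen = None
            self._E_timing = None

    def _aitken_staggered(self, solver, qs, ps, target_volume_ml, t_act,
                          tol_sig: float = 5e-4):
        """Relaxed fixed point on the active-stress field.

        Each inner solve sees a frozen activation field (a smooth
        constant-load problem); the frozen field is updated toward the
        instantaneous length-dependent stress with an Aitken-adapted
        relaxation factor, halved whenever an inner solve diverges.
        """
        sig_inst = self.active_stress_at(qs, t_act)
        sig_last = getattr(self, "_sig_last", None)
        q_good, p_good = qs.copy(), ps
        r_prev, beta = None, 0.5
        if sig_last is not None and sig_last.shape == sig_inst.shape:
            # anchor at the previous converged step's self-consistent
            # field (the warm state equilibrates it) and step toward the
            # new instantaneous stress
            sig_good, r_good = sig_last, sig_inst - sig_last
            sig = sig_good + beta * r_good
        else:
            sig_good, r_good = sig_inst, None
            sig = sig_inst
        for _ in range(60):
            self._sig_frozen = sig
            qn, pn, ok = solver(qs, ps, target_volume_ml)
            self._sig_frozen = None
            if not ok:
                beta *= 0.5
                if beta < 0.01 or r_good is None:
                    raise ConvergenceError(
                        "activation staggering stalled (inner solve)")
                sig = sig_good + beta * r_good
                qs, ps = q_good.copy(), p_good
                r_prev = None
                continue
            qs, ps = qn, pn
            r = self.active_stress_at(qs, t_act) - sig
            rmax = float(np.max(np.abs(r)))
            if rmax < tol_sig:
                return qs, ps
            if r_prev is not None:
                dr = r - r_prev
                denom = float(dr @ dr)
                if denom > 0:
                    beta = float(np.clip(-beta * (r_prev @ dr) / denom,
                                         0.02, 1.0))
            sig_good, r_good = sig, r
            q_good, p_good = qs.copy(), ps
            sig = sig + beta * r
            r_prev = r
        else:
            rmax = float(np.max(np.abs(r))) if r_prev is not None else np.inf
            if rmax < 4 * tol_sig:
                # jitter of a physically negligible residual stress
                return qs, ps
            raise ConvergenceError(
                f"activation fixed point did not converge (d sigma = "
                f"{rmax:.3g})")

    def _make_state(self, q, p, t_act, rnorm) -> MechanicalState:
        # remember the self-consistent active-stress field: it anchors the
        # staggered fallback of the next coupled step
        self._sig_last = (self.active_stress_at(q, t_act)
                          if self.active.T_max > 0 else None)
        return MechanicalState(
            q=np.asarray(q, float), pressure=float(p),
            cavity_volume=self.cavity_volume(q), activation_time=float(t_act),
            residual_norm=rnorm, spring_forces=self.axial_reaction(q))

    # ------------------------------------------------------------------
    # reactions / landmark kinematics
    # ------------------------------------------------------------------
    def axial_reaction(self, q_or_state) -> dict:
        """Spring force vectors (N), keyed by cluster id (-1 = aortic)."""
        q = (q_or_state.q if isinstance(q_or_state, MechanicalState)
             else np.asarray(q_or_state, float))
        forces = {}
        for s, Phi, direction in self._spring_entries:
            u = Phi.T @ q
            if direction is None:
                f = -s.stiffness * u if s.active else np.zeros(3)
            else:
                f = (-s.stiffness * (u @ direction) * direction
                     if s.active else np.zeros(3))
            forces[s.cluster_id] = f
        return forces

    def landmark_axial_displacements(self, q):
        """(apex, root, annulus-center) displacement along the apex-base
        axis (mm, positive toward the base)."""
        axis = self.geometry.axis
        q = np.asarray(q, float)
        return (float((self._Phi_apex.T @ q) @ axis),
                float((self._Phi_root.T @ q) @ axis),
                float((self._Phi_annulus.T @ q) @ axis))

    def nodal_displacements(self, q) -> np.ndarray:
        """Displacement (mm) of every mesh node."""
        p = self.geometry.node_params
        U = self.mode_displacements(p[:, 0], p[:, 1], p[:, 2])
        return np.tensordot(np.asarray(q, float), U, axes=(0, 0))

    def fiber_stress_field(self, q, t_act):
        """Per-Gauss-point Cauchy myofiber stress (MPa) and deformed
        volume weights (mm^3)."""
        q = np.asarray(q, float)
        self._sig_frozen = None
        self._E_timing = None
        F, S = self._second_pk(q, t_act)
        J = np.linalg.det(F)
        sig = np.einsum("pij,pjk,plk->pil", F, S, F) / J[:, None, None]
        fdef = np.einsum("pij,pj->pi", F, self._f0)
        fdef = fdef / np.linalg.norm(fdef, axis=1, keepdims=True)
        sig_f = np.einsum("pi,pij,pj->p", fdef, sig, fdef)
        return sig_f, self._w * J
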