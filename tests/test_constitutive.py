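"""Constitutive laws: energy, stress, active twitch, Klotz EDPVR.

Frozen reference numbers were computed beforehand with 40-digit
arbitrary-precision evaluations of the closed-form expressions.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apexfree.constitutive import (ActiveParams, KinematicsState,
                                   PassiveParams, active_fiber_stress, eca50,
                                   eff_sarcomere_length, kinematics_from_F,
                                   klotz_edpvr, passive_stress, psi_dev,
                                   psi_vol)
from apexfree.errors import MaterialError

VENT = PassiveParams()
ACT = ActiveParams()

# frozen high-precision references
PSI_IDENTITY = VENT.a / (2 * VENT.b)
PSI_UNIAXIAL_1p1 = 1.1645175468175720e-4      # isochoric fiber stretch 1.1
ECA50_LR = 2.6948328711249854                 # ECa50 at l_eff = l_r (mM)
SIGMA_PEAK_E0 = 0.14453138493099562           # sigma_a(t0, E_ff=0) (MPa)


def _state_uniaxial(lam):
    F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    f0 = np.array([1.0, 0.0, 0.0])
    s0 = np.array([0.0, 1.0, 0.0])
    return kinematics_from_F(F[None], f0[None], s0[None])


class TestPassiveEnergy:
    def test_identity_energy_is_isotropic_offset(self):
        st_ = KinematicsState.identity()
        assert psi_dev(st_, VENT)[0] == pytest.approx(PSI_IDENTITY, abs=0.0)
        assert psi_vol(st_, VENT)[0] == 0.0

    def test_uniaxial_fiber_stretch_matches_closed_form(self):
        psi = psi_dev(_state_uniaxial(1.1), VENT)[0]
        assert psi == pytest.approx(PSI_UNIAXIAL_1p1, rel=1e-12)

    def test_shear_term_vanishes_without_shear_or_modulus(self):
        st_ = KinematicsState.identity()
        st_.I8fs = np.array([0.0])
        base = psi_dev(st_, VENT)
        st_.I8fs = np.array([0.3])
        p0 = PassiveParams(a_fs=0.0)
        # with a_fs = 0 the shear invariant contributes exactly nothing
        assert psi_dev(st_, p0)[0] == psi_dev(
            KinematicsState.identity(), p0)[0]
        assert psi_dev(st_, VENT)[0] > base[0]

    def test_tension_only_gate(self):
        # compressed fiber (I4f < 1) must not stiffen the energy
        st_ = KinematicsState.identity()
        st_.I4f = np.array([0.8])
        assert psi_dev(st_, VENT)[0] == pytest.approx(PSI_IDENTITY)


class TestPassiveStress:
    def test_zero_at_identity(self):
        st_ = kinematics_from_F(np.eye(3)[None],
                                np.array([[1.0, 0, 0]]),
                                np.array([[0, 1.0, 0]]))
        S = passive_stress(st_, VENT)
        assert np.abs(S).max() == 0.0

    def test_matches_finite_difference_gradient(self, rng):
        """Analytic 1st Piola stress vs central FD of the energy, 100
        random admissible deformation states, 1e-6 relative."""
        n_ok = 0
        h = 1e-6
        while n_ok < 100:
            F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
            if np.linalg.det(F) < 0.3:
                continue
            f0 = rng.standard_normal(3)
            f0 /= np.linalg.norm(f0)
            s0 = rng.standard_normal(3)
            s0 -= (s0 @ f0) * f0
            s0 /= np.linalg.norm(s0)

            def energy(Fm):
                k = kinematics_from_F(Fm[None], f0[None], s0[None])
                return float(psi_dev(k, VENT)[0] + psi_vol(k, VENT)[0])

            S = passive_stress(kinematics_from_F(F[None], f0[None],
                                                 s0[None]), VENT)[0]
            P = F @ S
            Pfd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm_ = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm_[i, j] -= h
                    Pfd[i, j] = (energy(Fp) - energy(Fm_)) / (2 * h)
            scale = max(np.abs(Pfd).max(), 1e-12)
            assert np.abs(P - Pfd).max() / scale < 1e-6
            n_ok += 1

    def test_inverted_state_rejected(self):
        F = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(MaterialError):
            kinematics_from_F(F[None], np.array([[1.0, 0, 0]]),
                              np.array([[0, 1.0, 0]]))


class TestSarcomereKinematics:
    @pytest.mark.parametrize("E, expected", [
        (0.0, ACT.l_r),
        (1.5, 2 * ACT.l_r),
        (-0.18, 0.00148),          # l_r * sqrt(0.64) with l_r = 0.00185
    ])
    def test_effective_length(self, E, expected):
        assert eff_sarcomere_length(E, ACT) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_non_physical_compression_rejected(self):
        with pytest.raises(MaterialError):
            eff_sarcomere_length(-0.6, ACT)

    def test_eca50_reference_and_monotonicity(self):
        assert eca50(ACT.l_r, ACT) == pytest.approx(ECA50_LR, rel=1e-12)
        assert eca50(ACT.l_r, ACT) > eca50(1.05 * ACT.l_r, ACT)
        stiffer = ActiveParams(B=2 * ACT.B)
        assert eca50(ACT.l_r, stiffer) < eca50(ACT.l_r, ACT)

    def test_eca50_diverges_below_l0(self):
        assert np.isinf(eca50(ACT.l_0, ACT))
        assert np.isinf(eca50(0.9 * ACT.l_0, ACT))
        # hence no active force develops there
        assert active_fiber_stress(ACT.t_0,
                                   0.5 * ((ACT.l_0 / ACT.l_r) ** 2 - 1)
                                   - 1e-4, ACT, tr_floor=0.02) == 0.0


class TestActiveStress:
    def test_zero_at_onset_and_after_relaxation(self):
        assert active_fiber_stress(0.0, 0.0, ACT) == 0.0
        tr = ACT.m * ACT.l_r + ACT.b_relax
        assert active_fiber_stress(ACT.t_0 + tr + 1e-9, 0.0, ACT) == 0.0
        assert active_fiber_stress(ACT.t_0 + tr + 0.5, 0.0, ACT) == 0.0

    def test_peak_value_matches_closed_form(self):
        assert active_fiber_stress(ACT.t_0, 0.0, ACT) == pytest.approx(
            SIGMA_PEAK_E0, rel=1e-12)

    @given(st.floats(0.0, 0.9))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_linear_in_contractility(self, t):
        doubled = ActiveParams(T_max=2 * ACT.T_max)
        s1 = active_fiber_stress(t, 0.05, ACT)
        s2 = active_fiber_stress(t, 0.05, doubled)
        assert s2 == pytest.approx(2 * s1, rel=1e-12, abs=1e-15)
        assert s1 >= 0.0

    def test_continuous_at_phase_junctions(self):
        tr = float(ACT.m * eff_sarcomere_length(0.05, ACT) + ACT.b_relax)
        for tj in (ACT.t_0, ACT.t_0 + tr):
            lo = active_fiber_stress(tj - 1e-9, 0.05, ACT)
            hi = active_fiber_stress(tj + 1e-9, 0.05, ACT)
            assert hi == pytest.approx(lo, abs=1e-6)

    def test_frank_starling_peak_force_nondecreasing(self):
        E = np.linspace(-0.1, 0.3, 30)
        peak = active_fiber_stress(ACT.t_0, E, ACT)
        assert np.all(np.diff(peak) >= -1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(MaterialError):
            active_fiber_stress(-0.1, 0.0, ACT)


class TestParamValidation:
    def test_requires_near_incompressibility(self):
        with pytest.raises(MaterialError):
            PassiveParams(kappa=1e-3)

    def test_requires_positive_relaxation(self):
        with pytest.raises(MaterialError):
            ActiveParams(m=1.0, b_relax=-1.5)

    def test_requires_ordered_lengths(self):
        with pytest.raises(MaterialError):
            ActiveParams(l_0=0.002, l_r=0.0015)


class TestKlotz:
    def test_passes_through_anchor(self):
        P = klotz_edpvr([158.3], (11.85, 158.3))
        assert P[0] == pytest.approx(11.85, rel=1e-9)

    def test_zero_below_unloaded_volume(self):
        v0 = 158.3 * (0.6 - 0.006 * 11.85)
        assert klotz_edpvr([0.9 * v0], (11.85, 158.3))[0] == 0.0

    def test_strictly_increasing_above_v0(self):
        v0 = 158.3 * (0.6 - 0.006 * 11.85)
        V = np.linspace(v0 + 1, 200, 50)
        P = klotz_edpvr(V, (11.85, 158.3))
        assert np.all(np.diff(P) > 0)

    def test_invalid_anchor_rejected(self):
        with pytest.raises(MaterialError):
            klotz_edpvr([100.0], (-1.0, 150.0))
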