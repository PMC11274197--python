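"""Metrics, strains, stress summaries and table rendering."""

import numpy as np
import pytest

from apexfree.circulation import BeatTrace
from apexfree.errors import PostprocessError
from apexfree.postprocess import (apex_and_root_displacement,
                                  compute_pv_metrics, myofiber_stress_summary,
                                  percent_change, strain_between)
from apexfree.scenarios import pv_comparison_table, regional_comparison_table


def make_trace(t, p_lv, v_lv, p_art=None, x_apex=None, x_root=None):
    n = len(t)
    z = np.zeros(n)
    return BeatTrace(
        t=np.asarray(t, float), p_lv=np.asarray(p_lv, float),
        v_lv=np.asarray(v_lv, float),
        p_art=np.asarray(p_art if p_art is not None else z, float),
        p_la=z.copy(), q_mv=z.copy(), q_av=z.copy(),
        x_root=np.asarray(x_root if x_root is not None else z, float),
        x_apex=np.asarray(x_apex if x_apex is not None else z, float),
        q_modes=np.zeros((n, 1)), total_volume=z.copy())


class TestPVMetrics:
    def test_stroke_work_is_sv_times_map(self):
        # rectangular loop: fill at 10 mmHg, eject at 100 mmHg
        v = [70, 110, 150, 150, 150, 110, 70, 70]
        p = [10, 10, 10, 55, 100, 100, 100, 55]
        m = compute_pv_metrics(make_trace(np.linspace(0, 1, 8), p, v,
                                          p_art=np.full(8, 90.0)))
        assert m.SV == 80.0
        assert m.MAP == 90.0
        assert m.SW == 80.0 * 90.0

    def test_rectangular_loop_area_exact(self):
        v = [70, 150, 150, 70]
        p = [10, 10, 100, 100]
        m = compute_pv_metrics(make_trace(np.linspace(0, 1, 4), p, v,
                                          p_art=np.full(4, 90.0)))
        assert m.loop_area == pytest.approx((150 - 70) * (100 - 10))

    def test_printed_row_is_arithmetically_consistent(self):
        """The published baseline row satisfies SW = SV x MAP: the implied
        MAP is SW/SV; our metric must reproduce it when fed a loop with
        exactly that arterial pressure."""
        sv, sw = 92.20, 8747.50
        implied_map = sw / sv
        v = [66.10, 158.30, 158.30, 66.10]
        p = [11.85, 11.85, 117.10, 117.10]
        m = compute_pv_metrics(make_trace(
            np.linspace(0, 1, 4), p, v, p_art=np.full(4, implied_map)))
        assert m.SV == pytest.approx(sv, abs=1e-9)
        assert m.SW == pytest.approx(sw, rel=1e-9)

    def test_non_cyclic_trace_rejected(self):
        v = [70, 150, 150, 120]
        p = [10, 10, 100, 100]
        with pytest.raises(PostprocessError):
            compute_pv_metrics(make_trace(np.linspace(0, 1, 4), p, v))


class TestPercentChange:
    @pytest.mark.parametrize("base, var, expected", [
        (92.20, 82.20, -10.85),
        (66.10, 77.40, 17.10),
        (5.0, 5.0, 0.0),
        (-0.17, -0.01, -94.12),
        (-0.15, -0.24, 60.00),
    ])
    def test_examples(self, base, var, expected):
        assert percent_change(base, var) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(PostprocessError):
            percent_change(0.0, 1.0)


class TestStrainOperator:
    def test_no_deformation_zero_strain(self, rng):
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        s = strain_between(F, F, 0.7)
        assert np.abs(s).max() < 1e-12

    def test_axial_compression_is_pure_longitudinal(self):
        F_es = np.diag([1.0, 1.0, 0.84])
        for phi in (0.0, 1.1, 2.5, 4.0):
            r, c, l = strain_between(np.eye(3), F_es, phi)
            assert l == pytest.approx(-0.16, abs=1e-12)
            assert r == pytest.approx(0.0, abs=1e-12)
            assert c == pytest.approx(0.0, abs=1e-12)

    def test_radial_thickening_affine(self):
        F_es = np.diag([1.63, 1.63, 1.0])
        for phi in (0.0, 0.9, 3.3):
            r, c, l = strain_between(np.eye(3), F_es, phi)
            assert r == pytest.approx(0.63, abs=1e-12)
            assert c == pytest.approx(0.63, abs=1e-12)
            assert l == pytest.approx(0.0, abs=1e-12)

    def test_exact_for_arbitrary_affine_maps(self, rng):
        """Sampled strains equal closed-form stretch ratios minus one for
        any homogeneous deformation (to 1e-10)."""
        for _ in range(20):
            F_ed = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
            F_es = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
            if min(np.linalg.det(F_ed), np.linalg.det(F_es)) < 0.4:
                continue
            phi = float(rng.uniform(0, 2 * np.pi))
            dirs = [np.array([np.cos(phi), np.sin(phi), 0]),
                    np.array([-np.sin(phi), np.cos(phi), 0]),
                    np.array([0.0, 0, 1])]
            got = strain_between(F_ed, F_es, phi)
            for d, vec in enumerate(dirs):
                m = np.linalg.solve(F_ed, vec)
                expected = (np.linalg.norm(F_es @ m)
                            / np.linalg.norm(F_ed @ m) - 1.0)
                assert got[d] == pytest.approx(expected, abs=1e-10)


class TestRegionalTable:
    def test_sector_means_rendered_at_two_decimals(self):
        from apexfree.postprocess import (StrainReport,
                                          regional_longitudinal)
        vals = np.zeros((3, 4, 2, 3))
        vals[:, 0, :, 2] = -0.171   # septal
        vals[:, 1, :, 2] = -0.166   # anterior
        vals[:, 2, :, 2] = -0.149   # lateral
        vals[:, 3, :, 2] = -0.154   # posterior
        rep = StrainReport(values=vals,
                           azimuths=np.deg2rad([180, 270, 0, 90]),
                           axial_positions=np.array([0.3, 0.55, 0.8]))
        tbl = regional_longitudinal(rep)
        assert list(tbl.loc["longitudinal"]) == [-0.17, -0.17, -0.15,
                                                 -0.15]


class TestStressSummary:
    def test_uniform_field(self):
        rep = myofiber_stress_summary(np.full(10, 0.05), np.ones(10))
        assert rep.mean == pytest.approx(0.05)
        assert rep.sd == 0.0

    def test_self_reference_zero_change(self):
        a = myofiber_stress_summary(np.array([0.04, 0.08]), np.ones(2))
        b = myofiber_stress_summary(np.array([0.04, 0.08]), np.ones(2),
                                    reference=a)
        assert b.pct_change_mean == 0.0
        assert b.pct_change_sd == 0.0

    def test_elementwise_percent_convention(self):
        """{0.1, 0.2} vs {0.1, 0.1}: element-wise changes {0 %, 100 %}
        summarize as 50 +/- 50 (population SD), pinning the convention."""
        ref = myofiber_stress_summary(np.array([0.1, 0.1]), np.ones(2))
        rep = myofiber_stress_summary(np.array([0.1, 0.2]), np.ones(2),
                                      reference=ref)
        assert rep.pct_change_mean == pytest.approx(50.0)
        assert rep.pct_change_sd == pytest.approx(50.0)

    def test_mean_invariant_to_subdivision(self):
        rep1 = myofiber_stress_summary(np.array([0.05, 0.07]),
                                       np.array([2.0, 1.0]))
        rep2 = myofiber_stress_summary(np.array([0.05, 0.05, 0.07]),
                                       np.array([1.0, 1.0, 1.0]))
        assert rep1.mean == pytest.approx(rep2.mean)

    def test_discretization_mismatch_rejected(self):
        a = myofiber_stress_summary(np.ones(4), np.ones(4))
        with pytest.raises(PostprocessError):
            myofiber_stress_summary(np.ones(5), np.ones(5), reference=a)


class TestDisplacements:
    def test_rigid_translation_cancels_in_relative_motion(self):
        t = np.linspace(0, 1, 5)
        v = [100, 150, 150, 80, 100]
        shift = np.array([0.0, 3.0, 5.0, 7.0, 4.0])
        tr = make_trace(t, np.zeros(5), v, x_apex=shift, x_root=shift)
        apex, root = apex_and_root_displacement(tr)
        # both landmarks translate together: apex-toward-base motion equals
        # minus the root-toward-apex motion; relative shortening is zero
        assert apex == pytest.approx(-root)

    def test_sign_conventions(self):
        t = np.linspace(0, 1, 4)
        v = [100, 160, 70, 100]
        # root descends 11 mm toward the apex, apex sinks 1.9 mm away
        x_root = np.array([0.0, 0.0, -11.0, -2.0])
        x_apex = np.array([0.0, 0.0, -1.9, -0.4])
        tr = make_trace(t, np.zeros(4), v, x_apex=x_apex, x_root=x_root)
        apex, root = apex_and_root_displacement(tr)
        assert root == pytest.approx(11.0)
        assert apex == pytest.approx(-1.9)


class TestComparisonTables:
    def test_pv_percent_cells_match_published_rows(self):
        vals = {
            "A": dict(EDP=11.85, EDV=158.30, ESP=117.10, ESV=66.10,
                      SV=92.20, SW=8747.50),
            "B": dict(EDP=12.86, EDV=159.60, ESP=106.40, ESV=77.40,
                      SV=82.20, SW=7084.50),
            "C": dict(EDP=11.25, EDV=157.00, ESP=116.60, ESV=62.86,
                      SV=94.14, SW=8923.00),
        }
        tbl = pv_comparison_table(vals)
        rowB = tbl.loc["baseline vs. stiff AA (%)"]
        assert list(rowB) == [8.52, 0.82, -9.14, 17.10, -10.85, -19.01]
        rowC = tbl.loc["baseline vs. stiff AA free apex (%)"]
        assert list(rowC) == [-5.06, -0.82, -0.43, -4.90, 2.10, 2.01]

    def test_regional_percent_cells_match_published_rows(self):
        regional = {
            "A": dict(septal=-0.17, anterior=-0.17, lateral=-0.15,
                      posterior=-0.15),
            "B": dict(septal=-0.01, anterior=-0.10, lateral=-0.13,
                      posterior=-0.09),
            "C": dict(septal=-0.21, anterior=-0.20, lateral=-0.19,
                      posterior=-0.24),
        }
        tbl = regional_comparison_table(regional)
        rowB = tbl.loc["baseline vs. stiff AA (%)"]
        assert list(rowB) == [-94.12, -41.18, -13.33, -40.00]
        rowC = tbl.loc["baseline vs. stiff AA free apex (%)"]
        assert list(rowC) == [23.53, 17.65, 26.67, 60.00]

    def test_identical_inputs_zero_percent(self):
        vals = {s: dict(EDP=10.0, EDV=150.0, ESP=100.0, ESV=60.0,
                        SV=90.0, SW=8000.0) for s in ("A", "B", "C")}
        tbl = pv_comparison_table(vals)
        assert not tbl.loc["baseline vs. stiff AA (%)"].any()
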