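"""Beat metrics, strain and stress reporting.

Implements the quantities reported for each simulated beat: PV-loop
numbers (EDP/EDV/ESP/ESV, stroke volume, mean arterial pressure, stroke
work SW = SV x MAP and the shoelace loop area), the 12-location strain
decomposition (radial / circumferential / longitudinal at three axial and
four circumferential positions, endocardium and epicardium), regional
longitudinal strains for the septal / anterior / lateral / posterior
sectors, the volume-weighted myofiber stress summary, and the apex / root
axial displacements.

Sign conventions: tensile strains positive (radial thickening > 0),
compressive negative (circumferential and longitudinal shortening < 0);
apex displacement positive toward the base; root displacement reported
positive when the root moves toward the apex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circulation import BeatTrace
from .errors import PostprocessError
from .mechanics import WallModel

__all__ = [
    "BeatMetrics", "StrainReport", "StressReport",
    "compute_pv_metrics", "percent_change", "strain_at_locations",
    "regional_longitudinal", "myofiber_stress_summary",
    "apex_and_root_displacement", "REGION_NAMES",
]

REGION_NAMES = ("septal", "anterior", "lateral", "posterior")


@dataclass
class BeatMetrics:
    """PV-loop quantities of one converged beat (mmHg, mL, mmHg*mL)."""

    EDP: float
    EDV: float
    ESP: float
    ESV: float
    SV: float
    MAP: float
    SW: float
    loop_area: float

    def as_series(self) -> pd.Series:
        return pd.Series({"EDP": self.EDP, "EDV": self.EDV, "ESP": self.ESP,
                          "ESV": self.ESV, "SV": self.SV, "MAP": self.MAP,
                          "SW": self.SW, "loop_area": self.loop_area})


def compute_pv_metrics(trace: BeatTrace) -> BeatMetrics:
    """PV metrics from one beat trace.

    ED is the volume maximum, ES the volume minimum; MAP is the time
    average of the arterial (Windkessel) pressure over the cycle;
    SW = SV * MAP; the loop area is the shoelace integral of the (V, P)
    polygon (positive for the physiological counterclockwise loop).
    """
    v, p = trace.v_lv, trace.p_lv
    if abs(v[0] - v[-1]) > 0.01 * max(v[0], 1.0) + trace_cyclic_slack(trace):
        raise PostprocessError(
            f"trace is not cyclic (start {v[0]:.2f} mL vs end {v[-1]:.2f} mL)")
    ed, es = trace.ed_index, trace.es_index
    sv = float(v[ed] - v[es])
    map_ = float(np.mean(trace.p_art))
    x, y = v, p
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return BeatMetrics(EDP=float(p[ed]), EDV=float(v[ed]), ESP=float(p[es]),
                       ESV=float(v[es]), SV=sv, MAP=map_, SW=sv * map_,
                       loop_area=abs(area))


def trace_cyclic_slack(trace: BeatTrace) -> float:
    """Extra slack (mL) for the cyclicity check: one step of peak flow."""
    dt = trace.t[1] - trace.t[0] if len(trace.t) > 1 else 0.0
    qmax = max(float(np.max(np.abs(trace.q_mv))),
               float(np.max(np.abs(trace.q_av))), 0.0)
    return qmax * dt


def percent_change(baseline: float, variant: float) -> float:
    """Table-style percent change 100*(variant - baseline)/baseline,
    rounded to 2 decimals for rendering."""
    if baseline == 0:
        raise PostprocessError("percent change undefined for zero baseline")
    return round(100.0 * (variant - baseline) / baseline, 2)


@dataclass
class StrainReport:
    """Strains at the 12 sampling locations x {endo, epi} x 3 directions.

    ``values`` has shape (n_axial, n_circ, 2 surfaces, 3 directions) with
    directions ordered (radial, circumferential, longitudinal); strains
    are relative length changes of material fiducial directions between
    the ED and ES states (cylindrical radial / azimuthal / axial
    directions fixed at ED).
    """

    values: np.ndarray
    azimuths: np.ndarray
    axial_positions: np.ndarray
    region_names: tuple = REGION_NAMES

    def average(self, direction: str, pool_surfaces: bool = True):
        """(mean, SD) of one strain direction over the sampled locations."""
        d = {"radial": 0, "circumferential": 1, "longitudinal": 2}[direction]
        vals = self.values[..., d]
        if not pool_surfaces:
            vals = vals.mean(axis=2)
        return float(np.mean(vals)), float(np.std(vals))

    def regional_longitudinal(self) -> dict:
        """Mean longitudinal strain per circumferential sector."""
        out = {}
        for j, name in enumerate(self.region_names):
            out[name] = float(np.mean(self.values[:, j, :, 2]))
        return out

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.axial_positions):
            for j, az in enumerate(self.azimuths):
                for k, surf in enumerate(("endo", "epi")):
                    rows.append({
                        "axial": s, "azimuth_deg": np.rad2deg(az),
                        "surface": surf, "sector": self.region_names[j],
                        "radial": self.values[i, j, k, 0],
                        "circumferential": self.values[i, j, k, 1],
                        "longitudinal": self.values[i, j, k, 2]})
        return pd.DataFrame(rows)


def _direction_triplet(phi):
    """Cylindrical radial, azimuthal and axial unit vectors at azimuth phi."""
    e_r = np.array([np.cos(phi), np.sin(phi), 0.0])
    e_c = np.array([-np.sin(phi), np.cos(phi), 0.0])
    e_l = np.array([0.0, 0.0, 1.0])
    return e_r, e_c, e_l


def strain_between(F_ed, F_es, dirs):
    """Strains along the direction triplet ``dirs`` between two states.

    ``dirs`` is a sequence of three unit vectors (radial, circumferential,
    longitudinal) defining material fiducial directions; a scalar is
    interpreted as an azimuth and expands to the cylindrical triplet.
    Each strain is the relative stretch of the material fiducial that is
    aligned with the direction in the ED configuration: with
    ``m = F_ed^-1 d``, strain = |F_es m| / |F_ed m| - 1.  Exact for
    affine deformations.
    """
    if np.isscalar(dirs):
        dirs = _direction_triplet(dirs)
    out = np.empty(len(dirs))
    for d, vec in enumerate(dirs):
        m = np.linalg.solve(F_ed, vec)
        out[d] = (np.linalg.norm(F_es @ m) / np.linalg.norm(F_ed @ m)) - 1.0
    return out


def strain_at_locations(model: WallModel, q_ed, q_es,
                        axial_positions=(0.3, 0.55, 0.8),
                        n_sectors: int = 4,
                        surfaces=(0.05, 0.95)) -> StrainReport:
    """Strain decomposition between the ED and ES states.

    At each sampling point the strain along a direction (defined in the
    ED configuration) is the relative stretch of the corresponding
    material fiducial: with ``m = F_ED^-1 d`` the material direction,
    strain = |F_ES m| / |F_ED m| - 1 (exact for homogeneous
    deformations).  The directions are the anatomical wall triad at the
    sample point — transmural (radial), circumferential and wall-tangent
    longitudinal — so systolic wall thickening reads as positive radial
    strain and shortening as negative circumferential and longitudinal
    strains.
    """
    from .geometry import fiber_frame

    q_ed = np.asarray(q_ed, float)
    q_es = np.asarray(q_es, float)
    phi0 = model.geometry.params.septal_azimuth
    azimuths = (phi0 + 2 * np.pi * np.arange(n_sectors) / n_sectors) \
        % (2 * np.pi)
    vals = np.empty((len(axial_positions), n_sectors, len(surfaces), 3))
    for i, eta in enumerate(axial_positions):
        for j, phi in enumerate(azimuths):
            for k, xi in enumerate(surfaces):
                F_ed = model.deformation_gradients(q_ed, xi, eta, phi)
                F_es = model.deformation_gradients(q_es, xi, eta, phi)
                # fiber_frame at 0 deg: f0 = circumferential, s0 =
                # outward transmural normal; their cross is the
                # wall-tangent longitudinal direction
                e_c, e_t, _ = fiber_frame(model.geometry.params, xi, eta,
                                          phi, endo_angle=0.0,
                                          epi_angle=0.0)
                e_l = np.cross(e_t, e_c)
                e_l /= np.linalg.norm(e_l)
                vals[i, j, k] = strain_between(F_ed, F_es,
                                               (e_t, e_c, e_l))
    return StrainReport(values=vals, azimuths=azimuths,
                        axial_positions=np.asarray(axial_positions))


def regional_longitudinal(report: StrainReport) -> pd.DataFrame:
    """Four-sector longitudinal strain table (2-decimal rendering)."""
    reg = report.regional_longitudinal()
    if set(reg) != set(REGION_NAMES):
        raise PostprocessError("report lacks the four standard sectors")
    return pd.DataFrame({name: [round(reg[name], 2)]
                         for name in REGION_NAMES}, index=["longitudinal"])


@dataclass
class StressReport:
    """Volume-weighted myofiber stress summary at end-systole (MPa)."""

    mean: float
    sd: float
    values: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)
    pct_change_mean: float = None
    pct_change_sd: float = None


def myofiber_stress_summary(values, weights, reference: StressReport | None
                            = None) -> StressReport:
    """Volume-weighted mean +/- SD of a fiber-stress field.

    ``weights`` are deformed element volumes.  With a ``reference``
    (another field on the same discretization), element-wise percent
    changes are summarized as their weighted mean +/- SD — the
    convention that matches reporting like "37 +/- 43 %", which cannot be
    the ratio of the two field means.
    """
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if v.shape != w.shape:
        raise PostprocessError("values/weights shape mismatch")
    wsum = w.sum()
    mean = float((v * w).sum() / wsum)
    sd = float(np.sqrt((w * (v - mean) ** 2).sum() / wsum))
    rep = StressReport(mean=mean, sd=sd, values=v, weights=w)
    if reference is not None:
        if reference.values is None or reference.values.shape != v.shape:
            raise PostprocessError(
                "reference field is on a different discretization")
        pct = 100.0 * (v - reference.values) / reference.values
        pmean = float((pct * w).sum() / wsum)
        psd = float(np.sqrt((w * (pct - pmean) ** 2).sum() / wsum))
        rep.pct_change_mean = pmean
        rep.pct_change_sd = psd
    return rep


def apex_and_root_displacement(trace: BeatTrace):
    """Systolic axial displacements (mm) of the apex and the aortic root.

    Measured between the instants of maximum apex-base length
    (end-diastole) and minimum apex-base length (end-systole) — the base
    keeps rising through isovolumic contraction, so the length extrema,
    not the volume extrema, bracket the full atrioventricular-plane
    excursion.  Returns ``(apex, root)``: apex positive toward the base;
    root positive toward the apex (sign flipped from the axial convention
    so the physiological systolic root descent reads positive).
    """
    if trace.x_apex is None or trace.x_root is None:
        raise PostprocessError("trace lacks landmark trajectories")
    length = np.asarray(trace.x_root) - np.asarray(trace.x_apex)
    ed = int(np.argmax(length))
    es = int(np.argmin(length))
    apex = float(trace.x_apex[es] - trace.x_apex[ed])
    root = -float(trace.x_root[es] - trace.x_root[ed])
    return apex, root
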