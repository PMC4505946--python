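"""Synthetic vocal-tract generator with known ground truth.

Emulates the study design this package analyzes: a tubular airway with an
epilaryngeal constriction and a hypopharyngeal widening, five vowel shape
variants, and two phonation modes — a natural, speech-like reference and a
classical-singing mode that lowers the larynx and widens the hypopharynx.
Every generated object carries closed-form ground truth, so the geometry,
morphometry, acoustics and statistics stages can be validated end to end
without any imaging data.

Arc-length anchors are aligned to the analysis slice grid (0.3255 mm per
slice, 30 slices = 9.765 mm):

* slice 50 (16.275 mm): top of the complete posterior arytenoid closure;
  the reference plane is the slice just below it (slice 49),
* slice 20 (6.510 mm): ventricular-fold width minimum (lower ELV border),
* reference + 30 slices: hypopharyngeal area (HPA) measurement level,
* reference − 5 slices: endolaryngeal area (ELA) measurement level.

The singing transform multiplies hypopharyngeal areas by ``hpa_scale`` at
the HPA level with a linear arc-length taper solved so the integrated
hypopharyngeal volume changes by exactly ``hpv_scale`` (likewise
``ela_scale`` / ``elv_scale`` in the epilarynx), and shifts the laryngeal
landmarks caudally by ``larynx_lowering`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.spatial import cKDTree

from .containers import (
    MODES,
    S1_COLUMNS,
    VOWELS,
    AreaFunction,
    CrossSectionStack,
    LandmarkSet,
    TransferFunction,
    VoxelVolume,
)

__all__ = [
    "SLICE_SPACING_MM",
    "SyntheticVTParams",
    "BendSpec",
    "SyntheticCohort",
    "make_area_profile",
    "truth_measures",
    "analytic_stack",
    "voxelize",
    "make_cohort",
    "render_audio",
    "DEFAULT_EFFECTS",
]

#: Analysis slice spacing in mm; 30 slices span exactly 9.765 mm.
SLICE_SPACING_MM = 0.3255

# Arc-length anchors (slice indices on the 0.3255 mm grid).
_CLOSURE_TOP_IDX = 50      # uppermost complete posterior arytenoid closure
_FOLD_MIN_IDX = 20         # ventricular-fold width minimum
_VALLECULA_IDX = 90        # inferiormost point of the vallecula (splice point)
_REF_IDX = _CLOSURE_TOP_IDX - 1          # reference plane: just below closure
_ELA_IDX = _REF_IDX - 5
_HPA_IDX = _REF_IDX + 30

S_CLOSURE_TOP = _CLOSURE_TOP_IDX * SLICE_SPACING_MM   # 16.2750 mm
S_FOLD_MIN = _FOLD_MIN_IDX * SLICE_SPACING_MM         # 6.5100 mm
S_VALLECULA = _VALLECULA_IDX * SLICE_SPACING_MM       # 29.2950 mm
S_ELA = _ELA_IDX * SLICE_SPACING_MM                   # 14.3220 mm
S_HPA = _HPA_IDX * SLICE_SPACING_MM                   # 25.7145 mm

#: Width of the band of complete posterior closure below its top edge, mm.
CLOSURE_BAND_MM = 2.0

#: Injected cohort effects; the defaults are the study conditions emulated by
#: this generator (8 mm larynx lowering, +21.9 % HPA, +16.8 % HPV, +12.1 %
#: ELA, +7.2 % ELV in singing relative to speech-like phonation).
DEFAULT_EFFECTS: dict[str, float] = {
    "larynx_lowering": 8.0,
    "hpa_scale": 1.219,
    "hpv_scale": 1.168,
    "ela_scale": 1.121,
    "elv_scale": 1.072,
}

NEUTRAL_EFFECTS: dict[str, float] = {
    "larynx_lowering": 0.0,
    "hpa_scale": 1.0,
    "hpv_scale": 1.0,
    "ela_scale": 1.0,
    "elv_scale": 1.0,
}

# Fallback taper fractions (volume effect / area effect) used when the
# injected area effect is neutral and the ratio is undefined.
_TAPER_FRACTION_HYPO = (DEFAULT_EFFECTS["hpv_scale"] - 1) / (DEFAULT_EFFECTS["hpa_scale"] - 1)
_TAPER_FRACTION_EPI = (DEFAULT_EFFECTS["elv_scale"] - 1) / (DEFAULT_EFFECTS["ela_scale"] - 1)

# Base area control points for vowel /a/, (arc mm, area mm^2), glottis at 0.
# Lower VT: glottal end, ventricular-fold constriction, epilarynx tube;
# then a steep hypopharyngeal widening (piriform-sinus level) and the
# oropharynx / oral cavity up to the lips at ~175 mm.
_BASE_LOWER = [(0.0, 60.0), (3.255, 52.0), (S_FOLD_MIN, 40.0), (9.765, 50.0),
               (13.02, 54.0), (S_CLOSURE_TOP, 58.0)]
_BASE_HYPO = [(17.5, 160.0), (19.0, 210.0), (22.0, 215.0), (S_HPA, 190.0),
              (S_VALLECULA, 200.0)]
_BASE_UPPER = [(45.0, 260.0), (60.0, 300.0), (75.0, 330.0), (90.0, 300.0),
               (105.0, 340.0), (120.0, 380.0), (140.0, 420.0), (160.0, 340.0),
               (170.0, 300.0), (175.0, 280.0)]

# Per-vowel multipliers on (lower VT, hypopharynx, upper VT) areas and an
# additive laryngeal-height offset (mm).  All lower-VT measures and LH vary
# with vowel, as observed in sustained-vowel cohorts.
_VOWEL_SHAPE: dict[str, tuple[float, float, float, float]] = {
    "a": (1.00, 1.00, 1.00, 0.0),
    "e": (0.95, 0.93, 0.90, 1.5),
    "i": (0.90, 0.86, 0.80, 3.0),
    "o": (1.05, 1.08, 1.05, -2.0),
    "u": (1.10, 1.15, 1.10, -3.5),
}

#: Baseline laryngeal height (distance from the helpline intersection at the
#: anterior commissure down to the C7 landmark), mm.
LH_BASE_MM = 40.0


@dataclass
class SyntheticVTParams:
    """Parameters of one synthetic vocal tract.

    ``subject_noise_sd`` is the relative SD of the per-subject area
    perturbation (one factor for the lower VT, one for the upper VT, both
    drawn from ``seed``); inter-subject variability of real cohorts is not
    documented distributionally anywhere, so this is configurable.
    """

    vowel: str = "a"
    mode: str = "speech_like"
    base_area_profile: Sequence[tuple[float, float]] | None = None
    larynx_lowering: float = DEFAULT_EFFECTS["larynx_lowering"]
    hpa_scale: float = DEFAULT_EFFECTS["hpa_scale"]
    hpv_scale: float = DEFAULT_EFFECTS["hpv_scale"]
    ela_scale: float = DEFAULT_EFFECTS["ela_scale"]
    elv_scale: float = DEFAULT_EFFECTS["elv_scale"]
    subject_noise_sd: float = 0.0
    voxel_size: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vowel not in VOWELS:
            raise ValueError(f"vowel must be one of {VOWELS}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        for name in ("hpa_scale", "hpv_scale", "ela_scale", "elv_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be non-negative")
        if self.base_area_profile is not None:
            pts = np.asarray(self.base_area_profile, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or np.any(pts[:, 1] <= 0):
                raise ValueError("base_area_profile must be (arc, area>0) pairs")


def _control_points(vowel: str, base: Sequence[tuple[float, float]] | None) -> tuple[np.ndarray, np.ndarray]:
    if base is not None:
        pts = np.asarray(base, dtype=float)
        return pts[:, 0], pts[:, 1]
    ml, mh, mu, _ = _VOWEL_SHAPE[vowel]
    s = np.array([p[0] for p in _BASE_LOWER + _BASE_HYPO + _BASE_UPPER])
    a = np.array(
        [p[1] * ml for p in _BASE_LOWER]
        + [p[1] * mh for p in _BASE_HYPO]
        + [p[1] * mu for p in _BASE_UPPER]
    )
    return s, a


def _taper_weights(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unit taper shapes for the epilarynx and hypopharynx singing widening.

    Returns (w_fixed, w_free) pairs for each region: the applied weight is
    ``w_fixed + w0 * w_free`` with the free coefficient solved so the
    integrated (volume) effect matches its target while the weight is exactly
    1 at the area-measurement level.
    """
    # Epilarynx: 0 at the glottis, rising to v0 at the fold minimum, then
    # linearly to 1 at the ELA level, 1 up to the closure top.
    epi_fixed = np.zeros_like(grid)
    epi_free = np.zeros_like(grid)
    m = (grid > 0) & (grid < S_FOLD_MIN)
    epi_free[m] = grid[m] / S_FOLD_MIN
    m = (grid >= S_FOLD_MIN) & (grid < S_ELA)
    t = (grid[m] - S_FOLD_MIN) / (S_ELA - S_FOLD_MIN)
    epi_fixed[m] = t
    epi_free[m] = 1.0 - t
    m = (grid >= S_ELA) & (grid <= S_CLOSURE_TOP)
    epi_fixed[m] = 1.0
    # Hypopharynx: w0 just above the closure top, rising linearly to 1 at the
    # HPA level, then back to 0 at the vallecula so the upper VT is untouched.
    hyp_fixed = np.zeros_like(grid)
    hyp_free = np.zeros_like(grid)
    m = (grid > S_CLOSURE_TOP) & (grid < S_HPA)
    t = (grid[m] - S_CLOSURE_TOP) / (S_HPA - S_CLOSURE_TOP)
    hyp_fixed[m] = t
    hyp_free[m] = 1.0 - t
    m = (grid >= S_HPA) & (grid <= S_VALLECULA)
    hyp_fixed[m] = 1.0 - (grid[m] - S_HPA) / (S_VALLECULA - S_HPA)
    return epi_fixed, epi_free, hyp_fixed, hyp_free


def _solve_w0(areas: np.ndarray, w_fixed: np.ndarray, w_free: np.ndarray,
              idx: np.ndarray, area_scale: float, volume_scale: float,
              fallback_fraction: float,
              base_extra: np.ndarray | None = None) -> float:
    """Solve the free taper coefficient so the windowed volume ratio is exact.

    sum(A * (1 + base_extra + (area_scale-1) * (w_fixed + w0*w_free)))[idx]
        == volume_scale * sum(A)[idx]

    ``base_extra`` carries scale contributions already present in the window
    (the epilarynx taper overlaps the first slices of the hypopharyngeal
    volume window, which sit just below the closure top).
    """
    if abs(area_scale - 1.0) < 1e-12:
        return 2 * fallback_fraction - 1.0
    A = areas[idx]
    wf = w_fixed[idx]
    wv = w_free[idx]
    extra = 0.0 if base_extra is None else float((A * base_extra[idx]).sum())
    target = (volume_scale - 1.0) * A.sum() - extra
    denom = float((area_scale - 1.0) * (A * wv).sum())
    if denom == 0.0:
        return 0.0
    return float((target - (area_scale - 1.0) * (A * wf).sum()) / denom)


def make_area_profile(params: SyntheticVTParams) -> AreaFunction:
    """Build the glottis-to-lips area function for one synthetic tract.

    In singing mode the epilaryngeal and hypopharyngeal areas are widened by
    the configured tapers; per-subject noise multiplies the lower and upper
    VT by factors drawn from ``params.seed``.  Deterministic given identical
    parameters and seed.
    """
    s_ctrl, a_ctrl = _control_points(params.vowel, params.base_area_profile)
    length = float(s_ctrl[-1])
    n = int(np.floor(length / SLICE_SPACING_MM)) + 1
    grid = np.arange(n) * SLICE_SPACING_MM
    areas = PchipInterpolator(s_ctrl, a_ctrl)(grid)
    if np.any(areas <= 0):
        raise ValueError("base area profile produced non-positive areas")

    if params.mode == "singing":
        epi_f, epi_v, hyp_f, hyp_v = _taper_weights(grid)
        elv_idx = np.arange(_FOLD_MIN_IDX, _REF_IDX)
        v0 = _solve_w0(areas, epi_f, epi_v, elv_idx, params.ela_scale,
                       params.elv_scale, _TAPER_FRACTION_EPI)
        hpv_idx = np.arange(_REF_IDX, _REF_IDX + 30)
        epi_extra = (params.ela_scale - 1.0) * (epi_f + v0 * epi_v)
        w0 = _solve_w0(areas, hyp_f, hyp_v, hpv_idx, params.hpa_scale,
                       params.hpv_scale, _TAPER_FRACTION_HYPO,
                       base_extra=epi_extra)
        scale = (1.0
                 + (params.ela_scale - 1.0) * (epi_f + v0 * epi_v)
                 + (params.hpa_scale - 1.0) * (hyp_f + w0 * hyp_v))
        areas = areas * scale

    if params.subject_noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        for _ in range(10):
            lower_f, upper_f = 1.0 + rng.normal(0.0, params.subject_noise_sd, size=2)
            if lower_f > 0.05 and upper_f > 0.05:
                break
        else:
            raise ValueError("could not draw positive subject noise factors")
        factor = np.where(grid < S_VALLECULA, lower_f, upper_f)
        areas = areas * factor

    if np.any(areas <= 0):
        raise ValueError("area profile non-positive after perturbation")

    # Lowering the larynx stretches the pharynx: in singing the arc length
    # between the HPA level and the vallecula grows by ``larynx_lowering``,
    # leaving every measurement window (all at or below the HPA level)
    # untouched while lengthening the lower VT that enters the acoustics.
    positions = grid
    stretch = params.larynx_lowering if params.mode == "singing" else 0.0
    if stretch:
        ramp = np.clip((grid - S_HPA) / (S_VALLECULA - S_HPA), 0.0, 1.0)
        positions = grid + stretch * ramp

    ann = {
        "glottis": 0.0,
        "fold_min": S_FOLD_MIN,
        "closure_top": S_CLOSURE_TOP,
        "vallecula_inferior": S_VALLECULA + stretch,
        "lips": float(positions[-1]),
    }
    return AreaFunction(positions, areas, ann)


def truth_measures(af: AreaFunction, spacing: float = SLICE_SPACING_MM) -> dict[str, float]:
    """Closed-form morphometric ground truth of a generator area function.

    Applies the definitional chain on the analytic areas sampled at the slice
    grid: reference slice one below the closure top, ELA five slices below
    the reference, HPA thirty slices above, ELV integrated from the fold
    minimum to the reference, HPV from the reference over thirty slices
    (left Riemann sums, half-open upper bound).
    """
    n = int(np.floor((af.positions[-1] - af.positions[0]) / spacing)) + 1
    grid = af.positions[0] + np.arange(n) * spacing
    areas = np.asarray(af.area_at(grid), dtype=float)
    closure = af.annotations["closure_top"]
    fold = af.annotations["fold_min"]
    ref = int(round((closure - af.positions[0]) / spacing)) - 1
    lo = int(round((fold - af.positions[0]) / spacing))
    return {
        "ELA": float(areas[ref - 5]),
        "HPA": float(areas[ref + 30]),
        "ELV": float(areas[lo:ref].sum() * spacing),
        "HPV": float(areas[ref:ref + 30].sum() * spacing),
    }


def analytic_stack(af: AreaFunction, spacing: float = SLICE_SPACING_MM,
                   pixel_pitch: float | None = None,
                   eccentricity: float = 0.0) -> CrossSectionStack:
    """Rasterize an area function into a stack of circular cross-sections.

    Sections are circles of area ``af(s)`` (optionally ellipses of the given
    eccentricity at equal area), so the analytic areas serve as an oracle for
    the voxel-counted ones.  The posterior-closure flag is set for slices in
    the band of ``CLOSURE_BAND_MM`` below the ``closure_top`` annotation.
    """
    if not 0.0 <= eccentricity < 1.0:
        raise ValueError("eccentricity must be in [0, 1)")
    if pixel_pitch is None:
        pixel_pitch = spacing
    n = int(np.floor((af.positions[-1] - af.positions[0]) / spacing)) + 1
    grid = af.positions[0] + np.arange(n) * spacing
    areas = np.asarray(af.area_at(grid), dtype=float)
    rmax = np.sqrt(areas.max() / np.pi)
    stretch = (1.0 - eccentricity**2) ** -0.25
    half = int(np.ceil(rmax * stretch / pixel_pitch)) + 2
    size = 2 * half + 1
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1] * pixel_pitch
    r = np.sqrt(areas / np.pi)
    # Equal-area ellipse: semi-axes r*stretch (left-right) and r/stretch.
    a_ax = r * stretch
    b_ax = r / stretch
    masks = ((xx[None] / a_ax[:, None, None]) ** 2
             + (yy[None] / b_ax[:, None, None]) ** 2) <= 1.0
    closure = af.annotations.get("closure_top")
    closed = np.zeros(n, dtype=bool)
    if closure is not None:
        closed = (grid >= closure - CLOSURE_BAND_MM) & (grid <= closure + spacing / 2)
    return CrossSectionStack(masks.reshape(n, size, size), spacing=spacing,
                             pixel_pitch=pixel_pitch, posterior_closed=closed,
                             arc_start=float(grid[0]))


@dataclass
class BendSpec:
    """A single smooth in-plane bend of the tube centerline.

    The default is a 90 degree oropharyngeal bend: the tube runs caudocranially,
    turns anteriorly over a circular arc, and continues straight to the lips.
    """

    angle_deg: float = 90.0
    radius_mm: float = 40.0
    start_mm: float = 80.0

    def centerline(self, total_length: float, ds: float) -> np.ndarray:
        """Sample the bent centerline at arc steps ``ds`` (mm), from s=0."""
        s = np.arange(0.0, total_length + ds / 2, ds)
        ang = np.deg2rad(self.angle_deg)
        pts = np.zeros((len(s), 3))
        arc_len = self.radius_mm * ang
        for i, si in enumerate(s):
            if si <= self.start_mm or self.angle_deg == 0:
                pts[i] = (0.0, 0.0, si)
            elif si <= self.start_mm + arc_len:
                th = (si - self.start_mm) / self.radius_mm
                pts[i] = (0.0, self.radius_mm * (1 - np.cos(th)),
                          self.start_mm + self.radius_mm * np.sin(th))
            else:
                rem = si - self.start_mm - arc_len
                tip = np.array([0.0, self.radius_mm * (1 - np.cos(ang)),
                                self.start_mm + self.radius_mm * np.sin(ang)])
                direction = np.array([0.0, np.sin(ang), np.cos(ang)])
                pts[i] = tip + rem * direction
        return pts


def voxelize(profile: AreaFunction, bend: BendSpec | None = None,
             voxel_size: float = 0.5, seed: int = 0,
             lh_mm: float = LH_BASE_MM) -> tuple[VoxelVolume, LandmarkSet]:
    """Rasterize an area function into a labeled voxel volume plus landmarks.

    Cross-sections are circles normal to the generating centerline with area
    matching the profile.  Label 1 marks the airway; label 2 marks airway
    voxels within the posterior-closure band below the ``closure_top``
    annotation.  Landmarks (arytenoid-ventricular crossing, uvula tip,
    cervical-vertebra rims, anterior commissure) are emitted as coordinates,
    since their identification on real images is manual.

    Raises if the bend makes the tube self-intersect, naming the arc length
    of the first intersection.
    """
    if len(profile) < 2:
        raise ValueError("zero-length profile cannot be voxelized")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if bend is None:
        bend = BendSpec()
    length = float(profile.positions[-1] - profile.positions[0])
    ds = voxel_size / 2.0
    pts = bend.centerline(length, ds)
    s_fine = np.arange(len(pts)) * ds
    radii = np.sqrt(np.asarray(profile.area_at(profile.positions[0] + s_fine)) / np.pi)
    rmax = float(radii.max())

    # Self-intersection: two samples far apart in arc length but closer in
    # space than the sum of their tube radii.
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=2.0 * rmax, output_type="ndarray")
    if len(pairs):
        arc_gap = np.abs(s_fine[pairs[:, 0]] - s_fine[pairs[:, 1]])
        rad_sum = radii[pairs[:, 0]] + radii[pairs[:, 1]]
        dist = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        bad = (arc_gap > 4.0 * rmax) & (dist < rad_sum)
        if bad.any():
            s_bad = float(s_fine[pairs[bad][:, 0]].min())
            raise ValueError(f"tube self-intersects near arc length {s_bad:.1f} mm")

    margin = rmax + 3 * voxel_size
    # Reserve space on the posterior (-y) side for the cervical-spine
    # landmarks and caudally for C7.
    spine_y = -(rmax + 6.0)
    lo = pts.min(axis=0) - margin + np.array([0.0, spine_y - 2.0, -12.0])
    shift = -lo
    pts = pts + shift
    # extra anterior room for the commissure landmark offset
    hi = pts.max(axis=0) + margin + np.array([0.0, 10.0, 0.0])
    shape = np.ceil(hi / voxel_size).astype(int) + 1

    idx = np.indices(shape).reshape(3, -1).T * voxel_size
    tree = cKDTree(pts)
    dist, nearest = tree.query(idx, distance_upper_bound=rmax + voxel_size)
    near = np.clip(nearest, 0, len(radii) - 1)
    tangents = np.gradient(pts, ds, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    delta = idx - pts[near]
    axial = np.abs(np.einsum("ij,ij->i", delta, tangents[near]))
    with np.errstate(invalid="ignore"):
        radial = np.sqrt(np.maximum(dist**2 - axial**2, 0.0))
    # flat end faces: no spherical caps beyond the first/last sample
    inside = (radial <= radii[near]) & (axial <= ds) & np.isfinite(dist)
    labels = np.zeros(shape, dtype=np.int16)
    labels.reshape(-1)[inside] = 1
    closure = profile.annotations.get("closure_top")
    if closure is not None:
        s_near = s_fine[np.clip(nearest, 0, len(radii) - 1)]
        band = inside & (s_near >= closure - CLOSURE_BAND_MM) & (s_near <= closure)
        labels.reshape(-1)[band] = 2

    def at(s: float) -> np.ndarray:
        i = int(round(s / ds))
        return pts[min(i, len(pts) - 1)]

    fold = profile.annotations.get("fold_min", S_FOLD_MIN)
    vall = profile.annotations.get("vallecula_inferior", S_VALLECULA)
    top_world = (shape - 1) * voxel_size
    c7 = at(0.0) + np.array([0.0, spine_y, -8.0])
    c1 = c7.copy()
    c1[2] = min(c7[2] + 80.0, top_world[2] - voxel_size)
    commissure = at(fold) + np.array([0.0, 8.0, 0.0])
    commissure[2] = min(c7[2] + lh_mm, top_world[2] - voxel_size)
    lm = LandmarkSet(
        uvula_tip=at(vall + 12.0),
        arytenoid_ventricular_crossing=at(closure if closure is not None else 0.0),
        c1_anterior_rim=c1,
        c7_upper_anterior_rim=c7,
        anterior_commissure=commissure,
    )
    vol = VoxelVolume(labels, (voxel_size,) * 3, orientation="RAS", is_label=True)
    lm.check_inside(vol)
    return vol, lm


@dataclass
class SyntheticCohort:
    """A full-factorial subject x vowel x mode synthetic cohort.

    ``truth_table`` holds the measurement-noise-free per-record values
    (subject anatomy included), recomputable in closed form from the
    generating profiles; ``table`` adds measurement noise and is what the
    statistics stage consumes.  Volumes and audio are built on demand via
    :meth:`volume_for` and the acoustics/spectrum modules, one per record.
    """

    truth_table: pd.DataFrame
    table: pd.DataFrame
    delta_hi: pd.DataFrame
    params: dict[tuple[str, str, str], SyntheticVTParams]
    effects: dict[str, float]
    seed: int

    def volume_for(self, subject: str, vowel: str, mode: str,
                   bend: BendSpec | None = None) -> tuple[VoxelVolume, LandmarkSet]:
        p = self.params[(subject, vowel, mode)]
        row = self.truth_table.query(
            "subject == @subject and vowel == @vowel and mode == @mode").iloc[0]
        return voxelize(make_area_profile(p), bend=bend, voxel_size=p.voxel_size,
                        seed=p.seed, lh_mm=float(row.LH))


def make_cohort(n_subjects: int = 13,
                effects: Mapping[str, float] | None = None,
                seed: int = 0,
                vowels: Sequence[str] = VOWELS,
                subject_sd: float = 0.10,
                meas_sd: float = 0.01,
                lh_subject_sd: float = 4.0,
                lh_meas_sd: float = 0.3,
                heterogeneity: Mapping[str, float] | None = None,
                coupling: Mapping[str, object] | None = None,
                delta_hi_mean: float = 4.5,
                delta_hi_sd: float = 6.0,
                hi_coupling: float = 0.0) -> SyntheticCohort:
    """Generate a synthetic cohort in the supplementary-table schema.

    Parameters
    ----------
    effects : mapping, optional
        Injected singing-mode effects (``larynx_lowering`` in mm and the four
        area/volume scale factors).  Defaults to :data:`DEFAULT_EFFECTS`,
        the study conditions; pass :data:`NEUTRAL_EFFECTS` for a null cohort.
    subject_sd : float
        Relative SD of the per-subject anatomy size factors (lower and upper
        VT drawn independently).
    meas_sd : float
        Relative SD of the per-record multiplicative measurement error on
        areas and volumes — sub-voxel segmentation repeatability at the
        0.3255 mm grid.  LH gets additive noise of ``lh_meas_sd`` mm.
    heterogeneity : mapping, optional
        SDs of per-subject random deviations of the mode effects
        (``lowering_sd`` mm, ``hpa_scale_sd``, ``ela_scale_sd``).  Zero by
        default, so the truth table carries the injected effects exactly.
    coupling : mapping, optional
        ``{"vowels": (...), "kappa": x}`` — adds ``kappa * (lowering_i -
        mean)`` to the subject's HPA scale for the listed vowels, emulating
        larynx-lowering-driven pharyngeal widening.
    hi_coupling : float
        dB of extra per-subject ΔHI per percentage point of that subject's
        mean HPA change (used to inject an acoustic-morphometric coupling).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    eff = dict(DEFAULT_EFFECTS)
    if effects is not None:
        unknown = set(effects) - set(eff)
        if unknown:
            raise ValueError(f"unknown effect names: {sorted(unknown)}")
        eff.update(effects)
    het = {"lowering_sd": 0.0, "hpa_scale_sd": 0.0, "ela_scale_sd": 0.0}
    if heterogeneity is not None:
        het.update(heterogeneity)

    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1:02d}" for i in range(n_subjects)]
    lower_f = 1.0 + rng.normal(0.0, subject_sd, n_subjects)
    upper_f = 1.0 + rng.normal(0.0, subject_sd, n_subjects)
    lower_f = np.clip(lower_f, 0.3, None)
    upper_f = np.clip(upper_f, 0.3, None)
    lh_off = rng.normal(0.0, lh_subject_sd, n_subjects)
    lowering_i = eff["larynx_lowering"] + rng.normal(0.0, het["lowering_sd"], n_subjects)
    hpa_i = eff["hpa_scale"] + rng.normal(0.0, het["hpa_scale_sd"], n_subjects)
    ela_i = eff["ela_scale"] + rng.normal(0.0, het["ela_scale_sd"], n_subjects)

    mu_h = _ratio_or(eff["hpv_scale"], eff["hpa_scale"], _TAPER_FRACTION_HYPO)
    mu_e = _ratio_or(eff["elv_scale"], eff["ela_scale"], _TAPER_FRACTION_EPI)

    couple_vowels: tuple[str, ...] = ()
    kappa = 0.0
    if coupling is not None:
        couple_vowels = tuple(coupling.get("vowels", ("o", "u")))
        kappa = float(coupling.get("kappa", 0.0))

    # Noise-free base measures per vowel (speech-like reference).
    base: dict[str, dict[str, float]] = {}
    for v in vowels:
        prof = make_area_profile(SyntheticVTParams(vowel=v, mode="speech_like"))
        base[v] = truth_measures(prof)
        base[v]["LH"] = LH_BASE_MM + _VOWEL_SHAPE[v][3]

    truth_rows: list[dict] = []
    meas_rows: list[dict] = []
    params: dict[tuple[str, str, str], SyntheticVTParams] = {}
    for i, subj in enumerate(subjects):
        for v in vowels:
            hpa_scale_iv = hpa_i[i]
            if v in couple_vowels:
                hpa_scale_iv = hpa_scale_iv + kappa * (lowering_i[i] - eff["larynx_lowering"])
            hpv_scale_iv = 1.0 + (hpa_scale_iv - 1.0) * mu_h
            elv_scale_i = 1.0 + (ela_i[i] - 1.0) * mu_e
            for mode in MODES:
                singing = mode == "singing"
                fl = lower_f[i]
                truth = {
                    "ELA": base[v]["ELA"] * fl * (ela_i[i] if singing else 1.0),
                    "ELV": base[v]["ELV"] * fl * (elv_scale_i if singing else 1.0),
                    "HPA": base[v]["HPA"] * fl * (hpa_scale_iv if singing else 1.0),
                    "HPV": base[v]["HPV"] * fl * (hpv_scale_iv if singing else 1.0),
                    "LH": base[v]["LH"] + lh_off[i] - (lowering_i[i] if singing else 0.0),
                }
                truth_rows.append({"subject": subj, "vowel": v, "mode": mode, **truth})
                noisy = {
                    k: truth[k] * np.exp(rng.normal(0.0, meas_sd))
                    for k in ("ELA", "ELV", "HPA", "HPV")
                }
                noisy["LH"] = truth["LH"] + rng.normal(0.0, lh_meas_sd)
                meas_rows.append({"subject": subj, "vowel": v, "mode": mode, **noisy})
                params[(subj, v, mode)] = SyntheticVTParams(
                    vowel=v, mode=mode,
                    larynx_lowering=lowering_i[i] if singing else 0.0,
                    hpa_scale=hpa_scale_iv, hpv_scale=hpv_scale_iv,
                    ela_scale=ela_i[i], elv_scale=elv_scale_i,
                    subject_noise_sd=subject_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )

    truth_table = pd.DataFrame(truth_rows, columns=S1_COLUMNS)
    table = pd.DataFrame(meas_rows, columns=S1_COLUMNS)

    # Per-subject Hammarberg-index change, optionally coupled to the
    # subject's hypopharyngeal widening.
    pc_hpa = (
        table.pivot_table(index=["subject", "vowel"], columns="mode", values="HPA")
        .pipe(lambda d: d["singing"] / d["speech_like"] * 100.0)
        .groupby("subject").mean()
        .reindex(subjects)
    )
    dhi = (delta_hi_mean
           + hi_coupling * (pc_hpa.to_numpy() - pc_hpa.mean())
           + rng.normal(0.0, delta_hi_sd, n_subjects))
    delta_hi = pd.DataFrame({"subject": subjects, "delta_hi": dhi})
    return SyntheticCohort(truth_table=truth_table, table=table,
                           delta_hi=delta_hi, params=params,
                           effects=eff, seed=seed)


def _ratio_or(vol_scale: float, area_scale: float, default: float) -> float:
    if abs(area_scale - 1.0) < 1e-12:
        return default
    return (vol_scale - 1.0) / (area_scale - 1.0)


def render_audio(tf: TransferFunction, f0: float = 220.0, duration: float = 2.0,
                 source_slope: float = -12.0, seed: int = 0,
                 sample_rate: int = 44100) -> np.ndarray:
    """Render a sustained vowel: harmonic source filtered by ``tf``.

    The glottal source has harmonics at multiples of ``f0`` with the stated
    spectral slope in dB/octave and seeded random phases; each harmonic is
    weighted by the transfer-function gain at its frequency.  Output is a
    float waveform at 44.1 kHz (peak-normalized to 0.5).
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    nyquist = sample_rate / 2.0
    if f0 >= nyquist / 2.0:
        raise ValueError(f"f0={f0} Hz too high for sample rate {sample_rate}")
    rng = np.random.default_rng(seed)
    n_harm = int(np.floor(0.999 * nyquist / f0))
    k = np.arange(1, n_harm + 1)
    freqs = k * f0
    source_db = source_slope * np.log2(k)
    amp = 10.0 ** ((source_db + np.asarray(tf.gain_at(freqs))) / 20.0)
    phases = rng.uniform(0.0, 2 * np.pi, n_harm)
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    wave = np.sum(amp[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None] + phases[:, None]), axis=0)
    peak = np.abs(wave).max()
    if peak > 0:
        wave = 0.5 * wave / peak
    return wave
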