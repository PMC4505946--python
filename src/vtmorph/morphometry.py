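"""Morphometric measures of the lower vocal tract.

Five measures are taken from a centerline-resampled cross-section stack and
a landmark set:

* ``ELA`` — endolaryngeal cross-sectional area, five slices below the
  epilarynx-exit reference plane (mm^2),
* ``HPA`` — hypopharyngeal cross-sectional area, thirty slices above the
  reference plane (mm^2),
* ``ELV`` — endolaryngeal volume between the ventricular-fold width minimum
  and the reference plane (mm^3),
* ``HPV`` — hypopharyngeal volume over the thirty slices above the
  reference plane (mm^3),
* ``LH`` — laryngeal height, from the cervical-spine helpline to the C7
  landmark (mm).

The reference plane is the first slice just below the uppermost slice with
complete posterior closure of the arytenoid cartilages.  Singing values are
expressed relative to speech-like phonation as ``pc = singing / speech x
100``.  Volumes are left Riemann sums over half-open slice ranges, so the
reference slice shared by ELV and HPV is never counted twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import CrossSectionStack, LandmarkSet

__all__ = [
    "find_reference_plane",
    "measure_ELA",
    "measure_HPA",
    "find_elv_lower_border",
    "measure_volume",
    "measure_LH",
    "measure_record",
    "percentage_change",
    "area_error_estimate",
    "AreaErrorEstimate",
]

#: ELA is taken this many slices below the reference plane (about 1.7 mm).
ELA_OFFSET_SLICES = 5
#: HPA (and the HPV upper bound) is this many slices above the reference
#: plane; at the default 0.3255 mm spacing this spans 9.765 mm.
HPA_OFFSET_SLICES = 30

#: Plausible range of the ELV height (fold minimum to reference plane), mm.
ELV_HEIGHT_HARD_MM = (4.0, 20.0)
#: Range observed in cohorts; a height outside it triggers a warning.
ELV_HEIGHT_WARN_MM = (6.0, 14.5)


def find_reference_plane(stack: CrossSectionStack,
                         closure_labels: np.ndarray | None = None) -> int:
    """Locate the epilarynx-exit reference plane.

    Returns the index of the first slice just below the uppermost slice
    whose posterior arytenoid closure is complete.  Closure information is
    taken from ``closure_labels`` or from ``stack.posterior_closed``.
    """
    closed = closure_labels if closure_labels is not None else stack.posterior_closed
    if closed is None:
        raise ValueError("no posterior-closure information on this stack")
    closed = np.asarray(closed, dtype=bool)
    if len(closed) != len(stack):
        raise ValueError("closure flags must match slice count")
    idx = np.flatnonzero(closed)
    if len(idx) == 0:
        raise ValueError("no slice with complete posterior closure found")
    return int(idx.max()) - 1


def _checked_slice(stack: CrossSectionStack, i: int, what: str) -> float:
    if i < 0 or i >= len(stack):
        raise IndexError(f"{what} slice {i} outside stack of {len(stack)} slices")
    if stack.flags[i]:
        raise ValueError(f"{what} slice {i} is flagged as unreliable")
    return float(stack.areas[i])


def measure_ELA(stack: CrossSectionStack, ref: int) -> float:
    """Endolaryngeal area: the slice ``ELA_OFFSET_SLICES`` below ``ref``, mm^2."""
    if ref - ELA_OFFSET_SLICES < 0:
        raise IndexError(f"reference slice {ref} leaves no room for the ELA window")
    return _checked_slice(stack, ref - ELA_OFFSET_SLICES, "ELA")

def measure_HPA(stack: CrossSectionStack, ref: int) -> float:
    """Hypopharyngeal area: the slice ``HPA_OFFSET_SLICES`` above ``ref``, mm^2."""
    if ref + HPA_OFFSET_SLICES >= len(stack):
        raise IndexError(
            f"stack of {len(stack)} slices too short for HPA at ref {ref} + {HPA_OFFSET_SLICES}")
    return _checked_slice(stack, ref + HPA_OFFSET_SLICES, "HPA")


def find_elv_lower_border(stack: CrossSectionStack, ref: int,
                          spacing: float | None = None) -> int:
    """Slice of minimal left-right lumen width below the reference plane.

    The ventricular folds narrow the lumen mediolaterally; the lower ELV
    border is the slice where that width reaches its minimum.  The search
    window is bounded by the plausibility band of the resulting ELV height
    (hard limits 4-20 mm; a height outside 6-14.5 mm warns).  Ties are
    broken toward the slice closest to ``ref``; a monotone width profile
    (no interior minimum) is an error.
    """
    if spacing is None:
        spacing = stack.spacing
    lo = max(0, ref - int(np.floor(ELV_HEIGHT_HARD_MM[1] / spacing)))
    hi = ref - int(np.ceil(ELV_HEIGHT_HARD_MM[0] / spacing))
    if hi <= lo:
        raise ValueError("reference plane too close to the caudal end of the stack")
    widths = np.array([stack.lr_width(i) for i in range(lo, hi + 1)])
    wmin = widths.min()
    if wmin >= widths[0] or wmin >= widths[-1]:
        # minimum sits on the window boundary: monotone profile, no fold dip
        raise ValueError("no interior ventricular-fold width minimum found")
    # ties broken toward the slice closest to the reference plane
    best = lo + int(np.flatnonzero(widths == wmin).max())
    height = (ref - best) * spacing
    if not ELV_HEIGHT_WARN_MM[0] <= height <= ELV_HEIGHT_WARN_MM[1]:
        warnings.warn(
            f"ELV height {height:.1f} mm outside the typical 6-14.5 mm range",
            stacklevel=2)
    return int(best)


def measure_volume(stack: CrossSectionStack, lo: int, hi: int,
                   interpolate_flagged: bool = False) -> float:
    """Volume over slices [lo, hi): left Riemann sum of area x spacing, mm^3.

    A flagged slice inside the range raises unless ``interpolate_flagged``;
    then its area is linearly interpolated from the nearest clean slices.
    """
    if lo >= hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi})")
    if lo < 0 or hi > len(stack):
        raise IndexError(f"range [{lo}, {hi}) outside stack of {len(stack)} slices")
    areas = stack.areas.astype(float)
    flagged = stack.flags[lo:hi]
    if flagged.any():
        if not interpolate_flagged:
            raise ValueError(
                f"flagged slices {list(lo + np.flatnonzero(flagged))} in volume range")
        good = ~stack.flags
        areas = np.interp(np.arange(len(stack)),
                          np.flatnonzero(good), areas[good])
    return float(areas[lo:hi].sum() * stack.spacing)


def measure_LH(lm: LandmarkSet) -> float:
    """Laryngeal height from the cervical-spine helplines, mm.

    Helpline A runs through the C1 and C7 anterior rims; helpline B is
    normal to A through the anterior commissure.  LH is the distance from
    the intersection of A and B to the C7 landmark, signed positive toward
    C1 (a lower larynx gives a smaller LH).
    """
    c1 = lm.c1_anterior_rim
    c7 = lm.c7_upper_anterior_rim
    axis = c1 - c7
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("C1 and C7 landmarks coincide; helpline A undefined")
    axis = axis / norm
    return float(np.dot(lm.anterior_commissure - c7, axis))


@dataclass
class StackMeasures:
    ELA: float
    ELV: float
    HPA: float
    HPV: float
    ref_slice: int
    elv_lower_slice: int


def measure_record(stack: CrossSectionStack,
                   closure_labels: np.ndarray | None = None,
                   interpolate_flagged: bool = False) -> StackMeasures:
    """Run the full definitional chain on one cross-section stack."""
    ref = find_reference_plane(stack, closure_labels)
    lo = find_elv_lower_border(stack, ref)
    return StackMeasures(
        ELA=measure_ELA(stack, ref),
        ELV=measure_volume(stack, lo, ref, interpolate_flagged),
        HPA=measure_HPA(stack, ref),
        HPV=measure_volume(stack, ref, ref + HPA_OFFSET_SLICES, interpolate_flagged),
        ref_slice=ref,
        elv_lower_slice=lo,
    )


def percentage_change(singing_value: float, speech_value: float) -> tuple[float, float]:
    """Relative measure of singing against the speech-like reference.

    Returns ``(pc, delta_pc)`` with ``pc = singing / speech x 100`` and
    ``delta_pc = pc - 100`` (so +21.9 means a 21.9 % increase in singing).
    """
    if not speech_value > 0:
        raise ValueError("speech-like reference value must be positive")
    pc = singing_value / speech_value * 100.0
    return pc, pc - 100.0


@dataclass
class AreaErrorEstimate:
    """Analytic worst-case error of a circular-equivalent area measurement."""

    area: float            # measured area, mm^2
    diameter: float        # circular-equivalent diameter, mm
    area_minus: float      # area at diameter - delta_d, mm^2
    area_plus: float       # area at diameter + delta_d, mm^2
    rel_err_minus: float   # |measured - area_minus| / area_minus, percent
    rel_err_plus: float    # |measured - area_plus| / area_plus, percent


def area_error_estimate(area: float, delta_d: float) -> AreaErrorEstimate:
    """Worst-case relative area error for a diameter uncertainty ``delta_d``.

    Assumes a circular section of the measured area; an uncertainty of
    ``delta_d`` mm on the diameter (e.g. from vibrato or movement artefacts)
    brackets the real area between ``pi ((d - delta_d)/2)^2`` and
    ``pi ((d + delta_d)/2)^2``.  The relative errors are quoted against the
    perturbed ("real") areas, in percent — small measured areas are thus far
    less reliable than large ones.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if delta_d < 0:
        raise ValueError("diameter uncertainty must be non-negative")
    d = 2.0 * np.sqrt(area / np.pi)
    if delta_d >= d:
        raise ValueError(f"uncertainty {delta_d} mm exceeds the diameter {d:.2f} mm")
    a_minus = np.pi * ((d - delta_d) / 2.0) ** 2
    a_plus = np.pi * ((d + delta_d) / 2.0) ** 2
    return AreaErrorEstimate(
        area=area,
        diameter=float(d),
        area_minus=float(a_minus),
        area_plus=float(a_plus),
        rel_err_minus=float(abs(area - a_minus) / a_minus * 100.0),
        rel_err_plus=float(abs(area - a_plus) / a_plus * 100.0),
    )
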