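"""Core data containers for vocal-tract morpho-acoustic analysis.

The pipeline passes geometry through a small set of containers:

``VoxelVolume``
    a 3D scalar or label grid with physical voxel spacing, as read from NIfTI.
``LandmarkSet``
    the five anatomical points (mm, world coordinates) used to standardize
    the centerline and the larynx-height measurement.
``Centerline``
    an ordered polyline through the airway with cumulative arc length.
``CrossSectionStack``
    binary airway masks in planes normal to the centerline at a fixed
    spacing; slice 0 is the most caudal (glottal) slice.
``AreaFunction``
    cross-sectional area (mm^2) against arc-length position (mm) from the
    glottis to the lips, with named junction annotations.
``TransferFunction`` / ``LTASSpectrum``
    acoustic outputs: gain over a frequency grid, and 250 Hz band levels of
    a long-term average spectrum.

All physical quantities are in mm / mm^2 / mm^3 / Hz / dB.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelVolume",
    "LandmarkSet",
    "Centerline",
    "CrossSectionStack",
    "AreaFunction",
    "TransferFunction",
    "LTASSpectrum",
    "MorphometricRecord",
    "VOWELS",
    "MODES",
    "S1_COLUMNS",
]

VOWELS = ("a", "e", "i", "o", "u")
MODES = ("speech_like", "singing")

#: Column order of the per-record morphometric table (the supplementary-table
#: schema): laryngeal height in mm, areas in mm^2, volumes in mm^3.
S1_COLUMNS = ["subject", "vowel", "mode", "ELA", "ELV", "HPA", "HPV", "LH"]


@dataclass
class VoxelVolume:
    """A 3D image or label grid with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = "RAS"
    is_label: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on all axes")
        if not self.orientation:
            raise ValueError("orientation tag is required")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) 0-based voxel indices to mm coordinates."""
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) / np.asarray(self.spacing)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.int16 if self.is_label else np.float32), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, is_label: bool = True) -> "VoxelVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        axcodes = nib.orientations.aff2axcodes(img.affine)
        return cls(np.asarray(img.dataobj), spacing, orientation="".join(axcodes), is_label=is_label)


_LANDMARK_NAMES = (
    "uvula_tip",
    "arytenoid_ventricular_crossing",
    "c1_anterior_rim",
    "c7_upper_anterior_rim",
    "anterior_commissure",
)


@dataclass
class LandmarkSet:
    """Anatomical landmark points in mm (world coordinates).

    ``uvula_tip`` and ``arytenoid_ventricular_crossing`` standardize the
    centerline; the cervical-vertebra rims and the anterior commissure define
    the larynx-height helplines.
    """

    uvula_tip: np.ndarray
    arytenoid_ventricular_crossing: np.ndarray
    c1_anterior_rim: np.ndarray
    c7_upper_anterior_rim: np.ndarray
    anterior_commissure: np.ndarray

    def __post_init__(self) -> None:
        for name in _LANDMARK_NAMES:
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,):
                raise ValueError(f"landmark {name!r} must be a 3-vector")
            setattr(self, name, p)

    def check_inside(self, volume: VoxelVolume) -> None:
        hi = np.asarray(volume.shape) * np.asarray(volume.spacing)
        for name in _LANDMARK_NAMES:
            p = getattr(self, name)
            if np.any(p < 0) or np.any(p > hi):
                raise ValueError(f"landmark {name!r} at {p} lies outside volume bounds {hi}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({name: list(getattr(self, name)) for name in _LANDMARK_NAMES}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        d = json.loads(Path(path).read_text())
        return cls(**{name: np.asarray(d[name], dtype=float) for name in _LANDMARK_NAMES})


@dataclass
class Centerline:
    """Ordered 3D path (mm) through the airway with cumulative arc length."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("centerline needs at least two 3D points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline arc length must be strictly increasing")
        self.arc = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the path at arc position(s) ``s`` (mm)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.stack([np.interp(s, self.arc, self.points[:, k]) for k in range(3)], axis=-1)
        return out[0] if out.shape[0] == 1 else out

    def tangent_at(self, s: float, h: float = 0.5) -> np.ndarray:
        s0 = np.clip(s - h, 0.0, self.length)
        s1 = np.clip(s + h, 0.0, self.length)
        t = np.asarray(self.point_at(s1)) - np.asarray(self.point_at(s0))
        n = np.linalg.norm(t)
        if n == 0:
            raise ValueError("degenerate tangent")
        return t / n


@dataclass
class CrossSectionStack:
    """Binary cross-section masks normal to a centerline at fixed spacing.

    Parameters
    ----------
    masks : array of shape (n_slices, ny, nx), bool
        Airway masks; in-plane pixel pitch equals ``pixel_pitch`` mm.
        Slice index 0 is the most caudal (glottal) slice; increasing index
        runs toward the lips.  The in-plane x axis is the left-right
        (mediolateral) direction.
    spacing : float
        Distance between consecutive slice planes, mm (default 0.3255 —
        30 slices span 9.765 mm).
    posterior_closed : bool array, optional
        Per-slice flag marking complete posterior closure of the arytenoid
        cartilages (used to locate the epilarynx-exit reference plane).
    flags : bool array
        True where the slice could not be sampled reliably (plane exited the
        volume); flagged slices are carried, never silently dropped.
    """

    masks: np.ndarray
    spacing: float = 0.3255
    pixel_pitch: float | None = None
    posterior_closed: np.ndarray | None = None
    flags: np.ndarray | None = None
    arc_start: float = 0.0

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must have shape (n_slices, ny, nx)")
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValueError("slice spacing must be positive")
        if self.pixel_pitch is None:
            self.pixel_pitch = self.spacing
        self.pixel_pitch = float(self.pixel_pitch)
        n = len(self.masks)
        if self.flags is None:
            self.flags = np.zeros(n, dtype=bool)
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.posterior_closed is not None:
            self.posterior_closed = np.asarray(self.posterior_closed, dtype=bool)
            if len(self.posterior_closed) != n:
                raise ValueError("posterior_closed length must match slice count")

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def areas(self) -> np.ndarray:
        """Per-slice area in mm^2 (pixel count times pixel area)."""
        return self.masks.sum(axis=(1, 2)) * self.pixel_pitch**2

    def lr_width(self, i: int) -> float:
        """Left-right (mediolateral) extent of the lumen in slice ``i``, mm."""
        cols = np.any(self.masks[i], axis=0)
        if not cols.any():
            return 0.0
        idx = np.flatnonzero(cols)
        return float((idx[-1] - idx[0] + 1) * self.pixel_pitch)


@dataclass
class AreaFunction:
    """Cross-sectional area (mm^2) versus arc position (mm), glottis to lips.

    ``annotations`` maps junction names (``glottis``, ``vallecula_inferior``,
    ``lips``) to arc positions; the vallecula annotation is the splice point
    between the lower and upper vocal tract.
    """

    positions: np.ndarray
    areas: np.ndarray
    annotations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.areas.shape:
            raise ValueError("positions and areas must be matching 1D arrays")
        if len(self.positions) == 0:
            raise ValueError("area function is empty")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("arc positions must be strictly increasing")
        finite = np.isfinite(self.areas)
        if np.any(self.areas[finite] <= 0):
            raise ValueError("areas must be positive")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def length(self) -> float:
        return float(self.positions[-1] - self.positions[0])

    def area_at(self, s: float | np.ndarray) -> float | np.ndarray:
        return np.interp(s, self.positions, self.areas)

    def slice_between(self, lo: float, hi: float) -> "AreaFunction":
        """Sub-function on [lo, hi) keeping annotations inside the window."""
        m = (self.positions >= lo) & (self.positions < hi)
        ann = {k: v for k, v in self.annotations.items() if lo <= v < hi}
        return AreaFunction(self.positions[m], self.areas[m], ann)

    def to_csv(self, path: str | Path) -> None:
        inv = {}
        for name, pos in self.annotations.items():
            i = int(np.argmin(np.abs(self.positions - pos)))
            inv[i] = name
        df = pd.DataFrame(
            {
                "arc_mm": self.positions,
                "area_mm2": self.areas,
                "annotation": [inv.get(i, "") for i in range(len(self))],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AreaFunction":
        df = pd.read_csv(path, keep_default_na=False)
        ann = {
            str(row.annotation): float(row.arc_mm)
            for row in df.itertuples()
            if str(row.annotation)
        }
        return cls(df["arc_mm"].to_numpy(), df["area_mm2"].to_numpy(), ann)


@dataclass
class TransferFunction:
    """Vocal-tract gain (dB) over a frequency grid, with extracted formants."""

    freqs: np.ndarray
    gain_db: np.ndarray
    formants: list[tuple[float, float]] = field(default_factory=list)
    incomplete: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.gain_db = np.asarray(self.gain_db, dtype=float)
        if self.freqs.shape != self.gain_db.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and gain_db must be matching 1D arrays")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def grid_step(self) -> float:
        return float(np.median(np.diff(self.freqs)))

    def gain_at(self, f: float | np.ndarray) -> float | np.ndarray:
        return np.interp(f, self.freqs, self.gain_db)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"freq_hz": self.freqs, "gain_db": self.gain_db}).to_csv(path, index=False)


@dataclass
class LTASSpectrum:
    """Long-term average spectrum in contiguous bands [k*bw, (k+1)*bw).

    ``levels`` are band levels in dB re an arbitrary but fixed reference;
    only level differences are meaningful.  ``leq`` is the equivalent level
    of the underlying signal on the same dB scale.
    """

    band_edges: np.ndarray
    levels: np.ndarray
    leq: float

    def __post_init__(self) -> None:
        self.band_edges = np.asarray(self.band_edges, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if len(self.band_edges) != len(self.levels) + 1:
            raise ValueError("need one more band edge than band levels")
        if not np.all(np.isfinite(self.levels)):
            raise ValueError("band levels must be finite")

    @property
    def band_centers(self) -> np.ndarray:
        return 0.5 * (self.band_edges[:-1] + self.band_edges[1:])

    @property
    def bandwidth(self) -> float:
        return float(self.band_edges[1] - self.band_edges[0])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "band_lo_hz": self.band_edges[:-1],
                "band_hi_hz": self.band_edges[1:],
                "level_db": self.levels,
            }
        ).to_csv(path, index=False)


@dataclass
class MorphometricRecord:
    """One subject x vowel x mode row of the five lower-VT measures."""

    subject: str
    vowel: str
    mode: str
    ELA: float  # mm^2
    ELV: float  # mm^3
    HPA: float  # mm^2
    HPV: float  # mm^3
    LH: float  # mm

    def __post_init__(self) -> None:
        if self.vowel not in VOWELS:
            raise ValueError(f"vowel must be one of {VOWELS}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        for name in ("ELA", "ELV", "HPA", "HPV"):
            v = getattr(self, name)
            if np.isfinite(v) and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


def records_to_frame(records: Sequence[MorphometricRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=S1_COLUMNS)
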