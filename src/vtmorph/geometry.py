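"""Airway geometry: centerline extraction and normal-plane resampling.

A (synthetic or pre-segmented) airway volume is turned into a stack of
cross-sections normal to a centerline, whose voxel-counted areas form the
area function of the tract.  The pipeline is:

1. :func:`preprocess_volume` — integer upsampling (trilinear for gray
   values, nearest for labels) and edge-preserving Perona-Malik diffusion
   for gray-scale inputs,
2. :func:`build_centerline` — a distance-weighted minimal path through the
   lumen between its two tube ends, standardized by the arytenoid-
   ventricular-crossing and uvula-tip landmarks and smoothed by a spline,
3. :func:`resample_cross_sections` — binary masks in planes normal to the
   local tangent at a fixed spacing (0.3255 mm default, in-plane pixel
   pitch equal to the spacing), keeping per slice only the connected
   component that contains the centerline point,
4. :func:`cross_section_areas` — per-slice pixel-count areas as an
   :class:`~vtmorph.containers.AreaFunction`, with flagged slices carried
   as gaps rather than dropped.

Coordinates: 0-based voxel indices; world positions in mm as index times
spacing.  Slice 0 is the most caudal (glottal) slice; "above" means toward
the lips.  The in-plane x axis of every slice is the mediolateral
(left-right) direction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage import graph as skgraph
from skimage import measure as skmeasure

from .containers import AreaFunction, Centerline, CrossSectionStack, LandmarkSet, VoxelVolume

__all__ = [
    "preprocess_volume",
    "build_centerline",
    "resample_cross_sections",
    "cross_section_areas",
    "anisotropic_diffusion",
]


def anisotropic_diffusion(data: np.ndarray, iterations: int = 10,
                          conductance: float = 1.0, step: float = 0.1) -> np.ndarray:
    """Perona-Malik edge-preserving diffusion (exponential conductance)."""
    u = np.asarray(data, dtype=float).copy()
    for _ in range(iterations):
        flux_sum = np.zeros_like(u)
        for ax in range(u.ndim):
            grad = np.diff(u, axis=ax)
            cond = np.exp(-((grad / conductance) ** 2))
            flux = cond * grad
            pad = [(0, 0)] * u.ndim
            pad[ax] = (1, 0)
            fwd = np.pad(flux, pad)
            pad[ax] = (0, 1)
            bwd = np.pad(flux, pad)
            flux_sum += fwd - bwd
        u -= step * flux_sum
    return u


def preprocess_volume(v: VoxelVolume, scale_factor: int = 4,
                      diffusion: dict | None = None) -> VoxelVolume:
    """Upsample a volume by an integer factor and smooth gray values.

    Gray-scale volumes are trilinearly interpolated and then diffused
    edge-preservingly; label volumes are nearest-neighbor upsampled and
    bypass smoothing.  Voxel spacing shrinks by the scale factor, so world
    coordinates are preserved.
    """
    if not float(scale_factor).is_integer() or scale_factor < 1:
        raise ValueError(f"scale factor must be a positive integer, got {scale_factor}")
    scale_factor = int(scale_factor)
    cfg = {"iterations": 10, "conductance": 1.0}
    if diffusion is not None:
        cfg.update(diffusion)
    data = v.data
    if scale_factor > 1:
        order = 0 if v.is_label else 1
        data = ndimage.zoom(data, scale_factor, order=order, mode="nearest",
                            grid_mode=True)
    if not v.is_label and cfg["iterations"] > 0:
        data = anisotropic_diffusion(data, cfg["iterations"], cfg["conductance"])
    spacing = tuple(s / scale_factor for s in v.spacing)
    return VoxelVolume(data, spacing, orientation=v.orientation, is_label=v.is_label)


def _lumen_mask(v: VoxelVolume, threshold: float = 0.5) -> np.ndarray:
    return v.data >= (1 if v.is_label else threshold)


def _require_in_lumen(mask: np.ndarray, v: VoxelVolume, point_mm: np.ndarray,
                      name: str, tol_vox: int = 3) -> tuple[int, int, int]:
    idx = np.round(v.world_to_index(point_mm)).astype(int)
    lo = np.maximum(idx - tol_vox, 0)
    hi = np.minimum(idx + tol_vox + 1, mask.shape)
    nb = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if not nb.any():
        raise ValueError(f"landmark {name!r} at {point_mm} lies outside the airway")
    off = np.argwhere(nb)
    best = off[np.argmin(np.linalg.norm(off + lo - idx, axis=1))]
    return tuple(best + lo)


def _geodesic_farthest(mask: np.ndarray, seed: tuple[int, int, int]) -> tuple[tuple[int, int, int], np.ndarray]:
    costs = np.where(mask, 1.0, np.inf)
    mcp = skgraph.MCP_Geometric(costs)
    cum, _ = mcp.find_costs([seed])
    cum = np.where(np.isfinite(cum), cum, -1.0)
    far = np.unravel_index(int(np.argmax(cum)), cum.shape)
    return tuple(far), cum


def build_centerline(v: VoxelVolume, lm: LandmarkSet,
                     smoothing: float = 200.0,
                     centeredness_power: float = 2.0) -> Centerline:
    """Extract a smooth mid-lumen path from the glottal end to the lips.

    The path runs between the two geodesic tube ends of the airway (found
    from the arytenoid-ventricular-crossing landmark by the double-sweep
    farthest-point rule), follows the distance-transform ridge (minimal
    cost ``1/(1+D)^p``), and is smoothed with a parametric spline.  It is
    oriented so that arc length increases from the glottis toward the lips,
    with the arytenoid crossing caudal to the uvula tip.  The rule for
    extending beyond the two defining landmarks is simply to continue along
    the mid-lumen ridge to the tube ends.

    Raises if the airway is disconnected between the landmark levels, naming
    the components' locations.
    """
    mask = _lumen_mask(v)
    if not mask.any():
        raise ValueError("empty airway mask")
    ary = _require_in_lumen(mask, v, lm.arytenoid_ventricular_crossing,
                            "arytenoid_ventricular_crossing")
    uvu = _require_in_lumen(mask, v, lm.uvula_tip, "uvula_tip")

    labels, n_comp = ndimage.label(mask)
    if labels[ary] != labels[uvu]:
        c_ary = np.asarray(ndimage.center_of_mass(labels == labels[ary])) * v.spacing
        c_uvu = np.asarray(ndimage.center_of_mass(labels == labels[uvu])) * v.spacing
        raise ValueError(
            "airway disconnected between the landmark levels: components near "
            f"{np.round(c_ary, 1)} mm and {np.round(c_uvu, 1)} mm")

    end1, _ = _geodesic_farthest(mask, ary)
    end2, _ = _geodesic_farthest(mask, end1)

    dist = ndimage.distance_transform_edt(mask, sampling=v.spacing)
    # snap each tube end from the face rim to the on-axis ridge: the voxel
    # of maximal wall distance within the end cap region
    vox = float(min(v.spacing))
    end1 = _axis_end(mask, dist, end1, vox)
    end2 = _axis_end(mask, dist, end2, vox)

    costs = np.where(mask, 1.0 / (1.0 + dist) ** centeredness_power, np.inf)
    path, _ = skgraph.route_through_array(costs, end2, end1, fully_connected=True,
                                          geometric=True)
    pts = np.asarray(path, dtype=float) * np.asarray(v.spacing)

    # orient glottis -> lips: the arytenoid crossing must come before the uvula
    d_ary = np.argmin(np.linalg.norm(pts - v.index_to_world(np.asarray(ary)), axis=1))
    d_uvu = np.argmin(np.linalg.norm(pts - v.index_to_world(np.asarray(uvu)), axis=1))
    if d_ary > d_uvu:
        pts = pts[::-1]

    pts = _smooth_path(pts, weight=2.0)
    pts = _extend_to_ends(v, mask, _monotone_chain(pts))
    pts = _smooth_path(pts, weight=0.3)
    return Centerline(_monotone_chain(pts))


def _axis_end(mask: np.ndarray, dist: np.ndarray, corner: tuple[int, int, int],
              voxel_mm: float) -> tuple[int, int, int]:
    """Move a tube-end corner voxel to the mid-lumen point of its end cap.

    The end cap is the lumen region within a few maximal-radius geodesic
    steps of the corner; its maximal-wall-distance voxel sits on the ridge.
    """
    costs = np.where(mask, 1.0, np.inf)
    mcp = skgraph.MCP_Geometric(costs)
    cum, _ = mcp.find_costs([corner])
    cum = np.where(np.isfinite(cum), cum, np.inf) * voxel_mm
    region = cum <= 2.0 * float(dist.max())
    if not region.any():
        return corner
    # deepest-in-wall voxels of the cap, then the one nearest the corner
    dmax = dist[region].max()
    ridge = region & (dist >= dmax - voxel_mm)
    cand = np.where(ridge, cum, np.inf)
    return tuple(np.unravel_index(int(np.argmin(cand)), cand.shape))


def _smooth_path(pts: np.ndarray, weight: float) -> np.ndarray:
    """Parametric spline smoothing; ``weight`` is mm^2 of tolerated residual
    per point."""
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9])
    pts = pts[keep]
    if len(pts) <= 7 or weight <= 0:
        return pts
    tck, _ = splprep(pts.T, s=weight * len(pts))
    u = np.linspace(0.0, 1.0, max(2 * len(pts), 200))
    return np.asarray(splev(u, tck)).T


def _monotone_chain(pts: np.ndarray) -> np.ndarray:
    """Keep points whose projection on the end-to-end chord advances.

    Removes back-stepping artifacts near the tube ends; adequate for
    airway-like paths whose total turning stays below ~90 degrees.
    """
    chord = pts[-1] - pts[0]
    n = np.linalg.norm(chord)
    if n < 1e-9:
        return pts[:1]
    chord = chord / n
    proj = (pts - pts[0]) @ chord
    kept = [0]
    last = proj[0]
    for i in range(1, len(pts)):
        if proj[i] > last + 1e-9 and np.linalg.norm(pts[i] - pts[kept[-1]]) > 1e-9:
            kept.append(i)
            last = proj[i]
    return pts[kept]


def _plane_centroid(mask_u8: np.ndarray, spacing: np.ndarray, p: np.ndarray,
                    t: np.ndarray, half_extent: float = 15.0) -> np.ndarray | None:
    """Centroid of the lumen component containing ``p`` in the plane normal
    to ``t``; None if ``p`` is not in the lumen."""
    pitch = float(min(spacing))
    half_px = int(np.ceil(half_extent / pitch))
    size = 2 * half_px + 1
    offs = (np.arange(size) - half_px) * pitch
    jj, ii = np.meshgrid(offs, offs)
    u, w = _slice_basis(t)
    coords = (p[None, None, :] + jj[..., None] * u[None, None, :]
              + ii[..., None] * w[None, None, :])
    idx = (coords / spacing).reshape(-1, 3).T
    samp = ndimage.map_coordinates(mask_u8, idx, order=0, mode="constant",
                                   cval=0).reshape(size, size)
    if not samp[half_px, half_px]:
        return None
    comp = skmeasure.label(samp > 0, connectivity=2)
    sel = comp == comp[half_px, half_px]
    ci, cj = np.argwhere(sel).mean(axis=0)
    return p + (cj - half_px) * pitch * u + (ci - half_px) * pitch * w


def _extend_to_ends(v: VoxelVolume, mask: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """March the path to the tube ends, re-centering in-plane at each step.

    A straight extension would leave the lumen axis wherever the tube is
    still curving near its end; the predictor-corrector march (step along
    the running tangent, snap to the normal-plane lumen centroid) follows
    the curve until the next step exits the lumen.
    """
    step = float(min(v.spacing))
    spacing = np.asarray(v.spacing)
    mask_u8 = mask.astype(np.uint8)
    k = max(2, min(int(round(4.0 / step)), len(pts) - 1))
    max_ext = 6.0 * float(dist_max := ndimage.distance_transform_edt(
        mask, sampling=v.spacing).max())
    out = list(pts)
    for sign, tangent in ((0, pts[0] - pts[k]), (-1, pts[-1] - pts[-1 - k])):
        t = tangent / np.linalg.norm(tangent)
        p = pts[sign].copy()
        ext: list[np.ndarray] = []
        travelled = 0.0
        while travelled < max_ext:
            cand = p + step * t
            snapped = _plane_centroid(mask_u8, spacing, cand, t)
            if snapped is None:
                break
            # cap the in-plane correction and damp the direction update so
            # centroid jitter cannot turn the march around
            corr = snapped - cand
            n_corr = np.linalg.norm(corr)
            if n_corr > 0.4 * step:
                snapped = cand + corr * (0.4 * step / n_corr)
            t_new = (snapped - p) / np.linalg.norm(snapped - p)
            t = 0.8 * t + 0.2 * t_new
            t = t / np.linalg.norm(t)
            travelled += np.linalg.norm(snapped - p)
            p = snapped
            ext.append(p.copy())
        if sign == 0:
            out = ext[::-1] + out
        else:
            out = out + ext
    return np.asarray(out)


def _refine_by_centroids(v: VoxelVolume, mask: np.ndarray, pts: np.ndarray,
                         iterations: int = 2, step_mm: float = 1.0,
                         half_extent: float = 25.0) -> np.ndarray:
    """Snap a (pre-smoothed) path to the in-plane lumen centroids.

    The path is resampled at ``step_mm`` and each point replaced by the
    centroid of the lumen component containing it in the plane normal to
    the local tangent; planes whose center misses the lumen (beyond the
    tube ends, or off the airway) are dropped.  This removes the bias of
    the shortest-path route toward corners of the tube end faces.
    """
    spacing = np.asarray(v.spacing)
    pitch = float(min(v.spacing))
    half_px = int(np.ceil(half_extent / pitch))
    size = 2 * half_px + 1
    offs = (np.arange(size) - half_px) * pitch
    jj, ii = np.meshgrid(offs, offs)
    mask_u8 = mask.astype(np.uint8)
    for _ in range(iterations):
        cl = Centerline(_monotone_chain(pts))
        arcs = np.arange(0.0, cl.length + step_mm / 2, step_mm)
        new_pts = []
        for arc in arcs:
            p = np.asarray(cl.point_at(min(arc, cl.length)))
            t = cl.tangent_at(min(arc, cl.length))
            u, w = _slice_basis(t)
            coords = (p[None, None, :] + jj[..., None] * u[None, None, :]
                      + ii[..., None] * w[None, None, :])
            idx = (coords / spacing).reshape(-1, 3).T
            samp = ndimage.map_coordinates(mask_u8, idx, order=0,
                                           mode="constant", cval=0).reshape(size, size)
            if not samp[half_px, half_px]:
                continue
            comp = skmeasure.label(samp > 0, connectivity=2)
            sel = comp == comp[half_px, half_px]
            ci, cj = np.argwhere(sel).mean(axis=0)
            new_pts.append(p + (cj - half_px) * pitch * u + (ci - half_px) * pitch * w)
        if len(new_pts) < 2:
            return pts
        pts = np.asarray(new_pts)
    return pts


def _slice_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane axes: u along mediolateral x, v completing the frame."""
    x_hat = np.array([1.0, 0.0, 0.0])
    u = x_hat - np.dot(x_hat, tangent) * tangent
    if np.linalg.norm(u) < 1e-6:
        u = np.array([0.0, 1.0, 0.0]) - tangent[1] * tangent
    u = u / np.linalg.norm(u)
    w = np.cross(tangent, u)
    return u, w / np.linalg.norm(w)


def resample_cross_sections(v: VoxelVolume, c: Centerline,
                            s: float = 0.3255,
                            window: tuple[float, float] | None = None,
                            half_extent: float = 20.0,
                            pixel_pitch: float | None = None,
                            closure_label: int = 2) -> CrossSectionStack:
    """Sample binary airway masks in planes normal to the centerline.

    One mask every ``s`` mm along the centerline (slice 0 most caudal),
    nearest-neighbor sampled for label volumes and linearly thresholded for
    gray values, keeping per slice only the connected component containing
    the centerline point.  Slices whose plane exits the volume or misses
    the lumen are flagged, never dropped.  ``window`` restricts the arc
    range (mm along the centerline); the posterior-closure flag is set for
    slices containing voxels of ``closure_label``.
    """
    if s <= 0:
        raise ValueError("slice spacing must be positive")
    if pixel_pitch is None:
        pixel_pitch = s
    lo, hi = window if window is not None else (0.0, c.length)
    n = int(np.floor((hi - lo) / s)) + 1
    half_px = int(np.ceil(half_extent / pixel_pitch))
    size = 2 * half_px + 1
    offs = (np.arange(size) - half_px) * pixel_pitch
    jj, ii = np.meshgrid(offs, offs)  # ii: rows (v axis), jj: cols (u axis, LR)

    masks = np.zeros((n, size, size), dtype=bool)
    flags = np.zeros(n, dtype=bool)
    closed = np.zeros(n, dtype=bool)
    spacing = np.asarray(v.spacing)
    data = v.data
    for k in range(n):
        arc = lo + k * s
        p = np.asarray(c.point_at(arc))
        t = c.tangent_at(arc)
        u, w = _slice_basis(t)
        coords = (p[None, None, :] + jj[..., None] * u[None, None, :]
                  + ii[..., None] * w[None, None, :])
        idx = (coords / spacing).reshape(-1, 3).T
        out_of_bounds = np.any((idx < -0.5) | (idx >= np.asarray(data.shape)[:, None] - 0.5),
                               axis=0)
        if v.is_label:
            samp = ndimage.map_coordinates(data, idx, order=0, mode="constant", cval=0)
        else:
            samp = ndimage.map_coordinates(data, idx, order=1, mode="constant", cval=0.0)
            samp = (samp >= 0.5).astype(int)
        samp = samp.reshape(size, size)
        lum = samp >= 1
        if not lum[half_px, half_px]:
            flags[k] = True
            masks[k] = lum
            continue
        comp = skmeasure.label(lum, connectivity=2)
        keep = comp == comp[half_px, half_px]
        masks[k] = keep
        closed[k] = bool((samp[keep] == closure_label).any())
        border = np.zeros_like(keep)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        if (keep & border).any() or (out_of_bounds.reshape(size, size) & keep).any():
            flags[k] = True
    return CrossSectionStack(masks, spacing=s, pixel_pitch=pixel_pitch,
                             posterior_closed=closed, flags=flags, arc_start=lo)


def cross_section_areas(stack: CrossSectionStack) -> AreaFunction:
    """Area function of a cross-section stack.

    The area at arc position ``arc_start + i*spacing`` is the mask pixel
    count times the pixel area; flagged or empty slices carry NaN as a gap
    marker.  If the stack has posterior-closure flags, the arc position of
    the uppermost closed slice is annotated as ``closure_top``.
    """
    if len(stack) == 0:
        raise ValueError("empty cross-section stack")
    positions = stack.arc_start + np.arange(len(stack)) * stack.spacing
    areas = stack.areas.astype(float)
    bad = stack.flags | (areas <= 0)
    areas[bad] = np.nan
    ann: dict[str, float] = {}
    if stack.posterior_closed is not None and stack.posterior_closed.any():
        ann["closure_top"] = float(positions[np.flatnonzero(stack.posterior_closed).max()])
    return AreaFunction(positions, areas, ann)
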