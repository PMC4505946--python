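"""One-dimensional vocal-tract acoustics from area functions.

The tract is modeled as a chain of short cylindrical segments carrying plane
waves (lossy telegraphist equations).  Each segment of length ``l`` and area
``A`` contributes a 2x2 chain (ABCD) matrix in the pressure / volume-velocity
variables::

    [P_in ]   [ cosh(gl)        Zc sinh(gl) ] [P_out]
    [U_in ] = [ sinh(gl)/Zc     cosh(gl)    ] [U_out]

with propagation constant ``g`` and characteristic impedance ``Zc`` from the
per-length series impedance (air mass + viscous boundary-layer resistance)
and shunt admittance (air compliance + thermal-conduction conductance).  The
glottal source is a volume-velocity source with a high but finite internal
resistance; the lips radiate as a piston in an infinite baffle.  The
transfer function is the lip volume velocity per unit source volume
velocity, reported as gain in dB over a frequency grid.

Formant frequencies are the supported comparison surface; absolute levels
and bandwidths depend on the damping configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import j1, struve

from .containers import AreaFunction, TransferFunction

__all__ = [
    "AcousticConfig",
    "transfer_function",
    "splice_hybrid",
    "find_formants",
    "epilarynx_ratio_check",
]

log = logging.getLogger(__name__)

#: Area ratio below which the epilarynx resonance decouples from the pharynx.
DECOUPLING_RATIO = 1.0 / 6.0


@dataclass
class AcousticConfig:
    """Physical constants and termination models for the 1D tract.

    Defaults describe warm moist air in the vocal tract: speed of sound
    350 m/s, density 1.14 kg/m^3.  ``glottal_resistance_factor`` scales the
    source's internal resistance in units of the characteristic impedance of
    the glottal segment (``inf`` gives an ideal flow source); the lip end
    radiates as a piston in an infinite baffle (``lip_radiation="none"``
    short-circuits it, an ideal open end).
    """

    speed_of_sound: float = 350.0       # m/s
    density: float = 1.14               # kg/m^3
    viscosity: float = 1.86e-5          # Pa s
    thermal_conductivity: float = 0.0257  # W/(m K)
    specific_heat_cp: float = 1006.0    # J/(kg K)
    heat_capacity_ratio: float = 1.4
    losses: bool = True
    lip_radiation: str = "piston"
    glottal_resistance_factor: float = 20.0
    normalize: bool = True

    def __post_init__(self) -> None:
        for name in ("speed_of_sound", "density", "viscosity",
                     "thermal_conductivity", "specific_heat_cp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.heat_capacity_ratio <= 1:
            raise ValueError("heat_capacity_ratio must exceed 1")
        if self.lip_radiation not in ("piston", "none"):
            raise ValueError("lip_radiation must be 'piston' or 'none'")
        if self.glottal_resistance_factor <= 0:
            raise ValueError("glottal_resistance_factor must be positive")


#: Segments shorter than this (mm) are merged into their neighbor.
MIN_SEGMENT_MM = 1e-6


def _segments(af: AreaFunction) -> tuple[np.ndarray, np.ndarray]:
    """Cylinder lengths (m) and areas (m^2), glottis first."""
    pos = af.positions * 1e-3
    areas = af.areas * 1e-6
    lengths = np.diff(pos)
    mid_areas = 0.5 * (areas[:-1] + areas[1:])
    keep = lengths >= MIN_SEGMENT_MM * 1e-3
    if not keep.all():
        log.info("merged %d sub-tolerance segments", int((~keep).sum()))
        # fold dropped lengths into the following kept segment
        lengths = lengths.copy()
        acc = 0.0
        for i in range(len(lengths)):
            if not keep[i]:
                acc += lengths[i]
                lengths[i] = 0.0
            elif acc:
                lengths[i] += acc
                acc = 0.0
        mid_areas = mid_areas[lengths > 0]
        lengths = lengths[lengths > 0]
    return lengths, mid_areas


def _radiation_impedance(freqs: np.ndarray, area: float, cfg: AcousticConfig) -> np.ndarray:
    """Piston-in-infinite-baffle radiation impedance at the lip opening."""
    if cfg.lip_radiation == "none":
        return np.zeros_like(freqs, dtype=complex)
    a = np.sqrt(area / np.pi)
    ka = 2 * np.pi * freqs * a / cfg.speed_of_sound
    x = 2.0 * ka
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = np.where(x > 0, 1.0 - 2.0 * j1(x) / np.where(x > 0, x, 1.0), 0.0)
        x1 = np.where(x > 0, 2.0 * struve(1, x) / np.where(x > 0, x, 1.0), 0.0)
    return cfg.density * cfg.speed_of_sound / area * (r1 + 1j * x1)


def transfer_function(af: AreaFunction, cfg: AcousticConfig | None = None,
                      grid: np.ndarray | None = None) -> TransferFunction:
    """Volume-velocity transfer function of an area function.

    Parameters
    ----------
    af : AreaFunction
        Glottis-to-lips area function (mm, mm^2).
    cfg : AcousticConfig, optional
        Physical constants and terminations; defaults to lossy warm air.
    grid : array, optional
        Frequency grid in Hz, default 0-5500 Hz in 5 Hz steps; must stay
        within 0-10 kHz where the plane-wave assumption is tenable.
    """
    if cfg is None:
        cfg = AcousticConfig()
    if grid is None:
        grid = np.arange(0.0, 5500.0 + 1e-9, 5.0)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 0 or grid.max() > 10000.0:
        raise ValueError("frequency grid must lie within 0-10 kHz")
    if len(af) < 2:
        raise ValueError("area function needs at least two samples")
    if not np.all(np.isfinite(af.areas)):
        raise ValueError("area function has gaps (NaN areas); interpolate or trim first")

    lengths, areas = _segments(af)
    f = np.where(grid > 0, grid, 1e-2)
    omega = 2 * np.pi * f
    rho, c = cfg.density, cfg.speed_of_sound

    A = np.ones_like(f, dtype=complex)
    B = np.zeros_like(f, dtype=complex)
    C = np.zeros_like(f, dtype=complex)
    D = np.ones_like(f, dtype=complex)
    for l_seg, area in zip(lengths, areas):
        Lp = rho / area
        Cp = area / (rho * c * c)
        if cfg.losses:
            perim = 2.0 * np.sqrt(np.pi * area)
            Rp = perim / area**2 * np.sqrt(omega * rho * cfg.viscosity / 2.0)
            Gp = (perim * (cfg.heat_capacity_ratio - 1.0) / (rho * c * c)
                  * np.sqrt(cfg.thermal_conductivity * omega
                            / (2.0 * rho * cfg.specific_heat_cp)))
        else:
            Rp = Gp = 0.0
        z = Rp + 1j * omega * Lp
        y = Gp + 1j * omega * Cp
        gamma = np.sqrt(z * y)
        zc = np.sqrt(z / y)
        gl = gamma * l_seg
        ch, sh = np.cosh(gl), np.sinh(gl)
        a, b = ch, zc * sh
        cc, d = sh / zc, ch
        A, B, C, D = A * a + B * cc, A * b + B * d, C * a + D * cc, C * b + D * d

    z_rad = _radiation_impedance(f, areas[-1], cfg)
    denom = C * z_rad + D
    if np.isfinite(cfg.glottal_resistance_factor):
        zg = cfg.glottal_resistance_factor * rho * c / areas[0]
        denom = denom + (A * z_rad + B) / zg
    with np.errstate(divide="ignore"):
        gain = 20.0 * np.log10(np.abs(1.0 / denom))
    if cfg.normalize:
        gain = gain - gain.max()
    return TransferFunction(grid, gain)


def splice_hybrid(lower_donor: AreaFunction, upper_recipient: AreaFunction) -> AreaFunction:
    """Hybrid area function: donor lower VT joined to recipient upper VT.

    The donor contributes areas from the glottis up to (excluding) its
    ``vallecula_inferior`` junction, the recipient from its junction to the
    lips; arc positions are re-accumulated from segment lengths, with no
    smoothing at the junction.  Side branches (piriform sinuses, valleculae)
    are not represented in the area-function format and are therefore
    implicitly disregarded.  ``splice_hybrid(af, af)`` returns ``af``'s
    samples exactly.
    """
    for name, af in (("lower donor", lower_donor), ("upper recipient", upper_recipient)):
        if "vallecula_inferior" not in af.annotations:
            raise ValueError(f"{name} lacks the vallecula_inferior junction annotation")
    j_d = lower_donor.annotations["vallecula_inferior"]
    j_r = upper_recipient.annotations["vallecula_inferior"]
    lo_mask = lower_donor.positions < j_d
    hi_mask = upper_recipient.positions >= j_r
    shift = j_d - j_r
    positions = np.concatenate([lower_donor.positions[lo_mask],
                                upper_recipient.positions[hi_mask] + shift])
    areas = np.concatenate([lower_donor.areas[lo_mask],
                            upper_recipient.areas[hi_mask]])
    ann = {k: v for k, v in lower_donor.annotations.items() if v < j_d}
    ann["vallecula_inferior"] = j_d
    for k, v in upper_recipient.annotations.items():
        if v > j_r:
            ann[k] = v + shift
    return AreaFunction(positions, areas, ann)


def find_formants(tf: TransferFunction, max_n: int = 5) -> list[tuple[float, float]]:
    """Lowest ``max_n`` strict local maxima of the gain, ascending in Hz.

    Updates ``tf.formants`` in place.  If fewer than ``max_n`` peaks exist,
    the shorter list is returned and ``tf.incomplete`` is set (with a
    warning); a monotone spectrum yields an empty, flagged list.
    """
    g = tf.gain_db
    interior = np.flatnonzero((g[1:-1] > g[:-2]) & (g[1:-1] > g[2:])) + 1
    peaks = [(float(tf.freqs[i]), float(g[i])) for i in interior[:max_n]]
    tf.formants = peaks
    tf.incomplete = len(peaks) < max_n
    if tf.incomplete:
        warnings.warn(f"only {len(peaks)} formant peaks found (wanted {max_n})",
                      stacklevel=2)
    return peaks


def epilarynx_ratio_check(af: AreaFunction, outlet_idx: int,
                          pharynx_idx: int) -> tuple[float, bool]:
    """Outlet-to-pharynx area ratio and its acoustic-decoupling flag.

    When the ratio of the epilaryngeal outlet area to the pharyngeal area at
    the level of the outlet falls below 1:6, the epilarynx-tube resonance
    becomes nearly independent of the rest of the tract.
    """
    ratio = float(af.areas[outlet_idx] / af.areas[pharynx_idx])
    return ratio, ratio < DECOUPLING_RATIO
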