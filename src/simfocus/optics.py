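"""Pupils, PSFs, OTFs and the order decomposition of the lattice pattern.

The excitation side of a lattice light-sheet SIM instrument is modeled as a
set of coherent beams at the back pupil of the excitation objective: an
annular mask (NA ``na_ann_min``..``na_ann_max``) crossed by thin vertical
line segments, one per lattice beam.  The interference of those beams at the
sample forms the structured excitation pattern; its intensity is the squared
magnitude of the Fourier transform of the pupil field.  The detection side
is a widefield objective modeled in the Debye approximation as a spherical
cap of radius ``n_medium / lambda_det`` bounded by ``na_det``.

Axial and lateral displacements of the excitation pattern relative to the
detection focal plane are pure phase ramps in the pupil plane
(:func:`apply_axial_offset`, :func:`apply_lateral_phase`); this is the
mechanism both for simulating misaligned acquisitions and for building
transfer-function libraries at known offsets.

Sign/units conventions (see also :mod:`simfocus._fft`):

* frequencies in cycles/μm; k-radii are ``NA / lambda_vacuum`` and the
  medium index enters only the curvature of the detection cap;
* a positive axial offset ``dz`` translates the excitation pattern toward
  +z (the ramp applied is ``exp(-i 2π kz dz)`` under our inverse-FFT
  frequency->space convention);
* beam positions are snapped to the simulation frequency grid: the snapped
  lateral fundamental ``p_grid`` and axial fundamental ``q_grid`` are the
  frequencies actually present in the simulated pattern and are the values
  used by band shifting and offset bookkeeping.  Axial snapping preserves
  the exact 2:1 ratio of the hexagon's two kz rings so the axial harmonic
  comb n·q is grid-exact.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Tuple

import numpy as np

from ._fft import fft_centered, freq_axis, ifft_centered
from .errors import ConfigurationError, DecompositionError, SamplingError

__all__ = [
    "Lattice",
    "OpticalConfig",
    "LatticeGeometry",
    "Pupil",
    "PSF3D",
    "OTF3D",
    "make_lattice_geometry",
    "make_lattice_pupil",
    "apply_axial_offset",
    "apply_lateral_phase",
    "excitation_psf_from_pupil",
    "excitation_pattern_2d",
    "propagate_along_y",
    "make_detection_psf",
    "detection_otf",
    "decompose_excitation_orders",
    "excitation_axial_profiles",
    "measure_axial_period",
]


class Lattice(str, Enum):
    HEXAGONAL = "hexagonal"
    SQUARE = "square"


@dataclass(frozen=True)
class OpticalConfig:
    """Instrument and simulation-grid description.

    Lengths in μm.  ``grid_shape`` is the camera grid ``(nx, ny, nz)``; the
    forward model runs on a grid upsampled by ``upsample`` along every axis
    (same field of view, finer voxels), then integrates back onto camera
    pixels.
    """

    lambda_exc: float = 0.560
    lambda_det: float = 0.605
    n_medium: float = 1.33
    na_det: float = 1.0
    na_ann_max: float = 0.55
    na_ann_min: float = 0.5
    pattern: Lattice = Lattice.HEXAGONAL
    grid_shape: Tuple[int, int, int] = (128, 32, 128)  # (nx, ny, nz)
    voxel_xy: float = 0.1
    voxel_z: float = 0.1
    upsample: int = 2
    pupil_line_sigma: float = 0.0  # Gaussian transverse (kx) line profile, cycles/μm; 0 = ideal

    def __post_init__(self):
        if not (0 < self.na_ann_min < self.na_ann_max <= self.na_det <= self.n_medium):
            raise ConfigurationError(
                "require 0 < na_ann_min < na_ann_max <= na_det <= n_medium"
            )
        if self.upsample < 1:
            raise ConfigurationError("upsample must be >= 1")
        for n in self.grid_shape:
            if n < 16 or n % 2:
                raise ConfigurationError("grid dims must be even and >= 16")
        if self.lambda_exc <= 0 or self.lambda_det <= 0:
            raise ConfigurationError("wavelengths must be positive")
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ConfigurationError("voxel sizes must be positive")
        Lattice(self.pattern)

    # --- grid helpers (camera grid (nz, ny, nx) order for arrays) ---
    @property
    def camera_shape(self) -> Tuple[int, int, int]:
        nx, ny, nz = self.grid_shape
        return (nz, ny, nx)

    @property
    def sim_shape(self) -> Tuple[int, int, int]:
        nz, ny, nx = self.camera_shape
        u = self.upsample
        return (nz * u, ny * u, nx * u)

    @property
    def sim_voxel_xy(self) -> float:
        return self.voxel_xy / self.upsample

    @property
    def sim_voxel_z(self) -> float:
        return self.voxel_z / self.upsample

    @property
    def dk_x(self) -> float:
        """Lateral frequency step (identical on camera and simulation grids)."""
        return 1.0 / (self.grid_shape[0] * self.voxel_xy)

    @property
    def dk_y(self) -> float:
        return 1.0 / (self.grid_shape[1] * self.voxel_xy)

    @property
    def dk_z(self) -> float:
        return 1.0 / (self.grid_shape[2] * self.voxel_z)

    def config_hash(self) -> str:
        items = sorted(self.__dict__.items())
        blob = ";".join(f"{k}={v}" for k, v in items)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["pattern"] = Lattice(self.pattern).value
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(int(v) for v in d["grid_shape"])
        if "pattern" in d:
            d["pattern"] = Lattice(d["pattern"])
        return cls(**d)


@dataclass(frozen=True)
class LatticeGeometry:
    """Beam positions and harmonic structure of the illumination lattice.

    ``p_fund``/``q_fund`` are the analytic fundamentals; ``p_grid``/``q_grid``
    are the grid-snapped values actually realized by the sampled pupil (the
    ones every downstream shift and period uses).  ``beam_centers`` are the
    snapped ``(kx, kz)`` positions in cycles/μm.
    """

    beam_centers: Tuple[Tuple[float, float], ...]
    p_fund: float
    q_fund: float
    p_grid: float
    q_grid: float
    ip: int            # p_grid in lateral frequency samples
    iq: int            # q_grid in axial frequency samples
    order_table: Dict[int, Tuple[int, ...]]
    m_range: Tuple[int, ...]

    @property
    def t_x(self) -> float:
        return 1.0 / self.p_grid

    @property
    def t_z(self) -> float:
        """Axial period of the lattice pattern (μm)."""
        return 1.0 / self.q_grid

    def dz_to_pi(self, dz_um: float) -> float:
        """Offsets in 'π units': offset_π = 2·δz/T_z (half a period ↔ 1.0)."""
        return 2.0 * dz_um / self.t_z

    def pi_to_dz(self, dz_pi: float) -> float:
        return dz_pi * self.t_z / 2.0


_HEX_ORDER_TABLE = {
    0: (0, 2, -2, 4, -4),
    1: (1, -1, 3, -3),
    -1: (1, -1, 3, -3),
    2: (0, 2, -2),
    -2: (0, 2, -2),
}
# Square lattice (four beams at (0,±k0),(±k0,0)): kx differences 0,±k0,±2k0;
# kz differences per lateral order worked out from the same pair enumeration.
_SQ_ORDER_TABLE = {
    0: (0, 2, -2),
    1: (1, -1),
    -1: (1, -1),
    2: (0,),
    -2: (0,),
}


def make_lattice_geometry(cfg: OpticalConfig) -> LatticeGeometry:
    """Beam layout for the configured lattice, snapped to the simulation grid."""
    na_mid = 0.5 * (cfg.na_ann_min + cfg.na_ann_max)
    k0 = na_mid / cfg.lambda_exc
    if cfg.pattern == Lattice.HEXAGONAL:
        p = (math.sqrt(3.0) / 2.0) * k0
        q = k0 / 2.0
        order_table = dict(_HEX_ORDER_TABLE)
        # hexagon with two vertices on the kz axis
        iq = round(q / cfg.dk_z)
        ip = round(p / cfg.dk_x)
        if iq < 1 or ip < 1:
            raise SamplingError("grid too coarse to resolve the lattice fundamentals")
        centers = []
        for sx, sz in [(0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1)]:
            centers.append((sx * ip * cfg.dk_x, sz * iq * cfg.dk_z))
    elif cfg.pattern == Lattice.SQUARE:
        p = k0
        q = k0 / 2.0
        order_table = dict(_SQ_ORDER_TABLE)
        iq = round(q / cfg.dk_z)
        ip = round(p / cfg.dk_x)
        if iq < 1 or ip < 1:
            raise SamplingError("grid too coarse to resolve the lattice fundamentals")
        centers = [
            (0.0, 2 * iq * cfg.dk_z),
            (0.0, -2 * iq * cfg.dk_z),
            (ip * cfg.dk_x, 0.0),
            (-ip * cfg.dk_x, 0.0),
        ]
    else:  # pragma: no cover - guarded by config validation
        raise ConfigurationError(f"unknown pattern {cfg.pattern}")
    return LatticeGeometry(
        beam_centers=tuple(centers),
        p_fund=p,
        q_fund=q,
        p_grid=ip * cfg.dk_x,
        q_grid=iq * cfg.dk_z,
        ip=ip,
        iq=iq,
        order_table=order_table,
        m_range=(-2, -1, 0, 1, 2),
    )


@dataclass
class Pupil:
    """Complex excitation pupil field over (kz, kx), zero-centered layout."""

    field: np.ndarray                  # complex (nkz, nkx)
    kx_step: float
    kz_step: float
    annulus: Tuple[float, float]       # (na_min, na_max)
    lambda_exc: float

    @property
    def kx(self) -> np.ndarray:
        return freq_axis(self.field.shape[1], 1.0 / (self.field.shape[1] * self.kx_step))

    @property
    def kz(self) -> np.ndarray:
        return freq_axis(self.field.shape[0], 1.0 / (self.field.shape[0] * self.kz_step))


@dataclass
class PSF3D:
    """Real nonnegative intensity distribution, ``(z, y, x)``, zero-centered."""

    values: np.ndarray
    voxel_xy: float
    voxel_z: float
    kind: str  # "excitation" or "detection"


@dataclass
class OTF3D:
    """Complex spectrum over (kz, ky, kx), zero-centered layout."""

    values: np.ndarray
    dk_x: float
    dk_y: float
    dk_z: float


def _pupil_axes(cfg: OpticalConfig):
    nzs, _, nxs = cfg.sim_shape
    kx = freq_axis(nxs, cfg.sim_voxel_xy)
    kz = freq_axis(nzs, cfg.sim_voxel_z)
    return kz, kx


def _annulus_interval(kx_val: float, kz_center: float, k_lo: float, k_hi: float):
    """The kz interval of the annulus, on the column ``kx_val``, containing the beam."""
    if abs(kx_val) > k_hi:
        return None
    hi = math.sqrt(k_hi**2 - kx_val**2)
    if abs(kx_val) < k_lo:
        lo = math.sqrt(k_lo**2 - kx_val**2)
        if kz_center >= 0:
            a, b = lo, hi
        else:
            a, b = -hi, -lo
    else:
        a, b = -hi, hi
    if not (a - 1e-12 <= kz_center <= b + 1e-12):
        return None
    return a, b


def make_lattice_pupil(cfg: OpticalConfig, geom: LatticeGeometry) -> Pupil:
    """Thin vertical line segments through each beam position, inside the annulus.

    Each segment extends along kz symmetrically about its lattice wavevector
    as far as the annulus allows, so the axial spectrum of the pattern stays
    an exact harmonic comb at n·q (an asymmetric chord would split the
    harmonics).  Line width is one lateral frequency sample (idealized plane
    waves) unless ``cfg.pupil_line_sigma`` > 0, in which case each line
    carries a Gaussian transverse profile of that σ (cycles/μm).
    """
    kz, kx = _pupil_axes(cfg)
    k_lo = cfg.na_ann_min / cfg.lambda_exc
    k_hi = cfg.na_ann_max / cfg.lambda_exc
    field = np.zeros((len(kz), len(kx)), dtype=complex)
    cx = len(kx) // 2
    for bx, bz in geom.beam_centers:
        col = cx + round(bx / cfg.dk_x)
        if not (0 <= col < len(kx)):
            raise ConfigurationError("beam falls outside the simulated pupil grid")
        interval = _annulus_interval(kx[col], bz, k_lo, k_hi)
        if interval is None:
            raise ConfigurationError(
                "beam centers fall outside the annulus; check NA settings"
            )
        a, b = interval
        half = min(b - bz, bz - a)
        seg = np.abs(kz - bz) <= half + 1e-12
        seg[np.argmin(np.abs(kz - bz))] = True  # at least the vertex sample
        if cfg.pupil_line_sigma > 0:
            prof = np.exp(-0.5 * ((kx - kx[col]) / cfg.pupil_line_sigma) ** 2)
            field += seg[:, None] * prof[None, :]
        else:
            field[seg, col] += 1.0
    return Pupil(
        field=field,
        kx_step=cfg.dk_x,
        kz_step=cfg.dk_z,
        annulus=(cfg.na_ann_min, cfg.na_ann_max),
        lambda_exc=cfg.lambda_exc,
    )


def apply_axial_offset(pupil: Pupil, dz: float, *, warn_extent: float | None = None) -> Pupil:
    """Translate the excitation pattern by ``dz`` μm along z via a kz phase ramp."""
    if not np.isfinite(dz):
        raise ConfigurationError("dz must be finite")
    if warn_extent is not None and abs(dz) > warn_extent / 2:
        import warnings

        warnings.warn("axial offset exceeds half the grid extent; pattern wraps around")
    ramp = np.exp(-2j * np.pi * pupil.kz * dz)[:, None]
    return Pupil(pupil.field * ramp, pupil.kx_step, pupil.kz_step, pupil.annulus, pupil.lambda_exc)


def apply_lateral_phase(pupil: Pupil, phi: float, geom: LatticeGeometry) -> Pupil:
    """Advance the lateral starting phase by ``phi`` rad (2π = one period T_x)."""
    if not np.isfinite(phi):
        raise ConfigurationError("phi must be finite")
    x0 = (phi / (2.0 * np.pi)) / geom.p_grid
    ramp = np.exp(-2j * np.pi * pupil.kx * x0)[None, :]
    return Pupil(pupil.field * ramp, pupil.kx_step, pupil.kz_step, pupil.annulus, pupil.lambda_exc)


def excitation_pattern_2d(pupil: Pupil) -> np.ndarray:
    """Excitation intensity I(z, x), peak-normalized."""
    amp = ifft_centered(pupil.field)
    inten = np.abs(amp) ** 2
    m = inten.max()
    if m > 0:
        inten /= m
    return inten


def excitation_psf_from_pupil(pupil: Pupil, cfg: OpticalConfig) -> PSF3D:
    """3D excitation PSF: the (z, x) interference pattern replicated along y.

    The light sheet is treated as invariant along the propagation direction
    over the simulated field of view; see :func:`propagate_along_y` for the
    defocused variant.
    """
    inten = excitation_pattern_2d(pupil)
    ny = cfg.sim_shape[1]
    vol = np.repeat(inten[:, None, :], ny, axis=1)
    return PSF3D(vol, cfg.sim_voxel_xy, cfg.sim_voxel_z, kind="excitation")


def propagate_along_y(pupil: Pupil, y_offset: float, cfg: OpticalConfig) -> PSF3D:
    """Excitation PSF a distance ``y_offset`` from the beam waist.

    Angular-spectrum propagation: each pupil sample (kx, kz) is a plane wave
    with ky = sqrt((n/λ)² − kx² − kz²); propagating by y multiplies it by
    exp(i 2π ky y) before the intensity is formed.
    """
    if not np.isfinite(y_offset):
        raise ConfigurationError("y_offset must be finite")
    kzg, kxg = np.meshgrid(pupil.kz, pupil.kx, indexing="ij")
    k_n = cfg.n_medium / cfg.lambda_exc
    ky2 = k_n**2 - kxg**2 - kzg**2
    ky = np.sqrt(np.clip(ky2, 0.0, None))
    prop = np.exp(2j * np.pi * ky * y_offset)
    shifted = Pupil(pupil.field * prop, pupil.kx_step, pupil.kz_step, pupil.annulus, pupil.lambda_exc)
    return excitation_psf_from_pupil(shifted, cfg)


def make_detection_psf(cfg: OpticalConfig) -> PSF3D:
    """Widefield detection PSF in the Debye approximation.

    The amplitude pupil is a spherical cap ('cone in a sphere') of radius
    n/λ_det bounded by na_det, sampled onto the 3D frequency grid; the PSF is
    |FT|² of that cap, normalized to unit sum.
    """
    nzs, nys, nxs = cfg.sim_shape
    kx = freq_axis(nxs, cfg.sim_voxel_xy)
    ky = freq_axis(nys, cfg.sim_voxel_xy)
    kz = freq_axis(nzs, cfg.sim_voxel_z)
    k_n = cfg.n_medium / cfg.lambda_det
    k_na = cfg.na_det / cfg.lambda_det
    if kz.max() < k_n:
        raise SamplingError(
            "axial frequency range cannot contain the detection pupil cap; "
            "decrease voxel_z or increase upsample"
        )
    kyg, kxg = np.meshgrid(ky, kx, indexing="ij")
    kr2 = kxg**2 + kyg**2
    inside = kr2 <= k_na**2
    kz_cap = np.sqrt(np.clip(k_n**2 - kr2, 0.0, None))
    iz = np.round(kz_cap / cfg.dk_z).astype(int) + nzs // 2
    cap = np.zeros((nzs, nys, nxs), dtype=complex)
    yy, xx = np.nonzero(inside)
    cap[iz[yy, xx], yy, xx] = 1.0
    amp = ifft_centered(cap)
    psf = np.abs(amp) ** 2
    psf /= psf.sum()
    return PSF3D(psf, cfg.sim_voxel_xy, cfg.sim_voxel_z, kind="detection")


def detection_otf(psf: PSF3D) -> OTF3D:
    """Widefield (intensity) OTF: Fourier transform of the detection PSF."""
    vals = fft_centered(psf.values)
    nz, ny, nx = psf.values.shape
    return OTF3D(
        vals,
        dk_x=1.0 / (nx * psf.voxel_xy),
        dk_y=1.0 / (ny * psf.voxel_xy),
        dk_z=1.0 / (nz * psf.voxel_z),
    )


def decompose_excitation_orders(
    pupil: Pupil, geom: LatticeGeometry, *, rel_tol: float = 1e-9
) -> Dict[int, np.ndarray]:
    """Split the excitation OTF into lateral orders m -> axial spectrum Ĩ_m(kz).

    The excitation OTF (FT of the intensity pattern, i.e. the autocorrelation
    of the pupil) is supported on discrete kx columns at m·p; each column is
    returned as a 1D complex axial spectrum.  The lateral harmonic attached
    to order m is exp(i 2π m p x) with unit starting phase.
    """
    inten = excitation_pattern_2d(pupil)
    spec = fft_centered(inten)
    nkz, nkx = spec.shape
    cx = nkx // 2
    bands: Dict[int, np.ndarray] = {}
    claimed = np.zeros(nkx, dtype=bool)
    for m in geom.m_range:
        col = cx + m * geom.ip
        if not (0 <= col < nkx):
            raise DecompositionError("order band beyond the lateral Nyquist")
        if claimed[col]:
            raise DecompositionError(
                "lateral order bands overlap in kx; annulus too wide for this grid"
            )
        claimed[col] = True
        bands[m] = spec[:, col].copy()
    resid = spec[:, ~claimed]
    total = np.abs(spec).max()
    if cfg_line_is_ideal(pupil) and np.abs(resid).max() > rel_tol * total:
        raise DecompositionError("unexpected power outside the order bands")
    return bands


def cfg_line_is_ideal(pupil: Pupil) -> bool:
    """True when pupil lines are single-sample (band columns are exact)."""
    occupied = np.abs(pupil.field).sum(axis=0) > 0
    # ideal lines occupy isolated columns
    return not np.any(occupied[:-1] & occupied[1:])


def excitation_axial_profiles(
    pupil: Pupil, geom: LatticeGeometry
) -> Dict[int, np.ndarray]:
    """Real-space axial factors I_m(z) with I(x,z) = Σ_m I_m(z)·e^{i2πmpx}."""
    bands = decompose_excitation_orders(pupil, geom)
    nkx = pupil.field.shape[1]
    # the ortho 2D synthesis carries 1/sqrt(nkx) for the collapsed kx axis
    return {m: ifft_centered(b) / math.sqrt(nkx) for m, b in bands.items()}


def measure_axial_period(pattern_zx: np.ndarray, voxel_z: float, *, rel_peak: float = 0.02) -> float:
    """Measure the axial period of an excitation pattern I(z, x).

    The period of a z-periodic pattern is 1/(its fundamental axial
    frequency).  The per-column axial power spectra are averaged over x (so
    that harmonics carried by every lateral order contribute), local maxima
    above ``rel_peak`` of the strongest non-DC peak are located, and the
    period of the lowest-frequency one is returned.
    """
    spec = np.abs(fft_centered(pattern_zx, axes=(0,))) ** 2
    pw = spec.mean(axis=1)
    n = pw.size
    c = n // 2
    pos = pw[c + 1 :]  # positive-frequency half, DC excluded
    if pos.max() <= 0:
        raise SamplingError("pattern has no axial modulation")
    interior = pos[1:-1]
    is_max = (interior > pos[:-2]) & (interior >= pos[2:])
    idx = np.nonzero(is_max & (interior >= rel_peak * pos.max()))[0] + 1
    if idx.size == 0:
        raise SamplingError("no axial modulation peak found")
    # pos[i] holds frequency (i + 1)·dk
    k_fund = (idx.min() + 1) / (n * voxel_z)
    return 1.0 / k_fund
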