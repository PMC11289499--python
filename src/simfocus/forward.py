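"""Forward image formation: phase-stepped raw stacks and transfer functions.

A raw latticeSIM acquisition collects, for every z plane, one camera image
per lateral phase step of the excitation pattern.  With the order
decomposition of the pattern, each phase image is

    D_j(r) = Σ_m [(H · I_m,dz) ⊗ (S · J_m,φj)](r),

where H is the detection PSF, I_m(z) the axial factor of lateral order m
(carrying the applied axial offset dz as a phase ramp), S the sample and
J_m(x) = exp(i·2π·m·p·x) the lateral harmonic at starting phase φj.  The
simulation runs on a grid upsampled by ``cfg.upsample`` and is block-mean
integrated onto camera pixels, emulating detector discretization.

Transfer functions are the same quantities for a point sample: the
calibration identity  O'_m = FT{H(r) · I_m,dz'(z)}  (band-separated image of
a centered bead, lateral phase zero) anchors the offset retrieval.

Boundaries are periodic (FFT-native); bead placement keeps a two-axial-period
guard margin so detection tails do not wrap through the beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._fft import block_downsample, fft_centered, hermitian_conjugate, ifft_centered
from .errors import ConfigurationError, PlacementError, SimfocusError
from .optics import (
    LatticeGeometry,
    OpticalConfig,
    PSF3D,
    apply_axial_offset,
    excitation_axial_profiles,
    make_detection_psf,
    make_lattice_geometry,
    make_lattice_pupil,
)

__all__ = [
    "SampleVolume",
    "AcquisitionParams",
    "RawSIMStack",
    "TransferFunctionSet",
    "TFLibrary",
    "ForwardSimulator",
    "generate_beads",
    "simulate_raw_stack",
    "add_gaussian_noise",
    "simulate_tf_set",
    "build_tf_library",
]


@dataclass
class SampleVolume:
    """Nonnegative sample density S(r) on the simulation grid, (z, y, x)."""

    values: np.ndarray
    voxel_xy: float
    voxel_z: float
    positions: Optional[np.ndarray] = None  # (n, 3) voxel indices of point emitters

    def __post_init__(self):
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ConfigurationError("sample values must be finite and nonnegative")


def default_phases(n: int = 5) -> Tuple[float, ...]:
    return tuple(2.0 * np.pi * j / n for j in range(n))


@dataclass
class AcquisitionParams:
    """Acquisition settings for one simulated stack."""

    n_phases: int = 5
    phase_list: Optional[Tuple[float, ...]] = None
    applied_dz: float = 0.0      # μm, axial offset of the excitation pattern
    applied_phi: float = 0.0     # rad, extra lateral starting phase
    snr: Optional[float] = None  # peak-signal / noise-sigma; None = noise-free
    seed: int = 0

    def phases(self) -> Tuple[float, ...]:
        ph = self.phase_list if self.phase_list is not None else default_phases(self.n_phases)
        if len(ph) != self.n_phases:
            raise ConfigurationError("phase_list length must equal n_phases")
        wrapped = np.mod(ph, 2 * np.pi)
        if np.min(np.abs(np.subtract.outer(wrapped, wrapped))[~np.eye(len(ph), dtype=bool)]) < 1e-9:
            raise ConfigurationError("phase steps must be distinct modulo 2π")
        return tuple(ph)


@dataclass
class RawSIMStack:
    """Phase-stepped raw data, ``values`` shaped (phase, z, y, x), float32."""

    values: np.ndarray
    voxel_xy: float
    voxel_z: float
    meta: dict = field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return self.values.shape[0]


@dataclass
class TransferFunctionSet:
    """Per-order transfer functions O'_m(k) tagged with their axial offset.

    Orders m = 0, 1, 2 are stored; negative orders follow from Hermitian
    symmetry of the real-valued point image, O'_{-m}(k) = conj(O'_m(-k)).
    """

    otfs: Dict[int, np.ndarray]
    dz_um: float
    dz_pi: float
    config_hash: str

    def get(self, m: int) -> np.ndarray:
        if m in self.otfs:
            return self.otfs[m]
        if -m in self.otfs:
            return hermitian_conjugate(self.otfs[-m])
        raise KeyError(m)


@dataclass
class TFLibrary:
    """A gallery of transfer-function sets over a grid of axial offsets."""

    entries: List[TransferFunctionSet]
    config_hash: str
    geometry: LatticeGeometry

    @property
    def dz_um(self) -> np.ndarray:
        return np.array([e.dz_um for e in self.entries])

    @property
    def dz_pi(self) -> np.ndarray:
        return np.array([e.dz_pi for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


class ForwardSimulator:
    """Caches the pupil, geometry and detection PSF for repeated simulations."""

    def __init__(self, cfg: OpticalConfig, detection_psf: Optional[PSF3D] = None):
        self.cfg = cfg
        self.geom = make_lattice_geometry(cfg)
        self.pupil = make_lattice_pupil(cfg, self.geom)
        self.det_psf = detection_psf if detection_psf is not None else make_detection_psf(cfg)
        self._x = (np.arange(cfg.sim_shape[2]) - cfg.sim_shape[2] // 2) * cfg.sim_voxel_xy

    # ------------------------------------------------------------------ samples
    def random_beads(self, n_beads: int, seed: int, min_sep: float = 0.5) -> SampleVolume:
        """Random point emitters with the guard margins the forward model assumes."""
        cfg = self.cfg
        extent_z = cfg.sim_shape[0] * cfg.sim_voxel_z
        return generate_beads(
            n_beads,
            cfg.sim_shape,
            min_sep,
            seed,
            voxel_xy=cfg.sim_voxel_xy,
            voxel_z=cfg.sim_voxel_z,
            # two axial periods of guard, capped so small grids keep an interior
            margin_z=min(2.0 * self.geom.t_z, 0.3 * extent_z),
            margin_xy=0.3,
        )

    def centered_delta(self) -> SampleVolume:
        cfg = self.cfg
        vol = np.zeros(cfg.sim_shape)
        vol[cfg.sim_shape[0] // 2, cfg.sim_shape[1] // 2, cfg.sim_shape[2] // 2] = 1.0
        return SampleVolume(vol, cfg.sim_voxel_xy, cfg.sim_voxel_z)

    # ------------------------------------------------------------- building blocks
    def axial_profiles(self, dz_um: float) -> Dict[int, np.ndarray]:
        """I_m(z) on the simulation grid with the axial offset applied."""
        pup = apply_axial_offset(
            self.pupil, dz_um, warn_extent=self.cfg.sim_shape[0] * self.cfg.sim_voxel_z
        )
        return excitation_axial_profiles(pup, self.geom)

    def _order_transfer_spectra(self, dz_um: float, orders) -> Dict[int, np.ndarray]:
        """FT{H(r)·I_m(z)} per order on the (upsampled) simulation grid."""
        prof = self.axial_profiles(dz_um)
        H = self.det_psf.values
        return {m: fft_centered(H * prof[m][:, None, None]) for m in orders}

    # ------------------------------------------------------------------ raw stacks
    def simulate_stack(
        self,
        sample: SampleVolume,
        acq: AcquisitionParams,
        *,
        p_override: Optional[float] = None,
    ) -> RawSIMStack:
        """Simulate the phase-stepped raw stack of ``sample``.

        ``p_override`` replaces the lateral pattern frequency used for the
        sample-side harmonics J_m (the pattern-frequency estimator's test
        hook); the default is the grid-snapped geometry value.
        """
        cfg = self.cfg
        if sample.values.shape != cfg.sim_shape:
            raise ConfigurationError(
                f"sample shape {sample.values.shape} != simulation grid {cfg.sim_shape}"
            )
        p = self.geom.p_grid if p_override is None else p_override
        orders = self.geom.m_range
        T = self._order_transfer_spectra(acq.applied_dz, orders)
        U = {
            m: fft_centered(sample.values * np.exp(2j * np.pi * m * p * self._x)[None, None, :])
            for m in orders
        }
        phases = acq.phases()
        out = np.empty((acq.n_phases,) + cfg.camera_shape, dtype=np.float32)
        peak = 0.0
        for j, ph in enumerate(phases):
            phi = ph + acq.applied_phi
            spec = np.zeros(cfg.sim_shape, dtype=complex)
            for m in orders:
                spec += np.exp(1j * m * phi) * (T[m] * U[m])
            img = ifft_centered(spec)
            if not np.all(np.isfinite(img)):
                raise SimfocusError("non-finite intermediate in forward simulation")
            real = img.real
            peak = max(peak, float(real.max()))
            if real.min() < -1e-9 * max(real.max(), 1e-30):
                raise SimfocusError("forward model produced significantly negative intensity")
            cam = block_downsample(np.clip(real, 0.0, None), cfg.upsample)
            out[j] = cam.astype(np.float32)
        stack = RawSIMStack(
            out,
            cfg.voxel_xy,
            cfg.voxel_z,
            meta={
                "applied_dz_um": acq.applied_dz,
                "applied_dz_pi": self.geom.dz_to_pi(acq.applied_dz),
                "applied_phi": acq.applied_phi,
                "snr": acq.snr,
                "seed": acq.seed,
                "phases": list(phases),
                "config_hash": cfg.config_hash(),
            },
        )
        if acq.snr is not None:
            stack = add_gaussian_noise(stack, acq.snr, acq.seed)
        return stack

    # ------------------------------------------------------------- transfer functions
    def tf_set(self, dz_um: float) -> TransferFunctionSet:
        """Calibration transfer functions O'_m (m = 0..2) at offset ``dz_um``."""
        cfg = self.cfg
        prof = self.axial_profiles(dz_um)
        H = self.det_psf.values
        otfs = {}
        for m in (0, 1, 2):
            cam = block_downsample(H * prof[m][:, None, None], cfg.upsample)
            otfs[m] = fft_centered(cam)
        return TransferFunctionSet(
            otfs=otfs,
            dz_um=dz_um,
            dz_pi=self.geom.dz_to_pi(dz_um),
            config_hash=cfg.config_hash(),
        )

    def tf_library(
        self,
        dz_pi: Optional[Sequence[float]] = None,
        dz_um: Optional[Sequence[float]] = None,
    ) -> TFLibrary:
        """Gallery of TF sets; default grid ±1.0 π in 0.1 π steps."""
        if dz_um is None:
            if dz_pi is None:
                dz_pi = np.round(np.linspace(-1.0, 1.0, 21), 6)
            dz_um = [self.geom.pi_to_dz(v) for v in dz_pi]
        entries = [self.tf_set(v) for v in dz_um]
        return TFLibrary(entries, self.cfg.config_hash(), self.geom)


# ---------------------------------------------------------------- module-level ops

def generate_beads(
    n_beads: int,
    shape: Tuple[int, int, int],
    min_sep: float,
    seed: int,
    *,
    voxel_xy: float = 0.05,
    voxel_z: float = 0.05,
    margin_z: float = 0.0,
    margin_xy: float = 0.0,
    max_tries: int = 10000,
) -> SampleVolume:
    """Unit-intensity point emitters at uniform random voxels, ``min_sep`` apart (μm)."""
    if n_beads < 1:
        raise ConfigurationError("n_beads must be >= 1")
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    mz = int(np.ceil(margin_z / voxel_z))
    mxy = int(np.ceil(margin_xy / voxel_xy))
    lo = np.array([mz, mxy, mxy])
    hi = np.array([nz - mz, ny - mxy, nx - mxy])
    if np.any(hi - lo < 1):
        raise PlacementError("margins leave no room for beads")
    scale = np.array([voxel_z, voxel_xy, voxel_xy])
    placed: List[np.ndarray] = []
    tries = 0
    while len(placed) < n_beads:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n_beads} beads with min_sep={min_sep} μm"
            )
        tries += 1
        cand = rng.integers(lo, hi)
        if all(np.linalg.norm((cand - p) * scale) >= min_sep for p in placed):
            placed.append(cand)
    vol = np.zeros(shape)
    for p in placed:
        vol[tuple(p)] = 1.0
    return SampleVolume(vol, voxel_xy, voxel_z, positions=np.array(placed))


def simulate_raw_stack(
    sample: SampleVolume, cfg: OpticalConfig, acq: AcquisitionParams, **kw
) -> RawSIMStack:
    return ForwardSimulator(cfg).simulate_stack(sample, acq, **kw)


def add_gaussian_noise(stack: RawSIMStack, snr: float, seed: int) -> RawSIMStack:
    """Additive zero-mean Gaussian noise with σ = peak signal / snr."""
    if snr <= 0:
        raise ConfigurationError("snr must be positive")
    sigma = float(stack.values.max()) / snr
    rng = np.random.default_rng(seed)
    noisy = stack.values + rng.normal(0.0, sigma, stack.values.shape).astype(np.float32)
    meta = dict(stack.meta)
    meta.update({"snr": snr, "noise_sigma": sigma, "noise_seed": seed})
    return RawSIMStack(noisy.astype(np.float32), stack.voxel_xy, stack.voxel_z, meta)


def simulate_tf_set(cfg: OpticalConfig, dz_prime: float) -> TransferFunctionSet:
    return ForwardSimulator(cfg).tf_set(dz_prime)


def build_tf_library(cfg: OpticalConfig, dz_pi=None, dz_um=None) -> TFLibrary:
    return ForwardSimulator(cfg).tf_library(dz_pi=dz_pi, dz_um=dz_um)
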