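"""Shared fixtures: a small fast optical configuration for unit/property
tests, the full default configuration for the acceptance suite, and an
analytic pure-harmonic scene builder used to check the residual-phase
algebra in closed form."""

from __future__ import annotations

import numpy as np
import pytest

from simfocus import (
    AcquisitionParams,
    ForwardSimulator,
    OpticalConfig,
    SampleVolume,
)
from simfocus.bands import SeparatedBands
from simfocus.forward import TransferFunctionSet


@pytest.fixture(scope="session")
def small_cfg() -> OpticalConfig:
    """64×16×64 camera grid: same voxel sizes and axial period as the default."""
    return OpticalConfig(grid_shape=(64, 16, 64))


@pytest.fixture(scope="session")
def small_sim(small_cfg) -> ForwardSimulator:
    return ForwardSimulator(small_cfg)


@pytest.fixture(scope="session")
def small_lib(small_sim):
    """Transfer-function library, ±1.0 π at 0.1 π spacing."""
    return small_sim.tf_library()


@pytest.fixture(scope="session")
def stack_cache(small_sim):
    """Memoized noise-free bead stacks keyed by (n_beads, seed, dz_pi, phi)."""
    cache = {}

    def build(n_beads=8, seed=3, dz_pi=-0.4, phi=0.0):
        key = (n_beads, seed, round(dz_pi, 6), round(phi, 6))
        if key not in cache:
            beads = small_sim.random_beads(n_beads, seed=seed)
            acq = AcquisitionParams(
                applied_dz=small_sim.geom.pi_to_dz(dz_pi), applied_phi=phi
            )
            cache[key] = (small_sim.simulate_stack(beads, acq), beads)
        return cache[key]

    return build


@pytest.fixture(scope="session")
def default_cfg() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def default_sim(default_cfg) -> ForwardSimulator:
    return ForwardSimulator(default_cfg)


@pytest.fixture(scope="session")
def default_lib(default_sim):
    return default_sim.tf_library()


def gaussian_envelope(shape, dk_z, sigma_kz=0.6):
    """Smooth detection-like spectral envelope centered at k = 0."""
    nz, ny, nx = shape
    kz = (np.arange(nz) - nz // 2) * dk_z
    gz = np.exp(-0.5 * (kz / sigma_kz) ** 2)
    gy = np.exp(-0.5 * ((np.arange(ny) - ny // 2) / (ny / 5)) ** 2)
    gx = np.exp(-0.5 * ((np.arange(nx) - nx // 2) / (nx / 5)) ** 2)
    return gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def make_harmonic_scene(
    dz_data: float,
    dz_tf: float,
    phi: float = 0.0,
    *,
    shape=(64, 8, 16),
    q: float = 0.46875,
    dk_z: float = 0.15625,
    n_table={0: (0,), 1: (1,), 2: (2,)},
):
    """Bands and TFs with a single pure axial harmonic per order.

    Each order m is one delta harmonic at kz = n·q times a smooth envelope;
    the axial offset enters as the phase exp(-i·2π·n·q·dz) and the data
    bands carry exp(i·m·φ).  Lateral shifting is disabled (p = 0) so the
    overlap algebra can be checked in closed form.
    """
    env = gaussian_envelope(shape, dk_z)
    nz = shape[0]

    def one(dz, with_phi):
        out = {}
        for m, ns in n_table.items():
            band = np.zeros(shape, dtype=complex)
            for n in ns:
                steps = int(round(n * q / dk_z))
                band += np.roll(env, steps, axis=0) * np.exp(-2j * np.pi * n * q * dz)
            if with_phi:
                band *= np.exp(1j * m * phi)
            out[m] = band
        return out

    bands = SeparatedBands(
        bands=one(dz_data, True),
        p_used=0.0,
        dk_x=0.15625,
        phases=tuple(2 * np.pi * j / 5 for j in range(5)),
    )
    tf = TransferFunctionSet(otfs=one(dz_tf, False), dz_um=dz_tf, dz_pi=0.0, config_hash="toy")
    return bands, tf
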