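"""Pupil construction, PSF/OTF properties and the order decomposition."""

import numpy as np
import pytest

from simfocus._fft import fft_centered, hermitian_conjugate, ifft_centered
from simfocus.errors import ConfigurationError
from simfocus.optics import (
    Lattice,
    OpticalConfig,
    apply_axial_offset,
    apply_lateral_phase,
    decompose_excitation_orders,
    detection_otf,
    excitation_pattern_2d,
    make_detection_psf,
    make_lattice_geometry,
    make_lattice_pupil,
    measure_axial_period,
    propagate_along_y,
)


@pytest.mark.parametrize(
    "kw",
    [
        {"na_ann_min": 0.6, "na_ann_max": 0.55},          # inverted annulus
        {"na_det": 1.4},                                   # NA above medium index
        {"grid_shape": (14, 16, 64)},                      # too small / odd
        {"grid_shape": (63, 16, 64)},
        {"upsample": 0},
        {"voxel_xy": -0.1},
    ],
)
def test_config_validation_rejects_bad_settings(kw):
    with pytest.raises(ConfigurationError):
        OpticalConfig(**kw)


class TestGeometry:
    def test_hexagonal_periods_match_instrument(self, small_cfg):
        geom = make_lattice_geometry(small_cfg)
        # T_z = 2 λ_exc / NA_mid for the hexagon with two beams on the kz axis
        assert geom.t_z == pytest.approx(2 * 0.560 / 0.525, rel=1e-9)
        assert geom.t_z == pytest.approx(2.13, rel=0.005)
        assert set(geom.order_table[0]) == {0, 2, -2, 4, -4}
        assert set(geom.order_table[1]) == {1, -1, 3, -3}
        assert set(geom.order_table[2]) == {0, 2, -2}

    def test_square_lattice_beam_differences(self, small_cfg):
        cfg = OpticalConfig(**{**small_cfg.__dict__, "pattern": Lattice.SQUARE})
        geom = make_lattice_geometry(cfg)
        k0 = geom.p_grid
        kxs = [b[0] for b in geom.beam_centers]
        diffs = {round((a - b) / k0, 6) for a in kxs for b in kxs}
        assert diffs == {-2.0, -1.0, 0.0, 1.0, 2.0}

    def test_pi_unit_conversion_roundtrip(self, small_cfg):
        geom = make_lattice_geometry(small_cfg)
        assert geom.dz_to_pi(geom.pi_to_dz(0.4)) == pytest.approx(0.4, abs=1e-12)
        # half an axial period is 1.0 in π units
        assert geom.dz_to_pi(geom.t_z / 2) == pytest.approx(1.0, abs=1e-12)


class TestDetectionPSF:
    @pytest.fixture(scope="class")
    def psf(self, small_cfg):
        return make_detection_psf(small_cfg)

    def test_peak_centered_and_symmetric(self, psf):
        v = psf.values
        c = tuple(s // 2 for s in v.shape)
        assert np.unravel_index(np.argmax(v), v.shape) == c
        # H(x,y,z) = H(-x,-y,z) for a rotationally symmetric pupil
        flipped = np.roll(np.flip(v, axis=(1, 2)), 1, axis=(1, 2))
        assert np.allclose(v, flipped, rtol=0, atol=1e-9 * v.max())
        assert v.min() >= 0 and np.isfinite(v).all()

    def test_lateral_cutoff_matches_pupil_autocorrelation(self, psf, small_cfg):
        """Intensity-OTF lateral support ends at the autocorrelation width of
        the amplitude cap, 2·NA/λ (independent oracle: the cap's max lateral
        radius is NA/λ, so its autocorrelation support is twice that)."""
        otf = detection_otf(psf)
        mag = np.abs(otf.values)
        nz, ny, nx = mag.shape
        kx = (np.arange(nx) - nx // 2) * otf.dk_x
        ky = (np.arange(ny) - ny // 2) * otf.dk_y
        kr = np.sqrt(kx[None, :] ** 2 + ky[:, None] ** 2)
        cutoff = 2 * small_cfg.na_det / small_cfg.lambda_det
        beyond = mag[:, kr > cutoff + 2 * otf.dk_x]
        assert beyond.max() < 1e-6 * mag.max()
        inside = mag[:, kr < 0.5 * cutoff]
        assert inside.max() > 1e-3 * mag.max()

    def test_otf_hermitian_symmetry(self, psf):
        otf = detection_otf(psf).values
        assert np.allclose(
            otf, hermitian_conjugate(otf), rtol=0, atol=1e-9 * np.abs(otf).max()
        )


class TestLatticePupil:
    def test_six_segments_and_centrosymmetry(self, small_cfg):
        geom = make_lattice_geometry(small_cfg)
        pup = make_lattice_pupil(small_cfg, geom)
        f = np.abs(pup.field) > 0
        # count connected runs per occupied column
        segments = 0
        for col in np.nonzero(f.any(axis=0))[0]:
            runs = np.diff(np.concatenate(([0], f[:, col].astype(int), [0])))
            segments += int((runs == 1).sum())
        assert segments == 6
        flipped = np.roll(np.flip(pup.field.real, axis=(0, 1)), 1, axis=(0, 1))
        assert np.allclose(pup.field.real, flipped)
        assert np.allclose(pup.field.imag, 0)

    def test_wider_annulus_grows_support(self, small_cfg):
        geom = make_lattice_geometry(small_cfg)
        narrow = make_lattice_pupil(small_cfg, geom)
        wide_cfg = OpticalConfig(**{**small_cfg.__dict__, "na_ann_min": 0.05})
        wide = make_lattice_pupil(wide_cfg, make_lattice_geometry(wide_cfg))
        assert np.count_nonzero(wide.field) > np.count_nonzero(narrow.field)

    def test_parseval(self, small_cfg):
        geom = make_lattice_geometry(small_cfg)
        pup = make_lattice_pupil(small_cfg, geom)
        e_k = np.sum(np.abs(pup.field) ** 2)
        e_r = np.sum(np.abs(ifft_centered(pup.field)) ** 2)
        assert e_r == pytest.approx(e_k, rel=1e-9)


class TestOffsetsAndPhases:
    @pytest.fixture(scope="class")
    def pupil(self, small_cfg):
        return make_lattice_pupil(small_cfg, make_lattice_geometry(small_cfg))

    def test_zero_offset_identity(self, pupil, small_cfg):
        assert np.array_equal(apply_axial_offset(pupil, 0.0).field, pupil.field)
        geom = make_lattice_geometry(small_cfg)
        assert np.array_equal(apply_lateral_phase(pupil, 0.0, geom).field, pupil.field)

    def test_offset_then_inverse_restores(self, pupil):
        back = apply_axial_offset(apply_axial_offset(pupil, 0.3), -0.3)
        assert np.allclose(back.field, pupil.field, atol=1e-12)

    def test_grid_multiple_offset_translates_pattern(self, pupil, small_cfg):
        dz = 7 * small_cfg.sim_voxel_z
        pat0 = excitation_pattern_2d(pupil)
        pat = excitation_pattern_2d(apply_axial_offset(pupil, dz))
        assert np.allclose(pat, np.roll(pat0, 7, axis=0), atol=1e-9)

    def test_subgrid_offset_peaks_at_expected_lag(self, pupil, small_cfg):
        """Cross-correlation oracle: a 0.2·T_z offset moves the pattern's
        axial cross-correlation peak to lag 0.2·T_z (within one voxel)."""
        geom = make_lattice_geometry(small_cfg)
        dz = 0.2 * geom.t_z
        pat0 = excitation_pattern_2d(pupil)
        pat = excitation_pattern_2d(apply_axial_offset(pupil, dz))
        a = pat0 - pat0.mean()
        b = pat - pat.mean()
        fa = np.fft.fft(a, axis=0)
        fb = np.fft.fft(b, axis=0)
        xc = np.fft.ifft(np.conj(fa) * fb, axis=0).real.sum(axis=1)
        lag = np.argmax(xc)
        if lag > len(xc) // 2:
            lag -= len(xc)
        # the pattern is periodic: the lag is defined modulo T_z
        expect = dz / small_cfg.sim_voxel_z
        period = geom.t_z / small_cfg.sim_voxel_z
        residual = (lag - expect + period / 2) % period - period / 2
        assert abs(residual) <= 1.0

    def test_lateral_phase_period_and_step(self, pupil, small_cfg):
        geom = make_lattice_geometry(small_cfg)
        pat0 = excitation_pattern_2d(pupil)
        full = excitation_pattern_2d(apply_lateral_phase(pupil, 2 * np.pi, geom))
        assert np.allclose(full, pat0, atol=1e-7)
        # one of five phase steps moves the pattern by T_x/5 (≈ 0.24 μm class)
        fifth = excitation_pattern_2d(apply_lateral_phase(pupil, 2 * np.pi / 5, geom))
        a = pat0 - pat0.mean()
        b = fifth - fifth.mean()
        xc = np.fft.ifft(np.conj(np.fft.fft(a, axis=1)) * np.fft.fft(b, axis=1), axis=1)
        lag = np.argmax(xc.real.sum(axis=0))
        expect = geom.t_x / 5 / small_cfg.sim_voxel_xy
        period = geom.t_x / small_cfg.sim_voxel_xy
        # shift direction is a package sign convention; magnitude is T_x/5 mod T_x
        residual = min(
            abs((lag - s * expect + period / 2) % period - period / 2) for s in (1, -1)
        )
        assert residual <= 1.0


class TestExcitationPattern:
    def test_axial_period_matches_fundamental(self, small_sim, small_cfg):
        pat = excitation_pattern_2d(small_sim.pupil)
        period = measure_axial_period(pat, small_cfg.sim_voxel_z)
        assert period == pytest.approx(small_sim.geom.t_z, abs=small_cfg.sim_voxel_z)

    def test_x_averaged_profile_has_flanking_lobes(self, small_sim):
        """Central peak flanked by side lobes of similar magnitude half a
        period away — the structure that makes the half-period twin minimum."""
        pat = excitation_pattern_2d(small_sim.pupil)
        prof = pat.mean(axis=1)
        c = np.argmax(prof)
        half = int(round(small_sim.geom.t_z / 2 / small_sim.cfg.sim_voxel_z))
        side = max(prof[c - half], prof[c + half])
        assert side > 0.5 * prof[c]

    def test_single_beam_gives_uniform_intensity(self, small_cfg):
        geom = make_lattice_geometry(small_cfg)
        pup = make_lattice_pupil(small_cfg, geom)
        single = pup.field.copy()
        cols = np.nonzero(np.abs(single).any(axis=0))[0]
        single[:, cols[1:]] = 0
        rows = np.nonzero(np.abs(single[:, cols[0]]))[0]
        single[rows[1:], cols[0]] = 0  # exactly one plane wave
        pup.field = single
        pat = excitation_pattern_2d(pup)
        assert pat.std() < 1e-12 * pat.max()

    def test_decomposition_partition_and_emergent_orders(self, small_sim):
        geom = small_sim.geom
        pup = small_sim.pupil
        bands = decompose_excitation_orders(pup, geom)
        assert sorted(bands) == [-2, -1, 0, 1, 2]
        assert all(np.abs(b).max() > 0 for b in bands.values())
        # n(m) support is emergent: numerical peak positions match the table
        for m in (0, 1, 2):
            mag = np.abs(bands[m])
            c = len(mag) // 2
            found = {
                int((i - c) / geom.iq)
                for i in np.nonzero(mag > 1e-9 * mag.max())[0]
            }
            assert found == set(geom.order_table[m])
        # partition: reassembled bands reproduce the excitation OTF exactly
        pat = excitation_pattern_2d(pup)
        spec = fft_centered(pat)
        re = np.zeros_like(spec)
        cx = spec.shape[1] // 2
        for m, b in bands.items():
            re[:, cx + m * geom.ip] = b
        assert np.abs(re - spec).max() <= 1e-9 * np.abs(spec).max()


class TestPropagation:
    @pytest.fixture(scope="class")
    def long_cfg(self):
        # finer dk_z so the annulus gives beams a real kz extent (needed for
        # defocus to act: single-sample beams are propagation invariant)
        return OpticalConfig(grid_shape=(64, 16, 256))

    def test_zero_and_symmetric_offsets(self, long_cfg):
        geom = make_lattice_geometry(long_cfg)
        pup = make_lattice_pupil(long_cfg, geom)
        from simfocus.optics import excitation_psf_from_pupil

        base = excitation_psf_from_pupil(pup, long_cfg)
        at0 = propagate_along_y(pup, 0.0, long_cfg)
        assert np.allclose(at0.values, base.values, atol=1e-12)
        plus = propagate_along_y(pup, 4.0, long_cfg)
        minus = propagate_along_y(pup, -4.0, long_cfg)
        assert np.allclose(plus.values, minus.values, atol=1e-9)

    def test_defocus_reduces_modulation_depth(self, long_cfg):
        geom = make_lattice_geometry(long_cfg)
        pup = make_lattice_pupil(long_cfg, geom)

        pat0 = excitation_pattern_2d(pup)
        pat10 = propagate_along_y(pup, 10.0, long_cfg).values[:, 0, :]
        # fringe contrast (std/mean) drops away from the beam waist
        assert pat10.std() / pat10.mean() < pat0.std() / pat0.mean()
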