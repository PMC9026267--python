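"""Ewald-cap mapping, spectrum inversion, and the composed pipeline."""

import math

import numpy as np
import numpy.fft as fft
import pytest

import sixpacktomo as st
from sixpacktomo.demux import RytovField
from sixpacktomo.odt import EwaldSpectrum


def _rytov_fields(geometry, frames, channels):
    waves = st.demultiplex(frames["sample"][0])
    bgs = st.demultiplex(frames["background"][0])
    out = []
    for k in channels:
        out.append(st.extract_rytov(waves[k - 1], bgs[k - 1]))
    return out


class TestMapEwald:
    def test_deposits_lie_on_the_ewald_shell(self, geometry, frames):
        """Every filled voxel satisfies |K + k_i| = k_m to half a voxel."""
        g = geometry
        fields = _rytov_fields(g, frames, [1])
        spec = st.map_ewald(fields, g["illum"], g["optics"], grid_n=64,
                            hermitian=False)
        km = g["optics"].k_medium
        k_i = km * g["illum"].angles[0].direction_medium(g["optics"].n_medium)
        n3 = 64
        idx = np.argwhere(spec.counts > 0)
        freqs = (np.where(idx > n3 // 2, idx - n3, idx)) * spec.dk
        radius = np.linalg.norm(freqs + k_i, axis=1)
        assert np.all(np.abs(radius - km) <= spec.dk * math.sqrt(3) / 2 + 1e-12)

    def test_repeat_deposition_is_idempotent_on_average(self, geometry, frames):
        g = geometry
        fields = _rytov_fields(g, frames, [1])
        once = st.map_ewald(fields, g["illum"], g["optics"], grid_n=64)
        twice = st.map_ewald(fields + fields, g["illum"], g["optics"], grid_n=64)
        assert np.array_equal(twice.counts, 2 * once.counts)
        assert np.allclose(twice.averaged(), once.averaged())

    def test_twelve_channel_support_contains_six_channel(self, geometry, frames):
        g = geometry
        waves = st.demultiplex(frames["sample"][0])
        bgs = st.demultiplex(frames["background"][0])
        cam2 = st.MultiplexedHologram(
            st.register_second_camera(frames["sample"][1].data),
            frames["sample"][1].pixel_pitch_um, 8, 2, g["layout"])
        bg2 = st.MultiplexedHologram(
            st.register_second_camera(frames["background"][1].data),
            frames["background"][1].pixel_pitch_um, 8, 2, g["layout"])
        waves += st.demultiplex(cam2, channel_offset=6)
        bgs += st.demultiplex(bg2, channel_offset=6)
        fields = [st.extract_rytov(w, b) for w, b in zip(waves, bgs)]
        s6 = st.map_ewald(fields[:6], g["illum"], g["optics"], grid_n=64)
        s12 = st.map_ewald(fields, g["illum"], g["optics"], grid_n=64)
        assert np.all(s12.support[s6.support])
        assert s12.support.sum() > s6.support.sum()

    def test_unknown_channel_rejected(self, geometry, frames):
        g = geometry
        f = _rytov_fields(g, frames, [1])[0]
        bad = RytovField(f.data, channel=99)
        with pytest.raises(ValueError, match="channel"):
            st.map_ewald([bad], g["illum"], g["optics"], grid_n=32)


class TestInvertSpectrum:
    def test_empty_spectrum_gives_uniform_medium(self, optics):
        spec = EwaldSpectrum(np.zeros((32,) * 3, complex),
                             np.zeros((32,) * 3, np.int64), 0.1,
                             optics.k_medium)
        vol = st.invert_spectrum(spec, optics)
        assert np.allclose(vol.grid, optics.n_medium, atol=1e-12)

    def test_full_coverage_weak_sphere_recovered(self, optics):
        """Analytic full-coverage spectrum inverts to the phantom (<5% of Δn)."""
        n3, dv, dn = 64, 0.1, 0.005
        phan = st.make_sphere_phantom((n3,) * 3, dv, (3.2,) * 3, 1.2,
                                      optics.n_medium + dn, optics.n_medium)
        k0 = 2 * math.pi / optics.wavelength_um
        f = 2 * optics.n_medium * k0 ** 2 * (phan.grid - optics.n_medium)
        # the inverse expects the axial origin at the volume center plane
        F = fft.fftn(np.roll(f, -(n3 // 2), axis=2)) * dv ** 3
        spec = EwaldSpectrum(F, np.ones((n3,) * 3, np.int64), 1.0 / (n3 * dv),
                             optics.k_medium)
        vol = st.invert_spectrum(spec, optics)
        assert np.abs(vol.grid - phan.grid).max() < 0.05 * dn

    def test_hermitian_input_gives_negligible_imaginary_residue(
            self, geometry, frames):
        g = geometry
        fields = _rytov_fields(g, frames, [1, 2, 3])
        spec = st.map_ewald(fields, g["illum"], g["optics"], grid_n=64)
        vol = st.invert_spectrum(spec, g["optics"])
        assert vol.meta["imag_residual"] < 1e-6

    def test_quadratic_conversion_close_to_linear_for_weak_contrast(
            self, geometry, frames):
        g = geometry
        fields = _rytov_fields(g, frames, [1, 2])
        spec = st.map_ewald(fields, g["illum"], g["optics"], grid_n=64)
        lin = st.invert_spectrum(spec, g["optics"], conversion="linear")
        quad = st.invert_spectrum(spec, g["optics"], conversion="quadratic")
        assert np.abs(lin.grid - quad.grid).max() < 5e-3


class TestReconstructFrame:
    def test_bead_is_single_component_at_isovalue(self, geometry, nn_recon):
        from scipy import ndimage
        labels, n = ndimage.label(nn_recon.grid >= 1.40)
        assert n == 1

    def test_phantom_free_frame_reconstructs_medium(self, geometry):
        g = geometry
        uniform = st.RIVolume(np.full(g["phantom"].shape, g["optics"].n_medium),
                              g["voxel_size"], g["optics"].n_medium)
        frames = st.simulate_frame_pair(uniform, g["illum"], g["optics"],
                                        g["layout"], g["coherence"],
                                        frame_shape=g["frame_shape"], seed=3)
        vol = st.reconstruct_frame(frames["sample"], frames["background"],
                                   g["optics"], g["illum"], g["layout"],
                                   grid_n=64, nonneg=False, tv=False)
        assert np.abs(vol.grid - g["optics"].n_medium).max() < 1e-3

    def test_six_channel_mode_uses_camera_one_only(self, geometry, frames):
        g = geometry
        vol = st.reconstruct_frame(frames["sample"], frames["background"],
                                   g["optics"], g["illum"], g["layout"],
                                   channels=6, grid_n=64, nonneg=False, tv=False)
        assert vol.meta["channel_set"] == "1-6"

    def test_twelve_channel_accuracy_not_worse_than_six(self, geometry, frames,
                                                        nn_recon):
        g = geometry
        v6 = st.reconstruct_frame(frames["sample"], frames["background"],
                                  g["optics"], g["illum"], g["layout"],
                                  channels=6, grid_n=64, tv=False)
        r6 = st.ri_accuracy(v6, g["mask"], 1.457)
        r12 = st.ri_accuracy(nn_recon, g["mask"], 1.457)
        assert r12.relative_pct >= r6.relative_pct

    def test_missing_background_rejected(self, geometry, frames):
        g = geometry
        with pytest.raises(ValueError, match="background"):
            st.reconstruct_frame(frames["sample"], None, g["optics"],
                                 g["illum"], g["layout"])
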