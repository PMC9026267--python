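"""Forward model: illumination geometry, coherence gating, propagation,
carrier layout, and hologram synthesis."""

import math

import numpy as np
import numpy.fft as fft
import pytest
from hypothesis import given, settings, strategies as hst

import sixpacktomo as st
from sixpacktomo.forward import IlluminationAngle


class TestIllumination:
    def test_twelve_channels_six_per_group(self):
        ill = st.make_illumination_set()
        assert len(ill) == 12
        assert len(ill.group("A")) == 6 and len(ill.group("B")) == 6
        assert [a.channel for a in ill.group("A")] == [1, 2, 3, 4, 5, 6]
        assert [a.channel for a in ill.group("B")] == [7, 8, 9, 10, 11, 12]

    def test_normal_incidence(self):
        ill = st.make_illumination_set(0.0)
        for a in ill:
            assert np.allclose(a.direction_medium(1.344), [0, 0, 1])

    def test_snell_refraction_at_max_angle(self):
        a = IlluminationAngle(39.0, 0.0, 1, "A")
        s = a.direction_medium(1.344)
        theta_m = math.degrees(math.asin(math.hypot(s[0], s[1])))
        assert theta_m == pytest.approx(
            math.degrees(math.asin(math.sin(math.radians(39)) / 1.344)), abs=1e-9)
        assert theta_m == pytest.approx(27.9, abs=0.1)

    def test_angle_beyond_hardware_limit_rejected(self):
        with pytest.raises(ValueError):
            st.make_illumination_set(45.0)


class TestCoherence:
    def test_zero_delay_unity(self):
        assert st.coherence_gamma(0.0, 42.4) == 1.0

    def test_echelon_delay_kills_interference(self):
        assert abs(st.coherence_gamma(1160.0, 42.4)) < 1e-6

    @settings(derandomize=True, max_examples=50)
    @given(hst.floats(0.0, 5000.0))
    def test_monotone_nonincreasing(self, delay):
        assert st.coherence_gamma(delay, 42.4) >= st.coherence_gamma(2 * delay, 42.4)

    def test_invalid_coherence_length(self):
        with pytest.raises(ValueError):
            st.coherence_gamma(1.0, 0.0)


class TestCarrierLayout:
    def test_default_layout_valid(self, optics):
        lay = st.default_carrier_layout(optics, (256, 256))
        assert st.validate_carrier_layout(lay, optics.nyquist()) == []

    def test_duplicate_carriers_flagged(self, optics):
        lay = st.default_carrier_layout(optics, (256, 256))
        bad = st.CarrierLayout(np.vstack([lay.carriers[:1]] * 6), lay.k_na)
        msgs = st.validate_carrier_layout(bad, optics.nyquist())
        assert any("CC overlap" in m for m in msgs)

    def test_dc_clearance_violation(self, optics):
        lay = st.default_carrier_layout(optics, (256, 256))
        c = lay.carriers.copy()
        c[0] = c[0] / np.hypot(*c[0]) * 2.5 * lay.k_na
        msgs = st.validate_carrier_layout(st.CarrierLayout(c, lay.k_na),
                                          optics.nyquist())
        assert any("DC overlap" in m for m in msgs)


class TestPropagation:
    def test_uniform_phantom_gives_unit_field(self, optics):
        dv = 128 * optics.pixel_pitch_um / 64
        uniform = st.RIVolume(np.full((64,) * 3, optics.n_medium), dv,
                              optics.n_medium)
        e = st.propagate_field(uniform, IlluminationAngle(0, 0, 1, "A"), optics)
        assert np.allclose(e, 1.0, atol=1e-10)

    def test_bead_center_phase_matches_chord_integral(self, geometry):
        """Through-center phase = (2π/λ)·Δn·diameter for normal incidence."""
        optics = geometry["optics"]
        e = st.propagate_field(geometry["phantom"],
                               IlluminationAngle(0, 0, 1, "A"), optics,
                               na_filter=False)
        n = e.shape[0]
        phase = np.angle(e[n // 2, n // 2])
        expected = 2 * math.pi / optics.wavelength_um * (1.457 - 1.344) * 2.0
        if phase < 0:
            phase += 2 * math.pi
        assert phase == pytest.approx(expected, rel=0.02)

    def test_rytov_vs_multislice_weak_contrast(self, optics):
        dv = 128 * optics.pixel_pitch_um / 64
        center = (32 * dv,) * 3
        weak = st.make_sphere_phantom((64,) * 3, dv, center, 1.0,
                                      optics.n_medium + 0.01, optics.n_medium)
        ang = IlluminationAngle(0, 0, 1, "A")
        p1 = st.propagate_field(weak, ang, optics, model="rytov_projection",
                                na_filter=False)
        p2 = st.propagate_field(weak, ang, optics, model="multislice",
                                na_filter=False)
        c = p1.shape[0] // 2
        assert np.angle(p2[c, c]) == pytest.approx(np.angle(p1[c, c]), rel=0.02)

    def test_unknown_model_rejected(self, geometry):
        with pytest.raises(ValueError, match="model"):
            st.propagate_field(geometry["phantom"],
                               IlluminationAngle(0, 0, 1, "A"),
                               geometry["optics"], model="born")


class TestHologram:
    def test_thirteen_spectral_clusters(self, frames):
        for holo in frames["sample"]:
            n, _ = st.spectral_clusters(holo)
            assert n == 13      # DC + 6 CC + 6 conjugates

    def test_real_quantized_output(self, frames):
        h = frames["sample"][0]
        assert np.isrealobj(h.data)
        assert h.data.min() >= 0 and h.data.max() <= 255
        spec = fft.fft2(h.data)
        assert np.allclose(spec, np.conj(np.roll(np.flip(spec), 1, axis=(0, 1))),
                           atol=1e-6 * np.abs(spec).max())

    def test_parseval_energy_bookkeeping(self, geometry, frames):
        g = geometry
        fields = [frames["fields"][k] for k in range(1, 7)]
        h = st.synthesize_sixpack_hologram(fields, g["layout"], g["coherence"],
                                           g["optics"], angles=g["illum"].group("A"),
                                           quantize=False)
        spatial = np.sum(h.data ** 2)
        spectral = np.sum(np.abs(fft.fft2(h.data)) ** 2) / h.data.size
        assert spectral == pytest.approx(spatial, rel=1e-10)

    def test_gating_disabled_creates_extra_clusters(self, geometry, frames):
        g = geometry
        fields = [frames["fields"][k] for k in range(1, 7)]
        no_gate = st.CoherenceModel(l_c_um=42.4, step_um=0.0)
        h = st.synthesize_sixpack_hologram(fields, g["layout"], no_gate,
                                           g["optics"], angles=g["illum"].group("A"))
        n, _ = st.spectral_clusters(h)
        assert n > 13

    def test_noise_changes_with_seed(self, geometry, frames):
        g = geometry
        fields = [frames["fields"][k] for k in range(1, 7)]
        h1 = st.synthesize_sixpack_hologram(fields, g["layout"], g["coherence"],
                                            g["optics"], shot_noise_photons=1e4,
                                            seed=1)
        h2 = st.synthesize_sixpack_hologram(fields, g["layout"], g["coherence"],
                                            g["optics"], shot_noise_photons=1e4,
                                            seed=2)
        assert not np.array_equal(h1.data, h2.data)

    def test_invalid_layout_rejected(self, geometry, frames):
        g = geometry
        fields = [frames["fields"][k] for k in range(1, 7)]
        bad = st.CarrierLayout(np.vstack([g["layout"].carriers[:1]] * 6),
                               g["layout"].k_na)
        with pytest.raises(ValueError, match="layout"):
            st.synthesize_sixpack_hologram(fields, bad, g["coherence"],
                                           g["optics"])
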