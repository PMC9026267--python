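"""Forward simulation of double six-pack multiplexed off-axis holograms.

Twelve plane waves illuminate the sample simultaneously from polar angles
up to 39° in air.  Six of them (channels 1–6, polarization group A) reach
camera 1 and six (channels 7–12, group B) reach camera 2.  On each camera
the six sample beams interfere with six tilted reference beams, producing
six fringe systems with distinct carrier frequencies; an echelon gives
every sample/reference pair its own optical path delay so that, with a
short-coherence source, only matched pairs interfere (coherence gating).
The result is one multiplexed hologram per camera whose spectrum carries
six disjoint cross-correlation (CC) lobes plus their complex conjugates.

Spatial frequencies in this module are expressed in cycles/µm at the
sample plane.  The camera pixel pitch referred to the sample plane is
``camera_pixel_um / magnification``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import numpy.fft as fft

from .phantom import RIVolume

__all__ = [
    "OpticalConfig",
    "IlluminationAngle",
    "IlluminationSet",
    "CoherenceModel",
    "CarrierLayout",
    "MultiplexedHologram",
    "make_illumination_set",
    "coherence_gamma",
    "validate_carrier_layout",
    "default_carrier_layout",
    "propagate_field",
    "synthesize_sixpack_hologram",
    "simulate_frame_pair",
    "spectral_clusters",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition geometry and camera model.

    ``na`` is the detection numerical aperture used by the simulation.
    The default 1.0 leaves enough camera bandwidth to place six CC terms
    with full clearance at the 5.2 µm / 106× sample-plane pitch; the
    physical 1.35 oil objective is still the right value for analytic
    spot-size/throughput estimates (see :mod:`sixpacktomo.metrics`).
    """

    wavelength_um: float = 0.6328
    na: float = 1.0
    magnification: float = 106.0
    camera_pixel_um: float = 5.2
    bit_depth: int = 8
    n_medium: float = 1.344

    def __post_init__(self):
        if self.wavelength_um <= 0 or self.na <= 0:
            raise ValueError("wavelength and NA must be positive")

    @property
    def pixel_pitch_um(self) -> float:
        """Sample-plane pixel pitch (µm)."""
        return self.camera_pixel_um / self.magnification

    @property
    def k_na(self) -> float:
        """CC-lobe support radius NA/λ (cycles/µm)."""
        return self.na / self.wavelength_um

    @property
    def k_medium(self) -> float:
        """Wavenumber in the medium n_m/λ (cycles/µm)."""
        return self.n_medium / self.wavelength_um

    def nyquist(self) -> float:
        return 0.5 / self.pixel_pitch_um


MAX_POLAR_DEG = 39.0


@dataclass(frozen=True)
class IlluminationAngle:
    """One illumination beam: polar angle in air, azimuth, channel, group."""

    theta_deg: float
    phi_deg: float
    channel: int           # 1..12
    group: str             # "A" (camera 1) or "B" (camera 2)

    def direction_medium(self, n_medium: float) -> np.ndarray:
        """Unit propagation direction inside the medium (Snell refraction)."""
        sin_m = math.sin(math.radians(self.theta_deg)) / n_medium
        if sin_m > 1:
            raise ValueError("illumination angle beyond critical angle")
        cos_m = math.sqrt(1.0 - sin_m * sin_m)
        phi = math.radians(self.phi_deg)
        return np.array([sin_m * math.cos(phi), sin_m * math.sin(phi), cos_m])

    def tilt_freq(self, wavelength_um: float) -> np.ndarray:
        """Lateral spatial frequency of the illumination at the sample plane
        (cycles/µm).  By Snell's law n_m sinθ_m = sinθ_air, so this equals
        sinθ_air/λ independent of the medium."""
        s = math.sin(math.radians(self.theta_deg)) / wavelength_um
        phi = math.radians(self.phi_deg)
        return np.array([s * math.cos(phi), s * math.sin(phi)])


@dataclass
class IlluminationSet:
    angles: list[IlluminationAngle]

    def __post_init__(self):
        groups = [a.group for a in self.angles]
        if len(self.angles) not in (6, 12):
            raise ValueError("expected 6 or 12 illumination channels")

    def group(self, name: str) -> list[IlluminationAngle]:
        return [a for a in self.angles if a.group == name]

    def __iter__(self):
        return iter(self.angles)

    def __len__(self):
        return len(self.angles)


def make_illumination_set(max_polar_deg: float = MAX_POLAR_DEG,
                          scheme: str = "ring") -> IlluminationSet:
    """Twelve illumination directions on a cone of half-angle ``max_polar_deg``.

    Channels 1–6 (group A, camera 1) sit at azimuths 0°,60°,...,300° and
    channels 7–12 (group B, camera 2) at 30°,90°,...,330°, interleaving the
    two polarization groups for uniform azimuthal coverage.
    """
    if max_polar_deg > MAX_POLAR_DEG:
        raise ValueError(f"maximum off-axis angle is {MAX_POLAR_DEG}° in air")
    if max_polar_deg < 0:
        raise ValueError("polar angle must be non-negative")
    if scheme != "ring":
        raise ValueError(f"unknown azimuth scheme {scheme!r}")
    angles = []
    for k in range(6):
        angles.append(IlluminationAngle(max_polar_deg, 60.0 * k, k + 1, "A"))
    for k in range(6):
        angles.append(IlluminationAngle(max_polar_deg, 30.0 + 60.0 * k, k + 7, "B"))
    return IlluminationSet(angles)


# ----------------------------------------------------------------------
# Coherence gating

@dataclass(frozen=True)
class CoherenceModel:
    """Gaussian degree of coherence with the echelon delay ladder.

    Sample beams of pair p (channels p and p+6) and reference beam p share
    the optical path delay ``(p-1) * step_um``, so matched pairs see zero
    relative delay while any mismatched pair differs by at least one
    echelon step, far beyond the coherence length.
    """

    l_c_um: float = 42.4
    step_um: float = 1160.0

    def __post_init__(self):
        if self.l_c_um <= 0:
            raise ValueError("coherence length must be positive")

    def sample_delay(self, channel: int) -> float:
        return ((channel - 1) % 6) * self.step_um

    def reference_delay(self, ref_index: int) -> float:
        """Delay of reference beam ``ref_index`` in 1..6."""
        return (ref_index - 1) * self.step_um

    def gamma(self, delay_um: float) -> float:
        return coherence_gamma(delay_um, self.l_c_um)


def coherence_gamma(delay_um: float, l_c_um: float) -> float:
    """|γ(Δ)| for a Gaussian spectrum source: exp(-π Δ² / (2 l_c²)).

    γ(0) = 1 and the chosen constant makes |γ| fall below 1e-6 well before
    one echelon step (1.16 mm) at the 42.4 µm coherence length.
    """
    if l_c_um <= 0:
        raise ValueError("coherence length must be positive")
    x = math.pi * delay_um * delay_um / (2.0 * l_c_um * l_c_um)
    return math.exp(-min(x, 745.0)) if x < 745.0 else 0.0


# ----------------------------------------------------------------------
# Carrier layout

@dataclass
class CarrierLayout:
    """Six carrier frequency vectors (cycles/µm) and the CC support radius."""

    carriers: np.ndarray        # shape (6, 2)
    k_na: float

    def __post_init__(self):
        self.carriers = np.asarray(self.carriers, dtype=np.float64)
        if self.carriers.shape != (6, 2):
            raise ValueError("layout requires exactly six 2D carriers")
        if self.k_na <= 0:
            raise ValueError("k_na must be positive")


def validate_carrier_layout(layout: CarrierLayout, nyquist: float) -> list[str]:
    """Check that DC, the six CC lobes, and their conjugates never overlap.

    The DC (autocorrelation) lobe has radius 2·k_NA and each CC lobe radius
    k_NA, so the constraints are |c_i| ≥ 3 k_NA, |c_i| + k_NA ≤ Nyquist,
    and |c_i ± c_j| ≥ 2 k_NA for i ≠ j.  Returns a list of violations
    (empty when the layout is admissible).
    """
    c = layout.carriers
    k = layout.k_na
    bad = []
    mags = np.hypot(c[:, 0], c[:, 1])
    for i, m in enumerate(mags):
        if m < 3 * k - 1e-9:
            bad.append(f"carrier {i}: |c|={m:.3f} < 3 k_NA={3 * k:.3f} (DC overlap)")
        if m + k > nyquist + 1e-9:
            bad.append(f"carrier {i}: |c|+k_NA={m + k:.3f} exceeds Nyquist {nyquist:.3f}")
    for i in range(6):
        for j in range(i + 1, 6):
            d = np.hypot(*(c[i] - c[j]))
            s = np.hypot(*(c[i] + c[j]))
            if d < 2 * k - 1e-9:
                bad.append(f"carriers {i},{j}: separation {d:.3f} < 2 k_NA (CC overlap)")
            if s < 2 * k - 1e-9:
                bad.append(f"carriers {i},{j}: |c_i+c_j|={s:.3f} < 2 k_NA (conjugate overlap)")
    return bad


def default_carrier_layout(config: OpticalConfig, frame_shape: tuple[int, int]) -> CarrierLayout:
    """Six carriers on an upper-half-plane arc, snapped to integer FFT bins.

    Azimuths 15°..165° in 30° steps keep every carrier and every conjugate
    in opposite half-planes; the radius splits the admissible annulus
    between the DC clearance (3 k_NA) and the Nyquist limit.  Snapping to
    integer bins of the frame's FFT grid makes demodulation leak-free.
    """
    nyq = config.nyquist()
    k = config.k_na
    radius = 0.5 * (3 * k + (nyq - k))
    dk = 1.0 / (frame_shape[0] * config.pixel_pitch_um)
    dky = 1.0 / (frame_shape[1] * config.pixel_pitch_um)
    cs = []
    for j in range(6):
        phi = math.radians(15.0 + 30.0 * j)
        cx = round(radius * math.cos(phi) / dk) * dk
        cy = round(radius * math.sin(phi) / dky) * dky
        cs.append((cx, cy))
    layout = CarrierLayout(np.array(cs), k)
    bad = validate_carrier_layout(layout, nyq)
    if bad:
        raise ValueError("default carrier layout infeasible for this config:\n"
                         + "\n".join(bad))
    return layout


# ----------------------------------------------------------------------
# Field propagation

def _freq_grids(shape, pitch):
    qx = fft.fftfreq(shape[0], d=pitch)
    qy = fft.fftfreq(shape[1], d=pitch)
    return qx[:, None], qy[None, :]


def _fourier_resample2d(u: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Band-limited resampling by zero-padding/cropping the 2D spectrum."""
    if u.shape == tuple(out_shape):
        return u
    U = fft.fftshift(fft.fft2(u))
    out = np.zeros(out_shape, dtype=complex)
    n0, n1 = u.shape
    m0, m1 = out_shape
    a0, a1 = min(n0, m0), min(n1, m1)
    src = (slice(n0 // 2 - a0 // 2, n0 // 2 - a0 // 2 + a0),
           slice(n1 // 2 - a1 // 2, n1 // 2 - a1 // 2 + a1))
    dst = (slice(m0 // 2 - a0 // 2, m0 // 2 - a0 // 2 + a0),
           slice(m1 // 2 - a1 // 2, m1 // 2 - a1 // 2 + a1))
    out[dst] = U[src]
    return fft.ifft2(fft.ifftshift(out)) * (m0 * m1) / (n0 * n1)


def _lowpass_disk(u: np.ndarray, pitch: float, k_cut: float) -> np.ndarray:
    qx, qy = _freq_grids(u.shape, pitch)
    mask = qx * qx + qy * qy <= k_cut * k_cut
    return fft.ifft2(fft.fft2(u) * mask)


def propagate_field(phantom: RIVolume, angle: IlluminationAngle,
                    config: OpticalConfig, model: str = "rytov_projection",
                    frame_shape: tuple[int, int] | None = None,
                    na_filter: bool = True) -> np.ndarray:
    """Complex transmitted field envelope at the image (center) plane.

    The returned array is the total field divided by the illumination
    plane wave, sampled at the hologram grid (``frame_shape`` at the
    sample-plane pixel pitch).  Models:

    ``rytov_projection``
        The complex log of the output is the line integral of
        i·(2π/λ)(n − n_m) along the refracted illumination direction,
        referenced to the axial center plane of the volume.  This is the
        exact adjoint of the Ewald-cap reconstruction at low frequency.

    ``multislice``
        Angular-spectrum beam propagation through the volume (phase
        screens with obliquity correction), a higher-fidelity cross-check
        for weak contrast.

    With ``na_filter`` the envelope is low-passed to the detection pupil
    radius NA/λ, so the emitted CC lobes are strictly band-limited.
    """
    dn = phantom.grid - phantom.n_medium
    nvx = phantom.shape
    dv = phantom.voxel_size
    pitch = config.pixel_pitch_um
    if frame_shape is None:
        frame_shape = (int(round(nvx[0] * dv / pitch)),
                       int(round(nvx[1] * dv / pitch)))
    for ax in range(2):
        if abs(nvx[ax] * dv - frame_shape[ax] * pitch) > 1e-6 * dv:
            raise ValueError(
                "phantom lateral extent must match the hologram field of view "
                f"(axis {ax}: {nvx[ax] * dv:.4f} vs {frame_shape[ax] * pitch:.4f} µm)")

    s = angle.direction_medium(config.n_medium)
    k0 = 2.0 * math.pi / config.wavelength_um
    qx, qy = _freq_grids(nvx[:2], dv)
    # integer voxel offsets from the center plane keep the reconstruction
    # grid index-aligned with the phantom grid
    z_rel = (np.arange(nvx[2]) - nvx[2] // 2) * dv

    if model == "rytov_projection":
        acc = np.zeros(nvx[:2], dtype=complex)
        for iz, z in enumerate(z_rel):
            sl = dn[:, :, iz]
            if not sl.any():
                continue
            shift_x = s[0] / s[2] * z
            shift_y = s[1] / s[2] * z
            acc += fft.fft2(sl) * np.exp(2j * math.pi * (qx * shift_x + qy * shift_y))
        u = fft.ifft2(acc) * (1j * k0 * dv / s[2])
        e = np.exp(u)
    elif model == "multislice":
        km = config.k_medium
        a = angle.tilt_freq(config.wavelength_um)
        kx_abs = qx + a[0]
        ky_abs = qy + a[1]
        arg = km * km - kx_abs * kx_abs - ky_abs * ky_abs
        kz_abs = np.sqrt(np.maximum(arg, 0.0))
        k_iz = km * s[2]
        # envelope propagator over one slice; evanescent components dropped
        H = np.where(arg > 0, np.exp(2j * math.pi * (kz_abs - k_iz) * dv), 0.0)
        E = np.ones(nvx[:2], dtype=complex)
        for iz in range(nvx[2]):
            E = E * np.exp(1j * k0 * dn[:, :, iz] * dv / s[2])
            E = fft.ifft2(fft.fft2(E) * H)
        # refocus from the exit plane back to the volume center plane
        E = fft.ifft2(fft.fft2(E) * np.conj(H) ** (nvx[2] / 2.0))
        e = E
    else:
        raise ValueError(f"unsupported propagation model {model!r}")

    e = _fourier_resample2d(e, frame_shape)
    if na_filter:
        e = _lowpass_disk(e, pitch, config.k_na)
    return e


# ----------------------------------------------------------------------
# Hologram synthesis

@dataclass
class MultiplexedHologram:
    """A single-camera multiplexed intensity frame."""

    data: np.ndarray
    pixel_pitch_um: float
    bit_depth: int | None
    camera_id: int
    layout: CarrierLayout
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.data.shape


def synthesize_sixpack_hologram(fields, layout: CarrierLayout,
                                coherence: CoherenceModel,
                                config: OpticalConfig,
                                angles=None,
                                camera_id: int = 1,
                                shot_noise_photons: float | None = None,
                                seed: int = 0,
                                quantize: bool = True,
                                fill_fraction: float = 0.7) -> MultiplexedHologram:
    """Multiplex six complex sample fields into one camera frame.

    intensity = Σ_k |S_k|² + Σ_l |R_l|²
              + Σ_{k,l} 2 γ(Δ_kl) Re{S_k R_l* e^{-2πi (a_l - c_l)·r}}

    where S_k = e_k·e^{2πi a_k·r} carries the residual illumination tilt
    a_k and reference l is a unit plane wave tilted so the matched fringe
    lands on carrier c_l.  With the echelon delays only matched pairs
    (k = l) survive γ; disabling gating (``step_um=0``) makes the k ≠ l
    terms visible as extra spectral clusters — the negative control.
    """
    if len(fields) != 6:
        raise ValueError("exactly six sample fields are required per camera")
    shape = fields[0].shape
    for f in fields:
        if f.shape != shape:
            raise ValueError("all sample fields must share one shape")
    bad = validate_carrier_layout(layout, config.nyquist())
    if bad:
        raise ValueError("invalid carrier layout:\n" + "\n".join(bad))

    pitch = config.pixel_pitch_um
    x = (np.arange(shape[0]) * pitch)[:, None]
    y = (np.arange(shape[1]) * pitch)[None, :]
    tilts = [np.zeros(2)] * 6 if angles is None else \
        [a.tilt_freq(config.wavelength_um) for a in angles]

    intensity = np.zeros(shape)
    for e in fields:
        intensity += np.abs(e) ** 2
    intensity += 6.0  # six unit-amplitude reference beams

    for k in range(6):
        d_k = coherence.sample_delay(k + 1)
        for l in range(6):
            g = coherence.gamma(abs(d_k - coherence.reference_delay(l + 1)))
            if g < 1e-12:
                continue
            fr = tilts[k] - tilts[l] + layout.carriers[l]
            phase = 2.0 * math.pi * (fr[0] * x + fr[1] * y)
            intensity += 2.0 * g * (fields[k].real * np.cos(phase)
                                    - fields[k].imag * np.sin(phase))

    meta = {"seed": seed}
    if shot_noise_photons is not None:
        rng = np.random.default_rng(seed)
        peak = intensity.max()
        lam = np.clip(intensity, 0, None) / peak * shot_noise_photons
        intensity = rng.poisson(lam).astype(np.float64) / shot_noise_photons * peak
        meta["shot_noise_photons"] = shot_noise_photons

    bit_depth = config.bit_depth if quantize else None
    if quantize:
        full = 2 ** config.bit_depth - 1
        scale = fill_fraction * full / intensity.max()
        data = np.clip(np.round(intensity * scale), 0, full)
        meta["scale"] = scale
    else:
        data = intensity
    return MultiplexedHologram(data, pitch, bit_depth, camera_id, layout, meta)


def simulate_frame_pair(phantom: RIVolume, illum: IlluminationSet,
                        config: OpticalConfig, layout: CarrierLayout,
                        coherence: CoherenceModel,
                        frame_shape: tuple[int, int] | None = None,
                        model: str = "rytov_projection",
                        shot_noise_photons: float | None = None,
                        seed: int = 0, quantize: bool = True,
                        return_fields: bool = False):
    """Simulate one synchronized camera pair plus the background pair.

    Camera-2 frames are flipped horizontally before being returned, as a
    physical second camera at the other beam-splitter exit would record
    them; :func:`sixpacktomo.demux.register_second_camera` undoes this.

    Returns a dict with keys ``sample`` and ``background``, each a
    ``(cam1, cam2)`` tuple of :class:`MultiplexedHologram`.
    """
    if len(illum) != 12:
        raise ValueError("a frame pair requires 12 illumination channels")
    ang_a = illum.group("A")
    ang_b = illum.group("B")
    if frame_shape is None:
        pitch = config.pixel_pitch_um
        n = int(round(phantom.shape[0] * phantom.voxel_size / pitch))
        frame_shape = (n, int(round(phantom.shape[1] * phantom.voxel_size / pitch)))

    fields = {a.channel: propagate_field(phantom, a, config, model=model,
                                         frame_shape=frame_shape)
              for a in illum}
    ones = np.ones(frame_shape, dtype=complex)

    def build(fs, angs, cam, sd):
        h = synthesize_sixpack_hologram(fs, layout, coherence, config,
                                        angles=angs, camera_id=cam,
                                        shot_noise_photons=shot_noise_photons,
                                        seed=sd, quantize=quantize)
        if cam == 2:
            h.data = h.data[::-1, :].copy()   # horizontal flip of camera 2
        return h

    sample = (build([fields[a.channel] for a in ang_a], ang_a, 1, seed),
              build([fields[a.channel] for a in ang_b], ang_b, 2, seed + 1))
    background = (build([ones] * 6, ang_a, 1, seed + 2),
                  build([ones] * 6, ang_b, 2, seed + 3))
    out = {"sample": sample, "background": background}
    if return_fields:
        out["fields"] = fields
    return out


def spectral_clusters(holo: MultiplexedHologram, rel_threshold: float = 3e-3):
    """Count disjoint above-threshold clusters in the hologram spectrum.

    A clean six-pack hologram shows 13: the DC lobe, six CC lobes, and six
    conjugates.  Used as a multiplexing-integrity check and as a negative
    control when coherence gating is disabled.
    """
    from scipy import ndimage

    mag = np.abs(fft.fftshift(fft.fft2(holo.data.astype(np.float64))))
    labels, n = ndimage.label(mag > rel_threshold * mag.max())
    return n, labels
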