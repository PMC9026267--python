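"""Demultiplexing: from camera frames to filtered, unwrapped Rytov fields.

Each multiplexed hologram is 2D Fourier transformed; the six CC lobes are
cropped (a disk of radius ≤ NA/λ about each carrier), shifted to baseband
and inverse transformed, giving six complex perspective wavefronts per
camera.  Dividing by the matching background wavefront cancels the phase
curvature of the optical system; the quotient's log-amplitude and
unwrapped phase form the complex Rytov field used by the tomographic
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.fft as fft
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.restoration import unwrap_phase

from .forward import CarrierLayout, MultiplexedHologram

__all__ = [
    "ComplexWavefront",
    "RytovField",
    "register_second_camera",
    "estimate_translation",
    "demultiplex",
    "extract_rytov",
    "median_filter_phase",
]

UNWRAP_ALGORITHM = "2D reliability-sorting (scikit-image unwrap_phase)"


@dataclass
class ComplexWavefront:
    data: np.ndarray
    channel: int
    camera_id: int
    carrier: np.ndarray


@dataclass
class RytovField:
    """u = ln(A_s/A_bg) + i·φ_unwrapped for one perspective channel."""

    data: np.ndarray
    channel: int
    meta: dict = field(default_factory=dict)

    @property
    def log_amplitude(self) -> np.ndarray:
        return self.data.real

    @property
    def phase(self) -> np.ndarray:
        return self.data.imag


def register_second_camera(frame: np.ndarray,
                           reference: np.ndarray | None = None) -> np.ndarray:
    """Undo the horizontal mirror of the second camera and (optionally)
    align it to a camera-1 reference by integer-pixel translation."""
    out = np.asarray(frame)[::-1, :].copy()
    if reference is not None:
        if reference.shape != out.shape:
            raise ValueError("reference frame shape mismatch")
        shift = estimate_translation(out, reference)
        out = np.roll(out, shift, axis=(0, 1))
    return out


def estimate_translation(moving: np.ndarray, reference: np.ndarray) -> tuple[int, int]:
    """Integer shift that moves ``moving`` onto ``reference``
    (cross-correlation peak)."""
    shift, _, _ = phase_cross_correlation(reference, moving, upsample_factor=1,
                                          normalization=None)
    return int(round(shift[0])), int(round(shift[1]))


def demultiplex(holo: MultiplexedHologram, layout: CarrierLayout | None = None,
                crop_radius: float | None = None,
                channel_offset: int = 0) -> list[ComplexWavefront]:
    """Recover the six complex wavefronts from one multiplexed hologram.

    For each carrier c_k the spectrum disk |q - c_k| ≤ crop_radius is kept,
    rolled to baseband, and inverse transformed.  The crop is zero-padded
    back to the full frame, so wavefronts keep the hologram pixel pitch.
    ``channel_offset`` maps camera-local channels 1–6 onto global channel
    indices (6 for camera 2).
    """
    layout = layout or holo.layout
    r = crop_radius if crop_radius is not None else layout.k_na
    if r > layout.k_na + 1e-9:
        raise ValueError("crop radius must not exceed the CC support radius NA/λ")
    n0, n1 = holo.data.shape
    pitch = holo.pixel_pitch_um
    nyq = 0.5 / pitch
    qx = fft.fftfreq(n0, d=pitch)[:, None]
    qy = fft.fftfreq(n1, d=pitch)[None, :]
    F = fft.fft2(holo.data.astype(np.float64))
    out = []
    for k, c in enumerate(layout.carriers):
        if np.hypot(*c) + r > nyq + 1e-9:
            raise ValueError(f"carrier {k} lies (partly) outside the spectrum")
        mask = (qx - c[0]) ** 2 + (qy - c[1]) ** 2 <= r * r
        ix = int(round(c[0] * n0 * pitch))
        iy = int(round(c[1] * n1 * pitch))
        base = np.roll(F * mask, (-ix, -iy), axis=(0, 1))
        out.append(ComplexWavefront(fft.ifft2(base), k + 1 + channel_offset,
                                    holo.camera_id, np.asarray(c)))
    return out


def _background_region(shape, width: int | None = None) -> np.ndarray:
    """Default phase-reference region: a border frame of the field of view."""
    w = width if width is not None else max(4, shape[0] // 32)
    m = np.zeros(shape, dtype=bool)
    m[:w, :] = m[-w:, :] = True
    m[:, :w] = m[:, -w:] = True
    return m


def extract_rytov(wavefront: ComplexWavefront, background: ComplexWavefront,
                  bg_region: np.ndarray | None = None) -> RytovField:
    """Background-normalized complex Rytov field with unwrapped phase.

    The quotient w/b cancels any aberration common to sample and
    background acquisitions.  The global offset (complex, covering both
    the arbitrary reference-intensity ratio and the piston phase) is
    removed by zeroing the median of the field over a sample-free region
    (default: the frame border).
    """
    if wavefront.data.shape != background.data.shape:
        raise ValueError("wavefront and background shapes differ")
    if wavefront.channel != background.channel:
        raise ValueError("wavefront and background channels differ")
    b = background.data
    eps = 1e-12 * np.abs(b).max()
    dead = np.abs(b) <= eps
    ratio = np.where(dead, 1.0, wavefront.data / np.where(dead, 1.0, b))
    logamp = np.log(np.abs(ratio))
    wrapped = np.angle(ratio)
    phase = np.asarray(unwrap_phase(wrapped))
    region = _background_region(ratio.shape) if bg_region is None else bg_region
    logamp = logamp - np.median(logamp[region])
    phase = phase - np.median(phase[region])
    return RytovField(logamp + 1j * phase, wavefront.channel,
                      meta={"unwrap_algorithm": UNWRAP_ALGORITHM,
                            "masked_background_pixels": int(dead.sum())})


def median_filter_phase(fieldobj: RytovField, kernel: int = 3) -> RytovField:
    """Median filter (real and imaginary parts independently)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("median kernel must be odd and >= 1")
    if kernel == 1:
        return RytovField(fieldobj.data.copy(), fieldobj.channel,
                          dict(fieldobj.meta))
    re = ndimage.median_filter(fieldobj.data.real, size=kernel)
    im = ndimage.median_filter(fieldobj.data.imag, size=kernel)
    meta = dict(fieldobj.meta)
    meta["median_kernel"] = kernel
    return RytovField(re + 1j * im, fieldobj.channel, meta)
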