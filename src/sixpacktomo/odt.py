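"""Optical diffraction tomography: Ewald-cap mapping and inversion.

Under the Rytov (weak scattering) approximation each background-normalized
perspective field samples the 3D spectrum of the scattering potential

    f(r) = (2π/λ)² (n(r)² − n_m²)  ≈  2 n_m (2π/λ)² (n(r) − n_m)

on a spherical cap: a detected lateral frequency (k_x, k_y) lies on the
shell |k| = n_m/λ at k_z = sqrt(k_m² − k_x² − k_y²), and the potential
frequency is K = k − k_i with k_i the illumination wavevector in the
medium.  Accumulating all 12 caps (values averaged where caps overlap,
conjugates deposited for Hermitian symmetry), inverse transforming, and
converting the potential back to refractive index yields the tomogram.

The forward model in this package is linear in (n − n_m), so the default
index conversion is the matching linearization of the potential; the
quadratic (square-root) conversion is available via ``conversion``.  The
two agree to first order in the contrast and the choice is recorded in
the tomogram metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import numpy.fft as fft

from .demux import (RytovField, demultiplex, extract_rytov,
                    median_filter_phase, register_second_camera)
from .forward import CarrierLayout, IlluminationSet, MultiplexedHologram, OpticalConfig
from .phantom import RIVolume

__all__ = ["EwaldSpectrum", "map_ewald", "invert_spectrum", "reconstruct_frame"]


@dataclass
class EwaldSpectrum:
    """Accumulated 3D spectrum of the scattering potential.

    ``values`` holds per-voxel sums of deposited spectrum samples and
    ``counts`` the number of deposits; the estimate is their ratio.
    Arrays are in FFT (wrapped) frequency order with ``dk`` cycles/µm per
    bin on every axis.
    """

    values: np.ndarray          # complex sums
    counts: np.ndarray          # int deposits
    dk: float                   # cycles/µm per frequency voxel
    k_medium: float             # n_m / λ, cycles/µm
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.values.shape

    @property
    def support(self) -> np.ndarray:
        return self.counts > 0

    def averaged(self) -> np.ndarray:
        out = np.zeros_like(self.values)
        np.divide(self.values, self.counts, out=out, where=self.counts > 0)
        return out


def map_ewald(fields: list[RytovField], illum: IlluminationSet,
              config: OpticalConfig, grid_n: int = 128,
              crop_radius: float | None = None,
              hermitian: bool = True) -> EwaldSpectrum:
    """Deposit Rytov-field spectra onto their Ewald caps.

    All fields must share one shape and the sample-plane pixel pitch; the
    3D frequency grid inherits the 2D frequency step (the 3D volume spans
    the same physical extent as the hologram field of view, with
    ``grid_n`` voxels per axis).
    """
    if not fields:
        raise ValueError("no fields to map")
    shape2 = fields[0].data.shape
    pitch = config.pixel_pitch_um
    dk = 1.0 / (shape2[0] * pitch)
    if abs(1.0 / (shape2[1] * pitch) - dk) > 1e-9 * dk:
        raise ValueError("non-square field sampling is not supported")
    km = config.k_medium
    r = crop_radius if crop_radius is not None else config.k_na
    by_channel = {a.channel: a for a in illum}

    qx = fft.fftfreq(shape2[0], d=pitch)[:, None]
    qy = fft.fftfreq(shape2[1], d=pitch)[None, :]
    n3 = grid_n
    kmax = (n3 // 2 - 1) * dk
    values = np.zeros((n3, n3, n3), dtype=complex)
    counts = np.zeros((n3, n3, n3), dtype=np.int64)

    for fld in fields:
        if fld.data.shape != shape2:
            raise ValueError("all fields must share one shape")
        ang = by_channel.get(fld.channel)
        if ang is None:
            raise ValueError(f"no illumination angle for channel {fld.channel}")
        s = ang.direction_medium(config.n_medium)
        k_i = km * s                                     # cycles/µm
        u_hat = fft.fft2(fld.data) * pitch * pitch       # continuous-FT scaling
        kx_abs = qx + k_i[0]
        ky_abs = qy + k_i[1]
        arg = km * km - kx_abs ** 2 - ky_abs ** 2
        sel = (qx ** 2 + qy ** 2 <= r * r) & (arg > 0)
        kz_abs = np.sqrt(np.where(sel, arg, 1.0))
        # Fourier diffraction theorem prefactor (rad convention): -2i k_z û
        vals = (-2j * (2.0 * math.pi) * kz_abs * u_hat)[sel]
        Kx = np.broadcast_to(qx, shape2)[sel]
        Ky = np.broadcast_to(qy, shape2)[sel]
        Kz = (kz_abs - k_i[2])[sel]
        keep = (np.abs(Kx) <= kmax) & (np.abs(Ky) <= kmax) & (np.abs(Kz) <= kmax)
        ix = np.round(Kx[keep] / dk).astype(int) % n3
        iy = np.round(Ky[keep] / dk).astype(int) % n3
        iz = np.round(Kz[keep] / dk).astype(int) % n3
        v = vals[keep]
        np.add.at(values, (ix, iy, iz), v)
        np.add.at(counts, (ix, iy, iz), 1)
        if hermitian:
            np.add.at(values, ((-ix) % n3, (-iy) % n3, (-iz) % n3), np.conj(v))
            np.add.at(counts, ((-ix) % n3, (-iy) % n3, (-iz) % n3), 1)

    return EwaldSpectrum(values, counts, dk, km,
                         meta={"channels": sorted(f.channel for f in fields),
                               "crop_radius": r, "hermitian": hermitian})


def _hermitian_symmetrize(F: np.ndarray) -> np.ndarray:
    rev = np.roll(np.flip(F), 1, axis=(0, 1, 2))
    return 0.5 * (F + np.conj(rev))


def invert_spectrum(spec: EwaldSpectrum, config: OpticalConfig,
                    conversion: str = "linear") -> RIVolume:
    """Inverse Fourier transform of the Ewald spectrum → RI volume.

    ``conversion`` maps the scattering potential f back to index:

    - ``"linear"``   : n = n_m + f λ² / (8 π² n_m)   (matches the
      projection forward model; the package default)
    - ``"quadratic"``: n = n_m sqrt(1 + f λ² / (4 π² n_m²)); voxels with a
      negative radicand are clamped to n_m and counted.
    """
    n3 = spec.shape[0]
    L = 1.0 / spec.dk
    dv = L / n3
    F = _hermitian_symmetrize(spec.averaged())
    f_cplx = fft.ifftn(F) / dv ** 3
    resid = float(np.abs(f_cplx.imag).max() / (np.abs(f_cplx.real).max() + 1e-300))
    # the fields are referenced to the axial center plane (z_rel = 0 at
    # FFT index 0); roll so the center plane sits mid-grid like the phantom
    f = np.roll(f_cplx.real, n3 // 2, axis=2)
    lam = config.wavelength_um
    nm = config.n_medium
    clamped = 0
    if conversion == "linear":
        n = nm + f * lam * lam / (8.0 * math.pi ** 2 * nm)
    elif conversion == "quadratic":
        radicand = nm * nm + f * lam * lam / (4.0 * math.pi ** 2)
        bad = radicand < 0
        clamped = int(bad.sum())
        n = np.sqrt(np.where(bad, nm * nm, radicand))
    else:
        raise ValueError(f"unknown RI conversion {conversion!r}")
    return RIVolume(n, dv, nm,
                    meta={"conversion": conversion,
                          "clamped_voxels": clamped,
                          "imag_residual": resid,
                          "channels": spec.meta.get("channels"),
                          "support_voxels": int(spec.support.sum())})


def _estimate_psf_sigma(vol: RIVolume):
    """Approximate system PSF widths from the tomogram's own edge response.

    The anchor is the contrast centroid (adequate for a compact object
    such as a bead); per-axis edge-spread FWHMs are converted to Gaussian
    sigmas.  Returns ``None`` when no usable edge is found.
    """
    from .metrics import estimate_resolution

    contrast = np.clip(vol.grid - vol.n_medium, 0.0, None)
    total = contrast.sum()
    if total <= 0:
        return None
    idx = [float((contrast.sum(axis=tuple(a for a in range(3) if a != ax))
                  * np.arange(vol.shape[ax])).sum() / total) for ax in range(3)]
    anchor = [(i + 0.5) * vol.voxel_size for i in idx]
    try:
        res = estimate_resolution(vol, anchor)
    except ValueError:
        return None
    return (res.x_um / 2.355, res.y_um / 2.355, res.z_um / 2.355)


def reconstruct_frame(sample_pair, background_pair, config: OpticalConfig,
                      illum: IlluminationSet, layout: CarrierLayout | None = None,
                      channels: int = 12, grid_n: int = 128,
                      median_kernel: int = 3, crop_radius: float | None = None,
                      conversion: str = "linear",
                      nonneg: bool = True, nonneg_opts: dict | None = None,
                      tv: bool = True, tv_opts: dict | None = None,
                      register: bool = True,
                      return_intermediate: bool = False):
    """Full pipeline: camera frames → constrained, regularized RI tomogram.

    ``sample_pair`` and ``background_pair`` are ``(camera1, camera2)``
    tuples of :class:`~sixpacktomo.forward.MultiplexedHologram`.
    ``channels=6`` restricts the reconstruction to camera 1 (sample beams
    1–6), the single six-pack mode used for comparison studies.
    """
    from . import constraints

    if channels not in (6, 12):
        raise ValueError("channels must be 6 or 12")
    if background_pair is None:
        raise ValueError("a background frame pair is required")

    def _prep(pair):
        cam1, cam2 = pair
        holos = [cam1]
        if channels == 12:
            if register:
                flipped = MultiplexedHologram(
                    register_second_camera(cam2.data), cam2.pixel_pitch_um,
                    cam2.bit_depth, cam2.camera_id, cam2.layout, dict(cam2.meta))
            else:
                flipped = cam2
            holos.append(flipped)
        waves = []
        for idx, h in enumerate(holos):
            waves.extend(demultiplex(h, layout or h.layout, crop_radius,
                                     channel_offset=6 * idx))
        return waves

    sample_waves = _prep(sample_pair)
    bg_waves = _prep(background_pair)
    fields = []
    for w, b in zip(sample_waves, bg_waves):
        ryt = extract_rytov(w, b)
        fields.append(median_filter_phase(ryt, median_kernel))

    spec = map_ewald(fields, illum, config, grid_n=grid_n, crop_radius=crop_radius)
    vol = invert_spectrum(spec, config, conversion=conversion)
    vol.meta["channel_set"] = "1-6" if channels == 6 else "1-12"
    vol.meta["median_kernel"] = median_kernel
    raw = vol.copy() if return_intermediate else None

    if nonneg:
        vol = constraints.nonnegativity_iterate(
            vol, spec.support, config.n_medium, **(nonneg_opts or {}))
    if tv:
        opts = dict(tv_opts or {})
        if "psf" not in opts:
            sig = opts.pop("psf_sigma_um", None)
            if sig is None:
                sig = _estimate_psf_sigma(vol) \
                    or constraints.default_psf_sigma(config, illum)
            opts["psf"] = constraints.make_gaussian_psf(vol.voxel_size, sig)
            vol.meta["tv_psf_sigma_um"] = tuple(float(s) for s in sig)
        vol = constraints.tv_regularize(vol, **opts)

    if return_intermediate:
        return vol, {"raw": raw, "spectrum": spec, "fields": fields}
    return vol
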