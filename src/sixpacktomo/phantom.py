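"""3D refractive-index phantoms for holographic tomography simulations.

The phantoms emulate the samples used in flow-tomography experiments:
silica microbeads (single or a near-touching pair) suspended in a
polyvinylpyrrolidone/water medium, and a simplified sperm-like cell with
a dense nucleus (RI > 1.40), a lower-index acrosome, and a cylindrical
midpiece.

Coordinate conventions
----------------------
Voxel indices are 0-based with axis order ``(x, y, z)``; ``z`` is the
optical axis.  The physical position of voxel ``(i, j, k)`` is its center
at ``(i + 0.5) * voxel_size`` from the grid origin, so a grid of shape
``(N, N, N)`` spans ``N * voxel_size`` micrometres per axis.

All refractive indices are dimensionless; lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "RIVolume",
    "make_sphere_phantom",
    "make_bead_pair_phantom",
    "make_sperm_phantom",
    "sphere_mask",
    "save_volume",
    "load_volume",
]

#: Default silica-bead RI at 632.8 nm and PVP/water medium RI.
N_SILICA = 1.457
N_MEDIUM_PVP = 1.344


@dataclass
class RIVolume:
    """A 3D real-valued refractive-index grid.

    Attributes
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Refractive index n(x, y, z), dimensionless.
    voxel_size : float
        Isotropic voxel edge length in µm.
    n_medium : float
        Background (immersion medium) refractive index.
    meta : dict
        Free-form provenance (pipeline options, channel set, ...).
    """

    grid: np.ndarray
    voxel_size: float
    n_medium: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("RI grid must be 3D with at least 2 voxels per axis")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_size for s in self.grid.shape)

    def copy(self) -> "RIVolume":
        return RIVolume(self.grid.copy(), self.voxel_size, self.n_medium,
                        dict(self.meta))


def _voxel_centers(shape, voxel_size):
    """Physical center coordinates along each axis, origin at the grid corner."""
    return [(np.arange(n) + 0.5) * voxel_size for n in shape]


def _check_inside(center, radius, shape, voxel_size):
    for c, n in zip(center, shape):
        if c - radius < 0 or c + radius > n * voxel_size:
            raise ValueError(
                f"inclusion of radius {radius} µm at {tuple(center)} µm exceeds "
                f"grid bounds {tuple(s * voxel_size for s in shape)} µm"
            )


def sphere_mask(shape, voxel_size, center, radius):
    """Boolean mask of voxels whose centers lie strictly inside the sphere."""
    xs, ys, zs = _voxel_centers(shape, voxel_size)
    dx = xs[:, None, None] - center[0]
    dy = ys[None, :, None] - center[1]
    dz = zs[None, None, :] - center[2]
    return dx * dx + dy * dy + dz * dz <= radius * radius


def _sphere_fraction(shape, voxel_size, center, radius, supersample=3):
    """Per-voxel volume fraction covered by the sphere (supersampled)."""
    # Only voxels within one voxel of the surface need subsampling.
    xs, ys, zs = _voxel_centers(shape, voxel_size)
    dx = xs[:, None, None] - center[0]
    dy = ys[None, :, None] - center[1]
    dz = zs[None, None, :] - center[2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    half_diag = 0.5 * np.sqrt(3.0) * voxel_size
    frac = (r <= radius).astype(np.float64)
    band = np.abs(r - radius) <= half_diag
    if supersample > 1 and np.any(band):
        offs = (np.arange(supersample) + 0.5) / supersample - 0.5
        idx = np.argwhere(band)
        cx = (idx[:, 0] + 0.5) * voxel_size - center[0]
        cy = (idx[:, 1] + 0.5) * voxel_size - center[1]
        cz = (idx[:, 2] + 0.5) * voxel_size - center[2]
        sub = np.zeros(len(idx))
        for ox in offs:
            for oy in offs:
                for oz in offs:
                    d2 = ((cx + ox * voxel_size) ** 2
                          + (cy + oy * voxel_size) ** 2
                          + (cz + oz * voxel_size) ** 2)
                    sub += d2 <= radius * radius
        frac[tuple(idx.T)] = sub / supersample ** 3
    return frac


def make_sphere_phantom(shape, voxel_size, center, radius,
                        n_sphere=N_SILICA, n_medium=N_MEDIUM_PVP,
                        antialias=True, supersample=3) -> RIVolume:
    """Homogeneous sphere (silica bead) in a uniform medium.

    With ``antialias=True`` voxels cut by the surface receive a
    volume-fraction blend of the two indices (``supersample``³ subsamples),
    which suppresses staircase artifacts in simulated phase images.  With
    ``antialias=False`` the assignment is binary on voxel centers, which is
    what lattice-counting tests expect.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    _check_inside(center, radius, shape, voxel_size)
    if antialias:
        frac = _sphere_fraction(shape, voxel_size, center, radius, supersample)
    else:
        frac = sphere_mask(shape, voxel_size, center, radius).astype(np.float64)
    grid = n_medium + (n_sphere - n_medium) * frac
    return RIVolume(grid, voxel_size, n_medium,
                    meta={"kind": "sphere", "center_um": tuple(center),
                          "radius_um": radius, "n_sphere": n_sphere})


def make_bead_pair_phantom(shape, voxel_size, centers, radius,
                           n_sphere=N_SILICA, n_medium=N_MEDIUM_PVP,
                           antialias=True, supersample=3) -> RIVolume:
    """Union of two equal spheres (a bead pair recorded during flow)."""
    if len(centers) != 2:
        raise ValueError("centers must contain exactly two points")
    if radius <= 0:
        raise ValueError("radius must be positive")
    fracs = []
    for c in centers:
        _check_inside(c, radius, shape, voxel_size)
        if antialias:
            fracs.append(_sphere_fraction(shape, voxel_size, c, radius, supersample))
        else:
            fracs.append(sphere_mask(shape, voxel_size, c, radius).astype(np.float64))
    frac = np.maximum(fracs[0], fracs[1])
    grid = n_medium + (n_sphere - n_medium) * frac
    return RIVolume(grid, voxel_size, n_medium,
                    meta={"kind": "sphere_pair",
                          "centers_um": [tuple(c) for c in centers],
                          "radius_um": radius, "n_sphere": n_sphere})


def make_sperm_phantom(shape, voxel_size, center=None,
                       head_semiaxes=(2.25, 1.5, 1.0),
                       midpiece_radius=0.5, midpiece_length=4.0,
                       n_nucleus=1.42, n_acrosome=1.37, n_midpiece=1.38,
                       n_medium=1.351) -> RIVolume:
    """Simplified sperm-cell phantom.

    The head is an ellipsoid with semi-axes ``head_semiaxes`` (µm) along
    (x, y, z); the posterior half (x < head center) is the nucleus
    (RI > 1.40 with the default 1.42) and the anterior half the acrosome
    (1.344 < RI < 1.40).  A cylindrical midpiece of the given radius and
    length extends posteriorly from the head along x.  The geometry is a
    schematic calibrated only to reproduce the nucleus/acrosome RI
    threshold structure of real tomograms; it is not anatomically exact
    and the tail is omitted (below the diffraction limit in practice).
    """
    a, b, c = head_semiaxes
    if min(a, b, c) <= 0 or midpiece_radius <= 0 or midpiece_length <= 0:
        raise ValueError("semi-axes and midpiece dimensions must be positive")
    ext = [s * voxel_size for s in shape]
    if center is None:
        # leave room for the midpiece behind the head
        center = (0.5 * (ext[0] + midpiece_length), 0.5 * ext[1], 0.5 * ext[2])
    lo_x = center[0] - a - midpiece_length
    if lo_x < 0 or center[0] + a > ext[0] or center[1] - b < 0 \
            or center[1] + b > ext[1] or center[2] - c < 0 or center[2] + c > ext[2]:
        raise ValueError("sperm phantom does not fit inside the grid")

    xs, ys, zs = _voxel_centers(shape, voxel_size)
    dx = xs[:, None, None] - center[0]
    dy = ys[None, :, None] - center[1]
    dz = zs[None, None, :] - center[2]
    inside_head = (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0
    nucleus = inside_head & (dx < 0)
    acrosome = inside_head & (dx >= 0)
    # cylinder runs posteriorly from the head; head voxels take priority
    mid = ((dx <= 0) & (dx >= -(a + midpiece_length))
           & (dy * dy + dz * dz <= midpiece_radius ** 2) & ~inside_head)

    grid = np.full(shape, float(n_medium))
    grid[mid] = n_midpiece
    grid[acrosome] = n_acrosome
    grid[nucleus] = n_nucleus
    return RIVolume(grid, voxel_size, n_medium,
                    meta={"kind": "sperm", "center_um": tuple(center),
                          "head_semiaxes_um": tuple(head_semiaxes)})


# ----------------------------------------------------------------------
# HDF5 I/O: dataset "ri" with voxel size / medium attributes.

def save_volume(path, vol: RIVolume) -> None:
    """Write a tomogram or phantom as HDF5 (dataset ``ri``)."""
    with h5py.File(Path(path), "w") as f:
        d = f.create_dataset("ri", data=vol.grid.astype(np.float64))
        d.attrs["voxel_size_um"] = float(vol.voxel_size)
        d.attrs["n_medium"] = float(vol.n_medium)
        for k, v in vol.meta.items():
            try:
                d.attrs[f"meta_{k}"] = v
            except TypeError:
                d.attrs[f"meta_{k}"] = str(v)


def load_volume(path) -> RIVolume:
    with h5py.File(Path(path), "r") as f:
        d = f["ri"]
        meta = {k[5:]: d.attrs[k] for k in d.attrs if k.startswith("meta_")}
        return RIVolume(d[...], float(d.attrs["voxel_size_um"]),
                        float(d.attrs["n_medium"]), meta)
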