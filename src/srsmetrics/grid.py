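"""Voxel-lattice geometry: dose grids, fractional structure masks, margin offsets,
and equivalent-sphere conversions.

Conventions
-----------
* Arrays are indexed ``(z, y, x)``, 0-based, with coordinates attached to voxel
  *centers*.
* All physical lengths are millimetres, volumes are reported in cc
  (1 cc = 1000 mm^3), dose is Gy.
* Structure masks store *fractional* per-voxel occupancy in ``[0, 1]`` so that
  targets of a fraction of a cc are representable on a 1 mm lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateStructureError, DomainError, LatticeMismatchError

__all__ = [
    "DoseGrid",
    "StructureMask",
    "volume",
    "overlap_volume",
    "expand_mask",
    "equivalent_sphere_radius",
    "equivalent_sphere_diameter",
    "ball_mask",
    "check_congruent",
]


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise DomainError(f"spacing must be positive and finite, got {spacing!r}")
    return tuple(float(v) for v in s)


def _as_origin(origin) -> tuple[float, float, float]:
    o = np.broadcast_to(np.asarray(origin, dtype=float), (3,))
    if not np.all(np.isfinite(o)):
        raise DomainError(f"origin must be finite, got {origin!r}")
    return tuple(float(v) for v in o)


@dataclass(frozen=True)
class Lattice:
    """Shared geometry of a regular voxel grid (shape, spacing, origin)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm per axis, (z, y, x)
    origin: tuple[float, float, float]  # mm coordinates of voxel (0, 0, 0) center

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])


def _lattice_of(obj) -> Lattice:
    return Lattice(tuple(obj.shape), tuple(obj.spacing), tuple(obj.origin))


def check_congruent(a, b) -> None:
    """Raise :class:`LatticeMismatchError` unless ``a`` and ``b`` share a lattice."""
    la, lb = _lattice_of(a), _lattice_of(b)
    if la.shape != lb.shape:
        raise LatticeMismatchError(f"shape mismatch: {la.shape} vs {lb.shape}")
    if not np.allclose(la.spacing, lb.spacing, rtol=0, atol=1e-9):
        raise LatticeMismatchError(f"spacing mismatch: {la.spacing} vs {lb.spacing}")
    if not np.allclose(la.origin, lb.origin, rtol=0, atol=1e-6):
        raise LatticeMismatchError(f"origin mismatch: {la.origin} vs {lb.origin}")


@dataclass(frozen=True)
class DoseGrid:
    """A 3D absorbed-dose field (Gy) on a regular lattice.

    Parameters
    ----------
    dose
        Array of shape ``(nz, ny, nx)``; finite, non-negative, in Gy.
    spacing
        Physical voxel size in mm per axis ``(z, y, x)``; scalar broadcasts.
    origin
        mm coordinates of the center of voxel ``(0, 0, 0)``.
    """

    dose: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        dose = np.asarray(self.dose, dtype=float)
        if dose.ndim != 3:
            raise DomainError(f"dose must be 3-D, got ndim={dose.ndim}")
        if not np.all(np.isfinite(dose)) or np.any(dose < 0):
            raise DomainError("dose values must be finite and >= 0")
        object.__setattr__(self, "dose", dose)
        object.__setattr__(self, "spacing", _as_spacing(self.spacing))
        object.__setattr__(self, "origin", _as_origin(self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dose.shape

    @property
    def lattice(self) -> Lattice:
        return _lattice_of(self)

    @property
    def voxel_volume_cc(self) -> float:
        return self.lattice.voxel_volume_cc

    def scaled(self, s: float) -> "DoseGrid":
        """Return a copy with the dose field multiplied by ``s > 0``."""
        if not (s > 0):
            raise DomainError(f"scale factor must be > 0, got {s}")
        return replace(self, dose=self.dose * s)

    def boundary_max(self) -> float:
        """Maximum dose on the six faces of the grid (truncation detection)."""
        d = self.dose
        faces = [d[0], d[-1], d[:, 0], d[:, -1], d[:, :, 0], d[:, :, -1]]
        return float(max(f.max() for f in faces))


@dataclass(frozen=True)
class StructureMask:
    """Fractional voxel occupancy of a structure on a regular lattice."""

    occupancy: np.ndarray
    label: str = "structure"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 3:
            raise DomainError(f"occupancy must be 3-D, got ndim={occ.ndim}")
        if not np.all(np.isfinite(occ)) or occ.min() < -1e-9 or occ.max() > 1 + 1e-9:
            raise DomainError("occupancy must lie in [0, 1]")
        object.__setattr__(self, "occupancy", np.clip(occ, 0.0, 1.0))
        object.__setattr__(self, "spacing", _as_spacing(self.spacing))
        object.__setattr__(self, "origin", _as_origin(self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def lattice(self) -> Lattice:
        return _lattice_of(self)

    @property
    def volume_cc(self) -> float:
        return volume(self)

    def is_empty(self, atol: float = 1e-12) -> bool:
        return bool(self.occupancy.sum() * self.lattice.voxel_volume_cc <= atol)


def volume(mask: StructureMask) -> float:
    """Occupancy-weighted structure volume in cc."""
    return float(mask.occupancy.sum(dtype=float) * mask.lattice.voxel_volume_cc)


def overlap_volume(a: StructureMask, b: StructureMask) -> float:
    """Volume (cc) of the voxelwise intersection ``min(a, b)`` of two masks.

    Symmetric and bounded above by each argument's volume.
    """
    check_congruent(a, b)
    inter = np.minimum(a.occupancy, b.occupancy)
    return float(inter.sum(dtype=float) * a.lattice.voxel_volume_cc)


def equivalent_sphere_radius(volume_cc: float) -> float:
    """Radius (mm) of the sphere whose volume equals ``volume_cc``."""
    if volume_cc < 0:
        raise DomainError(f"volume must be >= 0, got {volume_cc}")
    return float((3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def equivalent_sphere_diameter(volume_cc: float) -> float:
    """Diameter (mm) of the sphere whose volume equals ``volume_cc``."""
    return 2.0 * equivalent_sphere_radius(volume_cc)


# --------------------------------------------------------------------------- #
# supersampled analytic shapes                                                #
# --------------------------------------------------------------------------- #


def _subvoxel_axis(lattice: Lattice, axis: int, factor: int) -> np.ndarray:
    """(n, factor) array of subvoxel-center coordinates along ``axis``."""
    n = lattice.shape[axis]
    h = lattice.spacing[axis]
    base = lattice.origin[axis] + h * np.arange(n)
    offsets = ((np.arange(factor) + 0.5) / factor - 0.5) * h
    return base[:, None] + offsets[None, :]


def supersampled_field(lattice: Lattice, fn, supersample: int = 3) -> np.ndarray:
    """Voxelize ``fn(z, y, x) -> value`` by averaging over subvoxel centers.

    ``fn`` must accept broadcastable mm-coordinate arrays and return values
    of the broadcast shape. Used for both analytic dose fields and fractional
    shape occupancies (pass an indicator function).
    """
    s = int(supersample)
    if s < 1:
        raise DomainError("supersample factor must be >= 1")
    z = _subvoxel_axis(lattice, 0, s)[:, :, None, None, None, None]
    y = _subvoxel_axis(lattice, 1, s)[None, None, :, :, None, None]
    x = _subvoxel_axis(lattice, 2, s)[None, None, None, None, :, :]
    vals = fn(z, y, x)
    vals = np.broadcast_to(vals, (lattice.shape[0], s, lattice.shape[1], s, lattice.shape[2], s))
    return vals.mean(axis=(1, 3, 5), dtype=float)


def ball_mask(
    lattice: Lattice,
    center_mm=(0.0, 0.0, 0.0),
    radius_mm: float = 5.0,
    label: str = "ball",
    supersample: int = 3,
    semiaxes_mm=None,
) -> StructureMask:
    """Fractional-occupancy mask of a ball (or axis-aligned ellipsoid).

    With ``semiaxes_mm=(az, ay, ax)`` the shape is the ellipsoid
    ``sum((r_i - c_i)^2 / a_i^2) <= 1``; otherwise a sphere of ``radius_mm``.
    """
    if radius_mm <= 0:
        raise DomainError(f"radius must be > 0, got {radius_mm}")
    c = np.broadcast_to(np.asarray(center_mm, dtype=float), (3,))
    a = (
        np.broadcast_to(np.asarray(semiaxes_mm, dtype=float), (3,))
        if semiaxes_mm is not None
        else np.full(3, float(radius_mm))
    )

    def indicator(z, y, x):
        q = ((z - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2 + ((x - c[2]) / a[2]) ** 2
        return (q <= 1.0).astype(float)

    occ = supersampled_field(lattice, indicator, supersample)
    return StructureMask(occ, label=label, spacing=lattice.spacing, origin=lattice.origin)


# --------------------------------------------------------------------------- #
# signed-distance margin expansion / contraction                              #
# --------------------------------------------------------------------------- #


# Net inward bias of the extracted 0.5-occupancy surface for a convex
# boundary, as a multiple of h^2 * mean curvature. Calibrated once on
# analytically voxelized spheres over R/h in [3, 20] at two grid spacings
# (see docs/methods.md); it absorbs the box-filter level bias plus the
# Gaussian pre-smoothing used for a stable triangulation.
_LEVEL_CURVATURE_BIAS = 0.90
_SURFACE_SMOOTH_SIGMA = 0.8  # in refined voxels, per refine step


def _boundary_point_cloud(mask: StructureMask, refine: int = 2) -> np.ndarray:
    """Sub-voxel sample points of the 0.5-occupancy isosurface, in mm (z, y, x).

    The fractional occupancy is zero-padded (so structures touching the grid
    edge still produce a closed surface), linearly refined, Gaussian-smoothed
    and triangulated with marching cubes. Vertices and face centroids are then
    Newton-projected onto the smooth 0.5 level set (removing interpolation
    scatter) and pushed outward by ``0.90 h^2 H`` (H = local mean curvature
    estimated from the field), compensating the known inward bias of the 0.5
    level of filtered occupancy on convex boundaries.
    """
    from skimage.measure import marching_cubes

    lat = mask.lattice
    occ = np.pad(mask.occupancy, 1)
    if refine > 1:
        occ = ndimage.zoom(occ, refine, order=1, mode="nearest", grid_mode=True)
    spacing = np.asarray(lat.spacing) / refine
    phi = ndimage.gaussian_filter(occ, sigma=_SURFACE_SMOOTH_SIGMA * refine)
    try:
        verts, faces, _, _ = marching_cubes(phi, level=0.5, spacing=tuple(spacing))
    except (ValueError, RuntimeError) as exc:  # no crossing of the 0.5 level
        raise DegenerateStructureError(
            f"mask {mask.label!r} has no resolvable boundary surface"
        ) from exc
    pts = np.vstack([verts, verts[faces].mean(axis=1)])

    grads = np.stack(np.gradient(phi, *spacing), axis=0)
    gnorm = np.sqrt((grads**2).sum(axis=0))
    n_out = -grads / np.maximum(gnorm, 1e-12)
    div = sum(np.gradient(n_out[ax], spacing[ax], axis=ax) for ax in range(3))
    h_mean = float(np.mean(lat.spacing))

    def _sample(field, p):
        return ndimage.map_coordinates(field, (p / spacing).T, order=1, mode="nearest")

    def _normals(p):
        n = np.stack([_sample(n_out[ax], p) for ax in range(3)], axis=-1)
        return n / np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-12)

    # Newton-project onto {phi = 0.5}; phi decreases along the outward normal
    for _ in range(2):
        val = _sample(phi, pts)
        slope = np.maximum(_sample(gnorm, pts), 1e-6)
        step = np.clip((val - 0.5) / slope, -h_mean, h_mean)
        pts = pts + step[:, None] * _normals(pts)

    curv = 0.5 * _sample(div, pts)
    push = np.clip(_LEVEL_CURVATURE_BIAS * h_mean**2 * curv, -0.35 * h_mean, 0.35 * h_mean)
    pts = pts + push[:, None] * _normals(pts)

    # index->mm: padded, refined voxel centers; padded voxel 0 center sits one
    # original voxel before the origin, and refinement offsets centers by
    # (refine-1)/(2*refine) of an original voxel.
    shift = np.array(
        [o - h - (refine - 1) / (2.0 * refine) * h for o, h in zip(lat.origin, lat.spacing)]
    )
    return pts + shift


def expand_mask(
    mask: StructureMask,
    signed_distance_mm: float,
    label: str | None = None,
    supersample: int = 3,
) -> StructureMask:
    """Offset a structure boundary by a signed distance (positive = outward).

    The boundary is the 0.5 level of the fractional occupancy, extracted as a
    sub-voxel-accurate marching-cubes surface. Each subvoxel center (at
    ``supersample`` per axis) is assigned the unsigned Euclidean distance to
    the nearest surface sample (KD-tree), signed by the interpolated occupancy;
    the offset region ``{signed distance <= d}`` is thresholded with linear
    anti-aliasing over one subvoxel and block-averaged back to fractional
    occupancy on the original lattice.

    Raises
    ------
    DegenerateStructureError
        If the input is empty or the contraction empties the mask.
    DomainError
        If ``|signed_distance_mm|`` exceeds half the smallest grid extent.
    """
    from scipy.spatial import cKDTree

    lat = mask.lattice
    d = float(signed_distance_mm)
    half_extent = min(n * h for n, h in zip(lat.shape, lat.spacing)) / 2.0
    if abs(d) >= half_extent:
        raise DomainError(
            f"|signed distance| {abs(d)} mm must be < half the grid extent ({half_extent} mm)"
        )
    if mask.is_empty():
        raise DegenerateStructureError(f"mask {mask.label!r} is empty")
    new_label = label if label is not None else _offset_label(mask.label, d)
    if d == 0.0:
        return replace(mask, label=new_label)

    occ_new_u = offset_subvoxel_occupancy(mask, d, supersample)
    u = int(supersample)
    nz, ny, nx = lat.shape
    occ_new = occ_new_u.reshape(nz, u, ny, u, nx, u).mean(axis=(1, 3, 5))
    out = StructureMask(occ_new, label=new_label, spacing=lat.spacing, origin=lat.origin)
    if out.is_empty(atol=1e-9):
        raise DegenerateStructureError(
            f"contracting {mask.label!r} by {abs(d)} mm empties the structure"
        )
    return out


def offset_subvoxel_occupancy(
    mask: StructureMask, signed_distance_mm: float, supersample: int
) -> np.ndarray:
    """Sharp anti-aliased occupancy of the offset region on the subvoxel lattice.

    Returns the occupancy of ``{signed distance to boundary <= d}`` sampled at
    ``supersample`` subvoxels per axis (shape ``supersample * mask.shape``).
    With ``d = 0`` this re-sharpens a fractional mask to sub-voxel resolution:
    unlike linear interpolation of the occupancy field (which smears the
    boundary over a full voxel), each subvoxel is classified against the
    reconstructed 0.5-level surface.
    """
    from scipy.spatial import cKDTree

    lat = mask.lattice
    u = int(supersample)
    d = float(signed_distance_mm)
    tree = cKDTree(_boundary_point_cloud(mask))
    occ_u = ndimage.zoom(mask.occupancy, u, order=1, mode="nearest", grid_mode=True)
    h = float(np.mean(lat.spacing)) / u

    # distances are only needed within a band of |d| (+ margin) around the
    # boundary; outside it the offset occupancy is trivially 0 or 1
    frac = (mask.occupancy > 0) & (mask.occupancy < 1)
    if not frac.any():
        frac = ndimage.binary_dilation(mask.occupancy >= 0.5) ^ (mask.occupancy >= 0.5)
    reach = int(np.ceil(abs(d) / float(min(lat.spacing)))) + 2
    band = ndimage.binary_dilation(frac, iterations=reach)
    band_u = np.kron(band, np.ones((u, u, u), dtype=bool))

    occ_new_u = np.where(occ_u >= 0.5, 1.0, 0.0)
    iz, iy, ix = np.nonzero(band_u)
    zc = _subvoxel_axis(lat, 0, u).ravel()
    yc = _subvoxel_axis(lat, 1, u).ravel()
    xc = _subvoxel_axis(lat, 2, u).ravel()
    pts = np.stack([zc[iz], yc[iy], xc[ix]], axis=-1)
    dist = tree.query(pts, workers=-1)[0]
    sd = np.where(occ_u[iz, iy, ix] >= 0.5, -dist, dist)
    # occupancy of the offset region {sd <= d}, anti-aliased over one subvoxel
    occ_new_u[iz, iy, ix] = np.clip(0.5 - (sd - d) / h, 0.0, 1.0)
    return occ_new_u


def _offset_label(label: str, d: float) -> str:
    sign = "+" if d >= 0 else "-"
    mag = abs(d)
    mag_s = f"{mag:g}"
    return f"{label} {sign} {mag_s} mm"
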