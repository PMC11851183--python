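"""Synthetic voxel phantoms, structure sets and ground-truth deformation fields.

Everything downstream of this module (raytracing, plan construction, adaptation,
optimization) is exercised on phantoms generated here, so the generators are
deterministic pure functions of their configuration and seed.

Conventions
-----------
* DICOM-like patient coordinate system: x = patient-left, y = patient-posterior,
  z = patient-superior.  All positions and spacings are in millimetres.
* Grids are numpy arrays indexed ``[ix, iy, iz]``; the centre of voxel
  ``(0, 0, 0)`` sits at ``origin`` and voxel ``(i, j, k)`` at
  ``origin + (i, j, k) * spacing``.
* Deformation fields map points of the first image ("CT1") onto the second
  ("CT2"): spot positions are pushed forward by adding the interpolated vector,
  images are resampled by pulling back through the (numerically inverted) field.
* Air is assigned a relative stopping power of 0.001 rather than 0 so that
  water-equivalent path integrals stay well defined along any ray.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: relative stopping power assigned to air voxels (keeps WEPL integrals defined)
AIR_RSP = 0.001
#: Gaussian smoothing sigma, in voxels, applied to every synthetic field
FIELD_SMOOTH_SIGMA_VOX = 3.0

ROLE_TAGS = ("target_high", "target_low", "oar_serial", "body", "cavity")


class GeometryError(ValueError):
    """Requested phantom geometry cannot be honoured (violated margin etc.)."""


class LatticeMismatchError(ValueError):
    """Two objects that must share a voxel lattice do not."""


class InvalidFieldError(ValueError):
    """A deformation field folds onto itself (non-positive Jacobian)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    return a


@dataclass
class VoxelGrid:
    """A 3-D relative-stopping-power scalar field standing in for a CT.

    Attributes
    ----------
    values : (nx, ny, nz) float array, dimensionless RSP (water = 1.0)
    spacing : (3,) voxel spacing in mm
    origin : (3,) position in mm of the centre of voxel (0, 0, 0)
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.spacing = _as_vec3(self.spacing)
        self.origin = _as_vec3(self.origin)
        if self.values.ndim != 3 or min(self.values.shape) < 8:
            raise ValueError(f"grid shape must be 3-D and >= (8,8,8), got {self.values.shape}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if np.any(self.values < 0):
            raise ValueError("relative stopping power must be >= 0 everywhere")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_lattice(self, other) -> bool:
        return (
            self.shape == tuple(other.shape)
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def bounding_box(self) -> Tuple[np.ndarray, np.ndarray]:
        """World-space box spanned by the outer voxel faces, (lo, hi) in mm."""
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.shape) - 0.5) * self.spacing
        return lo, hi

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of world points, shape (..., 3)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def sample(self, points: np.ndarray, order: int = 1, fill: float = AIR_RSP) -> np.ndarray:
        """Interpolate grid values at world points (trilinear by default)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ci = self.world_to_index(pts).T
        out = ndimage.map_coordinates(
            self.values.astype(float), ci, order=order, mode="constant", cval=fill
        )
        return out if np.asarray(points).ndim > 1 else float(out[0])

    def world_axes(self):
        """Per-axis world coordinates of voxel centres."""
        return [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        ]


@dataclass
class StructureSet:
    """Named binary masks on a common lattice plus a role tag for each mask."""

    masks: Dict[str, np.ndarray]
    roles: Dict[str, str]
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.spacing = _as_vec3(self.spacing)
        self.origin = _as_vec3(self.origin)
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise LatticeMismatchError(f"masks disagree on shape: {shapes}")
        for name, role in self.roles.items():
            if role not in ROLE_TAGS:
                raise ValueError(f"unknown role {role!r} for mask {name!r}")
        for name in self.masks:
            self.masks[name] = np.asarray(self.masks[name], dtype=bool)

    def mask(self, name: str) -> np.ndarray:
        return self.masks[name]

    def by_role(self, role: str) -> Dict[str, np.ndarray]:
        return {n: self.masks[n] for n, r in self.roles.items() if r == role}

    def target_union(self) -> np.ndarray:
        out = np.zeros(next(iter(self.masks.values())).shape, dtype=bool)
        for role in ("target_high", "target_low"):
            for m in self.by_role(role).values():
                out |= m
        return out

    def validate_against(self, grid: VoxelGrid) -> None:
        for name, m in self.masks.items():
            if m.shape != grid.shape:
                raise LatticeMismatchError(
                    f"mask {name!r} shape {m.shape} vs grid {grid.shape}"
                )
        if not (np.allclose(self.spacing, grid.spacing) and np.allclose(self.origin, grid.origin)):
            raise LatticeMismatchError(
                f"structure lattice ({self.spacing}, {self.origin}) vs "
                f"grid ({grid.spacing}, {grid.origin})"
            )


@dataclass
class DeformationField:
    """Per-voxel displacement in mm mapping CT1 space into CT2 space."""

    vectors: np.ndarray  # (nx, ny, nz, 3)
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        self.spacing = _as_vec3(self.spacing)
        self.origin = _as_vec3(self.origin)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(f"field must have shape (nx,ny,nz,3), got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise InvalidFieldError("deformation field contains non-finite vectors")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.vectors.shape[:3]

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.vectors.astype(float) ** 2).sum(axis=-1)).max())

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear displacement vectors at world points, shape (..., 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ci = ((pts - self.origin) / self.spacing).T
        comps = [
            ndimage.map_coordinates(
                self.vectors[..., c].astype(float), ci, order=1, mode="constant", cval=0.0
            )
            for c in range(3)
        ]
        out = np.stack(comps, axis=-1)
        return out if np.asarray(points).ndim > 1 else out[0]

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.shape) - 0.5) * self.spacing
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((pts >= lo) & (pts <= hi), axis=-1)


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Parameters of the head-and-neck-like synthetic phantom.

    The body is a water-equivalent elliptical cylinder in air; a spherical
    high-dose target and a surrounding low-dose target ellipsoid are embedded
    in it, with a serial organ at risk (cord-like cylinder along z) posterior
    to the targets and an optional air cavity anterior to them.
    """

    shape: Tuple[int, int, int] = (64, 64, 64)
    spacing: Tuple[float, float, float] = (3.0, 3.0, 3.0)
    body_semiaxes_mm: Optional[Tuple[float, float]] = None  # default: 0.85/0.78 of the half-extent
    target_high_radius_mm: float = 20.0
    target_high_center_mm: Tuple[float, float, float] = (0.0, -6.0, 0.0)
    target_low_semiaxes_mm: Optional[Tuple[float, float, float]] = (28.0, 26.0, 26.0)  # None disables
    oar_offset_mm: float = 38.0     # posterior (+y) offset of OAR axis from target centre
    oar_radius_mm: float = 5.0
    oar_halflength_mm: float = 70.0
    cavity_radius_mm: float = 0.0   # 0 disables the air cavity
    cavity_center_mm: Tuple[float, float, float] = (0.0, -45.0, 0.0)
    rsp_noise_sd: float = 0.015     # smooth seeded RSP texture inside the body
    center_jitter_mm: float = 3.0   # seeded jitter of the target centre
    seed: int = 0


def _ellipsoid_mask(grid_axes, center, semiaxes) -> np.ndarray:
    X, Y, Z = np.meshgrid(*grid_axes, indexing="ij")
    a, b, c = semiaxes
    return ((X - center[0]) / a) ** 2 + ((Y - center[1]) / b) ** 2 + (
        (Z - center[2]) / c
    ) ** 2 <= 1.0


def make_phantom(config: PhantomConfig) -> Tuple[VoxelGrid, StructureSet]:
    """Generate a seeded phantom grid and its structure set.

    Deterministic for a fixed configuration: the seed drives a small jitter of
    the target centre and a smooth RSP texture inside the body so that distinct
    seeds give genuinely distinct anatomies.

    Raises
    ------
    GeometryError
        If a target or the OAR does not fit inside the body with a 2-voxel
        margin, or the structures overlap.
    """
    shape = tuple(int(s) for s in config.shape)
    if min(shape) < 32:
        raise GeometryError(f"phantom shape must be >= (32,32,32), got {shape}")
    spacing = _as_vec3(config.spacing)
    # centre the lattice on the patient origin
    origin = -(np.array(shape) - 1) / 2.0 * spacing
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    rng = np.random.default_rng(config.seed)

    jitter = rng.uniform(-config.center_jitter_mm, config.center_jitter_mm, size=3)
    t_center = np.asarray(config.target_high_center_mm) + jitter

    if config.body_semiaxes_mm is None:
        half = (np.array(shape) - 1) / 2.0 * spacing
        ax, ay = 0.85 * half[0], 0.78 * half[1]
    else:
        ax, ay = config.body_semiaxes_mm
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    body = ((X / ax) ** 2 + (Y / ay) ** 2) <= 1.0  # elliptical cylinder, full z

    target_high = _ellipsoid_mask(axes, t_center, [config.target_high_radius_mm] * 3)
    if config.target_low_semiaxes_mm is not None:
        target_low = _ellipsoid_mask(axes, t_center, config.target_low_semiaxes_mm)
        target_low &= ~target_high  # targets never overlap
    else:
        target_low = None

    oar_center_y = t_center[1] + config.oar_offset_mm
    oar = ((X - t_center[0]) ** 2 + (Y - oar_center_y) ** 2 <= config.oar_radius_mm**2) & (
        np.abs(Z - t_center[2]) <= config.oar_halflength_mm
    )

    masks = {"body": body, "target_high": target_high, "oar": oar}
    roles = {"body": "body", "target_high": "target_high", "oar": "oar_serial"}
    if target_low is not None:
        masks["target_low"] = target_low
        roles["target_low"] = "target_low"

    cavity = None
    if config.cavity_radius_mm > 0:
        cavity = _ellipsoid_mask(axes, config.cavity_center_mm, [config.cavity_radius_mm] * 3)
        masks["cavity"] = cavity
        roles["cavity"] = "cavity"

    # containment checks: 2-voxel margin inside the body
    margin_vox = 2
    body_core = ndimage.binary_erosion(body, iterations=margin_vox)
    for name in ("target_high", "target_low"):
        if name in masks and masks[name].any() and not np.all(body_core[masks[name]]):
            raise GeometryError(
                f"{name} violates the {margin_vox}-voxel containment margin inside the body"
            )
    if config.oar_radius_mm > 0 and (not oar.any() or not np.all(body[oar])):
        raise GeometryError("oar_serial empty or outside the body (check oar_offset_mm)")
    targets_union = target_high if target_low is None else (target_high | target_low)
    if np.any(oar & targets_union):
        raise GeometryError("oar_serial overlaps a target volume")

    values = np.full(shape, AIR_RSP, dtype=np.float32)
    values[body] = 1.0
    if config.rsp_noise_sd > 0:
        noise = rng.standard_normal(shape)
        noise = ndimage.gaussian_filter(noise, sigma=3.0)
        noise *= config.rsp_noise_sd / max(noise.std(), 1e-12)
        values[body] = np.maximum(values[body] + noise[body].astype(np.float32), 0.2)
    if cavity is not None:
        values[cavity] = AIR_RSP

    grid = VoxelGrid(values=values, spacing=spacing, origin=origin)
    structures = StructureSet(masks=masks, roles=roles, spacing=spacing, origin=origin)
    structures.validate_against(grid)
    return grid, structures


# ---------------------------------------------------------------------------
# deformation fields
# ---------------------------------------------------------------------------

DEFORMATION_KINDS = ("identity", "rigid_shift", "target_shift", "target_shrink", "surface_erosion")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """C1 cubic smoothstep: 0 below 0, 1 above 1, 3t^2 - 2t^3 between."""
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _jacobian_determinant(vectors: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Determinant of d(phi)/dx with phi(x) = x + u(x), central differences."""
    J = np.empty(vectors.shape[:3] + (3, 3))
    for c in range(3):
        grads = np.gradient(vectors[..., c].astype(float), *spacing, axis=(0, 1, 2))
        for a in range(3):
            J[..., c, a] = grads[a]
        J[..., c, c] += 1.0
    return np.linalg.det(J)


def make_deformation_field(
    grid: VoxelGrid,
    kind: str,
    magnitude: float,
    structures: Optional[StructureSet] = None,
    direction: Optional[Sequence[float]] = None,
    seed: int = 0,
    boundary_margin_mm: float = 8.0,
    taper_mm: float = 16.0,
    target_taper_mm: float = 24.0,
) -> DeformationField:
    """Build a smooth synthetic displacement field of the requested kind.

    Taper weights are C1 smoothstep functions of the distance transform, so
    plateaus are exact (the core of a shift moves rigidly by exactly the
    requested vector) and the field is differentiable everywhere.

    Parameters
    ----------
    kind
        One of ``identity``, ``rigid_shift`` (body interior translated,
        tapering to zero toward the body surface and exactly zero outside the
        dilated body), ``target_shift`` (local translation of the target
        region), ``target_shrink`` (radial contraction toward the target
        centroid; ``magnitude`` is the linear shrink fraction) or
        ``surface_erosion`` (inward displacement of the body surface).
    magnitude
        Displacement in mm, or the shrink fraction for ``target_shrink``.
    direction
        Unit direction for the shift kinds; a seeded random direction when
        omitted.
    """
    if kind not in DEFORMATION_KINDS:
        raise ValueError(f"unknown deformation kind {kind!r}; choose from {DEFORMATION_KINDS}")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    shape = grid.shape
    vectors = np.zeros(shape + (3,), dtype=np.float32)
    if kind == "identity" or magnitude == 0:
        return DeformationField(vectors=vectors, spacing=grid.spacing, origin=grid.origin)

    rng = np.random.default_rng(seed)
    if direction is None:
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
    else:
        d = _as_vec3(direction)
        d /= np.linalg.norm(d)

    if structures is None:
        raise ValueError(f"kind {kind!r} requires a StructureSet (body/target masks)")
    body = structures.by_role("body")
    if not body:
        raise ValueError("structure set has no body mask")
    body_mask = next(iter(body.values()))
    margin_vox = max(1, int(round(boundary_margin_mm / float(grid.spacing.min()))))
    support = ndimage.binary_dilation(body_mask, iterations=margin_vox)

    axes = grid.world_axes()
    if kind == "rigid_shift":
        # interior translation: full displacement in the body core, fading to
        # zero at the body surface so the surrounding air stays in place
        d_in = ndimage.distance_transform_edt(support, sampling=grid.spacing)
        w = _smoothstep((d_in - boundary_margin_mm) / taper_mm)
        vectors = (w[..., None] * (magnitude * d)).astype(np.float32)
    elif kind in ("target_shift", "target_shrink"):
        targets = structures.by_role("target_high")
        if not targets:
            raise ValueError(f"kind {kind!r} requires a target_high mask")
        t_mask = next(iter(targets.values()))
        d_out = ndimage.distance_transform_edt(~t_mask, sampling=grid.spacing)
        w = _smoothstep(1.0 - d_out / target_taper_mm)
        if kind == "target_shift":
            vectors = (w[..., None] * (magnitude * d)).astype(np.float32)
        else:
            idx = np.argwhere(t_mask)
            centroid = grid.index_to_world(idx.mean(axis=0))
            X, Y, Z = np.meshgrid(*axes, indexing="ij")
            rel = np.stack([X - centroid[0], Y - centroid[1], Z - centroid[2]], axis=-1)
            vectors = (-magnitude * w[..., None] * rel).astype(np.float32)
    else:  # surface_erosion
        g = ndimage.gaussian_filter(body_mask.astype(float), sigma=FIELD_SMOOTH_SIGMA_VOX)
        grads = np.gradient(g, *grid.spacing, axis=(0, 1, 2))
        gvec = np.stack(grads, axis=-1)  # points inward (toward higher occupancy)
        gn = np.linalg.norm(gvec, axis=-1)
        w = gn / max(gn.max(), 1e-12)
        nhat = gvec / np.maximum(gn[..., None], 1e-12)
        vectors = (w[..., None] * nhat).astype(np.float32)

    vectors[~support] = 0.0

    if kind == "surface_erosion":
        # normalize so the peak displacement equals the requested magnitude
        mags = np.sqrt((vectors.astype(float) ** 2).sum(axis=-1))
        peak = mags.max()
        if peak > 0:
            vectors = (vectors * (magnitude / peak)).astype(np.float32)

    fld = DeformationField(vectors=vectors, spacing=grid.spacing, origin=grid.origin)
    detj = _jacobian_determinant(fld.vectors, grid.spacing)
    if np.any(detj <= 0):
        raise InvalidFieldError(
            f"field folds: min Jacobian determinant {detj.min():.3f} <= 0 "
            f"(kind={kind}, magnitude={magnitude})"
        )
    return fld


def invert_field(fld: DeformationField, iterations: int = 10) -> DeformationField:
    """Fixed-point inverse of a displacement field.

    Solves v(y) = -u(y + v(y)) so that resampling an image at ``y + v(y)``
    realizes the pull-back of the forward map phi(x) = x + u(x).  Exact in one
    step for constant fields; converges for the smooth small-strain fields
    produced here.
    """
    shape = fld.shape
    axes = [fld.origin[a] + np.arange(shape[a]) * fld.spacing[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    v = -fld.sample(pts)
    for _ in range(iterations):
        v = -fld.sample(pts + v)
    return DeformationField(
        vectors=v.reshape(shape + (3,)).astype(np.float32),
        spacing=fld.spacing,
        origin=fld.origin,
    )


def warp_grid(
    grid: VoxelGrid,
    fld: DeformationField,
    interpolation: str = "linear",
    fill: float = AIR_RSP,
    _inverse: Optional[DeformationField] = None,
) -> VoxelGrid:
    """Resample a grid through a CT1->CT2 field, producing the CT2 image.

    A zero field returns a bit-identical copy.  Constant integer-voxel
    translations with nearest interpolation reduce to an exact array shift with
    ``fill`` (air by default) padded at the edges.
    """
    if grid.shape != fld.shape or not (
        np.allclose(grid.spacing, fld.spacing) and np.allclose(grid.origin, fld.origin)
    ):
        raise LatticeMismatchError(
            f"grid lattice (shape={grid.shape}, spacing={grid.spacing}, origin={grid.origin})"
            f" != field lattice (shape={fld.shape}, spacing={fld.spacing}, origin={fld.origin})"
        )
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"interpolation must be linear|nearest, got {interpolation!r}")
    if not np.any(fld.vectors):
        return VoxelGrid(values=grid.values.copy(), spacing=grid.spacing, origin=grid.origin)
    inv = _inverse if _inverse is not None else invert_field(fld)
    shape = grid.shape
    axes = grid.world_axes()
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3) + inv.vectors.reshape(-1, 3)
    ci = grid.world_to_index(pts).T
    order = 1 if interpolation == "linear" else 0
    vals = ndimage.map_coordinates(
        grid.values.astype(float), ci, order=order, mode="constant", cval=fill
    ).reshape(shape)
    return VoxelGrid(values=np.maximum(vals, 0.0), spacing=grid.spacing, origin=grid.origin)


def warp_structures(
    structures: StructureSet,
    fld: DeformationField,
    _inverse: Optional[DeformationField] = None,
) -> StructureSet:
    """Warp every mask of a structure set (linear occupancy, 0.5 level set)."""
    inv = _inverse
    if inv is None and np.any(fld.vectors):
        inv = invert_field(fld)
    out = {}
    for name, m in structures.masks.items():
        g = VoxelGrid(
            values=m.astype(np.float32), spacing=structures.spacing, origin=structures.origin
        )
        w = warp_grid(g, fld, interpolation="linear", fill=0.0, _inverse=inv)
        out[name] = w.values > 0.5
    # preserve target disjointness under nearest-neighbour rounding
    for lo_name, lo_role in structures.roles.items():
        if lo_role == "target_low":
            for hi_name, hi_role in structures.roles.items():
                if hi_role == "target_high":
                    out[lo_name] &= ~out[hi_name]
    return StructureSet(
        masks=out, roles=dict(structures.roles),
        spacing=structures.spacing, origin=structures.origin,
    )


# ---------------------------------------------------------------------------
# MetaImage I/O (SimpleITK behind the scenes)
# ---------------------------------------------------------------------------

def write_metaimage(obj, path) -> None:
    """Write a VoxelGrid (float32), mask (uint8) or DeformationField (vector)."""
    import SimpleITK as sitk

    path = str(path)
    if isinstance(obj, DeformationField):
        arr = np.transpose(obj.vectors, (2, 1, 0, 3)).astype(np.float32)
        img = sitk.GetImageFromArray(arr, isVector=True)
        spacing, origin = obj.spacing, obj.origin
    elif isinstance(obj, VoxelGrid):
        arr = np.transpose(obj.values, (2, 1, 0)).astype(np.float32)
        img = sitk.GetImageFromArray(arr)
        spacing, origin = obj.spacing, obj.origin
    else:
        raise TypeError(f"cannot write object of type {type(obj)!r}")
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, path)


def write_mask(mask: np.ndarray, spacing, origin, path) -> None:
    import SimpleITK as sitk

    arr = np.transpose(mask.astype(np.uint8), (2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in _as_vec3(spacing)))
    img.SetOrigin(tuple(float(o) for o in _as_vec3(origin)))
    sitk.WriteImage(img, str(path))


def read_metaimage(path):
    """Read a MetaImage into a VoxelGrid or DeformationField (if vector-valued)."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    spacing = np.array(img.GetSpacing())
    origin = np.array(img.GetOrigin())
    arr = sitk.GetArrayFromImage(img)
    if img.GetNumberOfComponentsPerPixel() == 3:
        vec = np.transpose(arr, (2, 1, 0, 3))
        return DeformationField(vectors=vec, spacing=spacing, origin=origin)
    vals = np.transpose(arr, (2, 1, 0))
    return VoxelGrid(values=vals.astype(np.float32), spacing=spacing, origin=origin)
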