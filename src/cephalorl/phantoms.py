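"""Synthetic CT skull phantoms with analytically known landmarks.

Each phantom is an ellipsoidal cortical-bone shell (~1200 HU) with a thin
soft-tissue layer (~40 HU) over it and air (-1000 HU) inside and outside,
carrying three landmark-bearing features that mirror the geometric classes
of craniofacial landmarks:

* ``proto_ans``  -- apex of a bony protrusion on the anterior surface
  (a surface-extremum point, like the anterior nasal spine or nasion);
* ``proto_sella`` -- centre of a spherical air cavity inside an internal
  bone mass (a confined-space point, like sella turcica);
* ``proto_foramen`` -- point where the axis of a cylindrical canal through
  the lower shell pierces the outer surface (a foramen-type point).

Ground-truth coordinates are computed in continuous world space from the
jittered analytic geometry *before* rasterisation, so truth is independent
of voxelisation and sub-voxel detection error is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import HU_MAX, HU_MIN, LandmarkSet, Volume

PHANTOM_LANDMARK_TYPES = {"proto_ans": 2, "proto_sella": 2, "proto_foramen": 3}


@dataclass
class PhantomSpec:
    """Geometry and randomisation parameters of the skull phantom.

    Defaults give a 64 mm cube at 1 mm isotropic spacing; per-subject
    variation comes from uniform jitter of the shell centre and radii
    (±1.5 mm) plus additive Gaussian HU noise (sigma 30 HU, a typical CT
    noise level).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shell_radii: tuple[float, float, float] = (18.0, 21.0, 19.0)
    shell_thickness: float = 4.0
    soft_thickness: float = 1.5
    bone_hu: float = 1200.0
    soft_hu: float = 40.0
    air_hu: float = -1000.0
    bump_radius: float = 2.5
    blob_radius: float = 5.0
    blob_offset: tuple[float, float, float] = (0.0, 1.0, -7.0)
    cavity_radius: float = 2.2
    canal_radius: float = 2.2
    canal_offset: tuple[float, float] = (5.0, 0.0)  # (x, y) offset of canal axis
    jitter: float = 1.5
    noise_sigma: float = 30.0
    margin_voxels: int = 4


class PhantomGeometryError(RuntimeError):
    """Raised when jitter cannot satisfy the geometric invariants."""


@dataclass
class _Geometry:
    center: np.ndarray
    radii: np.ndarray
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def inner_radii(self) -> np.ndarray:
        return self.radii - self.spec.shell_thickness

    @property
    def bump_center(self) -> np.ndarray:
        return self.center + np.array([0.0, self.radii[1], 0.0])

    @property
    def blob_center(self) -> np.ndarray:
        return self.center + np.asarray(self.spec.blob_offset, dtype=float)

    def canal_surface_z(self) -> float:
        dx, dy = self.spec.canal_offset
        t = 1.0 - (dx / self.radii[0]) ** 2 - (dy / self.radii[1]) ** 2
        return float(self.center[2] - self.radii[2] * np.sqrt(t))

    def landmarks(self) -> LandmarkSet:
        dx, dy = self.spec.canal_offset
        return LandmarkSet(
            entries={
                "proto_ans": self.bump_center + np.array([0.0, self.spec.bump_radius, 0.0]),
                "proto_sella": self.blob_center.copy(),
                "proto_foramen": np.array(
                    [self.center[0] + dx, self.center[1] + dy, self.canal_surface_z()]
                ),
            },
            types=dict(PHANTOM_LANDMARK_TYPES),
        )


def _world_bounds(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(spec.origin, dtype=float)
    sp = np.asarray(spec.spacing, dtype=float)
    return o, o + (np.asarray(spec.shape) - 1) * sp


def _valid_geometry(g: _Geometry) -> bool:
    spec = g.spec
    lo, hi = _world_bounds(spec)
    margin = spec.margin_voxels * np.asarray(spec.spacing, dtype=float)
    outer = g.radii + spec.soft_thickness
    if np.any(g.center - outer - spec.bump_radius < lo + margin):
        return False
    if np.any(g.center + outer + spec.bump_radius > hi - margin):
        return False
    if np.any(g.inner_radii <= spec.blob_radius):
        return False
    # internal bone mass (and its cavity) strictly inside the shell interior
    rel = (g.blob_center - g.center) / g.inner_radii
    if np.sqrt((rel**2).sum()) + spec.blob_radius / g.inner_radii.min() >= 0.95:
        return False
    if spec.cavity_radius >= spec.blob_radius - 1.5:
        return False
    dx, dy = spec.canal_offset
    if 1.0 - (dx / g.radii[0]) ** 2 - (dy / g.radii[1]) ** 2 < 0.1:
        return False
    lms = g.landmarks()
    return all(np.all(p > lo) and np.all(p < hi) for p in lms.entries.values())


def _jittered_geometry(spec: PhantomSpec, rng: np.random.Generator) -> _Geometry:
    lo, hi = _world_bounds(spec)
    base_center = 0.5 * (lo + hi)
    for _ in range(100):
        g = _Geometry(
            center=base_center + rng.uniform(-spec.jitter, spec.jitter, size=3),
            radii=np.asarray(spec.shell_radii, dtype=float)
            + rng.uniform(-spec.jitter, spec.jitter, size=3),
            spec=spec,
        )
        if _valid_geometry(g):
            return g
    raise PhantomGeometryError("could not satisfy phantom invariants in 100 jitter draws")


def _rasterize(g: _Geometry) -> np.ndarray:
    spec = g.spec
    o = np.asarray(spec.origin, dtype=float)
    sp = np.asarray(spec.spacing, dtype=float)
    coords = [o[i] + np.arange(spec.shape[i]) * sp[i] for i in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")

    def ellipsoid_rho(radii: np.ndarray) -> np.ndarray:
        return (
            ((X - g.center[0]) / radii[0]) ** 2
            + ((Y - g.center[1]) / radii[1]) ** 2
            + ((Z - g.center[2]) / radii[2]) ** 2
        )

    rho_outer = ellipsoid_rho(g.radii)
    rho_inner = ellipsoid_rho(g.inner_radii)
    rho_soft = ellipsoid_rho(g.radii + spec.soft_thickness)

    def sphere(center: np.ndarray, radius: float) -> np.ndarray:
        return (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius**2

    hu = np.full(spec.shape, spec.air_hu, dtype=np.float32)
    hu[(rho_soft <= 1.0) & (rho_outer > 1.0)] = spec.soft_hu
    bone = (rho_outer <= 1.0) & (rho_inner > 1.0)
    bone |= sphere(g.bump_center, spec.bump_radius)
    bone |= sphere(g.blob_center, spec.blob_radius)
    hu[bone] = spec.bone_hu
    hu[sphere(g.blob_center, spec.cavity_radius)] = spec.air_hu
    dx, dy = spec.canal_offset
    # the canal pierces the lower shell wall (and its soft-tissue cover)
    # only; the interior is already air and must stay untouched so the
    # canal cannot drill through interior structures
    canal = (
        ((X - g.center[0] - dx) ** 2 + (Y - g.center[1] - dy) ** 2 <= spec.canal_radius**2)
        & (Z <= g.center[2])
        & (rho_inner >= 1.0)
    )
    hu[canal] = spec.air_hu
    return hu


def generate_phantom(
    spec: PhantomSpec | None = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[Volume, LandmarkSet]:
    """Generate one jittered phantom; deterministic for a given (spec, seed)."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    g = _jittered_geometry(spec, rng)
    hu = _rasterize(g)
    if spec.noise_sigma > 0:
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=hu.shape).astype(np.float32)
        hu = np.clip(hu, HU_MIN, HU_MAX)
    vol = Volume(voxels=hu, spacing=np.asarray(spec.spacing), origin=np.asarray(spec.origin))
    lms = g.landmarks()
    lms.validate_against(vol)
    return vol, lms


def generate_cohort(
    spec: PhantomSpec | None = None,
    n: int = 20,
    seed: int | np.random.SeedSequence | None = 0,
) -> list[tuple[Volume, LandmarkSet]]:
    """Generate ``n`` independent jittered phantoms from one master seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or PhantomSpec()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [generate_phantom(spec, child) for child in ss.spawn(n)]
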