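"""Orthographic volume rendering of CT views used as DRL environments.

Views are named by anatomical codes: plain views ``tv`` (top), ``bv``
(bottom), ``av`` (anterior), ``pv`` (posterior), ``rv``/``lv`` (right/left
lateral), and cutaway views ``scrv``/``sclv`` (sagittal-cut right/left
lateral), ``actv``/``acbv`` (axial-cut top/bottom) and ``ccpv`` (coronal-cut
posterior).  Rays are parallel and axis-aligned, so the pixel-to-world
mapping is affine and exactly invertible: this is what lets a 2D agent
position be converted back into world coordinates and rays.

Compositing is front-to-back with a piecewise-linear HU transfer function
(opacity treated as extinction per mm of path) plus exponential depth
cueing, which makes surface relief and cut cavities visible without
gradient shading.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volume_io import Volume

AXIS_NAMES = ("x", "y", "z")

# code -> (ray_axis, ray_sign, u_axis, u_sign, v_axis, v_sign, cut_axis)
# ray_sign is the direction rays travel (viewer sits on the opposite side).
_VIEW_TABLE: dict[str, tuple[int, int, int, int, int, int, int | None]] = {
    "tv": (2, -1, 0, +1, 1, -1, None),
    "bv": (2, +1, 0, -1, 1, -1, None),
    "av": (1, -1, 0, -1, 2, -1, None),
    "pv": (1, +1, 0, +1, 2, -1, None),
    "rv": (0, -1, 1, +1, 2, -1, None),
    "lv": (0, +1, 1, -1, 2, -1, None),
    "scrv": (0, -1, 1, +1, 2, -1, 0),
    "sclv": (0, +1, 1, -1, 2, -1, 0),
    "actv": (2, -1, 0, +1, 1, -1, 2),
    "acbv": (2, +1, 0, -1, 1, -1, 2),
    "ccpv": (1, +1, 0, +1, 2, -1, 1),
}

VIEW_CODES = tuple(_VIEW_TABLE)

#: fraction of the image width the largest in-plane extent maps to
#: (480 of 512 px, leaving a 16 px margin on each side).
_FILL_FRACTION = 480.0 / 512.0


class RenderError(RuntimeError):
    pass


@dataclass(frozen=True)
class CutPlane:
    """Axis-aligned cutting plane; voxels on the discarded side render
    fully transparent while their HU values are untouched."""

    axis: int
    position: float
    keep_side: str  # "below" | "above"

    def __post_init__(self) -> None:
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0 (x), 1 (y) or 2 (z)")
        if self.keep_side not in ("below", "above"):
            raise ValueError("keep_side must be 'below' or 'above'")
        if not np.isfinite(self.position):
            raise ValueError("cut position must be finite")


@dataclass(frozen=True)
class TransferFunction:
    """Piecewise-linear HU -> opacity and HU -> brightness maps.

    Both maps must be non-decreasing in HU; the bone preset is fully
    transparent below 200 HU (air and soft tissue) and fully opaque from
    700 HU (cortical bone), with brightness ramping 200 -> 1500 HU.
    """

    opacity_points: tuple[tuple[float, float], ...] = (
        (-1024.0, 0.0),
        (200.0, 0.0),
        (700.0, 1.0),
        (4000.0, 1.0),
    )
    brightness_points: tuple[tuple[float, float], ...] = (
        (-1024.0, 0.0),
        (200.0, 0.0),
        (1500.0, 1.0),
        (4000.0, 1.0),
    )

    def __post_init__(self) -> None:
        for pts, what in ((self.opacity_points, "opacity"), (self.brightness_points, "brightness")):
            xs = [p[0] for p in pts]
            ys = [p[1] for p in pts]
            if sorted(xs) != list(xs) or sorted(ys) != list(ys):
                raise ValueError(f"{what} map must be non-decreasing in HU")
            if any(y < 0 or y > 1 for y in ys):
                raise ValueError(f"{what} values must lie in [0, 1]")

    def opacity(self, hu: np.ndarray) -> np.ndarray:
        xs, ys = zip(*self.opacity_points)
        return np.interp(hu, xs, ys)

    def brightness(self, hu: np.ndarray) -> np.ndarray:
        xs, ys = zip(*self.brightness_points)
        return np.interp(hu, xs, ys)


@dataclass(frozen=True)
class ViewSpec:
    """A named orthographic view: ray direction, image-axis -> world-axis
    map, output size and scale, and an optional cut plane."""

    code: str
    ray_axis: int
    ray_sign: int
    u_axis: int
    u_sign: int
    v_axis: int
    v_sign: int
    size: int = 512
    mm_per_pixel: float | None = None
    cut: CutPlane | None = None

    @classmethod
    def from_code(
        cls,
        code: str,
        size: int = 512,
        cut_position: float | None = None,
        mm_per_pixel: float | None = None,
    ) -> "ViewSpec":
        if code not in _VIEW_TABLE:
            raise ValueError(f"unknown view code {code!r}; known: {sorted(_VIEW_TABLE)}")
        ra, rs, ua, us, va, vs, cut_axis = _VIEW_TABLE[code]
        cut = None
        if cut_axis is not None:
            if cut_position is None:
                raise ValueError(f"cutaway view {code!r} requires cut_position")
            # keep the far side of the plane relative to the viewer, so the
            # cut exposes interior structure facing the camera
            keep = "below" if rs < 0 else "above"
            cut = CutPlane(axis=cut_axis, position=float(cut_position), keep_side=keep)
        elif cut_position is not None:
            raise ValueError(f"plain view {code!r} does not take a cut_position")
        return cls(
            code=code, ray_axis=ra, ray_sign=rs, u_axis=ua, u_sign=us,
            v_axis=va, v_sign=vs, size=size, mm_per_pixel=mm_per_pixel, cut=cut,
        )

    @property
    def ray_direction(self) -> np.ndarray:
        d = np.zeros(3)
        d[self.ray_axis] = self.ray_sign
        return d

    def in_plane_axes(self) -> tuple[int, int]:
        return (self.u_axis, self.v_axis)


@dataclass(frozen=True)
class ViewGeometry:
    """Resolved pixel <-> world mapping for one rendered view of one volume."""

    spec: ViewSpec
    mm_per_pixel: float
    center: np.ndarray  # world-mm reference point mapping to the image centre
    ray_start: float  # world-mm coordinate (on ray_axis) where rays enter
    ray_length: float  # world-mm extent of the volume along the ray

    def project_point(self, p) -> np.ndarray:
        """Continuous pixel (u, v) of world point ``p`` (drops the depth)."""
        p = np.asarray(p, dtype=float)
        s = self.spec
        u = s.size / 2 + s.u_sign * (p[s.u_axis] - self.center[s.u_axis]) / self.mm_per_pixel
        v = s.size / 2 + s.v_sign * (p[s.v_axis] - self.center[s.v_axis]) / self.mm_per_pixel
        return np.array([u, v])

    def in_view(self, p) -> bool:
        u, v = self.project_point(p)
        return bool(0 <= u < self.spec.size and 0 <= v < self.spec.size)

    def pixel_to_inplane_world(self, u: float, v: float) -> dict[int, float]:
        """World coordinates of pixel (u, v) along the two image axes."""
        s = self.spec
        return {
            s.u_axis: self.center[s.u_axis] + s.u_sign * (u - s.size / 2) * self.mm_per_pixel,
            s.v_axis: self.center[s.v_axis] + s.v_sign * (v - s.size / 2) * self.mm_per_pixel,
        }

    def pixel_to_world_ray(self, u: float, v: float) -> tuple[np.ndarray, np.ndarray]:
        """World-space (origin, unit direction) of the ray cast for (u, v)."""
        s = self.spec
        if not (0 <= u < s.size and 0 <= v < s.size):
            raise ValueError(f"pixel ({u}, {v}) outside {s.size}x{s.size} image")
        origin = np.array(self.center, dtype=float)
        inplane = self.pixel_to_inplane_world(u, v)
        for ax, val in inplane.items():
            origin[ax] = val
        origin[s.ray_axis] = self.ray_start
        return origin, s.ray_direction

    def world_point(self, u: float, v: float, depth_coord: float) -> np.ndarray:
        """Assemble a 3D world point from a pixel and a ray-axis coordinate."""
        p = np.empty(3)
        inplane = self.pixel_to_inplane_world(u, v)
        for ax, val in inplane.items():
            p[ax] = val
        p[self.spec.ray_axis] = depth_coord
        return p


@dataclass
class ProjectedImage:
    """A rendered grayscale view plus the geometry to go back to 3D."""

    pixels: np.ndarray  # (size, size) float in [0, 1], indexed [v, u]
    geometry: ViewGeometry

    @property
    def spec(self) -> ViewSpec:
        return self.geometry.spec

    @property
    def size(self) -> int:
        return self.geometry.spec.size

    def project_point(self, p) -> np.ndarray:
        return self.geometry.project_point(p)

    def pixel_to_world_ray(self, u: float, v: float):
        return self.geometry.pixel_to_world_ray(u, v)

    def save_png(self, path) -> None:
        from PIL import Image  # optional; Pillow is in the scientific stack

        Image.fromarray((np.clip(self.pixels, 0, 1) * 255).astype(np.uint8)).save(str(path))


def resolve_geometry(v: Volume, spec: ViewSpec) -> ViewGeometry:
    """Fix the mm-per-pixel scale and reference point of a view for ``v``.

    The larger in-plane extent of the volume maps to 15/16 of the image
    width, leaving a margin; the volume centre maps to the image centre.
    """
    mmpp = spec.mm_per_pixel
    if mmpp is None:
        ext_u = v.world_max[spec.u_axis] - v.world_min[spec.u_axis]
        ext_v = v.world_max[spec.v_axis] - v.world_min[spec.v_axis]
        mmpp = max(ext_u, ext_v) / (spec.size * _FILL_FRACTION)
    if not np.isfinite(mmpp) or mmpp <= 0:
        raise RenderError(f"degenerate mm-per-pixel scale {mmpp!r}")
    if spec.ray_sign < 0:
        ray_start = v.world_max[spec.ray_axis]
    else:
        ray_start = v.world_min[spec.ray_axis]
    ray_len = v.world_max[spec.ray_axis] - v.world_min[spec.ray_axis]
    return ViewGeometry(
        spec=replace(spec, mm_per_pixel=float(mmpp)),
        mm_per_pixel=float(mmpp),
        center=v.world_center,
        ray_start=float(ray_start),
        ray_length=float(ray_len),
    )


def apply_cutaway(v: Volume, plane: CutPlane) -> Volume:
    """Mark voxels on the discarded side of ``plane`` as transparent."""
    coords = v.origin[plane.axis] + np.arange(v.shape[plane.axis]) * v.spacing[plane.axis]
    keep_1d = coords <= plane.position if plane.keep_side == "below" else coords >= plane.position
    shape = [1, 1, 1]
    shape[plane.axis] = -1
    keep = np.broadcast_to(keep_1d.reshape(shape), v.shape).copy()
    if v.mask is not None:
        keep &= v.mask
    if not keep.any():
        raise RenderError("empty render: cut plane discards every voxel")
    return Volume(voxels=v.voxels, spacing=v.spacing, origin=v.origin, mask=keep)


def render_view(
    v: Volume,
    spec: ViewSpec,
    tf: TransferFunction | None = None,
    depth_tau: float = 40.0,
) -> ProjectedImage:
    """Ray-cast an orthographic view of ``v``.

    Front-to-back compositing runs along the (axis-aligned) ray direction at
    half-voxel steps with linear inter-slice interpolation; the composited
    in-plane buffer is then resampled bilinearly onto the output pixel grid.
    Brightness is attenuated by ``exp(-depth / depth_tau)`` (depth in mm from
    the volume face) so nearer surfaces render brighter.
    """
    tf = tf or TransferFunction()
    geom = resolve_geometry(v, spec)

    alpha = tf.opacity(v.voxels)
    bright = tf.brightness(v.voxels)
    if v.mask is not None:
        alpha = alpha * v.mask
    if spec.cut is not None:
        masked = apply_cutaway(
            Volume(voxels=v.voxels, spacing=v.spacing, origin=v.origin, mask=v.mask), spec.cut
        )
        alpha = alpha * masked.mask

    ra = spec.ray_axis
    a = np.moveaxis(alpha, ra, -1)
    b = np.moveaxis(bright, ra, -1)
    if spec.ray_sign < 0:  # nearest-to-viewer slice first
        a = a[..., ::-1]
        b = b[..., ::-1]

    # half-voxel sampling along the ray via linear inter-slice interpolation
    n = a.shape[-1]
    step_mm = 0.5 * v.spacing[ra]
    n_samp = 2 * n - 1
    a_s = np.empty(a.shape[:2] + (n_samp,), dtype=np.float64)
    b_s = np.empty_like(a_s)
    a_s[..., 0::2] = a
    b_s[..., 0::2] = b
    a_s[..., 1::2] = 0.5 * (a[..., :-1] + a[..., 1:])
    b_s[..., 1::2] = 0.5 * (b[..., :-1] + b[..., 1:])

    # opacity is extinction per mm of path: alpha_step = 1 - (1-alpha)^step
    with np.errstate(divide="ignore"):
        a_step = -np.expm1(step_mm * np.log1p(-np.clip(a_s, 0.0, 1.0)))

    trans = np.ones(a.shape[:2])
    comp = np.zeros(a.shape[:2])
    depth_w = np.exp(-np.arange(n_samp) * step_mm / depth_tau)
    for k in range(n_samp):
        ak = a_step[..., k]
        comp += trans * ak * b_s[..., k] * depth_w[k]
        trans *= 1.0 - ak
        if trans.max() < 0.01:  # early termination at accumulated opacity 0.99
            break

    # resample the in-plane buffer (volume voxel grid) onto the pixel grid
    other_axes = [ax for ax in range(3) if ax != ra]  # ascending; comp dims
    idx = np.arange(spec.size)
    wu = geom.center[spec.u_axis] + spec.u_sign * (idx - spec.size / 2) * geom.mm_per_pixel
    wv = geom.center[spec.v_axis] + spec.v_sign * (idx - spec.size / 2) * geom.mm_per_pixel
    world = {spec.u_axis: wu, spec.v_axis: wv}
    # image is indexed [v, u]; wu varies with the column, wv with the row
    grids = []
    for ax in other_axes:
        ivox = (world[ax] - v.origin[ax]) / v.spacing[ax]
        if ax == spec.u_axis:
            grids.append(np.broadcast_to(ivox[None, :], (spec.size, spec.size)))
        else:
            grids.append(np.broadcast_to(ivox[:, None], (spec.size, spec.size)))
    c0, c1 = grids
    pixels = ndimage.map_coordinates(comp, [c0, c1], order=1, mode="constant", cval=0.0)
    return ProjectedImage(pixels=np.clip(pixels, 0.0, 1.0), geometry=geom)


def project_point(geom_or_img, p):
    """Module-level convenience: project a world point to pixel (u, v)."""
    geom = geom_or_img.geometry if isinstance(geom_or_img, ProjectedImage) else geom_or_img
    return geom.project_point(p)
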