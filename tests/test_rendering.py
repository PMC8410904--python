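"""Ray-cast view geometry and compositing properties."""

import numpy as np
import pytest

from cephalorl import (
    CutPlane,
    PhantomSpec,
    TransferFunction,
    VIEW_CODES,
    ViewSpec,
    Volume,
    apply_cutaway,
    generate_phantom,
    render_view,
)
from cephalorl.rendering import RenderError, resolve_geometry

CUT_CODES = ("scrv", "sclv", "actv", "acbv", "ccpv")


def _spec(code, size=128, cut=31.5):
    return ViewSpec.from_code(code, size=size, cut_position=cut if code in CUT_CODES else None)


def test_view_table_covers_all_codes():
    assert set(VIEW_CODES) == {"tv", "bv", "av", "pv", "rv", "lv", *CUT_CODES}
    for code in VIEW_CODES:
        s = _spec(code)
        assert {s.u_axis, s.v_axis, s.ray_axis} == {0, 1, 2}
        assert (s.cut is not None) == (code in CUT_CODES)


def test_cut_code_requires_position():
    with pytest.raises(ValueError, match="cut_position"):
        ViewSpec.from_code("sclv")
    with pytest.raises(ValueError, match="plain"):
        ViewSpec.from_code("av", cut_position=10.0)


@pytest.mark.parametrize("code", VIEW_CODES)
def test_project_backproject_round_trip(code, clean_phantom, rng):
    """pixel_to_world_ray(project_point(p)) passes within 0.5*spacing of p."""
    vol, _ = clean_phantom
    geom = resolve_geometry(vol, _spec(code))
    for _ in range(100):
        p = rng.uniform(vol.world_min, vol.world_max)
        u, v = geom.project_point(p)
        origin, direction = geom.pixel_to_world_ray(u, v)
        t = np.dot(p - origin, direction)
        closest = origin + t * direction
        assert np.linalg.norm(p - closest) <= 0.5 * vol.spacing.max()


def test_center_maps_to_image_center(clean_phantom):
    vol, _ = clean_phantom
    geom = resolve_geometry(vol, _spec("av", size=512))
    assert np.allclose(geom.project_point(vol.world_center), (256, 256))


def test_projection_linearity(clean_phantom):
    vol, _ = clean_phantom
    geom = resolve_geometry(vol, _spec("av"))
    p = vol.world_center
    q = p.copy()
    q[geom.spec.u_axis] += 1.0
    du = (geom.project_point(q) - geom.project_point(p))[0]
    assert np.isclose(abs(du), 1.0 / geom.mm_per_pixel)


def test_adjacent_pixel_rays_parallel(clean_phantom):
    vol, _ = clean_phantom
    geom = resolve_geometry(vol, _spec("tv"))
    o1, d1 = geom.pixel_to_world_ray(60, 64)
    o2, d2 = geom.pixel_to_world_ray(61, 64)
    assert np.allclose(d1, d2)
    assert np.isclose(np.linalg.norm(o2 - o1), geom.mm_per_pixel)


def test_out_of_bounds_pixel_rejected(clean_phantom):
    vol, _ = clean_phantom
    geom = resolve_geometry(vol, _spec("tv"))
    with pytest.raises(ValueError):
        geom.pixel_to_world_ray(-1, 0)


def test_all_air_renders_black():
    vol = Volume(np.full((32, 32, 32), -1000.0), spacing=(1, 1, 1), origin=(0, 0, 0))
    img = render_view(vol, ViewSpec.from_code("av", size=64))
    assert np.all(img.pixels == 0)


def test_single_opaque_voxel_brightest_at_projection():
    hu = np.full((32, 32, 32), -1000.0)
    hu[20, 11, 7] = 1500.0
    vol = Volume(hu, spacing=(1, 1, 1), origin=(0, 0, 0))
    world = np.array([20.0, 11.0, 7.0])
    for code in ("av", "tv", "lv"):
        img = render_view(vol, ViewSpec.from_code(code, size=128))
        v, u = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        pu, pv = img.project_point(world)
        assert abs(u - pu) <= 1.5 and abs(v - pv) <= 1.5
        assert img.pixels.max() > 0


def test_anterior_posterior_views_mirror():
    """A left-right symmetric phantom renders as horizontal mirror images
    in the anterior and posterior views."""
    # suppress every asymmetric feature so the shell is mirror-symmetric
    spec = PhantomSpec(
        noise_sigma=0.0,
        jitter=0.0,
        canal_offset=(0.0, 0.0),
        bump_radius=1e-6,
        blob_offset=(0.0, 0.0, -7.0),
    )
    vol, _ = generate_phantom(spec, seed=0)
    av = render_view(vol, ViewSpec.from_code("av", size=128))
    pv = render_view(vol, ViewSpec.from_code("pv", size=128))
    mirrored = pv.pixels[:, ::-1]
    # the image centre sits at pixel size/2, so the pixel grid spans
    # [-64, 63] pixels and mirroring shifts the sampling grid one column
    assert np.allclose(av.pixels[:, 1:], mirrored[:, :-1], atol=1e-6)
    assert av.pixels.max() > 0.1


def test_render_translation_invariance(clean_phantom):
    vol, _ = clean_phantom
    shifted = Volume(vol.voxels, spacing=vol.spacing, origin=vol.origin + 17.0)
    a = render_view(vol, ViewSpec.from_code("av", size=96))
    b = render_view(shifted, ViewSpec.from_code("av", size=96))
    assert np.allclose(a.pixels, b.pixels, atol=1e-9)


def test_apply_cutaway_marks_discarded_side(clean_phantom):
    vol, _ = clean_phantom
    cut = apply_cutaway(vol, CutPlane(axis=0, position=32.0, keep_side="below"))
    xs = vol.origin[0] + np.arange(vol.shape[0]) * vol.spacing[0]
    assert np.array_equal(cut.mask.all(axis=(1, 2)), xs <= 32.0)
    assert np.array_equal(cut.voxels, vol.voxels)  # HU untouched


def test_cutaway_beyond_extent_is_identity(clean_phantom):
    vol, _ = clean_phantom
    cut = apply_cutaway(vol, CutPlane(axis=0, position=1e4, keep_side="below"))
    assert cut.mask.all()


def test_cutaway_discarding_everything_errors(clean_phantom):
    vol, _ = clean_phantom
    with pytest.raises(RenderError, match="empty"):
        apply_cutaway(vol, CutPlane(axis=0, position=-1e4, keep_side="below"))


def test_cutaway_over_air_equals_full_render(clean_phantom):
    """Cutting away a slab that contains only air does not change the image."""
    vol, _ = clean_phantom
    full = render_view(vol, ViewSpec.from_code("av", size=96))
    cut_vol = apply_cutaway(vol, CutPlane(axis=0, position=1.0, keep_side="above"))
    cut = render_view(cut_vol, ViewSpec.from_code("av", size=96))
    assert np.allclose(full.pixels, cut.pixels, atol=1e-9)


def test_midsagittal_cutaway_exposes_interior(clean_phantom):
    """A mid-sagittal cutaway of the hollow shell makes the first opaque
    voxel along central rays an interior wall, matching a brute-force
    ray march on the masked volume."""
    vol, lms = clean_phantom
    spec = ViewSpec.from_code("sclv", size=128, cut_position=float(vol.world_center[0]))
    img = render_view(vol, spec)
    masked = apply_cutaway(vol, spec.cut)
    tf = TransferFunction()
    # central pixel: march the ray by brute force
    u, v = img.project_point(lms["proto_sella"])
    origin, direction = img.pixel_to_world_ray(float(u), float(v))
    t = 0.0
    first_hit = None
    while t <= 64.0:
        p = origin + t * direction
        idx = np.round((p - vol.origin) / vol.spacing).astype(int)
        if np.all(idx >= 0) and np.all(idx < vol.shape):
            if masked.mask[tuple(idx)] and tf.opacity(vol.voxels[tuple(idx)]) > 0.5:
                first_hit = p
                break
        t += 0.25
    assert first_hit is not None
    # the hit lies beyond the cut plane (interior side kept by the cut)
    assert first_hit[0] >= spec.cut.position - vol.spacing[0]


def test_degenerate_scale_rejected(clean_phantom):
    vol, _ = clean_phantom
    with pytest.raises(RenderError):
        render_view(vol, ViewSpec.from_code("av", size=64, mm_per_pixel=0.0))


def test_transfer_function_monotonicity_enforced():
    with pytest.raises(ValueError):
        TransferFunction(opacity_points=((-1000, 0.5), (0, 0.2), (1000, 1.0)))
    tf = TransferFunction()
    assert tf.opacity(np.array([-1000.0]))[0] == 0.0
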