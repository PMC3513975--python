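"""Boundary tracing, smoothed normals, margin grid, subregion labels."""

import numpy as np
import pytest

from regionbow.geometry import (
    SUBREGIONS,
    assign_subregions,
    boundary_normals,
    extract_margin_grid,
    margin_grid_for_image,
    trace_boundary,
)


def _square_mask(side, size, origin):
    mask = np.zeros((side, side), bool)
    r, c = origin
    mask[r : r + size, c : c + size] = True
    return mask


def _angle_diff_deg(a, b):
    return np.degrees(np.abs(np.angle(np.exp(1j * (a - b)))))


# --- tracing -----------------------------------------------------------------


def test_solid_square_perimeter_cycle():
    mask = _square_mask(20, 9, (5, 5))  # 81 px >= 50
    trace = trace_boundary(mask)
    # perimeter pixels of a 9x9 square
    assert len(trace) == 4 * 9 - 4
    # closed 8-connected cycle visiting each pixel once
    assert len(np.unique(trace, axis=0)) == len(trace)
    steps = np.abs(np.diff(np.vstack([trace, trace[:1]]), axis=0)).max(axis=1)
    assert (steps == 1).all()


def test_three_by_three_square_cycle_of_eight():
    mask = _square_mask(9, 3, (3, 3))
    trace = trace_boundary(mask, min_pixels=9)
    assert len(trace) == 8  # every pixel but the center


def test_disk_cycle_length_brackets_circumference(disk):
    mask, (cy, cx) = disk
    trace = trace_boundary(mask)
    # brute-force count of 4-boundary pixels
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    n_boundary = int((mask & ~eroded).sum())
    circ = 2 * np.pi * 20
    assert n_boundary <= len(trace) <= 1.5 * circ  # brute-force count brackets below
    trace_set = {tuple(p) for p in trace}
    boundary_set = {tuple(p) for p in np.argwhere(mask & ~eroded)}
    assert boundary_set <= trace_set


def test_degenerate_masks_rejected():
    tiny = np.zeros((10, 10), bool)
    tiny[5, 5] = True
    with pytest.raises(ValueError, match="50 px"):
        trace_boundary(tiny)
    with pytest.raises(ValueError, match="empty"):
        trace_boundary(np.zeros((10, 10), bool))
    two = _square_mask(40, 8, (2, 2)) | _square_mask(40, 8, (25, 25))
    with pytest.raises(ValueError, match="components"):
        trace_boundary(two)


# --- normals -----------------------------------------------------------------


def test_disk_normals_are_radial(disk):
    mask, (cy, cx) = disk
    trace = trace_boundary(mask)
    theta = boundary_normals(trace, 3.0, mask)
    radial = np.arctan2(trace[:, 0] - cy, trace[:, 1] - cx)
    assert _angle_diff_deg(theta, radial).max() <= 5.0


def test_square_right_edge_normal_points_plus_x():
    mask = _square_mask(60, 21, (20, 20))
    trace = trace_boundary(mask)
    theta = boundary_normals(trace, 3.0, mask)
    mid = np.where((trace[:, 1] == 40) & (trace[:, 0] == 30))[0]
    assert len(mid) == 1
    assert _angle_diff_deg(theta[mid[0]], 0.0) <= 2.0


def test_outwardness_on_phantoms(small_dataset):
    for img in small_dataset[:4]:
        trace = trace_boundary(img.mask)
        theta = boundary_normals(trace, 3.0, img.mask)
        pr = np.rint(trace[:, 0] + 2 * np.sin(theta)).astype(int)
        pc = np.rint(trace[:, 1] + 2 * np.cos(theta)).astype(int)
        outside = ~img.mask[pr, pc]
        assert outside.mean() >= 0.95


def test_normals_invariant_to_trace_start(disk):
    mask, _ = disk
    trace = trace_boundary(mask)
    theta = boundary_normals(trace, 3.0, mask)
    shift = 17
    theta_rolled = boundary_normals(np.roll(trace, shift, axis=0), 3.0, mask)
    assert np.allclose(np.roll(theta, shift), theta_rolled)


def test_sigma_must_be_positive(disk):
    mask, _ = disk
    trace = trace_boundary(mask)
    with pytest.raises(ValueError):
        boundary_normals(trace, 0.0, mask)


# --- margin grid -------------------------------------------------------------


def test_constant_image_gives_constant_grid(disk):
    mask, _ = disk
    trace = trace_boundary(mask)
    theta = boundary_normals(trace, 3.0, mask)
    grid = extract_margin_grid(np.full(mask.shape, 7.5), trace, theta, 15)
    assert np.allclose(grid, 7.5, rtol=0, atol=1e-12)


def test_radial_ramp_reproduced(disk):
    """On I(p) = ||p - center||, row i column l reads ~ r_i + l."""
    mask, (cy, cx) = disk
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    ramp = np.hypot(yy - cy, xx - cx)
    trace = trace_boundary(mask)
    theta = boundary_normals(trace, 3.0, mask)
    grid = extract_margin_grid(ramp, trace, theta, 15)
    r_i = np.hypot(trace[:, 0] - cy, trace[:, 1] - cx)
    expected = r_i[:, None] + np.arange(-15, 16)[None, :]
    assert grid.shape == (len(trace), 31)
    assert np.abs(grid - expected).max() <= 1.0


def test_grid_width_is_31_at_default_half_length(small_dataset):
    img = small_dataset[0]
    grid = margin_grid_for_image(img.pixels, img.mask)
    assert grid.values.shape == (len(trace_boundary(img.mask)), 31)
    assert grid.half_length == 15


def test_center_column_holds_boundary_intensities(disk):
    mask, _ = disk
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 100, mask.shape)
    trace = trace_boundary(mask)
    theta = boundary_normals(trace, 3.0, mask)
    grid = extract_margin_grid(img, trace, theta, 15)
    assert np.allclose(grid[:, 15], img[trace[:, 0], trace[:, 1]])


def test_inside_outside_membership(small_dataset):
    """Columns l<0 sample the lesion interior, l>0 mostly the exterior."""
    img = small_dataset[0]
    trace = trace_boundary(img.mask)
    theta = boundary_normals(trace, 3.0, img.mask)
    inside_grid = extract_margin_grid(img.mask.astype(float), trace, theta, 15)
    inner = inside_grid[:, :15]  # l = -15..-1
    outer = inside_grid[:, 16:]  # l = +1..+15
    assert (inner > 0.5).mean() >= 0.90
    assert (outer < 0.5).mean() >= 0.90


def test_out_of_bounds_coordinates_clamp_with_warning():
    mask = _square_mask(40, 11, (2, 2))  # lesion hugs the border
    trace = trace_boundary(mask)
    theta = boundary_normals(trace, 3.0, mask)
    with pytest.warns(UserWarning, match="clamping"):
        grid = extract_margin_grid(np.ones(mask.shape), trace, theta, 15)
    assert np.isfinite(grid).all()


def test_rotation_robustness(small_dataset):
    """A lossless 90-degree rotation barely changes the grid's histogram."""
    img = small_dataset[0]
    grid = margin_grid_for_image(img.pixels, img.mask)
    grid_rot = margin_grid_for_image(np.rot90(img.pixels).copy(), np.rot90(img.mask).copy())
    lo = min(grid.values.min(), grid_rot.values.min())
    hi = max(grid.values.max(), grid_rot.values.max())
    h1, _ = np.histogram(grid.values, bins=32, range=(lo, hi), density=False)
    h2, _ = np.histogram(grid_rot.values, bins=32, range=(lo, hi), density=False)
    l1 = np.abs(h1 / h1.sum() - h2 / h2.sum()).sum()
    assert l1 <= 0.05


# --- subregions --------------------------------------------------------------


def test_disk_quadrants_are_balanced(disk):
    mask, _ = disk
    trace = trace_boundary(mask)
    labels = assign_subregions(trace, mask)
    fracs = {name: (labels == name).mean() for name in SUBREGIONS}
    for name, frac in fracs.items():
        assert abs(frac - 0.25) <= 0.02, (name, frac)


def test_plus_x_axis_is_top_right(disk):
    mask, (cy, cx) = disk
    point = np.array([[int(cy), int(cx) + 20]])  # exactly on the +x axis
    labels = assign_subregions(point, mask)
    assert labels[0] == "top-right"


def test_all_four_labels_on_phantoms(small_dataset):
    for img in small_dataset[:4]:
        labels = assign_subregions(trace_boundary(img.mask), img.mask)
        assert set(labels) == set(SUBREGIONS)
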