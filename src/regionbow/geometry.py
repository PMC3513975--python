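"""Lesion boundary geometry and the margin-region rectangle.

The margin region is built by walking the lesion boundary, estimating a
smoothed outward normal at every boundary pixel, and sampling an
intensity profile of ``2h + 1`` unit-spaced points along each normal
(from ``l = -h`` inside the lesion to ``l = +h`` outside).  Stacking the
profiles row by row yields a rectangle — rows indexed by boundary
position, columns by signed distance from the boundary — that is
inherently rotation-invariant with respect to the lesion.

Conventions: arrays are indexed ``(row, col)``; geometric coordinates use
``x = col``, ``y = row`` with angles from ``atan2(dy, dx)``.  Subregion
labels (top-left/top-right/down-right/down-left) classify each boundary
point by the quadrant of the centroid-to-point vector measured with the
y axis pointing *up*, matching how a viewer reads the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MarginGrid",
    "SUBREGIONS",
    "trace_boundary",
    "boundary_normals",
    "extract_margin_grid",
    "assign_subregions",
    "margin_grid_for_image",
]

#: fixed subregion order used for margin-block concatenation downstream
SUBREGIONS = ("top-left", "top-right", "down-right", "down-left")

# Moore neighborhood in clockwise array order starting East; in (row, col)
# with the row axis pointing down this walks the boundary so the interior
# stays on the right, i.e. counterclockwise on screen (y up).
_MOORE = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
)


@dataclass
class MarginGrid:
    """Rectangle of intensities sampled along boundary normals.

    ``values[i, c]`` is the (interpolated) image intensity at signed
    distance ``l = c - h`` along the outward normal of boundary point
    ``i``; column ``h`` holds the on-boundary intensities.  Each row
    carries the subregion label of its boundary point.
    """

    values: np.ndarray  # (n_boundary, 2h+1)
    subregions: np.ndarray  # (n_boundary,) strings from SUBREGIONS
    half_length: int

    def __post_init__(self) -> None:
        if self.values.shape[1] != 2 * self.half_length + 1:
            raise ValueError("grid width must equal 2*half_length + 1")
        if self.values.shape[0] != len(self.subregions):
            raise ValueError("one subregion label per row required")


def trace_boundary(mask: np.ndarray, min_pixels: int = 50) -> np.ndarray:
    """Ordered closed cycle of boundary pixels, shape ``(n, 2)`` as (row, col).

    Boundary pixels are foreground pixels with at least one background
    4-neighbor, visited by Moore contour following so that consecutive
    pixels are 8-connected and the cycle runs counterclockwise on screen.
    Rejects empty masks, multi-component masks and lesions under
    ``min_pixels`` (default 50, the smallest lesion the margin-region
    machinery is meant for).
    """
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty mask")
    labeled, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} connected components, expected 1")
    if n_px < min_pixels:
        raise ValueError(f"lesion has {n_px} px, below the {min_pixels} px minimum")

    padded = np.pad(mask, 1)  # guard band: border pixels get background neighbors
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # topmost-then-leftmost foreground pixel

    trace: list[tuple[int, int]] = []
    # state = (current pixel, backtrack pixel we arrived from); for the
    # raster-first start pixel the pixel to its left is guaranteed background.
    # The walk is a deterministic map on states, so the first repeated state
    # closes the cycle (this subsumes Jacob's stopping criterion).
    state = (start, (start[0], start[1] - 1))
    seen: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    while state not in seen:
        seen.add(state)
        cur, back = state
        trace.append(cur)
        # search the Moore neighborhood clockwise, starting just after the
        # backtrack direction
        d0 = _moore_index(back[0] - cur[0], back[1] - cur[1])
        for k in range(1, 9):
            dr, dc = _MOORE[(d0 + k) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if padded[cand]:
                # backtrack for the next step: the background pixel examined
                # just before the hit
                pr, pc = _MOORE[(d0 + k - 1) % 8]
                state = (cand, (cur[0] + pr, cur[1] + pc))
                break
        else:  # pragma: no cover - isolated pixel, excluded by precondition
            break

    coords = np.array(trace, dtype=np.int64) - 1  # undo padding offset
    # Moore following can touch pixels whose only background contact is
    # diagonal; keep the visit order but drop duplicates of revisited pixels
    _, first = np.unique(coords, axis=0, return_index=True)
    keep = np.zeros(len(coords), dtype=bool)
    keep[np.sort(first)] = True
    return coords[keep]


def _moore_index(dr: int, dc: int) -> int:
    for i, (r, c) in enumerate(_MOORE):
        if r == dr and c == dc:
            return i
    raise ValueError(f"({dr}, {dc}) is not a Moore offset")


def _gaussian_derivative_kernel(sigma: float) -> np.ndarray:
    radius = max(1, int(np.ceil(4.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2)) / (np.sqrt(2.0 * np.pi) * sigma)
    return -x / sigma**2 * g  # first derivative of the Gaussian


def boundary_normals(trace: np.ndarray, sigma: float, mask: np.ndarray) -> np.ndarray:
    """Outward normal angle (radians) at every traced boundary point.

    The coordinate sequences are circularly convolved with the first
    derivative of a 1-D Gaussian of bandwidth ``sigma``, giving a smoothed
    tangent ``(x', y')``; the normal is the tangent rotated by 90 degrees,
    with a single global sign chosen so normals point out of ``mask``
    (majority vote of a probe at ``l = +2``), and the angle taken with the
    full-quadrant arctangent.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    trace = np.asarray(trace)
    y = trace[:, 0].astype(np.float64)
    x = trace[:, 1].astype(np.float64)
    kernel = _gaussian_derivative_kernel(sigma)
    # correlate with the derivative kernel == differentiate the smoothed
    # closed curve; wrap mode realises the circular convolution
    dx = ndimage.correlate1d(x, kernel[::-1], mode="wrap")
    dy = ndimage.correlate1d(y, kernel[::-1], mode="wrap")

    speed = np.hypot(dx, dy)
    bad = speed < 1e-12
    if bad.any():
        warnings.warn(f"{int(bad.sum())} boundary points with zero tangent; interpolating")
        good = ~bad
        idx = np.arange(len(trace))
        dx[bad] = np.interp(idx[bad], idx[good], dx[good], period=len(trace))
        dy[bad] = np.interp(idx[bad], idx[good], dy[good], period=len(trace))

    # rotate the tangent by 90 degrees; resolve the two candidate senses by
    # testing which one leaves the mask two pixels out
    for nx, ny in ((dy, -dx), (-dy, dx)):
        norm = np.hypot(nx, ny)
        px = x + 2.0 * nx / norm
        py = y + 2.0 * ny / norm
        pr = np.clip(np.rint(py), 0, mask.shape[0] - 1).astype(int)
        pc = np.clip(np.rint(px), 0, mask.shape[1] - 1).astype(int)
        outside_frac = 1.0 - mask[pr, pc].mean()
        if outside_frac >= 0.5:
            return np.arctan2(ny, nx)
    raise RuntimeError("could not orient boundary normals outward")  # pragma: no cover


def extract_margin_grid(
    image: np.ndarray, trace: np.ndarray, theta: np.ndarray, half_length: int = 15
) -> np.ndarray:
    """Sample intensity profiles along the normals; returns ``(n, 2h+1)``.

    Profile positions are unit-spaced integers ``l = -h..+h`` (negative =
    inside the lesion); off-grid coordinates are bilinearly interpolated,
    coordinates outside the image are clamped to the nearest edge pixel
    with a warning (a fallback for real data; phantoms keep clearance).
    """
    image = np.asarray(image, dtype=np.float64)
    trace = np.asarray(trace)
    ell = np.arange(-half_length, half_length + 1, dtype=np.float64)
    xs = trace[:, 1][:, None] + ell[None, :] * np.cos(theta)[:, None]
    ys = trace[:, 0][:, None] + ell[None, :] * np.sin(theta)[:, None]
    h_max, w_max = image.shape[0] - 1, image.shape[1] - 1
    if (xs < 0).any() or (ys < 0).any() or (xs > w_max).any() or (ys > h_max).any():
        warnings.warn("margin profile leaves the image; clamping to the edge")
    return ndimage.map_coordinates(
        image, np.stack([ys.ravel(), xs.ravel()]), order=1, mode="nearest"
    ).reshape(len(trace), len(ell))


def assign_subregions(trace: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Quadrant label of each boundary point relative to the mask centroid.

    Angles are measured with the y axis up; the half-open quadrants are
    [0, 90) -> top-right, [90, 180) -> top-left, [180, 270) -> down-left,
    [270, 360) -> down-right.
    """
    cy, cx = ndimage.center_of_mass(np.asarray(mask, dtype=float))
    vx = trace[:, 1] - cx
    vy = cy - trace[:, 0]  # flip: image rows grow downward
    ang = np.degrees(np.arctan2(vy, vx)) % 360.0
    labels = np.empty(len(trace), dtype=object)
    labels[(ang >= 0) & (ang < 90)] = "top-right"
    labels[(ang >= 90) & (ang < 180)] = "top-left"
    labels[(ang >= 180) & (ang < 270)] = "down-left"
    labels[(ang >= 270) & (ang < 360)] = "down-right"
    return labels.astype(str)


def margin_grid_for_image(
    image: np.ndarray, mask: np.ndarray, sigma: float = 3.0, half_length: int = 15
) -> MarginGrid:
    """Convenience: trace, orient, sample and label in one call."""
    trace = trace_boundary(mask)
    theta = boundary_normals(trace, sigma, mask)
    values = extract_margin_grid(image, trace, theta, half_length)
    labels = assign_subregions(trace, mask)
    return MarginGrid(values=values, subregions=labels, half_length=half_length)
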