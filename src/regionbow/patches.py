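"""Dense raw-patch sampling, per-patch normalization, and ZCA whitening.

Raw ``w x w`` intensity patches are the local descriptor: they are sampled
densely (stride 1) from the lesion interior and from the margin-region
rectangle, each patch is standardized to zero mean and unit (population)
standard deviation, and a symmetric whitening transform — fitted per
region from the uncentered second-moment matrix ``C = E[P P^T]`` via its
eigendecomposition ``C = V D V^T`` — decorrelates the components:

    P_white = V (D + eps I)^(-1/2) V^T P

The small ridge ``eps`` keeps near-null eigendirections of the patch
covariance from amplifying noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.util import view_as_windows

__all__ = [
    "PatchMatrix",
    "WhiteningModel",
    "sample_tumor_patches",
    "sample_margin_patches",
    "normalize_patches",
    "fit_whitening",
    "apply_whitening",
]

from .geometry import MarginGrid


@dataclass
class PatchMatrix:
    """Vectorized patches plus their region/subregion bookkeeping.

    ``data`` has one row of ``w*w`` values per patch.  ``subregions`` is
    only populated for margin patches (the quadrant of each patch's center
    row); every margin patch additionally belongs to the whole-margin
    level, so no separate tag is needed for it.
    """

    data: np.ndarray  # (n_patches, w*w)
    region: str  # "tumor" | "margin"
    width: int
    subregions: np.ndarray | None = None  # (n_patches,) for margin patches

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != self.width**2:
            raise ValueError("patch rows must have length width**2")
        if self.subregions is not None and len(self.subregions) != len(self.data):
            raise ValueError("one subregion tag per patch required")

    def __len__(self) -> int:
        return len(self.data)


def sample_tumor_patches(image: np.ndarray, mask: np.ndarray, width: int = 7) -> PatchMatrix:
    """One patch per mask pixel whose ``w x w`` window fits in the image.

    The window may extend past the mask (those pixels are included as-is);
    centers are mask pixels, visited in raster order, stride 1.
    """
    if width % 2 != 1:
        raise ValueError("patch width must be odd")
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    r = width // 2
    if image.shape[0] < width or image.shape[1] < width:
        raise ValueError("image smaller than the patch window")
    windows = view_as_windows(image, (width, width))  # (H-w+1, W-w+1, w, w)
    centers = mask[r : image.shape[0] - r, r : image.shape[1] - r]
    if not centers.any():
        raise ValueError("no in-bounds patch centers inside the mask")
    data = windows[centers].reshape(-1, width * width)
    return PatchMatrix(data=data, region="tumor", width=width)


def sample_margin_patches(grid: MarginGrid, width: int = 7) -> PatchMatrix:
    """Dense patches over the margin rectangle, wrapping across the seam.

    The row (boundary) dimension is circular — the trace's start point is
    arbitrary — so rows wrap; the column (profile) dimension does not, so
    only fully-interior column positions are used: ``R * (C - w + 1)``
    patches for an ``R x C`` grid.  Each patch is tagged with the
    subregion of its center row.
    """
    if width % 2 != 1:
        raise ValueError("patch width must be odd")
    values = np.asarray(grid.values, dtype=np.float64)
    n_rows, n_cols = values.shape
    if n_rows < width or n_cols < width:
        raise ValueError(
            f"margin grid {values.shape} smaller than the {width}x{width} window"
        )
    r = width // 2
    wrapped = np.concatenate([values[-r:], values, values[:r]], axis=0)
    windows = view_as_windows(wrapped, (width, width))  # (R, C-w+1, w, w)
    data = windows.reshape(-1, width * width)
    tags = np.repeat(np.asarray(grid.subregions), n_cols - width + 1)
    return PatchMatrix(data=data, region="margin", width=width, subregions=tags)


def normalize_patches(data: np.ndarray) -> np.ndarray:
    """Rowwise ``(p - mean(p)) / sd(p)`` with the population (n-divisor) sd.

    Zero-variance (constant) patches map to the zero vector.
    """
    data = np.asarray(data, dtype=np.float64)
    mu = data.mean(axis=-1, keepdims=True)
    sd = data.std(axis=-1, keepdims=True)
    out = data - mu
    np.divide(out, sd, out=out, where=sd > 0)
    out[np.broadcast_to(sd == 0, out.shape)] = 0.0
    return out


@dataclass
class WhiteningModel:
    """Eigendecomposition of the uncentered patch second-moment matrix."""

    eigenvectors: np.ndarray  # V, columns are eigenvectors
    eigenvalues: np.ndarray  # D, ascending, clipped at 0
    eps: float

    @property
    def transform(self) -> np.ndarray:
        """Symmetric whitening matrix ``V (D + eps I)^(-1/2) V^T``."""
        inv_sqrt = 1.0 / np.sqrt(self.eigenvalues + self.eps)
        return (self.eigenvectors * inv_sqrt) @ self.eigenvectors.T


def fit_whitening(data: np.ndarray, eps: float | None = None) -> WhiteningModel:
    """Fit the whitening transform to (already normalized) patch rows.

    ``C`` is the mean of ``p p^T`` over the rows — uncentered beyond the
    per-patch normalization.  ``eps`` defaults to ``1e-5`` times the mean
    eigenvalue.  Eigenvector signs are fixed (largest-magnitude entry
    positive) so refits are bitwise-stable.
    """
    data = np.asarray(data, dtype=np.float64)
    n, dim = data.shape
    if n <= dim:
        warnings.warn(
            f"whitening fitted from {n} patches in {dim} dimensions; "
            "the ridge eps guards the inverse square root"
        )
    cov = data.T @ data / n
    cov = (cov + cov.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals = np.clip(eigvals, 0.0, None)
    flip = np.abs(eigvecs).argmax(axis=0)
    signs = np.sign(eigvecs[flip, np.arange(eigvecs.shape[1])])
    signs[signs == 0] = 1.0
    eigvecs = eigvecs * signs
    if eps is None:
        eps = 1e-5 * float(eigvals.mean())
    return WhiteningModel(eigenvectors=eigvecs, eigenvalues=eigvals, eps=float(eps))


def apply_whitening(model: WhiteningModel, patches: PatchMatrix | np.ndarray):
    """Whiten patch rows; tags are preserved for :class:`PatchMatrix` input."""
    if isinstance(patches, PatchMatrix):
        data = patches.data
    else:
        data = np.asarray(patches, dtype=np.float64)
    if data.shape[1] != model.eigenvectors.shape[0]:
        raise ValueError(
            f"patch dimension {data.shape[1]} does not match the whitening "
            f"model dimension {model.eigenvectors.shape[0]}"
        )
    white = data @ model.transform  # transform is symmetric
    if isinstance(patches, PatchMatrix):
        return PatchMatrix(
            data=white,
            region=patches.region,
            width=patches.width,
            subregions=patches.subregions,
        )
    return white
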