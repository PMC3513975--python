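"""Synthetic lesion phantoms.

Generates grayscale images that each contain a single simply-connected
lesion on a dark background, together with a ground-truth binary mask and
a class label.  Classes differ in two ways that mirror what distinguishes
tumor categories in contrast-enhanced MRI slices:

* the intensity distribution *inside* the lesion (mean level, pixel noise,
  and a smooth spatially-correlated texture component), and
* the intensity distribution of the *tissue ring surrounding* the lesion,
  which is what the margin-region representation is designed to pick up.

Lesion shapes are smooth star-convex blobs (an ellipse-like base radius
modulated by a few low-frequency harmonics), so the boundary is traceable
and outward normals are well defined everywhere.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "ClassAppearance",
    "PhantomSpec",
    "LabeledImage",
    "generate_dataset",
    "write_manifest",
    "read_manifest",
    "default_spec",
]

#: clearance (pixels) a lesion must keep from every image border so that
#: margin profiles (half-length 15) and patch windows (radius 3) stay in
#: bounds for the downstream geometry and patch modules.
BORDER_CLEARANCE = 18


@dataclass(frozen=True)
class ClassAppearance:
    """Intensity statistics of one lesion class, in raw image units.

    ``texture_sd``/``texture_scale`` parameterise a smooth Gaussian random
    field added inside the lesion (white noise blurred with a Gaussian of
    that scale, rescaled to the requested standard deviation); it gives a
    class its characteristic interior texture grain.
    """

    name: str
    tumor_mean: float
    tumor_sd: float
    ring_mean: float
    ring_sd: float
    texture_sd: float = 0.0
    texture_scale: float = 3.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom generator.

    The lesion radius is drawn uniformly from ``radius_range`` and its
    boundary is perturbed by harmonics 2..4 with total relative amplitude
    ``boundary_amplitude``.  ``ring_width`` is the width in pixels of the
    surrounding-tissue annulus carrying the class-specific margin signal.
    """

    classes: tuple[ClassAppearance, ...]
    radius_range: tuple[float, float] = (18.0, 28.0)
    boundary_amplitude: float = 0.12
    image_side: int = 160
    ring_width: float = 20.0
    background_mean: float = 40.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("a phantom spec needs at least 2 classes")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid radius range {self.radius_range}")
        max_extent = hi * (1.0 + self.boundary_amplitude) + self.ring_width
        if 2 * (max_extent + BORDER_CLEARANCE) >= self.image_side:
            raise ValueError(
                f"image side {self.image_side} too small for lesions of radius "
                f"up to {hi} plus a {self.ring_width}px ring and "
                f"{BORDER_CLEARANCE}px border clearance; "
                f"needs at least {int(2 * (max_extent + BORDER_CLEARANCE)) + 1}"
            )


@dataclass
class LabeledImage:
    """One dataset atom: pixels, aligned binary mask, and class label."""

    pixels: np.ndarray  # 2-D float array, nonnegative intensities
    mask: np.ndarray  # same-shape bool array, one connected component
    label: int
    patient_id: str = ""
    view: str = "synthetic"
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask must have identical shapes")

    def with_pixels(self, pixels: np.ndarray) -> "LabeledImage":
        return replace(self, pixels=pixels)


def default_spec(seed: int = 0) -> PhantomSpec:
    """Three-class phantom family used throughout the test battery.

    Class separation is carried by both cues the retrieval pipeline
    exploits: interior level/texture (bright-smooth vs dark-plain vs
    mid-coarse) and the surrounding ring (dark halo vs bright halo vs
    intermediate), with interior means 50+ raw units apart against a
    pixel noise of 5.
    """
    classes = (
        ClassAppearance("bright-smooth", 180.0, 8.0, 70.0, 8.0, texture_sd=20.0, texture_scale=3.0),
        ClassAppearance("dark-plain", 80.0, 8.0, 150.0, 8.0, texture_sd=0.0),
        ClassAppearance("mid-coarse", 130.0, 8.0, 110.0, 12.0, texture_sd=30.0, texture_scale=6.0),
    )
    return PhantomSpec(classes=classes, seed=seed)


def _lesion_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one star-convex blob mask with border clearance."""
    side = spec.image_side
    lo, hi = spec.radius_range
    radius = rng.uniform(lo, hi)
    # harmonics 2..4: smooth, non-elliptical wobble; amplitude split so the
    # total perturbation never exceeds boundary_amplitude (keeps r > 0 and
    # the shape star-convex in practice)
    amps = rng.uniform(0.0, spec.boundary_amplitude / 3.0, size=3)
    phases = rng.uniform(0.0, 2 * np.pi, size=3)
    max_extent = radius * (1.0 + spec.boundary_amplitude) + spec.ring_width
    margin = max_extent + BORDER_CLEARANCE
    cy = rng.uniform(margin, side - margin)
    cx = rng.uniform(margin, side - margin)

    yy, xx = np.mgrid[0:side, 0:side]
    dy = yy - cy
    dx = xx - cx
    rho = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    r_phi = radius * (
        1.0
        + amps[0] * np.cos(2 * phi + phases[0])
        + amps[1] * np.cos(3 * phi + phases[1])
        + amps[2] * np.cos(4 * phi + phases[2])
    )
    return rho <= r_phi


def _validate_mask(mask: np.ndarray) -> None:
    _, n_fg = ndimage.label(mask, structure=np.ones((3, 3)))
    if n_fg != 1:
        raise RuntimeError(f"phantom mask has {n_fg} components, expected 1")
    if mask.sum() < 50:
        raise RuntimeError("phantom lesion smaller than 50 pixels")
    # no holes: background must be a single component
    _, n_bg = ndimage.label(~mask)
    if n_bg != 1:
        raise RuntimeError("phantom lesion is not simply connected")


def _render(
    spec: PhantomSpec, cls: ClassAppearance, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    side = spec.image_side
    img = np.full((side, side), spec.background_mean, dtype=np.float64)
    img[mask] = cls.tumor_mean + cls.tumor_sd * rng.standard_normal(int(mask.sum()))
    if cls.texture_sd > 0:
        field_ = ndimage.gaussian_filter(
            rng.standard_normal((side, side)), cls.texture_scale
        )
        sd = field_.std()
        if sd > 0:
            tex = cls.texture_sd / sd * field_[mask]
            img[mask] += tex - tex.mean()  # texture adds grain, not level
    dist_out = ndimage.distance_transform_edt(~mask)
    ring = (dist_out > 0) & (dist_out <= spec.ring_width)
    img[ring] = cls.ring_mean + cls.ring_sd * rng.standard_normal(int(ring.sum()))
    img += spec.noise_sd * rng.standard_normal((side, side))
    np.clip(img, 0.0, None, out=img)
    return img


def generate_dataset(spec: PhantomSpec, n_per_class: int) -> list[LabeledImage]:
    """Generate ``n_per_class`` labeled phantoms for every class in ``spec``.

    Deterministic given ``spec.seed``: the same spec and seed reproduce
    bitwise-identical pixel grids.  Lesion centers, sizes and boundary
    wobble vary image to image; each image gets its own patient id.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed)
    dataset: list[LabeledImage] = []
    idx = 0
    for label, cls in enumerate(spec.classes):
        for _ in range(n_per_class):
            mask = _lesion_mask(spec, rng)
            _validate_mask(mask)
            pixels = _render(spec, cls, mask, rng)
            dataset.append(
                LabeledImage(
                    pixels=pixels,
                    mask=mask,
                    label=label,
                    patient_id=f"P{idx:04d}",
                    view="synthetic",
                    image_id=f"img_{idx:04d}",
                )
            )
            idx += 1
    return dataset


def write_manifest(dataset: Sequence[LabeledImage], directory: str | Path) -> Path:
    """Write PNG images/masks plus a CSV manifest; return the manifest path.

    Images are written as 16-bit grayscale PNG (intensities rounded to the
    nearest integer, clipped to [0, 65535]); masks as 8-bit 0/255 PNG.
    Manifest columns: ``image,mask,label,view,patient_id`` with paths
    relative to the manifest's directory.
    """
    if len(dataset) == 0:
        raise ValueError("cannot write a manifest for an empty dataset")
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "mask", "label", "view", "patient_id"])
        for i, item in enumerate(dataset):
            stem = item.image_id or f"img_{i:04d}"
            img_rel = f"images/{stem}.png"
            mask_rel = f"masks/{stem}_mask.png"
            arr = np.clip(np.rint(item.pixels), 0, 65535).astype(np.uint16)
            Image.fromarray(arr).save(directory / img_rel)
            Image.fromarray(
                np.where(item.mask, 255, 0).astype(np.uint8), mode="L"
            ).save(directory / mask_rel)
            writer.writerow([img_rel, mask_rel, item.label, item.view, item.patient_id])
    return manifest


def read_manifest(manifest: str | Path) -> list[LabeledImage]:
    """Load a dataset previously written by :func:`write_manifest`."""
    manifest = Path(manifest)
    base = manifest.parent
    dataset: list[LabeledImage] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            pixels = np.asarray(Image.open(base / row["image"]), dtype=np.float64)
            mask = np.asarray(Image.open(base / row["mask"])) > 0
            dataset.append(
                LabeledImage(
                    pixels=pixels,
                    mask=mask,
                    label=int(row["label"]),
                    patient_id=row["patient_id"],
                    view=row["view"],
                    image_id=Path(row["image"]).stem,
                )
            )
    if not dataset:
        raise ValueError(f"empty manifest: {manifest}")
    return dataset
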