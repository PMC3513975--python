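"""Region-specific bag-of-visual-words representation.

Two visual vocabularies are learned by k-means — one from lesion-interior
patches, one from margin-region patches — and every image becomes the
concatenation of six hard-assignment histograms over three levels:

    [ tumor (k0) | margin whole (k1) | top-left | top-right |
      down-right | down-left ]                     (each quadrant k1 bins)

All five margin blocks share the single margin vocabulary.  Hard
assignment sends each patch to its nearest word by squared Euclidean
distance (ties to the lowest word index) and each block is normalized by
its own patch count, so every nonempty block sums to one and the
quadrant counts partition the whole-margin counts exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .geometry import SUBREGIONS
from .patches import PatchMatrix

__all__ = [
    "Vocabulary",
    "RegionBoW",
    "build_vocabulary",
    "encode_counts",
    "encode_histogram",
    "build_representation",
]


@dataclass
class Vocabulary:
    """k-means visual words for one region."""

    words: np.ndarray  # (k, dim)
    region: str  # "tumor" | "margin"

    @property
    def size(self) -> int:
        return len(self.words)


@dataclass
class RegionBoW:
    """Concatenated six-block histogram with its layout metadata."""

    vector: np.ndarray  # length k0 + 5*k1
    k_tumor: int
    k_margin: int
    block_counts: dict[str, int] = field(default_factory=dict)  # patches per block

    @property
    def blocks(self) -> dict[str, slice]:
        k0, k1 = self.k_tumor, self.k_margin
        names = ["tumor", "margin"] + list(SUBREGIONS)
        offsets = [0, k0] + [k0 + k1 * (i + 1) for i in range(len(SUBREGIONS))]
        return {
            name: slice(off, off + (k0 if name == "tumor" else k1))
            for name, off in zip(names, offsets)
        }


def build_vocabulary(
    patches: PatchMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_fit_patches: int = 100_000,
    region: str = "",
) -> Vocabulary:
    """Cluster (a seeded subsample of) the patches into ``k`` visual words.

    k-means with k-means++ initialization, run to convergence (relative
    tolerance 1e-4, at most 300 iterations); deterministic given ``seed``.
    If fewer distinct patches than ``k`` are available, ``k`` is reduced
    with a warning.
    """
    if isinstance(patches, PatchMatrix):
        region = region or patches.region
        data = patches.data
    else:
        data = np.asarray(patches, dtype=np.float64)
    if k < 2:
        raise ValueError("vocabulary size must be at least 2")
    rng = np.random.default_rng(seed)
    if len(data) > max_fit_patches:
        idx = rng.choice(len(data), size=max_fit_patches, replace=False)
        data = data[np.sort(idx)]
    n_distinct = len(np.unique(data, axis=0))
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct patches for a size-{k} vocabulary; "
            f"reducing k to {n_distinct}"
        )
        k = n_distinct
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=300,
        tol=1e-4,
        random_state=seed % (2**31),
        algorithm="lloyd",
    ).fit(data)
    return Vocabulary(words=km.cluster_centers_.astype(np.float64), region=region)


def _nearest_word(data: np.ndarray, words: np.ndarray) -> np.ndarray:
    d2 = cdist(data, words, metric="sqeuclidean")
    return d2.argmin(axis=1)  # argmin takes the lowest index on ties


def encode_counts(patches: PatchMatrix | np.ndarray, vocab: Vocabulary) -> np.ndarray:
    """Integer nearest-word counts (the histogram before 1/n scaling)."""
    data = patches.data if isinstance(patches, PatchMatrix) else np.asarray(patches)
    if len(data) == 0:
        return np.zeros(vocab.size, dtype=np.int64)
    if data.shape[1] != vocab.words.shape[1]:
        raise ValueError(
            f"patch dimension {data.shape[1]} does not match vocabulary "
            f"dimension {vocab.words.shape[1]}"
        )
    assignments = _nearest_word(np.asarray(data, dtype=np.float64), vocab.words)
    return np.bincount(assignments, minlength=vocab.size)


def encode_histogram(patches: PatchMatrix | np.ndarray, vocab: Vocabulary) -> np.ndarray:
    """Hard-assignment frequency histogram; all-zero for an empty patch set."""
    counts = encode_counts(patches, vocab)
    n = counts.sum()
    if n == 0:
        return np.zeros(vocab.size, dtype=np.float64)
    return counts / n


def build_representation(
    tumor_patches: PatchMatrix,
    margin_patches: PatchMatrix,
    tumor_vocab: Vocabulary,
    margin_vocab: Vocabulary,
) -> RegionBoW:
    """Assemble the six-block region-specific representation of one image.

    Patches are expected already whitened with their region-matched model.
    A region with no patches yields an all-zero block with a warning.
    """
    blocks: list[np.ndarray] = []
    block_counts: dict[str, int] = {}

    blocks.append(encode_histogram(tumor_patches, tumor_vocab))
    block_counts["tumor"] = len(tumor_patches)
    if len(tumor_patches) == 0:
        warnings.warn("no tumor patches: tumor block is all-zero")

    blocks.append(encode_histogram(margin_patches, margin_vocab))
    block_counts["margin"] = len(margin_patches)
    if len(margin_patches) == 0:
        warnings.warn("no margin patches: margin blocks are all-zero")

    tags = (
        margin_patches.subregions
        if margin_patches.subregions is not None
        else np.empty(0, dtype=str)
    )
    for name in SUBREGIONS:
        sel = tags == name
        sub = margin_patches.data[sel] if len(margin_patches) else margin_patches.data
        blocks.append(encode_histogram(sub, margin_vocab))
        block_counts[name] = int(sel.sum()) if len(margin_patches) else 0

    return RegionBoW(
        vector=np.concatenate(blocks),
        k_tumor=tumor_vocab.size,
        k_margin=margin_vocab.size,
        block_counts=block_counts,
    )
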