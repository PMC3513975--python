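"""End-to-end orchestration: config, model fitting, features, persistence.

A fitted experiment is a set of models — intensity standardization,
per-region whitening, per-region vocabulary, and the learned metric —
plus per-image representations, all stored in a single HDF5 container so
an experiment's provenance (config hash, seed) travels with its
artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import bow, geometry, metric, patches, standardize
from .phantoms import LabeledImage

__all__ = [
    "PipelineConfig",
    "FittedModels",
    "fit_standardization_stage",
    "collect_patches",
    "fit_feature_models",
    "extract_representation",
    "extract_representations",
    "fit_metric",
    "within_between_ratio",
    "save_models",
    "load_models",
    "save_features",
    "load_features",
    "save_metric",
    "load_metric",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters; the defaults are the method's standard settings.

    Profile half-length 15 (31-pixel profiles), 7x7 patches at stride 1,
    vocabularies of 1000 (tumor) and 300 (margin) words, CFML with
    lambda = 1e-6 and a 2-D projection, evaluated by five-fold
    cross-validation repeated five times.
    """

    # standardization
    s_low: float = 0.0
    s_high: float = 4095.0
    pc_low: float = 0.01
    pc_high: float = 0.99
    foreground_rule: str = "above-median"
    # geometry
    boundary_sigma: float = 3.0
    half_length: int = 15
    # patches
    patch_width: int = 7
    whitening_eps: float | None = None  # None -> 1e-5 x mean eigenvalue
    # vocabularies
    k_tumor: int = 1000
    k_margin: int = 300
    max_fit_patches: int = 100_000
    # metric
    lam: float = 1e-6
    dim_out: int = 2
    # evaluation
    n_folds: int = 5
    n_repeats: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class FittedModels:
    """Everything fitted on a training set, short of the metric."""

    standardization: standardize.StandardizationModel
    whitening_tumor: patches.WhiteningModel
    whitening_margin: patches.WhiteningModel
    vocab_tumor: bow.Vocabulary
    vocab_margin: bow.Vocabulary


def _image_patches(
    img: LabeledImage, config: PipelineConfig
) -> tuple[patches.PatchMatrix, patches.PatchMatrix]:
    """Normalized tumor and margin patches of one standardized image."""
    tumor = patches.sample_tumor_patches(img.pixels, img.mask, config.patch_width)
    grid = geometry.margin_grid_for_image(
        img.pixels, img.mask, sigma=config.boundary_sigma, half_length=config.half_length
    )
    margin = patches.sample_margin_patches(grid, config.patch_width)
    tumor.data = patches.normalize_patches(tumor.data)
    margin.data = patches.normalize_patches(margin.data)
    return tumor, margin


def fit_standardization_stage(
    train_images: list[LabeledImage], config: PipelineConfig
) -> standardize.StandardizationModel:
    return standardize.fit_standardization(
        train_images,
        s_low=config.s_low,
        s_high=config.s_high,
        pc_low=config.pc_low,
        pc_high=config.pc_high,
        foreground_rule=config.foreground_rule,
    )


def collect_patches(
    train_images: list[LabeledImage],
    std: standardize.StandardizationModel,
    config: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled normalized tumor and margin patch rows over a training set."""
    tumor_rows: list[np.ndarray] = []
    margin_rows: list[np.ndarray] = []
    for img in train_images:
        simg = standardize.apply_standardization(img, std)
        t, m = _image_patches(simg, config)
        tumor_rows.append(t.data)
        margin_rows.append(m.data)
    return np.concatenate(tumor_rows), np.concatenate(margin_rows)


def fit_feature_models(
    train_images: list[LabeledImage], config: PipelineConfig
) -> FittedModels:
    """Fit standardization, whitening and vocabularies on training images."""
    std = fit_standardization_stage(train_images, config)
    tumor_data, margin_data = collect_patches(train_images, std, config)

    # region-specific whitening, then region-specific vocabularies on the
    # whitened patches
    wt = patches.fit_whitening(tumor_data, eps=config.whitening_eps)
    wm = patches.fit_whitening(margin_data, eps=config.whitening_eps)
    vt = bow.build_vocabulary(
        patches.apply_whitening(wt, tumor_data),
        k=config.k_tumor,
        seed=config.seed,
        max_fit_patches=config.max_fit_patches,
        region="tumor",
    )
    vm = bow.build_vocabulary(
        patches.apply_whitening(wm, margin_data),
        k=config.k_margin,
        seed=config.seed + 1,
        max_fit_patches=config.max_fit_patches,
        region="margin",
    )
    return FittedModels(
        standardization=std,
        whitening_tumor=wt,
        whitening_margin=wm,
        vocab_tumor=vt,
        vocab_margin=vm,
    )


def extract_representation(
    img: LabeledImage, models: FittedModels, config: PipelineConfig
) -> bow.RegionBoW:
    """Standardize, sample, whiten and encode one image."""
    simg = standardize.apply_standardization(img, models.standardization)
    tumor, margin = _image_patches(simg, config)
    tumor = patches.apply_whitening(models.whitening_tumor, tumor)
    margin = patches.apply_whitening(models.whitening_margin, margin)
    return bow.build_representation(tumor, margin, models.vocab_tumor, models.vocab_margin)


def extract_representations(
    images: list[LabeledImage], models: FittedModels, config: PipelineConfig
) -> np.ndarray:
    """Stacked representation vectors, one row per image."""
    return np.stack(
        [extract_representation(img, models, config).vector for img in images]
    )


def fit_metric(
    features: np.ndarray, labels: np.ndarray, config: PipelineConfig
) -> metric.MetricModel:
    scatter = metric.compute_scatters(features, labels)
    return metric.fit_cfml(scatter, lam=config.lam, dim_out=config.dim_out)


def within_between_ratio(
    features: np.ndarray, labels: np.ndarray, model: metric.MetricModel | None = None
) -> float:
    """(mean within-class distance) / (mean between-class distance).

    With ``model=None`` the distances are squared Euclidean; otherwise the
    learned squared Mahalanobis distance.  Smaller is better: a good
    metric pulls same-class pairs together relative to cross-class pairs.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if model is not None:
        features = features @ model.projection.T
    within: list[float] = []
    between: list[float] = []
    for i in range(len(features)):
        for j in range(i + 1, len(features)):
            d = features[i] - features[j]
            (within if labels[i] == labels[j] else between).append(float(d @ d))
    if not within or not between:
        raise ValueError("need both within- and between-class pairs")
    return float(np.mean(within) / np.mean(between))


# ---------------------------------------------------------------------------
# HDF5 persistence


def _require(h5file, name: str, stage: str) -> None:
    if name not in h5file:
        raise FileNotFoundError(
            f"missing artifact {name!r}: run the {stage!r} stage first"
        )


def save_config(h5file, config: PipelineConfig) -> None:
    h5file.attrs["config_json"] = json.dumps(config.to_dict(), sort_keys=True)
    h5file.attrs["config_digest"] = config.digest
    h5file.attrs["seed"] = config.seed


def load_config(h5file) -> PipelineConfig:
    return PipelineConfig(**json.loads(h5file.attrs["config_json"]))


def save_models(h5file, models: FittedModels) -> None:
    std = models.standardization
    g = h5file.require_group("standardization")
    for key in ("s_low", "s_mid", "s_high", "pc_low", "pc_high"):
        g.attrs[key] = getattr(std, key)
    g.attrs["foreground_rule"] = std.foreground_rule
    for name, wm in (("tumor", models.whitening_tumor), ("margin", models.whitening_margin)):
        g = h5file.require_group(f"whitening/{name}")
        for ds in ("eigenvectors", "eigenvalues"):
            if ds in g:
                del g[ds]
        g.create_dataset("eigenvectors", data=wm.eigenvectors)
        g.create_dataset("eigenvalues", data=wm.eigenvalues)
        g.attrs["eps"] = wm.eps
    for name, vb in (("tumor", models.vocab_tumor), ("margin", models.vocab_margin)):
        g = h5file.require_group(f"vocab/{name}")
        if "words" in g:
            del g["words"]
        g.create_dataset("words", data=vb.words)
        g.attrs["region"] = vb.region


def load_models(h5file) -> FittedModels:
    for name, stage in (
        ("standardization", "standardize"),
        ("whitening/tumor", "features"),
        ("vocab/tumor", "vocab"),
    ):
        _require(h5file, name, stage)
    g = h5file["standardization"]
    std = standardize.StandardizationModel(
        s_low=float(g.attrs["s_low"]),
        s_mid=float(g.attrs["s_mid"]),
        s_high=float(g.attrs["s_high"]),
        pc_low=float(g.attrs["pc_low"]),
        pc_high=float(g.attrs["pc_high"]),
        foreground_rule=str(g.attrs["foreground_rule"]),
    )
    whit = {}
    for name in ("tumor", "margin"):
        g = h5file[f"whitening/{name}"]
        whit[name] = patches.WhiteningModel(
            eigenvectors=g["eigenvectors"][...],
            eigenvalues=g["eigenvalues"][...],
            eps=float(g.attrs["eps"]),
        )
    vocabs = {}
    for name in ("tumor", "margin"):
        g = h5file[f"vocab/{name}"]
        vocabs[name] = bow.Vocabulary(words=g["words"][...], region=str(g.attrs["region"]))
    return FittedModels(
        standardization=std,
        whitening_tumor=whit["tumor"],
        whitening_margin=whit["margin"],
        vocab_tumor=vocabs["tumor"],
        vocab_margin=vocabs["margin"],
    )


def save_features(h5file, features: np.ndarray, labels: np.ndarray, ids: list[str],
                  k_tumor: int, k_margin: int) -> None:
    g = h5file.require_group("features")
    for ds in ("x", "labels", "ids"):
        if ds in g:
            del g[ds]
    g.create_dataset("x", data=features)
    g.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
    g.create_dataset("ids", data=np.array(ids, dtype="S"))
    g.attrs["k_tumor"] = k_tumor
    g.attrs["k_margin"] = k_margin


def load_features(h5file):
    _require(h5file, "features", "encode")
    g = h5file["features"]
    ids = [s.decode() for s in g["ids"][...]]
    return g["x"][...], g["labels"][...], ids


def save_metric(h5file, model: metric.MetricModel) -> None:
    g = h5file.require_group("metric")
    if "projection" in g:
        del g["projection"]
    g.create_dataset("projection", data=model.projection)
    g.attrs["lam"] = model.lam
    g.attrs["dim_out"] = model.dim_out


def load_metric(h5file) -> metric.MetricModel:
    _require(h5file, "metric", "train-metric")
    g = h5file["metric"]
    return metric.MetricModel(projection=g["projection"][...], lam=float(g.attrs["lam"]))
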