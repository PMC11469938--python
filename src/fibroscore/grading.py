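"""Tile dataset assembly, classifier training and per-tile grade prediction.

Mirrors the training design of the automated Ashcroft pipeline: manually
graded tiles are class-balanced by resampling, divided into training
(75%), validation (20%) and test (5%) sets, augmented with rotations,
flips and brightness jitter, and used to train a convolutional classifier
over ten classes (grades 0-8 plus non-alveolar) for 25 epochs with Adam.

One deliberate deviation from that order: the split happens first and
only the training partition is balanced, so that duplicated tiles can
never leak across partitions and inflate validation agreement.

Two interchangeable classifiers satisfy the model contract: ``small_cnn``
(a compact numpy CNN, the reference) and ``baseline_texture`` (a
deterministic nearest-centroid classifier in a fixed texture-feature
space, useful as a fast oracle).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from .imaging_io import TileGrid
from .labels import (
    CLASS_ORDER,
    N_CLASSES,
    NON_ALVEOLAR_CODE,
    Label,
    to_code,
    to_label,
)
from .nn import SmallCNN
from .synthetic import LabeledTile, TextureParams, palette_fractions


@dataclass
class SplitFractions:
    """Train/validation/test fractions; default 0.75 / 0.20 / 0.05."""

    train: float = 0.75
    validation: float = 0.20
    test: float = 0.05

    def __post_init__(self) -> None:
        for f in (self.train, self.validation, self.test):
            if not (0.0 <= f <= 1.0):
                raise ValueError("split fractions must lie in [0, 1]")
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.train, self.validation, self.test)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions of a labeled tile set."""

    train: List[LabeledTile]
    validation: List[LabeledTile]
    test: List[LabeledTile]

    def class_counts(self) -> Dict[str, Dict[Label, int]]:
        out: Dict[str, Dict[Label, int]] = {}
        for name in ("train", "validation", "test"):
            counts: Dict[Label, int] = {}
            for t in getattr(self, name):
                counts[t.label] = counts.get(t.label, 0) + 1
            out[name] = counts
        return out


@dataclass
class TrainingConfig:
    """Training hyper-parameters for the tile classifier.

    Defaults follow the reference pipeline: 25 epochs, Adam at 1e-3,
    batches of 32, augmentation by 90-degree rotations, flips and
    multiplicative brightness in ±20%.
    """

    epochs: int = 25
    learning_rate: float = 1e-3
    batch_size: int = 32
    augment_rotations: bool = True
    augment_flips: bool = True
    augment_brightness: bool = True
    brightness_range: float = 0.2
    architecture: str = "small_cnn"
    input_size: int = 32
    balance_training: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.architecture not in ("small_cnn", "baseline_texture"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass
class TileGradeMap:
    """Per-tile grade assignments aligned to a tile grid.

    ``codes`` holds one label code per grid tile (0..8 or 9 for
    non-alveolar); ``excluded`` flags tiles that carry no grade
    contribution (non-alveolar predictions and low-tissue tiles).
    """

    codes: np.ndarray
    excluded: np.ndarray
    probabilities: Optional[np.ndarray] = None
    ident: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.codes.ndim != 2 or self.codes.shape != self.excluded.shape:
            raise ValueError("codes and excluded must be congruent 2-D arrays")
        if self.codes.min() < 0 or self.codes.max() > NON_ALVEOLAR_CODE:
            raise ValueError("grade codes must lie in 0..9")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=np.float64)
            if p.shape != self.codes.shape + (N_CLASSES,):
                raise ValueError("probability array shape mismatch")
            self.probabilities = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @classmethod
    def from_labels(
        cls, rows: Sequence[Sequence[Label]], excluded: Optional[np.ndarray] = None, ident: str = ""
    ) -> "TileGradeMap":
        codes = np.asarray([[to_code(v) for v in row] for row in rows])
        if excluded is None:
            excluded = codes == NON_ALVEOLAR_CODE
        return cls(codes=codes, excluded=excluded, ident=ident)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def balance_by_resampling(tiles: Sequence[LabeledTile], seed: int) -> List[LabeledTile]:
    """Oversample every represented class to the majority-class count.

    Added tiles are duplicates (same objects) of existing ones, drawn with
    replacement; no pixels are fabricated.  Deterministic given ``seed``.
    """
    if len(tiles) == 0:
        raise ValueError("cannot balance an empty tile set")
    by_class: Dict[int, List[LabeledTile]] = {}
    for t in tiles:
        by_class.setdefault(to_code(t.label), []).append(t)
    majority = max(len(v) for v in by_class.values())
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    out: List[LabeledTile] = []
    for code in sorted(by_class):
        group = by_class[code]
        out.extend(group)
        deficit = majority - len(group)
        if deficit > 0:
            picks = rng.integers(0, len(group), size=deficit)
            out.extend(group[i] for i in picks)
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def _apportion(n: int, fractions: Tuple[float, ...]) -> List[int]:
    """Largest-remainder apportionment of ``n`` items to ``fractions``."""
    quotas = [f * n for f in fractions]
    base = [int(np.floor(q)) for q in quotas]
    leftover = n - sum(base)
    order = sorted(
        range(len(fractions)),
        key=lambda i: (-(quotas[i] - base[i]), -fractions[i], i),
    )
    for i in order[:leftover]:
        base[i] += 1
    return base


def stratified_split(
    tiles: Sequence[LabeledTile],
    fractions: Optional[SplitFractions] = None,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified per-class train/validation/test split.

    Within each class, partition sizes follow largest-remainder
    apportionment of the fractions, so the error versus the exact
    fractional quota is below one tile per class per partition.
    Assignment is deterministic given ``seed``.
    """
    fractions = fractions or SplitFractions()
    if len(tiles) == 0:
        raise ValueError("cannot split an empty tile set")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    by_class: Dict[int, List[LabeledTile]] = {}
    for t in tiles:
        by_class.setdefault(to_code(t.label), []).append(t)
    parts: Tuple[List[LabeledTile], ...] = ([], [], [])
    for code in sorted(by_class):
        group = list(by_class[code])
        order = rng.permutation(len(group))
        group = [group[i] for i in order]
        n_tr, n_va, n_te = _apportion(len(group), fractions.as_tuple())
        parts[0].extend(group[:n_tr])
        parts[1].extend(group[n_tr : n_tr + n_va])
        parts[2].extend(group[n_tr + n_va :])
    return DatasetSplit(train=parts[0], validation=parts[1], test=parts[2])


def apply_augmentation(
    pixels: np.ndarray,
    rotations_90: int = 0,
    flip_horizontal: bool = False,
    flip_vertical: bool = False,
    brightness: float = 1.0,
) -> np.ndarray:
    """Apply one explicit augmentation combination to a uint8 tile raster."""
    out = np.rot90(pixels, k=int(rotations_90) % 4, axes=(0, 1))
    if flip_horizontal:
        out = out[:, ::-1]
    if flip_vertical:
        out = out[::-1, :]
    out = np.clip(np.rint(out.astype(np.float64) * brightness), 0, 255).astype(np.uint8)
    return out


def augment(
    tile: LabeledTile, seed: int, config: Optional[TrainingConfig] = None
) -> LabeledTile:
    """Seed-chosen rotation/flip/brightness augmentation; label unchanged."""
    config = config or TrainingConfig()
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    rot = int(rng.integers(0, 4)) if config.augment_rotations else 0
    fh = bool(rng.integers(0, 2)) if config.augment_flips else False
    fv = bool(rng.integers(0, 2)) if config.augment_flips else False
    br = (
        float(rng.uniform(1 - config.brightness_range, 1 + config.brightness_range))
        if config.augment_brightness
        else 1.0
    )
    return LabeledTile(
        pixels=apply_augmentation(tile.pixels, rot, fh, fv, br),
        label=tile.label,
        seed=tile.seed,
    )


# ---------------------------------------------------------------------------
# classifier contract and implementations
# ---------------------------------------------------------------------------


class ClassifierModel:
    """Contract: map tile pixels to a probability vector over the 10 classes."""

    class_order = CLASS_ORDER
    metadata: dict

    def predict_proba(self, pixels: np.ndarray) -> np.ndarray:
        return self.predict_proba_batch([pixels])[0]

    def predict_proba_batch(self, pixel_list: Sequence[np.ndarray]) -> np.ndarray:
        raise NotImplementedError


def _tiles_to_tensor(pixel_list: Sequence[np.ndarray], input_size: int) -> np.ndarray:
    out = np.empty((len(pixel_list), input_size, input_size, 3), dtype=np.float32)
    for i, px in enumerate(pixel_list):
        if px.shape[0] == input_size and px.shape[1] == input_size:
            out[i] = px.astype(np.float32) / 255.0
        else:
            out[i] = resize(
                px.astype(np.float64) / 255.0,
                (input_size, input_size, 3),
                order=1,
                anti_aliasing=px.shape[0] > input_size,
                preserve_range=True,
            ).astype(np.float32)
    return out


def _augment_tensor(config: TrainingConfig):
    """Per-epoch tensor augmentation matching :func:`augment`'s transform set."""

    def fn(xs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = xs.copy()
        n = out.shape[0]
        if config.augment_rotations:
            ks = rng.integers(0, 4, size=n)
            for k in (1, 2, 3):
                idx = ks == k
                if idx.any():
                    out[idx] = np.rot90(out[idx], k=k, axes=(1, 2))
        if config.augment_flips:
            fh = rng.integers(0, 2, size=n).astype(bool)
            fv = rng.integers(0, 2, size=n).astype(bool)
            out[fh] = out[fh][:, :, ::-1]
            out[fv] = out[fv][:, ::-1, :]
        if config.augment_brightness:
            b = rng.uniform(
                1 - config.brightness_range, 1 + config.brightness_range, size=n
            ).astype(np.float32)
            out = np.clip(out * b[:, None, None, None], 0.0, 1.0)
        return out

    return fn


class CNNClassifier(ClassifierModel):
    """Wrapper giving the numpy CNN the tile-level model contract."""

    def __init__(self, net: SmallCNN, input_size: int, metadata: Optional[dict] = None):
        self.net = net
        self.input_size = input_size
        self.metadata = metadata or {}

    def predict_proba_batch(self, pixel_list: Sequence[np.ndarray]) -> np.ndarray:
        x = _tiles_to_tensor(pixel_list, self.input_size)
        return self.net.predict_proba(x)


def texture_features(
    pixels: np.ndarray, params: Optional[TextureParams] = None
) -> np.ndarray:
    """Fixed texture-feature vector used by the baseline classifier.

    Features: airspace/tissue/collagen palette fractions, mean luminance,
    edge density (mean absolute gray gradient), and a ring-shape score
    (non-airspace density in a mid annulus minus the tile center) that
    isolates the non-alveolar bronchus/vessel surrogate.
    """
    params = params or TextureParams()
    fr = palette_fractions(pixels, params)
    gray = pixels.astype(np.float64).mean(axis=2) / 255.0
    gy, gx = np.gradient(gray)
    edge = float(np.hypot(gy, gx).mean())
    # non-airspace indicator by nearest palette color
    px = pixels.reshape(-1, 3).astype(np.float64)
    d = ((px[:, None, :] - params.palette[None, :, :]) ** 2).sum(axis=2)
    non_air = (d.argmin(axis=1) != 0).reshape(gray.shape)
    s = gray.shape[0]
    yy, xx = np.mgrid[0:s, 0 : gray.shape[1]]
    r = np.hypot(yy - (s - 1) / 2, xx - (gray.shape[1] - 1) / 2)
    annulus = (r >= 0.24 * s) & (r <= 0.42 * s)
    center = r < 0.18 * s
    ring = float(non_air[annulus].mean() - non_air[center].mean())
    return np.array([fr[0], fr[1], fr[2], gray.mean(), edge, ring])


class BaselineTextureClassifier(ClassifierModel):
    """Nearest-class-centroid classifier in the fixed texture-feature space.

    Deterministic, no iterative training — a fast oracle standing beside
    the CNN, not a replacement for it.
    """

    def __init__(self, params: Optional[TextureParams] = None):
        self.params = params or TextureParams()
        self.centroids: Optional[np.ndarray] = None
        self.centroid_codes: Optional[np.ndarray] = None
        self.feat_mean: Optional[np.ndarray] = None
        self.feat_scale: Optional[np.ndarray] = None
        self.metadata = {"architecture": "baseline_texture"}

    def fit(self, tiles: Sequence[LabeledTile]) -> "BaselineTextureClassifier":
        if len(tiles) == 0:
            raise ValueError("cannot fit on an empty tile set")
        feats = np.stack([texture_features(t.pixels, self.params) for t in tiles])
        codes = np.array([to_code(t.label) for t in tiles])
        self.feat_mean = feats.mean(axis=0)
        self.feat_scale = feats.std(axis=0)
        self.feat_scale[self.feat_scale < 1e-9] = 1.0
        z = (feats - self.feat_mean) / self.feat_scale
        self.centroid_codes = np.unique(codes)
        self.centroids = np.stack([z[codes == c].mean(axis=0) for c in self.centroid_codes])
        return self

    def predict_proba_batch(self, pixel_list: Sequence[np.ndarray]) -> np.ndarray:
        if self.centroids is None:
            raise ValueError("classifier is not fitted")
        feats = np.stack([texture_features(px, self.params) for px in pixel_list])
        z = (feats - self.feat_mean) / self.feat_scale
        d2 = ((z[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        # softmax over negative squared distance; sharp enough to act one-hot
        logit = -d2
        logit -= logit.max(axis=1, keepdims=True)
        p = np.exp(logit)
        p /= p.sum(axis=1, keepdims=True)
        out = np.zeros((len(pixel_list), N_CLASSES), dtype=np.float64)
        out[:, self.centroid_codes] = p
        return out


def baseline_texture_classifier(
    tiles: Sequence[LabeledTile], params: Optional[TextureParams] = None
) -> BaselineTextureClassifier:
    """Fit the deterministic nearest-centroid baseline on labeled tiles."""
    return BaselineTextureClassifier(params=params).fit(tiles)


def train_classifier(split: DatasetSplit, config: Optional[TrainingConfig] = None) -> ClassifierModel:
    """Train a tile classifier on a dataset split.

    Runs exactly ``config.epochs`` epochs, records validation accuracy per
    epoch, and returns the model from the best-validation epoch.  The
    training partition alone is class-balanced by resampling (when
    ``config.balance_training``); fully seeded and reproducible.
    """
    config = config or TrainingConfig()
    if len(split.train) == 0:
        raise ValueError("training partition is empty")
    if config.architecture == "baseline_texture":
        model = baseline_texture_classifier(split.train)
        model.metadata.update({"seed": config.seed, "epochs": 0, "epoch_trace": []})
        return model

    train_tiles = (
        balance_by_resampling(split.train, seed=config.seed)
        if config.balance_training
        else list(split.train)
    )
    x_tr = _tiles_to_tensor([t.pixels for t in train_tiles], config.input_size)
    y_tr = np.array([to_code(t.label) for t in train_tiles])
    x_va = _tiles_to_tensor([t.pixels for t in split.validation], config.input_size)
    y_va = np.array([to_code(t.label) for t in split.validation], dtype=np.int64)

    net = SmallCNN(n_classes=N_CLASSES, input_size=config.input_size, seed=config.seed)
    aug = (
        _augment_tensor(config)
        if (config.augment_rotations or config.augment_flips or config.augment_brightness)
        else None
    )
    trace = net.fit(
        x_tr,
        y_tr,
        x_va,
        y_va,
        epochs=config.epochs,
        lr=config.learning_rate,
        batch_size=config.batch_size,
        augment_fn=aug,
    )
    meta = {
        "architecture": "small_cnn",
        "seed": config.seed,
        "epochs": config.epochs,
        "class_order": [str(c) for c in CLASS_ORDER],
        "epoch_trace": trace,
    }
    return CNNClassifier(net=net, input_size=config.input_size, metadata=meta)


def predict_grades(model: ClassifierModel, grid: TileGrid) -> TileGradeMap:
    """Assign one grade per grid tile; argmax with ties to the lower grade.

    Non-alveolar predictions and tiles flagged low-tissue by the tiler are
    marked excluded (they never contribute to the composite score).
    """
    if len(grid) == 0:
        raise ValueError("tile grid is empty")
    probs = model.predict_proba_batch([t.pixels for t in grid.tiles])
    codes = np.zeros(grid.shape, dtype=np.int64)
    excl = np.zeros(grid.shape, dtype=bool)
    pr = np.zeros(grid.shape + (N_CLASSES,), dtype=np.float64)
    for t, p in zip(grid.tiles, probs):
        # np.argmax returns the first maximum: lower grades win ties and
        # the non-alveolar class (last) loses them
        code = int(np.argmax(p))
        codes[t.row_index, t.col_index] = code
        excl[t.row_index, t.col_index] = t.excluded or code == NON_ALVEOLAR_CODE
        pr[t.row_index, t.col_index] = p
    return TileGradeMap(codes=codes, excluded=excl, probabilities=pr, ident=grid.ident)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def save_model(model: ClassifierModel, directory) -> None:
    """Write a model artifact: weights (npz) plus JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = dict(model.metadata)
    if isinstance(model, CNNClassifier):
        np.savez(
            directory / "weights.npz",
            **{f"p{i}": p for i, p in enumerate(model.net.params)},
        )
        meta.update(
            {
                "kind": "small_cnn",
                "input_size": model.input_size,
                "channels": list(model.net.channels),
            }
        )
    elif isinstance(model, BaselineTextureClassifier):
        np.savez(
            directory / "weights.npz",
            centroids=model.centroids,
            centroid_codes=model.centroid_codes,
            feat_mean=model.feat_mean,
            feat_scale=model.feat_scale,
        )
        meta["kind"] = "baseline_texture"
    else:
        raise TypeError(f"cannot persist model of type {type(model).__name__}")
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_model(directory) -> ClassifierModel:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    data = np.load(directory / "weights.npz")
    if meta["kind"] == "small_cnn":
        net = SmallCNN(
            n_classes=N_CLASSES,
            input_size=meta["input_size"],
            channels=tuple(meta["channels"]),
            seed=int(meta.get("seed", 0)),
        )
        net.params = [data[f"p{i}"] for i in range(len(net.params))]
        return CNNClassifier(net=net, input_size=meta["input_size"], metadata=meta)
    if meta["kind"] == "baseline_texture":
        model = BaselineTextureClassifier()
        model.centroids = data["centroids"]
        model.centroid_codes = data["centroid_codes"]
        model.feat_mean = data["feat_mean"]
        model.feat_scale = data["feat_scale"]
        model.metadata = meta
        return model
    raise ValueError(f"unknown model kind {meta['kind']!r}")
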