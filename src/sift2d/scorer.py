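"""CNN quality regressor for 2D class averages with metadata fusion.

The network is a residual trunk (batch normalization after every
convolution) whose inter-stage downsampling uses two consecutive 2x2
stride-2 convolutions instead of pooling layers, followed by adaptive
average pooling to a fixed 6x6 spatial map.  The pooled map is flattened
and concatenated with six z-scored metadata features (pixel size, FRC
resolution, class distribution and the three mass deviations), and a fully
connected head emits a single unbounded score: 1.0 anchors the best
training grade and 5.0 the worst, but outputs are deliberately not clipped,
so classes worse than anything seen in training score above 5.

Training minimizes mean-square error with Adam (learning rate 1e-4, weight
decay 1e-4, batch size 32 by default); a seeded fraction of the corpus is
held out for validation before training starts.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from sift2d import nn
from sift2d.formats_io import ClassAverageStack, ClassRecord
from sift2d.preprocess import CANVAS_SIDE, CanvasImage, resample_to_canvas

__all__ = [
    "GRADE_SCORES",
    "POOLED_MAP_SIDE",
    "N_METADATA_FEATURES",
    "MetadataFeatures",
    "ScorerConfig",
    "desk_scorer_config",
    "ScorerModel",
    "EvaluationReport",
    "grade_to_score",
    "build_scorer",
    "train_scorer",
    "score_classes",
    "evaluate",
]

#: Expert grade rubric mapped onto the 1 (best) .. 5 (worst) score anchors.
GRADE_SCORES = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "F": 5.0}

#: Side of the spatial map produced by the adaptive average pooling stage.
POOLED_MAP_SIDE = 6

#: Number of fused metadata features.
N_METADATA_FEATURES = 6

#: Number of bins for the [0, 1] score-bin confusion matrix.
N_EVAL_BINS = 10


def grade_to_score(grade: str) -> float:
    """Map an expert grade (A best .. F unusable) onto the 1-5 score scale."""
    try:
        return GRADE_SCORES[grade]
    except KeyError:
        raise ValueError(f"unknown grade {grade!r}; expected one of {sorted(GRADE_SCORES)}") from None


@dataclass(frozen=True)
class MetadataFeatures:
    """The six per-class metadata features fused into the scorer."""

    pixel_size: float
    frc_resolution: float
    class_distribution: float
    dev_mean_mass: float
    dev_median_mass: float
    dev_mode_mass: float

    def __post_init__(self) -> None:
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"metadata features must all be finite; got {vec}")
        if not (0.0 <= self.class_distribution <= 1.0):
            raise ValueError(f"class_distribution must lie in [0, 1]; got {self.class_distribution}")

    def to_vector(self) -> np.ndarray:
        return np.array(
            [
                self.pixel_size,
                self.frc_resolution,
                self.class_distribution,
                self.dev_mean_mass,
                self.dev_median_mass,
                self.dev_mode_mass,
            ],
            dtype=np.float64,
        )


@dataclass
class ScorerConfig:
    """Training and architecture configuration.

    Optimizer constants default to Adam with learning rate 1e-4, weight
    decay 1e-4, batch size 32 and 200 epochs.  ``channel_widths`` sets the
    residual-stage widths; ``stem_downsample`` moves the first paired 2x2
    stride-2 downsampling unit in front of the 3x3 stem so no convolution
    runs at full canvas resolution (the position a classical ResNet
    reserves for its stem pooling).
    """

    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0
    validation_fraction: float = 0.10
    channel_widths: tuple[int, ...] = (32, 64, 128, 256)
    blocks_per_stage: int = 2
    stem_downsample: bool = False
    head_width: int = 256

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay <= 0:
            raise ValueError("learning_rate and weight_decay must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if len(self.channel_widths) < 1 or any(w < 1 for w in self.channel_widths):
            raise ValueError("channel_widths must be positive")
        self.channel_widths = tuple(int(w) for w in self.channel_widths)


def desk_scorer_config(seed: int = 0, epochs: int = 30) -> ScorerConfig:
    """Reduced-size configuration that trains in minutes on one CPU core.

    Same optimizer constants as the default; the trunk is narrowed to three
    stages of one residual block each with a stem-side downsampling pair.
    """
    return ScorerConfig(
        seed=seed,
        epochs=epochs,
        channel_widths=(4, 16, 32),
        blocks_per_stage=1,
        stem_downsample=True,
        head_width=64,
    )


class _ResidualBlock(nn.Layer):
    """Two 3x3 convs with batch norm; identity skip around both."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(channels, channels, 3, 1, 1, rng)
        self.bn1 = nn.BatchNorm2d(channels)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(channels, channels, 3, 1, 1, rng)
        self.bn2 = nn.BatchNorm2d(channels)
        self.relu_out = nn.ReLU()

    def params(self) -> list[nn.Param]:
        return sum((l.params() for l in (self.conv1, self.bn1, self.conv2, self.bn2)), [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        return self.relu_out.forward(x + h, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        db = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        return d + db


class _DownsamplePair(nn.Layer):
    """Two consecutive 2x2 stride-2 convolutions (with batch norm and ReLU),
    the learned replacement for a pooling layer; halves the side twice."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(c_in, c_out, 2, 2, 0, rng)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(c_out, c_out, 2, 2, 0, rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        self.relu2 = nn.ReLU()

    def params(self) -> list[nn.Param]:
        return sum((l.params() for l in (self.conv1, self.bn1, self.conv2, self.bn2)), [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in (self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2):
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in (self.relu2, self.bn2, self.conv2, self.relu1, self.bn1, self.conv1):
            dout = layer.backward(dout)
        return dout


class _QualityNet:
    """Residual trunk + adaptive 6x6 pool + metadata-fused dense head."""

    def __init__(self, config: ScorerConfig, rng: np.random.Generator):
        widths = config.channel_widths
        if config.stem_downsample:
            # strided stem: the paired 2x2 stride-2 convs act directly on
            # the raw canvas (the position a classical ResNet reserves for
            # its stem pooling), so no convolution runs at full resolution
            self.trunk: list[nn.Layer] = [_DownsamplePair(1, widths[0], rng)]
        else:
            self.trunk = [
                nn.Conv2d(1, widths[0], 3, 1, 1, rng),
                nn.BatchNorm2d(widths[0]),
                nn.ReLU(),
            ]
        for i, w in enumerate(widths):
            if i > 0:
                self.trunk.append(_DownsamplePair(widths[i - 1], w, rng))
            for _ in range(config.blocks_per_stage):
                self.trunk.append(_ResidualBlock(w, rng))
        self.pool = nn.AdaptiveAvgPool2d(POOLED_MAP_SIDE)
        n_flat = widths[-1] * POOLED_MAP_SIDE**2
        self.fc1 = nn.Linear(n_flat + N_METADATA_FEATURES, config.head_width, rng)
        self.fc_relu = nn.ReLU()
        self.fc2 = nn.Linear(config.head_width, 1, rng)
        # regression head: start near the constant predictor
        self.fc2.weight.value *= 0.1
        self._n_flat = n_flat

    def params(self) -> list[nn.Param]:
        layers = self.trunk + [self.fc1, self.fc2]
        return sum((l.params() for l in layers), [])

    def forward(self, images: np.ndarray, metadata: np.ndarray, train: bool = True) -> np.ndarray:
        x = images[:, None, :, :].astype(nn.DTYPE, copy=False)
        for layer in self.trunk:
            x = layer.forward(x, train)
        pooled = self.pool.forward(x, train)
        flat = pooled.reshape(pooled.shape[0], -1)
        fused = np.concatenate([flat, metadata.astype(nn.DTYPE)], axis=1)
        h = self.fc_relu.forward(self.fc1.forward(fused, train), train)
        return self.fc2.forward(h, train)[:, 0]

    def backward(self, dscore: np.ndarray) -> None:
        d = self.fc2.backward(dscore[:, None])
        d = self.fc1.backward(self.fc_relu.backward(d))
        dflat = d[:, : self._n_flat]
        n = dflat.shape[0]
        dpool = dflat.reshape(n, -1, POOLED_MAP_SIDE, POOLED_MAP_SIDE)
        dx = self.pool.backward(dpool)
        for layer in reversed(self.trunk):
            dx = layer.backward(dx)

    def trunk_layer_names(self) -> list[str]:
        """Class names of every trunk layer (structural introspection)."""
        names = []
        for layer in self.trunk:
            names.append(type(layer).__name__)
            for sub in vars(layer).values():
                if isinstance(sub, nn.Layer):
                    names.append(type(sub).__name__)
        return names


@dataclass
class ScorerModel:
    """A (possibly trained) quality regressor with its feature scaling."""

    net: _QualityNet
    config: ScorerConfig
    feature_mean: np.ndarray = field(default_factory=lambda: np.zeros(N_METADATA_FEATURES))
    feature_sd: np.ndarray = field(default_factory=lambda: np.ones(N_METADATA_FEATURES))
    history: list[dict] = field(default_factory=list)
    trained: bool = False
    #: indices of the seeded validation split (set by train_scorer; not persisted)
    val_indices: np.ndarray | None = None

    def scale_metadata(self, metadata: np.ndarray) -> np.ndarray:
        return (np.asarray(metadata, dtype=np.float64) - self.feature_mean) / self.feature_sd

    def predict(self, images: np.ndarray, metadata: np.ndarray, batch: int = 256) -> np.ndarray:
        """Scores for canvas images (n, 210, 210) + raw metadata (n, 6)."""
        images = np.asarray(images, dtype=np.float32)
        scaled = self.scale_metadata(metadata)
        out = np.empty(len(images), dtype=np.float64)
        for start in range(0, len(images), batch):
            sl = slice(start, start + batch)
            out[sl] = self.net.forward(images[sl], scaled[sl], train=False)
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint = weights + running stats + feature scaling + config."""
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.net.params()):
            arrays[f"param_{i}"] = p.value
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"bn_mean_{i}"] = bn.running_mean
            arrays[f"bn_var_{i}"] = bn.running_var
        arrays["feature_mean"] = self.feature_mean
        arrays["feature_sd"] = self.feature_sd
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        meta = {"config": asdict(self.config), "history": self.history, "trained": self.trained}
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("weights.npz", buf.getvalue())
            zf.writestr("model.json", json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ScorerModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("model.json"))
            npz = np.load(io.BytesIO(zf.read("weights.npz")))
            cfg_dict = meta["config"]
            cfg_dict["channel_widths"] = tuple(cfg_dict["channel_widths"])
            config = ScorerConfig(**cfg_dict)
            model = build_scorer(config)
            for i, p in enumerate(model.net.params()):
                p.value[...] = npz[f"param_{i}"]
            for i, bn in enumerate(model._batchnorms()):
                bn.running_mean[...] = npz[f"bn_mean_{i}"]
                bn.running_var[...] = npz[f"bn_var_{i}"]
            model.feature_mean = npz["feature_mean"]
            model.feature_sd = npz["feature_sd"]
            model.history = meta["history"]
            model.trained = meta["trained"]
        return model

    def _batchnorms(self) -> list[nn.BatchNorm2d]:
        found: list[nn.BatchNorm2d] = []
        for layer in self.net.trunk:
            if isinstance(layer, nn.BatchNorm2d):
                found.append(layer)
            else:
                for sub in vars(layer).values():
                    if isinstance(sub, nn.BatchNorm2d):
                        found.append(sub)
        return found


def build_scorer(config: ScorerConfig) -> ScorerModel:
    """Seeded, untrained model honoring the architecture constraints."""
    rng = np.random.default_rng(config.seed)
    return ScorerModel(net=_QualityNet(config, rng), config=config)


def _unpack_corpus(
    corpus: Sequence[tuple],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    images = np.stack(
        [item[0].pixels if isinstance(item[0], CanvasImage) else np.asarray(item[0]) for item in corpus]
    ).astype(np.float32)
    if images.shape[1:] != (CANVAS_SIDE, CANVAS_SIDE):
        raise ValueError(f"corpus images must be {CANVAS_SIDE}x{CANVAS_SIDE} canvases")
    metadata = np.stack(
        [item[1].to_vector() if isinstance(item[1], MetadataFeatures) else np.asarray(item[1], dtype=np.float64)
         for item in corpus]
    )
    labels = np.asarray([float(item[2]) for item in corpus])
    if not np.all(np.isfinite(labels)):
        raise ValueError("labels must be finite")
    return images, metadata, labels


def train_scorer(corpus: Sequence[tuple], config: ScorerConfig) -> ScorerModel:
    """Train on (canvas image, metadata, score) triples.

    A seeded ``validation_fraction`` of the corpus is held out before
    training; metadata is z-scored with training-split statistics (stored in
    the model); Adam minimizes the MSE over shuffled mini-batches.  The
    per-epoch train/validation MSE history is recorded on the model.
    """
    images, metadata, labels = _unpack_corpus(corpus)
    n = len(labels)
    if n < config.batch_size:
        raise ValueError(f"corpus size {n} is smaller than one batch ({config.batch_size})")

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    model = build_scorer(config)
    model.feature_mean = metadata[train_idx].mean(axis=0)
    sd = metadata[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    model.feature_sd = sd
    scaled = model.scale_metadata(metadata).astype(nn.DTYPE)
    # start the head at the constant predictor (training-label mean)
    model.net.fc2.bias.value[0] = labels[train_idx].mean()

    optimizer = nn.Adam(model.net.params(), lr=config.learning_rate, weight_decay=config.weight_decay)
    y = labels.astype(nn.DTYPE)

    for epoch in range(config.epochs):
        order = train_idx[rng.permutation(len(train_idx))]
        losses, sizes = [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:  # batch norm needs at least two samples
                continue
            pred = model.net.forward(images[idx], scaled[idx], train=True)
            err = pred - y[idx]
            losses.append(float(np.mean(err**2)))
            sizes.append(len(idx))
            optimizer.zero_grad()
            model.net.backward((2.0 / len(idx)) * err.astype(nn.DTYPE))
            optimizer.step()
        train_mse = float(np.average(losses, weights=sizes))
        val_pred = model.predict(images[val_idx], metadata[val_idx])
        val_mse = float(np.mean((val_pred - labels[val_idx]) ** 2))
        model.history.append({"epoch": epoch, "train_mse": train_mse, "val_mse": val_mse})
    model.trained = True
    model.val_indices = val_idx
    return model


def score_classes(
    model: ScorerModel, stack: ClassAverageStack, records: Sequence[ClassRecord]
) -> list[float]:
    """Score every class of a stack; order preserved, scores unclipped.

    Each record must carry all six metadata values; a missing field raises
    an error naming the class and the field.
    """
    if not model.trained:
        raise ValueError("model is not trained")
    if len(records) != stack.n:
        raise ValueError(f"got {len(records)} records for {stack.n} images")
    meta_rows = []
    for rec in records:
        fields = {
            "pixel_size": rec.pixel_size,
            "frc_resolution": rec.frc_resolution,
            "class_distribution": rec.class_distribution,
            "dev_mean_mass": rec.dev_mean_mass,
            "dev_median_mass": rec.dev_median_mass,
            "dev_mode_mass": rec.dev_mode_mass,
        }
        for name, value in fields.items():
            if value is None or not np.isfinite(value):
                raise ValueError(f"class {rec.class_index}: missing metadata field {name!r}")
        meta_rows.append(MetadataFeatures(**fields).to_vector())
    canvases = np.stack([resample_to_canvas(img).pixels for img in stack.images]).astype(np.float32)
    scores = model.predict(canvases, np.stack(meta_rows))
    return [float(s) for s in scores]


@dataclass(frozen=True)
class EvaluationReport:
    """Raw-scale MSE plus the 10-bin [0, 1] confusion matrix."""

    mse: float
    confusion: np.ndarray  # (10, 10), rows = label bins, cols = prediction bins
    n: int


def _to_bins(scores: np.ndarray) -> np.ndarray:
    # map 1..5 (lower = better) onto [0, 1] (higher = better), then 10 bins
    unit = (5.0 - np.asarray(scores, dtype=np.float64)) / 4.0
    idx = np.floor(unit * N_EVAL_BINS).astype(int)
    return np.clip(idx, 0, N_EVAL_BINS - 1)


def evaluate(model: ScorerModel, corpus: Sequence[tuple]) -> EvaluationReport:
    """MSE on the 1-5 scale plus a label-vs-prediction bin confusion matrix."""
    if len(corpus) == 0:
        raise ValueError("cannot evaluate on an empty corpus")
    images, metadata, labels = _unpack_corpus(corpus)
    pred = model.predict(images, metadata)
    mse = float(np.mean((pred - labels) ** 2))
    confusion = np.zeros((N_EVAL_BINS, N_EVAL_BINS), dtype=int)
    for lb, pb in zip(_to_bins(labels), _to_bins(pred)):
        confusion[lb, pb] += 1
    return EvaluationReport(mse=mse, confusion=confusion, n=len(labels))
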