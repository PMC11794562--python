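"""Heartbeat classifier: 2D-CNN feature extractor fused with RR features.

The image branch maps a 120x120 PMAT image through three convolution
blocks to a 128-length feature vector; the fixed layer chain and its
intermediate shapes are asserted at build time:

    120x120x1 -> conv 5x5/32 -> 116x116x32 -> maxpool 5/5 -> 23x23x32
    -> conv 5x5/64 -> 19x19x64 -> maxpool 3/3 -> 6x6x64
    -> conv 3x3/128 -> 4x4x128 -> adaptive max pool -> 1x1x128 -> 128

The 128 CNN features are concatenated with the four handcrafted RR
features (pre-RR, post-RR, local-RR, ratio-RR) and fed to a dense head
ending in a 3-way softmax over the AAMI classes N, S, V.  Either branch
can be disabled for ablations: image-only ("Exp. A") or handcrafted-only
("Exp. B", the same dense head acting as a plain ANN).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from pmat import nn

CLASSES = ("N", "S", "V")
N_CLASSES = 3
IMAGE_SIZE = (120, 120)
CNN_FEATURES = 128
HANDCRAFTED_FEATURES = 4

#: layer name -> expected output shape (C, H, W) or (F,)
EXPECTED_SHAPES = [
    ("conv1", (32, 116, 116)),
    ("bn1", (32, 116, 116)),
    ("relu1", (32, 116, 116)),
    ("pool1", (32, 23, 23)),
    ("conv2", (64, 19, 19)),
    ("bn2", (64, 19, 19)),
    ("relu2", (64, 19, 19)),
    ("pool2", (64, 6, 6)),
    ("conv3", (128, 4, 4)),
    ("bn3", (128, 4, 4)),
    ("relu3", (128, 4, 4)),
    ("gmp", (128,)),
]


@dataclass
class ModelConfig:
    """Configuration of the classifier and its training loop."""

    use_image_branch: bool = True
    use_handcrafted: bool = True
    dense_sizes: tuple[int, ...] = (128, 64, 3)
    extra_dense_128: bool = False  # optional fourth dense layer 128->128
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 30
    seed: int = 0
    standardize_features: bool = False
    class_weights: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not (self.use_image_branch or self.use_handcrafted):
            raise ValueError("at least one branch must be enabled")
        if tuple(self.dense_sizes)[-1] != N_CLASSES:
            raise ValueError(
                f"dense_sizes must end in {N_CLASSES}, got {self.dense_sizes}")

    @property
    def fused_input_length(self) -> int:
        return (CNN_FEATURES * self.use_image_branch
                + HANDCRAFTED_FEATURES * self.use_handcrafted)


def build_feature_extractor(config: ModelConfig | None = None,
                            rng: np.random.Generator | None = None) -> nn.Sequential:
    """CNN image branch; raises at build if any intermediate shape deviates."""
    if rng is None:
        seed = config.seed if config is not None else 0
        rng = np.random.default_rng(seed)
    layers = {
        "conv1": nn.Conv2D(1, 32, 5, rng, compute_dx=False),
        "bn1": nn.BatchNorm2d(32),
        "relu1": nn.ReLU(),
        "pool1": nn.MaxPool2d(5),
        "conv2": nn.Conv2D(32, 64, 5, rng),
        "bn2": nn.BatchNorm2d(64),
        "relu2": nn.ReLU(),
        "pool2": nn.MaxPool2d(3),
        "conv3": nn.Conv2D(64, 128, 3, rng),
        "bn3": nn.BatchNorm2d(128),
        "relu3": nn.ReLU(),
        "gmp": nn.GlobalMaxPool(),
    }
    shape = (1, *IMAGE_SIZE)
    for (name, expected), layer in zip(EXPECTED_SHAPES, layers.values()):
        shape = layer.output_shape(shape)
        if tuple(shape) != expected:
            raise ValueError(
                f"layer {name!r}: output shape {shape} != expected {expected}")
    return nn.Sequential(list(layers.values()))


def build_classifier_head(config: ModelConfig,
                          rng: np.random.Generator | None = None) -> nn.Sequential:
    """Dense head over the fused feature vector, ending in 3 logits."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    in_dim = config.fused_input_length
    if in_dim == 0:
        raise ValueError("fused input length is zero; enable a branch")
    sizes = list(config.dense_sizes)
    if config.extra_dense_128:
        sizes = [128] + sizes
    layers: list[nn.Layer] = []
    prev = in_dim
    for i, size in enumerate(sizes):
        layers.append(nn.Dense(prev, size, rng))
        if i < len(sizes) - 1:
            layers.append(nn.ReLU())
        prev = size
    return nn.Sequential(layers)


class HeartbeatClassifier:
    """Fused image + RR-feature model with a simple Adam training loop."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(self.config.seed)
        self.extractor = (build_feature_extractor(self.config, rng)
                          if self.config.use_image_branch else None)
        self.head = build_classifier_head(self.config, rng)
        self.feature_mean = np.zeros(HANDCRAFTED_FEATURES, dtype=np.float32)
        self.feature_std = np.ones(HANDCRAFTED_FEATURES, dtype=np.float32)
        self.history: dict[str, list[float]] = {"loss": []}

    # -- forward -----------------------------------------------------------

    def _check_inputs(self, images, features):
        if self.config.use_image_branch:
            if images is None:
                raise ValueError("image branch enabled but no images given")
            if images.shape[-2:] != IMAGE_SIZE:
                raise ValueError(
                    f"images must be {IMAGE_SIZE[0]}x{IMAGE_SIZE[1]}, "
                    f"got {images.shape[-2:]}")
        if self.config.use_handcrafted and features is None:
            raise ValueError("handcrafted branch enabled but no features given")

    def _fuse_forward(self, images, features, training):
        parts = []
        if self.config.use_image_branch:
            x = images.reshape(images.shape[0], 1, *IMAGE_SIZE).astype(np.float32)
            parts.append(self.extractor.forward(x, training))
        if self.config.use_handcrafted:
            f = features.astype(np.float32)
            if self.config.standardize_features:
                f = (f - self.feature_mean) / self.feature_std
            parts.append(f)
        fused = np.concatenate(parts, axis=1)
        return self.head.forward(fused, training)

    def _backward(self, dlogits):
        dfused = self.head.backward(dlogits)
        if self.config.use_image_branch:
            self.extractor.backward(dfused[:, :CNN_FEATURES])

    def params(self):
        ps = [] if self.extractor is None else self.extractor.params()
        return ps + self.head.params()

    # -- training ----------------------------------------------------------

    def fit(self, images, features, labels, epochs: int | None = None,
            verbose: bool = False) -> dict[str, list[float]]:
        """Minimize cross-entropy with Adam; deterministic given the seed.

        ``labels`` are integer indices into :data:`CLASSES` (or the class
        strings themselves).  Returns the training history.
        """
        cfg = self.config
        y = encode_labels(labels)
        self._check_inputs(images, features)
        n = y.size
        present = np.bincount(y, minlength=N_CLASSES)
        if np.any(present == 0):
            import warnings
            missing = [CLASSES[i] for i in np.flatnonzero(present == 0)]
            warnings.warn(f"training data lacks classes {missing}", stacklevel=2)
        if cfg.use_handcrafted and cfg.standardize_features:
            self.feature_mean = features.mean(axis=0).astype(np.float32)
            self.feature_std = np.maximum(
                features.std(axis=0), 1e-8).astype(np.float32)
        sample_w = None
        if cfg.class_weights is not None:
            cw = np.asarray(cfg.class_weights, dtype=np.float64)
            sample_w = cw[y]
        opt = nn.Adam(self.params(), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        n_epochs = cfg.epochs if epochs is None else epochs
        for epoch in range(n_epochs):
            order = rng.permutation(n)
            total, count = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                im = images[idx] if images is not None else None
                ft = features[idx] if features is not None else None
                logits = self._fuse_forward(im, ft, training=True)
                sw = sample_w[idx] if sample_w is not None else None
                loss, dlogits, _ = nn.softmax_cross_entropy(logits, y[idx], sw)
                self._backward(dlogits)
                opt.step()
                total += loss * idx.size
                count += idx.size
            epoch_loss = total / count
            self.history["loss"].append(epoch_loss)
            if verbose:
                print(f"epoch {epoch + 1}/{n_epochs}  loss {epoch_loss:.4f}")
        return self.history

    # -- inference ---------------------------------------------------------

    def predict_proba(self, images, features, batch_size: int = 256) -> np.ndarray:
        """Per-beat class probabilities (rows sum to 1)."""
        self._check_inputs(images, features)
        n = (images.shape[0] if images is not None else features.shape[0])
        out = np.empty((n, N_CLASSES), dtype=np.float64)
        for start in range(0, n, batch_size):
            sl = slice(start, start + batch_size)
            im = images[sl] if images is not None else None
            ft = features[sl] if features is not None else None
            logits = self._fuse_forward(im, ft, training=False)
            out[sl] = nn.softmax(logits.astype(np.float64))
        return out

    def predict(self, images, features) -> np.ndarray:
        """Argmax labels as strings; ties broken by class order N < S < V."""
        probs = self.predict_proba(images, features)
        return np.asarray(CLASSES)[probs.argmax(axis=1)]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = ([] if self.extractor is None else self.extractor.state_arrays())
        arrays = arrays + self.head.state_arrays()
        np.savez(path.with_suffix(".npz"),
                 *arrays, feature_mean=self.feature_mean,
                 feature_std=self.feature_std)
        sidecar = {"config": asdict(self.config), "history": self.history}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "HeartbeatClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = sidecar["config"]
        cfg_dict["dense_sizes"] = tuple(cfg_dict["dense_sizes"])
        if cfg_dict.get("class_weights") is not None:
            cfg_dict["class_weights"] = tuple(cfg_dict["class_weights"])
        model = cls(ModelConfig(**cfg_dict))
        data = np.load(path.with_suffix(".npz"))
        arrays = [data[k] for k in data.files
                  if k not in ("feature_mean", "feature_std")]
        n_ext = (0 if model.extractor is None
                 else len(model.extractor.state_arrays()))
        if model.extractor is not None:
            model.extractor.load_state(arrays[:n_ext])
        model.head.load_state(arrays[n_ext:])
        model.feature_mean = data["feature_mean"]
        model.feature_std = data["feature_std"]
        model.history = sidecar["history"]
        return model


def encode_labels(labels) -> np.ndarray:
    """Map N/S/V strings (or already-integer indices) to 0/1/2."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    lut = {c: i for i, c in enumerate(CLASSES)}
    try:
        return np.asarray([lut[str(v)] for v in arr], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc.args[0]!r}") from None


def train(model: HeartbeatClassifier, images, features, labels,
          epochs: int | None = None, verbose: bool = False):
    """Functional wrapper: train ``model`` in place, return (model, history)."""
    history = model.fit(images, features, labels, epochs=epochs, verbose=verbose)
    return model, history


def predict(model: HeartbeatClassifier, images, features):
    """Functional wrapper: (probabilities, argmax string labels)."""
    probs = model.predict_proba(images, features)
    return probs, np.asarray(CLASSES)[probs.argmax(axis=1)]
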