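"""The two-branch 3D convolutional texture-learning model.

Architecture (per branch, identical apart from input channel count)::

    [Conv3D 3x3x3 x32 -> ReLU -> Conv3D 1x1x1 x16 -> ReLU -> MaxPool 2x2x2] x2
    -> flatten

The branch outputs are concatenated and fed to a dense hidden layer of 10
ReLU units and a single sigmoid output giving the malignancy probability.
The 1x1x1 convolutions compress the feature maps so the learnable weight
count stays small.  Training minimizes a class-weighted mean-squared error
(per-sample weights against class imbalance) with Adam; a held-out
validation split of 1-in-4 samples (a 1:3 validation-to-training ratio) is
monitored every epoch.

With the default configuration (valid padding, 2x2x2 pooling) the model has
129,365 learnable parameters for the 1-channel T2 + 3-channel ADC input pair.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import Adam, Conv3D, Dense, Flatten, MaxPool3D, ReLU, Sequential, Sigmoid
from .io import ValidationError
from .preprocess import TARGET_SHAPE, NoduleSample

__all__ = [
    "NetworkConfig",
    "ClassWeights",
    "TrainedModel",
    "build_model",
    "count_parameters",
    "class_weights",
    "per_sample_weights",
    "weighted_mse",
    "train_model",
    "predict",
    "predict_proba",
    "vote_probability",
    "extract_kernels",
]


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters.

    ``pool_size`` defaults to 2x2x2; a 2x2x1 variant (no depth pooling) is
    accepted for comparison.  ``conv_padding`` defaults to ``"valid"``, which
    together with floor pooling yields the compact 1.3e5-parameter model;
    ``"same"`` roughly doubles the flattened feature length.
    """

    conv_kernel: tuple[int, int, int] = (3, 3, 3)
    conv_filters: int = 32
    compress_filters: int = 16
    blocks_per_branch: int = 2
    pool_size: tuple[int, int, int] = (2, 2, 2)
    pool_mode: str = "max"
    hidden_units: int = 10
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 4
    validation_fraction: float = 0.25
    weight_convention: str = "inverse-frequency"  # or "paper-literal"
    conv_padding: str = "valid"
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_filters <= 0 or self.compress_filters <= 0:
            raise ValidationError("filter counts must be > 0")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValidationError("validation_fraction must be in [0, 1)")
        if self.pool_mode != "max":
            raise ValidationError("only max pooling is supported")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class ClassWeights:
    """Per-class loss weights for malignant (positive) and benign samples."""

    w_malignant: float
    w_benign: float
    convention: str = "inverse-frequency"

    def __post_init__(self) -> None:
        if self.w_malignant <= 0 or self.w_benign <= 0:
            raise ValidationError("class weights must be > 0")

    @property
    def ratio(self) -> float:
        return self.w_malignant / self.w_benign


class TwoBranchCNN:
    """Container for the branch networks and the dense head."""

    def __init__(self, config: NetworkConfig, c1: int, c2: int):
        if c1 < 1 and c2 < 1:
            raise ValidationError("at least one branch must have >= 1 input channel")
        self.config = config
        self.c1, self.c2 = c1, c2
        rng = np.random.default_rng(config.seed)
        dtype = config.np_dtype
        self.branches: dict[str, Sequential] = {}
        for tag, c in (("t2", c1), ("adc", c2)):
            if c >= 1:
                self.branches[tag] = self._make_branch(c, rng, dtype, tag)
        feat = sum(self._branch_out_len() for _ in self.branches)
        self.head = Sequential(
            [
                Dense(feat, config.hidden_units, rng=rng, dtype=dtype, name="hidden"),
                ReLU(),
                Dense(config.hidden_units, 1, rng=rng, dtype=dtype, name="out"),
                Sigmoid(),
            ]
        )

    def _make_branch(self, channels: int, rng, dtype, tag: str) -> Sequential:
        cfg = self.config
        layers: list = []
        in_c = channels
        for blk in range(cfg.blocks_per_branch):
            layers += [
                Conv3D(in_c, cfg.conv_filters, cfg.conv_kernel, cfg.conv_padding,
                       rng=rng, dtype=dtype, name=f"{tag}.conv{blk}"),
                ReLU(),
                Conv3D(cfg.conv_filters, cfg.compress_filters, (1, 1, 1), "valid",
                       rng=rng, dtype=dtype, name=f"{tag}.compress{blk}"),
                ReLU(),
                MaxPool3D(cfg.pool_size),
            ]
            in_c = cfg.compress_filters
        layers.append(Flatten())
        return Sequential(layers)

    def _branch_out_len(self) -> int:
        cfg = self.config
        shape = list(TARGET_SHAPE)
        for _ in range(cfg.blocks_per_branch):
            if cfg.conv_padding == "valid":
                shape = [s - (k - 1) for s, k in zip(shape, cfg.conv_kernel)]
            shape = [s // p for s, p in zip(shape, cfg.pool_size)]
        if min(shape) < 1:
            raise ValidationError(f"architecture collapses spatial dims to {shape}")
        return int(np.prod(shape)) * cfg.compress_filters

    def params(self):
        ps = []
        for branch in self.branches.values():
            ps += branch.params()
        ps += self.head.params()
        return ps

    def _inputs(self, x_t2, x_adc) -> dict[str, np.ndarray]:
        feed = {}
        if "t2" in self.branches:
            feed["t2"] = x_t2
        if "adc" in self.branches:
            feed["adc"] = x_adc
        return feed

    def make_l1_cols(self, x_t2: np.ndarray | None, x_adc: np.ndarray | None):
        """Precompute first-layer im2col patches per sample (inputs are static)."""
        cache = {}
        for tag, branch in self.branches.items():
            x = {"t2": x_t2, "adc": x_adc}[tag]
            conv0 = branch.layers[0]
            cols_list, sp = [], None
            for i in range(x.shape[0]):
                c, sp = conv0.make_cols(x[i])
                cols_list.append(c)
            cache[tag] = (cols_list, sp)
        return cache

    def forward(self, x_t2: np.ndarray | None, x_adc: np.ndarray | None, train=True,
                l1_cols: dict | None = None) -> np.ndarray:
        feats, self._splits = [], []
        for tag, branch in self.branches.items():
            if l1_cols is not None:
                cols_list, sp = l1_cols[tag]
                h = branch.layers[0].forward_cols(cols_list, sp, train=train)
                for layer in branch.layers[1:]:
                    h = layer.forward(h, train=train)
                f = h
            else:
                x = {"t2": x_t2, "adc": x_adc}[tag]
                f = branch.forward(np.asarray(x, dtype=self.config.np_dtype), train=train)
            self._splits.append(f.shape[1])
            feats.append(f)
        concat = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        return self.head.forward(concat, train=train)[:, 0]

    def backward(self, dprob: np.ndarray) -> None:
        dconcat = self.head.backward(dprob[:, None], need_input_grad=True)
        off = 0
        for (tag, branch), width in zip(self.branches.items(), self._splits):
            branch.backward(dconcat[:, off : off + width])
            off += width


@dataclass
class TrainedModel:
    """A (possibly still untrained) model plus its config echo and history."""

    net: TwoBranchCNN
    config: NetworkConfig
    history: dict[str, list[float]] = field(default_factory=dict)
    fold_tag: str = ""

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {p.name: p.value for p in self.net.params()}
        np.savez(directory / "weights.npz", **arrays)
        meta = {
            "config": asdict(self.config),
            "c1": self.net.c1,
            "c2": self.net.c2,
            "fold_tag": self.fold_tag,
            "weight_init": "glorot-uniform(seeded)",
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        if self.history:
            import pandas as pd

            pd.DataFrame(self.history).to_csv(directory / "history.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        cfg_d = meta["config"]
        for key in ("conv_kernel", "pool_size"):
            cfg_d[key] = tuple(cfg_d[key])
        config = NetworkConfig(**cfg_d)
        model = cls(net=TwoBranchCNN(config, meta["c1"], meta["c2"]), config=config,
                    fold_tag=meta.get("fold_tag", ""))
        with np.load(directory / "weights.npz") as z:
            by_name = {p.name: p for p in model.net.params()}
            for name in z.files:
                by_name[name].value = z[name]
        hist = directory / "history.csv"
        if hist.exists():
            import pandas as pd

            model.history = {k: list(v) for k, v in pd.read_csv(hist).items()}
        return model


def build_model(config: NetworkConfig, c1: int = 1, c2: int = 3) -> TrainedModel:
    """Construct the (untrained) two-branch model for the given channel counts."""
    for k, t in zip(config.conv_kernel, TARGET_SHAPE):
        if k > t:
            raise ValidationError("conv kernel larger than input block")
    return TrainedModel(net=TwoBranchCNN(config, c1, c2), config=config)


def count_parameters(model: TrainedModel | TwoBranchCNN) -> int:
    net = model.net if isinstance(model, TrainedModel) else model
    return int(sum(p.size for p in net.params()))


def class_weights(train_labels: Sequence[int], convention: str = "inverse-frequency") -> ClassWeights:
    """Per-class loss weights from the training labels of one fold.

    ``inverse-frequency`` (default) up-weights the minority class so each
    class contributes equally to the loss; ``paper-literal`` sets the
    malignant:benign weight ratio to n_malignant/n_benign.  Both are
    normalized so the mean per-sample weight over the training set is 1.
    """
    labels = np.asarray(train_labels, dtype=int)
    n_mal = int((labels == 1).sum())
    n_ben = int((labels == 0).sum())
    if n_mal == 0 or n_ben == 0:
        raise ValidationError("both classes must be present to derive class weights")
    if convention == "inverse-frequency":
        w_mal, w_ben = 1.0 / n_mal, 1.0 / n_ben
    elif convention == "paper-literal":
        w_mal, w_ben = float(n_mal), float(n_ben)
    else:
        raise ValidationError(f"unknown class-weight convention {convention!r}")
    mean_w = (n_mal * w_mal + n_ben * w_ben) / (n_mal + n_ben)
    return ClassWeights(w_malignant=w_mal / mean_w, w_benign=w_ben / mean_w, convention=convention)


def per_sample_weights(labels: Sequence[int], cw: ClassWeights) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    return np.where(labels == 1, cw.w_malignant, cw.w_benign).astype(float)


def weighted_mse(predictions: Sequence[float], labels: Sequence[int],
                 weights: Sequence[float]) -> float:
    """``(1/N) * sum_i w_i (p_i - y_i)^2`` — the class-weighted training loss."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (p.shape == y.shape == w.shape):
        raise ValidationError(f"length mismatch: {p.shape}, {y.shape}, {w.shape}")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("predictions must lie in [0, 1]")
    return float(np.mean(w * (p - y) ** 2))


def _stack_samples(samples: Sequence[NoduleSample]):
    x_t2 = np.stack([s.t2_block for s in samples]) if samples[0].t2_block.shape[-1] else None
    x_adc = np.stack([s.adc_block for s in samples]) if samples[0].adc_block.shape[-1] else None
    y = np.array([s.label for s in samples], dtype=float)
    return x_t2, x_adc, y


def _validation_split(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """Stratified held-out indices of roughly ``fraction`` of the samples."""
    n = labels.size
    val_idx: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        k = min(int(round(fraction * idx.size)), max(idx.size - 1, 0))
        if k > 0:
            val_idx += list(rng.permutation(idx)[:k])
    val = np.array(sorted(val_idx), dtype=int)
    train = np.setdiff1d(np.arange(n), val)
    return train, val


def precompute_l1_cols(model: TrainedModel, samples: Sequence[NoduleSample]) -> dict:
    """First-layer patch matrices for each sample, reusable across epochs/folds."""
    x_t2, x_adc, _ = _stack_samples(list(samples))
    return model.net.make_l1_cols(x_t2, x_adc)


def _subset_cols(cache: dict, idx) -> dict:
    return {tag: ([cols[i] for i in idx], sp) for tag, (cols, sp) in cache.items()}


def train_model(model: TrainedModel, samples: Sequence[NoduleSample],
                config: NetworkConfig | None = None,
                weights: ClassWeights | None = None,
                l1_cols: dict | None = None) -> TrainedModel:
    """Train in place for ``config.epochs`` epochs of mini-batch Adam.

    A stratified 1-in-(1/validation_fraction) split is held out and monitored;
    per-epoch training/validation loss and accuracy are recorded in
    ``model.history``.  Deterministic given ``config.seed`` and a fixed thread
    count.
    """
    config = config or model.config
    labels_all = np.array([s.label for s in samples], dtype=int)
    if (labels_all == 1).sum() < 1 or (labels_all == 0).sum() < 1:
        raise ValidationError("both classes must be present to train")
    cw = weights or class_weights(labels_all, config.weight_convention)

    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _validation_split(labels_all, config.validation_fraction, rng)
    if train_idx.size == 0:
        raise ValidationError("empty training split")
    train_samples = [samples[i] for i in train_idx]
    val_samples = [samples[i] for i in val_idx]
    if l1_cols is None:
        l1_cols = precompute_l1_cols(model, samples)
    tr_cols = _subset_cols(l1_cols, train_idx)
    va_cols = _subset_cols(l1_cols, val_idx)
    y = np.array([s.label for s in train_samples], dtype=float)
    w = per_sample_weights(y.astype(int), cw)
    if val_samples:
        vy = np.array([s.label for s in val_samples], dtype=float)
        vw = per_sample_weights(vy.astype(int), cw)

    net = model.net
    opt = Adam(net.params(), lr=config.learning_rate)
    n = y.size
    history: dict[str, list[float]] = {
        "epoch": [], "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    bs = max(1, min(config.batch_size, n))
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        # epoch training stats are accumulated over the minibatch passes
        loss_sum = 0.0
        correct = 0
        for start in range(0, n, bs):
            sel = order[start : start + bs]
            p = net.forward(None, None, train=True, l1_cols=_subset_cols(tr_cols, sel))
            loss_sum += float(np.sum(w[sel] * (p - y[sel]) ** 2))
            correct += int(np.sum((p >= 0.5) == (y[sel] == 1)))
            # d/dp of (1/Nb) * sum w (p - y)^2
            dp = (2.0 / sel.size) * w[sel] * (p - y[sel])
            net.backward(dp.astype(config.np_dtype))
            opt.step()
        history["epoch"].append(epoch)
        history["train_loss"].append(loss_sum / n)
        history["train_acc"].append(correct / n)
        if val_samples:
            p_va = _predict_cached(net, va_cols, len(val_samples))
            history["val_loss"].append(weighted_mse(p_va, vy.astype(int), vw))
            history["val_acc"].append(float(np.mean((p_va >= 0.5) == (vy == 1))))
        else:
            history["val_loss"].append(float("nan"))
            history["val_acc"].append(float("nan"))
    model.history = history
    return model


def _predict_cached(net: TwoBranchCNN, cols: dict, n: int, batch_size: int = 8) -> np.ndarray:
    out = []
    for start in range(0, n, batch_size):
        idx = range(start, min(start + batch_size, n))
        out.append(net.forward(None, None, train=False, l1_cols=_subset_cols(cols, idx)))
    return np.concatenate(out) if out else np.array([])


def predict_proba(model: TrainedModel, samples: Sequence[NoduleSample],
                  batch_size: int = 8) -> np.ndarray:
    """Malignancy probabilities for a collection of samples."""
    out = []
    for start in range(0, len(samples), batch_size):
        chunk = list(samples[start : start + batch_size])
        x_t2, x_adc, _ = _stack_samples(chunk)
        out.append(model.net.forward(x_t2, x_adc, train=False))
    return np.concatenate(out) if out else np.array([])


def predict(model: TrainedModel, sample: NoduleSample) -> float:
    """Malignancy probability in (0, 1) for a single sample (stateless)."""
    return float(predict_proba(model, [sample])[0])


def vote_probability(p_t2: np.ndarray | float, p_adc: np.ndarray | float):
    """Two-CNN probability voting: the mean of the branch-model probabilities."""
    return 0.5 * (np.asarray(p_t2, float) + np.asarray(p_adc, float))


def extract_kernels(model: TrainedModel, branch: str) -> np.ndarray:
    """First-layer 3x3x3 kernels of ``branch`` as (n_filters, in_channels, 3, 3, 3)."""
    net = model.net
    if branch not in net.branches:
        raise ValidationError(f"unknown branch {branch!r}; have {sorted(net.branches)}")
    first_conv = net.branches[branch].layers[0]
    return first_conv.kernels()
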