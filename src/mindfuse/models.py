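"""The two fusion classifiers: a data-level deep ConvNet that consumes one
synchronized (window x channels) array, and a feature-level multi-branch
network (one deep-ConvNet branch per modality, concatenated, then a 500-unit
dense layer and a softmax head).

Both follow the same four-block deep ConvNet recipe for raw-biosignal
decoding: block 1 is a temporal convolution (25 filters, kernel 5 along
time) followed — for multi-channel inputs — by a spatial convolution
spanning all channel rows, then batch-norm, ELU, max-pool (2, stride 2,
floor) and dropout; blocks 2–4 repeat with 50/100/200 filters.  For a
600-sample window the time axis contracts as
600 -> 596 -> 298 -> 294 -> 147 -> 143 -> 71 -> 67 -> 33,
leaving 200 x 33 = 6600 features per branch.

Training minimizes categorical cross-entropy with Adam (batch 128), an L2
penalty on dense-layer weights (1.3 data-level, 0.7 feature-level), and
early stopping on a seeded stratified 10% validation split carved from the
training segments.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .preprocessing import Segment

SENSOR_CONFIGS = ("eeg", "eeg+spr", "eeg+ecg", "eeg+spr+ecg")
_CHANNEL_IDX = {
    "eeg": list(range(6)),
    "eeg+spr": list(range(7)),
    "eeg+ecg": list(range(6)) + [7],
    "eeg+spr+ecg": list(range(8)),
}
# per-branch column groups within the 8-channel segment
_BRANCHES = {
    "eeg": [("eeg", list(range(6)))],
    "eeg+spr": [("eeg", list(range(6))), ("spr", [6])],
    "eeg+ecg": [("eeg", list(range(6))), ("ecg", [7])],
    "eeg+spr+ecg": [("eeg", list(range(6))), ("spr", [6]), ("ecg", [7])],
}

FILTERS = (25, 50, 100, 200)
TEMPORAL_KERNEL = 5
POOL = 2


class TrainingError(ValueError):
    """Training set unusable (e.g. only one class present)."""


@dataclasses.dataclass
class ModelSpec:
    """Architecture kind, sensor configuration and hyperparameters.

    Defaults depend on the architecture: the data-level network uses
    dropout 0.38, L2 1.3, up to 200 epochs with patience 50; the
    feature-level network uses dropout 0.5, L2 0.7, a 500-unit hidden
    dense layer, up to 50 epochs with patience 20.
    """

    arch: str = "data_fusion"          # data_fusion | feature_fusion
    sensors: str = "eeg+spr+ecg"
    window_samples: int = 600
    n_eeg_channels: int = 6
    dropout: float | None = None
    l2_penalty: float | None = None
    dense_hidden: int = 500
    n_classes: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int | None = None
    early_stopping_patience: int | None = None
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ("data_fusion", "feature_fusion"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.sensors not in SENSOR_CONFIGS:
            raise ValueError(
                f"sensors must be one of {SENSOR_CONFIGS}, "
                f"got {self.sensors!r}")
        data_level = self.arch == "data_fusion"
        if self.dropout is None:
            self.dropout = 0.38 if data_level else 0.5
        if self.l2_penalty is None:
            self.l2_penalty = 1.3 if data_level else 0.7
        if self.max_epochs is None:
            self.max_epochs = 200 if data_level else 50
        if self.early_stopping_patience is None:
            self.early_stopping_patience = 50 if data_level else 20

    @property
    def n_input_channels(self) -> int:
        return len(_CHANNEL_IDX[self.sensors])


def time_after_blocks(window_samples: int, n_blocks: int = 4) -> int:
    """Time-axis length after the conv/pool chain (floor on odd lengths);
    raises if the window is too short for four valid conv+pool blocks."""
    t = window_samples
    for _ in range(n_blocks):
        t -= TEMPORAL_KERNEL - 1
        if t < POOL:
            raise nn.ArchitectureError(
                f"window of {window_samples} samples is too short for "
                f"{n_blocks} conv/pool blocks")
        t //= POOL
    return t


def min_window_samples(n_blocks: int = 4) -> int:
    """Smallest window admitting four valid conv+pool blocks."""
    w = TEMPORAL_KERNEL
    while True:
        try:
            time_after_blocks(w, n_blocks)
            return w
        except nn.ArchitectureError:
            w += 1


def _conv_stack(rng: np.random.Generator, height: int, dropout: float,
                spatial: bool) -> list[nn.Layer]:
    """The four-block deep-ConvNet feature extractor.

    ``spatial`` adds the channel-spanning convolution after the temporal
    one in block 1 (multi-channel inputs only).
    """
    layers: list[nn.Layer] = [
        nn.Conv2d(1, FILTERS[0], (TEMPORAL_KERNEL, 1), rng)]
    if spatial:
        layers.append(nn.Conv2d(FILTERS[0], FILTERS[0], (1, height), rng))
    layers += [nn.BatchNorm(FILTERS[0]), nn.Elu(), nn.MaxPoolTime(),
               nn.Dropout(dropout)]
    for f_in, f_out in zip(FILTERS, FILTERS[1:]):
        layers += [nn.Conv2d(f_in, f_out, (TEMPORAL_KERNEL, 1), rng),
                   nn.BatchNorm(f_out), nn.Elu(), nn.MaxPoolTime(),
                   nn.Dropout(dropout)]
    return layers


@dataclasses.dataclass
class NetworkHandle:
    """A built (possibly trained) network with its preprocessing state."""

    spec: ModelSpec
    net: object                                  # Sequential | BranchedNet
    channel_idx: list[int]
    branch_groups: list[tuple[str, list[int]]] | None
    norm_mean: np.ndarray | None = None
    norm_std: np.ndarray | None = None
    trained: bool = False
    history: dict = dataclasses.field(default_factory=dict)

    @property
    def inventory(self) -> list[dict]:
        return self.net.inventory()


def build_data_fusion(spec: ModelSpec) -> NetworkHandle:
    """Data-level fusion network: one (window x channels) input array."""
    if spec.arch != "data_fusion":
        raise ValueError("spec.arch must be 'data_fusion'")
    t_out = time_after_blocks(spec.window_samples)
    rng = np.random.default_rng(spec.seed)
    n_ch = spec.n_input_channels
    layers = _conv_stack(rng, n_ch, spec.dropout, spatial=True)
    layers += [nn.Flatten(),
               nn.Dense(FILTERS[-1] * t_out, spec.n_classes, rng,
                        l2=spec.l2_penalty)]
    return NetworkHandle(spec=spec, net=nn.Sequential(layers),
                         channel_idx=_CHANNEL_IDX[spec.sensors],
                         branch_groups=None)


def build_feature_fusion(spec: ModelSpec) -> NetworkHandle:
    """Feature-level fusion network: one deep-ConvNet branch per modality,
    concatenated, then dense 500 (ReLU) and a softmax head.  Single-channel
    branches (SPR, ECG) omit the spatial convolution."""
    if spec.arch != "feature_fusion":
        raise ValueError("spec.arch must be 'feature_fusion'")
    t_out = time_after_blocks(spec.window_samples)
    rng = np.random.default_rng(spec.seed)
    groups = _BRANCHES[spec.sensors]
    if not groups:
        raise nn.ArchitectureError("empty branch list")
    branches = []
    for _, cols in groups:
        stack = _conv_stack(rng, len(cols), spec.dropout,
                            spatial=len(cols) > 1)
        stack.append(nn.Flatten())
        branches.append(nn.Sequential(stack))
    concat_width = len(groups) * FILTERS[-1] * t_out
    if spec.dense_hidden:
        head = nn.Sequential([
            nn.Dense(concat_width, spec.dense_hidden, rng,
                     l2=spec.l2_penalty),
            nn.Relu(),
            nn.Dense(spec.dense_hidden, spec.n_classes, rng,
                     l2=spec.l2_penalty),
        ])
    else:
        # ablation: concatenated features feed the softmax head directly
        head = nn.Sequential([
            nn.Dense(concat_width, spec.n_classes, rng,
                     l2=spec.l2_penalty)])
    return NetworkHandle(spec=spec, net=nn.BranchedNet(branches, head),
                         channel_idx=_CHANNEL_IDX[spec.sensors],
                         branch_groups=groups)


def build(spec: ModelSpec) -> NetworkHandle:
    if spec.arch == "data_fusion":
        return build_data_fusion(spec)
    return build_feature_fusion(spec)


def count_trainable_parameters(handle: NetworkHandle) -> int:
    """Sum of trainable weights, biases and batch-norm scale/shift terms
    (running statistics excluded)."""
    return handle.net.param_count


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def _segment_tensor(segments: list[Segment],
                    handle: NetworkHandle) -> np.ndarray:
    data = np.stack([s.data for s in segments]).astype(np.float32)
    return data[:, :, handle.channel_idx]


def _standardize(x: np.ndarray, handle: NetworkHandle) -> np.ndarray:
    return (x - handle.norm_mean) / handle.norm_std


def _model_inputs(x: np.ndarray, handle: NetworkHandle):
    """Shape standardized segment data for the network: channels-last
    (N, T, channels, 1 map) for the data-level net, one such array per
    branch for the feature net."""
    if handle.branch_groups is None:
        return np.ascontiguousarray(x[:, :, :, None])
    # branch column groups index the *selected* channels: remap
    col_of = {c: i for i, c in enumerate(handle.channel_idx)}
    return [np.ascontiguousarray(x[:, :, [col_of[c] for c in cols], None])
            for _, cols in handle.branch_groups]


def _forward(handle: NetworkHandle, inputs, mode: str,
             rng: np.random.Generator) -> np.ndarray:
    return handle.net.forward(inputs, mode, rng)


def _take(inputs, idx):
    if isinstance(inputs, list):
        return [x[idx] for x in inputs]
    return inputs[idx]


def _stratified_split(labels: np.ndarray, val_fraction: float,
                      rng: np.random.Generator):
    """Seeded stratified split; at least one validation sample per class."""
    val_idx = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        rng.shuffle(members)
        k = max(1, int(round(val_fraction * len(members))))
        val_idx.append(members[:k])
    val = np.sort(np.concatenate(val_idx))
    train = np.setdiff1d(np.arange(len(labels)), val)
    return train, val


def train(handle: NetworkHandle, train_segments: list[Segment],
          spec: ModelSpec | None = None) -> NetworkHandle:
    """Train in place with Adam on categorical cross-entropy.

    Per-channel standardization statistics are computed from the training
    segments and stored on the handle so inference applies the identical
    transform.  Early stopping monitors loss on a seeded stratified
    validation split; the best-epoch weights are restored.
    """
    spec = spec or handle.spec
    if not train_segments:
        raise TrainingError("empty training set")
    labels = np.array([s.label for s in train_segments])
    if len(np.unique(labels)) < 2:
        raise TrainingError("training set contains a single class")

    x = _segment_tensor(train_segments, handle)
    handle.norm_mean = x.mean(axis=(0, 1), keepdims=True)
    handle.norm_std = x.std(axis=(0, 1), keepdims=True) + 1e-8
    x = _standardize(x, handle)

    rng = np.random.default_rng(spec.seed + 1)
    tr_idx, val_idx = _stratified_split(labels, spec.val_fraction, rng)
    inputs = _model_inputs(x, handle)
    x_tr, y_tr = _take(inputs, tr_idx), labels[tr_idx]
    x_val, y_val = _take(inputs, val_idx), labels[val_idx]

    net = handle.net
    opt = nn.Adam(net.param_pairs(), lr=spec.learning_rate)
    n_tr = len(y_tr)
    best_loss, best_state, since_best = np.inf, None, 0
    history = {"train_loss": [], "val_loss": []}

    for epoch in range(spec.max_epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        for start in range(0, n_tr, spec.batch_size):
            idx = order[start: start + spec.batch_size]
            logits = _forward(handle, _take(x_tr, idx), "train", rng)
            loss, grad = nn.cross_entropy(logits, y_tr[idx])
            net.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / n_tr)

        # monitored quantity: data term of the loss on the held-out split
        # (batch statistics: inference statistics are only set after the
        # final calibration pass)
        val_logits = _forward(handle, x_val, "calib", rng)
        val_loss, _ = nn.cross_entropy(val_logits, y_val)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-5:
            best_loss, since_best = val_loss, 0
            best_state = nn.get_state(net)
        else:
            since_best += 1
            if since_best >= spec.early_stopping_patience:
                break
    if best_state is not None:
        nn.set_state(net, best_state)

    # fix the inference batch-norm statistics exactly, from the full
    # training set under the restored weights
    batches = (_take(inputs, np.arange(s, min(s + 256, len(labels))))
               for s in range(0, len(labels), 256))
    nn.collect_bn_statistics(net, batches, rng)

    handle.trained = True
    handle.history = history
    return handle


def predict(handle: NetworkHandle, segments: list[Segment],
            batch_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and softmax probabilities for a list of segments.

    Deterministic at inference (no dropout, running batch-norm statistics);
    argmax ties break toward the lower class index.
    """
    if handle.norm_mean is None:
        raise TrainingError("network has not been trained")
    x = _segment_tensor(segments, handle)
    x = _standardize(x, handle)
    inputs = _model_inputs(x, handle)
    rng = np.random.default_rng(0)
    probs = []
    n = len(segments)
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        logits = _forward(handle, _take(inputs, idx), "eval", rng)
        probs.append(nn.softmax(logits.astype(np.float64)))
    probs = np.concatenate(probs, axis=0)
    labels = probs.argmax(axis=1)
    return labels, probs


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(handle: NetworkHandle, path: str | Path) -> None:
    """Save weights (npz) plus a JSON layer-inventory sidecar so parameter
    counts can be audited without loading the arrays."""
    path = Path(path)
    arrays = {f"p{i}": p for i, (p, _) in enumerate(
        handle.net.param_pairs())}
    for i, lyr in enumerate(nn._bn_layers(handle.net)):
        arrays[f"bn{i}_mean"] = lyr.running_mean
        arrays[f"bn{i}_var"] = lyr.running_var
    if handle.norm_mean is not None:
        arrays["norm_mean"] = handle.norm_mean
        arrays["norm_std"] = handle.norm_std
    np.savez(path, **arrays)
    sidecar = {
        "spec": dataclasses.asdict(handle.spec),
        "trained": handle.trained,
        "inventory": handle.inventory,
        "trainable_parameters": count_trainable_parameters(handle),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> NetworkHandle:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = ModelSpec(**sidecar["spec"])
    handle = build(spec)
    with np.load(path if path.suffix else path.with_suffix(".npz")) as z:
        for i, (p, _) in enumerate(handle.net.param_pairs()):
            p[...] = z[f"p{i}"]
        for i, lyr in enumerate(nn._bn_layers(handle.net)):
            lyr.running_mean = z[f"bn{i}_mean"]
            lyr.running_var = z[f"bn{i}_var"]
        if "norm_mean" in z:
            handle.norm_mean = z["norm_mean"]
            handle.norm_std = z["norm_std"]
    handle.trained = sidecar["trained"]
    return handle
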