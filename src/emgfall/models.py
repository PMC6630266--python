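"""Classifiers: the improved dual-parallel-channel CNN (IDPC-CNN), its
ablation variants, and classical baselines.

The IDPC-CNN consumes reduced-spectrogram tiles of shape
(time frames, PCA components, sEMG channels); the four electrode channels
enter as input depth so the convolutions mix muscles and capture
co-contraction. Two parallel convolutional branches see the same input:

* branch 1 uses 2 x 4 kernels (elongated along the component axis),
* branch 2 uses 4 x 2 kernels (elongated along the time axis),

each with filter counts [10, 20, 20] and 2 x 2 max pooling after the first
two convolutions. Their flattened outputs concatenate into a shared fully
connected head of sizes [40, 10, 4] with ReLU activations and dropout 0.5
between the dense layers, ending in a 4-way softmax over the gestures.

Ablations: DPC1 duplicates branch 1, DPC2 duplicates branch 2 (identical
parameter counts — the kernels are transposes), and the single-channel CNN
uses one branch of square 2 x 2 kernels. Baselines (RBF-SVM, LDA, KNN) wrap
scikit-learn estimators behind the same predict-probability contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import nn
from .nn import Network, softmax  # softmax re-exported: it is the classifier's output map

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "VARIANTS",
    "BASELINES",
    "build_network",
    "train",
    "predict",
    "aggregate_windows",
    "baseline_classifier",
    "softmax",
]

VARIANTS = ("idpc", "dpc1", "dpc2", "single")
BASELINES = ("svm_rbf", "lda", "knn")

_FILTERS = (10, 20, 20)
_HEAD = (40, 10, 4)
_DROPOUT = 0.5


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture descriptor emitted alongside every built model."""

    variant: str
    input_shape: tuple[int, int, int]  # (frames, components, channels)
    branch_kernels: tuple[tuple[int, int], ...]
    filters: tuple[int, ...] = _FILTERS
    head: tuple[int, ...] = _HEAD
    dropout: float = _DROPOUT
    n_parameters: int = 0

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "input_shape": list(self.input_shape),
            "branch_kernels": [list(k) for k in self.branch_kernels],
            "filters": list(self.filters),
            "head": list(self.head),
            "dropout": self.dropout,
            "n_parameters": self.n_parameters,
        }


@dataclass(frozen=True)
class TrainingConfig:
    """Minibatch training hyper-parameters; the seed is part of the artifact."""

    batch_size: int = 32
    epochs: int = 50
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    patience: int | None = None  # early stopping on held-out loss when set
    val_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimiser is implemented")


def _branch(kh: int, kw: int, cin: int, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c = cin
    for i, f in enumerate(_FILTERS):
        layers.append(nn.Conv2D(kh, kw, c, f, rng))
        layers.append(nn.ReLU())
        if i < 2:  # pooling follows the first two convolutions
            layers.append(nn.MaxPool2D(2))
        c = f
    layers.append(nn.Flatten())
    return nn.Sequential(layers)


def build_network(
    variant: str, input_shape: tuple[int, int, int], seed: int = 0
) -> tuple[NetworkSpec, Network]:
    """Construct an initialised model of the requested variant.

    ``input_shape`` is (frames, components, channels); frames and the
    component axis must survive two 2 x 2 poolings (>= 4 frames; the
    acceptance-scale default is 8 x 8 x 4).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    H, W, C = input_shape
    if H < 4:
        raise ValueError(
            f"input with {H} frames too small for MaxPool2D stack (layer 'pool2' empties the time axis)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC4A]))
    kernels = {
        "idpc": ((2, 4), (4, 2)),
        "dpc1": ((2, 4), (2, 4)),
        "dpc2": ((4, 2), (4, 2)),
        "single": ((2, 2),),
    }[variant]
    branches = [_branch(kh, kw, C, rng) for kh, kw in kernels]
    trunk = nn.ParallelBranches(branches) if len(branches) > 1 else branches[0]
    # probe the flattened width with a zero batch
    flat = trunk.forward(np.zeros((1, H, W, C)), train=False).shape[1]
    head: list[nn.Layer] = []
    widths = (flat,) + _HEAD
    for i in range(len(_HEAD)):
        head.append(nn.Dense(widths[i], widths[i + 1], rng))
        if i < len(_HEAD) - 1:
            head.append(nn.ReLU())
            head.append(nn.Dropout(_DROPOUT, rng))
    body = nn.Sequential([trunk, *head])
    net = Network(body)
    spec = NetworkSpec(
        variant=variant,
        input_shape=tuple(input_shape),
        branch_kernels=kernels,
        n_parameters=net.n_parameters(),
    )
    return spec, net


def train(
    model: Network, x: np.ndarray, y: np.ndarray, cfg: TrainingConfig | None = None
) -> list[float]:
    """Train on (N, frames, k, channels) tiles with integer labels.

    Refuses single-class training sets; returns the per-epoch loss history.
    Deterministic under ``cfg.seed``.
    """
    cfg = cfg or TrainingConfig()
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class; nothing to discriminate")
    return model.fit(
        np.asarray(x, dtype=float),
        np.asarray(y),
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.learning_rate,
        seed=cfg.seed,
        patience=cfg.patience,
        val_fraction=cfg.val_fraction if cfg.patience else 0.0,
    )


def predict(model: Network, x: np.ndarray) -> np.ndarray:
    """Class probabilities per input tile (dropout disabled)."""
    x = np.asarray(x, dtype=float)
    return model.predict_proba(x)


def aggregate_windows(window_probs: np.ndarray) -> np.ndarray:
    """Segment-level probability vector: mean of its windows' probabilities."""
    p = np.mean(np.atleast_2d(window_probs), axis=0)
    return p / p.sum()


def baseline_classifier(kind: str, seed: int = 0):
    """A classical classifier exposing fit / predict_proba on flat features."""
    if kind == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown baseline {kind!r}; expected one of {BASELINES}")
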