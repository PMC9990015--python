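"""Patch classifiers: the pluggable contract, the reference network, training.

Any object satisfying :class:`ClassifierContract` can drive the pipeline —
the reference :class:`DenResMiniClassifier` is a width-reduced numpy network
with the dual-branch topology, a ``"post_concat"`` Grad-CAM tap and two
Monte-Carlo dropout layers.  The training policy follows the study protocol:
seeded shuffle, 70/30 train/validation split, categorical cross-entropy,
plain SGD at a fixed learning rate of 1e-4, default 25 epochs, dropout 0.3.
"""

from __future__ import annotations

import json
import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import DenResMini, softmax
from .patching import N_CLASSES, CLASS_NAMES, PatchSet


class ClassifierContract(ABC):
    """What the pipeline requires of a six-class patch classifier."""

    #: patch extent (h, w, d) the classifier accepts
    input_size: tuple[int, int, int]
    #: tags of layers whose activations/gradients can be inspected
    layer_tags: tuple[str, ...] = ("post_concat",)

    @abstractmethod
    def predict_proba(
        self,
        batch: np.ndarray,
        stochastic: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Softmax probabilities, shape (n, 6).

        ``stochastic=False`` must be deterministic (dropout disabled);
        ``stochastic=True`` keeps the Monte-Carlo dropout layers active and
        requires an ``rng``.
        """

    @abstractmethod
    def activation_and_gradient(
        self, patch: np.ndarray, target_class: int, layer_tag: str = "post_concat"
    ) -> tuple[np.ndarray, np.ndarray]:
        """Activation maps and d(score_target)/d(activation) at a tagged layer."""

    def input_gradient(
        self, patch: np.ndarray, target_class: int, guided: bool = True
    ) -> np.ndarray:
        """Gradient of the target class score w.r.t. the input patch.

        With ``guided=True`` the backward pass zeroes negative gradients at
        every rectifier (guided backpropagation).  Optional: classifiers that
        cannot provide it raise ``NotImplementedError``.
        """
        raise NotImplementedError

    @property
    def has_stochastic_mode(self) -> bool:
        return True


@dataclass
class TrainSpec:
    """Training policy (defaults follow the study protocol)."""

    split: float = 0.70
    learning_rate: float = 0.0001
    epochs: int = 25
    dropout_p: float = 0.3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split < 1.0:
            raise ValueError(f"split must be in (0, 1), got {self.split}")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


class DenResMiniClassifier(ClassifierContract):
    """Reference numpy classifier (see :mod:`pulmotex.nn`)."""

    layer_tags = ("post_concat",)

    def __init__(self, input_size: tuple[int, int, int], width_factor: float = 1.0,
                 dropout_p: float = 0.3, seed: int = 0):
        self.net = DenResMini(input_size, width_factor=width_factor,
                              dropout_p=dropout_p, seed=seed)
        self.input_size = self.net.input_size

    # -- contract ----------------------------------------------------------

    def predict_proba(self, batch, stochastic=False, rng=None):
        batch = self._check_batch(batch)
        probs, _ = self.net.forward(batch, stochastic=stochastic, rng=rng)
        return probs

    def activation_and_gradient(self, patch, target_class, layer_tag="post_concat"):
        if layer_tag not in self.layer_tags:
            raise ValueError(
                f"unknown layer_tag {layer_tag!r}; available: {self.layer_tags}"
            )
        x = self._check_batch(patch[None])
        _, cache = self.net.forward(x, stochastic=False)
        dlogits = np.zeros((1, N_CLASSES))
        dlogits[0, target_class] = 1.0  # d(score)/d(logits) for the raw class score
        _, dA = self.net.backward(dlogits, cache, capture=layer_tag)
        return cache[layer_tag][0], dA[0]

    def input_gradient(self, patch, target_class, guided=True):
        x = self._check_batch(patch[None])
        _, cache = self.net.forward(x, stochastic=False)
        dlogits = np.zeros((1, N_CLASSES))
        dlogits[0, target_class] = 1.0
        dx, _ = self.net.backward(dlogits, cache, guided=guided)
        return dx[0]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights + architecture + class names."""
        config = {
            "input_size": list(self.net.input_size),
            "width_factor": self.net.width_factor,
            "dropout_p": self.net.dropout_p,
            "seed": self.net.seed,
            "class_names": list(CLASS_NAMES),
        }
        np.savez(path, __config__=json.dumps(config), **self.net.state_dict())

    @classmethod
    def load(cls, path) -> "DenResMiniClassifier":
        with np.load(path, allow_pickle=False) as archive:
            config = json.loads(str(archive["__config__"]))
            state = {k: archive[k] for k in archive.files if k != "__config__"}
        clf = cls(tuple(config["input_size"]), width_factor=config["width_factor"],
                  dropout_p=config["dropout_p"], seed=config["seed"])
        clf.net.load_state_dict(state)
        return clf

    # -- internals ---------------------------------------------------------

    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=float)
        if batch.ndim != 4 or batch.shape[1:] != self.input_size:
            raise ValueError(
                f"batch shape {batch.shape[1:]} does not match classifier "
                f"input size {self.input_size}"
            )
        return batch


def build_denres_mini(
    input_size: tuple[int, int, int],
    width_factor: float = 1.0,
    dropout_p: float = 0.3,
    seed: int = 0,
) -> DenResMiniClassifier:
    """Construct the reference dual-branch classifier for one patch size."""
    return DenResMiniClassifier(input_size, width_factor=width_factor,
                                dropout_p=dropout_p, seed=seed)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


def train(
    classifier: DenResMiniClassifier,
    patchset: PatchSet,
    spec: TrainSpec = TrainSpec(),
) -> tuple[DenResMiniClassifier, TrainHistory]:
    """Train in place with seeded shuffle, 70/30 split, cross-entropy + SGD.

    The gradient step uses the summed cross-entropy over each mini-batch at
    the fixed learning rate.  Dropout layers are active during training.
    Returns the classifier and the per-epoch loss/accuracy history.
    """
    if patchset.labels is None:
        raise ValueError("training requires a labelled PatchSet")
    X = patchset.stack().astype(float)
    y = np.asarray(patchset.labels)
    counts = np.bincount(y, minlength=N_CLASSES)
    present = counts[counts > 0]
    if (counts[np.isin(np.arange(N_CLASSES), np.unique(y))] < 2).any():
        small = [CLASS_NAMES[c] for c in np.unique(y) if counts[c] < 2]
        raise ValueError(f"fewer than 2 samples in class(es): {small}")
    if present.min() != present.max():
        warnings.warn(
            "class counts are unbalanced; a balanced sample per class is "
            "recommended for training",
            stacklevel=2,
        )

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(y))
    n_train = int(round(spec.split * len(y)))
    tr, va = order[:n_train], order[n_train:]
    net = classifier.net
    net.dropout_p = spec.dropout_p
    history = TrainHistory()

    for _ in range(spec.epochs):
        perm = tr[rng.permutation(len(tr))]
        losses, correct = [], 0
        for start in range(0, len(perm), spec.batch_size):
            idx = perm[start:start + spec.batch_size]
            xb, yb = X[idx], y[idx]
            probs, cache = net.forward(xb, stochastic=True, rng=rng)
            eps = 1e-12
            losses.append(-np.log(probs[np.arange(len(yb)), yb] + eps).sum())
            correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0  # summed cross-entropy
            net.backward(dlogits, cache)
            for p, g in net.param_grads():
                p -= spec.learning_rate * g
        history.train_loss.append(float(np.sum(losses) / len(perm)))
        history.train_accuracy.append(correct / len(perm))
        vl, vacc = _evaluate(net, X[va], y[va], spec.batch_size)
        history.val_loss.append(vl)
        history.val_accuracy.append(vacc)
    return classifier, history


def _evaluate(net: DenResMini, X: np.ndarray, y: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    losses, correct = 0.0, 0
    for start in range(0, len(y), batch_size):
        xb, yb = X[start:start + batch_size], y[start:start + batch_size]
        probs, _ = net.forward(xb, stochastic=False)
        losses += float(-np.log(probs[np.arange(len(yb)), yb] + 1e-12).sum())
        correct += int((probs.argmax(axis=1) == yb).sum())
    n = max(len(y), 1)
    return losses / n, correct / n


def classify_patchset(
    classifier: ClassifierContract,
    patchset: PatchSet,
    batch_size: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic labels and probabilities for every patch, in order.

    Labels are the argmax of the softmax vector; exact ties resolve to the
    lowest class id.
    """
    if len(patchset) == 0:
        return np.zeros(0, dtype=int), np.zeros((0, N_CLASSES))
    first = patchset.patches[0].size
    if tuple(first) != tuple(classifier.input_size):
        raise ValueError(
            f"patch size {tuple(first)} does not match classifier input size "
            f"{tuple(classifier.input_size)}"
        )
    X = patchset.stack().astype(float)
    probs = np.concatenate(
        [
            classifier.predict_proba(X[i:i + batch_size], stochastic=False)
            for i in range(0, len(X), batch_size)
        ]
    )
    labels = probs.argmax(axis=1)  # argmax returns the lowest index on ties
    return labels, probs
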