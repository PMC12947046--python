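"""Seeded mini-batch training for pairwise and pointwise objectives.

One training loop serves both scorer families (the distance-based
backbone over structures and the MLP head over precomputed embeddings)
and all three objectives:

* ``pairwise_entropy`` — the Siamese ranker as a soft binary classifier:
  cross-entropy of logistic(score_a - score_b) against the comparison
  label, computed in the numerically stable softplus form,
* ``pairwise_squared`` — regression of the score difference onto the
  property difference,
* ``pointwise`` — plain regression of each score onto the property.

Optimisation is Adam by default (plain gradient descent available).
Shuffling is seeded per epoch, and with a fixed seed and thread count a
run is bit-reproducible.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Protocol, Sequence, Tuple, Union

import numpy as np

from .autodiff import Tensor, constant
from .gnn import ModelParameters, RBFConfig, batch_structures, forward_scores_batch
from .moldata import PairExample, Structure
from .ranker import MLPHeadParameters, mlp_head_scores_batch

__all__ = [
    "TrainConfig",
    "TrainReport",
    "BackboneModel",
    "EmbeddingHeadModel",
    "Adam",
    "train",
]

OBJECTIVES = ("pairwise_entropy", "pairwise_squared", "pointwise")


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults: 64-pair batches, up to 60
    epochs, learning rate 1e-4)."""

    batch_size: int = 64
    max_epochs: int = 60
    learning_rate: float = 1e-4
    hidden_width: int = 128
    seed: int = 0
    objective: str = "pairwise_entropy"
    optimizer: str = "adam"            # or "sgd"
    standardize_targets: bool = True   # affine target scaling for the
                                       # squared objectives (train-set stats)
    patience: Optional[int] = None     # early stopping on epoch loss, off by default

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.objective not in OBJECTIVES:
            raise ValueError(
                f"objective must be one of {OBJECTIVES}, got {self.objective!r}"
            )
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass
class TrainReport:
    """Per-epoch mean losses and run bookkeeping."""

    losses: List[float]
    seed: int
    seconds: float
    objective: str
    n_examples: int

    @property
    def final_loss(self) -> float:
        return self.losses[-1]


# ---------------------------------------------------------------------------
# Scorer abstraction
# ---------------------------------------------------------------------------

class ScorerModel(Protocol):
    def batch_scores(self, items: Sequence) -> Tensor: ...
    def tensors(self) -> List[Tensor]: ...


class BackboneModel:
    """The distance-based graph scorer applied to Structures."""

    def __init__(self, params: ModelParameters, rbf: RBFConfig):
        self.params = params
        self.rbf = rbf

    def batch_scores(self, items: Sequence[Structure]) -> Tensor:
        Z, D, mask = batch_structures(items)
        return forward_scores_batch(Z, D, mask, self.params, self.rbf)

    def tensors(self) -> List[Tensor]:
        return self.params.all_tensors()

    def score_numpy(self, items: Sequence[Structure]) -> np.ndarray:
        return self.batch_scores(items).data.copy()


class EmbeddingHeadModel:
    """The MLP head applied to fixed-length embedding vectors.

    Items may be raw vectors or any object with a ``vector`` attribute
    (e.g. EmbeddingRecord).
    """

    def __init__(self, head: MLPHeadParameters):
        self.head = head

    @staticmethod
    def _vectors(items: Sequence) -> np.ndarray:
        return np.stack([
            np.asarray(getattr(it, "vector", it), dtype=np.float64)
            for it in items
        ])

    def batch_scores(self, items: Sequence) -> Tensor:
        return mlp_head_scores_batch(self._vectors(items), self.head)

    def tensors(self) -> List[Tensor]:
        return self.head.all_tensors()

    def score_numpy(self, items: Sequence) -> np.ndarray:
        return self.batch_scores(items).data.copy()


# ---------------------------------------------------------------------------
# Optimisers
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard moment coefficients (0.9, 0.999)."""

    def __init__(self, tensors: Sequence[Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.tensors = list(tensors)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in self.tensors]
        self.v = [np.zeros_like(t.data) for t in self.tensors]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.tensors):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad * p.grad
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.tensors:
            p.grad = None


class SGD:
    def __init__(self, tensors: Sequence[Tensor], lr: float):
        self.tensors = list(tensors)
        self.lr = lr

    def step(self) -> None:
        for p in self.tensors:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.tensors:
            p.grad = None


# ---------------------------------------------------------------------------
# Loss construction
# ---------------------------------------------------------------------------

def _pairwise_entropy_loss(diff: Tensor, labels: np.ndarray) -> Tensor:
    # -[l1 log sigma(d) + l2 log(1-sigma(d))] = softplus(d) - l1 * d
    l1 = constant(labels[:, 0])
    return (diff.softplus() - l1 * diff).mean()


def _squared_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    r = pred - constant(target)
    return (r * r).mean()


class _NonFiniteLoss(RuntimeError):
    pass


def train(model: ScorerModel,
          data: Sequence,
          cfg: TrainConfig,
          property_name: Optional[str] = None,
          log: Optional[Callable[[str], None]] = None) -> TrainReport:
    """Run seeded mini-batch training.

    For the pairwise objectives ``data`` is a sequence of pair examples
    (objects with ``a``, ``b``, ``label``, ``target_diff``). For
    ``pointwise`` it is a sequence of scoreable items, with the target
    taken from ``item.properties[property_name]`` (or ``(item, target)``
    tuples when ``property_name`` is None).

    Raises a RuntimeError naming the epoch and batch if the loss goes
    non-finite.
    """
    if len(data) == 0:
        raise ValueError("training data is empty")
    pairwise = cfg.objective.startswith("pairwise")
    if pairwise and not hasattr(data[0], "a"):
        raise ValueError(f"objective {cfg.objective} expects pair examples")
    if not pairwise and hasattr(data[0], "a"):
        raise ValueError("pointwise objective expects single items, not pairs")

    if pairwise:
        labels = np.array([ex.label for ex in data], dtype=np.float64)
        diffs = np.array([ex.target_diff for ex in data], dtype=np.float64)
        scale = 1.0
        if cfg.objective == "pairwise_squared" and cfg.standardize_targets:
            sd = diffs.std()
            scale = sd if sd > 0 else 1.0
        targets = diffs / scale
        items_a = [ex.a for ex in data]
        items_b = [ex.b for ex in data]
    else:
        if property_name is not None:
            items = list(data)
            raw = np.array([it.properties[property_name] for it in items])
        else:
            items = [it for it, _ in data]
            raw = np.array([t for _, t in data], dtype=np.float64)
        mu, sd = (raw.mean(), raw.std()) if cfg.standardize_targets else (0.0, 1.0)
        sd = sd if sd > 0 else 1.0
        targets = (raw - mu) / sd

    opt = (Adam(model.tensors(), cfg.learning_rate) if cfg.optimizer == "adam"
           else SGD(model.tensors(), cfg.learning_rate))
    rng = np.random.default_rng(cfg.seed)
    n = len(data)
    losses: List[float] = []
    best, since_best = np.inf, 0
    t0 = time.perf_counter()
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            if pairwise:
                sa = model.batch_scores([items_a[i] for i in idx])
                sb = model.batch_scores([items_b[i] for i in idx])
                diff = sa - sb
                if cfg.objective == "pairwise_entropy":
                    loss = _pairwise_entropy_loss(diff, labels[idx])
                else:
                    loss = _squared_loss(diff, targets[idx])
            else:
                s = model.batch_scores([items[i] for i in idx])
                loss = _squared_loss(s, targets[idx])
            val = float(loss.data)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(val)
        mean_loss = float(np.mean(epoch_losses))
        losses.append(mean_loss)
        if log is not None:
            log(f"epoch={epoch} mean_loss={mean_loss:.6f} "
                f"seconds={time.perf_counter() - t0:.1f}")
        if cfg.patience is not None:
            if mean_loss < best - 1e-12:
                best, since_best = mean_loss, 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    return TrainReport(losses=losses, seed=cfg.seed,
                       seconds=time.perf_counter() - t0,
                       objective=cfg.objective, n_examples=n)
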