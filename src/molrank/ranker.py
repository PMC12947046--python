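"""Siamese pairwise combination, ranking losses, and the embedding head.

The pairwise ranker applies one shared scorer to both members of a pair
and converts the score difference into a probability with a logistic
function, so antisymmetry (p(a,b) + p(b,a) = 1) and reflexivity
(p(x,x) = 0.5) hold exactly by construction. Training objectives:

* ``entropy_loss`` — binary cross-entropy against the comparison label
  (supports the soft tie label (0.5, 0.5)),
* ``squared_pair_loss`` — regression of the score difference onto the
  property difference,
* ``pointwise_loss`` — plain squared error of a single score against the
  property value (the regression baseline).

For precomputed fixed-length molecular embeddings the scorer is a small
MLP (dense 128 -> tanh -> dense 64 -> tanh -> dense 1); the same three
objectives apply unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .autodiff import Tensor, parameter

__all__ = [
    "PairPrediction",
    "EmbeddingRecord",
    "MLPHeadParameters",
    "pairwise_probability",
    "entropy_loss",
    "squared_pair_loss",
    "pointwise_loss",
    "mlp_head_score",
    "mlp_head_scores_batch",
    "init_mlp_head",
    "read_embedding_table",
]

PROB_CLIP = 1e-7


@dataclass(frozen=True)
class PairPrediction:
    """Scores of the two branches and the derived outranking probability."""

    score_a: float
    score_b: float

    @property
    def probability(self) -> float:
        return float(pairwise_probability(self.score_a, self.score_b))


@dataclass
class EmbeddingRecord:
    """One precomputed molecular embedding with its metadata."""

    structure_id: str
    group_id: str
    vector: np.ndarray
    properties: Dict[str, float]


def pairwise_probability(score_a, score_b):
    """P(a outranks b) = logistic(score_a - score_b); exactly antisymmetric."""
    diff = np.asarray(score_a, dtype=np.float64) - np.asarray(score_b, dtype=np.float64)
    out = np.empty_like(diff)
    pos = diff >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-diff[pos]))
    ex = np.exp(diff[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def entropy_loss(probability, label) -> float:
    """Cross-entropy -[l1 ln p + l2 ln(1-p)] with soft labels allowed.

    ``label`` is the pair (l1, l2) with l1 + l2 = 1; probabilities are
    clipped to [1e-7, 1 - 1e-7] for numerical stability.
    """
    l1, l2 = float(label[0]), float(label[1])
    if not np.isclose(l1 + l2, 1.0):
        raise ValueError("label components must sum to 1")
    p = np.clip(np.asarray(probability, dtype=np.float64),
                PROB_CLIP, 1.0 - PROB_CLIP)
    return float(np.mean(-(l1 * np.log(p) + l2 * np.log(1.0 - p))))


def squared_pair_loss(score_a, score_b, target_diff) -> float:
    """((score_a - score_b) - target_diff)^2, averaged if vectorised."""
    r = (np.asarray(score_a, dtype=np.float64)
         - np.asarray(score_b, dtype=np.float64)
         - np.asarray(target_diff, dtype=np.float64))
    return float(np.mean(r * r))


def pointwise_loss(score, target) -> float:
    """(score - target)^2, averaged if vectorised."""
    r = np.asarray(score, dtype=np.float64) - np.asarray(target, dtype=np.float64)
    return float(np.mean(r * r))


# ---------------------------------------------------------------------------
# MLP head over precomputed embeddings
# ---------------------------------------------------------------------------

@dataclass
class MLPHeadParameters:
    """Weights of the embedding-head scorer (dense/tanh/dense/tanh/dense)."""

    w1: Tensor  # (D, 128)
    b1: Tensor
    w2: Tensor  # (128, 64)
    b2: Tensor
    w3: Tensor  # (64, 1)
    b3: Tensor

    @property
    def input_width(self) -> int:
        return self.w1.shape[0]

    def all_tensors(self) -> List[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]


def init_mlp_head(input_width: int, hidden: Tuple[int, int] = (128, 64),
                  seed: int = 0) -> MLPHeadParameters:
    rng = np.random.default_rng(seed)

    def dense(fan_in, shape):
        return parameter(rng.uniform(-1, 1, size=shape) / np.sqrt(fan_in))

    h1, h2 = hidden
    return MLPHeadParameters(
        w1=dense(input_width, (input_width, h1)), b1=parameter(np.zeros(h1)),
        w2=dense(h1, (h1, h2)), b2=parameter(np.zeros(h2)),
        w3=dense(h2, (h2, 1)), b3=parameter(np.zeros(1)),
    )


def mlp_head_scores_batch(vectors: np.ndarray,
                          head: MLPHeadParameters) -> Tensor:
    """Score a (B, D) batch of embedding vectors; returns a (B,) tensor."""
    x = np.asarray(vectors, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != head.input_width:
        raise ValueError(
            f"expected (B, {head.input_width}) vectors, got {x.shape}"
        )
    from .autodiff import constant
    h = (constant(x) @ head.w1 + head.b1).tanh()
    h = (h @ head.w2 + head.b2).tanh()
    out = h @ head.w3 + head.b3          # (B, 1)
    return out.reshape(x.shape[0])


def mlp_head_score(vector: np.ndarray, head: MLPHeadParameters) -> float:
    """Score one embedding vector."""
    v = np.asarray(vector, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("expected a single 1-D embedding vector")
    return float(mlp_head_scores_batch(v[None], head).data[0])


def read_embedding_table(path: Union[str, Path]) -> List[EmbeddingRecord]:
    """Read a delimited embedding table.

    Columns: ``structure_id``, ``group_id``, any number of property
    columns, then the embedding components ``v0..v(D-1)``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("structure_id", "group_id"):
        if col not in df.columns:
            raise ValueError(f"embedding table lacks column {col!r}")
    vcols = sorted((c for c in df.columns if c.startswith("v") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    if not vcols:
        raise ValueError("embedding table has no v0..v(D-1) columns")
    prop_cols = [c for c in df.columns
                 if c not in ("structure_id", "group_id") and c not in vcols]
    records = []
    for _, row in df.iterrows():
        vec = row[vcols].to_numpy(dtype=np.float64)
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"non-finite embedding for {row['structure_id']}")
        records.append(EmbeddingRecord(
            structure_id=str(row["structure_id"]),
            group_id=str(row["group_id"]),
            vector=vec,
            properties={c: float(row[c]) for c in prop_cols},
        ))
    return records
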