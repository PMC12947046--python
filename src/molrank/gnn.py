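"""Distance-based graph neural scorer for molecular configurations.

The backbone maps a molecule (atomic numbers Z_i, positions r_i) to one
real score. It follows the continuous-filter message-passing family:

* per-element embedding x_i^0 = a_{Z_i} (learned table),
* shared atom-wise dense layers x_i <- x_i W + b,
* interaction steps in which atom i receives from every other atom j a
  message phi(d_ij) * x_j (.) W_f(e(d_ij)), where e(d) is a Gaussian
  radial-basis expansion of the interatomic distance, W_f is a two-layer
  filter network, and phi is a smooth quintic cutoff
      phi(u) = 1 - 6u^5 + 15u^4 - 10u^3,  u = d / r_cut,
  clamped to zero beyond r_cut; the aggregated message is passed through
  a two-layer update network and added residually,
* a prediction layer p_i = u (.) E_i + w1 (.) A1_i + w2 (.) A2_i merging
  the embedding with the outputs of the two final atom-wise layers
  (elementwise products with learned length-F vectors), and
* a readout: sum of p_i over atoms followed by a linear map to a scalar.

Because only interatomic distances enter, the score is invariant to
rigid rotations and translations; summation over atoms and neighbours
makes it invariant to atom permutation. The cutoff radius r_cut is a
learnable parameter (kept positive through a softplus reparameterisation).

All nonlinearities are the shifted softplus ssp(x) = ln(0.5 e^x + 0.5).
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .autodiff import Tensor, constant, parameter
from .moldata import Structure

__all__ = [
    "RBFConfig",
    "ModelParameters",
    "shifted_softplus",
    "rbf_expand",
    "cutoff_decay",
    "embed_atoms",
    "atom_wise",
    "interaction_step",
    "prediction_layer",
    "forward_score",
    "forward_scores_batch",
    "batch_structures",
    "init_parameters",
    "save_parameters",
    "load_parameters",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class RBFConfig:
    """Gaussian radial-basis grid for distance expansion.

    Defaults follow the 300-centre grid from 0 to 30 Angstrom with step
    0.1 and unit Gaussian width coefficient. ``width_coefficient`` stores
    the magnitude of the exponent prefactor, i.e. the basis function is
    exp(-width_coefficient * (d - mu_k)^2).
    """

    n_centers: int = 300
    centers: Tuple[float, ...] = tuple(np.round(np.arange(0.0, 30.0, 0.1), 10))
    width_coefficient: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=np.float64)
        if len(c) != self.n_centers:
            raise ValueError(
                f"n_centers={self.n_centers} but {len(c)} centers given"
            )
        if np.any(np.diff(c) <= 0):
            raise ValueError("centers must be strictly increasing")
        if self.width_coefficient <= 0:
            raise ValueError("width_coefficient must be positive")

    @classmethod
    def uniform(cls, start: float, stop: float, step: float,
                width_coefficient: float = 1.0) -> "RBFConfig":
        centers = tuple(np.round(np.arange(start, stop, step), 10))
        return cls(n_centers=len(centers), centers=centers,
                   width_coefficient=width_coefficient)


# ---------------------------------------------------------------------------
# Stateless numeric primitives (numpy in / numpy out)
# ---------------------------------------------------------------------------

def shifted_softplus(x):
    """ssp(x) = ln(0.5 e^x + 0.5), overflow-safe; ssp(0) = 0."""
    return np.logaddexp(0.0, np.asarray(x, dtype=np.float64)) - _LN2


def rbf_expand(d, cfg: RBFConfig = RBFConfig()) -> np.ndarray:
    """Expand distances on the Gaussian grid; output has a trailing axis
    of length ``cfg.n_centers``, every component in (0, 1]."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    mu = np.asarray(cfg.centers)
    return np.exp(-cfg.width_coefficient * (d[..., None] - mu) ** 2)


def cutoff_decay(d, r_cut: float):
    """Quintic cutoff phi(d) = 1 - 6u^5 + 15u^4 - 10u^3 (u = d/r_cut),
    clamped to 0 for d > r_cut. phi(0)=1, phi(r_cut)=0, with vanishing
    slope at both ends; monotone non-increasing on [0, r_cut]."""
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    d = np.asarray(d, dtype=np.float64)
    u = d / r_cut
    val = 1.0 - 6.0 * u ** 5 + 15.0 * u ** 4 - 10.0 * u ** 3
    return np.where(u <= 1.0, val, 0.0)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """All learnable quantities of the backbone.

    Structure (T = n_interactions, F = feature width, K = RBF centers):

    * ``embedding`` (Z_max+1, F): per-element embedding table a_Z.
    * ``atom_wise`` (T+1) x (W (F,F), b (F,)): shared dense layers; the
      extra final layer follows the last interaction so that the two
      tapped "final atom-wise" outputs bracket it and no interaction is
      dead weight.
    * ``filter_mlp`` T x (W1 (K,F), b1, W2 (F,F), b2): distance filters.
    * ``update_mlp`` T x (W1 (F,F), b1, W2 (F,F), b2): message updates.
    * ``pred_u``, ``pred_w1``, ``pred_w2`` (F,): skip-merge vectors.
    * ``readout_w`` (F,), ``readout_b`` (): final linear map.
    * ``cutoff_raw`` (): unconstrained; r_cut = softplus(cutoff_raw) > 0.
    """

    embedding: Tensor
    atom_wise: List[Tuple[Tensor, Tensor]]
    filter_mlp: List[Tuple[Tensor, Tensor, Tensor, Tensor]]
    update_mlp: List[Tuple[Tensor, Tensor, Tensor, Tensor]]
    pred_u: Tensor
    pred_w1: Tensor
    pred_w2: Tensor
    readout_w: Tensor
    readout_b: Tensor
    cutoff_raw: Tensor

    @property
    def n_interactions(self) -> int:
        return len(self.filter_mlp)

    @property
    def n_features(self) -> int:
        return self.embedding.shape[1]

    @property
    def r_cut(self) -> float:
        return float(np.logaddexp(0.0, self.cutoff_raw.data))

    def r_cut_tensor(self) -> Tensor:
        return self.cutoff_raw.softplus()

    def all_tensors(self) -> List[Tensor]:
        out = [self.embedding]
        for w, b in self.atom_wise:
            out += [w, b]
        for grp in self.filter_mlp:
            out += list(grp)
        for grp in self.update_mlp:
            out += list(grp)
        out += [self.pred_u, self.pred_w1, self.pred_w2,
                self.readout_w, self.readout_b, self.cutoff_raw]
        return out


def _dense_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_parameters(n_features: int = 128, n_interactions: int = 3,
                    cfg: RBFConfig = RBFConfig(), z_max: int = 10,
                    r_cut_init: float = 10.0, seed: int = 0) -> ModelParameters:
    """Seeded initialisation: embeddings from N(0, 1/F); dense layers by a
    fan-in-scaled uniform scheme; r_cut starts at ``r_cut_init`` Angstrom."""
    rng = np.random.default_rng(seed)
    F, K, T = n_features, cfg.n_centers, n_interactions
    emb = parameter(rng.standard_normal((z_max + 1, F)) / np.sqrt(F))
    atom_wise = [(parameter(_dense_init(rng, F, (F, F))),
                  parameter(np.zeros(F))) for _ in range(T + 1)]
    filter_mlp = [(parameter(_dense_init(rng, K, (K, F))),
                   parameter(np.zeros(F)),
                   parameter(_dense_init(rng, F, (F, F))),
                   parameter(np.zeros(F))) for _ in range(T)]
    update_mlp = [(parameter(_dense_init(rng, F, (F, F))),
                   parameter(np.zeros(F)),
                   parameter(_dense_init(rng, F, (F, F))),
                   parameter(np.zeros(F))) for _ in range(T)]
    # invert softplus so that r_cut starts at r_cut_init
    raw = np.log(np.expm1(r_cut_init))
    return ModelParameters(
        embedding=emb,
        atom_wise=atom_wise,
        filter_mlp=filter_mlp,
        update_mlp=update_mlp,
        pred_u=parameter(rng.standard_normal(F) / np.sqrt(F)),
        pred_w1=parameter(rng.standard_normal(F) / np.sqrt(F)),
        pred_w2=parameter(rng.standard_normal(F) / np.sqrt(F)),
        readout_w=parameter(_dense_init(rng, F, (F,))),
        readout_b=parameter(np.zeros(())),
        cutoff_raw=parameter(np.asarray(raw)),
    )


# ---------------------------------------------------------------------------
# Forward components (Tensor in / Tensor out)
# ---------------------------------------------------------------------------

def embed_atoms(atomic_numbers: Sequence[int],
                params: ModelParameters) -> Tensor:
    """Initial features: row i is the embedding of element Z_i."""
    z = np.asarray(atomic_numbers, dtype=np.int64)
    z_max = params.embedding.shape[0] - 1
    bad = z[(z < 1) | (z > z_max)]
    if bad.size:
        raise KeyError(f"element Z={int(bad[0])} not in embedding table "
                       f"(max Z={z_max})")
    return params.embedding.take(z)


def atom_wise(features: Tensor, layer: int, params: ModelParameters) -> Tensor:
    """Shared dense layer: every atom row mapped by the same W, b."""
    w, b = params.atom_wise[layer]
    if features.shape[-1] != w.shape[0]:
        raise ValueError(
            f"feature width {features.shape[-1]} != layer input {w.shape[0]}"
        )
    return features @ w + b


def _filter_net(rbf: Tensor, layer: int, params: ModelParameters) -> Tensor:
    w1, b1, w2, b2 = params.filter_mlp[layer]
    return ((rbf @ w1 + b1).shifted_softplus()) @ w2 + b2


def _update_net(m: Tensor, layer: int, params: ModelParameters) -> Tensor:
    w1, b1, w2, b2 = params.update_mlp[layer]
    return ((m @ w1 + b1).shifted_softplus()) @ w2 + b2


def _check_distances(distances: np.ndarray) -> np.ndarray:
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    if n > 1 and np.any(d[~np.eye(n, dtype=bool)] <= 0):
        raise ValueError("off-diagonal distances must be positive")
    return d


def _interaction_batch(features: Tensor, rbf: np.ndarray,
                       dist: np.ndarray, pair_mask: np.ndarray,
                       layer: int, params: ModelParameters,
                       r_cut: Tensor) -> Tensor:
    """One interaction step over a padded batch.

    ``features`` (B,n,F); ``rbf`` (B,n,n,K) constant; ``dist`` (B,n,n);
    ``pair_mask`` (B,n,n) true for valid i != j pairs. Messages from
    masked/padded atoms are exactly zero.
    """
    filt = _filter_net(constant(rbf), layer, params)          # (B,n,n,F)
    u = constant(dist) / r_cut                                 # (B,n,n)
    poly = 1.0 - 6.0 * u ** 5 + 15.0 * u ** 4 - 10.0 * u ** 3
    inside = (dist / max(r_cut.data.item(), 1e-12)) <= 1.0
    phi = poly.where(inside & pair_mask, constant(np.zeros_like(dist)))
    # m_i = sum_j phi_ij * x_j (.) filter_ij
    xj = features.reshape(features.shape[0], 1,
                          features.shape[1], features.shape[2])  # (B,1,n,F)
    msg = (phi.reshape(*phi.shape, 1) * xj * filt).sum(axis=2)   # (B,n,F)
    return features + _update_net(msg, layer, params)


def interaction_step(features: Tensor, distances: np.ndarray,
                     params: ModelParameters, cfg: RBFConfig,
                     layer: int = 0) -> Tensor:
    """Single-structure interaction step (see module docstring).

    ``features`` is (n, F); ``distances`` a symmetric n x n matrix with a
    zero diagonal. Returns the residually updated features.
    """
    d = _check_distances(distances)
    n = d.shape[0]
    rbf = rbf_expand(d, cfg)[None]                    # (1,n,n,K)
    pair_mask = ~np.eye(n, dtype=bool)[None]
    feats = features.reshape(1, n, features.shape[-1])
    out = _interaction_batch(feats, rbf, d[None], pair_mask, layer,
                             params, params.r_cut_tensor())
    return out.reshape(n, features.shape[-1])


def prediction_layer(embedding: Tensor, atw1: Tensor, atw2: Tensor,
                     params: ModelParameters) -> Tensor:
    """Skip-connection merge p_i = u (.) E_i + w1 (.) A1_i + w2 (.) A2_i."""
    if not (embedding.shape == atw1.shape == atw2.shape):
        raise ValueError("prediction layer inputs must share a shape")
    return (params.pred_u * embedding + params.pred_w1 * atw1
            + params.pred_w2 * atw2)


def batch_structures(structures: Sequence[Structure]
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad a list of structures to common atom count.

    Returns (Z (B,n) int with 0 padding, distances (B,n,n), atom mask
    (B,n) bool). Padded entries have Z=0 and distance 0.
    """
    n_max = max(s.n_atoms for s in structures)
    B = len(structures)
    Z = np.zeros((B, n_max), dtype=np.int64)
    D = np.zeros((B, n_max, n_max), dtype=np.float64)
    mask = np.zeros((B, n_max), dtype=bool)
    for k, s in enumerate(structures):
        n = s.n_atoms
        Z[k, :n] = s.atomic_numbers
        D[k, :n, :n] = s.distance_matrix()
        mask[k, :n] = True
    return Z, D, mask


def forward_scores_batch(Z: np.ndarray, D: np.ndarray, mask: np.ndarray,
                         params: ModelParameters, cfg: RBFConfig) -> Tensor:
    """Score a padded batch; returns a (B,) tensor.

    Padded atoms (mask False) contribute exactly zero to every message
    and to the readout sum.
    """
    B, n = Z.shape
    feats = params.embedding.take(Z)                         # (B,n,F)
    rbf = rbf_expand(D, cfg)                                 # (B,n,n,K)
    pair_mask = (mask[:, :, None] & mask[:, None, :]
                 & ~np.eye(n, dtype=bool)[None])
    r_cut = params.r_cut_tensor()
    emb0 = feats
    atw_outputs: List[Tensor] = []
    for t in range(params.n_interactions):
        feats = atom_wise(feats, t, params)
        atw_outputs.append(feats)
        feats = _interaction_batch(feats, rbf, D, pair_mask, t, params, r_cut)
    feats = atom_wise(feats, params.n_interactions, params)
    atw_outputs.append(feats)
    # the two final atom-wise outputs bracket the last interaction
    a1 = atw_outputs[-2] if len(atw_outputs) >= 2 else atw_outputs[-1]
    a2 = atw_outputs[-1]
    p = prediction_layer(emb0, a1, a2, params)               # (B,n,F)
    p = p * constant(mask[:, :, None].astype(np.float64))
    pooled = p.sum(axis=1)                                   # (B,F)
    return pooled @ params.readout_w + params.readout_b      # (B,)


def forward_score(structure: Structure, params: ModelParameters,
                  cfg: RBFConfig = RBFConfig(),
                  n_interactions: Optional[int] = None) -> float:
    """Score one structure (convenience wrapper over the batched path)."""
    if n_interactions is not None and n_interactions != params.n_interactions:
        raise ValueError(
            f"parameters were built for {params.n_interactions} interactions"
        )
    Z, D, mask = batch_structures([structure])
    return float(forward_scores_batch(Z, D, mask, params, cfg).data[0])


# ---------------------------------------------------------------------------
# Checkpoint I/O: npz archive of named arrays + JSON metadata block
# ---------------------------------------------------------------------------

def _named_arrays(params: ModelParameters) -> Dict[str, np.ndarray]:
    out = {"embedding": params.embedding.data,
           "pred_u": params.pred_u.data, "pred_w1": params.pred_w1.data,
           "pred_w2": params.pred_w2.data, "readout_w": params.readout_w.data,
           "readout_b": params.readout_b.data,
           "cutoff_raw": params.cutoff_raw.data}
    for t, (w, b) in enumerate(params.atom_wise):
        out[f"atom_wise_{t}_w"], out[f"atom_wise_{t}_b"] = w.data, b.data
    for name, groups in (("filter", params.filter_mlp),
                         ("update", params.update_mlp)):
        for t, (w1, b1, w2, b2) in enumerate(groups):
            out[f"{name}_{t}_w1"], out[f"{name}_{t}_b1"] = w1.data, b1.data
            out[f"{name}_{t}_w2"], out[f"{name}_{t}_b2"] = w2.data, b2.data
    return out


def save_parameters(params: ModelParameters, cfg: RBFConfig,
                    path: Union[str, Path]) -> None:
    """Save a checkpoint: one .npz of named arrays plus a JSON metadata
    entry describing shapes and the RBF grid."""
    path = Path(path)
    meta = {
        "n_features": params.n_features,
        "n_interactions": params.n_interactions,
        "z_max": params.embedding.shape[0] - 1,
        "r_cut": params.r_cut,
        "rbf": {"n_centers": cfg.n_centers,
                "centers": list(cfg.centers),
                "width_coefficient": cfg.width_coefficient},
    }
    np.savez(path, **_named_arrays(params))
    # np.savez writes a zip; append the metadata as a member
    with zipfile.ZipFile(path, "a") as zf:
        zf.writestr("metadata.json", json.dumps(meta))


def load_parameters(path: Union[str, Path]
                    ) -> Tuple[ModelParameters, RBFConfig]:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("metadata.json"))
    arrays = dict(np.load(path))
    T = meta["n_interactions"]
    params = ModelParameters(
        embedding=parameter(arrays["embedding"]),
        atom_wise=[(parameter(arrays[f"atom_wise_{t}_w"]),
                    parameter(arrays[f"atom_wise_{t}_b"])) for t in range(T + 1)],
        filter_mlp=[(parameter(arrays[f"filter_{t}_w1"]),
                     parameter(arrays[f"filter_{t}_b1"]),
                     parameter(arrays[f"filter_{t}_w2"]),
                     parameter(arrays[f"filter_{t}_b2"])) for t in range(T)],
        update_mlp=[(parameter(arrays[f"update_{t}_w1"]),
                     parameter(arrays[f"update_{t}_b1"]),
                     parameter(arrays[f"update_{t}_w2"]),
                     parameter(arrays[f"update_{t}_b2"])) for t in range(T)],
        pred_u=parameter(arrays["pred_u"]),
        pred_w1=parameter(arrays["pred_w1"]),
        pred_w2=parameter(arrays["pred_w2"]),
        readout_w=parameter(arrays["readout_w"]),
        readout_b=parameter(arrays["readout_b"]),
        cutoff_raw=parameter(arrays["cutoff_raw"]),
    )
    cfg = RBFConfig(n_centers=meta["rbf"]["n_centers"],
                    centers=tuple(meta["rbf"]["centers"]),
                    width_coefficient=meta["rbf"]["width_coefficient"])
    return params, cfg
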