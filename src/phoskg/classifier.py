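"""Bilinear kinase-substrate_motif classifier.

Two bilinear layers combine the kinase vector with the substrate and motif
vectors; a third bilinear layer fuses the two, followed by 40- and 50-unit
hidden layers (ReLU + dropout 0.5 after each) and a sigmoid output. Trained
with mean binary cross-entropy. Implemented in NumPy with hand-derived
gradients; a finite-difference check in the test suite guards them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .dataset import ClassificationSample, DatasetBundle
from .kge import EmbeddingTable, _Adam

_EPS = 1e-7


def bilinear(u: np.ndarray, v: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """out_j = u^T W[:, :, j] v + b_j; accepts single vectors or batches."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    single = u.ndim == 1
    U = np.atleast_2d(u)
    V = np.atleast_2d(v)
    if W.ndim != 3 or U.shape[1] != W.shape[0] or V.shape[1] != W.shape[1] or b.shape[0] != W.shape[2]:
        raise ValueError(
            f"shape mismatch: u {U.shape}, v {V.shape}, W {W.shape}, b {b.shape}"
        )
    d_u, d_v, d_b = W.shape
    # (B, d_u) @ (d_u, d_v*d_b) -> (B, d_v, d_b), contracted against V: BLAS
    # routes this far faster than a generic einsum
    T = (U @ W.reshape(d_u, d_v * d_b)).reshape(-1, d_v, d_b)
    out = (T * V[:, :, None]).sum(axis=1) + b
    return out[0] if single else out


def _bilinear_backward(U, V, W, G):
    """Gradients of sum(G * bilinear(U, V, W, b)) wrt W, b, U, V."""
    B = U.shape[0]
    d_u, d_v, d_b = W.shape
    # dW[i,l,j] = sum_b U[b,i] V[b,l] G[b,j]
    UV = (U[:, :, None] * V[:, None, :]).reshape(B, d_u * d_v)
    dW = (UV.T @ G).reshape(d_u, d_v, d_b)
    db = G.sum(axis=0)
    # dU[b,i] = sum_{l,j} W[i,l,j] V[b,l] G[b,j]
    T_v = (V @ np.ascontiguousarray(np.swapaxes(W, 0, 1)).reshape(d_v, d_u * d_b)).reshape(
        B, d_u, d_b
    )
    dU = (T_v * G[:, None, :]).sum(axis=2)
    # dV[b,l] = sum_{i,j} W[i,l,j] U[b,i] G[b,j]
    T_u = (U @ W.reshape(d_u, d_v * d_b)).reshape(B, d_v, d_b)
    dV = (T_u * G[:, None, :]).sum(axis=2)
    return dW, db, dU, dV


@dataclass
class ClassifierParams:
    W_ks: np.ndarray
    b_ks: np.ndarray
    W_km: np.ndarray
    b_km: np.ndarray
    W_ksm: np.ndarray
    b_ksm: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        d, db = self.d, self.d_b
        expected = {
            "W_ks": (d, d, db),
            "W_km": (d, d, db),
            "W_ksm": (db, db, db),
            "b_ks": (db,),
            "b_km": (db,),
            "b_ksm": (db,),
        }
        for name, shape in expected.items():
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, expected {shape}")
        if self.W1.shape[0] != db or self.W2.shape[0] != self.W1.shape[1] or self.W3.shape[0] != self.W2.shape[1]:
            raise ValueError("hidden-layer shapes are not chained consistently")
        if not 0 <= self.dropout_p < 1:
            raise ValueError(f"dropout_p must be in [0, 1), got {self.dropout_p}")

    @property
    def d(self) -> int:
        return int(self.W_ks.shape[0])

    @property
    def d_b(self) -> int:
        return int(self.W_ks.shape[2])

    # parameter traversal used by the optimizer and the gradient check
    _FIELDS = ("W_ks", "b_ks", "W_km", "b_km", "W_ksm", "b_ksm", "W1", "b1", "W2", "b2", "W3", "b3")

    def arrays(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self._FIELDS}

    def copy(self) -> "ClassifierParams":
        return ClassifierParams(
            **{name: getattr(self, name).copy() for name in self._FIELDS},
            dropout_p=self.dropout_p,
        )

    @classmethod
    def init(
        cls,
        d: int,
        d_b: int | None = None,
        hidden1: int = 40,
        hidden2: int = 50,
        dropout_p: float = 0.5,
        seed: int = 0,
    ) -> "ClassifierParams":
        """Seeded uniform Xavier-style initialization scaled by fan-in."""
        d_b = d if d_b is None else d_b
        rng = np.random.default_rng(seed)

        def u(shape, fan_in):
            bound = np.sqrt(6.0 / fan_in)
            return rng.uniform(-bound, bound, size=shape)

        return cls(
            W_ks=u((d, d, d_b), d * d),
            b_ks=np.zeros(d_b),
            W_km=u((d, d, d_b), d * d),
            b_km=np.zeros(d_b),
            W_ksm=u((d_b, d_b, d_b), d_b * d_b),
            b_ksm=np.zeros(d_b),
            W1=u((d_b, hidden1), d_b),
            b1=np.zeros(hidden1),
            W2=u((hidden1, hidden2), hidden1),
            b2=np.zeros(hidden2),
            W3=u((hidden2, 1), hidden2),
            b3=np.zeros(1),
            dropout_p=dropout_p,
        )

    # -- serialization -----------------------------------------------------
    def save(self, outdir: str | Path, meta: dict | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez(outdir / "params.npz", **self.arrays(), dropout_p=self.dropout_p)
        sidecar = {
            "d": self.d,
            "d_b": self.d_b,
            "hidden": [int(self.W1.shape[1]), int(self.W2.shape[1])],
            "dropout_p": self.dropout_p,
            "shapes": {k: list(v.shape) for k, v in self.arrays().items()},
        }
        sidecar.update(meta or {})
        (outdir / "params.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, outdir: str | Path) -> "ClassifierParams":
        data = np.load(Path(outdir) / "params.npz")
        kwargs = {name: data[name] for name in cls._FIELDS}
        return cls(**kwargs, dropout_p=float(data["dropout_p"]))


@dataclass
class ForwardActivations:
    V_k: np.ndarray
    V_s: np.ndarray
    V_m: np.ndarray
    V_ks: np.ndarray
    V_km: np.ndarray
    V_ksm: np.ndarray
    p: float


def _forward_batch(
    Vk: np.ndarray,
    Vs: np.ndarray,
    Vm: np.ndarray,
    params: ClassifierParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> dict:
    """Full forward pass; returns every intermediate needed for backprop."""
    X1 = bilinear(Vk, Vs, params.W_ks, params.b_ks)
    X2 = bilinear(Vk, Vm, params.W_km, params.b_km)
    X3 = bilinear(X1, X2, params.W_ksm, params.b_ksm)
    pre1 = X3 @ params.W1 + params.b1
    A1 = np.maximum(pre1, 0.0)
    if training and params.dropout_p > 0:
        assert rng is not None, "training-mode dropout needs an RNG"
        keep = 1.0 - params.dropout_p
        mask1 = (rng.random(A1.shape) < keep) / keep
    else:
        mask1 = np.ones_like(A1)
    D1 = A1 * mask1
    pre2 = D1 @ params.W2 + params.b2
    A2 = np.maximum(pre2, 0.0)
    if training and params.dropout_p > 0:
        keep = 1.0 - params.dropout_p
        mask2 = (rng.random(A2.shape) < keep) / keep
    else:
        mask2 = np.ones_like(A2)
    D2 = A2 * mask2
    z = D2 @ params.W3 + params.b3
    p = expit(z)
    return dict(
        Vk=Vk, Vs=Vs, Vm=Vm, X1=X1, X2=X2, X3=X3,
        pre1=pre1, D1=D1, mask1=mask1, pre2=pre2, D2=D2, mask2=mask2,
        z=z, p=p,
    )


def _backward_batch(
    cache: dict,
    y: np.ndarray,
    params: ClassifierParams,
    weights: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Gradients of the (optionally weighted) mean BCE loss wrt parameters."""
    n = len(y)
    p = np.clip(cache["p"], _EPS, 1 - _EPS)
    dz = (p - y.reshape(-1, 1)) / n  # sigmoid+BCE shortcut
    if weights is not None:
        dz = dz * weights.reshape(-1, 1)
    g = {}
    g["W3"] = cache["D2"].T @ dz
    g["b3"] = dz.sum(axis=0)
    dD2 = dz @ params.W3.T
    dA2 = dD2 * cache["mask2"]
    dpre2 = dA2 * (cache["pre2"] > 0)
    g["W2"] = cache["D1"].T @ dpre2
    g["b2"] = dpre2.sum(axis=0)
    dD1 = dpre2 @ params.W2.T
    dA1 = dD1 * cache["mask1"]
    dpre1 = dA1 * (cache["pre1"] > 0)
    g["W1"] = cache["X3"].T @ dpre1
    g["b1"] = dpre1.sum(axis=0)
    dX3 = dpre1 @ params.W1.T
    g["W_ksm"], g["b_ksm"], dX1, dX2 = _bilinear_backward(
        cache["X1"], cache["X2"], params.W_ksm, dX3
    )
    g["W_ks"], g["b_ks"], _, _ = _bilinear_backward(cache["Vk"], cache["Vs"], params.W_ks, dX1)
    g["W_km"], g["b_km"], _, _ = _bilinear_backward(cache["Vk"], cache["Vm"], params.W_km, dX2)
    return g


def forward(
    kinase: str,
    substrate: str,
    motif: str,
    emb: EmbeddingTable,
    params: ClassifierParams,
    training: bool = False,
    seed: int = 0,
) -> ForwardActivations:
    """Single-sample forward pass; dropout is active only when training."""
    vecs = []
    for ident in (kinase, substrate, motif):
        try:
            vecs.append(emb.entity_vector(ident))
        except KeyError:
            raise KeyError(f"no embedding for identifier {ident!r}") from None
    Vk, Vs, Vm = (v[None, :] for v in vecs)
    rng = np.random.default_rng(seed) if training else None
    c = _forward_batch(Vk, Vs, Vm, params, training=training, rng=rng)
    return ForwardActivations(
        V_k=vecs[0], V_s=vecs[1], V_m=vecs[2],
        V_ks=c["X1"][0], V_km=c["X2"][0], V_ksm=c["X3"][0],
        p=float(c["p"][0, 0]),
    )


def bce_loss(predictions: Sequence[float], labels: Sequence[int]) -> float:
    """Mean binary cross-entropy; probabilities clamped to [1e-7, 1 - 1e-7]."""
    p = np.asarray(predictions, float).ravel()
    y = np.asarray(labels, float).ravel()
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} predictions vs {y.shape} labels")
    if len(p) == 0:
        raise ValueError("empty batch")
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class ClassifierTrainConfig:
    d_b: int | None = None  # None -> same as embedding dimension
    hidden1: int = 40
    hidden2: int = 50
    dropout_p: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 512
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.1
    pos_weight: float | None = None
    seed: int = 0


@dataclass
class ClassifierTrainLog:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0
    n_dropped_missing: int = 0


def _sample_matrix(
    samples: Sequence[ClassificationSample], emb: EmbeddingTable, drop_missing: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    Vk, Vs, Vm, y = [], [], [], []
    dropped = 0
    for i, s in enumerate(samples):
        try:
            vk = emb.entity_vector(s.kinase)
            vs = emb.entity_vector(s.substrate)
            vm = emb.entity_vector(s.motif)
        except KeyError as exc:
            if drop_missing:
                dropped += 1
                continue
            raise KeyError(f"sample {i}: {exc}") from None
        Vk.append(vk)
        Vs.append(vs)
        Vm.append(vm)
        y.append(s.label)
    if not y:
        raise ValueError("no samples with complete embeddings")
    return np.array(Vk), np.array(Vs), np.array(Vm), np.array(y, float), dropped


def train_classifier(
    bundle: DatasetBundle,
    emb: EmbeddingTable,
    config: ClassifierTrainConfig | None = None,
) -> tuple[ClassifierParams, ClassifierTrainLog]:
    """Minibatch Adam on mean BCE with a seeded 10% carve-out for early
    stopping; returns the best-validation-loss parameters."""
    config = config or ClassifierTrainConfig()
    if not bundle.train:
        raise ValueError("empty training set")
    Vk, Vs, Vm, y, dropped = _sample_matrix(bundle.train, emb, drop_missing=True)
    log = ClassifierTrainLog(n_dropped_missing=dropped)

    rng = np.random.default_rng(config.seed)
    n = len(y)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n))) if n > 1 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = perm, perm[:0]

    params = ClassifierParams.init(
        d=emb.dim,
        d_b=config.d_b,
        hidden1=config.hidden1,
        hidden2=config.hidden2,
        dropout_p=config.dropout_p,
        seed=config.seed,
    )
    opts = {name: _Adam(arr.shape, config.learning_rate) for name, arr in params.arrays().items()}
    w_pos = config.pos_weight

    best = params.copy()
    best_val = np.inf
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(tr_idx))
        epoch_losses = []
        for start in range(0, len(tr_idx), config.batch_size):
            b = tr_idx[order[start : start + config.batch_size]]
            cache = _forward_batch(Vk[b], Vs[b], Vm[b], params, training=True, rng=rng)
            yb = y[b]
            if w_pos is not None:
                scale = np.where(yb == 1, w_pos, 1.0)
                grads = _backward_batch(cache, yb, params, weights=scale)
                pb = np.clip(cache["p"].ravel(), _EPS, 1 - _EPS)
                loss = float(
                    -np.mean(scale * (yb * np.log(pb) + (1 - yb) * np.log(1 - pb)))
                )
            else:
                grads = _backward_batch(cache, yb, params)
                loss = bce_loss(cache["p"].ravel(), yb)
            epoch_losses.append(loss)
            for name, arr in params.arrays().items():
                arr -= opts[name].step(grads[name])
        log.train_losses.append(float(np.mean(epoch_losses)))

        if len(val_idx):
            vc = _forward_batch(Vk[val_idx], Vs[val_idx], Vm[val_idx], params, training=False)
            val_loss = bce_loss(vc["p"].ravel(), y[val_idx])
        else:
            val_loss = log.train_losses[-1]
        log.val_losses.append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best = params.copy()
            log.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return best, log


def predict(
    params: ClassifierParams,
    emb: EmbeddingTable,
    samples: Sequence[ClassificationSample],
) -> np.ndarray:
    """Inference-mode probabilities, order preserving."""
    if not samples:
        return np.empty(0)
    Vk, Vs, Vm, _, _ = _sample_matrix(samples, emb, drop_missing=False)
    out = []
    for start in range(0, len(Vk), 4096):
        c = _forward_batch(
            Vk[start : start + 4096],
            Vs[start : start + 4096],
            Vm[start : start + 4096],
            params,
            training=False,
        )
        out.append(c["p"].ravel())
    return np.concatenate(out)
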