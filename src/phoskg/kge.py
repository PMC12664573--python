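"""Knowledge-graph embedding: TransE / DistMult / ComplEx scoring, pairwise
hinge training with corruption negatives, and MRR ranking with early stopping.

Everything is NumPy; graphs at desk scale train in seconds. Vectors for
ComplEx store the real half in the first d/2 coordinates and the imaginary
half in the last d/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .kg import KGSplit, KnowledgeGraph, Triple

ALGORITHMS = ("transe", "distmult", "complex")


# ---------------------------------------------------------------------------
# Scoring functions (1-D vectors or batched 2-D arrays; higher = plausible)
# ---------------------------------------------------------------------------

def _check_dims(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> None:
    if not (h.shape[-1] == r.shape[-1] == t.shape[-1]):
        raise ValueError(
            f"dimension mismatch: h={h.shape[-1]}, r={r.shape[-1]}, t={t.shape[-1]}"
        )


def score_transe(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray | float:
    """-||h + r - t||_1 (translation with the L1 norm)."""
    h, r, t = np.asarray(h, float), np.asarray(r, float), np.asarray(t, float)
    _check_dims(h, r, t)
    return -np.abs(h + r - t).sum(axis=-1)


def score_distmult(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray | float:
    """Trilinear product sum_i h_i r_i t_i; symmetric in h and t."""
    h, r, t = np.asarray(h, float), np.asarray(r, float), np.asarray(t, float)
    _check_dims(h, r, t)
    return (h * r * t).sum(axis=-1)


def score_complex(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray | float:
    """Re(sum_i h_i r_i conj(t_i)) over d/2 complex coordinates."""
    h, r, t = np.asarray(h, float), np.asarray(r, float), np.asarray(t, float)
    _check_dims(h, r, t)
    d = h.shape[-1]
    if d % 2:
        raise ValueError(f"ComplEx needs an even raw dimension, got {d}")
    k = d // 2
    hr, hi = h[..., :k], h[..., k:]
    rr, ri = r[..., :k], r[..., k:]
    tr, ti = t[..., :k], t[..., k:]
    return (tr * (hr * rr - hi * ri) + ti * (hr * ri + hi * rr)).sum(axis=-1)


_SCORERS = {"transe": score_transe, "distmult": score_distmult, "complex": score_complex}


def hinge_loss(pos_score: float, neg_score: float, margin: float) -> float:
    """Pairwise hinge: max(0, margin + neg_score - pos_score)."""
    if margin <= 0:
        raise ValueError(f"margin must be positive, got {margin}")
    return float(np.maximum(0.0, margin + np.asarray(neg_score) - np.asarray(pos_score)))


# ---------------------------------------------------------------------------
# Embedding table
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingTable:
    entities: list[str]
    relations: list[str]
    E: np.ndarray  # (n_entities, d)
    R: np.ndarray  # (n_relations, d)
    algorithm: str = "transe"

    def __post_init__(self) -> None:
        if self.E.shape[1] != self.R.shape[1]:
            raise ValueError("entity and relation vectors must share one dimension")
        self._ent_idx = {e: i for i, e in enumerate(self.entities)}
        self._rel_idx = {r: i for i, r in enumerate(self.relations)}

    @property
    def dim(self) -> int:
        return int(self.E.shape[1])

    def entity_vector(self, name: str) -> np.ndarray:
        try:
            return self.E[self._ent_idx[name]]
        except KeyError:
            raise KeyError(f"no embedding for entity {name!r}") from None

    def relation_vector(self, name: str) -> np.ndarray:
        try:
            return self.R[self._rel_idx[name]]
        except KeyError:
            raise KeyError(f"no embedding for relation {name!r}") from None

    def entity_index(self, name: str) -> int:
        try:
            return self._ent_idx[name]
        except KeyError:
            raise KeyError(f"no embedding for entity {name!r}") from None

    @property
    def entity_vectors(self) -> dict[str, np.ndarray]:
        return {e: self.E[i] for e, i in self._ent_idx.items()}

    @property
    def relation_vectors(self) -> dict[str, np.ndarray]:
        return {r: self.R[i] for r, i in self._rel_idx.items()}

    def score(self, triple: Triple) -> float:
        fn = _SCORERS[self.algorithm]
        return float(
            fn(
                self.entity_vector(triple.head),
                self.relation_vector(triple.relation),
                self.entity_vector(triple.tail),
            )
        )

    # -- serialization ------------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        """identifier-plus-floats TSV; a leading kind column disambiguates."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"#algorithm={self.algorithm}\tdim={self.dim}\n")
            for name, row in zip(self.entities, self.E):
                vals = "\t".join(format(v, ".17g") for v in row)
                fh.write(f"entity\t{name}\t{vals}\n")
            for name, row in zip(self.relations, self.R):
                vals = "\t".join(format(v, ".17g") for v in row)
                fh.write(f"relation\t{name}\t{vals}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EmbeddingTable":
        entities, relations, evecs, rvecs = [], [], [], []
        algorithm = "transe"
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line[1:].split("\t"):
                        if tok.startswith("algorithm="):
                            algorithm = tok.split("=", 1)[1]
                    continue
                parts = line.split("\t")
                kind, name, vec = parts[0], parts[1], [float(x) for x in parts[2:]]
                if kind == "entity":
                    entities.append(name)
                    evecs.append(vec)
                elif kind == "relation":
                    relations.append(name)
                    rvecs.append(vec)
                else:
                    raise ValueError(f"unknown row kind {kind!r} in {path}")
        return cls(entities, relations, np.array(evecs), np.array(rvecs), algorithm)

    @classmethod
    def random(
        cls,
        entities: Sequence[str],
        relations: Sequence[str],
        dim: int,
        seed: int,
        algorithm: str = "transe",
    ) -> "EmbeddingTable":
        """Independent standard-normal vectors (the random-embedding control)."""
        rng = np.random.default_rng(seed)
        return cls(
            list(entities),
            list(relations),
            rng.standard_normal((len(entities), dim)),
            rng.standard_normal((len(relations), dim)),
            algorithm,
        )


# ---------------------------------------------------------------------------
# Corruption negatives
# ---------------------------------------------------------------------------

def corrupt(triple: Triple, kg: KnowledgeGraph, n: int = 1, seed: int = 0) -> list[Triple]:
    """n corrupted copies: head or tail (uniform) replaced by a random
    different entity; the relation never changes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    entities = kg.entities
    if len(entities) < 2:
        raise ValueError("need at least 2 entities to corrupt")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        replace_head = rng.integers(0, 2) == 0
        original = triple.head if replace_head else triple.tail
        while True:
            cand = entities[rng.integers(0, len(entities))]
            if cand != original:
                break
        out.append(
            Triple(cand, triple.relation, triple.tail)
            if replace_head
            else Triple(triple.head, triple.relation, cand)
        )
    return out


# ---------------------------------------------------------------------------
# Ranking / MRR
# ---------------------------------------------------------------------------

@dataclass
class RankingResult:
    reciprocal_ranks: list[float]
    mrr: float


def _scores_vs_all(emb_E: np.ndarray, algorithm: str, fixed: np.ndarray, rel: np.ndarray,
                   side: str) -> np.ndarray:
    """Scores of (fixed, rel, e) for all entities e (side='tail') or
    (e, rel, fixed) (side='head')."""
    if algorithm == "transe":
        if side == "tail":
            return -np.abs((fixed + rel)[None, :] - emb_E).sum(axis=1)
        return -np.abs(emb_E + rel[None, :] - fixed[None, :]).sum(axis=1)
    if algorithm == "distmult":
        if side == "tail":
            return emb_E @ (fixed * rel)
        return emb_E @ (rel * fixed)
    if algorithm == "complex":
        d = emb_E.shape[1]
        k = d // 2
        Er, Ei = emb_E[:, :k], emb_E[:, k:]
        rr, ri = rel[:k], rel[k:]
        fr, fi = fixed[:k], fixed[k:]
        if side == "tail":
            # Re(h r conj(t)) with h fixed, t = each entity
            a = fr * rr - fi * ri
            b = fr * ri + fi * rr
            return Er @ a + Ei @ b
        # h = each entity, t fixed
        a = rr * fr + ri * fi
        b = rr * fi - ri * fr
        return Er @ a + Ei @ b
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _realistic_rank(scores: np.ndarray, true_idx: int) -> float:
    s = scores[true_idx]
    better = int(np.sum(scores > s))
    ties = int(np.sum(scores == s))  # includes the true entity
    return better + (ties + 1) / 2.0


def rank_triples(
    validation: Iterable[Triple],
    emb: EmbeddingTable,
    kg: KnowledgeGraph | None = None,
    filtered: bool = False,
) -> RankingResult:
    """Head- and tail-replacement rankings over all embedded entities.

    Reciprocal rank uses the realistic (mean-over-ties) rank. With
    ``filtered=True``, entities forming other known-true triples of ``kg``
    are masked out before ranking.
    """
    known: set[Triple] = set(kg.triples) if (filtered and kg is not None) else set()
    rrs: list[float] = []
    for trip in sorted(validation):
        try:
            h_i = emb.entity_index(trip.head)
            t_i = emb.entity_index(trip.tail)
            r_vec = emb.relation_vector(trip.relation)
        except KeyError as exc:
            raise KeyError(f"validation triple {trip} has an unembedded element: {exc}") from exc
        for side, true_idx, fixed_vec in (
            ("tail", t_i, emb.E[h_i]),
            ("head", h_i, emb.E[t_i]),
        ):
            scores = _scores_vs_all(emb.E, emb.algorithm, fixed_vec, r_vec, side)
            if known:
                for j, ent in enumerate(emb.entities):
                    if j == true_idx:
                        continue
                    cand = (
                        Triple(trip.head, trip.relation, ent)
                        if side == "tail"
                        else Triple(ent, trip.relation, trip.tail)
                    )
                    if cand in known:
                        scores[j] = -np.inf
            rank = _realistic_rank(scores, true_idx)
            rrs.append(1.0 / rank)
    if not rrs:
        raise ValueError("no validation triples to rank")
    return RankingResult(reciprocal_ranks=rrs, mrr=float(np.mean(rrs)))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class KGETrainConfig:
    algorithm: str = "transe"
    dimension: int = 100
    batch_size: int = 25_000
    margin: float = 1.0
    negatives_per_positive: int = 1
    learning_rate: float = 1e-3
    eval_every: int = 20  # epochs between MRR evaluations
    patience: int = 2
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        algo = self.algorithm.lower()
        if algo == "expressive":
            raise ValueError(
                "the ExpressivE algorithm is not implemented here; "
                "choose one of transe, distmult, complex"
            )
        if algo not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        self.algorithm = algo
        if self.dimension < 1 or self.batch_size < 1 or self.negatives_per_positive < 1:
            raise ValueError("dimension, batch_size and negatives_per_positive must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.eval_every < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("eval_every, patience and max_epochs must be positive")
        if self.algorithm == "complex" and self.dimension % 2:
            raise ValueError("ComplEx needs an even dimension")


class _Adam:
    def __init__(self, shape: tuple, lr: float) -> None:
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.lr = lr
        self.t = 0

    def step(self, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.m = b1 * self.m + (1 - b1) * grad
        self.v = b2 * self.v + (1 - b2) * grad * grad
        mhat = self.m / (1 - b1**self.t)
        vhat = self.v / (1 - b2**self.t)
        return self.lr * mhat / (np.sqrt(vhat) + eps)


def _pair_gradients(
    algo: str,
    E: np.ndarray,
    R: np.ndarray,
    h: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
    h2: np.ndarray,
    t2: np.ndarray,
    margin: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Hinge-loss gradients for a batch of (positive, corrupted) pairs.

    (h, r, t) index the positive triples, (h2, r, t2) the corrupted ones.
    Returns (dE, dR, mean_loss).
    """
    fn = _SCORERS[algo]
    sp = fn(E[h], R[r], E[t])
    sn = fn(E[h2], R[r], E[t2])
    active = (margin + sn - sp) > 0
    mean_loss = float(np.mean(np.maximum(0.0, margin + sn - sp)))
    dE = np.zeros_like(E)
    dR = np.zeros_like(R)
    if not np.any(active):
        return dE, dR, mean_loss
    w = active.astype(float) / len(h)  # mean-reduced loss

    def accumulate(hi, ti, sign):
        # sign=-1 for the positive triple (its score is subtracted), +1 for neg
        if algo == "transe":
            g = np.sign(E[hi] + R[r] - E[ti])  # d(-score)/dh
            gh, gt, gr = g, -g, g
        elif algo == "distmult":
            gh = -(R[r] * E[ti])  # d(-score)/dh
            gt = -(E[hi] * R[r])
            gr = -(E[hi] * E[ti])
        else:  # complex
            d = E.shape[1]
            k = d // 2
            hr, hx = E[hi][:, :k], E[hi][:, k:]
            rr, rx = R[r][:, :k], R[r][:, k:]
            tr, tx = E[ti][:, :k], E[ti][:, k:]
            gh = -np.concatenate([rr * tr + rx * tx, -rx * tr + rr * tx], axis=1)
            gt = -np.concatenate([hr * rr - hx * rx, hr * rx + hx * rr], axis=1)
            gr = -np.concatenate([hr * tr + hx * tx, -hx * tr + hr * tx], axis=1)
        c = (sign * w)[:, None]
        np.add.at(dE, hi, c * gh)
        np.add.at(dE, ti, c * gt)
        np.add.at(dR, r, c * gr)

    # loss = margin + sn - sp  =>  d/dθ = dsn/dθ - dsp/dθ, and the g's above
    # are d(-score)/dθ, so positive triples get sign +1 and negatives -1.
    accumulate(h, t, +1.0)
    accumulate(h2, t2, -1.0)
    return dE, dR, mean_loss


@dataclass
class TrainLog:
    epoch_losses: list[float] = field(default_factory=list)
    mrr_trajectory: list[tuple[int, float]] = field(default_factory=list)
    best_mrr: float = 0.0
    best_epoch: int = 0
    stopped_epoch: int = 0


def train_kge(split: KGSplit, config: KGETrainConfig) -> tuple[EmbeddingTable, TrainLog]:
    """Minibatch hinge training with corruption negatives and MRR early stop.

    Stops after ``patience`` consecutive evaluations without improvement and
    returns the embeddings of the best-MRR checkpoint.
    """
    train_triples = sorted(split.train.triples)
    if not train_triples:
        raise ValueError("empty training set")
    val_triples = sorted(split.validation)
    entities = sorted(
        {t.head for t in train_triples}
        | {t.tail for t in train_triples}
        | {t.head for t in val_triples}
        | {t.tail for t in val_triples}
    )
    relations = sorted(
        {t.relation for t in train_triples} | {t.relation for t in val_triples}
    )
    ent_idx = {e: i for i, e in enumerate(entities)}
    rel_idx = {r: i for i, r in enumerate(relations)}
    H = np.array([ent_idx[t.head] for t in train_triples])
    Rl = np.array([rel_idx[t.relation] for t in train_triples])
    T = np.array([ent_idx[t.tail] for t in train_triples])

    rng = np.random.default_rng(config.seed)
    d = config.dimension
    bound = 6.0 / np.sqrt(d)
    E = rng.uniform(-bound, bound, size=(len(entities), d))
    R = rng.uniform(-bound, bound, size=(len(relations), d))
    if config.algorithm == "transe":
        R /= np.maximum(np.linalg.norm(R, axis=1, keepdims=True), 1e-12)
        E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)

    optE = _Adam(E.shape, config.learning_rate)
    optR = _Adam(R.shape, config.learning_rate)
    n = len(train_triples)
    n_ent = len(entities)
    log = TrainLog()
    best_E, best_R = E.copy(), R.copy()
    stale = 0

    def evaluate(epoch: int) -> float:
        emb = EmbeddingTable(entities, relations, E, R, config.algorithm)
        res = rank_triples(val_triples, emb, split.train)
        log.mrr_trajectory.append((epoch, res.mrr))
        return res.mrr

    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            h, r, t = H[idx], Rl[idx], T[idx]
            for _ in range(config.negatives_per_positive):
                side_head = rng.integers(0, 2, size=len(idx)).astype(bool)
                cand = rng.integers(0, n_ent, size=len(idx))
                # avoid re-drawing the original entity
                orig = np.where(side_head, h, t)
                clash = cand == orig
                while np.any(clash):
                    cand[clash] = rng.integers(0, n_ent, size=int(clash.sum()))
                    clash = cand == orig
                h2 = np.where(side_head, cand, h)
                t2 = np.where(side_head, t, cand)
                dE, dR, loss = _pair_gradients(
                    config.algorithm, E, R, h, r, t, h2, t2, config.margin
                )
                E -= optE.step(dE)
                R -= optR.step(dR)
                if config.algorithm == "transe":
                    E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
                losses.append(loss)
        log.epoch_losses.append(float(np.mean(losses)))

        if val_triples and epoch % config.eval_every == 0:
            mrr = evaluate(epoch)
            if mrr > log.best_mrr:
                log.best_mrr = mrr
                log.best_epoch = epoch
                best_E, best_R = E.copy(), R.copy()
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    log.stopped_epoch = epoch
                    break
    else:
        log.stopped_epoch = config.max_epochs

    if not val_triples:
        best_E, best_R = E, R
    return EmbeddingTable(entities, relations, best_E, best_R, config.algorithm), log
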