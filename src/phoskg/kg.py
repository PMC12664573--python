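"""Typed knowledge-graph construction.

Triples are (head, relation, tail) facts over proteins, 9-mer motifs and
annotation entities. This module covers triple ingestion from TSV, the
positional motif-to-triple encoding, the classification-set leakage guard,
and the per-relation train/validation split used for embedding early
stopping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

from .vocab import (
    CENTER_INDEX,
    DEFAULT_RELATIONS,
    MOTIF_LENGTH,
    PAD,
    PHOSPHOACCEPTORS,
    residue_node,
)


class Triple(NamedTuple):
    """One (head, relation, tail) fact."""

    head: str
    relation: str
    tail: str


@dataclass(frozen=True)
class Motif:
    """A 9-character phosphosite window; position 5 is the phosphoacceptor."""

    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != MOTIF_LENGTH:
            raise ValueError(
                f"motif must have length {MOTIF_LENGTH}, got {len(self.sequence)}: "
                f"{self.sequence!r}"
            )

    @property
    def center(self) -> str:
        return self.sequence[CENTER_INDEX]

    def validate_phosphosite(self) -> "Motif":
        if self.center not in PHOSPHOACCEPTORS:
            raise ValueError(
                f"phosphosite motif center must be S, T or Y; found {self.center!r} "
                f"in {self.sequence!r}"
            )
        return self


class KnowledgeGraph:
    """Deduplicated triple store with entity/relation indices.

    Parameters
    ----------
    triples:
        Any iterable of :class:`Triple`; duplicates are collapsed.
    vocabulary:
        Allowed relation names. ``None`` uses the shipped 32-name default;
        passing an explicit set overrides it (unknown relations are always
        rejected against the active vocabulary).
    namespaces:
        Optional entity -> category tag mapping (protein, motif, ...).
    """

    def __init__(
        self,
        triples: Iterable[Triple] = (),
        vocabulary: frozenset[str] | set[str] | None = None,
        namespaces: Mapping[str, str] | None = None,
    ) -> None:
        self.vocabulary = frozenset(vocabulary) if vocabulary is not None else DEFAULT_RELATIONS
        self.namespaces: dict[str, str] = dict(namespaces or {})
        self._triples: set[Triple] = set()
        self.add_triples(triples)

    # -- construction -----------------------------------------------------
    def add_triples(self, triples: Iterable[Triple]) -> int:
        added = 0
        for t in triples:
            t = Triple(*t)
            if not t.head or not t.tail:
                raise ValueError(f"empty head or tail in triple {t}")
            if t.relation not in self.vocabulary:
                raise ValueError(
                    f"unknown relation {t.relation!r}; configure an override vocabulary "
                    "to accept it"
                )
            if t not in self._triples:
                self._triples.add(t)
                added += 1
        return added

    # -- views -------------------------------------------------------------
    @property
    def triples(self) -> frozenset[Triple]:
        return frozenset(self._triples)

    @property
    def entities(self) -> list[str]:
        ents = {t.head for t in self._triples} | {t.tail for t in self._triples}
        return sorted(ents)

    @property
    def relations(self) -> list[str]:
        return sorted({t.relation for t in self._triples})

    def relation_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self._triples:
            counts[t.relation] = counts.get(t.relation, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._triples)

    def __contains__(self, triple: Triple) -> bool:
        return Triple(*triple) in self._triples

    # -- serialization -----------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        """Write sorted 3-column TSV (diffable, round-trip safe)."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for t in sorted(self._triples):
                fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def encode_motif(motif: Motif | str) -> list[Triple]:
    """Encode a 9-mer into its nine positional residue triples.

    Triple *i* is ``(sequence, residue_i, aa_<char_i>)``; pads map to
    ``aa__`` and non-standard residues to ``aa_X``.
    """
    if isinstance(motif, str):
        motif = Motif(motif)
    seq = motif.sequence
    return [Triple(seq, f"residue_{i + 1}", residue_node(seq[i])) for i in range(MOTIF_LENGTH)]


def extract_motif(sequence: str, site: int) -> Motif:
    """Cut the 9-mer window around a 1-based S/T/Y site; pad at termini."""
    if not 1 <= site <= len(sequence):
        raise ValueError(f"site {site} out of range for sequence of length {len(sequence)}")
    center = sequence[site - 1]
    if center.upper() not in PHOSPHOACCEPTORS:
        raise ValueError(f"residue at site {site} is {center!r}, expected S, T or Y")
    start = site - 1 - 4
    chars = []
    for i in range(start, start + MOTIF_LENGTH):
        chars.append(sequence[i] if 0 <= i < len(sequence) else PAD)
    return Motif("".join(chars))


def ingest_triples(
    path: str | Path,
    vocabulary: frozenset[str] | set[str] | None = None,
) -> KnowledgeGraph:
    """Read a 3-column TSV (optional header) into a deduplicated graph."""
    path = Path(path)
    kg = KnowledgeGraph(vocabulary=vocabulary)
    vocab = kg.vocabulary
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines:
        first = lines[0].split("\t")
        # tolerate a header row like "head\trelation\ttail"
        if len(first) == 3 and first[1] not in vocab and first[1].lower() in {
            "relation",
            "rel",
            "predicate",
            "r",
        }:
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
        try:
            kg.add_triples([Triple(parts[0], parts[1], parts[2])])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if len(kg) == 0:
        warnings.warn(f"{path}: no triples ingested", stacklevel=2)
    return kg


def apply_leakage_guard(kg: KnowledgeGraph, positives: Sequence) -> tuple[KnowledgeGraph, int]:
    """Drop every k_specific_motif triple whose (kinase, motif) is a positive.

    ``positives`` is any sequence of objects with ``kinase`` and ``motif``
    attributes (or (kinase, motif) tuples). Returns the filtered graph and
    the number of removed triples.
    """
    pos_pairs = set()
    for p in positives:
        if hasattr(p, "kinase"):
            motif = p.motif.sequence if hasattr(p.motif, "sequence") else p.motif
            pos_pairs.add((p.kinase, motif))
        else:
            k, m = p[0], p[1]
            pos_pairs.add((k, m.sequence if hasattr(m, "sequence") else m))
    kept, removed = [], 0
    for t in kg:
        if t.relation == "k_specific_motif" and (t.head, t.tail) in pos_pairs:
            removed += 1
        else:
            kept.append(t)
    out = KnowledgeGraph(kept, vocabulary=kg.vocabulary, namespaces=kg.namespaces)
    return out, removed


@dataclass
class KGSplit:
    """Train graph + held-out validation triples for MRR early stopping."""

    train: KnowledgeGraph
    validation: frozenset[Triple]
    eval_relations: frozenset[str]
    fraction: float
    seed: int = field(default=0)


def split_kg(
    kg: KnowledgeGraph,
    eval_relations: Iterable[str],
    fraction: float = 0.025,
    seed: int = 0,
) -> KGSplit:
    """Per eval relation, move round(fraction x count) triples to validation.

    A non-empty eval relation always contributes at least one validation
    triple when fraction > 0.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    eval_relations = frozenset(eval_relations)
    present = set(kg.relations)
    missing = eval_relations - present
    if missing:
        raise ValueError(f"eval relations absent from graph: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    validation: set[Triple] = set()
    by_rel: dict[str, list[Triple]] = {r: [] for r in eval_relations}
    for t in kg:
        if t.relation in by_rel:
            by_rel[t.relation].append(t)
    for rel in sorted(by_rel):
        pool = sorted(by_rel[rel])
        n = int(np.floor(fraction * len(pool) + 0.5))  # round half up
        n = max(n, 1)
        n = min(n, len(pool))
        chosen = rng.choice(len(pool), size=n, replace=False)
        validation.update(pool[i] for i in chosen)
    train = KnowledgeGraph(
        (t for t in kg if t not in validation),
        vocabulary=kg.vocabulary,
        namespaces=kg.namespaces,
    )
    return KGSplit(
        train=train,
        validation=frozenset(validation),
        eval_relations=eval_relations,
        fraction=fraction,
        seed=seed,
    )
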