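"""Classification dataset construction.

Positives come from kinase-phosphosite tables; negatives are drawn from two
biologically motivated pools: kinase-substrate pairs with no interaction
evidence (neg-ks) and kinase-motif pairs with experimentally unfavored
specificity (neg-km). Four generation methods plus a fallback yield at most
four negatives per positive, followed by a per-kinase 20% test split that
produces a balanced test set (test1) and a natural-ratio test set (test2).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .kg import Motif, extract_motif


class ClassificationSample(NamedTuple):
    """One <kinase, substrate, motif, label> record."""

    kinase: str
    substrate: str
    motif: str
    label: int


def _motif_str(m) -> str:
    return m.sequence if isinstance(m, Motif) else str(m)


# ---------------------------------------------------------------------------
# Interaction evidence
# ---------------------------------------------------------------------------

class InteractionSet:
    """Undirected protein pairs with per-source confidences (no self-pairs)."""

    def __init__(self) -> None:
        self._pairs: dict[frozenset, list[tuple[str, float]]] = {}

    def add(self, a: str, b: str, source: str = "unknown", confidence: float = 1.0) -> None:
        if a == b:
            raise ValueError(f"self-interaction {a!r} not allowed")
        conf = float(confidence)
        # tolerate the 0-999 STRING score dialect
        if conf > 1.0:
            conf = conf / 1000.0
        if not 0.0 <= conf <= 1.0:
            raise ValueError(f"confidence {confidence} outside [0, 1] after normalization")
        self._pairs.setdefault(frozenset((a, b)), []).append((source.lower(), conf))

    @classmethod
    def from_table(cls, table: pd.DataFrame | str | Path) -> "InteractionSet":
        """Columns: protein_a, protein_b, optional source, optional confidence."""
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t")
        out = cls()
        cols = {c.lower(): c for c in table.columns}
        a_col = cols.get("protein_a", table.columns[0])
        b_col = cols.get("protein_b", table.columns[1])
        for _, row in table.iterrows():
            out.add(
                str(row[a_col]),
                str(row[b_col]),
                str(row[cols["source"]]) if "source" in cols else "unknown",
                float(row[cols["confidence"]]) if "confidence" in cols else 1.0,
            )
        return out

    def evidence_pairs(self, string_threshold: float = 0.75) -> set[frozenset]:
        """Pairs retained as interaction evidence; STRING entries below the
        confidence threshold are discarded, other sources always count."""
        kept = set()
        for pair, records in self._pairs.items():
            for source, conf in records:
                if source == "string" and conf < string_threshold:
                    continue
                kept.add(pair)
                break
        return kept

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self._pairs


# ---------------------------------------------------------------------------
# Specificity tables
# ---------------------------------------------------------------------------

@dataclass
class SpecificityTable:
    """Per-(kinase, motif) specificity: ST kinases carry integer ranks
    (1 = most favored), Y kinases carry percentiles (100 = most favored)."""

    kinase_class: str  # "ST" | "Y"
    values: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kinase_class not in ("ST", "Y"):
            raise ValueError(f"kinase_class must be 'ST' or 'Y', got {self.kinase_class!r}")
        for (k, m), v in self.values.items():
            self._check(v)

    def _check(self, v: float) -> None:
        if self.kinase_class == "ST" and v < 1:
            raise ValueError(f"ST rank must be >= 1, got {v}")
        if self.kinase_class == "Y" and not 0 <= v <= 100:
            raise ValueError(f"Y percentile must be in [0, 100], got {v}")

    def add(self, kinase: str, motif: str, value: float) -> None:
        self._check(value)
        self.values[(kinase, _motif_str(motif))] = float(value)

    @property
    def kinases(self) -> set[str]:
        return {k for k, _ in self.values}

    @classmethod
    def from_table(cls, table: pd.DataFrame | str | Path, kinase_class: str) -> "SpecificityTable":
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t")
        value_col = "rank" if kinase_class == "ST" else "percentile"
        out = cls(kinase_class)
        for _, row in table.iterrows():
            out.add(str(row["kinase"]), str(row["motif"]), float(row[value_col]))
        return out


def build_neg_km(
    st_table: SpecificityTable,
    y_table: SpecificityTable,
    st_rank: float = 150,
    y_percentile: float = 10,
) -> set[tuple[str, str]]:
    """Unfavored kinase-motif pairs: ST rank >= 150 plus Y percentile <= 10
    (both boundaries inclusive)."""
    if st_table.kinase_class != "ST" or y_table.kinase_class != "Y":
        raise ValueError("expected an ST table and a Y table, in that order")
    overlap = st_table.kinases & y_table.kinases
    if overlap:
        raise ValueError(
            f"kinases present in both specificity classes: {sorted(overlap)[:5]}"
        )
    neg = {pair for pair, rank in st_table.values.items() if rank >= st_rank}
    neg |= {pair for pair, pct in y_table.values.items() if pct <= y_percentile}
    return neg


def build_neg_ks(
    kinases: Sequence[str],
    substrates: Sequence[str],
    interactions: InteractionSet,
    string_threshold: float = 0.75,
) -> set[tuple[str, str]]:
    """Kinase-substrate pairs with no interaction evidence in any source."""
    if not kinases or not substrates:
        raise ValueError("kinase and substrate lists must be non-empty")
    if not 0 <= string_threshold <= 1:
        raise ValueError(f"string_threshold must be in [0, 1], got {string_threshold}")
    evidence = interactions.evidence_pairs(string_threshold)
    return {
        (k, s)
        for k in kinases
        for s in substrates
        if k != s and frozenset((k, s)) not in evidence
    }


# ---------------------------------------------------------------------------
# Positives
# ---------------------------------------------------------------------------

def load_positives(
    tables: Iterable[pd.DataFrame | str | Path],
    min_confidence: float = 1.0,
    sequences: Mapping[str, str] | None = None,
) -> list[ClassificationSample]:
    """Load and deduplicate positive kinase-phosphosite rows.

    Each table needs ``kinase``, ``substrate`` and either ``motif`` or
    ``site`` columns; rows with a ``confidence`` value below
    ``min_confidence`` are dropped (rows without one are kept). When only a
    site is given, the 9-mer is derived from ``sequences[substrate]``.
    """
    seen: set[tuple[str, str, str]] = set()
    out: list[ClassificationSample] = []
    missing_seqs: set[str] = set()
    for table in tables:
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t")
        has_conf = "confidence" in table.columns
        for _, row in table.iterrows():
            if has_conf and not pd.isna(row["confidence"]) and float(row["confidence"]) < min_confidence:
                continue
            k, s = str(row["kinase"]), str(row["substrate"])
            if "motif" in table.columns and not pd.isna(row.get("motif")):
                motif = str(row["motif"])
                Motif(motif).validate_phosphosite()
            else:
                site = int(row["site"])
                if sequences is None or s not in sequences:
                    missing_seqs.add(s)
                    continue
                motif = extract_motif(sequences[s], site).sequence
            key = (k, s, motif)
            if key in seen:
                continue
            seen.add(key)
            out.append(ClassificationSample(k, s, motif, 1))
    if missing_seqs:
        raise KeyError(
            "motif derivation needs sequences for substrates: "
            + ", ".join(sorted(missing_seqs)[:10])
        )
    return out


# ---------------------------------------------------------------------------
# Negative generation
# ---------------------------------------------------------------------------

def _sample_rng(global_seed: int, key: tuple[str, ...]) -> np.random.Generator:
    """Stable per-positive RNG: sha256 of the key XOR the global seed.

    Python's built-in hash() is salted per process, so a cryptographic
    digest keeps runs reproducible across processes and input orderings.
    """
    digest = hashlib.sha256("\x1f".join(key).encode()).digest()
    h = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(h ^ (global_seed & 0xFFFFFFFFFFFFFFFF))


def generate_negatives(
    positives: Sequence[ClassificationSample],
    neg_ks: set[tuple[str, str]],
    neg_km: set[tuple[str, str]],
    registry: set[tuple[str, str]],
    seed: int = 0,
    max_attempts: int = 20,
) -> tuple[list[ClassificationSample], int]:
    """Generate up to four negatives per positive via the four methods.

    1. same (s, m), kinase drawn from neg-km partners of m;
    2. same (s, m), kinase drawn from neg-ks partners of s;
    3. same (k, s), motif drawn from neg-km partners of k that are valid
       sites of s;
    4. same (k, m), substrate drawn from neg-ks partners of k that carry m.

    When 3 or 4 has no candidate, the fallback pairs k with a random
    negative motif (on any registry substrate carrying it) or a random
    negative substrate (with any registry motif it carries). Candidates
    colliding with positives or already-emitted negatives are resampled up
    to ``max_attempts`` times. Returns (negatives, n_positives_skipped).
    """
    if not neg_ks and not neg_km:
        raise ValueError("both negative pools are empty")
    registry = {(s, _motif_str(m)) for s, m in registry}
    for p in positives:
        if (p.substrate, p.motif) not in registry:
            raise ValueError(
                f"positive ({p.substrate}, {p.motif}) missing from the substrate-motif registry"
            )

    km_by_motif: dict[str, list[str]] = {}
    km_by_kinase: dict[str, list[str]] = {}
    for k, m in sorted(neg_km):
        km_by_motif.setdefault(m, []).append(k)
        km_by_kinase.setdefault(k, []).append(m)
    ks_by_substrate: dict[str, list[str]] = {}
    ks_by_kinase: dict[str, list[str]] = {}
    for k, s in sorted(neg_ks):
        ks_by_substrate.setdefault(s, []).append(k)
        ks_by_kinase.setdefault(k, []).append(s)
    reg_by_substrate: dict[str, list[str]] = {}
    reg_by_motif: dict[str, list[str]] = {}
    for s, m in sorted(registry):
        reg_by_substrate.setdefault(s, []).append(m)
        reg_by_motif.setdefault(m, []).append(s)

    pos_keys = {(p.kinase, p.substrate, p.motif) for p in positives}
    emitted: set[tuple[str, str, str]] = set()
    negatives: list[ClassificationSample] = []
    skipped = 0

    def try_emit(rng, candidates_fn) -> bool:
        for _ in range(max_attempts):
            cand = candidates_fn(rng)
            if cand is None:
                return False
            if cand in pos_keys or cand in emitted:
                continue
            emitted.add(cand)
            negatives.append(ClassificationSample(*cand, 0))
            return True
        return False

    def pick(rng, items):
        return items[int(rng.integers(0, len(items)))] if items else None

    for p in sorted(positives):
        k, s, m = p.kinase, p.substrate, p.motif
        rng = _sample_rng(seed, (k, s, m))
        produced_any = False

        # (1) replace kinase using neg-km partners of the motif
        def m1(r):
            kp = pick(r, km_by_motif.get(m, []))
            return None if kp is None else (kp, s, m)

        # (2) replace kinase using neg-ks partners of the substrate
        def m2(r):
            kp = pick(r, ks_by_substrate.get(s, []))
            return None if kp is None else (kp, s, m)

        # (3) replace motif: negative motif of k that is a valid site of s
        def m3(r):
            cands = [mp for mp in km_by_kinase.get(k, []) if (s, mp) in registry]
            mp = pick(r, cands)
            return None if mp is None else (k, s, mp)

        # (4) replace substrate: negative substrate of k carrying the motif
        def m4(r):
            cands = [sp for sp in ks_by_kinase.get(k, []) if (sp, m) in registry]
            sp = pick(r, cands)
            return None if sp is None else (k, sp, m)

        # fallbacks: any negative motif / substrate of k, re-anchored in the
        # registry
        def fb3(r):
            mps = km_by_kinase.get(k, [])
            if not mps:
                return None
            mp = pick(r, mps)
            sp = pick(r, reg_by_motif.get(mp, []))
            return None if sp is None else (k, sp, mp)

        def fb4(r):
            sps = ks_by_kinase.get(k, [])
            if not sps:
                return None
            sp = pick(r, sps)
            mp = pick(r, reg_by_substrate.get(sp, []))
            return None if mp is None else (k, sp, mp)

        produced_any |= try_emit(rng, m1)
        produced_any |= try_emit(rng, m2)
        # the fallback fires only when a method has NO candidates at all;
        # collision exhaustion just skips the method for this positive
        has_m3 = any((s, mp) in registry for mp in km_by_kinase.get(k, []))
        produced_any |= try_emit(rng, m3 if has_m3 else fb3)
        has_m4 = any((sp, m) in registry for sp in ks_by_kinase.get(k, []))
        produced_any |= try_emit(rng, m4 if has_m4 else fb4)

        if not produced_any:
            skipped += 1
    return negatives, skipped


# ---------------------------------------------------------------------------
# Per-kinase split
# ---------------------------------------------------------------------------

@dataclass
class DatasetBundle:
    """Train split plus the balanced (test1) and natural-ratio (test2) tests."""

    train: list[ClassificationSample]
    test1: list[ClassificationSample]
    test2: list[ClassificationSample]
    split_seed: int = 0

    def counts(self) -> dict[str, tuple[int, int]]:
        def pn(samples):
            pos = sum(1 for x in samples if x.label == 1)
            return pos, len(samples) - pos

        return {"train": pn(self.train), "test1": pn(self.test1), "test2": pn(self.test2)}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("train", "test1", "test2"):
            write_samples(getattr(self, name), outdir / f"{name}.tsv")


def write_samples(samples: Iterable[ClassificationSample], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("kinase\tsubstrate\tmotif\tlabel\n")
        for s in samples:
            fh.write(f"{s.kinase}\t{s.substrate}\t{s.motif}\t{s.label}\n")


def read_samples(path: str | Path) -> list[ClassificationSample]:
    df = pd.read_csv(path, sep="\t")
    return [
        ClassificationSample(str(r.kinase), str(r.substrate), str(r.motif), int(r.label))
        for r in df.itertuples()
    ]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_per_kinase(
    samples: Sequence[ClassificationSample],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> DatasetBundle:
    """Per kinase and per label, hold out round(test_fraction x count)
    samples. test2 is the full held-out set; test1 keeps all held-out
    positives plus an equal-size uniform draw of held-out negatives."""
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    by_kinase: dict[str, list[ClassificationSample]] = {}
    for s in samples:
        by_kinase.setdefault(s.kinase, []).append(s)

    train: list[ClassificationSample] = []
    test2: list[ClassificationSample] = []
    for kinase in sorted(by_kinase):
        group = sorted(by_kinase[kinase])
        if len(group) < 2:
            warnings.warn(f"kinase {kinase} has a single sample; kept in train", stacklevel=2)
            train.extend(group)
            continue
        for label in (1, 0):
            sub = [x for x in group if x.label == label]
            if not sub:
                continue
            n_test = min(_round_half_up(test_fraction * len(sub)), len(sub))
            chosen = set(rng.choice(len(sub), size=n_test, replace=False)) if n_test else set()
            for i, x in enumerate(sub):
                (test2 if i in chosen else train).append(x)

    held_pos = [x for x in test2 if x.label == 1]
    held_neg = [x for x in test2 if x.label == 0]
    n_bal = min(len(held_pos), len(held_neg))
    pos1 = held_pos if len(held_pos) == n_bal else [
        held_pos[i] for i in sorted(rng.choice(len(held_pos), size=n_bal, replace=False))
    ]
    neg1 = held_neg if len(held_neg) == n_bal else [
        held_neg[i] for i in sorted(rng.choice(len(held_neg), size=n_bal, replace=False))
    ]
    test1 = pos1 + neg1
    return DatasetBundle(train=train, test1=test1, test2=test2, split_seed=seed)
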