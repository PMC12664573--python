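"""Seeded generator of a toy phosphorylation world.

Produces KG triples, positive kinase-site events, interaction evidence,
kinase-motif specificity tables and a substrate-motif registry with planted
structure: kinase families carry position-specific residue preferences
(sharpened by ``family_motif_bias``) and true kinase-substrate pairs share
functional modules with probability ``functional_coupling``. Ground truth
is emitted alongside the inputs so tests can compute oracle labels; the
pipeline itself never reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ClassificationSample
from .kg import Triple, encode_motif
from .vocab import AMINO_ACIDS


@dataclass
class WorldConfig:
    n_kinases: int = 50
    n_substrates: int = 1000
    n_families: int = 8
    n_pathways: int = 12
    n_tissues: int = 6
    motif_alphabet: str = AMINO_ACIDS
    sites_per_substrate: int = 5
    family_motif_bias: float = 0.8
    functional_coupling: float = 0.7
    interaction_noise: float = 0.2
    seed: int = 0
    #: per-kinase cap on emitted specificity rows (ranks stay global)
    max_spec_rows: int = 3000
    #: fraction of Y-class families (the rest are serine/threonine)
    y_family_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_kinases", "n_substrates", "n_families", "n_pathways",
                     "n_tissues", "sites_per_substrate"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("family_motif_bias", "functional_coupling", "y_family_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.interaction_noise < 0:
            raise ValueError("interaction_noise must be >= 0")
        required = set("STY") - set(self.motif_alphabet)
        if required:
            raise ValueError(f"motif_alphabet must contain S, T and Y; missing {required}")


_PRESETS = {
    # small is serine/threonine-only: the Y-class percentile threshold covers
    # ~10% of motifs vs ~76% for the ST rank threshold, and at 20 kinases that
    # coverage gap alone plants a family-level class-ratio signal that would
    # confound the zero-bias control
    "small": dict(n_kinases=20, n_substrates=200, n_families=5, n_pathways=8,
                  n_tissues=4, sites_per_substrate=4, y_family_fraction=0.0),
    "default": dict(n_kinases=50, n_substrates=1000, n_families=8, n_pathways=12,
                    n_tissues=6, sites_per_substrate=5),
    # 430 kinases: the tool's full human-kinase coverage scale
    "stress": dict(n_kinases=430, n_substrates=5000, n_families=40, n_pathways=40,
                   n_tissues=12, sites_per_substrate=5),
}


def preset(name: str, **overrides) -> WorldConfig:
    """Named world sizes: 'small' (CI speed), 'default', 'stress'."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return WorldConfig(**kwargs)


@dataclass
class WorldBundle:
    config: WorldConfig
    kg_triples: list[Triple]
    positives: list[ClassificationSample]
    positives_table: pd.DataFrame  # kinase, substrate, site, motif, confidence
    interactions: pd.DataFrame  # protein_a, protein_b, source, confidence
    st_spec: pd.DataFrame  # kinase, motif, rank
    y_spec: pd.DataFrame  # kinase, motif, percentile
    registry: set = field(default_factory=set)  # (substrate, motif)
    ground_truth: set = field(default_factory=set)  # (kinase, substrate, motif)
    kinases: list[str] = field(default_factory=list)
    substrates: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with (outdir / "triples.tsv").open("w", encoding="utf-8") as fh:
            for t in sorted(set(self.kg_triples)):
                fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")
        self.positives_table.to_csv(outdir / "positives.tsv", sep="\t", index=False)
        self.interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
        self.st_spec.to_csv(outdir / "st_spec.tsv", sep="\t", index=False)
        self.y_spec.to_csv(outdir / "y_spec.tsv", sep="\t", index=False)
        with (outdir / "registry.tsv").open("w", encoding="utf-8") as fh:
            fh.write("substrate\tmotif\n")
            for s, m in sorted(self.registry):
                fh.write(f"{s}\t{m}\n")
        with (outdir / "ground_truth.tsv").open("w", encoding="utf-8") as fh:
            fh.write("kinase\tsubstrate\tmotif\n")
            for k, s, m in sorted(self.ground_truth):
                fh.write(f"{k}\t{s}\t{m}\n")


def _family_profiles(
    rng: np.random.Generator, config: WorldConfig
) -> tuple[list[np.ndarray], list[str]]:
    """Per-family 9 x |alphabet| categorical profiles and family classes."""
    A = list(config.motif_alphabet)
    nA = len(A)
    idx = {c: i for i, c in enumerate(A)}
    n_y = int(round(config.y_family_fraction * config.n_families))
    classes = ["Y"] * n_y + ["ST"] * (config.n_families - n_y)
    rng.shuffle(classes)
    profiles = []
    for f in range(config.n_families):
        prof = np.full((9, nA), 1.0 / nA)
        for pos in range(9):
            if pos == 4:
                center = np.full(nA, 1e-9)
                if classes[f] == "Y":
                    center[idx["Y"]] = 1.0
                else:
                    center[idx["S"]] = 0.7
                    center[idx["T"]] = 0.3
                prof[pos] = center / center.sum()
            else:
                # spread the planted preference over three residues so motif
                # strings stay (near-)unique across sites even at high bias
                preferred = rng.choice(nA, size=3, replace=False)
                sharp = np.zeros(nA)
                sharp[preferred] = (0.5, 0.3, 0.2)
                prof[pos] = (1 - config.family_motif_bias) / nA + config.family_motif_bias * sharp
                prof[pos] /= prof[pos].sum()
        profiles.append(prof)
    return profiles, classes


def simulate_world(config: WorldConfig) -> WorldBundle:
    """Generate the complete toy world; byte-reproducible under the seed."""
    rng = np.random.default_rng(config.seed)
    A = list(config.motif_alphabet)
    nA = len(A)

    kinases = [f"KIN{i:04d}" for i in range(config.n_kinases)]
    substrates = [f"SUB{j:05d}" for j in range(config.n_substrates)]
    families = [f"FAM{f:03d}" for f in range(config.n_families)]
    kin_family = np.array([i % config.n_families for i in range(config.n_kinases)])
    profiles, classes = _family_profiles(rng, config)
    kin_class = [classes[f] for f in kin_family]

    proteins = kinases + substrates
    # round-robin pathway assignment keeps module sizes (and therefore
    # per-kinase positive counts) even, so entity identity alone carries no
    # class-ratio signal into the classification dataset
    kin_perm = rng.permutation(config.n_kinases)
    sub_perm = rng.permutation(config.n_substrates)
    pathway_of = np.empty(len(proteins), dtype=int)
    pathway_of[:config.n_kinases][kin_perm] = np.arange(config.n_kinases) % config.n_pathways
    pathway_of[config.n_kinases:][sub_perm] = np.arange(config.n_substrates) % config.n_pathways
    tissue_of = rng.integers(0, config.n_tissues, size=len(proteins))
    n_comp = max(2, config.n_tissues // 2 + 1)
    comp_of = rng.integers(0, n_comp, size=len(proteins))

    # group kinases by pathway for the coupling draw
    kin_by_pathway: dict[int, list[int]] = {}
    for i in range(config.n_kinases):
        kin_by_pathway.setdefault(int(pathway_of[i]), []).append(i)

    cum = [np.cumsum(profiles[f], axis=1) for f in range(config.n_families)]

    positives_rows = []
    registry: set[tuple[str, str]] = set()
    ground_truth: set[tuple[str, str, str]] = set()
    true_pairs: set[tuple[str, str]] = set()
    site_of: dict[tuple[str, str], int] = {}

    for j, sub in enumerate(substrates):
        sub_pw = int(pathway_of[config.n_kinases + j])
        for site_idx in range(config.sites_per_substrate):
            # pick the true kinase: functionally coupled with given probability
            pool = kin_by_pathway.get(sub_pw, [])
            if pool and rng.random() < config.functional_coupling:
                ki = pool[int(rng.integers(0, len(pool)))]
            else:
                ki = int(rng.integers(0, config.n_kinases))
            f = int(kin_family[ki])
            u = rng.random(9)
            chars = [A[int(np.searchsorted(cum[f][pos], u[pos]))] for pos in range(9)]
            motif = "".join(chars)
            site = 5 + 10 * site_idx
            key = (sub, motif)
            registry.add(key)
            if (kinases[ki], sub, motif) in ground_truth:
                continue
            ground_truth.add((kinases[ki], sub, motif))
            true_pairs.add((kinases[ki], sub))
            site_of.setdefault(key, site)
            positives_rows.append(
                dict(kinase=kinases[ki], substrate=sub, site=site_of[key],
                     motif=motif, confidence=1.0)
            )

    positives_table = pd.DataFrame(positives_rows)
    positives = [
        ClassificationSample(r["kinase"], r["substrate"], r["motif"], 1)
        for r in positives_rows
    ]

    # -- interaction evidence: true pairs plus noise edges -------------------
    sources = ["string", "biogrid", "bioplex"]
    inter_rows = []
    for i, (a, b) in enumerate(sorted(true_pairs)):
        inter_rows.append(
            dict(protein_a=a, protein_b=b, source=sources[i % 3],
                 confidence=round(float(rng.uniform(0.8, 1.0)), 4))
        )
    n_noise = int(config.interaction_noise * len(true_pairs))
    for i in range(n_noise):
        a = proteins[int(rng.integers(0, len(proteins)))]
        b = proteins[int(rng.integers(0, len(proteins)))]
        if a == b:
            continue
        inter_rows.append(
            dict(protein_a=a, protein_b=b, source=sources[i % 3],
                 confidence=round(float(rng.uniform(0.75, 1.0)), 4))
        )
    interactions = pd.DataFrame(inter_rows)

    # -- specificity tables: global ranks under the family profile ----------
    motifs = sorted({m for _, m in registry})
    n_motifs = len(motifs)
    char_idx = {c: i for i, c in enumerate(A)}
    motif_idx = np.array([[char_idx[c] for c in m] for m in motifs])
    pos_idx = np.arange(9)
    fam_loglik = {}
    for f in range(config.n_families):
        logp = np.log(np.maximum(profiles[f], 1e-12))
        ll = logp[pos_idx[None, :], motif_idx].sum(axis=1)
        # random per-family tie-break: at bias 0 all profiles are flat and a
        # stable sort would hand every family the same fake favored/unfavored
        # partition, planting signal where none is configured
        fam_loglik[f] = ll + rng.uniform(0, 1e-9, size=n_motifs)

    st_rows, y_rows = [], []
    for ki, kin in enumerate(kinases):
        f = int(kin_family[ki])
        loglik = fam_loglik[f]
        order = np.argsort(-loglik, kind="stable")
        ranks = np.empty(n_motifs, dtype=int)
        ranks[order] = np.arange(1, n_motifs + 1)
        if n_motifs <= config.max_spec_rows:
            emit = np.arange(n_motifs)
        else:
            top = order[: config.max_spec_rows // 3]
            rest = rng.choice(n_motifs, size=config.max_spec_rows - len(top), replace=False)
            emit = np.unique(np.concatenate([top, rest]))
        if kin_class[ki] == "ST":
            for mi in emit:
                st_rows.append(dict(kinase=kin, motif=motifs[mi], rank=int(ranks[mi])))
        else:
            denom = max(n_motifs - 1, 1)
            for mi in emit:
                pct = 100.0 * (n_motifs - ranks[mi]) / denom
                y_rows.append(dict(kinase=kin, motif=motifs[mi], percentile=round(pct, 4)))
    st_spec = pd.DataFrame(st_rows, columns=["kinase", "motif", "rank"])
    y_spec = pd.DataFrame(y_rows, columns=["kinase", "motif", "percentile"])

    # -- KG triples ----------------------------------------------------------
    triples: list[Triple] = []
    for p_i, prot in enumerate(proteins):
        triples.append(Triple(prot, "participating_pathway", f"PW{pathway_of[p_i]:03d}"))
        triples.append(Triple(prot, "expressed_in", f"TS{tissue_of[p_i]:03d}"))
        triples.append(Triple(prot, "cellular_comp", f"CC{comp_of[p_i]:03d}"))
    for ki, kin in enumerate(kinases):
        fam = families[kin_family[ki]]
        triples.append(Triple(kin, "belongs_to_family", fam))
        triples.append(Triple(kin, "has_domain", f"DOM{kin_family[ki]:03d}"))
    for s, m in sorted(registry):
        triples.append(Triple(s, "has_motif", m))
    for m in motifs:
        triples.extend(encode_motif(m))
    # kinase-favored motifs: top slice of the family ranking
    n_fav = max(10, n_motifs // 50)
    for ki, kin in enumerate(kinases):
        loglik = fam_loglik[int(kin_family[ki])]
        top = np.argsort(-loglik, kind="stable")[:n_fav]
        for mi in top:
            triples.append(Triple(kin, "k_specific_motif", motifs[mi]))

    return WorldBundle(
        config=config,
        kg_triples=triples,
        positives=positives,
        positives_table=positives_table,
        interactions=interactions,
        st_spec=st_spec,
        y_spec=y_spec,
        registry=registry,
        ground_truth=ground_truth,
        kinases=kinases,
        substrates=substrates,
    )
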