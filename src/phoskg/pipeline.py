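"""End-to-end glue: world -> KG -> embeddings -> dataset -> classifier -> reports.

These helpers exist so the CLI, the test suite and the acceptance script all
run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classifier import ClassifierTrainConfig, predict, train_classifier
from .dataset import (
    DatasetBundle,
    InteractionSet,
    SpecificityTable,
    build_neg_km,
    build_neg_ks,
    generate_negatives,
    split_per_kinase,
)
from .evaluation import EvalReport, evaluate_scores, random_embedding_control
from .kg import KGSplit, KnowledgeGraph, apply_leakage_guard, split_kg
from .kge import EmbeddingTable, KGETrainConfig, TrainLog, train_kge
from .synthetic import WorldBundle

#: relations held out for embedding validation: the ones that directly
#: involve kinases, substrates and motifs
DEFAULT_EVAL_RELATIONS = ("k_specific_motif", "has_motif", "belongs_to_family")


def build_kg(world: WorldBundle, guard_positives: bool = True) -> tuple[KnowledgeGraph, int]:
    """Deduplicated graph from world triples, minus leaking kinase-motif links."""
    kg = KnowledgeGraph(world.kg_triples)
    if guard_positives:
        return apply_leakage_guard(kg, world.positives)
    return kg, 0


def build_dataset(
    world: WorldBundle,
    seed: int = 0,
    string_threshold: float = 0.75,
    st_rank: float = 150,
    y_percentile: float = 10,
    test_fraction: float = 0.2,
) -> tuple[DatasetBundle, dict]:
    """Negative pools + four-way generation + per-kinase split."""
    interactions = InteractionSet.from_table(world.interactions)
    st = SpecificityTable.from_table(world.st_spec, "ST") if len(world.st_spec) else SpecificityTable("ST")
    yt = SpecificityTable.from_table(world.y_spec, "Y") if len(world.y_spec) else SpecificityTable("Y")
    neg_km = build_neg_km(st, yt, st_rank=st_rank, y_percentile=y_percentile)
    neg_ks = build_neg_ks(world.kinases, world.substrates, interactions, string_threshold)
    negatives, skipped = generate_negatives(
        world.positives, neg_ks, neg_km, world.registry, seed=seed
    )
    bundle = split_per_kinase(world.positives + negatives, test_fraction, seed=seed)
    stats = {
        "n_positives": len(world.positives),
        "n_negatives": len(negatives),
        "n_skipped_positives": skipped,
        "neg_ks_size": len(neg_ks),
        "neg_km_size": len(neg_km),
    }
    return bundle, stats


@dataclass
class PipelineResult:
    kg_split: KGSplit
    embeddings: EmbeddingTable
    kge_log: TrainLog
    bundle: DatasetBundle
    dataset_stats: dict
    reports: dict[str, EvalReport] = field(default_factory=dict)
    control_reports: dict[str, EvalReport] = field(default_factory=dict)


def run_pipeline(
    world: WorldBundle,
    kge_config: KGETrainConfig | None = None,
    clf_config: ClassifierTrainConfig | None = None,
    seed: int = 0,
    n_bootstrap: int = 200,
    kg_fraction: float = 0.025,
    with_random_control: bool = False,
) -> PipelineResult:
    """Train embeddings on the guarded KG, build the classification dataset,
    train the classifier and evaluate on both test sets."""
    kge_config = kge_config or KGETrainConfig(seed=seed)
    clf_config = clf_config or ClassifierTrainConfig(seed=seed)
    kg, _removed = build_kg(world)
    eval_rels = [r for r in DEFAULT_EVAL_RELATIONS if r in kg.relations]
    split = split_kg(kg, eval_rels, fraction=kg_fraction, seed=seed)
    emb, kge_log = train_kge(split, kge_config)
    bundle, stats = build_dataset(world, seed=seed)
    params, _clf_log = train_classifier(bundle, emb, clf_config)
    reports = {}
    for name in ("test1", "test2"):
        samples = getattr(bundle, name)
        probs = predict(params, emb, samples)
        reports[name] = evaluate_scores(
            probs, [s.label for s in samples], n_bootstrap=n_bootstrap, seed=seed
        )
    result = PipelineResult(
        kg_split=split,
        embeddings=emb,
        kge_log=kge_log,
        bundle=bundle,
        dataset_stats=stats,
        reports=reports,
    )
    if with_random_control:
        result.control_reports = random_embedding_control(
            bundle, dim=emb.dim, config=clf_config, seed=seed, n_bootstrap=n_bootstrap
        )
    return result
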