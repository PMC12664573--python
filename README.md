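# phoskg

Phosphorylation knowledge-graph embeddings and a bilinear
kinase–substrate_motif classifier, with a seeded synthetic-world harness so
the whole pipeline is testable without any database downloads.

The pipeline has five stages:

1. **kg** — a typed knowledge graph over kinases, substrate proteins,
   9-mer phosphosite motifs and their functional context (32-relation
   vocabulary; motifs are linked position-by-position to amino-acid nodes).
   Includes a leakage guard that strips kinase–motif links duplicated in the
   supervised positives, and a per-relation train/validation split.
2. **kge** — TransE / DistMult / ComplEx embeddings trained with pairwise
   hinge loss over corruption negatives, validated by mean reciprocal rank
   (MRR) with patience-based early stopping. Pure NumPy.
3. **dataset** — supervised samples `<kinase, substrate, motif, label>`:
   positives from kinase-phosphosite tables; negatives from two
   biologically motivated pools (non-interacting kinase–substrate pairs and
   experimentally unfavored kinase–motif pairs) combined by four generation
   methods with a fallback, then a per-kinase 20% test split yielding a
   balanced test set (test1) and a natural-ratio test set (test2).
4. **classifier** — three bilinear layers (kinase×substrate, kinase×motif,
   fusion) feeding 40- and 50-unit ReLU layers with dropout 0.5 and a
   sigmoid output, trained with binary cross-entropy. NumPy with
   hand-derived gradients (finite-difference checked in the test suite).
5. **evaluation** — ROC-AUC / PR-AUC with fixed tie handling, 1000-resample
   percentile bootstrap CIs, an "easy test" filter based on similar kinases
   (shared family or domain), and a random-embedding control experiment.

The **synthetic** module generates complete toy worlds (KG triples,
positives, interaction evidence, specificity tables, registry, ground
truth) with planted family-level motif preferences and functional coupling,
fully reproducible under a seed. Presets: `small`, `default`, `stress`
(430 kinases).

## CLI

Every stage is exposed under one entry point:

```bash
phoskg simulate --preset small --seed 1 --out world/
phoskg build-kg --triples world/triples.tsv --out kg/ --seed 1 --fraction 0.025
phoskg train-kge --train kg/train.tsv --validation kg/validation.tsv \
    --algo transe --dim 100 --batch 25000 --lr 1e-3 --margin 1.0 \
    --eval-every 20 --patience 2 --seed 1 --out emb.tsv
phoskg make-dataset --positives world/positives.tsv \
    --interactions world/interactions.tsv --st-spec world/st_spec.tsv \
    --y-spec world/y_spec.tsv --registry world/registry.tsv \
    --string-threshold 0.75 --st-rank 150 --y-percentile 10 \
    --test-fraction 0.2 --seed 1 --out ds/
phoskg train-clf --embeddings emb.tsv --train ds/train.tsv --seed 1 --out model/
phoskg predict --model model/ --embeddings emb.tsv --samples ds/test1.tsv --out preds.tsv
phoskg evaluate --model model/ --embeddings emb.tsv --test ds/test1.tsv \
    --train ds/train.tsv --kg kg/train.tsv --bootstrap 1000 --filter-easy --seed 1
```

All TSV dialects are plain text: 3-column triples, 4-column samples
(kinase, substrate, motif, label), 2-column registry, and interaction /
specificity tables with headers.

## Layout

```
src/phoskg/
  vocab.py       relation vocabulary, amino-acid alphabet
  kg.py          Triple, KnowledgeGraph, motif encode/extract, split, guard
  kge.py         scorers, corruption, MRR ranking, hinge training
  dataset.py     positives, neg-ks / neg-km pools, negative generation, split
  classifier.py  bilinear network, BCE, training loop, predict
  evaluation.py  ROC/PR AUC, bootstrap, easy-test filter, random control
  synthetic.py   world generator and presets
  pipeline.py    end-to-end glue used by CLI, tests and the report
  cli.py         click entry points
```
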