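# ontopop

Semi-supervised population of a fixed ontology skeleton using averaged word
embeddings, together with the structural metrics (granularity, cohesiveness),
success metrics (precision, hop distance), string-similarity baselines
(Jaccard, Hamming, random), and a synthetic-data generator that makes every
component testable fully offline.

## What it does

Given a rooted multi-parent class DAG with ground-truth instance assignments,
a **seeded skeleton** reveals `n_seed` random instances per target class and
holds out the rest as candidates. Each candidate `i` is scored against every
target class `c` as

```
score(c; i) = alpha * sim(i_vec, seed_centroid(c)) + (1 - alpha) * sim(i_vec, class_vec(c))
```

where label vectors are the arithmetic mean of the constituent word vectors
(skip-gram-trained or pre-trained), `sim` is cosine (or negative Euclidean
distance), and the candidate is assigned to the argmax class. Evaluation
reports precision (predicted class is a ground-truth parent) and the shortest
undirected hop distance between predicted and true class, over repeated
randomly seeded skeletons.

## Modules

| module | contents |
|---|---|
| `ontopop.graph` | ontology data model, TSV I/O, depth / paths-to-root / instance counts, skeleton seeding |
| `ontopop.text` | 8-step label & corpus preprocessing (lower-case, synonyms, punctuation, whitespace, numerics, stop-words, short words, lemmatization) |
| `ontopop.embeddings` | numpy skip-gram (negative sampling) trainer, word2vec/GloVe text-format loader, averaged label vectors |
| `ontopop.population` | embedding mapper plus Jaccard / Hamming / random baselines |
| `ontopop.evaluation` | precision, hop distances, granularity, cohesiveness, repeated experiments, structure-precision correlation |
| `ontopop.synthetic` | synthetic DAGs + clustered embeddings (per-class centroid + isotropic noise) |
| `ontopop.cli` | `ontopop` command-line entry point |

## CLI

```bash
# generate a synthetic fixture (edges.tsv, labels.tsv, vectors.txt)
ontopop simulate --out sim/ --classes 100 --sigma 0.3 --seed 1

# preprocess a corpus directory and train embeddings
ontopop preprocess --corpus docs/ --out prep/
ontopop train --tokens prep/corpus_tokens.txt --out emb/ --dim 100 --epochs 100 --seed 1

# seed a skeleton and map all candidates
ontopop populate --edges sim/edges.tsv --labels sim/labels.tsv \
    --vectors sim/vectors.txt --out pop/ --alpha 0.8 --n-seed 2 --seed 1

# compare methods over repeated seeded skeletons
ontopop evaluate --edges sim/edges.tsv --labels sim/labels.tsv \
    --vectors sim/vectors.txt --out eval/ --repeats 10 --seed 1

# structural analytics (depth / paths-to-root / instances-per-class histograms)
ontopop analyze --edges sim/edges.tsv --labels sim/labels.tsv --out stats/
```

Every run writes a `run_meta.json` with the effective configuration and seeds;
reruns with identical inputs and seeds reproduce outputs byte-for-byte.

## File formats

- **Edges TSV** (no header): `child_id<TAB>parent_id<TAB>kind`, kind in
  `{class, instance}`; multi-parent children repeat the line; the root has an
  empty parent field.
- **Labels TSV**: `id<TAB>label` (UTF-8).
- **Vectors**: word2vec text (`vocab dim` header, then `token v1 ... vd`) or
  GloVe text (same rows without a header).
- **Cohesiveness annotations TSV**: `superclass_id<TAB>subclass_id<TAB>{0,1}`.
- **Mapping TSV**: `instance_id`, `predicted_class_id`, `score`,
  `score_siblings`, `score_parent`, `fallback`.
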