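# probkg

Probabilistic knowledge graphs for disease-target prioritization.

`probkg` builds heterogeneous biological knowledge graphs (drugs, proteins,
diseases, side effects) whose edges carry probabilities fused from two
evidence sources: the binary relations observed in curated networks, and the
frequency with which each entity pair co-occurs in a literature corpus.
Observed edges of the literature-weighted relation types (drug–protein,
drug–disease, protein–disease) get probability `sigmoid(count + alpha)`;
the two dense similarity relations (drug structure via Morgan/Dice, protein
sequence via Smith–Waterman/BLOSUM50) carry similarity scores; other observed
edges carry 1 and unobserved pairs 0.

A relation-specific graph-embedding model reconstructs the weighted graph:
per-relation neighborhood aggregation, a shared ReLU projection to
row-normalized node embeddings, and bilinear per-relation decoders (tied for
symmetric relations). Training minimizes the evidence-weighted squared
reconstruction error over all relations, with observed literature edges
weighted by `sigmoid(count + beta)` so well-supported edges count more.
Reconstructed protein–disease scores are the target predictions. Four control
variants (`og`, `rp`, `rw`, `rpw`) nullify the literature evidence for
ablation studies.

Evaluation includes entry-wise stratified and cluster-wise (average-linkage
on 1−Jaccard disease profiles) 5-fold cross-validation with anti-leakage
masking of held-out entries, AUROC/AUPR, exposure-bias diagnostics
(performance on low-degree targets/diseases, max-score-vs-degree Spearman),
and literature-support analyses of novel predictions (μ+2σ row selection,
top-k co-occurrence counts and correlations).

The model is implemented in numpy with analytic gradients (full-batch Adam);
no deep-learning framework is required. A synthetic-data module generates
desk-scale graphs with planted low-rank structure, two-rate Poisson
co-occurrence counts, and toy corpora, so everything is testable offline.

## Command line

```sh
# generate a synthetic graph, train, predict, evaluate
probkg simulate --seed 1 --out-dir runs/sim
probkg train    --kg-dir runs/sim --seed 1 --out-dir runs/train
probkg predict  --kg-dir runs/sim --params runs/train/params_full.npz --out-dir runs/pred
probkg evaluate --kg-dir runs/sim --scores runs/pred/tda_scores.tsv --out-dir runs/eval

# ablation across variants on one synthetic graph
probkg ablate --seed 1 --variants full,og,rp,rw,rpw --out-dir runs/ablate

# real data: edge lists + relation manifest -> graph; corpus -> counts
probkg build-kg --relation-manifest relations.yaml --catalog catalog.tsv --out-dir runs/kg
probkg count-lit --kg-dir runs/kg --corpus corpus.txt --relation protein_disease --out-dir runs/lit
probkg similarity --fasta proteins.fasta --fingerprints drugs.tsv --out-dir runs/simnet
```

Every command writes a run manifest (config hash, seed, version) beside its
outputs; stochastic commands require an explicit `--seed`. A YAML config with
per-command sections can be passed with `--config`; flags override file
values.

Input formats: edge lists are TSV `source<TAB>target[<TAB>value]` (the value
column, in [0, 1], is required for similarity relations); catalogs are TSV
`type<TAB>id`; corpora are one document per line (or a directory of `.txt`
files); synonym dictionaries are TSV `type<TAB>id<TAB>synonym`.

## Layout

- `src/probkg/graph.py` — entity catalogs, relation specs, probabilistic
  adjacencies, evidence fusion, anti-leakage masking, TSV serialization
- `src/probkg/literature.py` — trie/failure-link multi-pattern matcher and
  document-level co-occurrence counting
- `src/probkg/similarity.py` — Smith–Waterman protein similarity (normalized)
  and Dice/Morgan drug similarity
- `src/probkg/model.py` — the embedding model, training loop, prediction,
  randomized controls
- `src/probkg/evaluation.py` — split construction, metrics, exposure-bias
  and literature-support diagnostics
- `src/probkg/synthetic.py` — planted-structure generators and the recovery
  experiment
- `src/probkg/cli.py` — the `probkg` command
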