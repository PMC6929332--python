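# birwalk

Drug repositioning by **individual-length bi-random walks with restart** on a
drug–disease heterogeneous network.

The pipeline has four parts:

1. **Composite similarity** (`birwalk.similarity`) — cosine similarity of
   binary feature vectors (chemical fingerprints for drugs, symptoms for
   diseases), a data-driven logistic shrink of non-informative similarities,
   a cohesiveness boost for pairs co-occurring in clusters of the
   association-sharing graph, and an average with a Gaussian kernel on
   association profiles. Every stage can be toggled independently.
2. **Walk-length quantification** (`birwalk.walk_length`) — a bipartite
   Jaccard index between each drug's disease set and each disease's two-hop
   disease set; per-node walk budgets are its row/column sums. The raw index
   doubles as the standalone "JI" baseline ranker.
3. **Bi-random walks** (`birwalk.birw`) — Laplacian-normalized similarities
   drive two independent restart walks (drug side and disease side); each
   node stops propagating once the iteration index exceeds its floored walk
   budget; the two score matrices are averaged once at the end. A fixed-length
   mode supports ablation grids.
4. **Evaluation & diagnostics** (`birwalk.evaluation`, `birwalk.diagnostics`)
   — leak-free k-fold cross-validation with six ranking/threshold metrics,
   plus shortest-path analyses relating walk budgets to network distances.

`birwalk.synthetic` generates seeded planted-block fixtures (block-structured
features and associations) so everything is testable offline; `birwalk.net_core`
holds the domain types and TSV readers/writers.

## CLI

All commands are subcommands of `birwalk` (or `python -m birwalk.cli`), write
a `manifest.json` recording the resolved configuration, seed, input digests
and timings, and are byte-deterministic given a seed.

```sh
birwalk --show-config                        # print all configuration defaults
birwalk simulate --out-dir data --seed 7     # planted synthetic fixture
birwalk similarity --drug-features data/drug_features.tsv \
    --disease-features data/disease_features.tsv \
    --associations data/associations.tsv --out-dir sim
birwalk walklen --associations data/associations.tsv --out-dir wl
birwalk predict --drug-features data/drug_features.tsv \
    --disease-features data/disease_features.tsv \
    --associations data/associations.tsv --out-dir pred --top-k 10
birwalk predict ... --mode fixed --lr 2 --ld 2    # fixed-length ablation
birwalk evaluate ... --k 10 --seed 1              # 10-fold cross-validation
birwalk diagnose ... --out-dir diag               # walk-length/shortest-path report
```

Configuration can also come from a flat `key=value` file via `--config`
(flags override the file): `alpha`, `mode`, `fixed_lr`, `fixed_ld`, `seed`,
`steps.{2,3,4}.enabled`, `logistic.d`, `shuffles`, `clusterone.penalty`,
`clusterone.min_size`, `clusterone.overlap`, `gip.gamma_tilde`.

### File formats

* feature tables — TSV with a header row, first column `id`, binary cells;
* association lists — headerless two-column TSV of `drug_id<TAB>disease_id`;
* predictions — TSV of `rank, drug, disease, score` over not-yet-known pairs,
  scores at six significant digits, ties broken lexicographically.

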