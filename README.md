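# relgraph

Toolkit for inferring weighted relationship graphs between two controlled
vocabularies (e.g. foods and health conditions) from a document corpus by
cross-space co-occurrence counting, and for exploring them interactively:

- **corpus** — term spaces, presence-based phrase matching, corpus I/O, and a
  synthetic corpus generator that plants exact per-pair co-occurrence counts.
- **graph_inference** — document co-occurrence counting, threshold filtering
  (strictly greater than `min_weight`), graph metrics, top-k ranking, and TSV
  edge-table / GraphML I/O.  Small published edge-table fixtures ship under
  `src/relgraph/data/`.
- **exploration** — query-centered graph-of-interest (GOI) extraction,
  personalization by graph intersection with a user-profile graph, and the
  edge-based overlap percentage.
- **multiscale** — supernode coarsening (category / community / singleton
  policies), seed-deterministic force-directed layout with a minimum
  touch-target separation, screen-budget view filtering, edge color mixing,
  and an exact-round-trip XML stream (schema in `data/goi.xsd`).
- **lsa_baseline** — truncated-SVD latent semantic analysis edge weighting
  plus a coefficient-of-variation dispersion statistic for comparing how
  spread-out two edge weightings are.
- **cli** — `relgraph` command-line front end tying it all together.

## CLI

All subcommands write a JSON run manifest (inputs, parameters, output
hashes) next to their primary output.

```sh
# plant a synthetic corpus (pairs.tsv: term_a <TAB> term_b <TAB> count)
relgraph simulate --space-a foods.txt --space-b diseases.txt \
    --pairs pairs.tsv --noise 40 --seed 7 --out corpus.jsonl

# infer the relationship graph (keep edges with weight > 50)
relgraph infer --space-a foods.txt --space-b diseases.txt \
    --corpus corpus.jsonl --min-weight 50 --out graph.graphml

relgraph metrics --graph graph.graphml
relgraph goi --graph graph.graphml --query stroke --radius 1 --out goi.graphml
relgraph personalize --goi goi.graphml --center stroke \
    --profile profile.graphml --out personalized.graphml
relgraph abstract --graph graph.graphml --policy category --out g2.graphml
relgraph view --graph goi.graphml --center stroke \
    --width 1080 --height 1920 --touch 96 --out view.graphml
relgraph export --graph view.graphml --format xml --seed 7 \
    --centre stroke --out stream.xml
relgraph lsa --space-a foods.txt --space-b diseases.txt \
    --corpus corpus.jsonl --dim 10 --out lsa.tsv
```

## Conventions

- Tokenization case-folds and splits on non-alphanumerics; a multi-word term
  matches as a contiguous token subsequence; matching is presence-based
  (one count per document).
- Edge weights are integer document counts; the normalized probability
  (weight / corpus size) rides along.  The LSA baseline reuses the weight
  slot with cosine similarities in [0, 1].
- Top-k ties break lexicographically by (condition term, food term).
- Screen budget is `floor(width/touch) * floor(height/touch)` nodes;
  layouts are seeded (default seed 7) and positions live in the unit square.
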