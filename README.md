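# pagkit

Offline toolkit for integrative gene-set interpretation of differential-
expression results:

* **Candidate selection** — volcano-plot thresholds (p-value and absolute
  log2 fold change, inclusive boundaries) with named disease-study presets.
* **Over-representation analysis** — hypergeometric upper-tail enrichment of
  a candidate list against a GMT gene-set collection, with a rank-aware
  p-value adjustment `min(1, p0 · (m + n_le − 1))` applied over the tests
  surviving the overlap/similarity pre-filters, and a combined
  overlap-coefficient/Jaccard similarity score.
* **Cross-tool term consensus** — optimal string alignment (restricted
  Damerau–Levenshtein) similarity between normalized enrichment terms,
  row-wise best matching, and Venn-region counts from the connected
  components of the cross-tool match graph.
* **Co-membership networks** — pairwise hypergeometric edges (BH-adjusted)
  weighted by Jaccard, Louvain community detection (seeded, deterministic),
  and per-community bag-of-words keyword frequencies.
* **Literature co-citation scoring** — a log-space hypergeometric
  co-citation score (−ln of the upper tail) and odds ratio computed from a
  local citation-count table, plus precision at configurable cutoffs.
* **Validation framework** — ground-truth labeling from a reference
  method's adjusted p-values and input overlap, ROC/AUC over ranked
  pathways (tie-aware, equal to the normalized Mann–Whitney U), and the
  top-n% vs bottom-(100−n)% t-test curve over co-citation scores.
* **Synthetic fixtures** — a seeded generator planting known enriched gene
  sets, consensus term regions, citation-count boosts and a two-normal
  truth model with closed-form expected AUC, written to plain-text formats
  with a JSON truth manifest.

## Test

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) and brute-force oracles
(exact rational hypergeometric tails, a memoized transcription of the OSA
recursion, exhaustive modularity maximization, AUC pair counting);
`tests/test_acceptance.py` holds the acceptance criteria.

## CLI

All stages are exposed under a single entry point:

```sh
pagkit simulate --seed 1 --outdir fixtures/
pagkit select   --de-table fixtures/de_table.tsv --out candidates.txt
pagkit enrich   --candidates candidates.txt --gmt fixtures/collection.gmt \
                --out results.tsv
pagkit match    --terms fixtures/terms_toolA.tsv --terms fixtures/terms_toolB.tsv \
                --terms fixtures/terms_toolC.tsv --cutoff 0.8 \
                --out pairs.tsv --venn venn.tsv
pagkit network  --gmt fixtures/collection.gmt --seed 42 --out net.graphml \
                --clusters clusters.tsv --words words.tsv
pagkit litscore --citations fixtures/citations.tsv --N 1000000 --K 50000 \
                --out scores.tsv
pagkit validate --labels fixtures/truth.tsv --results fixtures/tool_scores.tsv \
                --out validation.tsv --roc roc_points.tsv
```

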