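# scadvisor

An LLM-backed workflow advisor for single-cell RNA-seq analysis. For each
stage of a standard scRNA-seq workflow (quality filtering, normalization,
dimensionality reduction, neighbor-graph construction, clustering,
annotation, enrichment), `scadvisor` computes the relevant data metrics
from your count matrix, populates a per-task prompt template with them,
submits the augmented prompt to an LLM backend, and parses the response
into a structured, auditable recommendation.

Key properties:

- **Ten advisor tasks**: `analyze_quality`, `recommend_normalization`,
  `analyze_variable_features`, `recommend_pcs`, `analyze_pcs`,
  `recommend_k`, `recommend_res`, `analyze_and_annotate`,
  `analyze_enrichment`, `summary_network`.
- **Pluggable backends**: Google, OpenAI, or a local Ollama server — plus
  a deterministic **replay** backend that serves canned responses from a
  JSON fixture store, so everything runs offline and reproducibly.
- **Native enrichment**: over-representation analysis (exact
  hypergeometric tail + Benjamini–Hochberg) against user-supplied GMT
  gene sets; significant rows feed the enrichment prompt, and a second
  LLM round extracts a typed pathway/regulator/gene network rendered as
  self-contained interactive HTML.
- **Evaluation statistics**: groundedness (`G = |GT ∩ RESP| / |RESP|`
  over normalized term sets) and chunked-embedding cosine similarity
  with a deterministic bag-of-words embedder (a transformer embedder can
  be plugged in).
- **Synthetic data**: seeded negative-binomial count matrices with
  planted population markers, rank-sum marker tables, and default replay
  fixtures for all ten tasks.

## Test

```bash
python -m pytest tests/
```

The suite is fully offline: every LLM call goes through the replay
backend. `tests/test_acceptance.py` holds the acceptance criteria
(parser worked examples, groundedness/ORA/metric oracles, end-to-end
determinism).

## CLI

```bash
# make a synthetic dataset (MTX triplet + labels.tsv)
scadvisor synth make --cells 500 --genes 1000 --pops 3 --seed 1 --out data/

# ask for a clustering-resolution recommendation, offline
scadvisor res --input data/ --server replay --fixtures default --out runs/

# quality cutoffs against a live server (key file: first line is the key)
scadvisor quality --input data/ --server google --api-key-file ~/.keys/google

# annotation from a marker table, written back onto the dataset
scadvisor annotate --input data/ --markers markers.tsv --apply --out runs/

# native ORA + LLM summary, then the second-round network extraction
scadvisor enrich --input data/ --genes query.txt --gene-sets sets.gmt --out runs/
scadvisor network --summary runs/analyze_enrichment.json --out runs/

# evaluation
scadvisor evaluate groundedness --run-dir runs/ --response report.txt
scadvisor evaluate similarity --doc-a summary.txt --doc-b input_terms.txt
```

Every task run writes a `RecommendationRecord` JSON (prompt, raw
response, parsed payload, provenance) into the output directory. Exit
codes: 0 success, 2 user/configuration error, 1 internal error.

Prompt templates live in `src/scadvisor/templates/` (one editable text
file per task); `--template-dir` points at user overrides.

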