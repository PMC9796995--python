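# fluencylab

Strategy analysis for timed letter-fluency transcripts (e.g., "name as
many words starting with *f* as you can in 60 seconds"). Each
participant's ordered word list is scored on two axes:

* **Phonological strategy** — Troyer-style clustering and switching.
  Consecutive words cluster when related by any of four pronunciation
  rules (shared first two phonemes, rhyme, single-vowel difference,
  homonymy), scored against a CMU Pronouncing Dictionary lexicon. A
  k-word cluster has size k − 1 (singletons are size-0 clusters), giving
  the mean cluster size (MCS) and the number of switches (NoS).
* **Semantic strategy** — a semantic-relatedness index (SR). The angles
  between consecutive word-embedding vectors form a discrete chain; the
  persistence length Lp of that chain measures how long a semantic
  "direction" persists, and SR = exp(−1/Lp) (the mean adjacent cosine,
  floored at 0) is its bounded summary.

Cohort-level statistics (exclusion rules, descriptive table, Pearson
correlation matrix with significance stars, stepwise multiple regression
with tolerance/VIF diagnostics) and a synthetic-cohort generator with
known ground truth complete the pipeline.

## Layout

| module | contents |
| --- | --- |
| `fluencylab.sessions` | transcript reading (plain lists, minimal CHAT dialect), normalization, error/repetition flags, correct-word count |
| `fluencylab.phonological` | CMUdict lexicon, pair relations, cluster spans, MCS/NoS |
| `fluencylab.semantic` | embedding tables, turning angles, chain layout, Lp estimators, SR |
| `fluencylab.cohort` | exclusions, descriptives, Pearson matrix, stepwise regression |
| `fluencylab.synth` | synthetic lexicons/participants/cohorts with planted cluster structure and worm-like-chain angle truth |
| `fluencylab.pipeline` | end-to-end run with provenance (config hash in every artifact) |
| `fluencylab.cli` | `fluencylab score / cohort / simulate / plot` |

Bundled plain-text data (`src/fluencylab/data/`): a CMUdict excerpt for
letter-f words and pretrained 300-d vectors for the same words extracted
from spaCy `en_core_web_lg` 3.8.0, so the worked examples run offline.

## CLI

```bash
# generate a synthetic cohort (pipeline-readable plain-text formats)
fluencylab simulate --preset phonological --seed 1 --n 47 --out sim/

# full cohort pipeline from a JSON config
cat > config.json <<EOF
{"transcripts_dir": "sim/transcripts", "lexicon_path": "sim/lexicon.txt",
 "embeddings_path": "sim/embeddings.txt",
 "demographics_path": "sim/demographics.csv", "output_dir": "out"}
EOF
fluencylab cohort --config config.json

# score one transcript
fluencylab score --transcript sim/transcripts/synth000.txt \
    --lexicon sim/lexicon.txt --embeddings sim/embeddings.txt

# chain-diagram plots, ordered by ascending SR
fluencylab plot --transcripts sim/transcripts --embeddings sim/embeddings.txt \
    --indices out/indices.csv --out plots/
```

Pipeline outputs: `indices.csv` (per-participant NoCW/MCS/NoS/SR),
`exclusions.csv`, `descriptives.csv`, `correlations.csv`,
`regression.json` / `regression.txt`, and the verbatim `config.json`.
Every artifact carries the hash of the configuration that produced it
(CSV files start with a `# config_hash:` comment line; read them with
`pandas.read_csv(..., comment="#")`).

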