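# chemquiz

Algorithmic generation and scoring of short-answer organic-chemistry
benchmark questions with machine-verifiable ground truths.

Benchmarks built from static question banks leak into training corpora and
multiple-choice formats reward elimination over reasoning. `chemquiz`
instead *generates* every question from a seed — so fresh, unseen question
sets can be produced at will — and grades free-text answers with
structure-aware equivalence rules, so any correct representation of the
answer is accepted. It is aimed at people evaluating language models (or
students, or their own code) on molecular comprehension and chemical
reasoning.

## Question categories

Eight task families, 816 questions in the default build:

| family | categories | ground truth |
|---|---|---|
| counting | `carbon_count`, `ring_count` | integer (element tally; cycle rank *b* − *a* + *c*) |
| shortest path | `shortest_path` | bonds between two wildcard-marked positions (BFS) |
| atom mapping | `atom_map` | position bijection between two SMILES spellings of one molecule |
| naming | `iupac_zinc`, `iupac_fg`, `iupac_locant` | the structure itself — any name that parses back to it is correct |
| additive SAR | `free_wilson` | score of an unseen R-group combination under a Free-Wilson model *y* = Σ<sub>p</sub> *v*[p, R<sub>p</sub>] |
| reactions | `reaction` | canonical product SMILES from nine reaction-class rewrites |
| NMR | `nmr_1d`, `nmr_2d` | structure consistent with simulated ¹H/¹³C (and COSY/HSQC/HMBC) peak lists |

Scoring statistics follow the usual conventions for paired benchmark
comparisons: per-category accuracies with Wald 95% intervals
(p̂ ± 1.96·√(p̂(1−p̂)/n)) and exact one-tailed McNemar tests on discordant
counts, P(X ≥ max(b,c)), X ~ Binomial(b+c, ½).

## Worked example

```python
from chemquiz import BenchmarkConfig, build_benchmark, score_benchmark
from chemquiz.scoring import truth_as_response, render_report

records = build_benchmark(BenchmarkConfig(master_seed=1))   # 816 questions
print(next(r for r in records if r.category == "nmr_1d").prompt)
```

```
The following NMR data were recorded for an unknown compound (shifts in ppm, d denotes delta):
Molecular formula: C7H17N
1H NMR: d 2.85 (t, 2H); d 2.50 (s, 6H); d 1.35 (m, 2H); d 1.30 (m, 2H); d 1.25 (m, 2H); d 0.90 (t, 3H)
13C NMR: d 47.0; d 36.0; d 28.0; d 27.5; d 27.0; d 16.0
Determine the structure and write it as a SMILES string.
Give your final answer on the last line in the form "Answer: <answer>".
```

The stored truth is `CCCCCN(C)C` (N,N-dimethylpentan-1-amine); any SMILES
for the same graph scores as correct. Feeding every stored truth back as a
response checks the scorer's self-consistency:

```python
responses = {r.id: truth_as_response(r) for r in records}
print(render_report(score_benchmark(records, responses, "strict")))
```

```
category             n     k     acc            95% CI
atom_map            72    72   1.000   [1.000, 1.000]
carbon_count        60    60   1.000   [1.000, 1.000]
...
overall            816   816   1.000   [1.000, 1.000]
```

A 1.000 overall accuracy here means every one of the 816 stored truths is
accepted by the scorer that will judge external answers — the benchmark is
internally consistent, nothing more.

## Command line

```bash
chemquiz generate --config cfg.yaml --out bench.jsonl   # + bench.manifest.json
chemquiz score --bench bench.jsonl --responses resp.jsonl --mode lenient --out report/
chemquiz compare --bench bench.jsonl --a resp1.jsonl --b resp2.jsonl
```

Responses are JSONL rows `{"id": ..., "response": ...}`. Identical
configuration produces byte-identical benchmark files.

## Acceptance script

`scripts/acceptance.py` rebuilds the full default benchmark from a master
seed, re-scores the stored ground truths in strict mode, and writes its
result object to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/chemquiz/core.py` — molecule substrate, SMILES variants, libraries
- `src/chemquiz/structure.py` — counting / path / mapping generators
- `src/chemquiz/naming.py`, `nameparse.py` — naming questions and the name parser backends
- `src/chemquiz/freewilson.py` — additive SAR instances and exact solver
- `src/chemquiz/reactions.py` — nine reaction-class templates
- `src/chemquiz/nmr.py` — rule-based 1D/2D NMR simulation
- `src/chemquiz/scoring.py` — extraction, equivalence checks, statistics
- `src/chemquiz/benchmark.py`, `cli.py` — assembly and orchestration

See `docs/methods.md` for the scientific and numerical design choices.
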