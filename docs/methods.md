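# Methods

This note records how the benchmark generator and scorer work, the
assumptions behind each task family, and the choices made where the design
was genuinely open.

## Molecular substrate

All molecules are RDKit graphs, sanitized on ingestion with
stereochemistry removed. Nothing in the benchmark encodes stereo ground
truth, so stripping it keeps every comparison unambiguous: two answers are
the same molecule if and only if their stereo-free canonical SMILES (and,
as a cross-check, their standard InChI) coincide.

Two fixture libraries replace external compound collections so that no
download is needed and builds are reproducible:

- **drug-like** (560 molecules, 10–30 heavy atoms, organic-subset
  elements): assembled combinatorially by decorating 27 common ring
  scaffolds (benzene through quinazoline, including fused bicyclics so
  shortest paths can cross ring fusions) with 1–3 substituents from a
  40-fragment pool, then deduplicated by canonical SMILES.
- **small C/H/N/O** (176 molecules, ≤10 heavy atoms): enumerated from
  simple skeleton × functional-head combinations plus a curated list of
  common small organics.

Both are emitted by `scripts/build_fixture_libraries.py` (fixed seed) and
committed as plain-text SMILES files. They emulate the *size and
functional-group distribution* of drug-like screening compounds, not any
specific vendor catalogue; conclusions about a model's performance
distribution on real libraries do not transfer automatically. Molecules
where the cycle rank (bonds − atoms + components) would disagree with the
SSSR ring count are excluded at build time, so "number of rings" has a
single defensible answer for every fixture.

## SMILES variants and atom bookkeeping

Three writers cover the representation axis:

- *canonical* — RDKit's canonical output;
- *randomized* — atoms renumbered by a seeded permutation, then written
  non-canonically;
- *semicanonical* — canonical ranking rooted at a seeded random atom, so
  large substructures keep their canonical spelling.

Every variant records the writer's atom output order, giving an exact map
from position-in-string (1-based over heavy atoms, the convention used in
all prompts) to reference atom id. Atom-mapping truths are the composition
of two such maps. The scorer does **not** require the stored mapping: an
answer is accepted when its induced atom correspondence preserves element,
charge, aromaticity, H count and every bond with its order — i.e. the
truth composed with any graph automorphism. On symmetric fixtures the
number of accepted mappings is exactly |Aut(G)| (verified exhaustively for
≤10-atom fixtures in the tests).

Shortest-path questions mark two random H-bearing positions with wildcard
(`*`) atoms rather than substituting existing atoms, keeping the parent
graph intact; the reported distance therefore includes the two attachment
bonds. The truth is BFS distance and is independent of the SMILES mode
shown in the prompt.

## Naming

Naming ground truth is always the structure, never a preferred name
string: an answer is correct when a parser converts it to the intended
graph. The reference arbiter is OPSIN, wrapped as an optional backend
(`py2opsin` or an `opsin` executable). Because a Java runtime may be
absent, a built-in restricted parser is the fallback: it handles
locant-prefixed substituent names on benzene, pyridine, naphthalene and
quinoline parents (the grammar this package's own constructions emit,
including multiplying prefixes and shadowed names like *dimethylamino*)
plus a dictionary of common trivial names, and returns "unparseable" for
anything else rather than guessing. Free-form names of arbitrary drug-like
molecules therefore need OPSIN installed; without it they can only score
via a SMILES-form answer. This narrowing is deliberate and environmental,
not scientific.

The functional-group diagnostic attaches six distinct groups from a
40-entry library (halogens, alkyls, O/N/S substituents, carbonyl-derived
groups) to one benzene ring; the locant diagnostic places three halogens
(drawn with replacement from F/Cl/Br/I) on distinct CH positions of the
four scaffolds. Every construction is validated at build time by
round-tripping a systematic name of its own recipe through the built-in
parser; failing draws are resampled.

## Additive SAR (Free-Wilson) questions

A benzofuran scaffold carries one of {F, Cl, Br} at each of three fixed CH
positions; each (position, substituent) pair has a hidden integer value
drawn uniformly from 1–20, and a molecule's score is the sum of its three
values. Seven scored molecules are shown and an eighth must be predicted.
Identifiability is enforced, not hoped for: the training draw is accepted
only when the reparameterized design matrix (intercept + two indicator
columns per position) has full rank 7, which pins the query exactly. The
solver solves that linear system (least squares on a consistent,
full-rank system; exact up to float round-off, rounded to integer) and
recovers the generating sum on every noise-free seed.

The noisy variant perturbs only the *displayed* training scores with a
rounded Gaussian. Because seven equations determine seven parameters,
training noise propagates to the prediction undamped; the noise scale is
therefore a calibrated trade-off against the fixed ±2 scoring band. At
sd = 1 an exact solver lands inside the band for only ~68% of seeds,
which would cap achievable accuracy far below what careful reasoning
should earn; the default is sd = 0.3 score units (an occasional ±1 flip
after rounding), which keeps an exact solver inside the band for ≥95% of
seeds — the generator health target checked in the test suite. Noise-free
questions require an exact integer match.

## Reaction prediction

Nine undergraduate reaction classes, each an RDKit reaction-SMARTS rewrite
plus a seeded reactant sampler: SN2 hydroxide substitution, copper-
catalyzed azide–alkyne cycloaddition (product asserted to be the
1,4-regioisomer on every instance), Simmons–Smith cyclopropanation,
Suzuki–Miyaura coupling, acid-chloride amide formation, reductive
amination, Fischer esterification, Grignard addition to ketones, and
Wittig olefination (stereochemistry stripped). The last five classes are
this package's own selection under the "undergraduate-level, single
unambiguous product" criterion. A substituent draw is accepted only when
the rewrite yields exactly one distinct sanitizable product; draws with
competing reactive sites are discarded. Reagents and conditions appear as
plain text in the prompt, never as SMILES to transform.

## NMR simulation

The simulator is deliberately rule-based rather than an ML shift
predictor: the elucidation task is scored on the structure, so the
requirements are that equivalent nuclei collapse correctly, shifts land in
chemically sensible windows, and the peak-list combinatorics are exact for
the graph. Fidelity of the shift *values* to experiment is explicitly not
claimed, and a green test establishes consistency of the spectra with the
graph, not predictive accuracy.

- **Equivalence classes**: canonical-rank orbits of the heavy-atom graph
  (validated against an independent automorphism enumeration in tests),
  split per nucleus kind; protons on O/N/S are flagged exchangeable.
- **Shifts**: environment base values plus neighbor increments (e.g.
  aromatic H 7.25 base with ring-heteroatom and substituent corrections;
  carbonyl carbons 170–206 by type; sp³ carbons by H count plus
  electronegative-neighbor increments), rounded to 0.01 ppm (¹H) /
  0.1 ppm (¹³C). Colliding class shifts are nudged apart by a minimum
  0.05 / 0.5 ppm separation, deterministically in shift-then-class order,
  so distinct classes are always distinguishable in the rendered text.
- **Multiplicity**: n+1 rule over non-exchangeable protons on adjacent
  carbons in *other* classes; equivalent neighbors do not split; more than
  one distinct partner class, or n > 4, buckets to "m". Exchangeable
  classes are "br s" by definition but are omitted from the rendered list
  entirely and reported only through the gap between summed integrations
  and the molecular formula — reproducing the standard inference "the
  remaining protons must be exchangeable".
- **2D**: COSY = three-bond H–H between distinct classes (this includes
  weak benzylic-type couplings that a real spectrum might not resolve);
  HSQC = one-bond C–H; HMBC = two- and three-bond C–H with all one-bond
  (HSQC) class pairs excluded, so HSQC ∩ HMBC = ∅ by construction.

1D questions draw from the small library (≤10 heavy atoms), 2D questions
from the drug-like library (≤30 heavy atoms). Within each category the
rendered spectrum text must be unique; molecules whose spectra duplicate
an earlier pick are skipped (discriminability guard).

## Scoring and statistics

Answer extraction is regex-based. Strict mode accepts only the last
`Answer: <...>` line; lenient mode falls back per category (last number,
last parseable SMILES token, last position-pair list, last non-empty line
for names). Lenient can never score below strict because it only adds
extraction paths. Missing or unextractable responses count as incorrect.
The lenient fallback grammar is a documented approximation — no claim is
made that it matches any particular historical parser.

Aggregation reports per-category and overall accuracy with Wald 95%
intervals (±1.96 × SE of the binomial proportion, clipped to [0, 1] and
degenerate at k = 0 or k = n by construction), and paired comparisons use
the exact one-tailed McNemar test, P(X ≥ max(b, c)) with
X ~ Binomial(b + c, ½), evaluated from the binomial survival function and
cross-checked against direct tail summation in tests.

## Reproducibility

One master seed determines everything: per-category molecule pools and
per-question seeds are derived by hashing `seed:label` strings, so adding
a category never perturbs another category's draws. Identical
configuration yields byte-identical JSONL output; the manifest records the
config hash, per-category counts and library sizes.

## Known limitations

- The fixture libraries are synthetic stand-ins; their property
  distributions only approximate "drug-like".
- The built-in name parser covers the benchmark's own constructions, not
  general nomenclature; OPSIN is required for arbitrary names.
- NMR shifts are window-plausible, not predictive; coupling constants,
  second-order effects and NOESY are out of scope.
- Reaction questions assert single-product discipline by construction and
  cannot express selectivity or yield.
- The per-category split of the 816-question default is a reconstruction
  (the subset sizes that are pinned by tests are: 100 naming molecules per
  representation, 50 2D-NMR questions, 7 training molecules per SAR
  question, 5 questions per reaction class and mode); all counts are
  configurable.
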