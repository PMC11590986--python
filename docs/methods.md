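# Methods

## Corpus model and text cubes

The pipeline operates on MEDLINE-style records: a document ID, title,
abstract, and the list of MeSH descriptors assigned by indexers.  Category
membership is decided **by MeSH indexing only**, never by matching disease
names in text: a document belongs to a CVD category when at least one of its
descriptors lies in the category's expansion.  Expansion uses the positional
semantics of MeSH tree numbers — descriptor `t` descends from root `r` iff
`t == r` or `t` starts with `r + "."` — so no separate parent table is
needed, and a dot-boundary test prevents false prefixes (`C14.280.06` is not
an ancestor of `C14.280.067`).

Documents may sit in several category cells at once (multi-membership);
grand totals deduplicate.  Oxidative-stress membership is a per-phase flag
(IOS / MOS / OOS), not a ninth category, because the downstream analyses
cross OS phases with CVD categories.  Documents with no CVD category are
excluded from the cube universe and only counted in a report.

The bundled OS vocabulary keeps 77 subcategory rows but 75 unique
descriptors: the per-phase counts (12 + 59 + 6) overshoot the stated total
because two descriptors (glutathione, thioredoxins) belong to two
subcategories.  The loader deduplicates by ID, keeps the first-seen
phase/subcategory, and logs a warning.

## Mention detection

Protein mentions are found with a curated dictionary (primary name +
synonyms per UniProt-style accession), matched case-insensitively at word
boundaries.  A boundary is a transition between `[A-Za-z0-9]` and anything
else: protein symbols like `RyR2` end in digits, so the conventional
letters-only word boundary would over-match (`RyR21`).  Hyphens must match
literally.  Overlapping candidates resolve longest-match-first
(`troponin I` beats `troponin`).  Cross-entity surface-form collisions are
rejected at load time, which keeps matching deterministic without any
disambiguation model.  The matcher is a compiled regex alternation ordered
longest-first; at the corpus sizes this package targets (10³–10⁵ abstracts)
this is simpler than an automaton library and fast enough.

Counting is occurrence-based by default (a document mentioning a protein
three times contributes 3 to tf), with a binary per-document mode as a
switch; occurrence counting is what makes the popularity component
frequency-based.

## CaseOLAP scoring

Per (protein p, category C), with T_C the category's total mention count:

* popularity `Pop = ln(1 + tf(p,C)) / ln(1 + T_C)` — log-saturated
  within-category frequency, 0 for empty categories, 1 when the protein is
  the category's only mentioned entity;
* distinctiveness `Dist = rtf(p,C) / Σ_C′ rtf(p,C′)` with
  `rtf = tf / T_C` — the protein's relative-frequency share across
  categories, summing to 1 for every mentioned protein;
* score `S = Pop · Dist ∈ [0, 1]`, with `S = 0 ⇔ tf = 0`.

The exact normalizations behind published CaseOLAP variants differ; this
package fixes the formulas above because they realize the verbal definitions
(within-category strength × cross-category contrast), stay in [0, 1], and
make class-imbalance robustness provable: `rtf` is invariant under k-fold
replication of a category's documents, so Dist is unaffected by document
imbalance.  The formula block is isolated behind `compute_score_matrix`, and
a `popularity_denominator="total"|"max"` switch covers the plausible
alternative of normalizing by the maximum entity frequency instead of the
category total.  Ranking ties break lexicographically by protein ID.

## Knowledge graph and association scores

Four node types (protein, document, MeSH, pathway) and three edge types:
document–assigns–MeSH, document–mentions–protein (occurrence count stored as
an edge attribute), pathway–contains–protein.  The CaseOLAP score matrix is
kept as an attribute table beside the graph rather than a fourth edge type,
matching the three-edge schema.  Exports target graph-database bulk import
(`id:ID` / `:LABEL` / `:START_ID` / `:END_ID` / `:TYPE` CSV headers) and
GraphML; both round-trip.

A protein *co-occurs* with an OS molecule when some document both mentions
the protein and is assigned the molecule's descriptor — graph traversal, not
textual co-mention of the molecule name.  Association scores:

* OS molecule score in category C = mean of S(p, C) over co-occurring
  proteins p;
* pathway score in category C = mean over member proteins (restricted, by
  reverse mapping, to the curated entity set — only those have scores) of
  S(p, C) · (1 − p-value of the pathway).

Molecules or pathways with no supporting protein emit **no row** rather than
a zero, so "significant" item counts are support counts.  Sunburst
aggregation assigns each leaf its summed score over the categories of
interest and every internal node the sum of its children, conserving the
leaf total at the root.

## Link prediction

Four common-neighbor measures over the undirected graph: common neighbors,
Adamic–Adar, resource allocation, preferential attachment; default
Adamic–Adar, and the measure used is recorded in every output row.
Degree-1 common neighbors are skipped in Adamic–Adar (1/ln 1 is undefined);
for protein × MeSH candidates this case cannot arise, since their common
neighbors are documents carrying at least the two connecting edges.  Scores
are reported raw — heatmap rescaling is a rendering concern.  Because the
schema never joins proteins and MeSH directly, the candidate universe is the
full type-a × type-b product minus (asserted-empty) direct edges.

## PCA and clustering

PCA runs on the scoring proteins (max_C S > 0) with column mean-centering
and **no** variance scaling — all columns share the [0, 1] score scale.
Components come from the singular decomposition; each component's sign is
flipped so its largest-magnitude loading is positive, making loadings
reproducible.  Hierarchical clustering uses average linkage by default
(linkage choice is genuinely open; average is a robust default for bounded
score profiles, with complete/ward available through the `linkage_method`
argument).  The pairwise matrix is reported either as Euclidean distance
(zero diagonal) or as the Pearson correlation value in [−1, 1]; a similarity
heatmap needs the correlation mode, whereas the dendrogram defaults to
Euclidean.  Constant rows have undefined correlation and are recorded as 0
with a warning.

## Synthetic-data generator

The generator emulates the corpus features the analysis depends on:

* **Category imbalance** — default per-category document counts follow the
  published corpus spread (largest ≈ 11× smallest; IHD largest, VOO
  smallest), scaled to desk size.
* **Multi-membership** — with probability `p_multi_category` (default 0.1) a
  document also carries a second category's descriptor.
* **OS co-assignment** — per phase, probability `p_os_assign` (defaults
  IOS 0.02 / MOS 0.06 / OOS 0.01, echoing MOS dominance) of carrying an OS
  descriptor of that phase.
* **Mention counts** — Poisson, mean `λ_signal` (default 2.0) for planted
  (protein, category) pairs and `λ_background` (default 0.05) otherwise; the
  simplest count model consistent with frequency-based scoring.  Counts are
  realized as literal surface forms inside generated abstract text, so
  recovery experiments exercise the matcher, cube, aggregation, and scoring
  end to end rather than injecting counts downstream.

Everything is deterministic given the config and seed, including the corpus
bytes on disk.  What the generator does **not** emulate: real English prose,
indexing errors, ambiguous or context-dependent protein names, full-text
articles, or MeSH qualifier semantics — so passing recovery tests show the
pipeline machinery is correct, not that curated dictionaries are adequate
for real literature.

### Two-block design for structure recovery

A naive two-block design (block A mentioned only in ARR+CCS, block B only in
the other six) concentrates *all* score variance in the block contrast, which
then lands on PC1 — there is no shared popularity factor, because
distinctiveness is row-normalized.  To reproduce the qualitative structure
of interest (PC1 an even, all-positive mix; PC2 an ARR/CCS contrast), the
design gives every protein a mention rate in every category proportional to
a lognormal per-protein magnitude (σ = 2.0) — the shared factor that
survives into popularity and becomes PC1 — and multiplies block A's rate by
3 in ARR and CCS, a contrast concentrated in two columns that dominates PC2.
Defaults: 30% of proteins in block A, base rate 1.0 mention/document.

### Recovery metrics

precision@k: fraction of the top-k proteins per category (score-descending,
lexicographic ties) that are planted in that category.  AUC: probability
that a random planted (protein, category) pair outscores a random
non-planted pair, ties counted ½, computed from rank statistics.

## Problem sizes

The reference recovery experiment uses 8 categories × 200 documents, 100
proteins, 10 planted pairs per category; the PCA structure-recovery rate is
estimated over 100 runs at 40 proteins × 480 documents.  These sizes give
stable statistics (Poisson totals of ~400 mentions per planted pair) while
keeping a full test-suite run in minutes on one core.

## Known limitations

* Popularity/distinctiveness normalizations are one defensible realization
  of CaseOLAP's verbal definition, not a bit-exact reimplementation of any
  deployed system; the `popularity_denominator` switch and the isolated
  formula block exist for exactly that reason.
* Whether OS co-occurrence should be restricted per category rather than
  computed over the whole cube universe is ambiguous; the default uses the
  whole universe (a per-category restriction can be applied by filtering the
  cube before graph construction).
* The packaged vocabularies are synthetic stand-ins with the correct
  structure and counts, anchored by real descriptors; analyses of real
  literature should substitute curated tables in the same CSV formats.
* Pathway p-values are accepted as an input column; no enrichment test is
  performed in-package.
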