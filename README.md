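# cardiomine

Literature mining of the interplay between Ca²⁺-regulating proteins,
oxidative stress (OS), and cardiovascular disease (CVD).

Biomedical abstracts indexed with MeSH (Medical Subject Headings) descriptors
carry enough structure to quantify protein–disease associations at scale:
which of the proteins governing cardiac calcium handling (RyR2, SERCA2,
cardiac troponins, …) are discussed in which disease context, and how those
associations connect to oxidative-stress molecules such as reactive oxygen
species and antioxidants.  `cardiomine` implements that analysis as a
reusable, file-based pipeline:

1. **Text cubes** — documents are grouped into eight CVD categories (CM, ARR,
   CHD, VD, IHD, CCS, VOO, OHD) by expanding each category's MeSH root tree
   numbers to all descendants (dot-boundary prefix on tree numbers), with an
   OS sub-cube flagging documents per OS phase (initiation / modulation /
   outcome).
2. **CaseOLAP scoring** — dictionary-matched protein mentions are aggregated
   into tf(p, C) and scored per (protein, category) as

   S(p, C) = Pop(p, C) · Dist(p, C),
   Pop = ln(1 + tf(p,C)) / ln(1 + T_C),
   Dist = rtf(p,C) / Σ_C′ rtf(p,C′) with rtf = tf / T_C,

   where T_C is the category's total mention count.  Dist is scale-free, so
   rankings are robust to the heavy class imbalance between categories.
3. **Knowledge graph** — protein / document / MeSH / pathway nodes with
   mentions / assigns / contains edges; exported as graph-database
   bulk-import CSV or GraphML.  Co-occurrence queries score OS molecules
   (mean CaseOLAP score of co-occurring proteins) and pathways (mean member
   score × (1 − p-value)), with sunburst-ready hierarchical aggregation.
4. **Link prediction** — common-neighbor topological measures
   (common neighbors, Adamic–Adar, resource allocation, preferential
   attachment) rank candidate protein×OS and protein×CVD pairs.
5. **Matrix analysis** — PCA and hierarchical clustering of the
   protein × category score matrix.
6. **Synthetic corpora** — a generator plants (protein, category)
   associations with known rates inside realistic corpus structure, so the
   whole pipeline can be validated by recovery experiments.

## Worked example

`examples/01_score_micro_corpus.py` scores a four-abstract corpus by hand:

```
Mention counts tf(protein, category):
    ARR  CM
P1    3   0
P2    1   2

CaseOLAP scores S = popularity x distinctiveness:
       ARR   CM
P1  0.8614  0.0
P2  0.0861  0.8
```

P1 appears only in arrhythmia documents — 3 of the ARR cell's 4 mentions —
so its distinctiveness there is 1 and S(P1, ARR) = ln 4 / ln 5 ≈ 0.8614.
P2's relative frequency splits 0.2 / 0.8 between ARR and CM, giving
S(P2, CM) = 1.0 × 0.8 = 0.8.

`examples/02_synthetic_recovery.py` runs the full pipeline on a 1,600
document synthetic corpus with ten planted proteins per category:

```
proteins with a CaseOLAP score: 100
precision@10 per category: {'CM': 1.0, 'ARR': 1.0, 'CHD': 1.0, 'VD': 1.0,
                            'IHD': 1.0, 'CCS': 1.0, 'VOO': 1.0, 'OHD': 1.0}
planted-vs-background AUC: 1.000
```

The other examples cover knowledge-graph queries and sunburst aggregation
(`03`), link prediction (`04`), and PCA / clustering structure recovery
(`05`).

## Data

`src/cardiomine/data/` ships synthetic stand-in vocabularies (clearly
labelled `*_synthetic.csv`) that reproduce the structure of the curated
study vocabularies — 176 CVD descriptors under the eight category roots,
75 unique OS descriptors across 77 phase/subcategory rows, 128 protein
entries — anchored by well-known real descriptors and proteins.  Input
formats are plain text throughout: JSON Lines corpora, CSV/TSV vocabulary
tables, bulk-import CSV / GraphML graph exports, JSON sunburst trees.
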