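# phoscoreg

Phosphosite-centric meta-analysis of multi-study phosphoproteomics corpora.

Site-level phosphoproteomics datasets — hundreds of test-vs-control
comparisons compiled from the literature — can reveal which phosphosites of
a protein of interest (an *anchor* protein such as Tau/MAPT) are detected
most often, which of its sites rise and fall together, and which
phosphosites on other proteins (*PsOPs*) are co-regulated with them.
`phoscoreg` turns canonical tab-separated site tables into:

* per-dataset **U/D/NR regulation calls** with Class-1 localisation
  filtering (localisation probability ≥ 0.75 or A-score ≥ 13; fold change
  ≥ 1.3 / ≤ 0.76 with p < 0.05),
* **predominant-site rankings** by detection frequency across profiling and
  differential datasets,
* within-protein **co-occurrence ratios**
  (nUU + nDD)/(nUD + nDU) per ordered site pair,
* anchor-vs-PsOP **co-regulation statistics**: for each pair, the 2×2
  table a (neither regulated) / b (exactly one) / c (both, discordant) /
  d (both, concordant) over a declared dataset universe, tested with an
  exact **one-sided Fisher's exact test** per polarity
  (P(d′ ≥ d) for positive, its U↔D dual for negative co-regulation),
* a multi-layer **high-confidence filter**: winning-tail p < 0.05, support
  ≥ 10% of the anchor's detections, evidence from ≥ 3 experimental
  conditions and ≥ 3 studies, winning ratio > 1,
* annotation joins (binary/complex interactors, upstream kinases) and typed
  network edge-list export,
* a **synthetic corpus generator** with planted co-regulation structure and
  ground truth, so the whole pipeline is testable without any downloads.

See `docs/methods.md` for the statistical model, parameter defaults and
design decisions.

## Worked example

Simulate a small corpus (10 studies × 3 conditions, 80 background sites)
with one positively and one negatively co-regulated planted pair, then scan
the anchor site MAPT:S519 against every candidate site:

```bash
cat > sim.yaml <<'YAML'
n_studies: 10
conditions_per_study: 3
n_background_sites: 80
n_proteins: 20
planted_pairs:
  - {anchor: "MAPT:S519", partner: "NUCKS1:S214", polarity: positive,
     concordance: 0.95, co_measurement_rate: 0.9}
  - {anchor: "MAPT:S717", partner: "LYSMD1:S99", polarity: negative,
     concordance: 0.95, co_measurement_rate: 0.9}
seed: 12
YAML

phoscoreg simulate --config sim.yaml --out corpus --seed 12
phoscoreg coreg --anchor MAPT:S519 \
    --differential corpus/differential.tsv --out coreg_S519.tsv
# -> 85 pairs tested, 1 high-confidence
```

The one high-confidence row in `coreg_S519.tsv` is the planted partner:

```
   anchor psop_gene psop_site  nUU  nDD  c  d  fet_p_pos  support_fraction  n_studies classification
MAPT:S519    NUCKS1      S214    3    1  0  4   0.012042          0.148148          4       positive
```

Reading it: across the 30 differential datasets in which S519 was measured,
NUCKS1:S214 was concordantly regulated with it in d = 4 datasets (3 both-up,
1 both-down) and never discordantly (c = 0); the one-sided Fisher test on
the a/b/c/d table gives p = 0.012, the 4 supporting datasets are 14.8% of
the anchor's 27 Class-1 detections and span 4 distinct studies, so the pair
clears every layer of the high-confidence filter with positive polarity.
The background pairs — regulated independently of the anchor — are all
classified `none` or fail the filter.

The full pipeline (`phoscoreg run --config ...`) chains ingest → calling →
predominant-site ranking → co-occurrence → co-regulation → annotation →
export, writes every stage's TSV plus a `report.json` with counts at each
filter layer, and is byte-identical across reruns with the same config and
seed.  Every subcommand also works standalone on intermediate TSVs; the
canonical input schema is documented in `src/phoscoreg/io_registry.py`.

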