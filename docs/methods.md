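# Methods

## Scope and model

`phoscoreg` implements a phosphosite-centric meta-analysis over a corpus of
site-level phosphoproteomics datasets.  A *dataset* is one test-vs-control
comparison (differential) or one qualitative catalogue of detected
phosphopeptides (profiling); datasets are grouped into experimental
*conditions* and *studies*.  A phosphosite is identified by gene symbol,
residue (S/T/Y) and 1-based position on whatever reference sequence the
input tables declare; no isoform remapping is attempted, because source
tables rarely state which isoform their coordinates use.  Positions are
therefore opaque but consistent coordinates.

The analysis proceeds in five stages.

### 1. Regulation calling

Measurements first pass the Class-1 localisation filter: localisation
probability >= `min_loc_prob` (default 0.75) **or** A-score >=
`min_a_score` (default 13).  Sites failing both (or lacking both) are
excluded and counted.  Each surviving measurement is then called

* **U** if fold change >= `fc_up` (default 1.3) and p < `alpha` (0.05),
* **D** if fold change <= `fc_down` (default 0.76) and p < `alpha`,
* **NR** otherwise.

Boundary semantics are asymmetric on purpose: the fold-change gates are
inclusive, the significance gate strict.  `fc_down` is 0.76 exactly, not
1/1.3 — the conventional pairing in this literature, kept as printed rather
than symmetrised.  A missing p-value yields NR with a `missing-p` flag
(conservative); `allow_missing_p` switches to calling on fold change alone
for tables that ship no test statistic.  Multiple peptide-level rows for
one (dataset, site) collapse to a single call: unanimous non-NR direction
wins, a U/D conflict collapses to NR with a `conflict` flag — we do not
invent a majority-vote direction that the evidence does not support.

### 2. Predominant-site ranking

For an anchor protein, each site's *profiling frequency* counts profiling
datasets with a Class-1 detection, and its *differential frequency* counts
differential datasets in which the site was called U or D
(`freq_mode="detected"` counts any measured dataset instead; the
distinction matters for sparse sites).  Ranking is total and deterministic:
differential frequency desc, then profiling frequency desc, then position
asc.  "Predominant" has no natural numeric cutoff, so both selectors are
exposed: `top_k` (default 4) and `min_frequency`.

### 3. Within-protein co-occurrence

For an ordered site pair (T1, T2), pattern counts nUU, nUD, nDU, nDD are
taken over the differential datasets in which *both* sites carry a non-NR
call; NR or absent contributes nothing.  The positive co-occurrence ratio
is (nUU + nDD)/(nUD + nDU), the negative ratio its inverse.  Ratios are
reported unsmoothed: x/0 with x > 0 is +inf, 0/0 is NaN (undefined) — these
are sentinels, not errors, because downstream ranking must distinguish
"perfectly concordant" from "never co-regulated".  An optional pseudocount
stabilises rankings when many pairs have zero discordant counts.

### 4. Co-regulation and the Fisher test

For an anchor site and each candidate site regulated at least once in the
dataset *universe* (default: every differential dataset in which the anchor
was measured; `universe="all"` uses the whole corpus), each universe
dataset lands in exactly one contingency cell:

| cell | meaning |
|------|----------------------------------------------|
| a    | neither site regulated                        |
| b    | exactly one site regulated                    |
| c    | both regulated, discordant (U/D or D/U)       |
| d    | both regulated, concordant (U/U or D/D)       |

The source literature describes a and b once in terms of *detection* and
once in terms of *differential regulation*; regulation-based cells are the
default because the inputs are differential datasets, and
`cell_mode="detected"` is provided as a sensitivity variant (a = neither
site measured at all).

The one-sided Fisher exact test treats the table with rows (a, b)/(c, d)
and columns (a, c)/(b, d).  The concordant (positive co-regulation) tail
sums hypergeometric probabilities over tables at the observed margins with
d' >= d.  The discordant tail is defined as the concordant test of the
U<->D-relabelled table (a, b, d, c) — relabelling the second site's
directions exchanges c and d while leaving a and b unchanged, so this is
the only definition under which the two tails are exact duals.  Fixing one
set of margins for both tails would make discordance essentially
undetectable whenever a dominates the table (the discordant cell would sit
in the large column and its tail probability would saturate near 1 even
for perfectly anti-correlated pairs).  Tail sums are computed with
log-gamma arithmetic (exact to ~1e-13 against both a rational brute-force
enumeration and `scipy.stats.fisher_exact`, which serve as independent
cross-checks in the test suite, never as the implementation).

A pair is classified positive (negative) when the corresponding tail
p-value is below `alpha` and the matching ratio exceeds 1.  If both tails
reach significance — possible in small, pathological tables — the smaller
p wins and a `both-significant` flag is set.  No multiple-testing
correction is applied by default, matching the raw p < 0.05 convention of
the source analyses; `fdr=True` adds Benjamini–Hochberg adjusted winning
p-values as a clearly-marked deviation.

### 5. High-confidence filter

A classified pair is *high-confidence* when all layers pass:

1. winning-tail p < `alpha`;
2. winning-polarity support (the d or c cell) is at least
   `min_support_fraction` (default 0.10) of the anchor's **total
   detections** — the number of universe datasets in which the anchor
   carries a Class-1 call.  The detection denominator follows the
   "10% of total detections" phrasing of the filter and is the only
   reading consistent with reported detection counts being several-fold
   larger than top co-regulation frequencies;
   `support_denominator="regulated"` (datasets where the anchor was called
   U/D) is provided but is a far laxer gate;
3. the winning evidence spans >= `min_conditions` (3) distinct experimental
   conditions and >= `min_studies` (3) distinct studies — the guard against
   one large multi-timepoint experiment or a single lab dominating the
   evidence;
4. the winning ratio exceeds 1.

All "at least" thresholds are boundary-inclusive.  Whether the 10% gate
should be evaluated per polarity or on total co-regulated counts is not
specified anywhere; the winning polarity alone is used.

Annotation joins are purely static table joins (gene-level for binary and
complex interactors, site-level for kinase -> substrate records); no live
database retrieval is performed, so results are reproducible offline.

## Synthetic corpora

Hand-compiled study corpora are not redistributable in machine-readable
form, so validation uses a generator with planted structure.  Defaults
describe a desk-scale corpus: 20 studies x 3 conditions x 1 differential
dataset (60 datasets), 500 background sites on 100 proteins, one profiling
dataset per study, background regulation rates p_up = p_down = 0.1 per
site per dataset, 10% missing measurements, and a 5% Class-1 failure rate.
Regulated fold changes are the gate times exp(|N(0.5, 0.3)|) on the log
scale — unambiguously beyond the gates — with p ~ Uniform(0, alpha);
unregulated sites draw fold changes strictly inside the gates with
p ~ Uniform(0, 1).  `boundary_fraction` optionally plants gate-exact values
to stress the inclusive boundaries.  A planted pair couples a partner site
to an anchor: when the anchor is regulated and the partner co-measured
(probability `co_measurement_rate`), the partner matches (positive) or
opposes (negative) the anchor's direction with probability `concordance`;
otherwise the partner behaves as background.  Fixed (config, seed) pairs
produce byte-identical corpora.

What the generator does *not* emulate: correlated background regulation
(real phosphoproteomes co-regulate in pathways, so real null distributions
are wider than independent-site nulls), study-size imbalance, batch
effects, missingness that depends on abundance, and anchor sites whose
regulation frequency is high relative to their detection frequency.  The
last point matters for interpreting the filter: in real predominant-site
data the anchor is regulated in a large fraction of the datasets that
detect it, which separates planted-like signal cleanly from chance
concordance.  Under the generator's independent-background conditions
(anchor regulated in ~11 of 60 datasets), the 10%-of-detections support
gate (~6 datasets) sits close to both the planted-pair concordant count
(~8 on average, binomially variable) and the extreme tail of chance
concordance, so a small number of background pairs pass the full filter
per corpus and planted pairs anchored on rarely-regulated sites are
missed.  The test suite measures exactly this: passing tests demonstrate
calibration of the test statistic and faithful mechanics of the filter,
not that the filter's false-discovery behaviour on real corpora is zero.

## Numerical choices

* FET tail sums use `math.lgamma` with peak-shifted log-sum-exp; p-values
  are clipped into (0, 1].  An empty universe or an empty (c, d) row gives
  p = 1 (single admissible table).
* Ratios use IEEE inf/NaN sentinels; NaN never compares greater than 1, so
  undefined ratios can never classify or pass the filter.
* Ranking ties break deterministically (profiling frequency, then
  position); all outputs are sorted before writing so reruns are
  byte-identical.
* Floats are serialised at full round-trip precision; "." or empty cells
  denote missing values in all TSVs.
* Gene symbols are uppercased at ingest; duplicate profiling detections
  collapse (set semantics); duplicate differential rows are kept as
  separate evidence and resolved by the call collapse rule.

## Known limitations

* Contingency cells are computed from collapsed calls, so a dataset whose
  within-dataset evidence conflicted (NR-conflict) counts as unregulated.
* The anchor-measured universe makes each anchor's test conditional on its
  own detection pattern; anchors measured in very few datasets yield wide,
  underpowered tables rather than an error.
* `truth_eval` scores only (anchor, partner) identity and polarity; a
  planted pair recovered at a different anchor counts as a background
  false positive, which is conservative.
* Problem sizes in the test suite (20 x 3 corpora, 500 sites, <= 20
  replicates) were chosen as the smallest scale at which the calibration
  properties are measurable with stable Monte-Carlo error.
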