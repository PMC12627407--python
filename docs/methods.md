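# Methods

This note records the model, the conventions and defaults the package
commits to, the places where the design was genuinely open and what was
chosen, and what the synthetic-fixture tests do and do not demonstrate.

## Coordinates and formats

All intervals are held internally as 0-based half-open `[start, end)`.
BED-family inputs (narrowPeak, bedpe) are native to that convention;
FIMO TSV and GTF use 1-based inclusive coordinates and are converted on
read (`start - 1`) and back on write, so every conversion is an exact
inverse. Overlap always means ≥ 1 shared bp; no minimum-fraction rule is
applied anywhere.

Readers distinguish malformed *data* lines (skipped, with a counted
warning carrying the line number) from *structural* defects (wrong
column count, missing header column, duplicate `gene_id`), which are
fatal. Inter-chromosomal bedpe rows are dropped and counted: the span
filter and the interloop window presume intra-chromosomal loops. The
bedpe PET-count and FDR column positions are arguments (defaults: columns
7 and 8) because loop callers disagree on layout.

## Candidate construction

Loop calls are filtered by `pet_count >= 2` and `fdr <= 0.05`, with both
removal rules read strictly so boundary values survive. Anchor windows of
width `2 * half_width` are centred on the anchor **midpoints** — the only
anchor-size-invariant choice — and clamped at position 0. Span is
measured midpoint-to-midpoint and restricted to `[2 kb, 2 Mb]`, both
bounds inclusive; essentially all reported human loops fall in that
range. The interloop interval runs from the start-window end to the
end-window start; when the windows touch or overlap (span ≤ 2·half_width)
the interloop is empty, the loop is flagged degenerate, and every
interloop presence flag reads 0.

Two window widths are in use: 1000-bp windows (`half_width = 500`) for
the ChIA-PET cell-line design and 500-bp windows (`half_width = 250`)
for the Hi-C case/control design. The width is a configuration value
throughout; "window of N bp" is read as full width.

Each anchor window is assigned the overlapping motif with the highest
FIMO score (ties: leftmost start). Candidates missing a motif in either
window are dropped from training — under the model they cannot be CTCF
loops.

## Labeling

A candidate is **positive** iff

1. its anchor motifs are convergent — `+` at the upstream anchor, `-` at
   the downstream one, the loop-extrusion geometry;
2. both anchor motifs overlap a CTCF ChIP-seq peak (≥ 1 bp — "occupied");
3. a RAD21 peak overlaps at least one loop window. By default all three
   windows qualify (`rad21_windows="all3"`); an anchors-only mode is
   provided because the two readings are both defensible.

RAD21 exists only in the labeler. The feature schema rejects any column
containing `rad21`, and the trainer re-checks — otherwise the label would
leak into the model and the classifier would merely memorise the rule.

**Negatives** are sampled same-chromosome pairs of *unbound* motifs
(no CTCF peak on either motif, no RAD21 in any of the three windows)
with spans inside the filter range. The sampler matches the negative
span distribution to the positive one by quantile bins (10 by default):
without matching, the classifier could separate classes on span alone.
The positive:negative ratio defaults to 1:1. Sampling is driven by a
single integer seed and is reproducible.

## Loop classifier

XGBoost, binary logistic objective, 300 trees, depth 4, learning rate
0.1, single-threaded histogram growth (bit-reproducible per seed). One
non-obvious default: `min_child_weight = 0`. With the conventional value
of 1, boosting stalls once the hessian mass of a cleanly separated class
drops below 1, capping probabilities near 0.995 / 0.005. The discordance
thresholds below (0.0005 / 0.999) presume scores that can reach the
near-0/near-1 regime on confidently classified loops, so pure leaves are
allowed to keep refining. All hyperparameters are exposed.

The feature schema (names and order) is frozen at training time and
serialized with the model into a single JSON file together with
hyperparameters, seed, importances, and imputation sentinels; a
predict-time schema mismatch is a hard error naming the differing
columns. Training rows must be complete; at predict time a missing
anchor-motif score is imputed as (minimum training score − 1), pushing
such loops toward the unbound regime rather than mid-range.

Splits are stratified 2/3–1/3 by default. Evaluation reports the
confusion counts with precision/recall/F computed from their exact
identities, ROC-AUC by trapezoid over the ROC curve, and PR-AUC as
average precision — trapezoidal interpolation is biased for PR curves.
With one-class labels the AUCs are reported as undefined (`None`), never
as 0. Feature importance is total gain, normalised to sum 1 (descending,
ties by schema order).

## Binding predictor

Each candidate site (FIMO motif hit) gets a 500-bp span centred on the
motif midpoint, tiled into twenty 25-bp bins; every configured track
contributes one 0/1 overlap flag per bin, and the FIMO score is appended
(`20 * n_tracks + 1` columns). Sites are labeled bound iff the motif
overlaps a CTCF peak. The model is a Random Forest, 500 trees, sqrt
features per split, seeded. Per-bin values stay binary to mirror the
loop-feature convention; signal strengths are out of scope.

Three evaluation regimes mirror a multi-sample design: 2/3–1/3 self-split
within one sample, leave-one-sample-out across controls, and pooled
controls → case. The case probabilities from the last regime can replace
the CTCF presence features of the loop classifier
(`substitute_binding_predictions`, mode `replace` — the default, chosen
because substituting is the scenario where ChIP is absent — or `augment`
to keep both).

## Discordance

With $s_{control}$ (mean over control samples — the simplest symmetric
aggregate; per-sample scores are retained) and $s_{case}$:

* $D = (s_{control} - s_{case})^2$, symmetric and in [0, 1];
* **lost**: $s_{control} \ge 0.9995$ and $s_{case} < 0.0005$;
* **gained**: $s_{control} \le 0.0005$ and $s_{case} > 0.999$;
* otherwise concordant.

"Control score of 1" / "of 0" is operationalised as ≥ 0.9995 / ≤ 0.0005
because exactly 1.0 or 0.0 is a measure-zero event for a probabilistic
classifier; all four thresholds are arguments. Gene annotation intersects
the **inter-anchor span** (midpoint to midpoint) with gene bodies and
keeps the single longest-overlap gene (ties: leftmost gene start); a
top-k option exists because reporting two genes per loop is sometimes
wanted. Genes are ranked by the sum of $D$ over their discordant loops,
lost and gained separately. Discordance tables print floats at 6
decimals.

## Synthetic fixtures

The generator lays candidate loops out in exclusive, non-overlapping
territories (gap > one window width plus peak overshoot) so a window
query can never pick up a neighbour's signal, and emits every input
format through the same writers the readers invert. Its parameters *are*
the study conditions:

* spans log-uniform on [2 kb, 2 Mb] — real span distributions are
  heavy-tailed but broad, and log-uniform exercises both short loops
  (including degenerate interloops) and Mb-scale ones;
* true loops: convergent motif pairs with bound-level FIMO scores
  (N(18, 3) by default vs N(12, 3) for unbound — overlapping, so motif
  score is informative but not decisive), CTCF peaks over both anchor
  motifs, RAD21 at the anchors;
* per-mark, per-window peak presence emitted with probability
  `P(peak | positive)` / `P(peak | negative)` — default 0.9/0.1, a
  moderate-noise regime; 1/0 is the noiseless limit in which pipeline
  labeling recovers the planted status exactly;
* filter decoys straddling the PET/FDR thresholds exercise the loop
  filter boundaries;
* case samples replay the control generative model except that a
  configured fraction of true loops has its CTCF and RAD21 occupancy
  deleted — the lost-loop signature; motifs and other marks remain;
* one gene body is planted inside each true loop's inter-anchor span;
  under disruption, one gene is deliberately shared by two adjacent
  disrupted loops so the gene ranking has a unique expected winner,
  recorded in `meta.json`.

All randomness derives from one seed through per-purpose spawned
generator streams; the emitted file set is byte-identical across runs.

What the fixtures do **not** emulate: real nucleotide sequence, peak
width/signal distributions, correlated marks, anchor-calling uncertainty,
cell-type mixtures, or the heavy-tailed clustering of real CTCF sites.
Passing tests therefore demonstrate the pipeline's correctness and its
behaviour under the planted statistical structure — not performance on
real ENCODE data.

## Problem sizes and numerical choices

The test suite runs the classifier-performance checks at 2,000 positive
+ 2,000 negative loops, importance checks at 600 + 600, and disruption
recovery at 200 true loops with 10% disrupted across 3 control samples
and 1 case — sizes at which every planted effect is comfortably resolved
while the whole suite stays fast. Determinism is enforced everywhere:
single-threaded tree growth, seeds threaded through every sampler, and
fixed table column orders with 6-decimal float printing.

## Known limitations

* Presence features are binary; peak counts and signal values are
  deliberately ignored (a stated non-goal), which discards information
  when multiple peaks stack in one window.
* Anchor motif assignment keeps only the top-scoring motif per window;
  anchors with several strong motifs lose the alternatives.
* The discordance thresholds are calibrated to a classifier that
  saturates; a recalibrated or regularised model would need different
  thresholds.
* `aggregate_control_scores` assumes every loop is scored in every
  control sample and fails loudly otherwise; there is no imputation
  across samples.
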