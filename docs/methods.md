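# Methods

## Problem and model

`m6adeg` classifies 501-nt mRNA windows centered on YTHDF2-bound m⁶A sites
as decay-regulating (positive) or not (negative), and attributes the trained
classifier's decisions back to nucleotides to nominate co-factor binding
motifs. The model is a BERT-style bidirectional transformer over overlapping
k-mer tokens with learned position embeddings, an MLM head for
self-supervised pre-training, and a single-logit sigmoid head on the `[CLS]`
vector for classification.

The encoder is written in NumPy with hand-derived backpropagation (verified
against finite differences in the test suite) so the package has no deep
learning framework dependency and is exactly reproducible on CPU: all
randomness flows through explicit seeds and two equal-seed runs produce
bit-identical parameter trajectories. Pre-norm residual blocks are used
rather than the original post-norm arrangement because they train stably
without long warmup at the small widths this package typically runs; the
published 12×768×12 geometry instantiates and runs forward unchanged.
Parameters default to float32; float64 is available via the `dtype` argument
where tighter gradients are wanted.

## Tokenization

A length-L window yields L−K+1 overlapping k-mers, framed as
`[CLS] k-mers… [PAD]… [SEP]` and padded to `max_tokens` (default 501, the
window length, which the K=3 body fills exactly). Note the non-standard pad
placement — pads sit *before* the terminal `[SEP]` — and attention masks
exclude `[PAD]` key positions accordingly. Whether the original input length
was kept at 501 for K>3 is not documented anywhere we could verify; we fix
501 for all K (larger K simply leaves a little more padding) and expose it in
`TokenizerConfig`. Non-ACGT characters are a hard error rather than being
mapped to `[UNK]`: silent substitution would corrupt downstream motif
statistics, so the dataset builder is expected to filter such windows. RNA
input is converted to DNA (U→T) on ingest.

## Dataset construction

Coordinates are transcript-space and 0-based throughout; BED intervals are
half-open. Genome→transcript projection (and assembly liftover) must happen
upstream — this package deliberately does not reimplement it.

Decisions where the procedure was under-specified:

- "log2FC greater than 1" is strict; a gene at exactly 1.0 is negative.
- Sites whose gene is absent from the half-life table default to negative
  (with a warning); configurable to `drop`. Treating unmeasured genes as
  negative mirrors treating "everything not in the stabilized set" as
  negative, but it is a guess.
- Sites whose transcript base is not A are kept with a warning: single-base
  m⁶A calls come from heterogeneous profiling technologies and a hard drop
  would silently shrink the data.
- The 70/20/10 train/test/validation split is stratified by label (round to
  nearest for test and validation, remainder to train).
- Redundancy removal is an exact greedy clustering, longest-first: a sequence
  joins the first cluster whose representative it matches at ≥ 90 % identity,
  where identity is the best ungapped sliding alignment of the shorter
  sequence against the longer divided by the shorter length. This reproduces
  CD-HIT's semantics at desk scale without the binary or its word-filter
  heuristics, and is applied within the positive and negative sets
  separately.

## Training

**Pre-training.** Two phases of masked-language modelling: 15 % of real
tokens until convergence (holdout loss improvement < 1e-3 over a patience
window, or a step cap), then 20 % for a fixed number of further steps, with
10 % of the corpus held out. Masking selects span *centers* uniformly among
real tokens and masks K contiguous tokens per selection (clipped at the body
edges) until ⌈rate·n⌉ tokens are covered, trimming the final span's
overshoot to hit the count exactly — single-token masking would be trivially
solvable from overlapping neighbours. Within the selected set the standard
80/10/10 `[MASK]`/random/unchanged replacement applies. The pre-training
optimizer and schedule are not documented in any source we treat as
authoritative, so we default to AdamW (β=0.9/0.999, weight decay 0.01 on
matrices only) with linear warmup; everything is exposed in
`PretrainSchedule`.

**Fine-tuning.** Binary cross-entropy on the `[CLS]` logit with
classifier-head dropout (0.1); all encoder layers remain trainable. After
every epoch the validation AUC is computed and the best checkpoint (earliest
epoch on ties) is restored at the end. The reference configuration is lr
1e-5 for 100 epochs; the desk-scale study uses 2e-4 for 8 epochs, which the
much smaller model and dataset make appropriate.

## Metrics

ACC, MCC, precision, recall and FPR come from the confusion matrix; MCC
returns 0 when any marginal is empty and precision 0 (with a warning) when
nothing is predicted positive. AUC is computed by midrank Mann–Whitney,
which with midpoint tie handling equals trapezoidal integration of the
empirical ROC curve exactly; both routes are implemented and cross-checked.
Cross-validation is stratified, seeded, 5-fold, reporting mean ± sd per
metric in the conventional "71.65%±2.06%" style.

## Interpretation

**Integrated gradients.** The reference input is `[CLS] [PAD]… [SEP]`. The
path runs in embedding space (token + position embeddings) from reference to
input; gradients of the positive-class logit — not the post-sigmoid
probability, so that the completeness axiom holds additively — are averaged
with a midpoint Riemann rule (default 50 steps; the bulk profiling in the
desk study uses 16, which empirically leaves a completeness gap well under
2 % of the logit span). The input's attention mask is held fixed along the
path, including at both endpoints, so F(x)−F(x_ref) is well defined. The
recorded `completeness_gap` lets callers check the approximation on their own
model.

Each sequence is attributed *toward its own class*: the binary head has one
logit, so negative-class attribution is the exact negation of positive-class
attribution. Without this convention a stability motif in a negative
sequence receives a strongly negative score and can never rise above the
sequence mean, and the region caller would systematically miss exactly the
elements the analysis is looking for in the negative set.

**Nucleotide aggregation.** nt score = mean of the scores of the 1..K tokens
covering that nucleotide (exact coverage map recorded at encode time).

**Region calling.** Maximal runs of nucleotides strictly above the
per-sequence mean, minimum length 5 nt (both configurable; a global-mean
threshold is available via the `threshold` argument). A constant profile
yields no regions. "Per-sequence mean" was chosen over a global mean because
attribution scales vary between sequences; the flag exists because the
alternative reading is defensible.

**Motif test.** Each region contributes one candidate occurrence of its
exact substring; strings occurring fewer than 5 times overall are excluded.
For string m with N total candidate occurrences, K in the query set, n of m
overall and k of m in the query set, the p-value is the upper tail
P(X ≥ k), X ~ Hypergeometric(N, n, K), with the standard pmf
C(n,k)·C(N−n,K−k)/C(N,K). Adjustment is
Benjamini–Hochberg (the adjustment method was unspecified; BH is the field
standard for enrichment lists). Near-identical variants are *not* merged —
that is what downstream TOMTOM matching is for — and significant motifs are
exported as 24-nt windows centered on each occurrence for exactly that
purpose.

**RBP enrichment.** Sequence-level presence/absence: a sequence "has" a
protein if any of its high-attribution regions overlaps any of that
protein's intervals by ≥ 1 base (regions are translated into track
coordinates via each window's transcript offset). Per protein a 2×2 table
over positive/negative sequences is tested with both one-sided Fisher exact
tests — the original direction convention is ambiguous, so both directions
enter the BH family (proteins × directions) and significant directions are
reported.

## Synthetic data

The generator emulates the *structure* of the real inputs so that every
pipeline stage is testable without downloads: one transcript/gene per site,
uniform i.i.d. ACGT background (a first-order Markov background with
configurable GC content is a flag, because enrichment nulls are sensitive to
composition), a DRACH consensus written around the methylated A, a YTHDF2
interval covering every site, and half-life log2FC drawn from (1.5, 3.0) for
positives and (−1.0, 0.5) for negatives. The discriminative signal is an
AU-rich-element-like 6-mer (`TATTTA`) planted at a Gaussian-jittered offset
(mean −80 nt, sd 8) in 90 % of negative and 0 % of positive sequences —
mirroring the biological picture in which stabilizing co-factor motifs near
the m⁶A site mark the *non*-degraded class. The matched RBP track places one
padded, jittered interval per planted motif plus uniform decoy intervals in
both classes (rate 0.2).

What the generator does **not** emulate: real nucleotide composition and
repeat structure, multiple sites per transcript, degenerate/partial motifs,
correlated RBP tracks, region annotation errors, or measurement noise in
half-lives beyond a simple label-flip probability. Passing the planted-motif
study therefore demonstrates that the machinery is correct and sensitive,
not that any particular biological effect size is attainable on real data.

## Desk-scale study sizes

The validation study uses 500 sites per class with 201-nt windows (±100 nt),
a 2-layer/64-hidden/4-head encoder with K=3, 200+60 pre-training steps
(batch 16, lr 3e-4), 8 fine-tuning epochs (lr 2e-4), and IG with 16 path
steps over a seeded subset of 250 sequences per class. These sizes were
chosen as the smallest round numbers at which the study's read-outs are
stable across seeds; all are arguments of
`m6adeg.pipeline.run_planted_motif_study`.

## Known limitations

- Full-scale pre-training (hundreds of thousands of 501-nt windows, 12×768
  geometry, >100k steps) is architecturally supported but far outside what
  the NumPy implementation is meant for; published-scale performance numbers
  are not reproducible here and are not claimed.
- The greedy clustering is O(n²) pairwise; fine for thousands of windows,
  not for millions.
- `overlap_sites` requires sites and intervals to share a coordinate system
  and errs on the side of returning nothing (with a warning) when their ids
  are disjoint.
- Checkpoints are NumPy `.npz` archives tied to this implementation; there
  is no interchange with framework checkpoint formats.
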