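# m6adeg

Predicting YTHDF2-mediated degradation of m⁶A-methylated mRNAs from sequence,
and interpreting what the model learned.

N6-methyladenosine (m⁶A) is the most abundant internal mRNA modification. The
reader protein YTHDF2 binds methylated sites and recruits decay machinery —
yet most YTHDF2-bound transcripts are *not* degraded. `m6adeg` is a toolkit
for studying this selectivity: it trains a k-mer-tokenized BERT-style
transformer to classify whether the 501-nt sequence window around a
YTHDF2-bound m⁶A site regulates mRNA decay, then interrogates the trained
model with integrated gradients to find the sequence elements — candidate
co-factor RBP binding motifs — that drive the distinction.

It is aimed at computational epitranscriptomics researchers who have
single-base m⁶A site calls, RBP binding intervals (e.g. PAR-CLIP) and
half-life measurements, and want a fully reproducible, CPU-sized
implementation of the whole workflow, including a synthetic planted-motif
cohort generator for validating every stage against known ground truth.

## Method

**Dataset assembly.** m⁶A sites overlapping YTHDF2 binding intervals are
labeled *positive* (decay-regulating) when their gene's mRNA half-life
log₂(knockdown/control) fold change exceeds 1 and the site lies in the CDS or
3′UTR (5′UTR sites of stabilized genes are excluded: 5′UTR binding is linked
to translation, not decay); all other bound sites are negative. Each site is
extended ±250 nt (trimmed at transcript ends), redundant windows are removed
per class by greedy clustering at 90 % identity (CD-HIT's short-sequence
convention), negatives are downsampled to balance, and the set is split
70/20/10 into train/test/validation, stratified by label.

**Model.** Windows are tokenized into overlapping k-mers (K ∈ {3,4,5,6})
framed as `[CLS] k-mers… [PAD]… [SEP]`, padded to a fixed 501-token input. A
transformer encoder (the published geometry is 12 layers × 768 hidden × 12
heads; desk-scale defaults are much smaller) is pre-trained with masked
language modelling — 15 % of real tokens masked until convergence, then 20 %
for a final stretch, masking K contiguous tokens per selection so overlapping
k-mers cannot leak the hidden base — then fine-tuned with a binary head on
the `[CLS]` vector, keeping the epoch with the best validation AUC.
Performance is reported as ACC, AUC, MCC, precision and recall, with 5-fold
cross-validation support. The encoder, its backpropagation and the optimizer
are implemented in NumPy, so the package runs anywhere on CPU.

**Interpretation.** Integrated gradients attribute the classifier's logit to
each token along the straight embedding-space path from an all-`[PAD]`
reference (IG(x) = (x−x_ref)·∫₀¹ ∂F/∂x dα, midpoint rule); attributions
satisfy the completeness axiom Σᵢ IGᵢ = F(x) − F(x_ref), which is verified
numerically. Token scores are averaged onto nucleotides through the k-mer
coverage map; maximal runs of above-average nucleotides (≥ 5 nt) become
high-attribution regions; region substrings are tested for set enrichment
with a one-sided hypergeometric tail test (BH-adjusted, candidates occurring
< 5 times excluded) and exported as centered 24-nt FASTA windows for TOMTOM;
RBP tracks are tested per protein for enrichment of binding inside
high-attribution regions of positive vs. negative sequences with one-sided
Fisher exact tests.

## Worked example

Run the miniature planted-motif study — a synthetic cohort of 1,000 sites
(201-nt windows) where an AU-rich stability element `TATTTA` is planted ~80 nt
upstream of the m⁶A center in 90 % of negative sequences, a 2-layer/64-hidden
encoder is pre-trained and fine-tuned, and the interpretation stack is asked
to rediscover the plant:

```python
from m6adeg.pipeline import run_planted_motif_study

res = run_planted_motif_study(seed=1)
print(f"held-out AUC        {res.test_auc:.3f}")
print(f"attribution peak    {res.peak_offset} nt (planted at -80)")
print(f"top motif candidate {res.planted_motif_hits[0].motif} "
      f"adj. p = {res.planted_motif_hits[0].adjusted_p:.2e}")
e = res.enrichment[0]
print(f"RBP enrichment      {e.rbp} {e.direction} adj. p = {e.adjusted_p:.2e}")
```

```
held-out AUC        0.890
attribution peak    -82 nt (planted at -80)
top motif candidate TATTTA adj. p = 3.29e-59
RBP enrichment      STABRBP1 negative-enriched adj. p = 4.65e-63
```

The classifier separates the classes on held-out data; the column-mean of the
per-nucleotide attribution over negative sequences peaks at the planted
offset; the hypergeometric test recovers the planted 6-mer from
high-attribution regions; and the matched synthetic RBP track is flagged as
significantly enriched in negative (non-degraded) sequences — the same
read-out that, on real data, points to stabilizing co-factors such as HuR or
HNRNPC disrupting YTHDF2-mediated decay.

The same workflow is available as a CLI over files
(FASTA/BED/TSV in, TSV/BED/FASTA out):

```bash
m6adeg simulate --out sim --seed 1
m6adeg build-dataset --transcripts sim/transcripts.fa --sites sim/sites.tsv \
    --bindings sim/ythdf2.bed --half-life sim/half_life.tsv --out ds
m6adeg pretrain --dataset ds --out pre.npz
m6adeg finetune --dataset ds --checkpoint pre.npz --out clf.npz
m6adeg evaluate --dataset ds --checkpoint clf.npz --out metrics.tsv
m6adeg interpret --dataset ds --checkpoint clf.npz --rbp-bed sim/rbp.bed --out interp
```

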