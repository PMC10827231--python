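"""Model interpretation: attribution, motif discovery, RBP enrichment.

Integrated gradients (IG) attribute the classifier's positive-class logit to
each input token by integrating the gradient along the straight line in
embedding space from a reference input (all-[PAD] body framed by [CLS] and
[SEP]) to the actual input:

    IG_i(x) = (x_i - x_ref_i) * integral_0^1 dF/dx_i (x_ref + a (x - x_ref)) da

approximated with a midpoint Riemann rule over ``n_steps``.  IG satisfies the
completeness axiom — attributions sum to F(x) - F(x_ref) — which is checked
via the recorded ``completeness_gap``.

Token scores are averaged down to nucleotides through the k-mer coverage map,
contiguous runs of above-average nucleotides become high-attribution regions,
region subsequences are tested for set enrichment with a hypergeometric tail
test (BH-adjusted), and RBP binding tracks are tested for sequence-level
enrichment in high-attribution regions with one-sided Fisher exact tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

from m6adeg.io import BindingInterval
from m6adeg.nn import TransformerEncoder
from m6adeg.tokenizer import KmerVocabulary, TokenizedSequence

logger = logging.getLogger(__name__)

DEFAULT_N_STEPS = 50
DEFAULT_MIN_REGION_LEN = 5
DEFAULT_MIN_MOTIF_COUNT = 5
DEFAULT_ALPHA = 0.05
DEFAULT_MOTIF_WINDOW = 24


@dataclass(frozen=True)
class AttributionProfile:
    """Per-token and per-nucleotide IG scores for one sequence."""

    sequence_id: str
    token_scores: np.ndarray  # length n_kmers
    nt_scores: np.ndarray  # length source_length
    n_steps: int
    reference_id: str
    completeness_gap: float  # |sum(attr) - (F(x) - F(x_ref))|


@dataclass(frozen=True)
class HighAttributionRegion:
    """A maximal run of nucleotides scoring strictly above the sequence mean."""

    sequence_id: str
    start: int  # 0-based half-open, window-local nucleotide coordinates
    end: int
    mean_score: float
    subsequence: str


@dataclass(frozen=True)
class MotifCandidate:
    """A candidate substring with its enrichment counts and p-values.

    Counts: ``k_in_set`` occurrences in the query set, ``K_set`` total
    candidate occurrences in the query set, ``n_motif`` occurrences of this
    string among all candidates, ``N_total`` candidate occurrences overall.
    """

    motif: str
    k_in_set: int
    K_set: int
    n_motif: int
    N_total: int
    p_value: float
    adjusted_p: float


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher 2x2 result for one RBP and one direction."""

    rbp: str
    a: int  # positives with binding in a high-attribution region
    b: int  # positives without
    c: int  # negatives with
    d: int  # negatives without
    odds_ratio: float
    p_value: float
    adjusted_p: float
    direction: Literal["positive-enriched", "negative-enriched"]


# ------------------------------------------------------------------ IG core

def _reference_ids(tok: TokenizedSequence, vocab: KmerVocabulary) -> np.ndarray:
    """All-[PAD] body with [CLS]/[SEP] framing, same length as the input."""
    ref = np.full(len(tok.ids), vocab.pad_id, dtype=np.int64)
    ref[0] = vocab.cls_id
    ref[-1] = vocab.sep_id
    return ref


def integrated_gradients(
    model: TransformerEncoder,
    tok: TokenizedSequence,
    vocab: KmerVocabulary,
    n_steps: int = DEFAULT_N_STEPS,
    batch_steps: int = 25,
) -> tuple[np.ndarray, float]:
    """Per-token IG scores of the positive-class logit, and the completeness gap.

    The path runs in embedding space from the [PAD]-reference embedding to the
    input embedding; the attention mask is that of the *input* and is held
    fixed along the path (the endpoint values F(x), F(x_ref) use it too, so
    completeness is well defined).  Midpoint rule: gradients are evaluated at
    alpha = (s + 0.5)/n_steps for s = 0..n_steps-1.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    ids = np.array(tok.ids, dtype=np.int64)[None, :]
    ref = _reference_ids(tok, vocab)[None, :]
    bias = model.attention_bias(ids, vocab.pad_id)
    x = model.embed(ids)
    x_ref = model.embed(ref)
    diff = x - x_ref
    grad_sum = np.zeros_like(x, dtype=np.float64)
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    for lo in range(0, n_steps, batch_steps):
        chunk = alphas[lo : lo + batch_steps]
        h0 = x_ref + chunk[:, None, None] * diff  # (S,T,H) batch over path steps
        _, dh0 = model.cls_logit_grad_wrt_embeddings(
            h0.astype(model.dtype), np.repeat(bias, len(chunk), axis=0)
        )
        grad_sum += dh0.sum(axis=0, dtype=np.float64)
    avg_grad = grad_sum / n_steps
    attr = (diff.astype(np.float64) * avg_grad)[0].sum(axis=-1)  # (T,)
    z_x, _ = model.cls_logit_from_embeddings(x, bias)
    z_ref, _ = model.cls_logit_from_embeddings(x_ref, bias)
    gap = float(abs(attr.sum() - (float(z_x[0]) - float(z_ref[0]))))
    token_scores = attr[1 : 1 + tok.n_kmers]
    return token_scores, gap


def aggregate_to_nucleotides(
    token_scores: np.ndarray, coverage: Sequence[Sequence[int]], K: int
) -> np.ndarray:
    """Average token scores over the tokens covering each nucleotide.

    ``coverage[i]`` lists token *positions* (1-based within ids, as stored on
    TokenizedSequence) covering nucleotide i; token_scores is indexed by k-mer
    number (position - 1).
    """
    nt = np.empty(len(coverage), dtype=float)
    for i, toks in enumerate(coverage):
        if not 1 <= len(toks) <= K:
            raise ValueError(f"nucleotide {i} covered by {len(toks)} tokens, expected 1..{K}")
        vals = [token_scores[t - 1] for t in toks]
        nt[i] = sum(vals) / len(vals)
    return nt


def attribute_sequence(
    model: TransformerEncoder,
    tok: TokenizedSequence,
    vocab: KmerVocabulary,
    sequence_id: str = "",
    n_steps: int = DEFAULT_N_STEPS,
    target_label: int = 1,
) -> AttributionProfile:
    """IG token scores + nucleotide aggregation for one tokenized sequence.

    ``target_label`` selects the class whose evidence is scored.  The path
    integral itself targets the positive-class logit z; because the binary
    head has a single logit, attribution toward the negative class is exactly
    its negation, so scoring a negative sequence toward its own class is a
    sign flip.  This keeps "high attribution" meaning "supports this
    sequence's class" in both sets, which is what the region caller and the
    motif tests consume.
    """
    token_scores, gap = integrated_gradients(model, tok, vocab, n_steps=n_steps)
    if target_label == 0:
        token_scores = -token_scores
    nt = aggregate_to_nucleotides(token_scores, tok.coverage, vocab.K)
    return AttributionProfile(
        sequence_id=sequence_id,
        token_scores=token_scores,
        nt_scores=nt,
        n_steps=n_steps,
        reference_id="[CLS] + [PAD]*n + [SEP]",
        completeness_gap=gap,
    )


# ----------------------------------------------------------- region calling

def call_high_regions(
    nt_scores: np.ndarray,
    sequence: str,
    sequence_id: str = "",
    min_region_len: int = DEFAULT_MIN_REGION_LEN,
    threshold: float | None = None,
) -> list[HighAttributionRegion]:
    """Maximal runs of nucleotides scoring strictly above the mean.

    ``threshold`` defaults to the arithmetic mean of this sequence's scores;
    pass a global mean to threshold across samples instead.  A constant score
    vector yields no regions (nothing is strictly above its own mean).
    """
    s = np.asarray(nt_scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score vector")
    thr = float(s.mean()) if threshold is None else float(threshold)
    above = s > thr
    regions: list[HighAttributionRegion] = []
    i = 0
    n = len(s)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_region_len:
                regions.append(
                    HighAttributionRegion(
                        sequence_id=sequence_id,
                        start=i,
                        end=j + 1,
                        mean_score=float(s[i : j + 1].mean()),
                        subsequence=sequence[i : j + 1],
                    )
                )
            i = j + 1
        else:
            i += 1
    return regions


# ------------------------------------------------------------ motif testing

def hypergeometric_motif_test(
    query_regions: Sequence[HighAttributionRegion],
    other_regions: Sequence[HighAttributionRegion],
    min_count: int = DEFAULT_MIN_MOTIF_COUNT,
    alpha: float = DEFAULT_ALPHA,
) -> list[MotifCandidate]:
    """Hypergeometric enrichment of candidate strings in the query set.

    Each high-attribution region contributes one candidate occurrence of its
    exact subsequence.  For a string m, with N total occurrences overall, K
    occurrences in the query set, n occurrences of m overall and k of them in
    the query set, the one-sided upper-tail p-value is P(X >= k) for
    X ~ Hypergeometric(N, n, K).  Strings with n < ``min_count`` are excluded;
    p-values are BH-adjusted across all tested strings and candidates with
    adjusted p < ``alpha`` are returned sorted by adjusted p (ties: by p, then
    lexicographically).
    """
    if not query_regions:
        return []
    q = [r.subsequence for r in query_regions]
    o = [r.subsequence for r in other_regions]
    K_set = len(q)
    N_total = len(q) + len(o)
    from collections import Counter

    in_q = Counter(q)
    overall = Counter(q) + Counter(o)
    motifs = sorted(m for m, n in overall.items() if n >= min_count)
    if not motifs:
        return []
    pvals = []
    for m in motifs:
        n_m = overall[m]
        k = in_q.get(m, 0)
        # upper tail P(X >= k) = sf(k-1); hypergeom(M=N, n=n_m, N=K_set)
        pvals.append(float(hypergeom.sf(k - 1, N_total, n_m, K_set)))
    rejected, adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out = [
        MotifCandidate(
            motif=m,
            k_in_set=in_q.get(m, 0),
            K_set=K_set,
            n_motif=overall[m],
            N_total=N_total,
            p_value=p,
            adjusted_p=float(ap),
        )
        for m, p, ap, rej in zip(motifs, pvals, adj, rejected)
        if rej
    ]
    out.sort(key=lambda c: (c.adjusted_p, c.p_value, c.motif))
    return out


def extract_motif_windows(
    sequence: str, motif_start: int, motif_len: int, width: int = DEFAULT_MOTIF_WINDOW
) -> str:
    """``width``-nt window centered on the motif midpoint, clipped at the ends."""
    center = motif_start + motif_len / 2
    lo = int(round(center - width / 2))
    hi = lo + width
    lo_c, hi_c = max(0, lo), min(len(sequence), hi)
    if hi_c - lo_c < width:
        logger.info(
            "motif window clipped to %d nt at sequence edge (requested %d)",
            hi_c - lo_c, width,
        )
    return sequence[lo_c:hi_c]


# ---------------------------------------------------------- RBP enrichment

def rbp_enrichment(
    regions_by_sequence: Mapping[str, Sequence[HighAttributionRegion]],
    labels_by_sequence: Mapping[str, int],
    rbp_tracks: Sequence[BindingInterval],
    region_offsets: Mapping[str, tuple[str, int]] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Sequence-level Fisher enrichment of RBP binding in high-attribution regions.

    A sequence "has" an RBP iff any of that protein's intervals overlaps any
    of its high-attribution regions by at least one base.  ``region_offsets``
    maps a sequence id to ``(track_seq_id, window_start)`` translating
    window-local region coordinates into the coordinate space of the BED
    track; by default regions are matched against intervals whose seq_id
    equals the sequence id with no shift.

    Per protein, a 2x2 table over positive/negative sequences is tested with
    both one-sided Fisher exact tests; BH adjustment runs across proteins x
    directions and significant directions (adjusted p < ``alpha``) are
    returned sorted by adjusted p.
    """
    by_protein: dict[str, dict[str, list[BindingInterval]]] = {}
    for iv in rbp_tracks:
        by_protein.setdefault(iv.protein, {}).setdefault(iv.seq_id, []).append(iv)

    seq_ids = sorted(regions_by_sequence)
    n_pos = sum(1 for s in seq_ids if labels_by_sequence[s] == 1)
    n_neg = len(seq_ids) - n_pos

    tests: list[tuple[str, str, tuple[int, int, int, int], float, float]] = []
    for protein in sorted(by_protein):
        tracks = by_protein[protein]
        if not any(tracks.values()):
            logger.warning("protein %s has no mapped intervals; skipped", protein)
            continue
        a = b = c = d = 0
        for sid in seq_ids:
            if region_offsets is not None:
                track_id, shift = region_offsets[sid]
            else:
                track_id, shift = sid, 0
            has = False
            for reg in regions_by_sequence[sid]:
                lo, hi = reg.start + shift, reg.end + shift
                if any(iv.start < hi and lo < iv.end for iv in tracks.get(track_id, ())):
                    has = True
                    break
            if labels_by_sequence[sid] == 1:
                a += has
                b += not has
            else:
                c += has
                d += not has
        table = [[a, b], [c, d]]
        odds = (a * d) / (b * c) if b * c else float("inf") if a * d else float("nan")
        p_pos = float(fisher_exact(table, alternative="greater")[1])
        p_neg = float(fisher_exact(table, alternative="less")[1])
        tests.append((protein, "positive-enriched", (a, b, c, d), odds, p_pos))
        tests.append((protein, "negative-enriched", (a, b, c, d), odds, p_neg))

    if not tests:
        return []
    pvals = [t[4] for t in tests]
    rejected, adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out = []
    for (protein, direction, (a, b, c, d), odds, p), ap, rej in zip(tests, adj, rejected):
        if rej:
            out.append(
                EnrichmentResult(
                    rbp=protein, a=a, b=b, c=c, d=d,
                    odds_ratio=odds, p_value=p, adjusted_p=float(ap),
                    direction=direction,
                )
            )
    assert all(r.a + r.b == n_pos and r.c + r.d == n_neg for r in out)
    out.sort(key=lambda r: (r.adjusted_p, r.p_value, r.rbp))
    return out


# ------------------------------------------------------- position-wise view

def positionwise_attribution_matrix(
    profiles: Sequence[AttributionProfile],
    center_offsets: Sequence[int],
    flank: int = 250,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align nucleotide scores on the m6A center.

    Returns ``(matrix, positions, column_mean)``: matrix has one row per
    profile and 2*flank+1 columns indexed -flank..+flank relative to the m6A
    base; positions trimmed away at transcript ends are NaN gaps, and
    ``column_mean`` is the NaN-ignoring per-position mean used to locate
    attribution peaks.
    """
    n_cols = 2 * flank + 1
    mat = np.full((len(profiles), n_cols), np.nan)
    for row, (prof, off) in enumerate(zip(profiles, center_offsets)):
        start_col = flank - off
        mat[row, start_col : start_col + len(prof.nt_scores)] = prof.nt_scores
    positions = np.arange(-flank, flank + 1)
    import warnings

    with warnings.catch_warnings():
        # columns with no observations (all windows trimmed there) are NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_mean = np.nanmean(mat, axis=0)
    return mat, positions, col_mean
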