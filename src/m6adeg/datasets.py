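"""Assembly of labeled m6A site windows for degradation classification.

Starting from transcript sequences, single-base m6A site coordinates, YTHDF2
binding intervals and a per-gene mRNA half-life log2 fold-change table
(knockdown vs control), the builder

1. keeps sites overlapping a YTHDF2 binding interval,
2. labels a site *positive* (regulates decay) when its gene's half-life
   log2FC is strictly greater than the threshold (default 1.0) and the site
   lies in the CDS or 3'UTR — 5'UTR sites of such genes are discarded because
   5'UTR binding is linked to translation, not decay; everything else is
   negative,
3. extracts a window of ±250 nt around each site (trimmed at transcript ends),
4. removes redundant sequences within each class by greedy clustering at 90%
   identity, and
5. balances classes by sampling the negatives.

All coordinates are transcript-space, 0-based; BED intervals are half-open.
Genome-to-transcript projection must happen upstream.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

from m6adeg.io import BindingInterval

logger = logging.getLogger(__name__)

Region = Literal["5UTR", "CDS", "3UTR", "unknown"]

DEFAULT_FLANK = 250
DEFAULT_IDENTITY_CUTOFF = 0.90
DEFAULT_LOG2FC_THRESHOLD = 1.0


class CoordinateError(ValueError):
    """A site falls outside its transcript."""


@dataclass(frozen=True)
class SiteRecord:
    """A single-base m6A site in transcript coordinates (0-based)."""

    transcript_id: str
    position: int
    gene_id: str
    region: Region = "unknown"
    site_id: str = ""

    def with_id(self, site_id: str) -> "SiteRecord":
        return replace(self, site_id=site_id)


@dataclass(frozen=True)
class HalfLifeRecord:
    """Averaged log2(knockdown/control) half-life fold change for one gene."""

    gene_id: str
    log2fc: float


@dataclass(frozen=True)
class LabeledSite:
    """An m6A site with its extracted window and degradation label."""

    site: SiteRecord
    window_seq: str
    window_start: int  # transcript coordinate of window_seq[0]
    center_offset: int  # index of the m6A base within window_seq
    label: int  # 1 = regulates degradation (positive), 0 = negative


def extract_site_window(
    transcript_seq: str, site: SiteRecord, flank: int = DEFAULT_FLANK
) -> tuple[str, int]:
    """Extract the window of ±``flank`` nt around the site (trimmed at ends).

    Returns ``(window_seq, center_offset)`` where ``center_offset`` is the
    index of the m6A base within the window. A full window has length
    ``2*flank + 1``.
    """
    p, L = site.position, len(transcript_seq)
    if not 0 <= p < L:
        raise CoordinateError(
            f"site {site.site_id or site.transcript_id}:{p} outside transcript "
            f"of length {L}"
        )
    start = max(0, p - flank)
    end = min(L, p + flank + 1)
    return transcript_seq[start:end], p - start


def validate_site(transcript_seq: str, site: SiteRecord) -> bool:
    """Check the transcript base at the site is A; warn-and-keep otherwise."""
    base = transcript_seq[site.position]
    if base != "A":
        logger.warning(
            "site %s at %s:%d is %r, not A; keeping",
            site.site_id, site.transcript_id, site.position, base,
        )
        return False
    return True


def overlap_sites(
    sites: Sequence[SiteRecord], bindings: Sequence[BindingInterval]
) -> list[SiteRecord]:
    """Keep sites whose position lies within any binding interval (half-open).

    Preserves input order. If the two inputs share no sequence ids at all the
    coordinate systems probably differ; a warning is logged and the result is
    empty.
    """
    by_id: dict[str, list[BindingInterval]] = {}
    for iv in bindings:
        by_id.setdefault(iv.seq_id, []).append(iv)
    if sites and bindings and not ({s.transcript_id for s in sites} & by_id.keys()):
        logger.warning(
            "no shared sequence ids between sites and binding intervals; "
            "check that both are transcript-space"
        )
        return []
    kept = []
    for s in sites:
        if any(iv.contains(s.position) for iv in by_id.get(s.transcript_id, ())):
            kept.append(s)
    return kept


def label_sites(
    sites: Sequence[SiteRecord],
    half_life: Sequence[HalfLifeRecord],
    threshold: float = DEFAULT_LOG2FC_THRESHOLD,
    missing_gene_policy: Literal["negative", "drop"] = "negative",
) -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Split sites into (positives, negatives) by half-life fold change.

    A site is positive iff its gene's log2FC is strictly > ``threshold`` AND
    its region is CDS or 3'UTR.  Sites in the 5'UTR of such stabilized genes
    are discarded entirely.  Sites of all other genes are negative; genes
    absent from the half-life table follow ``missing_gene_policy`` (default:
    negative, with a warning).
    """
    fc = {}
    for rec in half_life:
        if rec.gene_id in fc:
            raise ValueError(f"gene {rec.gene_id} appears twice in half-life table")
        fc[rec.gene_id] = rec.log2fc
    positives: list[SiteRecord] = []
    negatives: list[SiteRecord] = []
    n_missing = 0
    for s in sites:
        if s.gene_id not in fc:
            n_missing += 1
            if missing_gene_policy == "negative":
                negatives.append(s)
            continue
        if fc[s.gene_id] > threshold:
            if s.region in ("CDS", "3UTR"):
                positives.append(s)
            # 5'UTR (and unknown-region) sites of stabilized genes are dropped
        else:
            negatives.append(s)
    if n_missing:
        logger.warning(
            "%d site(s) in genes absent from the half-life table routed per "
            "policy %r", n_missing, missing_gene_policy,
        )
    return positives, negatives


def _as_bytes(s: str):
    import numpy as np

    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _identity_arr(a, b) -> float:
    """Ungapped sliding identity of the shorter sequence against the longer,
    divided by the shorter length (CD-HIT's short-sequence convention).
    Operates on uint8 arrays for speed; exact, no word-filter heuristics."""
    import numpy as np

    if len(a) > len(b):
        a, b = b, a
    la, lb = len(a), len(b)
    best = 0
    for off in range(lb - la + 1):
        m = int(np.count_nonzero(a == b[off : off + la]))
        if m > best:
            best = m
            if best == la:
                break
    return best / la


def _identity(a: str, b: str) -> float:
    return _identity_arr(_as_bytes(a), _as_bytes(b))


def dedup_sequences(
    seqs: Sequence[str], identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF
) -> list[str]:
    """Greedy longest-first redundancy removal at the given identity cutoff.

    Sequences are visited longest first (ties: input order); a sequence joins
    the first existing cluster whose representative it matches at >= cutoff
    identity, otherwise it founds a new cluster.  Returns the representatives
    in founding order.  Exact at desk scale — no word-filter heuristics.
    """
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    arrs = {i: _as_bytes(seqs[i]) for i in order}
    reps: list[int] = []
    for i in order:
        if not any(_identity_arr(arrs[i], arrs[j]) >= identity_cutoff for j in reps):
            reps.append(i)
    return [seqs[i] for i in reps]


def dedup_labeled(
    labeled: Sequence[LabeledSite], identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF
) -> list[LabeledSite]:
    """Greedy redundancy removal over LabeledSites, keeping one per cluster."""
    order = sorted(range(len(labeled)), key=lambda i: (-len(labeled[i].window_seq), i))
    arrs = {i: _as_bytes(labeled[i].window_seq) for i in order}
    reps: list[int] = []
    for i in order:
        if not any(_identity_arr(arrs[i], arrs[j]) >= identity_cutoff for j in reps):
            reps.append(i)
    return [labeled[i] for i in reps]


def balance_classes(negatives: Sequence, n: int, seed: int) -> list:
    """Uniform sample of ``n`` items without replacement, seeded."""
    if n > len(negatives):
        raise ValueError(f"cannot sample {n} from {len(negatives)} negatives")
    rng = random.Random(seed)
    return rng.sample(list(negatives), n)


def split_dataset(
    labeled: Sequence[LabeledSite],
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> tuple[list[LabeledSite], list[LabeledSite], list[LabeledSite]]:
    """Stratified train/test/validation split.

    Per class, partition sizes are round(f*n) for test and validation with the
    remainder going to train; the three parts are disjoint and exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = random.Random(seed)
    train: list[LabeledSite] = []
    test: list[LabeledSite] = []
    val: list[LabeledSite] = []
    for label in (0, 1):
        group = [s for s in labeled if s.label == label]
        if not group:
            continue
        if len(group) < 10:
            logger.warning("only %d samples with label %d; stratification is thin", len(group), label)
        rng.shuffle(group)
        n = len(group)
        n_test = round(fractions[1] * n)
        n_val = round(fractions[2] * n)
        test.extend(group[:n_test])
        val.extend(group[n_test : n_test + n_val])
        train.extend(group[n_test + n_val :])
    return train, test, val


def build_labeled_windows(
    transcripts: dict[str, str],
    sites: Sequence[SiteRecord],
    bindings: Sequence[BindingInterval],
    half_life: Sequence[HalfLifeRecord],
    *,
    flank: int = DEFAULT_FLANK,
    threshold: float = DEFAULT_LOG2FC_THRESHOLD,
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
    balance: bool = True,
    seed: int = 0,
) -> list[LabeledSite]:
    """Full dataset-construction pipeline; returns the final labeled windows.

    Order of operations: YTHDF2-overlap filter -> half-life labeling (with
    5'UTR exclusion) -> window extraction -> per-class redundancy removal ->
    optional negative downsampling to the positive count.
    """
    bound = overlap_sites(sites, bindings)
    positives, negatives = label_sites(bound, half_life, threshold=threshold)

    def windows(records: Iterable[SiteRecord], label: int) -> list[LabeledSite]:
        out = []
        for s in records:
            seq = transcripts[s.transcript_id]
            validate_site(seq, s)
            w, off = extract_site_window(seq, s, flank=flank)
            out.append(
                LabeledSite(
                    site=s,
                    window_seq=w,
                    window_start=s.position - off,
                    center_offset=off,
                    label=label,
                )
            )
        return out

    pos = dedup_labeled(windows(positives, 1), identity_cutoff)
    neg = dedup_labeled(windows(negatives, 0), identity_cutoff)
    if balance and len(neg) > len(pos):
        neg = balance_classes(neg, len(pos), seed)
    logger.info("built %d positive and %d negative windows", len(pos), len(neg))
    return pos + neg
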