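"""Overlapping k-mer tokenization of nucleotide sequences.

A sequence of length L is rendered as its L-K+1 overlapping k-mers (sliding
window, step 1), framed as ``[CLS] kmer_1 ... kmer_{L-K+1} [PAD]* [SEP]`` and
padded to a fixed model input length.  Note the pad placement: [PAD] tokens sit
*between* the last real k-mer and the terminal [SEP]; attention masks built
elsewhere must honour this layout.

Because k-mers overlap, each nucleotide is covered by up to K tokens; the
coverage map recorded on every :class:`TokenizedSequence` drives the
aggregation of per-token attribution scores back to single nucleotides.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "SPECIAL_TOKENS",
    "CLS",
    "SEP",
    "MASK",
    "PAD",
    "UNK",
    "TokenizerConfig",
    "KmerVocabulary",
    "TokenizedSequence",
    "build_vocab",
    "kmerize",
    "encode",
    "decode",
]

CLS = "[CLS]"
SEP = "[SEP]"
MASK = "[MASK]"
PAD = "[PAD]"
UNK = "[UNK]"
#: Special tokens, in vocabulary order (before the k-mers).
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP, MASK)

_DNA = "ACGT"


class TokenizationError(ValueError):
    """Raised on invalid tokenizer input (bad alphabet, bad length, bad K)."""


@dataclass(frozen=True)
class TokenizerConfig:
    """Tokenizer settings.

    Parameters
    ----------
    K : int
        k-mer length; one of 3, 4, 5, 6.
    max_tokens : int
        Total model input length including [CLS] and [SEP] (default 501).
    alphabet : str
        Nucleotide alphabet; must be the 4 DNA letters.
    """

    K: int = 3
    max_tokens: int = 501
    alphabet: str = _DNA

    def __post_init__(self) -> None:
        if self.K not in (3, 4, 5, 6):
            raise TokenizationError(f"K must be in {{3,4,5,6}}, got {self.K}")
        if self.max_tokens <= 2:
            raise TokenizationError("max_tokens must leave room for [CLS]/[SEP]")
        if sorted(self.alphabet) != sorted(_DNA):
            raise TokenizationError(f"alphabet must be the DNA letters ACGT, got {self.alphabet!r}")

    @property
    def max_seq_len(self) -> int:
        """Longest nucleotide sequence encodable: max_tokens-2 k-mers."""
        return self.max_tokens - 2 + self.K - 1


@dataclass(frozen=True)
class KmerVocabulary:
    """Mapping between k-mer/special tokens and contiguous integer ids.

    Specials occupy ids 0..4 ([PAD],[UNK],[CLS],[SEP],[MASK]); the 4**K k-mers
    follow in lexicographic order, so the vocabulary is identical across runs
    and platforms.
    """

    K: int
    token_to_id: dict[str, int]
    id_to_token: tuple[str, ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __getitem__(self, token: str) -> int:
        return self.token_to_id[token]

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def sep_id(self) -> int:
        return self.token_to_id[SEP]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(self.token_to_id[t] for t in SPECIAL_TOKENS)

    @property
    def first_kmer_id(self) -> int:
        return len(SPECIAL_TOKENS)

    def save(self, path) -> None:
        """Write the vocabulary as token<TAB>id text."""
        with open(path, "w") as fh:
            for tok, idx in self.token_to_id.items():
                fh.write(f"{tok}\t{idx}\n")

    @classmethod
    def load(cls, path) -> "KmerVocabulary":
        token_to_id: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                tok, idx = line.rstrip("\n").split("\t")
                token_to_id[tok] = int(idx)
        K = max(len(t) for t in token_to_id if t not in SPECIAL_TOKENS)
        id_to_token = tuple(t for t, _ in sorted(token_to_id.items(), key=lambda kv: kv[1]))
        return cls(K=K, token_to_id=token_to_id, id_to_token=id_to_token)


@dataclass(frozen=True)
class TokenizedSequence:
    """A fixed-length encoded sequence plus its nucleotide coverage map.

    Attributes
    ----------
    ids : tuple[int, ...]
        Token ids, length exactly ``max_tokens``; ids[0] is [CLS], ids[-1] is
        [SEP], pads (if any) sit between the last k-mer and [SEP].
    n_kmers : int
        Number of real (k-mer) tokens, ``source_length - K + 1``.
    coverage : tuple[tuple[int, ...], ...]
        For nucleotide i, the token positions (indices into ``ids``) of the
        k-mers covering it; between 1 and K entries each.
    source_length : int
        Nucleotide length of the encoded sequence.
    """

    ids: tuple[int, ...]
    n_kmers: int
    coverage: tuple[tuple[int, ...], ...]
    source_length: int


def build_vocab(config: TokenizerConfig) -> KmerVocabulary:
    """Build the deterministic vocabulary of 4**K k-mers plus 5 specials."""
    tokens = list(SPECIAL_TOKENS) + [
        "".join(p) for p in itertools.product(_DNA, repeat=config.K)
    ]
    token_to_id = {t: i for i, t in enumerate(tokens)}
    return KmerVocabulary(K=config.K, token_to_id=token_to_id, id_to_token=tuple(tokens))


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - set(_DNA)
    if bad:
        raise TokenizationError(
            f"sequence contains non-ACGT character(s) {sorted(bad)}; "
            "map U->T and filter ambiguous bases upstream"
        )


def kmerize(seq: str, K: int) -> list[str]:
    """Slide a window of length K over ``seq``, step 1, left to right."""
    if len(seq) < K:
        raise TokenizationError(f"sequence length {len(seq)} < K={K}: no k-mers")
    _check_alphabet(seq)
    return [seq[i : i + K] for i in range(len(seq) - K + 1)]


def encode(seq: str, vocab: KmerVocabulary, config: TokenizerConfig) -> TokenizedSequence:
    """Encode a nucleotide sequence to a fixed-length token id vector.

    Layout: ``[CLS] k-mers... [PAD]... [SEP]`` of total length
    ``config.max_tokens``.  Raises if the sequence is too long to fit — the
    dataset builder, not the tokenizer, is responsible for trimming windows.
    """
    if config.K != vocab.K:
        raise TokenizationError(f"config K={config.K} != vocab K={vocab.K}")
    kmers = kmerize(seq, config.K)
    n_kmers = len(kmers)
    if n_kmers > config.max_tokens - 2:
        raise TokenizationError(
            f"{len(seq)} nt yields {n_kmers} k-mers > {config.max_tokens - 2} slots"
        )
    n_pad = config.max_tokens - 2 - n_kmers
    ids = (
        [vocab.cls_id]
        + [vocab.token_to_id[k] for k in kmers]
        + [vocab.pad_id] * n_pad
        + [vocab.sep_id]
    )
    # token position of k-mer j is j+1 ([CLS] shift); k-mer j covers
    # nucleotides j..j+K-1, so nucleotide i is covered by k-mers
    # max(0, i-K+1)..min(i, n_kmers-1).
    K = config.K
    coverage = tuple(
        tuple(range(max(0, i - K + 1) + 1, min(i, n_kmers - 1) + 2))
        for i in range(len(seq))
    )
    return TokenizedSequence(
        ids=tuple(ids), n_kmers=n_kmers, coverage=coverage, source_length=len(seq)
    )


def decode(tok: TokenizedSequence, vocab: KmerVocabulary) -> str:
    """Reconstruct the nucleotide sequence from the k-mer body.

    Uses the first k-mer plus the last letter of each subsequent k-mer, after
    verifying that every overlap is consistent; a masked or substituted token
    breaks an overlap and raises with the first conflicting position.
    """
    body = [vocab.id_to_token[i] for i in tok.ids[1 : 1 + tok.n_kmers]]
    if not body:
        return ""
    for kmer in body:
        if kmer in SPECIAL_TOKENS:
            raise TokenizationError(
                f"cannot decode: special token {kmer} in k-mer body"
            )
    seq = body[0]
    for j, kmer in enumerate(body[1:], start=1):
        if kmer[:-1] != seq[j:]:
            raise TokenizationError(
                f"inconsistent k-mer overlap at nucleotide {j}: "
                f"{kmer[:-1]!r} vs {seq[j:]!r}"
            )
        seq += kmer[-1]
    return seq
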