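"""Readers/writers for FASTA, BED and the pipeline's TSV tables.

All sequences are held internally as uppercase DNA (U/u mapped to T/t on
ingest).  Interval formats are BED-style 0-based half-open.  Tabular outputs
are TSV with a comment header recording tool version, subcommand and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

_IUPAC = set("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class BindingInterval:
    """A protein binding interval, 0-based half-open, on a transcript or chrom."""

    seq_id: str
    start: int
    end: int
    protein: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"interval start {self.start} >= end {self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase-DNA map.

    RNA letters are converted (U->T); duplicate ids, empty records and
    non-IUPAC characters are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r} in {path}")
        bad = set(seq) - _IUPAC
        if bad:
            raise FormatError(
                f"record {rec.id!r} contains non-IUPAC character(s) {sorted(bad)}"
            )
        seqs[rec.id] = seq
    return seqs


def write_fasta(path, seqs: Mapping[str, str] | Iterable[tuple[str, str]], width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[BindingInterval]:
    """Read BED3+name / BED6; the name column becomes the protein."""
    out: list[BindingInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            protein = parts[3] if len(parts) > 3 else "."
            out.append(BindingInterval(seq_id=parts[0], start=start, end=end, protein=protein))
    return out


def write_bed(path, intervals: Iterable[BindingInterval], header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.protein}\n")


def tsv_header(subcommand: str, seed: int | None = None) -> str:
    """Standard comment header for every tabular/FASTA output."""
    from m6adeg import __version__

    parts = [f"m6adeg v{__version__}", f"subcommand={subcommand}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
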