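"""Synthetic m6A-site datasets with planted, class-discriminative motifs.

The generator emulates the structure of the real inputs: transcripts with a
single-base m6A site in a DRACH consensus, a YTHDF2 binding track covering
every site, a per-gene half-life log2 fold-change table that drives the
positive/negative labels, and a stability motif planted upstream of the m6A
center in a controlled fraction of each class.  Defaults mirror the study
conditions the pipeline targets: an AU-rich-element-like 6-mer planted ~80 nt
upstream of the site predominantly in *negative* (non-degraded) sequences,
because stabilizing co-factor motifs are the discriminative signal the
classifier and the interpretation stack are meant to recover.

Backgrounds are i.i.d. uniform ACGT by default; a first-order Markov
background with a configurable GC bias is available because motif-enrichment
nulls are sensitive to composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from m6adeg.datasets import HalfLifeRecord, SiteRecord
from m6adeg.io import BindingInterval, write_bed, write_fasta

_DNA = "ACGT"
_DEGENERATE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the planted-motif simulation.

    ``motif_offset_mean`` is the signed position of the motif *center*
    relative to the m6A base (negative = upstream).  Prevalences are the
    fractions of each intended class carrying the planted motif.
    """

    n_sites_per_class: int = 500
    transcript_length_range: tuple[int, int] = (700, 900)
    flank: int = 250
    planted_motif: str = "TATTTA"  # ARE-like AU-rich stability element
    motif_offset_mean: int = -80
    motif_offset_sd: float = 8.0
    motif_prevalence_in_negatives: float = 0.90
    motif_prevalence_in_positives: float = 0.0
    center_consensus: str = "DRACH"
    label_noise: float = 0.0
    markov_background: bool = False
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.motif_prevalence_in_negatives, self.motif_prevalence_in_positives):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence must be in [0,1], got {p}")
        if set(self.planted_motif) - set(_DNA):
            raise ValueError("planted motif must be over ACGT")
        if abs(self.motif_offset_mean) + len(self.planted_motif) > self.flank:
            raise ValueError("motif offset + length exceeds the window flank")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0,1]")


@dataclass(frozen=True)
class SiteTruth:
    """Ground truth for one simulated site."""

    site_id: str
    transcript_id: str
    gene_id: str
    position: int  # m6A base, transcript coords
    intended_label: int  # 1 = degradation-regulating
    emitted_label: int  # after label noise
    motif_start: int  # transcript coords, -1 if not planted
    motif_len: int


@dataclass
class SimulatedData:
    """In-memory simulation output; ``write`` emits the on-disk formats."""

    config: SimulationConfig
    transcripts: dict[str, str]
    sites: list[SiteRecord]
    bindings: list[BindingInterval]
    half_life: list[HalfLifeRecord]
    truth: list[SiteTruth] = field(default_factory=list)

    def write(self, outdir, seed_note: int | None = None) -> None:
        from m6adeg.io import tsv_header

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "transcripts.fa", self.transcripts)
        hdr = tsv_header("simulate", seed_note if seed_note is not None else self.config.seed)
        with open(out / "sites.tsv", "w") as fh:
            fh.write(hdr + "\n")
            fh.write("transcript_id\tposition\tgene_id\tregion\tsite_id\n")
            for s in self.sites:
                fh.write(f"{s.transcript_id}\t{s.position}\t{s.gene_id}\t{s.region}\t{s.site_id}\n")
        write_bed(out / "ythdf2.bed", self.bindings)
        with open(out / "half_life.tsv", "w") as fh:
            fh.write(hdr + "\n")
            fh.write("gene_id\tlog2fc\n")
            for r in self.half_life:
                fh.write(f"{r.gene_id}\t{r.log2fc:.6f}\n")
        with open(out / "ground_truth.tsv", "w") as fh:
            fh.write(hdr + "\n")
            fh.write(
                "site_id\ttranscript_id\tgene_id\tposition\tintended_label\t"
                "emitted_label\tmotif_start\tmotif_len\n"
            )
            for t in self.truth:
                fh.write(
                    f"{t.site_id}\t{t.transcript_id}\t{t.gene_id}\t{t.position}\t"
                    f"{t.intended_label}\t{t.emitted_label}\t{t.motif_start}\t{t.motif_len}\n"
                )


def _random_sequence(rng: np.random.Generator, length: int, cfg: SimulationConfig) -> str:
    if not cfg.markov_background:
        return "".join(np.array(list(_DNA))[rng.integers(4, size=length)])
    # first-order Markov chain with stationary GC bias and mild persistence
    g = cfg.gc_content / 2
    a = (1 - cfg.gc_content) / 2
    stat = np.array([a, g, g, a])
    persist = 0.15
    trans = (1 - persist) * np.tile(stat, (4, 1)) + persist * np.eye(4)
    out = [int(rng.choice(4, p=stat))]
    for _ in range(length - 1):
        out.append(int(rng.choice(4, p=trans[out[-1]])))
    return "".join(_DNA[i] for i in out)


def _sample_consensus(rng: np.random.Generator, consensus: str) -> str:
    return "".join(_DEGENERATE[c][rng.integers(len(_DEGENERATE[c]))] for c in consensus)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedData:
    """Generate transcripts, sites, YTHDF2 track, half-life table and truth.

    One site per transcript/gene.  The m6A base sits in the sampled DRACH
    consensus (A at the third consensus position); the planted motif is
    written at a Gaussian-jittered offset upstream in the configured fraction
    of each intended class; YTHDF2 intervals cover every site so the overlap
    filter keeps them all; half-life log2FC values are drawn so intended
    positives exceed 1 and intended negatives do not, with ``label_noise``
    flipping the half-life assignment (not the sequence content).
    """
    rng = np.random.default_rng(cfg.seed)
    motif = cfg.planted_motif
    transcripts: dict[str, str] = {}
    sites: list[SiteRecord] = []
    bindings: list[BindingInterval] = []
    half_life: list[HalfLifeRecord] = []
    truth: list[SiteTruth] = []

    lo, hi = cfg.transcript_length_range
    if lo < 2 * cfg.flank + 1:
        raise ValueError("transcripts must be at least one full window long")

    order = [1] * cfg.n_sites_per_class + [0] * cfg.n_sites_per_class
    prevalence = {
        1: cfg.motif_prevalence_in_positives,
        0: cfg.motif_prevalence_in_negatives,
    }
    for i, intended in enumerate(order):
        tid, gid, sid = f"tx{i:05d}", f"gene{i:05d}", f"site{i:05d}"
        L = int(rng.integers(lo, hi + 1))
        seq = list(_random_sequence(rng, L, cfg))
        pos = int(rng.integers(cfg.flank, L - cfg.flank))
        # DRACH-like center: A of the consensus lands exactly on `pos`
        cons = _sample_consensus(rng, cfg.center_consensus)
        a_idx = cfg.center_consensus.index("A")
        for j, base in enumerate(cons):
            seq[pos - a_idx + j] = base
        motif_start = -1
        if rng.random() < prevalence[intended]:
            offset = int(round(rng.normal(cfg.motif_offset_mean, cfg.motif_offset_sd)))
            mstart = pos + offset - len(motif) // 2
            mstart = max(0, min(mstart, L - len(motif)))
            # keep the motif clear of the consensus center
            if mstart + len(motif) > pos - a_idx and mstart < pos - a_idx + len(cons):
                mstart = pos - a_idx - len(motif)
            seq[mstart : mstart + len(motif)] = motif
            motif_start = mstart
        transcripts[tid] = "".join(seq)
        region = "3UTR" if rng.random() < 0.6 else "CDS"
        sites.append(SiteRecord(transcript_id=tid, position=pos, gene_id=gid,
                                region=region, site_id=sid))
        bindings.append(BindingInterval(seq_id=tid, start=max(0, pos - 20),
                                        end=min(L, pos + 21), protein="YTHDF2"))
        emitted = intended if rng.random() >= cfg.label_noise else 1 - intended
        log2fc = float(rng.uniform(1.5, 3.0)) if emitted == 1 else float(rng.uniform(-1.0, 0.5))
        half_life.append(HalfLifeRecord(gene_id=gid, log2fc=log2fc))
        truth.append(SiteTruth(site_id=sid, transcript_id=tid, gene_id=gid, position=pos,
                               intended_label=intended, emitted_label=emitted,
                               motif_start=motif_start, motif_len=len(motif)))
    return SimulatedData(config=cfg, transcripts=transcripts, sites=sites,
                         bindings=bindings, half_life=half_life, truth=truth)


def simulate_rbp_track(
    data: SimulatedData,
    protein_name: str = "STABRBP1",
    jitter: float = 0.0,
    decoy_rate: float = 0.2,
    pad: int = 2,
    seed: int = 0,
) -> list[BindingInterval]:
    """A matched RBP BED track: one interval per planted motif, plus decoys.

    Each planted motif occurrence yields an interval covering the motif
    (padded by ``pad`` nt, start jittered by a centered Gaussian of sd
    ``jitter``); in addition every site, of either class, receives a uniform
    decoy interval within its window with probability ``decoy_rate``.
    """
    rng = np.random.default_rng(seed)
    cfg = data.config
    out: list[BindingInterval] = []
    for t in data.truth:
        L = len(data.transcripts[t.transcript_id])
        if t.motif_start >= 0:
            shift = int(round(rng.normal(0, jitter))) if jitter > 0 else 0
            start = max(0, t.motif_start - pad + shift)
            end = min(L, t.motif_start + t.motif_len + pad + shift)
            if start < end:
                out.append(BindingInterval(seq_id=t.transcript_id, start=start,
                                           end=end, protein=protein_name))
        if rng.random() < decoy_rate:
            w_lo, w_hi = t.position - cfg.flank, t.position + cfg.flank + 1
            start = int(rng.integers(max(0, w_lo), w_hi - 10))
            out.append(BindingInterval(seq_id=t.transcript_id, start=start,
                                       end=min(L, start + 10), protein=protein_name))
    return out
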