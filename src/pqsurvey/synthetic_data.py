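"""Synthetic genomes with planted PQSs and known ground truth.

Generates a random background at a target GC fraction, optionally caps every
G/C homopolymer run below three bases (so the background can contribute no
PQS on either strand), lays out non-overlapping genes, and splices in PQS
cassettes at controlled offsets from TSSs (or uniformly over the genome) on
a controlled strand. Each cassette is flanked by an A/T-only buffer longer
than the maximal loop, so it is always detected as exactly one hit with
exact coordinates — the truth table is byte-comparable to scanner output.

This emulates the statistical structure the survey assumes (i.i.d. bases at
fixed GC%, genes on both strands); it has no operon structure, codon bias or
GC heterogeneity, and run-capping shifts realized GC slightly below target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pqs_scanner import PQSHit, reverse_complement, write_bed
from .sequence_io import Contig, TSSRecord, write_fasta
from .tss_profiler import DistanceRecord, strand_classify

#: A/T buffer around each cassette; longer than the 12-nt maximal loop so a
#: cassette can never chain with background G runs or a neighboring cassette.
BUFFER = 15

_G, _C, _A, _T = (ord(b) for b in "GCAT")


@dataclass(frozen=True, slots=True)
class SyntheticSpec:
    """Recipe for one synthetic genome.

    ``tss_offset=None`` plants cassettes uniformly over the genome
    (requires ``strand_rule="random"``); an integer plants each cassette's
    midpoint at that gene-oriented offset from a distinct gene's TSS
    (negative = upstream). ``strand_rule`` places the G-rich face on the
    gene's strand ("coding"), the opposite strand ("template") or at random.
    """

    length_bp: int
    gc_fraction: float = 0.40
    n_genes: int = 0
    gene_length_range: tuple[int, int] = (300, 900)
    n_planted: int = 0
    planted_n_tracks: int = 4
    planted_track_len: int = 3
    planted_loop_len: int = 2
    tss_offset: int | None = None
    strand_rule: str = "random"
    cap_background_g_runs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_bp < 100:
            raise ValueError("length_bp too small")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must be in (0,1)")
        if self.strand_rule not in ("coding", "template", "random"):
            raise ValueError(f"unknown strand_rule {self.strand_rule!r}")
        if self.tss_offset is None and self.n_planted and self.strand_rule != "random":
            raise ValueError(
                "coding/template strand rules require TSS-relative planting"
            )
        if self.planted_n_tracks < 2 or self.planted_track_len < 3:
            raise ValueError("planted PQS must have >=2 tracks of >=3 Gs")
        if not (1 <= self.planted_loop_len <= 12):
            raise ValueError("planted_loop_len must be in [1,12]")


@dataclass(slots=True)
class GeneModel:
    gene_id: str
    start: int  # 0-based half-open
    end: int
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(slots=True)
class SyntheticGenome:
    """A generated genome plus its ground truth."""

    spec: SyntheticSpec
    contig: Contig
    genes: list[GeneModel]
    tss_records: list[TSSRecord]
    truth_hits: list[PQSHit]
    truth_records: list[DistanceRecord]  # only for TSS-relative planting

    def gff3(self) -> str:
        lines = ["##gff-version 3"]
        lines.append(
            f"##sequence-region {self.contig.id} 1 {len(self.contig.sequence)}"
        )
        for g in self.genes:
            lines.append(
                f"{self.contig.id}\tpqsurvey\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};locus_tag={g.gene_id}"
            )
        return "\n".join(lines) + "\n"

    def write(self, prefix: str | Path) -> dict[str, Path]:
        """Write FASTA, GFF3, truth BED and truth TSV under ``prefix``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": prefix.with_suffix(".fna"),
            "gff3": prefix.with_suffix(".gff3"),
            "truth_bed": Path(str(prefix) + ".truth.bed"),
            "truth_tsv": Path(str(prefix) + ".truth.tsv"),
        }
        write_fasta([self.contig], paths["fasta"])
        paths["gff3"].write_text(self.gff3())
        write_bed(self.truth_hits, paths["truth_bed"])
        with open(paths["truth_tsv"], "w") as fh:
            fh.write("contig_id\tstart\tend\tstrand\tn_tracks\tgene_id\t"
                     "signed_distance\tstrand_class\n")
            for r in self.truth_records:
                h = r.hit
                fh.write(
                    f"{h.contig_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.n_tracks}\t"
                    f"{r.gene_id}\t{r.signed_distance}\t{r.strand_class}\n"
                )
        return paths


def _background(length: int, gc: float, cap: bool, rng: np.random.Generator) -> np.ndarray:
    half_gc, half_at = gc / 2.0, (1.0 - gc) / 2.0
    arr = rng.choice(
        np.frombuffer(b"GCAT", dtype=np.uint8),
        size=length,
        p=[half_gc, half_gc, half_at, half_at],
    )
    if cap and length >= 3:
        # break every G/C homopolymer at length 3: any base equal to its two
        # predecessors (flagged on the original draw) becomes A or T; A/T
        # substitutions cannot create new G/C runs, so one pass suffices
        is_gc = (arr == _G) | (arr == _C)
        triple = np.zeros(length, dtype=bool)
        triple[2:] = (arr[2:] == arr[1:-1]) & (arr[1:-1] == arr[:-2]) & is_gc[2:]
        n = int(triple.sum())
        if n:
            arr[triple] = rng.choice(
                np.frombuffer(b"AT", dtype=np.uint8), size=n
            )
    return arr


def _cassette(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[str, tuple[int, ...], tuple[int, ...]]:
    """G-rich cassette sequence plus its track/loop length tuples."""
    track = "G" * spec.planted_track_len
    loops = tuple(spec.planted_loop_len for _ in range(spec.planted_n_tracks - 1))
    loop_alphabet = "AT"
    parts = [track]
    for loop_len in loops:
        parts.append("".join(rng.choice(list(loop_alphabet), size=loop_len)))
        parts.append(track)
    seq = "".join(parts)
    tracks = tuple(spec.planted_track_len for _ in range(spec.planted_n_tracks))
    return seq, tracks, loops


def _place_genes(spec: SyntheticSpec, margin: int, rng: np.random.Generator) -> list[GeneModel]:
    if spec.n_genes == 0:
        return []
    slot = spec.length_bp // spec.n_genes
    lo, hi = spec.gene_length_range
    genes: list[GeneModel] = []
    for i in range(spec.n_genes):
        slot_start = i * slot
        max_len = slot - 2 * margin
        if max_len < 50:
            raise ValueError(
                f"infeasible packing: slot of {slot} bp cannot hold a gene "
                f"with {margin} bp margins"
            )
        glen = int(rng.integers(lo, hi + 1))
        glen = min(glen, max_len)
        start = slot_start + margin
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(gene_id=f"g{i + 1:04d}", start=start, end=start + glen, strand=strand)
        )
    return genes


def make_genome_with_truth(spec: SyntheticSpec) -> SyntheticGenome:
    """Build the genome, annotation and truth table described by ``spec``.

    Deterministic for a fixed seed. Raises ``ValueError`` naming the violated
    constraint when the requested cassettes cannot be packed.
    """
    rng = np.random.default_rng(spec.seed)
    arr = _background(spec.length_bp, spec.gc_fraction, spec.cap_background_g_runs, rng)

    cassette_seq, track_lengths, loop_lengths = _cassette(spec, rng)
    clen = len(cassette_seq)
    margin = clen + 2 * BUFFER + (abs(spec.tss_offset) if spec.tss_offset else 0) + 5

    genes = _place_genes(spec, margin, rng)

    if spec.n_planted and spec.tss_offset is not None and spec.n_planted > len(genes):
        raise ValueError(
            f"infeasible packing: {spec.n_planted} TSS-relative cassettes but "
            f"only {len(genes)} genes"
        )

    contig_id = "synth_1"
    truth_hits: list[PQSHit] = []
    truth_records: list[DistanceRecord] = []

    placements: list[tuple[int, GeneModel | None]] = []  # (midpoint, gene)
    if spec.n_planted:
        if spec.tss_offset is not None:
            chosen = sorted(rng.choice(len(genes), size=spec.n_planted, replace=False))
            for gi in chosen:
                gene = genes[int(gi)]
                mid = (
                    gene.tss + spec.tss_offset
                    if gene.strand == "+"
                    else gene.tss - spec.tss_offset
                )
                placements.append((mid, gene))
        else:
            min_sep = clen + 2 * BUFFER + 1
            lo = BUFFER + clen // 2 + 1
            hi = spec.length_bp - BUFFER - clen - 1
            if hi <= lo:
                raise ValueError("infeasible packing: genome too short for cassette")
            mids: list[int] = []
            for _ in range(10_000):
                if len(mids) == spec.n_planted:
                    break
                cand = int(rng.integers(lo, hi))
                if all(abs(cand - m) >= min_sep for m in mids):
                    mids.append(cand)
            if len(mids) < spec.n_planted:
                raise ValueError(
                    "infeasible packing: could not place cassettes with "
                    f"pairwise separation >= {min_sep} bp"
                )
            placements = [(m, None) for m in sorted(mids)]

    # validate pairwise separation and bounds, then splice
    spans: list[tuple[int, int]] = []
    for mid, gene in placements:
        start = mid - clen // 2
        end = start + clen
        if start - BUFFER < 0 or end + BUFFER > spec.length_bp:
            raise ValueError("infeasible packing: cassette buffer crosses contig end")
        for s, e in spans:
            if start - BUFFER < e + BUFFER and s - BUFFER < end + BUFFER:
                raise ValueError("infeasible packing: cassette buffers overlap")
        spans.append((start, end))

        if gene is None:
            hit_strand = "+" if rng.random() < 0.5 else "-"
        elif spec.strand_rule == "coding":
            hit_strand = gene.strand
        elif spec.strand_rule == "template":
            hit_strand = "-" if gene.strand == "+" else "+"
        else:
            hit_strand = "+" if rng.random() < 0.5 else "-"

        inserted = cassette_seq if hit_strand == "+" else reverse_complement(cassette_seq)
        buf = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=2 * BUFFER)
        arr[start - BUFFER : start] = buf[:BUFFER]
        arr[end : end + BUFFER] = buf[BUFFER:]
        arr[start:end] = np.frombuffer(inserted.encode("ascii"), dtype=np.uint8)

        hit = PQSHit(
            contig_id=contig_id,
            start=start,
            end=end,
            strand=hit_strand,
            sequence=cassette_seq,
            n_tracks=spec.planted_n_tracks,
            track_lengths=track_lengths,
            loop_lengths=loop_lengths,
        )
        truth_hits.append(hit)
        if gene is not None:
            truth_records.append(
                DistanceRecord(
                    hit=hit,
                    gene_id=gene.gene_id,
                    signed_distance=spec.tss_offset,
                    strand_class=strand_classify(hit_strand, gene.strand),
                )
            )

    truth_hits.sort(key=lambda h: (h.start, h.strand))
    contig = Contig(id=contig_id, sequence=arr.tobytes().decode("ascii"))
    tss_records = [
        TSSRecord(
            gene_id=g.gene_id,
            contig_id=contig_id,
            tss_position=g.tss,
            gene_strand=g.strand,
        )
        for g in genes
    ]
    return SyntheticGenome(
        spec=spec,
        contig=contig,
        genes=genes,
        tss_records=tss_records,
        truth_hits=truth_hits,
        truth_records=truth_records,
    )
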