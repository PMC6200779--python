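"""Detection of potential G-quadruplex-forming sequences (PQSs).

A PQS follows 5'-(G>=3 N1-12)>=3 G>=3-3': four or more G tracks of at least
three guanines each, separated by loops of 1-12 arbitrary nucleotides. The
scanner implements a Quadparser-style greedy maximal rule:

* a G track is a *maximal* run of >= ``min_track_len`` consecutive Gs — a run
  of seven Gs is one track of length 7, never two tracks;
* consecutive qualifying tracks whose gap lies in [``loop_min``,
  ``loop_max``] chain together; a chain of >= ``min_tracks`` tracks is one
  hit spanning from the first track's start to the last track's end;
* hits never overlap; scanning resumes after each hit.

Counting *all* accumulated tracks per hit is what makes the ">4 G tracks"
("spare tire") statistic well defined. N bases break G tracks and count
toward loop length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .sequence_io import Contig, GenomeStats

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class ScanParams:
    """Pattern parameters; defaults encode (G>=3 N1-12)>=3 G>=3."""

    min_track_len: int = 3
    min_tracks: int = 4
    loop_min: int = 1
    loop_max: int = 12

    def __post_init__(self) -> None:
        if self.min_track_len < 2:
            raise ValueError("min_track_len must be >= 2")
        if self.min_tracks < 2:
            raise ValueError("min_tracks must be >= 2")
        if not (0 <= self.loop_min <= self.loop_max):
            raise ValueError("need 0 <= loop_min <= loop_max")


@dataclass(frozen=True, slots=True)
class PQSHit:
    """One detected PQS.

    Coordinates are 0-based half-open on the forward strand of the contig;
    ``sequence`` is the matched G-rich string read 5'->3' on its own strand.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    n_tracks: int
    track_lengths: tuple[int, ...]
    loop_lengths: tuple[int, ...]


@dataclass(slots=True)
class ScanSummary:
    """Hit counts relative to genome size (the GenomeStats fragment)."""

    n_pqs: int
    pqs_density: float
    extra_track_fraction: float
    degenerate: bool = False


def _run_pattern(min_track_len: int) -> re.Pattern[str]:
    return re.compile("G{%d,}" % min_track_len)


def scan_strand(
    sequence: str, params: ScanParams = ScanParams(), contig_id: str = ""
) -> list[PQSHit]:
    """Scan one strand left to right; all hits are reported as strand '+'.

    Returns maximal non-overlapping hits in coordinate order.
    """
    runs = [
        (m.start(), m.end()) for m in _run_pattern(params.min_track_len).finditer(sequence)
    ]
    hits: list[PQSHit] = []
    i = 0
    n_runs = len(runs)
    while i < n_runs:
        j = i
        while (
            j + 1 < n_runs
            and params.loop_min <= runs[j + 1][0] - runs[j][1] <= params.loop_max
        ):
            j += 1
        chain = runs[i : j + 1]
        if len(chain) >= params.min_tracks:
            start, end = chain[0][0], chain[-1][1]
            tracks = tuple(e - s for s, e in chain)
            loops = tuple(chain[k + 1][0] - chain[k][1] for k in range(len(chain) - 1))
            hits.append(
                PQSHit(
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand="+",
                    sequence=sequence[start:end],
                    n_tracks=len(chain),
                    track_lengths=tracks,
                    loop_lengths=loops,
                )
            )
        i = j + 1
    return hits


def scan_genome(
    contigs: Sequence[Contig], params: ScanParams = ScanParams()
) -> list[PQSHit]:
    """Scan both strands of every contig.

    Minus-strand hits are found on the reverse complement and mapped back to
    forward-strand coordinates; their ``sequence`` field stays 5'->3' on the
    minus strand (the G-rich reading). Hits are sorted by
    (contig input order, start, strand).
    """
    all_hits: list[PQSHit] = []
    for contig in contigs:
        fwd = scan_strand(contig.sequence, params, contig.id)
        length = len(contig.sequence)
        rev = []
        for hit in scan_strand(reverse_complement(contig.sequence), params, contig.id):
            rev.append(
                PQSHit(
                    contig_id=contig.id,
                    start=length - hit.end,
                    end=length - hit.start,
                    strand="-",
                    sequence=hit.sequence,
                    n_tracks=hit.n_tracks,
                    track_lengths=hit.track_lengths,
                    loop_lengths=hit.loop_lengths,
                )
            )
        merged = fwd + rev
        merged.sort(key=lambda h: (h.start, h.strand))
        all_hits.extend(merged)
    return all_hits


def summarize(
    hits: Sequence[PQSHit], length_bp: int, extra_tracks_above: int = 4
) -> ScanSummary:
    """Density (PQSs per Mbp, both strands pooled over single-strand length)
    and the fraction of hits with more than ``extra_tracks_above`` G tracks.
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    n = len(hits)
    if n == 0:
        return ScanSummary(0, 0.0, 0.0, degenerate=True)
    n_extra = sum(1 for h in hits if h.n_tracks > extra_tracks_above)
    return ScanSummary(
        n_pqs=n,
        pqs_density=n / (length_bp / 1e6),
        extra_track_fraction=n_extra / n,
    )


def genome_stats(
    genome_id: str, contigs: Sequence[Contig], params: ScanParams = ScanParams()
) -> GenomeStats:
    """Convenience: scan a genome and assemble the full GenomeStats record."""
    from .sequence_io import genome_gc_and_length

    length, gc = genome_gc_and_length(contigs)
    summary = summarize(scan_genome(contigs, params), length)
    return GenomeStats(
        genome_id=genome_id,
        length_bp=length,
        gc_fraction=gc,
        n_pqs=summary.n_pqs,
        pqs_density=summary.pqs_density,
        extra_track_fraction=summary.extra_track_fraction,
        degenerate=summary.degenerate,
    )


# ---------------------------------------------------------------------------
# BED6+3 serialization: chrom start end name score=n_tracks strand
#                       track_lengths loop_lengths sequence

def write_bed(hits: Iterable[PQSHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, hit in enumerate(hits, start=1):
            tracks = ",".join(map(str, hit.track_lengths))
            loops = ",".join(map(str, hit.loop_lengths)) or "."
            fh.write(
                f"{hit.contig_id}\t{hit.start}\t{hit.end}\tPQS_{k}\t"
                f"{hit.n_tracks}\t{hit.strand}\t{tracks}\t{loops}\t{hit.sequence}\n"
            )


def read_bed(path: str | Path) -> list[PQSHit]:
    hits: list[PQSHit] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: expected BED6+3, got {len(f)} fields")
            loops = () if f[7] == "." else tuple(int(x) for x in f[7].split(","))
            hits.append(
                PQSHit(
                    contig_id=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5],
                    sequence=f[8],
                    n_tracks=int(f[4]),
                    track_lengths=tuple(int(x) for x in f[6].split(",")),
                    loop_lengths=loops,
                )
            )
    return hits
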