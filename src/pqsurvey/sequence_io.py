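"""Genome and annotation input/output.

Reads FASTA genomes and GFF3 annotations and computes per-genome metadata
(length, GC fraction, transcription start sites). All coordinates are 0-based
half-open internally; conversion to/from the 1-based inclusive GFF3 convention
happens only at the format boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Alphabet after normalization. Anything else is mapped to N on load.
VALID_BASES = frozenset("ACGTN")

_NORMALIZE = {c: c for c in "ACGTN"}


@dataclass(frozen=True, slots=True)
class Contig:
    """One sequence record of a genome, uppercased over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")


@dataclass(frozen=True, slots=True)
class TSSRecord:
    """Transcription start site of one gene.

    ``tss_position`` is the 0-based coordinate of the first transcribed base:
    the annotation start for a + gene, the annotation end for a - gene.
    """

    gene_id: str
    contig_id: str
    tss_position: int
    gene_strand: str

    def __post_init__(self) -> None:
        if self.gene_strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.gene_strand!r}")


@dataclass(slots=True)
class GenomeStats:
    """Per-genome summary: size, composition and PQS load.

    ``pqs_density`` is PQS count (both strands pooled) per million base pairs
    of single-strand genome length; ``extra_track_fraction`` is the fraction
    of PQSs carrying more than four G tracks. ``degenerate`` flags the
    zero-PQS convention (density and fraction reported as 0).
    """

    genome_id: str
    length_bp: int
    gc_fraction: float
    n_pqs: int = 0
    pqs_density: float = 0.0
    extra_track_fraction: float = 0.0
    degenerate: bool = False


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase ``raw`` and map characters outside {A,C,G,T,N} to N.

    Returns the normalized sequence and the number of replaced characters.
    """
    up = raw.upper()
    n_replaced = sum(1 for c in up if c not in VALID_BASES)
    if n_replaced:
        up = "".join(c if c in VALID_BASES else "N" for c in up)
    return up, n_replaced


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a (multi-)FASTA file into a list of normalized contigs.

    Characters outside {A,C,G,T,N} are replaced by N; the total replacement
    count is logged as a warning. Raises ``ValueError`` on an empty file or
    a file whose first non-blank line is not a FASTA header.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = line
                break
        if not first:
            raise ValueError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ValueError(
                f"{path}: line {lineno} is not a FASTA header: {first.strip()!r}"
            )

    contigs: list[Contig] = []
    seen: set[str] = set()
    total_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, n_replaced = normalize_sequence(str(rec.seq))
        total_replaced += n_replaced
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        contigs.append(Contig(id=rec.id, sequence=seq))
    if not contigs:
        raise ValueError(f"{path}: no FASTA records")
    if total_replaced:
        logger.warning(
            "%s: %d non-ACGTN characters replaced by N", path, total_replaced
        )
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    """Write contigs to FASTA with fixed line wrapping (deterministic output)."""
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.id}\n")
            seq = contig.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def genome_gc_and_length(contigs: Sequence[Contig]) -> tuple[int, float]:
    """Total genome length (N included) and GC fraction (N excluded).

    GC fraction is (#G + #C) / (#A + #C + #G + #T); an all-N genome has no
    defined GC and raises ``ValueError``.
    """
    if not contigs:
        raise ValueError("no contigs")
    length = 0
    gc = 0
    acgt = 0
    for contig in contigs:
        s = contig.sequence
        length += len(s)
        g, c = s.count("G"), s.count("C")
        gc += g + c
        acgt += g + c + s.count("A") + s.count("T")
    if acgt == 0:
        raise ValueError("all-N genome: GC fraction undefined")
    return length, gc / acgt


def _feature_id(feature: gffutils.Feature) -> str:
    for key in ("ID", "locus_tag", "Name", "gene"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return f"{feature.seqid}:{feature.start}-{feature.end}"


def extract_tss(
    gff3_path: str | Path, feature_type: str = "gene"
) -> list[TSSRecord]:
    """Extract one TSS per stranded feature of ``feature_type`` from a GFF3.

    The TSS is approximated by the feature's 5' end: for a + feature the
    GFF3 start, for a - feature the GFF3 end, both converted to 0-based.
    Features with strand "." are skipped with a warning; a file with no
    features of the requested type yields an empty list plus a warning.
    Bacterial annotations often lack ``gene`` features, in which case
    ``feature_type="CDS"`` is the usual fallback.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[TSSRecord] = []
    n_unstranded = 0
    for feature in db.features_of_type(feature_type, order_by=("seqid", "start")):
        if feature.strand not in ("+", "-"):
            n_unstranded += 1
            continue
        if feature.strand == "+":
            tss = feature.start - 1  # GFF3 1-based inclusive -> 0-based
        else:
            tss = feature.end - 1
        records.append(
            TSSRecord(
                gene_id=_feature_id(feature),
                contig_id=feature.seqid,
                tss_position=tss,
                gene_strand=feature.strand,
            )
        )
    if n_unstranded:
        logger.warning(
            "%s: skipped %d unstranded %s feature(s)",
            gff3_path,
            n_unstranded,
            feature_type,
        )
    if not records and not n_unstranded:
        logger.warning("%s: no features of type %r", gff3_path, feature_type)
    return records


def write_contig_stats(
    contigs: Sequence[Contig], genome_id: str, path: str | Path
) -> None:
    """Per-contig length and GC as TSV (genome_id, contig_id, length, gc_fraction)."""
    with open(path, "w") as fh:
        fh.write("genome_id\tcontig_id\tlength\tgc_fraction\n")
        for contig in contigs:
            try:
                _, gc = genome_gc_and_length([contig])
                gc_txt = f"{gc:.6f}"
            except ValueError:
                gc_txt = "NA"
            fh.write(f"{genome_id}\t{contig.id}\t{len(contig.sequence)}\t{gc_txt}\n")
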