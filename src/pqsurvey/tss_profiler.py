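"""PQS distribution around transcription start sites.

Distances are measured from a PQS midpoint to the nearest TSS on the same
contig and expressed in the gene's reading orientation: negative means the
PQS lies upstream of the gene, positive downstream (inside the transcription
unit). A PQS is *coding-strand* when its G-rich face lies on the same strand
as the gene (it appears in the mRNA-like strand) and *template-strand*
otherwise. Distances are binned (default 30 bp bins over +/-1500 bp) and the
binned vector is normalized by the organism's total PQS count, which makes
profiles comparable between organisms with different PQS loads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .pqs_scanner import PQSHit
from .sequence_io import TSSRecord

logger = logging.getLogger(__name__)

StrandClass = Literal["coding", "template"]


@dataclass(frozen=True, slots=True)
class DistanceRecord:
    """A PQS assigned to its nearest TSS."""

    hit: PQSHit
    gene_id: str
    signed_distance: int
    strand_class: str


@dataclass(slots=True)
class DistributionVector:
    """Binned, normalized PQS-to-TSS distance profile for one organism.

    Bins cover [-window, window) in steps of ``bin_size``; ``normalized``
    divides by the organism's total PQS count (not the in-window count), so
    its sum is <= 1.
    """

    organism_id: str
    bin_size: int
    window: int
    bin_counts: np.ndarray
    normalized: np.ndarray
    total_pqs: int

    @property
    def bin_left_edges(self) -> np.ndarray:
        return np.arange(-self.window, self.window, self.bin_size)


def strand_classify(hit_strand: str, gene_strand: str) -> StrandClass:
    """coding iff the PQS strand equals the gene strand."""
    return "coding" if hit_strand == gene_strand else "template"


def hit_midpoint(hit: PQSHit) -> int:
    return (hit.start + hit.end) // 2


def _signed_distance(midpoint: int, tss: TSSRecord) -> int:
    d = midpoint - tss.tss_position
    return d if tss.gene_strand == "+" else -d


def nearest_tss(
    hits: Sequence[PQSHit], tss: Sequence[TSSRecord]
) -> list[DistanceRecord]:
    """Assign each PQS to the closest TSS on its contig.

    Ties in absolute distance are broken toward the gene for which the PQS is
    downstream (inside the transcription unit), then toward the lower TSS
    coordinate, then the lexicographically smaller gene id — deterministic
    regardless of input order. Hits on contigs with no TSS are dropped with
    a log message; an empty TSS set yields an empty result plus a warning.
    """
    if not tss:
        logger.warning("nearest_tss: empty TSS set")
        return []
    by_contig: dict[str, list[TSSRecord]] = {}
    for rec in tss:
        by_contig.setdefault(rec.contig_id, []).append(rec)
    positions: dict[str, np.ndarray] = {}
    for contig_id, recs in by_contig.items():
        recs.sort(key=lambda r: (r.tss_position, r.gene_id))
        positions[contig_id] = np.array([r.tss_position for r in recs])

    out: list[DistanceRecord] = []
    n_orphan = 0
    for hit in hits:
        recs = by_contig.get(hit.contig_id)
        if not recs:
            n_orphan += 1
            continue
        pos = positions[hit.contig_id]
        mid = hit_midpoint(hit)
        idx = int(np.searchsorted(pos, mid))
        # candidate TSSs adjacent to the insertion point
        cand = range(max(idx - 1, 0), min(idx + 1, len(recs) - 1) + 1)
        best_abs = min(abs(mid - pos[i]) for i in cand)
        ties = [recs[i] for i in cand if abs(mid - pos[i]) == best_abs]
        # equal TSS coordinates elsewhere in the sorted list share a position
        # value, so widen to every record at a tied coordinate
        tied_positions = {t.tss_position for t in ties}
        ties = [r for r in recs if r.tss_position in tied_positions]
        ties.sort(
            key=lambda r: (
                _signed_distance(mid, r) < 0,  # prefer downstream
                r.tss_position,
                r.gene_id,
            )
        )
        chosen = ties[0]
        out.append(
            DistanceRecord(
                hit=hit,
                gene_id=chosen.gene_id,
                signed_distance=_signed_distance(mid, chosen),
                strand_class=strand_classify(hit.strand, chosen.gene_strand),
            )
        )
    if n_orphan:
        logger.info("nearest_tss: %d hit(s) on contigs without any TSS", n_orphan)
    return out


def bin_distribution(
    records: Sequence[DistanceRecord],
    total_pqs: int,
    bin_size: int = 30,
    window: int = 1500,
    track_filter: Literal["all", "gt4_only"] = "all",
    organism_id: str = "",
) -> DistributionVector:
    """Bin signed distances over [-window, window); normalize by total_pqs.

    ``track_filter="gt4_only"`` keeps only PQSs with more than four G tracks.
    Records outside the window are excluded from the counts but total_pqs
    (the normalizer) is the organism's full PQS count.
    """
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    if total_pqs <= 0:
        raise ValueError("total_pqs must be positive for normalization")
    if track_filter == "gt4_only":
        records = [r for r in records if r.hit.n_tracks > 4]
    elif track_filter != "all":
        raise ValueError(f"unknown track_filter {track_filter!r}")
    distances = np.array([r.signed_distance for r in records], dtype=float)
    edges = np.arange(-window, window + bin_size, bin_size)
    # np.histogram closes the last bin; drop exact right-edge values to keep
    # every bin half-open [left, right)
    distances = distances[(distances >= -window) & (distances < window)]
    counts, _ = np.histogram(distances, bins=edges)
    return DistributionVector(
        organism_id=organism_id,
        bin_size=bin_size,
        window=window,
        bin_counts=counts,
        normalized=counts / total_pqs,
        total_pqs=total_pqs,
    )


@dataclass(slots=True)
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    method: str


def count_table(
    records: Sequence[DistanceRecord], near_bp: int = 100
) -> np.ndarray:
    """2x2 table of {>4 tracks, <=4 tracks} x {near TSS, elsewhere}.

    "Near" means |signed distance| <= ``near_bp`` (default 100 bp, mirroring
    the promoter gene-list window).
    """
    table = np.zeros((2, 2), dtype=int)
    for r in records:
        row = 0 if r.hit.n_tracks > 4 else 1
        col = 0 if abs(r.signed_distance) <= near_bp else 1
        table[row, col] += 1
    return table


def tss_enrichment_test(
    table: np.ndarray | Sequence[Sequence[int]],
    method: Literal["fisher", "chi2", "ztest"] = "fisher",
) -> EnrichmentResult:
    """Association between extra G tracks and TSS proximity.

    Two-sided Fisher's exact test by default (chi-squared and two-proportion
    z-test selectable). The odds ratio is the sample (a*d)/(b*c) with a
    Haldane 0.5 correction applied to every cell when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    ct = t + 0.5 if (t == 0).any() else t
    odds = (ct[0, 0] * ct[1, 1]) / (ct[0, 1] * ct[1, 0])
    if method == "fisher":
        _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    elif method == "chi2":
        _, p, _, _ = stats.chi2_contingency(t, correction=True)
    elif method == "ztest":
        # two-proportion z-test on P(near | >4 tracks) vs P(near | <=4)
        n1, n2 = t[0].sum(), t[1].sum()
        if n1 == 0 or n2 == 0:
            raise ValueError("empty row in contingency table")
        p1, p2 = t[0, 0] / n1, t[1, 0] / n2
        pool = (t[0, 0] + t[1, 0]) / (n1 + n2)
        se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        z = 0.0 if se == 0 else (p1 - p2) / se
        p = 2 * stats.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown method {method!r}")
    return EnrichmentResult(odds_ratio=float(odds), p_value=float(p), method=method)


def promoter_gene_list(
    tss: Sequence[TSSRecord],
    hits: Sequence[PQSHit],
    window: tuple[int, int] = (-100, 100),
    strand_filter: Literal["any", "template", "coding"] = "any",
) -> list[str]:
    """Genes with at least one PQS midpoint within ``window`` of their TSS.

    The window is gene-oriented (negative upstream); the optional strand
    filter keeps only template- or coding-strand PQSs. Returns unique gene
    ids sorted lexicographically, ready for external GO tools.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("window must be (low, high) with low <= high")
    mids_by_contig: dict[str, list[tuple[int, str]]] = {}
    for hit in hits:
        mids_by_contig.setdefault(hit.contig_id, []).append(
            (hit_midpoint(hit), hit.strand)
        )
    genes: set[str] = set()
    for rec in tss:
        for mid, strand in mids_by_contig.get(rec.contig_id, ()):
            d = _signed_distance(mid, rec)
            if not (lo <= d <= hi):
                continue
            if strand_filter != "any" and strand_classify(strand, rec.gene_strand) != strand_filter:
                continue
            genes.add(rec.gene_id)
            break
    return sorted(genes)


# ---------------------------------------------------------------------------
# serialization

def write_distance_records(records: Iterable[DistanceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "contig_id\tpqs_start\tpqs_end\tpqs_strand\tn_tracks\t"
            "gene_id\tsigned_distance\tstrand_class\n"
        )
        for r in records:
            h = r.hit
            fh.write(
                f"{h.contig_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.n_tracks}\t"
                f"{r.gene_id}\t{r.signed_distance}\t{r.strand_class}\n"
            )


def write_profiles(vectors: Sequence[DistributionVector], path: str | Path) -> None:
    """Wide-format TSV: one row per organism, one column per bin left edge."""
    if not vectors:
        raise ValueError("no vectors to write")
    edges = vectors[0].bin_left_edges
    for v in vectors[1:]:
        if v.bin_size != vectors[0].bin_size or v.window != vectors[0].window:
            raise ValueError("all vectors must share bin_size and window")
    with open(path, "w") as fh:
        fh.write("organism_id\t" + "\t".join(str(e) for e in edges) + "\n")
        for v in vectors:
            fh.write(
                v.organism_id
                + "\t"
                + "\t".join(f"{x:.8g}" for x in v.normalized)
                + "\n"
            )


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in genes))
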