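"""Random-genome null model for PQS density and extra-track fraction.

Random genomes are i.i.d. nucleotide strings at a specified GC fraction with
a symmetric split (P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2), which makes the two
strands statistically exchangeable. Scanning replicate random genomes across
a grid of GC levels yields the theoretical density-vs-GC curve (summarized
box-plot style, median + quartiles) against which observed genomes are
compared. Paper-scale defaults: 2 Mbp genomes, 10 replicates per level, GC
from 20% to 80% in 2% steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pqs_scanner import ScanParams, scan_genome, summarize
from .sequence_io import Contig, GenomeStats

_BASES = np.frombuffer(b"GCAT", dtype=np.uint8)


def random_genome(
    length: int, gc_fraction: float, seed: int | np.random.Generator
) -> Contig:
    """I.i.d. random genome: G and C each with probability gc/2, A and T
    each with (1-gc)/2. Deterministic for a fixed integer seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    half_gc = gc_fraction / 2.0
    half_at = (1.0 - gc_fraction) / 2.0
    arr = rng.choice(_BASES, size=length, p=[half_gc, half_gc, half_at, half_at])
    return Contig(
        id=f"random_gc{gc_fraction:.3f}", sequence=arr.tobytes().decode("ascii")
    )


@dataclass(slots=True)
class NullCurve:
    """Replicate PQS densities and extra-track fractions per GC level.

    ``densities`` and ``extra_track_fractions`` are (n_levels, n_replicates)
    arrays; densities are PQSs/Mbp with both strands pooled.
    """

    gc_levels: np.ndarray
    densities: np.ndarray
    extra_track_fractions: np.ndarray
    genome_length: int
    n_replicates: int
    seed: int
    scan_params: ScanParams = field(default_factory=ScanParams)

    def median_density(self) -> np.ndarray:
        return np.median(self.densities, axis=1)

    def summary(self):
        """Box-plot statistics per GC level as a pandas DataFrame."""
        import pandas as pd

        q1, med, q3 = np.percentile(self.densities, [25, 50, 75], axis=1)
        return pd.DataFrame(
            {
                "gc": self.gc_levels,
                "density_q1": q1,
                "density_median": med,
                "density_q3": q3,
                "extra_track_fraction_mean": self.extra_track_fractions.mean(axis=1),
            }
        )


def build_null_curve(
    gc_min: float = 0.20,
    gc_max: float = 0.80,
    gc_step: float = 0.02,
    genome_length: int = 2_000_000,
    n_replicates: int = 10,
    seed: int = 0,
    scan_params: ScanParams = ScanParams(),
) -> NullCurve:
    """Simulate replicate random genomes at each GC level and scan them.

    Each (level, replicate) genome gets an independent child seed derived
    from ``seed`` so the curve is reproducible and individual cells are
    regenerable.
    """
    if not (0.0 < gc_min <= gc_max < 1.0) or gc_step <= 0:
        raise ValueError("invalid GC range")
    if genome_length < 1 or n_replicates < 1:
        raise ValueError("genome_length and n_replicates must be >= 1")
    n_levels = int(round((gc_max - gc_min) / gc_step)) + 1
    levels = gc_min + gc_step * np.arange(n_levels)
    densities = np.empty((n_levels, n_replicates))
    fractions = np.empty((n_levels, n_replicates))
    streams = np.random.SeedSequence(seed).spawn(n_levels * n_replicates)
    for i, gc in enumerate(levels):
        for r in range(n_replicates):
            rng = np.random.default_rng(streams[i * n_replicates + r])
            contig = random_genome(genome_length, float(gc), rng)
            s = summarize(scan_genome([contig], scan_params), genome_length)
            densities[i, r] = s.pqs_density
            fractions[i, r] = s.extra_track_fraction
    return NullCurve(
        gc_levels=levels,
        densities=densities,
        extra_track_fractions=fractions,
        genome_length=genome_length,
        n_replicates=n_replicates,
        seed=seed,
        scan_params=scan_params,
    )


@dataclass(slots=True)
class NullComparison:
    """Observed genome against the null curve at its GC content."""

    deviation: float  # observed density - interpolated null median
    percentile: float  # empirical percentile among bracketing replicates
    null_median: float
    extrapolated: bool


def enrichment_vs_null(observed: GenomeStats, curve: NullCurve) -> NullComparison:
    """Signed density deviation and empirical percentile versus the null.

    The null median is linearly interpolated between the two GC levels
    bracketing the genome's GC; the percentile is computed against the pooled
    replicate densities of those two levels. A GC outside the curve's range
    is clamped to the nearest level and flagged ``extrapolated``.
    """
    gc = observed.gc_fraction
    levels = curve.gc_levels
    extrapolated = bool(gc < levels[0] or gc > levels[-1])
    gc_clamped = float(min(max(gc, levels[0]), levels[-1]))
    medians = curve.median_density()
    null_median = float(np.interp(gc_clamped, levels, medians))
    hi = int(np.searchsorted(levels, gc_clamped))
    lo = max(hi - 1, 0)
    hi = min(hi, len(levels) - 1)
    pool = np.concatenate([curve.densities[lo], curve.densities[hi]])
    below = np.sum(pool < observed.pqs_density)
    equal = np.sum(pool == observed.pqs_density)
    percentile = 100.0 * (below + 0.5 * equal) / pool.size
    return NullComparison(
        deviation=observed.pqs_density - null_median,
        percentile=float(percentile),
        null_median=null_median,
        extrapolated=extrapolated,
    )


def write_null_curve(
    curve: NullCurve, tsv_path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Long-format TSV (gc, replicate, density, extra_track_fraction) plus a
    JSON metadata block recording the seed and simulation parameters."""
    with open(tsv_path, "w") as fh:
        fh.write("gc\treplicate\tdensity\textra_track_fraction\n")
        for i, gc in enumerate(curve.gc_levels):
            for r in range(curve.n_replicates):
                fh.write(
                    f"{gc:.3f}\t{r}\t{curve.densities[i, r]:.6g}\t"
                    f"{curve.extra_track_fractions[i, r]:.6g}\n"
                )
    if meta_path is not None:
        p = curve.scan_params
        meta = {
            "seed": curve.seed,
            "genome_length": curve.genome_length,
            "n_replicates": curve.n_replicates,
            "gc_levels": [round(float(g), 4) for g in curve.gc_levels],
            "scan_params": {
                "min_track_len": p.min_track_len,
                "min_tracks": p.min_tracks,
                "loop_min": p.loop_min,
                "loop_max": p.loop_max,
            },
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n")
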