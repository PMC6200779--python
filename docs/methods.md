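# Methods

## PQS model and scanner semantics

A potential G-quadruplex-forming sequence (PQS) is modelled as
`(G≥3 N1-12)≥3 G≥3`: at least `min_tracks` = 4 G tracks of at least
`min_track_len` = 3 guanines, separated by loops of `loop_min` = 1 to
`loop_max` = 12 arbitrary nucleotides (N bases included; N breaks a G track
but counts toward loop length). The textual pattern is ambiguous about
overlap and track-count maximality, so the scanner fixes a deterministic
convention (the Quadparser-family reading):

* a **G track is a maximal run** of ≥3 consecutive Gs — a run of seven Gs is
  one track of length 7, never split;
* consecutive qualifying runs whose gap lies in [1, 12] chain together
  greedily; a chain with ≥4 tracks is emitted as **one hit** spanning the
  first track's start to the last track's end, with *all* accumulated tracks
  counted (`n_tracks`), which makes the ">4 G tracks" statistic well
  defined; scanning resumes after the hit, so hits never overlap;
* both strands are scanned (the minus strand via reverse complement, with
  coordinates mapped back to the forward strand); a locus G-rich on one
  strand and its C-rich mirror elsewhere count as two hits;
* chromosomes are treated as linear; no wrap-around across a circular
  origin (costs at most one hit per replicon);
* no bulged or long-loop G4 variants — those are a different sequence class
  and out of scope.

PQS density is hits per Mbp with both strands pooled over **single-strand**
genome length; N bases count toward length but are excluded from both the
numerator and denominator of the GC fraction (this matches how public
assemblies report genome size). Coordinates are 0-based half-open
everywhere internally; GFF3's 1-based inclusive convention is converted
only at the parsing boundary.

An independent brute-force oracle (direct character-walk enumeration of
maximal runs and gaps, `tests/oracles.py`) encodes the same convention and
must agree exactly with the scanner on random sequences — this is a
regression guard on the convention itself, not just on the code.

## Random-genome null model

Null genomes are i.i.d. strings at a target GC with a **symmetric split**
(P(G)=P(C)=gc/2, P(A)=P(T)=(1−gc)/2) — the maximum-entropy choice, which
also makes the two strands statistically exchangeable. The null curve scans
replicate genomes over a GC grid (defaults: 20–80% in 2% steps, 10
replicates of 2 Mbp each) and is summarized box-plot style (median + IQR)
per level; every stochastic output records its seed, and each
(level, replicate) cell draws from an independent child stream of the master
seed. Observed genomes are compared to the curve by linear interpolation of
the median between the bracketing GC levels plus an empirical percentile
against the pooled replicate densities of those two levels; a GC outside
the grid is clamped and flagged as extrapolation rather than silently
extended.

The scanner's chain rule admits an **exact renewal computation** for i.i.d.
sequence, used as an independent cross-check: with per-base G probability
g, qualifying runs start at rate (1−g)g³ per base; the probability p_c that
the next qualifying run starts within 12 bases of a run end is computed by
exhaustive enumeration over the following 14 bases; chains are geometric in
p_c, so the expected hit rate per strand is (1−g)g³(1−p_c)p_c³ and the
expected fraction of hits with more than four tracks is p_c itself. At 40%
GC this gives p_c ≈ 0.0768, i.e. an expected extra-track fraction of
≈7.7% and a density of ≈6/Mbp; simulations must match the closed form
within 3× the replicate standard error. Note that at the 10 × 2 Mbp
simulation scale a 40% GC run yields only ~120 hits, so the measured
extra-track fraction carries a sampling standard error of ~2.4 percentage
points — single runs landing anywhere from ~5% to ~10% are expected
behaviour, not drift.

## TSS-relative profiling

Each PQS is represented by its **midpoint** (symmetric for hits on either
strand; whether start, end or midpoint is used is an arbitrary convention
and midpoint is the neutral one) and assigned to the closest TSS on its
contig. TSSs are approximated by the annotated gene's 5' end (bacterial
GFF3 files rarely carry explicit TSS features); `CDS` can be selected for
annotations lacking `gene` features. Distances are **gene-oriented**:
negative upstream of the gene, positive inside the transcription unit.
Exact ties between two TSSs are broken toward the gene for which the PQS is
downstream, then toward the lower TSS coordinate, then the smaller gene id
— fully deterministic regardless of input order.

A PQS is *coding-strand* iff its strand equals the gene's strand, else
*template-strand*; the coding and template binned vectors always sum to the
all-PQS vector. Distances are binned in 30 bp bins over a ±1500 bp window
(the window half-width is a display choice and configurable; 1500 bp keeps
~2–3 genes' context in a dense bacterial genome) and the binned vector is
normalized by the organism's **total** PQS count, not the in-window count,
so profiles are comparable between organisms with different PQS loads (the
vector then sums to ≤1).

The >4-track-near-TSS association is tested on the 2×2 table
{>4 tracks, ≤4 tracks} × {|distance| ≤ 100 bp, elsewhere} with a two-sided
Fisher exact test by default; chi-squared and two-proportion z alternatives
are selectable because the test behind published p-values of this kind is
often unnamed, and exact reproduction of any particular p-value should not
be expected. The sample odds ratio gets a Haldane 0.5 correction when a
cell is zero. The 100 bp "near" radius mirrors the −100..+100 bp window
used for promoter gene lists (unique gene ids with a qualifying PQS
midpoint in the window, optionally restricted to template- or coding-strand
hits, written one id per line for external GO tools — the enrichment
analysis itself is external).

## Classification

Organism profile vectors (rows of a profile matrix) are clustered with the
Ward minimum-variance criterion in the **`ward.D2` convention**: plain
Euclidean distances are handed to an algorithm that squares internally, so
merge heights stay on the distance scale (scipy's `linkage(X, "ward")` has
exactly these semantics; a hand-computed three-point case pins this down in
the tests). The merge order is deterministic for a fixed row order; on
exactly-equal merge distances the nearest-neighbor-chain order of the
underlying library is used as the tie-break. Trees export to Newick with
branch lengths = parent height − child height.

PCA is computed on column-mean-centered, **unscaled** vectors — the rows
are already normalized fractions on a common scale, so correlation-PCA
would only inflate empty bins. Components are oriented so the
largest-magnitude loading is positive (a deterministic sign convention);
a constant matrix is flagged degenerate with zero variance ratios rather
than producing NaNs. Concordance with taxon labels is measured by cutting
the dendrogram into k = #labels clusters and counting members whose
cluster's majority label (ties to the lexicographically smallest label)
differs from their own.

## Synthetic data generator

The generator emulates the statistical structure the survey assumes:
i.i.d. background at a chosen GC, genes on both strands, and PQS cassettes
either at a fixed gene-oriented TSS offset on a chosen strand class or
uniformly over the genome. Construction guarantees make truth exact:

* by default every G/C homopolymer in the background is capped below three
  bases (any base equal to its two predecessors is redrawn from A/T), so
  the background can contribute no PQS on either strand — planted-hit
  recall is exactly 1.0 and a zero-cassette genome scans to zero hits;
  the capping shifts realized GC slightly below target (~1–2%);
* each cassette is flanked by 15 nt A/T buffers (> the 12 nt maximal loop),
  so it can neither chain with background runs nor merge with a neighbour;
  cassette placement enforces pairwise separation and in-bounds buffers and
  fails loudly ("infeasible packing") otherwise;
* template/coding planting inserts the reverse complement or the G-rich
  string itself relative to the gene's strand; truth tables (BED6+3 +
  distance TSV) use the same dialect as the scanner, so recovery checks are
  value-exact.

Everything is deterministic per seed, byte-identical across runs. What the
generator does **not** emulate: operon structure, codon/coding bias, GC
isochores, repeat families, or realistic gene density — so passing tests
demonstrate correctness of the machinery on the assumed model, not
biological realism of any particular genome.

## Problem sizes and numerical choices

The test suite runs the null simulation at the published scale for the 40%
GC level (10 × 2 Mbp) because the scanner is fast enough to afford it; the
GC-monotonicity sweep uses a reduced 3 × 200 kb per-level preset, and
renewal-oracle agreement uses 8 × 200 kb at GC 0.6/0.7 with a 3-standard-
error tolerance. Scanner–oracle equivalence uses 200 random 10 kb
sequences across GC 0.3/0.5/0.7 with exact comparison. Degenerate inputs
are flagged rather than silently defaulted: zero-hit genomes (density and
extra-track fraction reported as 0 with a degenerate flag), all-N genomes
(GC undefined → error), all-zero contingency tables (error), constant PCA
matrices (degenerate flag).

## Known limitations

* Hit-level greediness means a locus with ≥5 tracks is one hit, never
  several overlapping 4-track windows; statistics are not comparable to
  scanners that emit overlapping windows.
* The TSS is the annotated gene 5' end; leader/UTR lengths and operon
  internal starts are ignored, so "promoter-proximal" is approximate for
  operonic genes.
* The null model has no dinucleotide or local-composition structure;
  genomes with strong GC skew or isochores will deviate from it for
  reasons unrelated to G4 biology.
* Bootstrap support on dendrograms is not computed.
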