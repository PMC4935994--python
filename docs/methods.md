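# Methods

This note records the models, algorithms and numerical choices behind
`satkit`, in the order a read set flows through the package.

## Quality filtering (`satkit.seqio`)

Read pairs are kept only when *both* mates would survive
Trimmomatic-style trimming unmodified at full length: leading/trailing
base quality ≥ 3, every sliding window of 4 bases with mean quality
≥ 20, and length ≥ `min_len` (default 100). The full-length-retention
rule keeps the read set at uniform length, which the overlap criterion
of the clustering stage assumes. Only Phred+33 FASTQ is accepted;
quality characters above Q42 trigger an explicit error naming the
record, since they indicate the legacy +64 encoding. Adapter-clipped
reads are simply dropped by the full-length rule; no adapter database is
consulted.

Sampling is uniform without replacement (`random.Random(seed).sample`),
deterministic per seed.

## Read-similarity graph (`satkit.clustering`)

Two reads are linked when their best alignment on either strand reaches
**90% identity over ≥ 0.55 of the shorter read** (the defaults of the
graph-clustering stage this emulates). Candidate pairs come from shared
canonical 13-mers; the alignment is evaluated on the seeded diagonal by
end-to-end edit distance of the implied overlap, which is exact for
substitution-type divergence and tolerant of occasional indels. Above
5 000 reads, k-mers are subsampled by a stable sequence hash (1 in 8):
selection depends on the k-mer string alone, so overlapping reads always
retain the same seeds; this bounds the quadratic pair enumeration inside
deep repeat bins. An `exact=True` mode runs full Smith–Waterman on every
pair and is used as the reference semantics in tests.

Cluster **density** is the mean number of links per read, 2E/V.
**Shape** is classified in this order: *ring* if the 2-core is a single
cycle covering ≥ 80% of nodes (checked first — an n-cycle also has
normalized diameter 0.5 and would otherwise be mislabelled linear);
*linear* if the estimated graph diameter (two-sweep BFS) is ≥ 0.5·V,
the signature of reads tiling single-copy sequence; otherwise
*globular*. Satellite candidates are globular or ring clusters with
density strictly above 0.1. Clusters of fewer than 10 reads are not
taken to consensus: below that depth, period calls and column majorities
are unreliable.

## Contig layout and consensus monomers (`satkit.tandem`)

Cluster reads are laid out on one coordinate system using the pairwise
offsets stored on graph edges (breadth-first placement); the contig is
the per-column majority, with zero-coverage columns written as N. Reads
from different monomer copies legitimately land on period-shifted
coordinates — harmless for consensus calling, because a tandem array is
invariant under period shifts, but it means a tandem contig typically
spans one period plus a read length rather than the full array. Two
consequences drive the period machinery:

* **Shift scan.** The smallest period *p* with gapless self-match
  identity ≥ 70% between `contig[p:]` and `contig[:-p]` is reported;
  shifts are scanned as long as ≥ 30 bp of self-overlap remain, so a
  period can be called from less than two full copies. Matching is
  deliberately gapless: a gapped comparison lets *any* small shift
  resynchronise on a true tandem and destroys the smallest-period
  property. N positions never count as matches.
* **Layout back-edges.** Graph edges whose implied placement disagrees
  with the assigned coordinate have discrepancies that are exact
  multiples of the period. The smallest discrepancy ≥ 20 bp seen at
  least 3 times is used when the shift scan fails (long monomers).

Before consensus calling the contig is trimmed to its **periodic core**
(the longest run where the smoothed shift-*p* self-match stays ≥ 0.6,
plus one trailing period): assembled contigs often carry single-copy
flanking sequence, and flank windows must not vote against array
windows. The core is split into period-length windows from position 0;
the consensus is the per-column majority (ties in the fixed order
A < C < G < T; columns > 50% gap dropped; mixed-length monomers are
first projected onto a reference of median length). The result is
reported in **canonical rotation**: the lexicographically smallest
string over all rotations of the monomer and of its reverse complement,
so independent discoveries of one satellite compare equal regardless of
phase or strand. A+T content is computed on the consensus with N
excluded from the denominator.

## The mining loop (`satkit.mining`)

Per iteration: filter the remaining pool against everything known, then
sample the scheduled number of pairs (fresh reads each round), cluster,
and take each candidate cluster's contigs to consensus. A consensus is a
*new* family only if its rotation/strand-maximised identity to every
known satellite is ≤ 95% (above that it is a variant of a known
family). Candidate clusters whose contigs show no tandem structure go
into the custom repeat database and are subtracted like satellites —
this is what keeps later, deeper rounds from re-discovering abundant
non-satellite repeats. The loop stops when an iteration adds zero new
satellites; exhausting the schedule first sets a warning flag.

Filter references are **concatenated monomers**: at least two copies,
extended until the reference strictly exceeds 200 bp, so reads spanning
the monomer junction still align end-to-end. A mate matches when its
full length — or its leading or trailing `min_coverage` fraction
(default 0.9) — aligns to a reference infix at ≥ 90% identity; a read at
a uniform 85% identity is retained.

## Quantification (`satkit.quantify`)

Reads are Smith–Waterman aligned (match 1, mismatch −1, gap open −3,
extend −2) to the concatenated-monomer library on both strands,
candidates prefiltered by shared 13-mers. Hits shorter than 25 aligned
nt or below 65% identity are discarded; per read, best-scoring hits are
kept greedily, discarding hits overlapping an accepted one by more than
half their length. Transitions are A↔G and C↔T; gap columns are excluded
from P, Q and aligned nucleotides. Hits outside the K2P domain
(1−2P−Q ≤ 0 or 1−2Q ≤ 0) are flagged saturated, excluded from weighted
means, and placed in the landscape overflow bin so that bin sums still
reproduce abundance exactly.

Assembly scanning finds seed regions per reference (adaptive seed size,
`min(13, monomer)`, floored at 6 so microsatellite-scale motifs are
findable), aligns each region against a tandem extension of the monomer,
trims alignment ends to the first/last run of 8 consecutive matches
(removing flank dragged in by region padding), and requires ≥ 65%
identity computed over *all* alignment columns — gap-inclusive, which
keeps heavily gapped chance alignments of unrelated sequence out.
MNRPC is the floor of aligned nt over monomer length, maximised over
contigs; the per-family contig count uses a 200-bp aligned floor.

## Null genomes (`satkit.randgen`)

The dinucleotide-preserving shuffle is the Euler-path construction:
random last-edge assignment per vertex, retried until the last edges
form an arborescence into the final base (cheap on a 4-vertex graph),
then a random Eulerian walk. Length, mononucleotide and all 16
dinucleotide counts, and the first and last base are conserved exactly.
N runs split the input and each segment shuffles independently, per
contig — so contig-count semantics of the chance-occurrence score are
preserved. The chance-occurrence experiment shuffles every contig per
replicate and scans the result against the library; defaults are
desk-scale (megabase genomes, a handful of replicates), with scale as
configuration.

## Classification thresholds (`satkit.catalog`)

Grouping is single-linkage at every tier — the only closure that makes
the result independent of input order. Thresholds are strict
inequalities (> 95, > 80), configurable. Variant merges keep the most
abundant representative and pool abundance. Superfamily linking demands
a local alignment of ≥ 50 bp at ≥ 60% identity under stiff gap costs
(open −4, extend −2): with lax gaps, maximal local alignments between
*unrelated* ~200-bp monomers reach that floor roughly a third of the
time (measured on random pairs), which would wire spurious
superfamilies; under the stiff costs the false-link rate on random pairs
drops below 2% while ancestor-derived pairs at ~75% identity always
link. The query is doubled so rotated matches spanning the monomer
junction are found.

MST edges between variants are weighted by substitutions plus indel
*events* (a contiguous gap run counts once; the per-gap-column
alternative sits behind `indel_mode="positions"`). Event counting uses
an affine-gap global alignment (open −4, extend −0.5): unit-cost
edit-distance paths may split one multi-base indel across several runs
and inflate the event count. Naming ties break deterministically: larger
monomer first, then lexicographic consensus.

## Annotation statistics (`satkit.satstats`)

The packaged table is the 62-family locust satellitome (12 chromosome
pairs; location tokens p/i/d/t per chromosome; patterns c/nc/m). The
working set for statistics excludes the telomeric repeat (known
function) and three families not confirmed by PCR, leaving 58; the
exclusions are data in the table (`in_working_set`), not code.

* The location census counts each p/i/d token over clustered and mixed
  families, telomeric repeat excluded.
* The **length gap** is the largest difference between consecutive
  distinct monomer lengths *that splits the families into two groups of
  ≥ 2* (`min_group=2`). Without the group-size floor the statistic
  degenerates to whatever gap isolates the single longest family
  (here 299→400 bp) and says nothing about bimodality.
* The abundance–contig Spearman correlation defaults to the
  Northern-lineage abundance column with missing values as zero,
  because the contig counts come from the Northern-lineage draft
  assembly; the column is a parameter.
* Mann–Whitney U is reported as min(U₁, U₂) with half credit for ties;
  clustered means pattern c or m, non-clustered nc.
* Chromosome-specific families are clustered/mixed families whose
  location tokens fall on exactly one chromosome.

Spearman and Mann–Whitney delegate to `scipy.stats`; the test suite
checks both against independent brute-force implementations (explicit
average ranks, explicit pair counting) on hundreds of random vectors.

## Synthetic data (`satkit.simdata`)

The generator embodies the array-size model of satellite organisation:
*clustered* families sit in a few large arrays (≥ 1.5 kb, the FISH
visibility scale), *scattered* families in many arrays below 1.5 kb,
*mixed* in both. Copy counts are integers chosen to track the target
genome proportion (realized proportions are exact accounting of planted
intervals and are the reference for recovery tests). Each copy is
independently substituted at the per-copy divergence rate; indels are
off by default to keep truth accounting exact (a flag adds them at a
configurable rate). Reads use truncated-normal inserts (default
226 ± 81 bp, floored at the read length), both strands, uniform
substitution errors (default 0.5%, a typical post-QC Illumina rate) and
qualities consistent with that rate. What the simulator does *not*
model: indel sequencing errors, quality-by-cycle profiles, GC bias,
adapter read-through and transposable elements — so passing recovery
tests demonstrate algorithmic correctness under the stated repeat
model, not robustness to every artefact of real libraries.

## Study conditions used by the tests and the acceptance script

* **Mining sensitivity.** 1-Mb genome; abundant family 1% (193-bp
  monomer, three clustered loci, 2% per-copy divergence); rare family
  0.02% (20-bp monomer, one 200-bp array, 1% divergence). Pool of
  80 000 pairs (~16× nucleotide coverage) with schedule
  4 000 / 70 000 / 70 000: a 200-bp locus yields only ~0.19
  array-dominated reads per 1 000 sampled mates, so the deep round must
  see most of the pool for the rare cluster to clear the 10-read
  consensus floor (expected ~30 reads). The first round is kept shallow
  (0.8× coverage), matching the protocol's shallow initial run; the
  single-run control uses that first round alone and recovers only the
  abundant family.
* **Quantification recovery.** 1-Mb genome with planted proportions 5%,
  1% and 0.1% (per-copy divergences 5%, 2%, 1%); 200 000 read pairs at
  0.5% error. At this depth the 0.1% family receives enough fragments
  that sampling noise sits well inside the 20% relative-error check;
  the 5%-divergence family's landscape peaks in the 4–6% bins
  (K2P of 5% substitutions plus read error ≈ 5.7%).

## Known limitations

* The read graph sees overlaps only up to read length; arrays of
  monomers much longer than the read cannot be phased into full-length
  copies (the consensus is still correct, recovered via period hints).
* Very diverged families (per-copy divergence near the 90% edge
  identity) fragment into multiple clusters and may be catalogued as
  separate variants.
* Greedy non-overlapping hit selection can misassign reads in regions
  where two families' references overlap substantially (they would be
  variants or superfamily partners anyway).
* The shift-scan period detector reports the smallest qualifying
  period; nested or higher-order repeat structure is out of scope.
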