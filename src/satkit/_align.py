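"""Shared low-level alignment helpers.

Thin wrappers around edlib (fast edit-distance alignment with CIGAR
recovery) and Bio.Align (Smith-Waterman local alignment), plus the
canonical k-mer machinery used to prefilter all-vs-all comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio.Align import PairwiseAligner

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AlignmentStats:
    """Column-level summary of a pairwise alignment."""

    columns: int
    matches: int
    substitutions: int
    indel_events: int
    indel_nt: int
    transitions: int
    transversions: int

    @property
    def identity(self) -> float:
        """Percent identity: matches / alignment columns * 100."""
        return 100.0 * self.matches / self.columns if self.columns else 0.0


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def stats_from_pairs(pairs) -> AlignmentStats:
    """Summarise an alignment given as (query_char, target_char) columns.

    Gap columns are encoded with '-' on one side; runs of gaps on the same
    side count as a single indel event.
    """
    columns = matches = subs = events = indel_nt = ti = tv = 0
    prev_gap = None  # 'q' or 't' while inside a gap run
    for a, b in pairs:
        columns += 1
        if a == "-" or b == "-":
            side = "q" if a == "-" else "t"
            if side != prev_gap:
                events += 1
            indel_nt += 1
            prev_gap = side
            continue
        prev_gap = None
        if a == b:
            matches += 1
        else:
            subs += 1
            if (a, b) in _TRANSITIONS:
                ti += 1
            else:
                tv += 1
    return AlignmentStats(columns, matches, subs, events, indel_nt, ti, tv)


def edlib_pairs(query: str, target: str, mode: str = "NW"):
    """Align with edlib and return the aligned column pairs."""
    res = edlib.align(query, target, mode=mode, task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    return list(zip(nice["query_aligned"], nice["target_aligned"]))


def global_stats(query: str, target: str) -> AlignmentStats:
    """End-to-end (Needleman-Wunsch style, edit-distance) alignment stats."""
    return stats_from_pairs(edlib_pairs(query, target, mode="NW"))


def edlib_distance(query: str, target: str, mode: str = "NW", k: int = -1) -> int:
    """Edit distance; -1 if it exceeds the cap ``k``."""
    return edlib.align(query, target, mode=mode, task="distance", k=k)["editDistance"]


def infix_identity(query: str, target: str) -> float:
    """Percent identity of the full query aligned to the best infix of target."""
    d = edlib_distance(query, target, mode="HW")
    if d < 0:
        return 0.0
    return 100.0 * (len(query) - d) / len(query)


def rotations(seq: str):
    for i in range(len(seq)):
        yield seq[i:] + seq[:i]


def rotation_strand_identity(a: str, b: str, with_stats: bool = False):
    """Best global identity between monomers, maximised over all rotations
    of ``a`` and both strands.

    Rotation/strand invariance makes the measure well defined for tandem
    repeat units, which have no natural phase or orientation. A cheap
    infix prescreen (``a`` against the doubled ``b``) skips the exhaustive
    rotation scan for clearly unrelated pairs.
    """
    targets = (b, revcomp(b))
    # Upper bound per strand: full `a` against the best infix of the doubled
    # target is at least as good as any rotation aligned end-to-end.
    bounds = []
    for target in targets:
        d = edlib_distance(a, target + target, mode="HW")
        bounds.append(100.0 * (len(a) - d) / max(len(a), len(b)))
    if max(bounds) < 55.0 and not with_stats:
        # Clearly unrelated: the bound itself is below every classification
        # threshold, so the exhaustive rotation scan is unnecessary.
        return max(bounds)
    best = -1.0
    best_pair = (a, b)
    for target, bound in zip(targets, bounds):
        if bound <= best:
            continue
        for rot in rotations(a):
            dist = edlib_distance(rot, target)
            cols = max(len(rot), len(target))  # lower bound on columns
            ident = 100.0 * (cols - dist) / cols
            if ident > best:
                best, best_pair = ident, (rot, target)
    if with_stats:
        st = global_affine_stats(*best_pair)
        return st.identity, st
    return best


_AFFINE_GLOBAL = None


def global_affine_stats(query: str, target: str) -> AlignmentStats:
    """Global alignment stats under affine gap costs.

    Cheap gap extension keeps multi-base indels in one contiguous run, so
    indel EVENTS are counted the way a biologist reads an alignment
    (edlib's unit-cost paths may split a single event across runs).
    """
    global _AFFINE_GLOBAL
    if _AFFINE_GLOBAL is None:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = -2.0
        aligner.open_gap_score = -4.0
        aligner.extend_gap_score = -0.5
        _AFFINE_GLOBAL = aligner
    aln = _AFFINE_GLOBAL.align(query, target)[0]
    qblocks, tblocks = aln.aligned
    pairs = []
    prev_q = prev_t = 0
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        for i in range(prev_q, qs):
            pairs.append((query[i], "-"))
        for i in range(prev_t, ts):
            pairs.append(("-", target[i]))
        for i in range(qe - qs):
            pairs.append((query[qs + i], target[ts + i]))
        prev_q, prev_t = qe, te
    for i in range(prev_q, len(query)):
        pairs.append((query[i], "-"))
    for i in range(prev_t, len(target)):
        pairs.append(("-", target[i]))
    return stats_from_pairs(pairs)


def make_local_aligner(match: float = 1.0, mismatch: float = -1.0,
                       gap_open: float = -2.0, gap_extend: float = -2.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def local_alignment_pairs(aligner: PairwiseAligner, query: str, target: str):
    """Best local alignment as column pairs plus the aligned spans.

    Returns (pairs, q_start, q_end, t_start, score) or None when nothing
    aligns.
    """
    try:
        alns = aligner.align(query, target)
        if len(alns) == 0:
            return None
        aln = alns[0]
    except (ValueError, OverflowError, MemoryError):
        return None
    # aligned = (blocks of the first sequence passed, blocks of the second)
    qblocks, tblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    pairs = []
    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        if prev_q is not None:
            for i in range(prev_q, qs):
                pairs.append((query[i], "-"))
            for i in range(prev_t, ts):
                pairs.append(("-", target[i]))
        for i in range(qe - qs):
            pairs.append((query[qs + i], target[ts + i]))
        prev_q, prev_t = qe, te
    q_start = int(qblocks[0][0])
    q_end = int(qblocks[-1][1])
    t_start = int(tblocks[0][0])
    return pairs, q_start, q_end, t_start, float(aln.score)


# ---------------------------------------------------------------------------
# canonical k-mer indexing

def canonical_kmers(seq: str, k: int):
    """Yield (canonical_kmer, position, is_forward) over ``seq``.

    ``is_forward`` is True when the forward k-mer is the canonical one.
    Ambiguous (non-ACGT) k-mers are skipped.
    """
    n = len(seq)
    rc = revcomp(seq)
    for i in range(n - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        rkmer = rc[n - k - i:n - i]
        if kmer <= rkmer:
            yield kmer, i, True
        else:
            yield rkmer, i, False


class KmerIndex:
    """Canonical k-mer index over a collection of named sequences."""

    def __init__(self, k: int = 13):
        self.k = k
        self.bins: dict[str, list[tuple]] = {}
        self.lengths: dict = {}

    def add(self, name, seq: str) -> None:
        self.lengths[name] = len(seq)
        bins = self.bins
        for kmer, pos, fwd in canonical_kmers(seq, self.k):
            bins.setdefault(kmer, []).append((name, pos, fwd))

    def candidates(self, seq: str):
        """Names of indexed sequences sharing at least one canonical k-mer."""
        hits = set()
        bins = self.bins
        for kmer, _pos, _fwd in canonical_kmers(seq, self.k):
            entries = bins.get(kmer)
            if entries:
                for name, _p, _f in entries:
                    hits.add(name)
        return hits
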