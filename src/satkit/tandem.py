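"""Cluster assembly, tandem-period detection and consensus monomer calling.

A repeat cluster's reads are laid out on a common coordinate system using
the pairwise offsets recorded on the read-graph edges (reads from
different monomer copies may land on period-shifted coordinates; this is
harmless for consensus calling because a tandem array is invariant under
period shifts). The contig is the per-column majority over the layout.
Tandem periodicity is the smallest shift under which the contig matches
itself, and the consensus monomer is the column majority over the split
monomers, reported in a canonical rotation/strand so that independent
discoveries of the same satellite compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._align import edlib_pairs, revcomp

MIN_PERIOD_CONTIG = 30
PERIOD_IDENTITY = 0.70

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass
class ConsensusMonomer:
    """Canonical-rotation consensus repeat unit."""

    seq: str
    length: int
    at_content: float

    @classmethod
    def from_seq(cls, seq: str) -> "ConsensusMonomer":
        seq = canonical_rotation(seq)
        return cls(seq, len(seq), at_content(seq))


@dataclass
class TandemContig:
    seq: str
    period: int | None
    n_full_monomers: int
    remainder: int


@dataclass
class AssembledContig:
    seq: str
    coverage: np.ndarray
    n_reads: int
    # tandem-period evidence from layout back-edges: when an edge's implied
    # placement of an already-placed read disagrees with its assigned
    # coordinate, the discrepancy is a multiple of the repeat period
    period_hints: dict = None

    def hinted_period(self, min_period: int = 20, min_count: int = 3) -> int | None:
        """Smallest well-supported back-edge discrepancy, if any."""
        if not self.period_hints:
            return None
        supported = [p for p, c in self.period_hints.items()
                     if p >= min_period and c >= min_count]
        return min(supported) if supported else None


def at_content(seq: str) -> float:
    """Percent A+T; N bases are excluded from the denominator."""
    acgt = sum(seq.count(b) for b in _BASES)
    if acgt == 0:
        return 0.0
    return 100.0 * (seq.count("A") + seq.count("T")) / acgt


def canonical_rotation(monomer: str) -> str:
    """Lexicographically smallest rotation over both strands."""
    if not monomer:
        raise ValueError("empty monomer")
    rc = revcomp(monomer)
    best = min(monomer[i:] + monomer[:i] for i in range(len(monomer)))
    best_rc = min(rc[i:] + rc[:i] for i in range(len(rc)))
    return min(best, best_rc)


# ---------------------------------------------------------------------------
# layout assembly

def _place_neighbour(cu, ou, Lu, Lv, d, same, first_is_u):
    """Coordinates of read v given placed read u and one graph edge."""
    if first_is_u:
        if ou:  # u laid forward
            return cu + d, same
        return cu + Lu - d - Lv, not same
    if ou:
        if same:
            return cu - d, True
        return cu - (Lv - d - Lu), False
    if same:
        return cu - (Lv - d - Lu), False
    return cu - d, True


def _layout_component(reads: dict, sub: nx.Graph, members) -> AssembledContig:
    placement = {}
    seed = members[0]
    placement[seed] = (0, True)
    stack = [seed]
    while stack:
        u = stack.pop()
        cu, ou = placement[u]
        for v in sub.neighbors(u):
            if v in placement:
                continue
            e = sub.edges[u, v]
            first_is_u = e.get("first", u) == u
            cv, ov = _place_neighbour(cu, ou, len(reads[u]), len(reads[v]),
                                      e["offset"], e["same_strand"], first_is_u)
            placement[v] = (cv, ov)
            stack.append(v)
    # back-edge discrepancies: multiples of the tandem period
    hints: dict = {}
    for u, v in sub.edges:
        if u not in placement or v not in placement:
            continue
        e = sub.edges[u, v]
        cu, ou = placement[u]
        first_is_u = e.get("first", u) == u
        cv_implied, ov_implied = _place_neighbour(
            cu, ou, len(reads[u]), len(reads[v]),
            e["offset"], e["same_strand"], first_is_u)
        cv, ov = placement[v]
        if ov_implied != ov:
            continue
        delta = abs(cv_implied - cv)
        if delta:
            hints[delta] = hints.get(delta, 0) + 1

    lo = min(c for c, _o in placement.values())
    hi = max(c + len(reads[r]) for r, (c, _o) in placement.items())
    counts = np.zeros((hi - lo, 4), dtype=np.int32)
    for r, (c, o) in placement.items():
        seq = reads[r] if o else revcomp(reads[r])
        idx = np.frombuffer(seq.encode(), dtype=np.uint8)
        code = np.full(idx.shape, -1, dtype=np.int8)
        for b, i in _BASE_INDEX.items():
            code[idx == ord(b)] = i
        valid = code >= 0
        pos = np.arange(c - lo, c - lo + len(seq))[valid]
        counts[pos, code[valid]] += 1
    coverage = counts.sum(axis=1)
    cons = np.frombuffer(_BASES.encode(), dtype=np.uint8)[counts.argmax(axis=1)]
    cons = cons.tobytes().decode()
    # argmax on an all-zero row yields 'A'; mask zero-coverage columns as N
    if (coverage == 0).any():
        cons = "".join("N" if cov == 0 else b for b, cov in zip(cons, coverage))
    return AssembledContig(cons, coverage, len(placement), hints)


def assemble_cluster(reads: dict, graph: nx.Graph | None = None) -> list:
    """Greedy layout assembly of a cluster's reads into consensus contigs.

    ``graph`` is the read-similarity (sub)graph carrying edge offsets; when
    absent it is rebuilt from the reads. Contigs are returned richest
    first (by number of contributing reads).
    """
    if not reads:
        raise ValueError("empty cluster")
    if len(reads) == 1:
        seq = next(iter(reads.values()))
        return [AssembledContig(seq, np.ones(len(seq), dtype=np.int32), 1)]
    if graph is None:
        from .clustering import build_read_graph
        graph = build_read_graph(reads, exact=len(reads) <= 30).graph
    sub = graph.subgraph(reads)
    contigs = []
    for comp in nx.connected_components(sub):
        members = sorted(comp, key=str)
        if len(members) == 1:
            r = members[0]
            contigs.append(AssembledContig(
                reads[r], np.ones(len(reads[r]), dtype=np.int32), 1))
        else:
            contigs.append(_layout_component(reads, sub, members))
    contigs.sort(key=lambda c: (-c.n_reads, -len(c.seq)))
    return contigs


def assemble_cluster_contig(reads: dict, graph: nx.Graph | None = None) -> list:
    """Contig sequences only, ordered by read coverage (richest first)."""
    return [c.seq for c in assemble_cluster(reads, graph)]


# ---------------------------------------------------------------------------
# periodicity

def detect_tandem_period(contig: str, min_identity: float = PERIOD_IDENTITY,
                         max_period: int | None = None,
                         min_overlap: int = 30) -> int | None:
    """Smallest tandem period of a contig, or None.

    A shift ``p`` qualifies when contig[p:] matches contig[:-p] at
    ``min_identity`` over the overlap; shifts are scanned up to the point
    where at least ``min_overlap`` bp of self-overlap remain, so a period
    can be called even when the contig holds less than two full copies
    (read-layout contigs of a tandem typically span one period plus a
    read length, because reads from different copies stack modulo the
    period). The scan compares positions directly -- a gapless
    self-match, which is what keeps the smallest-period property: a
    gapped alignment would let any small shift resynchronise on a true
    tandem. N positions never count as matches.
    """
    n = len(contig)
    if n < MIN_PERIOD_CONTIG:
        raise ValueError(f"contig of {n} bp is too short for period detection")
    arr = np.frombuffer(contig.encode(), dtype=np.uint8)
    not_n = arr != ord("N")
    limit = min(max_period or n - min_overlap, n - min_overlap)
    for p in range(2, limit + 1):
        hits = (arr[p:] == arr[:-p]) & not_n[p:]
        if float(np.mean(hits)) >= min_identity:
            return p
    return None


def periodic_core(contig: str, period: int, min_identity: float = 0.6,
                  smooth: int | None = None) -> str:
    """The maximal region of the contig that is actually periodic.

    Assembled contigs often carry single-copy flanking sequence around a
    tandem array; consensus calling must not vote flank windows against
    array windows. Positions are scored by agreement with the base one
    period away, smoothed over ``smooth`` bp (default ``2 * period``,
    at least 20); the longest run above ``min_identity`` plus one
    trailing period is the core. Falls back to the whole contig when no
    run qualifies or the self-overlap is too short to score.
    """
    n = len(contig)
    if period < 2 or n - period < 10:
        return contig
    arr = np.frombuffer(contig.encode(), dtype=np.uint8)
    m = ((arr[period:] == arr[:-period]) & (arr[period:] != ord("N"))).astype(float)
    w = min(max(smooth or 2 * period, 20), len(m))
    kernel = np.ones(w) / w
    avg = np.convolve(m, kernel, mode="same")
    good = avg >= min_identity
    if not good.any():
        return contig
    # longest run of good positions
    best_len = cur_len = 0
    best_end = 0
    for i, g in enumerate(good):
        cur_len = cur_len + 1 if g else 0
        if cur_len > best_len:
            best_len, best_end = cur_len, i + 1
    start = best_end - best_len
    end = min(n, best_end + period)
    if best_len < period // 2 and best_len < 20:
        return contig
    return contig[start:end]


def split_into_monomers(contig: str, period: int) -> tuple[list, str]:
    """Non-overlapping windows of ``period`` bp from position 0.

    Returns (monomers, remainder); the terminal remainder (< period bp) is
    reported separately. Fewer than two full monomers is an error.
    """
    if period < 2:
        raise ValueError("period must be >= 2")
    n_full = len(contig) // period
    if n_full < 2:
        raise ValueError(
            f"contig of {len(contig)} bp holds fewer than two {period} bp monomers")
    monomers = [contig[i * period:(i + 1) * period] for i in range(n_full)]
    return monomers, contig[n_full * period:]


def characterize_contig(contig: str, **kwargs) -> TandemContig:
    period = detect_tandem_period(contig, **kwargs)
    if period is None:
        return TandemContig(contig, None, 0, 0)
    monomers, remainder = split_into_monomers(contig, period)
    return TandemContig(contig, period, len(monomers), len(remainder))


# ---------------------------------------------------------------------------
# consensus

def _project_onto_reference(ref: str, other: str) -> str:
    """``other`` written in ``ref`` coordinates: deletions become gaps,
    insertions relative to the reference are dropped."""
    out = []
    for q, t in edlib_pairs(other, ref):
        if t == "-":
            continue  # insertion in `other`
        out.append("-" if q == "-" else q)
    return "".join(out)


def consensus_monomer(monomers: list) -> ConsensusMonomer:
    """Majority-rule consensus of aligned monomers, canonicalized.

    Same-length monomers vote column by column; mixed lengths are aligned
    to a reference monomer of median length first. Columns that are gaps
    in more than half of the rows are dropped; base ties break in the
    fixed order A < C < G < T.
    """
    if not monomers:
        raise ValueError("no monomers supplied")
    if len(monomers) == 1:
        return ConsensusMonomer.from_seq(monomers[0])
    lengths = {len(m) for m in monomers}
    if len(lengths) == 1:
        rows = monomers
    else:
        by_len = sorted(monomers, key=lambda m: (len(m), m))
        ref = by_len[len(by_len) // 2]
        rows = [m if len(m) == len(ref) else _project_onto_reference(ref, m)
                for m in monomers]
        rows = [r if len(r) == len(ref) else r.ljust(len(ref), "-") for r in rows]
    n = len(rows)
    width = len(rows[0])
    out = []
    for col in range(width):
        column = [r[col] for r in rows]
        gaps = column.count("-")
        if 2 * gaps > n:
            continue
        counts = [(column.count(b), -i) for i, b in enumerate(_BASES)]
        best = max(range(4), key=lambda i: counts[i])
        if counts[best][0] == 0:
            continue  # all-N or all-gap column
        out.append(_BASES[best])
    if not out:
        raise ValueError("consensus is empty")
    return ConsensusMonomer.from_seq("".join(out))
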